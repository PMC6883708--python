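"""Exact tests against independent enumeration oracles."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sltop.enrichment import (
    chisq_with_residuals,
    class_contingency,
    fisher_exact_2x2,
    go_overrepresentation,
    welch_t,
)


# ---------------------------------------------------------------------------
# Fisher exact
# ---------------------------------------------------------------------------


def fisher_oracle(a, b, c, d) -> Fraction:
    """Independent enumeration: multiply out every table with the observed
    margins and sum the probability mass <= that of the observed table."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    total = Fraction(0)
    num = Fraction(0)
    p_obs = Fraction(comb(row1, a) * comb(n - row1, col1 - a))
    for x in range(0, col1 + 1):
        if x > row1 or col1 - x > n - row1:
            continue
        w = Fraction(comb(row1, x) * comb(n - row1, col1 - x))
        total += w
        if w <= p_obs:
            num += w
    return num / total


def test_fisher_derived_examples():
    assert fisher_exact_2x2([[2, 0], [0, 2]]).p == pytest.approx(1 / 3, rel=1e-12)
    assert fisher_exact_2x2([[5, 5], [5, 5]]).p == pytest.approx(1.0)
    assert fisher_exact_2x2([[10, 2], [3, 15]]).odds_ratio == pytest.approx(25.0)


def test_fisher_zero_cell_odds_ratio_sentinels():
    r = fisher_exact_2x2([[5, 0], [0, 5]])
    assert r.odds_ratio == float("inf")
    assert r.odds_ratio_haldane == pytest.approx((5.5 * 5.5) / (0.5 * 0.5))
    assert fisher_exact_2x2([[0, 5], [5, 0]]).odds_ratio == 0.0


def test_fisher_all_zero_rejected():
    with pytest.raises(ValueError):
        fisher_exact_2x2([[0, 0], [0, 0]])


def test_fisher_matches_enumeration_small_tables():
    """Exhaustive sweep of all 2x2 tables with total <= 18 against the
    Fraction oracle (the total <= 40 sweep runs in the acceptance suite)."""
    for n in range(1, 19):
        for a in range(n + 1):
            for b in range(n - a + 1):
                for c in range(n - a - b + 1):
                    d = n - a - b - c
                    got = fisher_exact_2x2([[a, b], [c, d]]).p
                    want = float(fisher_oracle(a, b, c, d))
                    assert got == pytest.approx(want, rel=1e-12, abs=1e-15), (a, b, c, d)


@pytest.mark.parametrize("seed", [0])
def test_fisher_matches_scipy_on_random_tables(seed):
    rng = np.random.default_rng(seed)
    for _ in range(200):
        t = rng.integers(0, 60, size=(2, 2))
        if t.sum() == 0:
            continue
        ours = fisher_exact_2x2(t.tolist()).p
        ref = stats.fisher_exact(t, alternative="two-sided")[1]
        assert ours == pytest.approx(ref, rel=1e-7, abs=1e-12)


# ---------------------------------------------------------------------------
# chi-square with residuals
# ---------------------------------------------------------------------------


def test_chisq_uniform_table_zero_statistic():
    r = chisq_with_residuals([[10, 10], [10, 10]])
    assert r.statistic == 0.0
    np.testing.assert_allclose(r.pearson_residuals, 0.0)


def test_chisq_closed_form_2x2():
    r = chisq_with_residuals([[20, 10], [10, 20]])
    assert r.statistic == pytest.approx(20 / 3, rel=1e-12)
    assert r.df == 1
    assert r.pearson_residuals[0, 0] == pytest.approx(5 / np.sqrt(15), rel=1e-12)
    assert r.p == pytest.approx(float(stats.chi2.sf(20 / 3, 1)), rel=1e-12)


def test_chisq_df_and_transposition_invariance():
    t = [[5, 7, 9], [4, 4, 4], [9, 2, 1]]
    r = chisq_with_residuals(t)
    rt = chisq_with_residuals(np.asarray(t).T.tolist())
    assert r.df == 4
    assert r.statistic == pytest.approx(rt.statistic, rel=1e-12)
    np.testing.assert_allclose(r.pearson_residuals, rt.pearson_residuals.T)


def test_chisq_zero_margin_rejected():
    with pytest.raises(ValueError, match="margin"):
        chisq_with_residuals([[0, 0], [5, 5]])


def test_chisq_residual_margins_near_zero():
    """Residuals weighted by sqrt(expected) sum to ~0 along each margin."""
    t = np.array([[30, 5, 12], [8, 19, 6]])
    r = chisq_with_residuals(t.tolist())
    e = np.outer(t.sum(1), t.sum(0)) / t.sum()
    np.testing.assert_allclose((r.pearson_residuals * np.sqrt(e)).sum(axis=0), 0.0, atol=1e-9)
    np.testing.assert_allclose((r.pearson_residuals * np.sqrt(e)).sum(axis=1), 0.0, atol=1e-9)


# ---------------------------------------------------------------------------
# Welch t
# ---------------------------------------------------------------------------


def test_welch_closed_form():
    t, df, p = welch_t([1, 2, 3], [4, 5, 6])
    assert t == pytest.approx(-3 / np.sqrt(2 / 3), rel=1e-12)
    assert df == pytest.approx(4.0, rel=1e-12)
    t2, df2, p2 = welch_t([4, 5, 6], [1, 2, 3])
    assert t2 == pytest.approx(-t)
    assert p2 == pytest.approx(p)


def test_welch_identical_samples():
    t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert t == 0.0
    assert p == pytest.approx(1.0)


def test_welch_degenerate_rejected():
    with pytest.raises(ValueError):
        welch_t([1.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        welch_t([2.0, 2.0], [3.0, 3.0])


# ---------------------------------------------------------------------------
# GO over-representation
# ---------------------------------------------------------------------------


def test_go_single_term_tail():
    universe = [f"g{i}" for i in range(10)]
    selected = universe[:5]
    ann = {g: {"T"} for g in universe[:5]}
    (res,) = go_overrepresentation(selected, universe, ann)
    assert res.p_hyper == pytest.approx(1 / comb(10, 5), rel=1e-9)  # 1/252


def test_go_term_covering_universe_and_zero_k_omitted():
    universe = [f"g{i}" for i in range(8)]
    ann = {g: {"ALL"} for g in universe}
    ann["g0"].add("UNSELECTED")
    (res,) = go_overrepresentation(universe[1:4], universe, ann)
    assert res.term == "ALL"
    assert res.p_hyper == pytest.approx(1.0)


def test_go_selected_outside_universe_rejected():
    with pytest.raises(ValueError):
        go_overrepresentation(["x"], ["a", "b"], {})


def go_oracle(selected, universe, term_genes) -> Fraction:
    """Brute-force draw enumeration: over all C(N, n) selections, the
    fraction annotating at least the observed count."""
    uni = sorted(universe)
    k_obs = len(set(selected) & term_genes)
    n = len(selected)
    hits = 0
    total = 0
    for sel in itertools.combinations(uni, n):
        total += 1
        if len(set(sel) & term_genes) >= k_obs:
            hits += 1
    return Fraction(hits, total)


@pytest.mark.parametrize("seed, N, n", [(1, 10, 4), (2, 12, 5), (3, 14, 6)])
def test_go_matches_enumeration_oracle(seed, N, n):
    rng = np.random.default_rng(seed)
    universe = [f"g{i}" for i in range(N)]
    term_genes = set(rng.choice(universe, size=N // 3, replace=False))
    ann = {g: {"T"} for g in term_genes}
    selected = list(rng.choice(universe, size=n, replace=False))
    res = go_overrepresentation(selected, universe, ann)
    if not res:
        assert len(set(selected) & term_genes) == 0
        return
    want = float(go_oracle(selected, universe, term_genes))
    assert res[0].p_hyper == pytest.approx(want, rel=1e-9)


# ---------------------------------------------------------------------------
# class contingency
# ---------------------------------------------------------------------------


def test_class_contingency_counts_and_order():
    sl = {"g1": "SL", "g2": "SL", "g3": "nonSL", "g4": "nonSL"}
    cat = {"g1": "down", "g2": "down", "g3": "down", "g4": "unaffected"}
    tab = class_contingency(sl, cat)
    assert tab.loc["SL", "down"] == 2
    assert tab.loc["nonSL", "down"] == 1
    assert tab.loc["nonSL", "unaffected"] == 1
    # permuting gene order leaves the table unchanged
    tab2 = class_contingency(dict(reversed(list(sl.items()))), cat)
    pd.testing.assert_frame_equal(tab, tab2)


def test_class_contingency_disjoint_universes_rejected():
    with pytest.raises(ValueError):
        class_contingency({"a": 1}, {"b": 2})


def test_planted_enrichment_detected():
    """Trans-splicing planted with odds ratio ~3 among suppressed genes in a
    2,000-gene study yields Fisher p < 0.001."""
    from sltop.synthetic import SimConfig, simulate_annotation

    cfg = SimConfig(
        seed=41, n_genes=2000, frac_suppressed=0.1, frac_suppressed_both=0.0,
        suppression_ts_odds=3.0, frac_dormant=0.0,
    )
    _, _, truth = simulate_annotation(cfg)
    ts = truth["trans_spliced"]
    sup = truth["suppressed"]
    tab = [
        [int((ts & sup).sum()), int((~ts & sup).sum())],
        [int((ts & ~sup).sum()), int((~ts & ~sup).sum())],
    ]
    assert fisher_exact_2x2(tab).p < 1e-3
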