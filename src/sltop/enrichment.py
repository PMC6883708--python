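"""Contingency and gene-set statistics: Fisher exact 2x2, chi-square with
Pearson residuals, Welch two-sample t, hypergeometric GO over-representation,
and gene-class cross-tabulation.

The Fisher two-sided p uses the probability-mass rule (sum the hypergeometric
probabilities of all tables, under fixed margins, that are no more probable
than the observed one) computed in exact integer arithmetic, matching the
convention of R's ``fisher.test``. Several two-sided definitions exist; this
one is stated explicitly because the choice changes p for asymmetric tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyResult",
    "GOResult",
    "fisher_exact_2x2",
    "chisq_with_residuals",
    "welch_t",
    "go_overrepresentation",
    "class_contingency",
]


@dataclass
class ContingencyResult:
    table: np.ndarray
    statistic: float  # odds ratio (Fisher) or chi-square statistic
    df: int | None
    p: float
    odds_ratio: float | None
    odds_ratio_haldane: float | None
    pearson_residuals: np.ndarray | None


@dataclass
class GOResult:
    term: str
    k_selected_annotated: int
    n_selected: int
    K_universe_annotated: int
    N_universe: int
    p_hyper: float
    fdr: float = float("nan")


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> ContingencyResult:
    """Two-sided Fisher exact test for a 2x2 table [[a, b], [c, d]].

    p sums, over the support of tables with the observed margins, the
    hypergeometric probabilities <= that of the observed table (exact
    integer comparison, no floating-point slack). The sample odds ratio is
    (a d)/(b c); with a zero cell it is reported as +/-inf (0 if the
    numerator is zero) alongside the Haldane-corrected (+0.5) value.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n = a + b + c + d
    if n == 0:
        raise ValueError("all-zero table")
    row1, col1 = a + b, a + c
    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    # unnormalised probabilities share the denominator C(n, col1)
    weights = [comb(row1, x) * comb(n - row1, col1 - x) for x in range(lo, hi + 1)]
    obs = weights[a - lo]
    num = sum(w for w in weights if w <= obs)
    p = float(Fraction(num, sum(weights)))

    if b * c > 0:
        odds = (a * d) / (b * c)
    elif a * d > 0:
        odds = float("inf")
    else:
        odds = 0.0
    haldane = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    return ContingencyResult(
        table=t, statistic=odds, df=None, p=min(p, 1.0),
        odds_ratio=odds, odds_ratio_haldane=haldane, pearson_residuals=None,
    )


def chisq_with_residuals(table: Sequence[Sequence[int]]) -> ContingencyResult:
    """Pearson chi-square test of independence for an r x c table with the
    matrix of Pearson residuals (O - E) / sqrt(E)."""
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("table must be at least 2x2")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero margin")
    n = t.sum()
    expected = np.outer(rows, cols) / n
    resid = (t - expected) / np.sqrt(expected)
    statistic = float((resid**2).sum())
    df = (t.shape[0] - 1) * (t.shape[1] - 1)
    p = float(stats.chi2.sf(statistic, df))
    return ContingencyResult(
        table=t.astype(np.int64), statistic=statistic, df=df, p=max(p, np.nextafter(0, 1)),
        odds_ratio=None, odds_ratio_haldane=None, pearson_residuals=resid,
    )


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch two-sample t test: (t, Welch–Satterthwaite df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0
        raise ValueError("both samples are degenerate (zero variance)")
    se2 = vx / x.size + vy / y.size
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2**2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), min(p, 1.0)


def go_overrepresentation(
    selected: Iterable[str],
    universe: Iterable[str],
    annotation: Mapping[str, set[str]],
    with_fdr: bool = True,
) -> list[GOResult]:
    """Hypergeometric over-representation of terms in ``selected`` against
    ``universe``: per term, p = P(X >= k) under Hypergeometric(N, K, n).

    Annotations are restricted to the universe; terms with k = 0 in the
    selection are omitted. No ontology-graph propagation is performed. A BH
    column is attached (the raw p-values remain the primary report).
    """
    sel = set(selected)
    uni = set(universe)
    if not sel <= uni:
        raise ValueError("selected gene set must be a subset of the universe")
    n_uni = len(uni)
    n_sel = len(sel)
    term_universe: dict[str, int] = {}
    term_selected: dict[str, int] = {}
    for gid in uni:
        for term in annotation.get(gid, ()):
            term_universe[term] = term_universe.get(term, 0) + 1
            if gid in sel:
                term_selected[term] = term_selected.get(term, 0) + 1
    results = []
    for term in sorted(term_selected):
        k = term_selected[term]
        K = term_universe[term]
        p = float(stats.hypergeom.sf(k - 1, n_uni, K, n_sel))
        results.append(GOResult(term, k, n_sel, K, n_uni, min(p, 1.0)))
    if with_fdr and results:
        from statsmodels.stats.multitest import multipletests

        adj = multipletests([r.p_hyper for r in results], method="fdr_bh")[1]
        for r, q in zip(results, adj):
            r.fdr = float(q)
    return results


def class_contingency(
    flags_a: Mapping[str, object], flags_b: Mapping[str, object]
) -> pd.DataFrame:
    """Cross-tabulate two per-gene labelings over their shared gene universe.

    Row/column order is deterministic (sorted labels); raises if the
    universes are disjoint.
    """
    shared = sorted(set(flags_a) & set(flags_b))
    if not shared:
        raise ValueError("gene universes are disjoint")
    a = pd.Series({g: flags_a[g] for g in shared}, name="a")
    b = pd.Series({g: flags_b[g] for g in shared}, name="b")
    tab = pd.crosstab(a, b)
    return tab.sort_index(axis=0).sort_index(axis=1)
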