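"""Translational-efficiency quantification and differential testing.

Translational efficiency (TE) of a gene is its ribosome-protected-fragment
(RPF) density divided by its mRNA density. Counts are normalised to reads
per million (RPM) per library, replicates are averaged, and TE(condition) =
mean RPF RPM / mean RNA RPM. The treatment effect is
log2 dTE = log2 TE(treatment) - log2 TE(control).

Differential testing uses a replicate-stratified Cochran–Mantel–Haenszel
style score on the RPF:(RPF+RNA) split, with the conditional variance
inflated by a single genome-wide quasi-dispersion parameter. Per replicate
pair r the 2x2 stratum is::

        RPF              RNA
  trt   a_r = x_t,r      b_r = y_t,r
  ctl   c_r = x_c,r      d_r = y_c,r

on depth-adjusted counts. The score is T = sum_r (a_r - E_r) with E_r and
V_r the hypergeometric mean and variance given the stratum margins. Count
overdispersion makes the true variance of T exceed sum_r V_r by a factor
that grows with the stratum total n_r, so V_r is inflated to
V_r * (1 + rho * (n_r - 1)) with one genome-wide rho estimated by matching
the median of the per-gene Pearson (squared score) statistics to the
chi-square(1) median. The two-sided p comes from the normal reference and
Benjamini–Hochberg controls the FDR across tested genes.

The same machinery tests differential mRNA abundance with strata
gene-count vs rest-of-library per condition.

The fitted interface is :class:`TranslationalEfficiencyModel` ->
:class:`TranslationResults`; the individual steps are module functions.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CountMatrix, Sample

__all__ = [
    "Regulation",
    "ResponseCategory",
    "OocyteCall",
    "normalize_rpm",
    "filter_low_count",
    "compute_te",
    "diff_te_test",
    "diff_rna_test",
    "classify_regulation_fc",
    "assign_response_category",
    "classify_oocyte",
    "TranslationalEfficiencyModel",
    "TranslationResults",
]

_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))  # ~0.4549


class Regulation(str, Enum):
    UP = "up"
    DOWN = "down"
    UNAFFECTED = "unaffected"


class ResponseCategory(str, Enum):
    TRANSLATION_ONLY = "translation_only"
    BOTH = "both"
    TRANSCRIPTION_ONLY = "transcription_only"
    UNAFFECTED = "unaffected"


# ---------------------------------------------------------------------------
# Normalisation, filtering, TE
# ---------------------------------------------------------------------------


def normalize_rpm(counts: CountMatrix) -> pd.DataFrame:
    """Reads-per-million per library; every column sums to 1e6."""
    totals = counts.library_sizes()
    if (totals == 0).any():
        empty = [s.label for s, t in zip(counts.samples, totals) if t == 0]
        raise ValueError(f"empty libraries: {', '.join(empty)}")
    return counts.df / totals * 1e6


def filter_low_count(counts: CountMatrix, min_total: int = 100) -> CountMatrix:
    """Drop genes with fewer than ``min_total`` reads summed over all
    samples (both assays, all conditions); the threshold itself is kept."""
    keep = counts.df.sum(axis=1) >= min_total
    return CountMatrix(counts.df.loc[keep])


def compute_te(
    rpm: pd.DataFrame,
    control: str,
    treatment: str,
    pseudocount: float = 0.0,
) -> pd.DataFrame:
    """Per-gene TE per condition and log2 dTE.

    TE(cond) = mean-over-replicates(RPF RPM) / mean-over-replicates(RNA RPM).
    A zero RNA denominator yields NaN TE (never imputed); an optional
    pseudocount is added to both mean RPMs before the ratio.
    """
    samples = [c if isinstance(c, Sample) else Sample(*c) for c in rpm.columns]
    out = pd.DataFrame(index=rpm.index.copy())
    for cond in (control, treatment):
        rpf_cols = [s for s in samples if s.assay == "RPF" and s.condition == cond]
        rna_cols = [s for s in samples if s.assay == "RNA" and s.condition == cond]
        if not rpf_cols or not rna_cols:
            raise ValueError(f"condition {cond!r} lacks RPF or RNA libraries")
        num = rpm[rpf_cols].mean(axis=1) + pseudocount
        den = rpm[rna_cols].mean(axis=1) + pseudocount
        te = num / den.where(den > 0)
        out[f"te_{cond}"] = te
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out[f"te_{treatment}"] / out[f"te_{control}"]
        out["log2_dte"] = np.log2(ratio.where(ratio > 0))
    return out


# ---------------------------------------------------------------------------
# Stratified score test with genome-wide quasi-dispersion
# ---------------------------------------------------------------------------


def _cmh_components(a, b, c, d):
    """Score component, hypergeometric variance and stratum total for 2x2
    strata with rows (a, b) / (c, d); arrays are genes x strata."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    row1, row2 = a + b, c + d
    col1, col2 = a + c, b + d
    with np.errstate(divide="ignore", invalid="ignore"):
        e = row1 * col1 / n
        v = row1 * row2 * col1 * col2 / (n**2 * np.maximum(n - 1.0, 1.0))
    e = np.where(n > 0, e, 0.0)
    v = np.where(n > 0, v, 0.0)
    return a - e, v, n


def _estimate_rho(t: np.ndarray, v0: np.ndarray, m: np.ndarray) -> float:
    """Genome-wide quasi-dispersion: rho >= 0 such that the median of
    T^2 / (V0 + rho M) over genes equals the chi-square(1) median."""
    ok = v0 > 0
    if ok.sum() < 10:
        return 0.0
    t, v0, m = t[ok], v0[ok], m[ok]

    def med(rho: float) -> float:
        return float(np.median(t**2 / (v0 + rho * m))) - _CHI2_1_MEDIAN

    if med(0.0) <= 0.0:
        return 0.0
    hi = 1e-6
    while med(hi) > 0.0 and hi < 1.0:
        hi *= 4.0
    return float(optimize.brentq(med, 0.0, hi, xtol=1e-12))


def _score_test(t, v0, m, rho):
    var = v0 + rho * m
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, t / np.sqrt(np.where(var > 0, var, 1.0)), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(var > 0, p, 1.0)
    return z, np.minimum(p, 1.0)


def _bh(p: np.ndarray) -> np.ndarray:
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _replicate_strata(counts: CountMatrix, control: str, treatment: str) -> list[int]:
    reps: set[int] | None = None
    for assay in ("RPF", "RNA"):
        for cond in (control, treatment):
            got = {s.replicate for s in counts.samples if s.assay == assay and s.condition == cond}
            if not got:
                raise ValueError(f"missing {assay} libraries for condition {cond!r}")
            reps = got if reps is None else reps & got
    assert reps is not None
    if not reps:
        raise ValueError("no common replicate indices across assays/conditions")
    return sorted(reps)


def diff_te_test(
    counts: CountMatrix, control: str, treatment: str
) -> pd.DataFrame:
    """Per-gene differential-TE test: columns statistic, p_te, fdr_te,
    flagged (all-zero genes, reported with p = 1)."""
    reps = _replicate_strata(counts, control, treatment)
    libsize = counts.library_sizes()
    common = float(np.exp(np.log(libsize.to_numpy(dtype=float)).mean()))
    adj = counts.df / libsize * common

    scores, varis, totals = [], [], []
    for r in reps:
        a = adj[Sample("RPF", treatment, r)]
        b = adj[Sample("RNA", treatment, r)]
        c = adj[Sample("RPF", control, r)]
        d = adj[Sample("RNA", control, r)]
        t_r, v_r, n_r = _cmh_components(a, b, c, d)
        scores.append(t_r)
        varis.append(v_r)
        totals.append(n_r)
    t = np.sum(scores, axis=0)
    v0 = np.sum(varis, axis=0)
    m = np.sum([v * np.maximum(n - 1.0, 0.0) for v, n in zip(varis, totals)], axis=0)

    rho = _estimate_rho(t, v0, m)
    z, p = _score_test(t, v0, m, rho)
    flagged = v0 <= 0
    return pd.DataFrame(
        {"statistic": z, "p_te": p, "fdr_te": _bh(p), "flagged": flagged},
        index=counts.df.index.copy(),
    ).assign(quasi_dispersion=rho)


def diff_rna_test(
    counts: CountMatrix, control: str, treatment: str
) -> pd.DataFrame:
    """Per-gene differential mRNA-abundance test (proportion of library):
    columns statistic, p_rna, fdr_rna, direction."""
    rna = counts.subset_assay("RNA")
    samples = [c if isinstance(c, Sample) else Sample(*c) for c in rna.columns]
    reps_t = sorted(s.replicate for s in samples if s.condition == treatment)
    reps_c = sorted(s.replicate for s in samples if s.condition == control)
    if not reps_t or not reps_c:
        raise ValueError("both conditions need RNA libraries")
    reps = sorted(set(reps_t) & set(reps_c))
    if not reps:
        raise ValueError("no common replicate indices in RNA libraries")

    scores, varis, totals = [], [], []
    for r in reps:
        kt = rna[Sample("RNA", treatment, r)].to_numpy(dtype=float)
        kc = rna[Sample("RNA", control, r)].to_numpy(dtype=float)
        nt, nc = kt.sum(), kc.sum()
        t_r, v_r, _ = _cmh_components(kt, nt - kt, kc, nc - kc)
        scores.append(t_r)
        varis.append(v_r)
        # overdispersion couples through the gene's own count, not the
        # library total: quasi-NB inflation 1 + rho * (per-condition count)
        totals.append((kt + kc) / 2.0)
    t = np.sum(scores, axis=0)
    v0 = np.sum(varis, axis=0)
    m = np.sum([v * n for v, n in zip(varis, totals)], axis=0)

    rho = _estimate_rho(t, v0, m)
    z, p = _score_test(t, v0, m, rho)
    direction = np.where(t > 0, "up", np.where(t < 0, "down", "none"))
    return pd.DataFrame(
        {"statistic": z, "p_rna": p, "fdr_rna": _bh(p), "direction": direction},
        index=rna.index.copy(),
    ).assign(quasi_dispersion=rho)


# ---------------------------------------------------------------------------
# Categorical calls
# ---------------------------------------------------------------------------


def classify_regulation_fc(
    fold_change: float,
    adj_p: float,
    fc_threshold: float = 1.0,
    p_threshold: float = 0.001,
) -> Regulation:
    """Up if fold change > threshold and adjusted p < p_threshold; down if
    fold change < threshold under the same p gate; otherwise unaffected."""
    if not fold_change > 0:
        raise ValueError("fold change must be positive")
    if adj_p < p_threshold:
        if fold_change > fc_threshold:
            return Regulation.UP
        if fold_change < fc_threshold:
            return Regulation.DOWN
    return Regulation.UNAFFECTED


def assign_response_category(
    regulation_te: Regulation, regulation_rna: Regulation
) -> ResponseCategory:
    """Combine TE and mRNA regulation calls into the response category:
    translation_only (TE changed, mRNA unaffected), both (same direction),
    transcription_only (mRNA changed, TE unaffected), else unaffected
    (including discordant directions)."""
    te, rna = Regulation(regulation_te), Regulation(regulation_rna)
    if te != Regulation.UNAFFECTED and rna == Regulation.UNAFFECTED:
        return ResponseCategory.TRANSLATION_ONLY
    if te != Regulation.UNAFFECTED and rna == te:
        return ResponseCategory.BOTH
    if te == Regulation.UNAFFECTED and rna != Regulation.UNAFFECTED:
        return ResponseCategory.TRANSCRIPTION_ONLY
    return ResponseCategory.UNAFFECTED


@dataclass
class OocyteCall:
    gene_id: str
    in_oocyte: bool
    tiling_intensity: float
    cage_tpm: float


def classify_oocyte(
    tiling_intensity: float, cage_tpm: float, gene_id: str = ""
) -> OocyteCall:
    """Oocyte-stocked call: tiling probe intensity > 0 OR dominant CAGE
    TSS >= 1 tpm (inclusive)."""
    if cage_tpm < 0:
        raise ValueError("cage_tpm must be non-negative")
    return OocyteCall(
        gene_id, tiling_intensity > 0 or cage_tpm >= 1.0, tiling_intensity, cage_tpm
    )


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class TranslationalEfficiencyModel:
    """Paired RPF/RNA count model of translational efficiency.

    Parameters
    ----------
    counts : CountMatrix
        Raw per-gene counts with RPF and RNA libraries for both conditions.
    control, treatment : str
        Condition labels; log2 dTE is treatment relative to control.
    """

    def __init__(self, counts: CountMatrix, control: str, treatment: str):
        conds = counts.conditions()
        for cond in (control, treatment):
            if cond not in conds:
                raise ValueError(f"condition {cond!r} not present in counts")
        self.counts = counts
        self.control = control
        self.treatment = treatment

    @classmethod
    def from_tsv(cls, path, control: str, treatment: str) -> "TranslationalEfficiencyModel":
        from .io_formats import read_counts

        return cls(read_counts(path), control, treatment)

    def fit(
        self,
        min_total: int = 100,
        fdr: float = 0.05,
        pseudocount: float = 0.0,
    ) -> "TranslationResults":
        """Filter, normalise, quantify TE and run both differential tests.

        ``fdr`` is the BH-adjusted significance cutoff used for the
        up/down/unaffected regulation calls.
        """
        n_input = len(self.counts.genes)
        filtered = filter_low_count(self.counts, min_total)
        rpm = normalize_rpm(filtered)
        te = compute_te(rpm, self.control, self.treatment, pseudocount)
        dte = diff_te_test(filtered, self.control, self.treatment)
        drna = diff_rna_test(filtered, self.control, self.treatment)

        table = te.join(dte.drop(columns="quasi_dispersion")).join(
            drna.drop(columns=["quasi_dispersion", "direction", "statistic"])
        )
        log2_dte = table["log2_dte"].to_numpy()
        sig_te = table["fdr_te"].to_numpy() < fdr
        sig_rna = table["fdr_rna"].to_numpy() < fdr
        rna_stat = drna["statistic"].to_numpy()
        reg_te = np.where(
            sig_te & (log2_dte < 0), "down", np.where(sig_te & (log2_dte > 0), "up", "unaffected")
        )
        reg_rna = np.where(
            sig_rna & (rna_stat < 0), "down", np.where(sig_rna & (rna_stat > 0), "up", "unaffected")
        )
        table["regulation_te"] = reg_te
        table["regulation_rna"] = reg_rna
        table["response_category"] = [
            assign_response_category(Regulation(a), Regulation(b)).value
            for a, b in zip(reg_te, reg_rna)
        ]
        return TranslationResults(
            table=table.sort_index(),
            model=self,
            n_input=n_input,
            min_total=min_total,
            fdr=fdr,
            quasi_dispersion_te=float(dte["quasi_dispersion"].iloc[0]) if len(dte) else 0.0,
            quasi_dispersion_rna=float(drna["quasi_dispersion"].iloc[0]) if len(drna) else 0.0,
        )


@dataclass
class TranslationResults:
    """Fitted per-gene TE estimates, tests and category calls.

    ``table`` has one row per tested gene: te_<control>, te_<treatment>,
    log2_dte, statistic, p_te, fdr_te, p_rna, fdr_rna, regulation_te,
    regulation_rna, response_category.
    """

    table: pd.DataFrame
    model: TranslationalEfficiencyModel
    n_input: int
    min_total: int
    fdr: float
    quasi_dispersion_te: float
    quasi_dispersion_rna: float

    @property
    def n_tested(self) -> int:
        return len(self.table)

    def significant(self, direction: str = "down", assay: str = "te") -> pd.Index:
        col = f"regulation_{assay}"
        return self.table.index[self.table[col] == direction]

    def category_counts(self) -> pd.Series:
        cats = [c.value for c in ResponseCategory]
        return self.table["response_category"].value_counts().reindex(cats, fill_value=0)

    def summary(self) -> str:
        lines = [
            "Translational efficiency model",
            f"  conditions:        {self.model.treatment} vs {self.model.control}",
            f"  genes (input):     {self.n_input}",
            f"  genes (tested):    {self.n_tested}  (min total reads {self.min_total})",
            f"  quasi-dispersion:  TE {self.quasi_dispersion_te:.3g}, RNA {self.quasi_dispersion_rna:.3g}",
            f"  significance:      BH FDR < {self.fdr:g}",
            f"  TE down / up:      {len(self.significant('down', 'te'))} / {len(self.significant('up', 'te'))}",
            f"  RNA down / up:     {len(self.significant('down', 'rna'))} / {len(self.significant('up', 'rna'))}",
            "  response categories:",
        ]
        for cat, n in self.category_counts().items():
            lines.append(f"    {cat:<20s} {n}")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        with open(path, "w") as fh:
            fh.write("#gene_id\t" + "\t".join(map(str, out.columns)) + "\n")
            for gid, row in out.iterrows():
                fields = []
                for v in row:
                    if isinstance(v, (float, np.floating)):
                        fields.append("NA" if np.isnan(v) else f"{v:.6g}")
                    elif isinstance(v, (bool, np.bool_)):
                        fields.append(str(int(v)))
                    else:
                        fields.append(str(v))
                fh.write(str(gid) + "\t" + "\t".join(fields) + "\n")
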