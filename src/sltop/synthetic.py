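"""Synthetic study generator: genome, gene models, CAGE-style tags, SL read
counts and NB-dispersed RPF/RNA count matrices with planted effects.

The generator emulates the structure of a ribosome-profiling + RNA-seq
experiment on an organism that trans-splices a spliced leader onto a subset
of its mRNAs:

* a fraction of genes is trans-spliced (default 0.43, the fraction observed
  among female-expressed genes) and receives an acceptor site with a genomic
  ``AG`` immediately 5' of it, inside the gene body or <= 500 bp upstream;
* a fraction of genes carries a planted translational-suppression effect
  (default log2 dTE = -1 in the treatment condition), enriched among
  trans-spliced genes with a configurable odds ratio;
* a dormant compartment of genes drawn from the top abundance quantile with
  8-fold reduced baseline translational efficiency, insensitive to the
  treatment (true log2 dTE = 0) — the oocyte-stocked maternal mRNA pool;
* TOP-motif genes receive a 5' ``C`` + 4..14 pyrimidines at the TSS, all
  other genes receive a guaranteed motif-free 5' region;
* RPF/RNA counts are negative binomial with variance mu + phi * mu^2 and a
  single shared dispersion phi.

Every draw is governed by the mandatory config seed through per-stage
substreams, so outputs are byte-identical under a fixed (config, seed) and
inserting a stage never perturbs another stage's draws.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (
    CountMatrix,
    GeneModel,
    GeneModelSet,
    GenomeSequence,
    Sample,
    TagRecord,
)

__all__ = [
    "SimConfig",
    "simulate_annotation",
    "simulate_tags",
    "simulate_counts",
    "simulate_sl_reads",
    "simulate_oocyte_evidence",
    "simulate_go_terms",
    "write_truth",
    "read_truth",
]

# Stage identifiers mixed into the seed so each stage has an independent
# substream and stage insertion does not shift other stages' draws.
_STAGE_ANNOTATION = 101
_STAGE_TAGS = 102
_STAGE_COUNTS = 103
_STAGE_SL = 104
_STAGE_OOCYTE = 105
_STAGE_GO = 106

_PURINES = np.array(list("AG"))
_PYRIMIDINES = np.array(list("CT"))
_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic experiment.

    Proportions are fractions of ``n_genes``; ``mean_rna``/``mean_rpf`` are
    expected per-gene per-replicate counts for a gene with unit size factor;
    ``nb_dispersion`` is phi in Var = mu + phi * mu^2.
    """

    seed: int
    n_genes: int = 2000
    frac_trans_spliced: float = 0.43
    frac_suppressed: float = 0.05
    effect_log2dte: float = -1.0
    # fraction of suppressed genes whose transcription is also down-regulated
    # (the secondary, "both" response); translation-only suppression carries
    # the trans-splicing enrichment
    frac_suppressed_both: float = 0.5
    effect_log2drna: float = -1.0
    frac_rna_only: float = 0.01
    frac_dormant: float = 0.15
    dormant_te_scale: float = 0.125
    frac_top: float = 0.076
    mean_rna: float = 200.0
    mean_rpf: float = 100.0
    nb_dispersion: float = 0.05
    n_replicates: int = 3
    conditions: tuple[str, str] = ("control", "treatment")
    size_factor_sigma: float = 0.5
    suppression_ts_odds: float = 2.5
    top_suppressed_odds: float = 1.0
    dormant_suppressed_overlap: bool = False
    # SL1/SL2 scenario
    sl_depth: float = 50.0
    sl_class_probs: tuple[float, float, float] = (0.6, 0.25, 0.15)  # SL1, SL2, mixed
    # decoy acceptor sites exercising exactly one classifier rule each
    decoy_frac: float = 0.1
    decoy_mode: str = "cycle"  # "count1" | "nonAG" | "far" | "cycle"
    # CAGE TSS tag depth scale (tags ~ 1 + Poisson(scale * size_factor))
    cage_tag_scale: float = 5.0
    chrom_name: str = "chrS"

    def validate(self) -> None:
        for name in (
            "frac_trans_spliced",
            "frac_suppressed",
            "frac_suppressed_both",
            "frac_rna_only",
            "frac_dormant",
            "frac_top",
            "decoy_frac",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.mean_rna <= 0 or self.mean_rpf <= 0:
            raise ValueError("library means must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if len(self.conditions) != 2 or self.conditions[0] == self.conditions[1]:
            raise ValueError("conditions must be two distinct labels")
        if not 0 < self.dormant_te_scale <= 1:
            raise ValueError("dormant_te_scale must be in (0, 1]")
        if self.decoy_mode not in ("count1", "nonAG", "far", "cycle"):
            raise ValueError(f"unknown decoy_mode {self.decoy_mode!r}")
        if abs(sum(self.sl_class_probs) - 1.0) > 1e-9:
            raise ValueError("sl_class_probs must sum to 1")


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng([int(config.seed), stage])


def _pick(rng: np.random.Generator, n: int, count: int, weights=None) -> np.ndarray:
    """Boolean mask with exactly ``count`` True entries."""
    mask = np.zeros(n, dtype=bool)
    if count > 0:
        p = None if weights is None else np.asarray(weights) / np.sum(weights)
        mask[rng.choice(n, size=count, replace=False, p=p)] = True
    return mask


def _motif_free_prefix(rng: np.random.Generator, length: int = 20) -> str:
    """Random sequence guaranteed to contain no pyrimidine run >= 4."""
    out: list[str] = []
    run = 0
    for _ in range(length):
        if run >= 3:
            base = str(rng.choice(_PURINES))
        else:
            base = str(rng.choice(_BASES))
        run = run + 1 if base in "CT" else 0
        out.append(base)
    return "".join(out)


def _write_transcript(seq: list[str], strand: str, five_prime: int, sub: str) -> None:
    """Write ``sub`` into the genome so that reading from ``five_prime`` in
    transcript orientation yields ``sub``."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if strand == "+":
        for i, b in enumerate(sub):
            seq[five_prime + i] = b
    else:
        for i, b in enumerate(sub):
            seq[five_prime - i] = comp[b]


def simulate_annotation(config: SimConfig) -> tuple[GenomeSequence, GeneModelSet, pd.DataFrame]:
    """Build the synthetic chromosome, gene models and the per-gene truth.

    The truth table (index gene_id) carries the planted flags
    (trans_spliced, suppressed, dormant, oocyte, has_top_motif), the planted
    ``true_log2dte``, per-gene ``size_factor``, the SL scenario
    ``sl2_fraction`` and the acceptor/decoy bookkeeping used by
    :func:`simulate_tags`.
    """
    config.validate()
    rng = _rng(config, _STAGE_ANNOTATION)
    n = config.n_genes

    # ---- planted gene classes -------------------------------------------
    n_ts = round(config.frac_trans_spliced * n)
    ts = _pick(rng, n, n_ts)

    # translation-only suppressed genes carry the trans-splicing enrichment;
    # "both" (translational + transcriptional) suppression is drawn uniformly
    n_sup = round(config.frac_suppressed * n)
    n_both = round(n_sup * config.frac_suppressed_both)
    n_to = n_sup - n_both
    w_to = np.where(ts, config.suppression_ts_odds, 1.0)
    sup_to = _pick(rng, n, n_to, weights=w_to)
    pool_both = np.flatnonzero(~sup_to)
    sup_both = np.zeros(n, dtype=bool)
    if n_both:
        sup_both[rng.choice(pool_both, size=n_both, replace=False)] = True
    suppressed = sup_to | sup_both

    n_rna_only = round(config.frac_rna_only * n)
    pool_rna = np.flatnonzero(~suppressed)
    rna_only = np.zeros(n, dtype=bool)
    if n_rna_only:
        rna_only[rng.choice(pool_rna, size=n_rna_only, replace=False)] = True
    rna_down = sup_both | rna_only
    true_log2drna = np.where(rna_down, config.effect_log2drna, 0.0)

    n_dorm = round(config.frac_dormant * n)
    if config.dormant_suppressed_overlap:
        dormant = _pick(rng, n, n_dorm)
    else:
        pool = np.flatnonzero(~suppressed)
        if n_dorm > pool.size:
            raise ValueError("not enough non-suppressed genes for the dormant fraction")
        dormant = np.zeros(n, dtype=bool)
        dormant[rng.choice(pool, size=n_dorm, replace=False)] = True

    n_top = round(config.frac_top * n)
    w_top = np.where(suppressed, config.top_suppressed_odds, 1.0)
    has_top = _pick(rng, n, n_top, weights=w_top)

    true_log2dte = np.where(suppressed, config.effect_log2dte, 0.0)

    # size factors: lognormal; dormant genes redrawn from the top decile
    size_factor = np.exp(rng.normal(0.0, config.size_factor_sigma, size=n))
    if n_dorm:
        from scipy import stats as _st

        q = rng.uniform(0.9, 1.0 - 1e-9, size=n_dorm)
        size_factor[dormant] = np.exp(config.size_factor_sigma * _st.norm.ppf(q))

    # SL1/SL2 scenario fractions for trans-spliced genes
    sl2_fraction = np.full(n, np.nan)
    if n_ts:
        cat = rng.choice(3, size=n_ts, p=list(config.sl_class_probs))
        sl2_fraction[ts] = np.choose(cat, [0.0, 1.0, 0.5])

    # decoys among non-trans-spliced genes
    modes = ("count1", "nonAG", "far")
    non_ts_idx = np.flatnonzero(~ts)
    n_decoy = round(config.decoy_frac * non_ts_idx.size)
    decoy_mode = np.array([""] * n, dtype=object)
    if n_decoy:
        chosen = rng.choice(non_ts_idx, size=n_decoy, replace=False)
        for k, gi in enumerate(sorted(chosen)):
            decoy_mode[gi] = modes[k % 3] if config.decoy_mode == "cycle" else config.decoy_mode

    # ---- chromosome layout ----------------------------------------------
    lengths = rng.integers(500, 1501, size=n)
    gaps = rng.integers(700, 1201, size=n)
    strands = rng.choice(np.array(["+", "-"]), size=n)
    total = int(lengths.sum() + gaps.sum()) + 1000
    seq = list(rng.choice(_BASES, size=total))

    starts = np.empty(n, dtype=int)
    pos = 0
    for i in range(n):
        pos += int(gaps[i])
        starts[i] = pos
        pos += int(lengths[i])
    ends = starts + lengths

    gene_ids = [f"g{i:05d}" for i in range(n)]
    tx_sign = np.where(strands == "+", 1, -1)
    five_prime = np.where(strands == "+", starts, ends - 1)
    tss = five_prime.copy()

    # acceptor offsets in transcript coordinates relative to the 5' end
    acceptor_offset = np.full(n, 0)
    has_acceptor = ts.copy()
    for i in range(n):
        if not ts[i]:
            continue
        if has_top[i] or rng.random() < 0.5:
            acceptor_offset[i] = -int(rng.integers(30, 451))  # upstream
        else:
            acceptor_offset[i] = int(rng.integers(30, 151))  # in the gene body

    # ---- sequence planting ----------------------------------------------
    for i in range(n):
        fp = int(five_prime[i])
        strand = str(strands[i])
        sign = int(tx_sign[i])
        # 5' region: TOP motif or guaranteed motif-free prefix
        if has_top[i]:
            k = int(rng.integers(4, 15))
            motif = "C" + "".join(rng.choice(_PYRIMIDINES, size=k))
            motif += _motif_free_prefix(rng, 20 - len(motif)) if len(motif) < 20 else ""
            _write_transcript(seq, strand, fp, motif[:20])
        else:
            _write_transcript(seq, strand, fp, _motif_free_prefix(rng, 20))
        # dinucleotide immediately 5' of the TSS: pyrimidines, so a CAGE TSS
        # tag can never satisfy the AG acceptor rule
        if strand == "+":
            seq[fp - 2], seq[fp - 1] = "C", "C"
        else:
            # transcript bases -2,-1 are genomic fp+2, fp+1; complement of C is G
            seq[fp + 2], seq[fp + 1] = "G", "G"
        # acceptor site with AG immediately 5' (transcript orientation)
        if has_acceptor[i]:
            apos = fp + sign * int(acceptor_offset[i])
            if strand == "+":
                seq[apos - 2], seq[apos - 1] = "A", "G"
            else:
                seq[apos + 2], seq[apos + 1] = "T", "C"  # revcomp(AG)
        # decoy planting
        mode = decoy_mode[i]
        if mode:
            if mode == "far":
                off = -501
            else:
                off = -int(rng.integers(30, 451))
            acceptor_offset[i] = off
            apos = fp + sign * off
            if mode == "nonAG":
                up1, up2 = "C", "C"  # transcript dinucleotide CC, never AG
            else:
                up1, up2 = "A", "G"
            if strand == "+":
                seq[apos - 2], seq[apos - 1] = up1, up2
            else:
                comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
                seq[apos + 2], seq[apos + 1] = comp[up1], comp[up2]

    genome = GenomeSequence({config.chrom_name: "".join(seq)})
    models = GeneModelSet(
        GeneModel(gene_ids[i], config.chrom_name, str(strands[i]), int(starts[i]), int(ends[i]), int(tss[i]))
        for i in range(n)
    )
    truth = pd.DataFrame(
        {
            "trans_spliced": ts,
            "suppressed": suppressed,
            "dormant": dormant,
            "oocyte": dormant.copy(),  # refined by simulate_oocyte_evidence
            "has_top_motif": has_top,
            "rna_down": rna_down,
            "true_log2dte": true_log2dte,
            "true_log2drna": true_log2drna,
            "size_factor": size_factor,
            "sl2_fraction": sl2_fraction,
            "acceptor_offset": acceptor_offset,
            "decoy_mode": decoy_mode,
            "strand": strands,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return genome, models, truth


def _acceptor_genomic_pos(gene: GeneModel, offset: int) -> int:
    if gene.strand == "+":
        return gene.start + offset
    return (gene.end - 1) - offset


def simulate_tags(truth: pd.DataFrame, models: GeneModelSet, config: SimConfig) -> list[TagRecord]:
    """Emit CAGE-style tags: acceptor-site tags (count >= 2) for every
    trans-spliced gene, rule-violating decoy tags, and a TSS tag for every
    gene with a depth-scalable count."""
    config.validate()
    rng = _rng(config, _STAGE_TAGS)
    tags: list[TagRecord] = []
    for gene in models:
        row = truth.loc[gene.gene_id]
        if row["trans_spliced"]:
            pos = _acceptor_genomic_pos(gene, int(row["acceptor_offset"]))
            count = 2 + int(rng.poisson(3.0))
            tags.append(TagRecord(gene.chrom, pos, gene.strand, count))
        elif row["decoy_mode"]:
            pos = _acceptor_genomic_pos(gene, int(row["acceptor_offset"]))
            count = 1 if row["decoy_mode"] == "count1" else 2 + int(rng.poisson(3.0))
            tags.append(TagRecord(gene.chrom, pos, gene.strand, count))
        # TSS tag for every expressed gene
        tss_count = 1 + int(rng.poisson(config.cage_tag_scale * float(row["size_factor"])))
        tags.append(TagRecord(gene.chrom, gene.tss, gene.strand, tss_count))
    return tags


def simulate_counts(truth: pd.DataFrame, config: SimConfig) -> CountMatrix:
    """NB-dispersed RPF/RNA counts with planted TE effects.

    RNA mean = mean_rna * size_factor in both conditions; RPF mean =
    mean_rpf * size_factor * te_base, multiplied by 2^true_log2dte in the
    treatment condition; dormant genes have te_base scaled by
    ``dormant_te_scale``.

    Counts are gamma-Poisson: per (gene, condition, replicate) one
    mean-one gamma multiplier with variance phi models the biological
    expression-level fluctuation and is shared between the RPF and RNA
    libraries of that replicate pair — the two libraries sequence the same
    biology, and translational efficiency is the within-pair ratio. Each
    count's marginal distribution is exactly NB with Var = mu + phi mu^2.
    """
    config.validate()
    rng = _rng(config, _STAGE_COUNTS)
    control, treatment = config.conditions
    n = len(truth)
    sf = truth["size_factor"].to_numpy()
    te_base = np.where(truth["dormant"].to_numpy(), config.dormant_te_scale, 1.0)
    effect_te = np.power(2.0, truth["true_log2dte"].to_numpy())
    if "true_log2drna" in truth:
        effect_rna = np.power(2.0, truth["true_log2drna"].to_numpy())
    else:
        effect_rna = np.ones(n)

    # RPF tracks both transcript abundance and translational efficiency
    mu_rna = {
        control: config.mean_rna * sf,
        treatment: config.mean_rna * sf * effect_rna,
    }
    mu_rpf = {
        control: config.mean_rpf * sf * te_base,
        treatment: config.mean_rpf * sf * te_base * effect_te * effect_rna,
    }
    phi = config.nb_dispersion
    shape = 1.0 / phi
    cols: dict[Sample, np.ndarray] = {}
    for cond in config.conditions:
        for rep in range(1, config.n_replicates + 1):
            eps = rng.gamma(shape, phi, size=n)  # mean 1, variance phi
            cols[Sample("RPF", cond, rep)] = rng.poisson(mu_rpf[cond] * eps)
            cols[Sample("RNA", cond, rep)] = rng.poisson(mu_rna[cond] * eps)
    order = [
        Sample(assay, cond, rep)
        for assay in ("RPF", "RNA")
        for cond in config.conditions
        for rep in range(1, config.n_replicates + 1)
    ]
    df = pd.DataFrame(cols, index=truth.index.copy())[order]
    return CountMatrix(df)


def simulate_sl_reads(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Per-gene SL1/SL2 read counts: total ~ Poisson(sl_depth) for
    trans-spliced genes, split Binomial(total, sl2_fraction); (0, 0) for
    non-trans-spliced genes."""
    config.validate()
    rng = _rng(config, _STAGE_SL)
    n = len(truth)
    ts = truth["trans_spliced"].to_numpy()
    total = np.where(ts, rng.poisson(config.sl_depth, size=n), 0)
    frac = np.nan_to_num(truth["sl2_fraction"].to_numpy(), nan=0.0)
    sl2 = rng.binomial(total, frac)
    return pd.DataFrame(
        {"sl1_count": total - sl2, "sl2_count": sl2}, index=truth.index.copy()
    )


def simulate_oocyte_evidence(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Tiling-array intensity and CAGE tpm evidence for oocyte presence.

    Dormant genes always carry oocyte evidence; each gets either a positive
    tiling intensity, a CAGE tpm >= 1, or both. Non-dormant genes get
    sub-threshold evidence.
    """
    config.validate()
    rng = _rng(config, _STAGE_OOCYTE)
    n = len(truth)
    dorm = truth["dormant"].to_numpy()
    which = rng.integers(0, 3, size=n)  # 0 tiling, 1 cage, 2 both
    tiling = np.where(dorm & (which != 1), np.abs(rng.normal(1.0, 0.3, size=n)) + 1e-6, 0.0)
    cage = np.where(dorm & (which != 0), 1.0 + np.abs(rng.normal(2.0, 1.0, size=n)), rng.uniform(0.0, 0.99, size=n))
    return pd.DataFrame({"tiling_intensity": tiling, "cage_tpm": cage}, index=truth.index.copy())


def simulate_go_terms(truth: pd.DataFrame, config: SimConfig) -> dict[str, set[str]]:
    """Flat gene -> term annotation with one term planted to be enriched
    among suppressed genes (translation-related), plus background terms."""
    config.validate()
    rng = _rng(config, _STAGE_GO)
    ann: dict[str, set[str]] = {}
    sup = truth["suppressed"].to_numpy()
    for i, gid in enumerate(truth.index):
        terms = set()
        if rng.random() < (0.5 if sup[i] else 0.08):
            terms.add("GO:translation")
        if rng.random() < 0.25:
            terms.add("GO:metabolism")
        if rng.random() < 0.10:
            terms.add("GO:muscle_contraction")
        if terms:
            ann[gid] = terms
    return ann


# ---------------------------------------------------------------------------
# Truth table round-trip
# ---------------------------------------------------------------------------

_TRUTH_BOOL = ["trans_spliced", "suppressed", "dormant", "oocyte", "has_top_motif", "rna_down"]


def write_truth(truth: pd.DataFrame, path) -> None:
    out = truth.copy()
    for c in _TRUTH_BOOL:
        out[c] = out[c].astype(int)
    with open(path, "w") as fh:
        fh.write("#gene_id\t" + "\t".join(out.columns) + "\n")
        for gid, row in out.iterrows():
            fields = []
            for c in out.columns:
                v = row[c]
                if isinstance(v, float):
                    fields.append(repr(v))
                else:
                    fields.append(str(v))
            fh.write(gid + "\t" + "\t".join(fields) + "\n")


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={"decoy_mode": str, "strand": str})
    df.index.name = "gene_id"
    for c in _TRUTH_BOOL:
        df[c] = df[c].astype(bool)
    df["decoy_mode"] = df["decoy_mode"].fillna("")
    return df
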