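"""End-to-end orchestration: simulate -> classify -> quantify -> test ->
enrich, with a machine-readable run summary.

A run is fully determined by its :class:`RunConfig` (including the mandatory
seed): re-running with an identical config produces byte-identical output
files. Stages execute in a fixed order and any stage failure aborts the run
with a stage-named error.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io_formats import (
    CountMatrix,
    GeneModelSet,
    GenomeSequence,
    TagRecord,
    read_annotation,
    read_counts,
    read_gene_models,
    read_tags,
    write_annotation,
    write_gene_models,
    write_tags,
)
from .splice_leader import (
    TransSpliceCall,
    classify_sl,
    classify_trans_spliced,
    scan_canonical_top,
    scan_top_like,
)
from .synthetic import (
    SimConfig,
    simulate_annotation,
    simulate_counts,
    simulate_go_terms,
    simulate_oocyte_evidence,
    simulate_sl_reads,
    simulate_tags,
    write_truth,
)
from .translatome import TranslationalEfficiencyModel, classify_oocyte
from .enrichment import chisq_with_residuals, class_contingency, fisher_exact_2x2, go_overrepresentation

logger = logging.getLogger("sltop")

__all__ = ["RunConfig", "RunSummary", "run_pipeline", "motif_frequency_report", "classify_all_trans_spliced"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``sim`` (synthetic mode) or the input paths (real mode)
    must be provided. All thresholds are validated up front.
    """

    outdir: str
    seed: int
    sim: SimConfig | None = None
    # real-input mode paths
    genome_fasta: str | None = None
    gene_models: str | None = None
    gene_models_dialect: str = "gff3"
    tags_bed: str | None = None
    counts_tsv: str | None = None
    sl_reads_tsv: str | None = None
    annotation_tsv: str | None = None
    control: str = "control"
    treatment: str = "treatment"
    # thresholds
    fdr: float = 0.05
    min_total: int = 100
    p0: float = 0.5
    alpha: float = 0.05
    fc_threshold: float = 1.0
    p_threshold: float = 0.001
    upstream: int = 500
    motif_windows: tuple[int, int] = (4, 15)
    min_run: int = 5
    pseudocount: float = 0.0

    def validate(self) -> None:
        for name, lo, hi in (
            ("fdr", 0.0, 1.0),
            ("alpha", 0.0, 1.0),
            ("p_threshold", 0.0, 1.0),
        ):
            v = getattr(self, name)
            if not lo < v <= hi:
                raise ValueError(f"{name} must be in ({lo}, {hi}], got {v}")
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must be strictly inside (0, 1)")
        if self.min_total < 0 or self.upstream < 0 or self.min_run < 1:
            raise ValueError("min_total/upstream/min_run out of range")
        if self.fc_threshold <= 0 or self.pseudocount < 0:
            raise ValueError("fc_threshold must be > 0 and pseudocount >= 0")
        real_inputs = self.counts_tsv is not None
        if self.sim is not None and real_inputs:
            raise ValueError("synthetic and real-input modes are mutually exclusive")
        if self.sim is None and not real_inputs:
            raise ValueError("either sim config or input paths must be given")
        if self.sim is not None:
            self.sim.validate()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        cfg = cls(**{**raw, "sim": SimConfig(**sim) if sim is not None else None})
        if isinstance(cfg.motif_windows, list):
            cfg.motif_windows = tuple(cfg.motif_windows)
        if cfg.sim is not None and isinstance(cfg.sim.conditions, list):
            cfg.sim.conditions = tuple(cfg.sim.conditions)
        return cfg

    def echo(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = dataclasses.asdict(self.sim)
        return d


@dataclass
class RunSummary:
    """Per-stage counts and headline statistics of one run."""

    seed: int
    version: str
    config: dict
    counts: dict = field(default_factory=dict)
    statistics: dict = field(default_factory=dict)

    def to_json(self) -> str:
        def clean(o):
            if isinstance(o, dict):
                return {k: clean(v) for k, v in sorted(o.items())}
            if isinstance(o, (list, tuple)):
                return [clean(v) for v in o]
            if isinstance(o, (np.floating, float)):
                f = float(o)
                return None if np.isnan(f) else round(f, 10)
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.bool_,)):
                return bool(o)
            return o

        return json.dumps(
            clean({"seed": self.seed, "version": self.version, "config": self.config,
                   "counts": self.counts, "statistics": self.statistics}),
            indent=2, sort_keys=True,
        )


# ---------------------------------------------------------------------------
# Vectorised trans-splice classification over a tag collection
# ---------------------------------------------------------------------------


def classify_all_trans_spliced(
    models: GeneModelSet,
    tags: Sequence[TagRecord],
    genome: GenomeSequence,
    upstream: int = 500,
    min_count: int = 2,
) -> dict[str, TransSpliceCall]:
    """Classify every gene, indexing tags by (chrom, strand) and window to
    avoid the all-pairs scan."""
    by_key: dict[tuple[str, str], tuple[list[int], list[TagRecord]]] = {}
    for t in sorted(tags, key=lambda t: t.pos):
        by_key.setdefault((t.chrom, t.strand), ([], []))
        pos_list, tag_list = by_key[(t.chrom, t.strand)]
        pos_list.append(t.pos)
        tag_list.append(t)
    calls: dict[str, TransSpliceCall] = {}
    for gene in models:
        pos_list, tag_list = by_key.get((gene.chrom, gene.strand), ([], []))
        if gene.strand == "+":
            lo, hi = gene.start - upstream, gene.end
        else:
            lo, hi = gene.start, gene.end + upstream
        # include a margin so near-window sites are reported with failures
        i = bisect_left(pos_list, lo - 50)
        j = bisect_right(pos_list, hi + 50)
        calls[gene.gene_id] = classify_trans_spliced(
            gene, tag_list[i:j], genome, upstream=upstream, min_count=min_count
        )
    return calls


# ---------------------------------------------------------------------------
# Motif frequency report
# ---------------------------------------------------------------------------


def motif_frequency_report(
    gene_classes: Mapping[str, str],
    sequences: Mapping[str, str],
    windows: Sequence[int] = (4, 15),
    min_run: int = 5,
    compare: tuple[str, str] = ("down", "unaffected"),
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Per-class motif frequencies plus Fisher comparisons.

    Returns (frequency table indexed by class, Fisher comparison table
    between the two classes in ``compare``, list of genes skipped for
    missing sequences).
    """
    missing = sorted(g for g in gene_classes if g not in sequences)
    if missing:
        logger.warning("motif report: %d genes lack 5' sequence, excluded", len(missing))
    usable = [g for g in gene_classes if g in sequences]
    motif_cols = ["canonical_TOP"] + [f"top_like_w{w}" for w in windows]
    hits = {}
    for g in usable:
        seq = sequences[g]
        row = {"canonical_TOP": scan_canonical_top(seq) is not None}
        for w in windows:
            row[f"top_like_w{w}"] = bool(scan_top_like(seq, window=w, min_run=min_run))
        hits[g] = row
    hit_df = pd.DataFrame.from_dict(hits, orient="index").reindex(columns=motif_cols)
    cls = pd.Series({g: gene_classes[g] for g in usable})
    freq = hit_df.groupby(cls).mean().sort_index()
    freq["n_genes"] = hit_df.groupby(cls).size()

    rows = []
    a_cls, b_cls = compare
    if a_cls in freq.index and b_cls in freq.index:
        a_genes = cls.index[cls == a_cls]
        b_genes = cls.index[cls == b_cls]
        for col in motif_cols:
            ka = int(hit_df.loc[a_genes, col].sum())
            kb = int(hit_df.loc[b_genes, col].sum())
            res = fisher_exact_2x2(
                [[ka, len(a_genes) - ka], [kb, len(b_genes) - kb]]
            )
            rows.append(
                {
                    "motif": col,
                    f"freq_{a_cls}": ka / len(a_genes) if len(a_genes) else np.nan,
                    f"freq_{b_cls}": kb / len(b_genes) if len(b_genes) else np.nan,
                    "odds_ratio": res.odds_ratio,
                    "p": res.p,
                }
            )
    return freq, pd.DataFrame(rows), missing


def _five_prime_sequences(
    models: GeneModelSet, genome: GenomeSequence, length: int = 30
) -> dict[str, str]:
    seqs = {}
    for g in models:
        chrom_len = len(genome.chroms[g.chrom])
        if g.strand == "+":
            start, end = g.tss, min(g.tss + length, chrom_len)
        else:
            start, end = max(g.tss - length + 1, 0), g.tss + 1
        if end > start:
            seqs[g.gene_id] = genome.fetch(g.chrom, start, end, g.strand)
    return seqs


# ---------------------------------------------------------------------------
# The run
# ---------------------------------------------------------------------------


def _write_df(df: pd.DataFrame, path: Path, index_name: str = "gene_id") -> None:
    with open(path, "w") as fh:
        fh.write(f"#{index_name}\t" + "\t".join(map(str, df.columns)) + "\n")
        for idx, row in df.iterrows():
            fields = []
            for v in row:
                if isinstance(v, (float, np.floating)):
                    fields.append("NA" if np.isnan(v) else f"{v:.6g}")
                elif isinstance(v, (bool, np.bool_)):
                    fields.append(str(int(v)))
                else:
                    fields.append(str(v))
            fh.write(str(idx) + "\t" + "\t".join(fields) + "\n")


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute the full pipeline and write all stage TSVs plus summary.json
    under ``config.outdir``. Deterministic given the config (incl. seed)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary = RunSummary(seed=config.seed, version=__version__, config=config.echo())

    def stage(name):
        logger.info("stage %s", name)
        return name

    truth = None
    try:
        if config.sim is not None:
            stage("simulate")
            genome, models, truth = simulate_annotation(config.sim)
            tags = simulate_tags(truth, models, config.sim)
            counts = simulate_counts(truth, config.sim)
            sl_reads = simulate_sl_reads(truth, config.sim)
            oocyte_ev = simulate_oocyte_evidence(truth, config.sim)
            annotation = simulate_go_terms(truth, config.sim)
            control, treatment = config.sim.conditions
            genome.to_fasta(outdir / "genome.fa")
            write_gene_models(models, outdir / "genes.gff3")
            write_tags(tags, outdir / "tags.bed")
            counts.to_tsv(outdir / "counts.tsv")
            _write_df(sl_reads, outdir / "sl_reads.tsv")
            _write_df(oocyte_ev, outdir / "oocyte_evidence.tsv")
            write_annotation(annotation, outdir / "annotation.tsv")
            write_truth(truth, outdir / "truth.tsv")
        else:
            stage("load")
            genome = GenomeSequence.from_fasta(config.genome_fasta)
            models = read_gene_models(config.gene_models, config.gene_models_dialect)
            tags = read_tags(config.tags_bed) if config.tags_bed else []
            counts = read_counts(config.counts_tsv)
            sl_reads = (
                pd.read_csv(config.sl_reads_tsv, sep="\t", index_col=0)
                if config.sl_reads_tsv
                else None
            )
            oocyte_ev = None
            annotation = read_annotation(config.annotation_tsv) if config.annotation_tsv else {}
            control, treatment = config.control, config.treatment
    except Exception as exc:
        raise RuntimeError(f"stage simulate/load failed: {exc}") from exc

    summary.counts["genes_input"] = len(models)
    summary.counts["tags"] = len(tags)

    # ---- trans-splice classification ------------------------------------
    try:
        stage("classify_trans_spliced")
        calls = classify_all_trans_spliced(models, tags, genome, upstream=config.upstream)
        ts_df = pd.DataFrame(
            {
                "is_trans_spliced": {g: c.is_trans_spliced for g, c in calls.items()},
                "n_supporting_sites": {g: len(c.supporting_sites) for g, c in calls.items()},
                "rule_failures": {g: ";".join(c.rule_failures) for g, c in calls.items()},
            }
        ).sort_index()
        _write_df(ts_df, outdir / "trans_splice_calls.tsv")
        summary.counts["genes_trans_spliced"] = int(ts_df["is_trans_spliced"].sum())
    except Exception as exc:
        raise RuntimeError(f"stage classify_trans_spliced failed: {exc}") from exc

    # ---- SL1/SL2 ---------------------------------------------------------
    try:
        stage("classify_sl")
        if sl_reads is not None:
            sl_rows = {}
            for gid, row in sl_reads.iterrows():
                r = classify_sl(
                    int(row["sl1_count"]), int(row["sl2_count"]),
                    p0=config.p0, alpha=config.alpha, gene_id=str(gid),
                )
                sl_rows[gid] = {
                    "sl_class": r.cls.value,
                    "sl2_fraction": r.sl2_fraction,
                    "p_value": r.p_value,
                }
            sl_df = pd.DataFrame.from_dict(sl_rows, orient="index").sort_index()
            _write_df(sl_df, outdir / "sl_classes.tsv")
            summary.counts["sl_class"] = sl_df["sl_class"].value_counts().to_dict()
    except Exception as exc:
        raise RuntimeError(f"stage classify_sl failed: {exc}") from exc

    # ---- TE model --------------------------------------------------------
    try:
        stage("translatome")
        model = TranslationalEfficiencyModel(counts, control, treatment)
        results = model.fit(
            min_total=config.min_total, fdr=config.fdr, pseudocount=config.pseudocount
        )
        results.to_tsv(outdir / "te_results.tsv")
        n_undef = int(results.table["log2_dte"].isna().sum())
        if n_undef:
            logger.warning("translatome: %d genes with undefined TE", n_undef)
        summary.counts.update(
            genes_tested=results.n_tested,
            genes_filtered=summary.counts["genes_input"] - results.n_tested,
            te_undefined=n_undef,
            te_down=len(results.significant("down", "te")),
            te_up=len(results.significant("up", "te")),
            rna_down=len(results.significant("down", "rna")),
            rna_up=len(results.significant("up", "rna")),
            response_categories=results.category_counts().to_dict(),
        )
        summary.statistics["quasi_dispersion_te"] = results.quasi_dispersion_te
        summary.statistics["quasi_dispersion_rna"] = results.quasi_dispersion_rna
    except Exception as exc:
        raise RuntimeError(f"stage translatome failed: {exc}") from exc

    # ---- oocyte calls ----------------------------------------------------
    if oocyte_ev is not None:
        stage("classify_oocyte")
        oo = {
            gid: classify_oocyte(row["tiling_intensity"], row["cage_tpm"], gid).in_oocyte
            for gid, row in oocyte_ev.iterrows()
        }
        summary.counts["genes_oocyte"] = int(sum(oo.values()))

    # ---- contingency: trans-splicing vs response category ----------------
    try:
        stage("enrichment")
        tested = results.table.index
        ts_flags = {g: ("SL" if ts_df.loc[g, "is_trans_spliced"] else "nonSL") for g in tested}
        cats = results.table["response_category"].to_dict()
        tab = class_contingency(ts_flags, cats)
        _write_df(tab, outdir / "contingency_sl_by_category.tsv", index_name="sl")
        if tab.shape[0] == 2 and tab.shape[1] >= 2:
            chi = chisq_with_residuals(tab.to_numpy())
            summary.statistics["chisq_sl_by_category"] = {
                "statistic": chi.statistic, "df": chi.df, "p": chi.p,
            }
        # the headline comparison: trans-spliced fraction among
        # translation-only vs both (translational + transcriptional) suppression
        down = results.table[results.table["regulation_te"] == "down"]
        t_only = down.index[down["response_category"] == "translation_only"]
        both = down.index[down["response_category"] == "both"]
        if len(t_only) and len(both):
            k1 = sum(ts_df.loc[g, "is_trans_spliced"] for g in t_only)
            k2 = sum(ts_df.loc[g, "is_trans_spliced"] for g in both)
            fr = fisher_exact_2x2(
                [[int(k1), len(t_only) - int(k1)], [int(k2), len(both) - int(k2)]]
            )
            summary.statistics["fisher_translation_only_vs_both"] = {
                "frac_sl_translation_only": k1 / len(t_only),
                "frac_sl_both": k2 / len(both),
                "odds_ratio": fr.odds_ratio,
                "p": fr.p,
            }
        if annotation:
            go = go_overrepresentation(
                sorted(down.index), sorted(tested), annotation
            )
            go_df = pd.DataFrame(
                [
                    {
                        "term": r.term, "k": r.k_selected_annotated, "n": r.n_selected,
                        "K": r.K_universe_annotated, "N": r.N_universe,
                        "p_hyper": r.p_hyper, "fdr": r.fdr,
                    }
                    for r in go
                ]
            )
            if len(go_df):
                go_df = go_df.set_index("term")
                _write_df(go_df, outdir / "go_overrepresentation.tsv", index_name="term")
    except Exception as exc:
        raise RuntimeError(f"stage enrichment failed: {exc}") from exc

    # ---- motif frequencies ----------------------------------------------
    try:
        stage("motifs")
        seqs = _five_prime_sequences(models, genome)
        classes = {
            g: ("down" if results.table.loc[g, "regulation_te"] == "down" else "unaffected")
            for g in tested
        }
        freq, comp, missing = motif_frequency_report(
            classes, seqs, windows=config.motif_windows, min_run=config.min_run
        )
        _write_df(freq, outdir / "motif_frequencies.tsv", index_name="class")
        if len(comp):
            _write_df(comp.set_index("motif"), outdir / "motif_comparisons.tsv", index_name="motif")
        summary.counts["motif_missing_sequences"] = len(missing)
        summary.statistics["motif_frequencies"] = {
            str(cls): {c: float(freq.loc[cls, c]) for c in freq.columns if c != "n_genes"}
            for cls in freq.index
        }
    except Exception as exc:
        raise RuntimeError(f"stage motifs failed: {exc}") from exc

    # consistency: significant <= tested <= input
    assert summary.counts["te_down"] + summary.counts["te_up"] <= summary.counts["genes_tested"]
    assert summary.counts["genes_tested"] <= summary.counts["genes_input"]

    (outdir / "summary.json").write_text(summary.to_json() + "\n")
    return summary
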