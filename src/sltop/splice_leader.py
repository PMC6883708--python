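"""Spliced-leader classifications and 5' oligopyrimidine motif scanners.

Three rule families live here:

* the trans-splice call for a gene — a CAGE-supported acceptor site within
  the gene body or 500 bp upstream, > 1 tag count, and a genomic ``AG``
  immediately 5' of the site in transcript orientation;
* the SL1/SL2 class from per-gene spliced-leader read counts, using the
  25% / 75% fraction thresholds with an exact binomial test;
* TOP-motif scanners: the canonical motif (a 5' cytosine followed by a run
  of 4–14 pyrimidines) and the TOP-like relaxations (a run of >= 5
  pyrimidines starting within 4, or within 15, nucleotides of the TSS).

Pyrimidine means C or T throughout; N (or any other symbol) counts as a
non-pyrimidine. Offsets are 0-based from the 5' base (offset 0 = the TSS
base itself), measured in transcript orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

from scipy import stats

from .io_formats import GeneModel, GenomeSequence, TagRecord

__all__ = [
    "OIKOPLEURA_SL",
    "TransSpliceCall",
    "SLCategory",
    "SLClass",
    "MotifType",
    "MotifHit",
    "classify_trans_spliced",
    "classify_sl",
    "scan_canonical_top",
    "scan_top_like",
    "pyrimidine_stats",
]

#: The 40-nt Oikopleura dioica spliced-leader RNA sequence that is
#: trans-spliced onto mRNA 5' ends. Pyrimidine-enriched (12 of the first 15
#: bases) but begins with an adenine, so it is not a canonical TOP motif.
OIKOPLEURA_SL = "ACTCATCCCATTTTTGAGTCCGATTTCGATTGTCTAACAG"

PYRIMIDINES = frozenset("CT")

UPSTREAM_WINDOW = 500  # bp upstream of the gene start searched for acceptors


# ---------------------------------------------------------------------------
# Trans-splice acceptor classification
# ---------------------------------------------------------------------------


@dataclass
class TransSpliceCall:
    """Evidence-backed trans-splice classification for one gene."""

    gene_id: str
    is_trans_spliced: bool
    supporting_sites: list[tuple[int, int, str]] = field(default_factory=list)
    rule_failures: list[str] = field(default_factory=list)


def _acceptor_dinucleotide(genome: GenomeSequence, gene: GeneModel, pos: int) -> str:
    """The two genomic bases immediately 5' of ``pos`` in transcript
    orientation, read 5'->3' on the transcript strand."""
    seq = genome.chroms[gene.chrom]
    if gene.strand == "+":
        if pos < 2:
            return ""
        return genome.fetch(gene.chrom, pos - 2, pos, "+")
    if pos + 3 > len(seq):
        return ""
    return genome.fetch(gene.chrom, pos + 1, pos + 3, "-")


def classify_trans_spliced(
    gene: GeneModel,
    tags: list[TagRecord],
    genome: GenomeSequence,
    upstream: int = UPSTREAM_WINDOW,
    min_count: int = 2,
) -> TransSpliceCall:
    """Call a gene trans-spliced from strand-aware acceptor-site tags.

    A site qualifies iff (a) it matches the gene strand and lies within the
    gene body or ``upstream`` bp 5' of the gene start in transcript
    orientation, (b) its tag count is >= ``min_count`` (the "> 1 tag count"
    rule), and (c) the two genomic bases immediately 5' of the site in
    transcript orientation read ``AG``. One qualifying site suffices; every
    failed rule is recorded per site.
    """
    if gene.strand == "+":
        lo, hi = gene.start - upstream, gene.end
    else:
        lo, hi = gene.start, gene.end + upstream
    sites: list[tuple[int, int, str]] = []
    failures: list[str] = []
    for tag in tags:
        if tag.chrom != gene.chrom or tag.strand != gene.strand:
            continue
        site_fail: list[str] = []
        if not (lo <= tag.pos < hi):
            site_fail.append("window")
        if tag.count < min_count:
            site_fail.append("tag_count")
        dinuc = _acceptor_dinucleotide(genome, gene, tag.pos)
        if dinuc != "AG":
            site_fail.append("acceptor_motif")
        if site_fail:
            failures.extend(f"{tag.pos}:{f}" for f in site_fail)
        else:
            sites.append((tag.pos, tag.count, dinuc))
    return TransSpliceCall(gene.gene_id, bool(sites), sites, failures)


# ---------------------------------------------------------------------------
# SL1 / SL2 classification
# ---------------------------------------------------------------------------


class SLCategory(str, Enum):
    SL1 = "SL1"
    SL2 = "SL2"
    MIXED = "mixed"
    UNKNOWN = "unknown"
    NON_SL = "nonSL"


@dataclass
class SLClass:
    gene_id: str
    cls: SLCategory
    sl2_fraction: float
    p_value: float  # NaN for nonSL


def classify_sl(
    sl1_count: int,
    sl2_count: int,
    p0: float = 0.5,
    alpha: float = 0.05,
    gene_id: str = "",
) -> SLClass:
    """Classify a gene's spliced-leader usage from SL1/SL2 read counts.

    With n = sl1 + sl2 and f = sl2 / n: genes with f <= 0.25 and one-sided
    exact binomial P(X <= sl2 | n, p0) < alpha are SL1; f >= 0.75 with
    P(X >= sl2 | n, p0) < alpha are SL2; 0.25 < f < 0.75 is mixed; f beyond
    a threshold but with p >= alpha is unknown; n = 0 is nonSL.
    """
    if sl1_count < 0 or sl2_count < 0:
        raise ValueError("SL read counts must be non-negative")
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie strictly between 0 and 1")
    total = sl1_count + sl2_count
    if total == 0:
        return SLClass(gene_id, SLCategory.NON_SL, float("nan"), float("nan"))
    frac = sl2_count / total
    if frac <= 0.25:
        p = float(stats.binom.cdf(sl2_count, total, p0))
        cls = SLCategory.SL1 if p < alpha else SLCategory.UNKNOWN
    elif frac >= 0.75:
        p = float(stats.binom.sf(sl2_count - 1, total, p0))
        cls = SLCategory.SL2 if p < alpha else SLCategory.UNKNOWN
    else:
        p = float("nan")
        cls = SLCategory.MIXED
    return SLClass(gene_id, cls, frac, p)


# ---------------------------------------------------------------------------
# TOP / TOP-like motif scanners
# ---------------------------------------------------------------------------


class MotifType(str, Enum):
    CANONICAL_TOP = "canonical_TOP"
    TOP_LIKE_W4 = "TOP_like_w4"
    TOP_LIKE_W15 = "TOP_like_w15"
    SL_LIKE_PYR = "SL_like_pyr"


@dataclass(frozen=True)
class MotifHit:
    motif_type: MotifType
    start_offset: int
    run_length: int


def _pyrimidine_runs(seq: str) -> list[tuple[int, int]]:
    """Maximal pyrimidine runs as (start_offset, length), left to right."""
    runs: list[tuple[int, int]] = []
    i, n = 0, len(seq)
    while i < n:
        if seq[i] in PYRIMIDINES:
            j = i
            while j < n and seq[j] in PYRIMIDINES:
                j += 1
            runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def scan_canonical_top(seq: str) -> MotifHit | None:
    """Scan for the canonical TOP motif: a 5' cytosine followed by a stretch
    of 4–14 pyrimidines.

    Returns a hit at offset 0 whose run_length counts the cytosine plus the
    following pyrimidine run capped at 14, or None.
    """
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    if seq[0] != "C":
        return None
    run = 0
    for base in seq[1:]:
        if base in PYRIMIDINES:
            run += 1
        else:
            break
    if run < 4:
        return None
    return MotifHit(MotifType.CANONICAL_TOP, 0, min(run, 14) + 1)


def scan_top_like(seq: str, window: int, min_run: int = 5) -> list[MotifHit]:
    """Scan for TOP-like motifs: maximal runs of >= ``min_run`` pyrimidines
    starting within ``window`` nucleotides of the 5' end (offsets 0..window).

    ``window`` is 4 for the strict TOP-like definition and 15 for the relaxed
    one. Hits are reported left to right.
    """
    seq = seq.upper()
    if not seq:
        raise ValueError("empty sequence")
    if window < 0:
        raise ValueError("window must be >= 0")
    mtype = {4: MotifType.TOP_LIKE_W4, 15: MotifType.TOP_LIKE_W15}.get(
        window, MotifType.SL_LIKE_PYR
    )
    return [
        MotifHit(mtype, start, length)
        for start, length in _pyrimidine_runs(seq)
        if length >= min_run and start <= window
    ]


def pyrimidine_stats(seq: str, prefix_len: int) -> tuple[int, float, int]:
    """(count, fraction) of pyrimidines among the first ``prefix_len`` bases,
    plus the longest pyrimidine run over the full sequence."""
    if prefix_len <= 0:
        raise ValueError("prefix_len must be positive")
    if prefix_len > len(seq):
        raise ValueError("prefix_len exceeds sequence length")
    seq = seq.upper()
    count = sum(1 for b in seq[:prefix_len] if b in PYRIMIDINES)
    runs = _pyrimidine_runs(seq)
    longest = max((length for _, length in runs), default=0)
    return count, count / prefix_len, longest
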