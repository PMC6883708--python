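"""Readers, writers and core data containers shared by every analysis stage.

All genomic coordinates are stored 0-based, half-open. GFF3 (1-based,
inclusive) is converted at the parsing boundary; BED is taken as-is. Strand
``+``/``-`` is required everywhere; minus-strand sequence fetches return the
reverse complement so that index 0 of the result is the 5'-most transcript
base.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, NamedTuple, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "GeneModel",
    "GeneModelSet",
    "TagRecord",
    "Sample",
    "CountMatrix",
    "GenomeSequence",
    "read_gene_models",
    "write_gene_models",
    "read_tags",
    "write_tags",
    "read_counts",
    "read_annotation",
    "write_annotation",
    "fetch_sequence",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """A file violated the expected dialect."""


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene span with its dominant transcription start site.

    ``start``/``end`` are 0-based half-open genomic coordinates. ``tss`` is a
    single genomic base position; it need not fall inside [start, end) since
    TSS calls may be annotation-independent.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    tss: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.start < 0 or self.tss < 0:
            raise ValueError(f"{self.gene_id}: negative coordinate")

    @property
    def five_prime(self) -> int:
        """Genomic position of the 5' end of the gene span."""
        return self.start if self.strand == "+" else self.end - 1


class GeneModelSet:
    """Ordered, uniquely keyed collection of :class:`GeneModel`.

    Ordering is deterministic: (chrom, start, gene_id).
    """

    def __init__(self, genes: Iterable[GeneModel]):
        ordered = sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))
        self._genes = ordered
        self._by_id = {}
        for g in ordered:
            if g.gene_id in self._by_id:
                raise FormatError(f"duplicate gene_id {g.gene_id!r}")
            self._by_id[g.gene_id] = g

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self._genes)

    def __len__(self) -> int:
        return len(self._genes)

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self._by_id[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self._genes]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneModelSet) and self._genes == other._genes


_GFF_ATTR_RE = re.compile(r"([^=;]+)=([^;]*)")


def read_gene_models(path: str | Path, dialect: str = "gff3") -> GeneModelSet:
    """Parse gene models from GFF3 or BED12.

    GFF3: only ``gene`` features are read; the ``ID`` attribute supplies
    gene_id and an optional ``tss`` attribute the dominant TSS (defaulting to
    the 5' end of the span). 1-based inclusive coordinates are converted to
    0-based half-open. BED12: chromStart/chromEnd taken as-is; the ``name``
    column is the gene_id and the TSS defaults to the 5' end.
    """
    if dialect not in ("gff3", "bed12"):
        raise ValueError(f"unknown dialect {dialect!r}")
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "gff3":
                    if len(fields) != 9:
                        raise FormatError("expected 9 columns")
                    if fields[2] != "gene":
                        continue
                    chrom, start1, end1, strand = fields[0], fields[3], fields[4], fields[6]
                    start = int(start1) - 1  # GFF3 is 1-based inclusive
                    end = int(end1)
                    attrs = dict(_GFF_ATTR_RE.findall(fields[8]))
                    if "ID" not in attrs:
                        raise FormatError("gene feature lacks ID attribute")
                    gene_id = attrs["ID"]
                    tss = int(attrs["tss"]) if "tss" in attrs else (start if strand == "+" else end - 1)
                else:
                    if len(fields) != 12:
                        raise FormatError("expected 12 columns")
                    chrom, gene_id, strand = fields[0], fields[3], fields[5]
                    start = int(fields[1])
                    end = int(fields[2])
                    tss = start if strand == "+" else end - 1
                genes.append(GeneModel(gene_id, chrom, strand, start, end, tss))
            except (ValueError, FormatError) as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return GeneModelSet(genes)


def write_gene_models(models: GeneModelSet, path: str | Path, dialect: str = "gff3") -> None:
    with open(path, "w") as fh:
        if dialect == "gff3":
            fh.write("##gff-version 3\n")
            for g in models:
                attrs = f"ID={g.gene_id};tss={g.tss}"
                fh.write(
                    f"{g.chrom}\tsltop\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )
        elif dialect == "bed12":
            for g in models:
                size = g.end - g.start
                fh.write(
                    f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}"
                    f"\t{g.start}\t{g.end}\t0\t1\t{size},\t0,\n"
                )
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# CAGE-style tags
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TagRecord:
    """A single-position, strand-aware tag count (CAGE TSS or trans-splice)."""

    chrom: str
    pos: int
    strand: str
    count: int

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError("tag position must be >= 0")
        if self.count < 1:
            raise ValueError("tag count must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


def read_tags(path: str | Path) -> list[TagRecord]:
    """Read a 6-column BED where the score column holds the tag count."""
    tags: list[TagRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected 6 BED columns")
            chrom, start, _end, _name, score, strand = fields[:6]
            try:
                pos = int(start)
                count = int(score)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer field: {exc}") from exc
            if not strand:
                raise FormatError(f"{path}:{lineno}: missing strand")
            try:
                tags.append(TagRecord(chrom, pos, strand, count))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
    return tags


def write_tags(tags: Sequence[TagRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in tags:
            fh.write(f"{t.chrom}\t{t.pos}\t{t.pos + 1}\t.\t{t.count}\t{t.strand}\n")


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------


class Sample(NamedTuple):
    """A sequencing library: (assay, condition, replicate)."""

    assay: str  # "RPF" or "RNA"
    condition: str
    replicate: int

    @property
    def label(self) -> str:
        return f"{self.assay}_{self.condition}_{self.replicate}"


_SAMPLE_RE = re.compile(r"^(RPF|RNA)_(.+)_(\d+)$")


def parse_sample_label(label: str) -> Sample:
    m = _SAMPLE_RE.match(label)
    if m is None:
        raise FormatError(
            f"sample header {label!r} does not follow ASSAY_CONDITION_REP "
            "(assay in RPF/RNA, replicate a positive integer)"
        )
    rep = int(m.group(3))
    if rep < 1:
        raise FormatError(f"replicate index must be >= 1 in {label!r}")
    return Sample(m.group(1), m.group(2), rep)


class CountMatrix:
    """Per-gene integer counts over (assay, condition, replicate) libraries.

    Backed by a pandas DataFrame with gene_id index (sorted) and
    :class:`Sample` columns. Entries are non-negative integers.
    """

    def __init__(self, counts: pd.DataFrame):
        # canonicalise columns to a (assay, condition, replicate) MultiIndex
        # so label-based selection behaves identically however the frame was
        # constructed
        counts = counts.copy()
        counts.columns = pd.MultiIndex.from_tuples(
            [tuple(Sample(*c)) for c in counts.columns],
            names=("assay", "condition", "replicate"),
        )
        if counts.columns.duplicated().any():
            raise FormatError("duplicate sample columns")
        if counts.index.duplicated().any():
            raise FormatError("duplicate gene_id rows")
        if (counts.to_numpy() < 0).any():
            raise FormatError("negative counts are not allowed")
        df = counts.sort_index()
        df.index.name = "gene_id"
        self.df = df.astype("int64")

    @property
    def genes(self) -> list[str]:
        return list(self.df.index)

    @property
    def samples(self) -> list[Sample]:
        # pandas may coerce NamedTuple columns into a MultiIndex of tuples
        return [c if isinstance(c, Sample) else Sample(*c) for c in self.df.columns]

    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.condition, None)
        return list(seen)

    def subset_assay(self, assay: str) -> pd.DataFrame:
        cols = [s for s in self.samples if s.assay == assay]
        return self.df[cols]

    def library_sizes(self) -> pd.Series:
        return self.df.sum(axis=0)

    def to_tsv(self, path: str | Path) -> None:
        out = self.df.copy()
        out.columns = [s.label for s in self.samples]
        with open(path, "w") as fh:
            fh.write("#gene_id\t" + "\t".join(out.columns) + "\n")
            for gid, row in out.iterrows():
                fh.write(gid + "\t" + "\t".join(str(int(v)) for v in row) + "\n")

    def __eq__(self, other: object) -> bool:
        return isinstance(other, CountMatrix) and self.df.equals(other.df)


def read_counts(path: str | Path) -> CountMatrix:
    """Read a TSV count table with an ASSAY_CONDITION_REP header."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header.startswith("#"):
            header = header[1:]
        cols = header.split("\t")
        if len(cols) < 2:
            raise FormatError(f"{path}: header must name gene_id plus samples")
        samples = [parse_sample_label(c) for c in cols[1:]]
        rows: list[list[int]] = []
        index: list[str] = []
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(cols):
                raise FormatError(f"{path}:{lineno}: ragged row ({len(fields)} fields)")
            index.append(fields[0])
            vals: list[int] = []
            for c in fields[1:]:
                try:
                    v = int(c)
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: count {c!r} is not an integer"
                    ) from exc
                if v < 0:
                    raise FormatError(f"{path}:{lineno}: negative count {v}")
                vals.append(v)
            rows.append(vals)
    df = pd.DataFrame(rows, index=index, columns=samples)
    return CountMatrix(df)


# ---------------------------------------------------------------------------
# Annotation map (flat gene -> GO terms)
# ---------------------------------------------------------------------------


def read_annotation(path: str | Path) -> dict[str, set[str]]:
    """Read a flat two-column TSV mapping gene_id to a term identifier."""
    ann: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 or not fields[0] or not fields[1]:
                raise FormatError(f"{path}:{lineno}: expected gene_id<TAB>term")
            ann.setdefault(fields[0], set()).add(fields[1])
    return ann


def write_annotation(ann: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#gene_id\tterm\n")
        for gid in sorted(ann):
            for term in sorted(ann[gid]):
                fh.write(f"{gid}\t{term}\n")


# ---------------------------------------------------------------------------
# Genome sequence
# ---------------------------------------------------------------------------


@dataclass
class GenomeSequence:
    """In-memory genome: chrom -> uppercase sequence string."""

    chroms: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSequence":
        chroms = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls(chroms)

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name in sorted(self.chroms):
                fh.write(f">{name}\n")
                seq = self.chroms[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        return fetch_sequence(self, chrom, start, end, strand)

    def __len__(self) -> int:
        return len(self.chroms)


def fetch_sequence(
    genome: GenomeSequence, chrom: str, start: int, end: int, strand: str = "+"
) -> str:
    """Fetch [start, end) on ``chrom``; minus strand returns the reverse
    complement so position 0 of the result is the 5'-most transcript base."""
    if chrom not in genome.chroms:
        raise KeyError(f"unknown chromosome {chrom!r}")
    seq = genome.chroms[chrom]
    if start < 0 or end > len(seq) or start > end:
        raise IndexError(
            f"interval [{start}, {end}) out of bounds for {chrom} (length {len(seq)})"
        )
    sub = seq[start:end].upper()
    if strand == "+":
        return sub
    if strand == "-":
        return reverse_complement(sub)
    raise ValueError(f"strand must be '+' or '-', got {strand!r}")
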