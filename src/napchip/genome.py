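"""Genome sequences, gene annotation and genomic interval arithmetic.

All coordinates inside the package are 0-based half-open ``[start, end)``.
GFF3 input (1-based inclusive) and any 1-based peak-table dialect are
converted at the I/O boundary, never downstream.

AT-content conventions: ``N`` bases are excluded from the denominator of
every AT fraction; an interval consisting entirely of ``N`` yields ``nan``
("undefined"), which propagates as missing rather than as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "GenomeAssembly",
    "Gene",
    "GeneSet",
    "IntervalSet",
    "GenicPartition",
    "read_genome",
    "read_annotation",
    "derive_intergenic",
    "genic_partition",
    "at_fraction",
    "gc_fraction",
    "pooled_at",
    "per_region_at",
    "write_bed",
]

_VALID_BASES = frozenset("ACGTN")
# IUPAC ambiguity codes collapse to N; anything else is a parse error.
_AMBIGUITY_TO_N = str.maketrans("RYSWKMBDHVU", "NNNNNNNNNNN")


class GenomeFormatError(ValueError):
    """Raised when a sequence or annotation file violates its format contract."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on one contig."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig!r}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Number of bases shared with ``other`` (0 if different contigs)."""
        if self.contig != other.contig:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass
class GenomeAssembly:
    """Named contigs of uppercase A/C/G/T/N sequence."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if not seq:
                raise GenomeFormatError(f"contig {name!r} is empty")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise GenomeFormatError(
                    f"contig {name!r} contains illegal characters {sorted(bad)}"
                )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.contigs.items()}

    @property
    def total_length(self) -> int:
        return sum(self.lengths.values())

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def fetch(self, interval: GenomicInterval) -> str:
        """Sequence of ``interval``; raises if out of bounds."""
        seq = self.contigs.get(interval.contig)
        if seq is None:
            raise KeyError(f"unknown contig {interval.contig!r}")
        if interval.end > len(seq):
            raise ValueError(
                f"interval [{interval.start}, {interval.end}) exceeds contig "
                f"{interval.contig!r} of length {len(seq)}"
            )
        return seq[interval.start : interval.end]

    def to_fasta(self, path: str | Path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.contigs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


def _clean_sequence(raw: str, record_id: str) -> str:
    seq = raw.upper().translate(_AMBIGUITY_TO_N)
    bad = set(seq) - _VALID_BASES
    if bad:
        raise GenomeFormatError(
            f"record {record_id!r} contains illegal characters {sorted(bad)}"
        )
    return seq


def read_genome(path: str | Path) -> GenomeAssembly:
    """Read a (multi-record, possibly line-wrapped) FASTA file.

    Sequences are uppercased, IUPAC ambiguity codes are mapped to ``N`` and
    duplicate record IDs are rejected.
    """
    contigs: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in contigs:
            raise GenomeFormatError(f"duplicate contig ID {record.id!r}")
        contigs[record.id] = _clean_sequence(str(record.seq), record.id)
    if not contigs:
        raise GenomeFormatError(f"no FASTA records found in {path}")
    return GenomeAssembly(contigs)


@dataclass(frozen=True)
class Gene:
    interval: GenomicInterval
    locus_tag: str
    product: str = ""


@dataclass
class GeneSet:
    """Annotated gene features with unique locus tags."""

    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gene in self.genes:
            if gene.locus_tag in seen:
                raise GenomeFormatError(f"duplicate locus tag {gene.locus_tag!r}")
            seen.add(gene.locus_tag)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)

    def intervals(self) -> list[GenomicInterval]:
        return [g.interval for g in self.genes]


def read_annotation(
    path: str | Path,
    genome: GenomeAssembly,
    feature_types: Iterable[str] = ("gene",),
) -> GeneSet:
    """Read gene features from GFF3, converting 1-based inclusive coordinates
    to the internal 0-based half-open convention.

    Features on unknown contigs or outside contig bounds are errors; a
    missing locus_tag gets a synthetic ID with a warning.
    """
    import gffutils

    feature_types = set(feature_types)
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[Gene] = []
    n_anon = 0
    for feat in db.all_features():
        if feat.featuretype not in feature_types:
            continue
        if feat.seqid not in genome:
            raise GenomeFormatError(
                f"feature {feat.id!r} references unknown contig {feat.seqid!r}"
            )
        start, end = feat.start - 1, feat.end  # GFF3 1-based inclusive
        if not 0 <= start < end <= genome.lengths[feat.seqid]:
            raise GenomeFormatError(
                f"feature {feat.id!r} at [{feat.start}, {feat.end}] is outside "
                f"contig {feat.seqid!r}"
            )
        tags = feat.attributes.get("locus_tag")
        if tags:
            locus_tag = tags[0]
        else:
            n_anon += 1
            locus_tag = f"feature_{n_anon:05d}"
            warnings.warn(
                f"feature at {feat.seqid}:{feat.start}-{feat.end} has no "
                f"locus_tag; assigned {locus_tag!r}"
            )
        product = (feat.attributes.get("product") or [""])[0]
        strand = feat.strand if feat.strand in ("+", "-") else "."
        genes.append(
            Gene(GenomicInterval(feat.seqid, start, end, strand), locus_tag, product)
        )
    return GeneSet(genes)


def _merge_sorted(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/abutting strand-ignored intervals (input any order)."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.contig, x.start, x.end)):
        if merged and merged[-1].contig == iv.contig and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.contig, last.start, iv.end)
        else:
            merged.append(GenomicInterval(iv.contig, iv.start, iv.end))
    return merged


@dataclass
class IntervalSet:
    """Sorted, non-overlapping, strand-ignored intervals with a role label."""

    intervals: list[GenomicInterval]
    role: str = ""

    @classmethod
    def from_intervals(
        cls, intervals: Iterable[GenomicInterval], role: str = ""
    ) -> "IntervalSet":
        return cls(_merge_sorted(list(intervals)), role)

    def __post_init__(self) -> None:
        for prev, cur in zip(self.intervals, self.intervals[1:]):
            if prev.contig == cur.contig and cur.start < prev.end:
                raise ValueError("intervals overlap; use IntervalSet.from_intervals")
        # per-contig coordinate arrays for fast overlap queries
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        for iv in self.intervals:
            self._starts.setdefault(iv.contig, []).append(iv.start)  # type: ignore[attr-defined]
            self._ends.setdefault(iv.contig, []).append(iv.end)  # type: ignore[attr-defined]
        self._starts = {c: np.asarray(v) for c, v in self._starts.items()}
        self._ends = {c: np.asarray(v) for c, v in self._ends.items()}

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    @property
    def total_length(self) -> int:
        return sum(iv.width for iv in self.intervals)

    def overlap_bp(self, query: GenomicInterval) -> int:
        """Total bases of ``query`` covered by this set."""
        starts = self._starts.get(query.contig)
        if starts is None:
            return 0
        ends = self._ends[query.contig]
        lo = int(np.searchsorted(ends, query.start, side="right"))
        hi = int(np.searchsorted(starts, query.end, side="left"))
        if hi <= lo:
            return 0
        s = np.maximum(starts[lo:hi], query.start)
        e = np.minimum(ends[lo:hi], query.end)
        return int(np.maximum(e - s, 0).sum())

    def complement(self, genome: GenomeAssembly, role: str = "") -> "IntervalSet":
        out: list[GenomicInterval] = []
        for contig, length in genome.lengths.items():
            pos = 0
            for iv in self.intervals:
                if iv.contig != contig:
                    continue
                if iv.start > pos:
                    out.append(GenomicInterval(contig, pos, iv.start))
                pos = max(pos, iv.end)
            if pos < length:
                out.append(GenomicInterval(contig, pos, length))
        return IntervalSet(out, role)


@dataclass
class GenicPartition:
    """Complementary coding/intergenic partition of a genome."""

    coding: IntervalSet
    intergenic: IntervalSet


def genic_partition(genes: GeneSet, genome: GenomeAssembly) -> GenicPartition:
    """Merge gene intervals (strand ignored) and complement per contig.

    Coding length + intergenic length equals genome length on every contig.
    """
    for gene in genes:
        if gene.interval.contig not in genome:
            raise GenomeFormatError(
                f"gene {gene.locus_tag!r} on unknown contig {gene.interval.contig!r}"
            )
        if gene.interval.end > genome.lengths[gene.interval.contig]:
            raise GenomeFormatError(f"gene {gene.locus_tag!r} out of contig bounds")
    coding = IntervalSet.from_intervals(genes.intervals(), role="coding")
    intergenic = coding.complement(genome, role="intergenic")
    return GenicPartition(coding=coding, intergenic=intergenic)


def derive_intergenic(genes: GeneSet, genome: GenomeAssembly) -> IntervalSet:
    """Intergenic complement of the merged gene set (see :func:`genic_partition`)."""
    return genic_partition(genes, genome).intergenic


def _at_counts(seq: str) -> tuple[int, int]:
    """(#A+#T, #unambiguous bases) for a sequence slice."""
    a = seq.count("A") + seq.count("T")
    n_valid = len(seq) - seq.count("N")
    return a, n_valid


def at_fraction(genome: GenomeAssembly, interval: GenomicInterval) -> float:
    """AT fraction of an interval; ``nan`` if every base is N."""
    at, valid = _at_counts(genome.fetch(interval))
    return at / valid if valid else float("nan")


def gc_fraction(genome: GenomeAssembly, interval: GenomicInterval) -> float:
    at, valid = _at_counts(genome.fetch(interval))
    return (valid - at) / valid if valid else float("nan")


def pooled_at(genome: GenomeAssembly, interval_set: IntervalSet) -> float:
    """Length-weighted AT fraction over the whole set (counts pooled, then divided)."""
    if len(interval_set) == 0:
        raise ValueError("empty interval set")
    at_total = valid_total = 0
    for iv in interval_set:
        at, valid = _at_counts(genome.fetch(iv))
        at_total += at
        valid_total += valid
    return at_total / valid_total if valid_total else float("nan")


def per_region_at(genome: GenomeAssembly, interval_set: IntervalSet) -> np.ndarray:
    """One AT fraction per interval, in set order (``nan`` for all-N intervals)."""
    if len(interval_set) == 0:
        raise ValueError("empty interval set")
    return np.array([at_fraction(genome, iv) for iv in interval_set])


def write_bed(interval_set: IntervalSet, path: str | Path, name_prefix: str = "") -> None:
    """Write the set as BED (0-based half-open, matching internal coordinates)."""
    prefix = name_prefix or interval_set.role or "region"
    with open(path, "w") as fh:
        for i, iv in enumerate(interval_set, start=1):
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{prefix}_{i}\n")
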