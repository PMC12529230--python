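"""Pairwise protein alignment identity/similarity with residue-class scoring.

Similarity is scored against a partition of the 20 amino acids into
physicochemical classes; the default partition is: basic (K, R, H), acidic
(D, E), polar uncharged (S, T, N, Q), hydrophobic (A, V, I, L, M, F, Y, W)
and special cases (C, G, P).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
GAP = "-"

DEFAULT_GROUPS: dict[str, str] = {
    "basic": "KRH",
    "acidic": "DE",
    "polar_uncharged": "STNQ",
    "hydrophobic": "AVILMFYW",
    "special": "CGP",
}


@dataclass(frozen=True)
class SimilarityGroups:
    """Disjoint named residue classes covering all 20 amino acids."""

    groups: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_GROUPS))

    def __post_init__(self) -> None:
        letters = "".join(self.groups.values())
        if len(letters) != len(set(letters)):
            raise ValueError("residue classes are not disjoint")
        if set(letters) != AMINO_ACIDS:
            missing = AMINO_ACIDS - set(letters)
            extra = set(letters) - AMINO_ACIDS
            raise ValueError(
                f"classes must cover exactly the 20 amino acids "
                f"(missing {sorted(missing)}, extra {sorted(extra)})"
            )

    def class_of(self, residue: str) -> str | None:
        for name, members in self.groups.items():
            if residue in members:
                return name
        return None

    def same_group(self, a: str, b: str) -> bool:
        cls = self.class_of(a)
        return cls is not None and cls == self.class_of(b)


@dataclass(frozen=True)
class AlignmentScore:
    identity_percent: float
    similarity_percent: float
    n_columns: int
    denominator: str  # "all_columns" or "ungapped_columns"


def identity_similarity(
    seq_a: str,
    seq_b: str,
    groups: SimilarityGroups | None = None,
    denominator: str = "all_columns",
) -> AlignmentScore:
    """Percent identity and similarity of two rows of a pairwise alignment.

    Identity counts columns with identical non-gap residues; similarity
    additionally counts non-identical residue pairs from the same class.
    ``denominator`` is either every alignment column ("all_columns", gaps
    counting as mismatch/dissimilar) or only gap-free columns
    ("ungapped_columns"); the choice is recorded in the result.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError(
            f"aligned rows differ in length ({len(seq_a)} vs {len(seq_b)})"
        )
    if not seq_a:
        raise ValueError("empty alignment")
    if denominator not in ("all_columns", "ungapped_columns"):
        raise ValueError(f"unknown denominator mode {denominator!r}")
    groups = groups or SimilarityGroups()

    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    identical = similar = ungapped = 0
    for a, b in zip(seq_a, seq_b):
        gapped = GAP in (a, b)
        if not gapped:
            ungapped += 1
            if a == b:
                identical += 1
                similar += 1
            elif groups.same_group(a, b):
                similar += 1
    denom = len(seq_a) if denominator == "all_columns" else ungapped
    if denom == 0:
        raise ValueError("alignment has no scorable columns")
    return AlignmentScore(
        identity_percent=100.0 * identical / denom,
        similarity_percent=100.0 * similar / denom,
        n_columns=len(seq_a),
        denominator=denominator,
    )


def read_pairwise_alignment(path: str | Path) -> tuple[str, str]:
    """Read an aligned FASTA with exactly two rows of equal length."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError(f"expected exactly 2 aligned records, got {len(records)}")
    a, b = (str(r.seq).upper() for r in records)
    if len(a) != len(b):
        raise ValueError("aligned records differ in length")
    return a, b
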