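"""Structured alignments: aligned sequences bound to a consensus structure.

File formats: aligned FASTA (gap '-'); structure as a single dot-bracket
line (Vienna convention) or a FASTA-like record whose sequence is the
dot-bracket string; optional exclusion mask as whitespace-separated
1-based inclusive ranges (e.g. "12-40 95 210-230").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .structure import IUPAC, StructureError, parse_dot_bracket


class AlignmentError(ValueError):
    pass


@dataclass
class StructuredAlignment:
    """Aligned rRNA sequences plus per-column pairing map and exclusion mask.

    ``matrix`` holds one uppercase character per cell (T normalized to U);
    ``pairs`` is a symmetric map column -> partner; ``excluded`` the
    0-based mask; ``partition_labels`` an optional per-column gene tag
    (e.g. SSU / LSU).
    """

    taxa: list
    matrix: np.ndarray
    pairs: dict = field(default_factory=dict)
    excluded: frozenset = frozenset()
    partition_labels: list | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix)
        if self.matrix.ndim != 2:
            raise AlignmentError("matrix must be 2-D (taxa x columns)")
        if len(self.taxa) != self.matrix.shape[0]:
            raise AlignmentError(
                f"{len(self.taxa)} labels but {self.matrix.shape[0]} rows")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate sequence labels")
        self.excluded = frozenset(self.excluded)
        self.validate()

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def validate(self):
        bad = set(np.unique(self.matrix)) - set(IUPAC)
        if bad:
            rows, cols = np.where(np.isin(self.matrix, sorted(bad)))
            raise AlignmentError(
                f"non-IUPAC character {self.matrix[rows[0], cols[0]]!r} in "
                f"sequence {self.taxa[rows[0]]!r}, column {cols[0] + 1}")
        L = self.length
        for i, j in self.pairs.items():
            if not (0 <= i < L and 0 <= j < L):
                raise AlignmentError(f"pair column {i}<->{j} outside alignment")
            if self.pairs.get(j) != i or i == j:
                raise AlignmentError(f"pairing map not symmetric at {i}<->{j}")
        if any(not 0 <= c < L for c in self.excluded):
            raise AlignmentError("excluded column outside alignment")
        if self.partition_labels is not None and len(self.partition_labels) != L:
            raise AlignmentError("partition_labels length mismatch")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_sequences(cls, taxa, sequences, structure=None, excluded=(),
                       partition_labels=None) -> "StructuredAlignment":
        seqs = [s.upper().replace("T", "U") for s in sequences]
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise AlignmentError(f"unequal row lengths: {sorted(lengths)}")
        matrix = np.array([list(s) for s in seqs], dtype="<U1")
        pairs = {}
        if structure is not None:
            text = structure.strip()
            if len(text) != matrix.shape[1]:
                raise AlignmentError(
                    f"structure length {len(text)} != alignment length "
                    f"{matrix.shape[1]}")
            pairs = parse_dot_bracket(text)
        return cls(taxa=list(taxa), matrix=matrix, pairs=pairs,
                   excluded=frozenset(excluded),
                   partition_labels=list(partition_labels) if partition_labels else None)

    @classmethod
    def from_files(cls, fasta_path, structure_path=None, mask_path=None,
                   partition_labels=None) -> "StructuredAlignment":
        taxa, seqs = read_fasta(fasta_path)
        structure = read_structure(structure_path) if structure_path else None
        excluded = read_mask(mask_path) if mask_path else frozenset()
        return cls.from_sequences(taxa, seqs, structure=structure,
                                  excluded=excluded,
                                  partition_labels=partition_labels)

    # -- derived views ------------------------------------------------------

    def structure_string(self) -> str:
        from .structure import pairs_to_dot_bracket
        return pairs_to_dot_bracket(self.pairs, self.length)

    def row(self, name: str) -> str:
        return "".join(self.matrix[self.taxa.index(name)])

    def subset_taxa(self, names) -> "StructuredAlignment":
        names = list(names)
        missing = [n for n in names if n not in self.taxa]
        if missing:
            raise AlignmentError(f"unknown taxa: {missing}")
        idx = [self.taxa.index(n) for n in names]
        return StructuredAlignment(
            taxa=names, matrix=self.matrix[idx],
            pairs=dict(self.pairs), excluded=self.excluded,
            partition_labels=self.partition_labels)

    def to_fasta(self) -> str:
        out = StringIO()
        for name, row in zip(self.taxa, self.matrix):
            out.write(f">{name}\n{''.join(row)}\n")
        return out.getvalue()


# ---------------------------------------------------------------------------
# file readers

def read_fasta(path):
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no sequences in {path}")
    return [r.id for r in records], [str(r.seq) for r in records]


def read_structure(path) -> str:
    """Single dot-bracket line, or a FASTA-like record holding one."""
    text = Path(path).read_text()
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise StructureError(f"empty structure file {path}")
    if lines[0].startswith(">"):
        lines = lines[1:]
        if not lines:
            raise StructureError(f"structure record without body in {path}")
    return "".join(lines)


def read_mask(path) -> frozenset:
    """Whitespace-separated 1-based inclusive ranges -> 0-based column set."""
    cols = set()
    for token in Path(path).read_text().split():
        if "-" in token:
            lo, hi = token.split("-", 1)
            lo, hi = int(lo), int(hi)
        else:
            lo = hi = int(token)
        if lo < 1 or hi < lo:
            raise AlignmentError(f"bad mask range {token!r}")
        cols.update(range(lo - 1, hi))
    return frozenset(cols)


def write_fasta(aln: StructuredAlignment, path):
    Path(path).write_text(aln.to_fasta())
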