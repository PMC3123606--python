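"""Secondary-structure parsing, doublet encoding and alignment partitioning.

A consensus secondary structure (Vienna dot-bracket, one character per
alignment column) splits an rRNA alignment into a stem partition of paired
columns -- analysed as doublet sites under a 6/7/16-state model -- and loop
partitions of unpaired columns analysed as independent nucleotide sites.

All column indices are 0-based internally; user-facing reports are 1-based.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

from .models import CANONICAL_PAIRS, PAIR6, STATES16

if TYPE_CHECKING:  # pragma: no cover
    from .alignment import StructuredAlignment

log = logging.getLogger(__name__)


class StructureError(ValueError):
    pass


class EncodingError(ValueError):
    pass


#: IUPAC nucleotide codes mapped to the compatible {A,C,G,U} set.
#: T is read as U; gaps and N carry no information (full ambiguity).
IUPAC = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG",
    "N": "ACGU", "-": "ACGU", "?": "ACGU", ".": "ACGU",
}

_NUC_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}
_OPENERS = "([{<"
_CLOSERS = ")]}>"
_UNPAIRED = ".,-"


def nucleotide_set(ch: str, context: str = "") -> str:
    """Compatible nucleotides for one alignment character."""
    try:
        return IUPAC[ch.upper()]
    except KeyError:
        where = f" at {context}" if context else ""
        raise EncodingError(f"non-IUPAC character {ch!r}{where}") from None


def parse_dot_bracket(text: str) -> dict:
    """Parse a dot-bracket string into a symmetric pairing map.

    Supports up to four bracket tiers '()', '[]', '{}', '<>' (pseudoknots
    must use distinct tiers; within a tier matching is strict stack
    nesting).  Returns ``{i: j, j: i}`` for every pair, with nothing for
    unpaired columns.
    """
    stacks: list[list[int]] = [[] for _ in _OPENERS]
    pairs: dict[int, int] = {}
    for pos, ch in enumerate(text.strip()):
        if ch in _UNPAIRED:
            continue
        tier = _OPENERS.find(ch)
        if tier >= 0:
            stacks[tier].append(pos)
            continue
        tier = _CLOSERS.find(ch)
        if tier >= 0:
            if not stacks[tier]:
                raise StructureError(
                    f"unbalanced {ch!r} at position {pos} "
                    f"(tier {_OPENERS[tier]}{_CLOSERS[tier]})")
            i = stacks[tier].pop()
            pairs[i] = pos
            pairs[pos] = i
            continue
        raise StructureError(f"unexpected character {ch!r} at position {pos}")
    for tier, stack in enumerate(stacks):
        if stack:
            raise StructureError(
                f"unbalanced {_OPENERS[tier]!r} at position {stack[0]} "
                f"(tier {_OPENERS[tier]}{_CLOSERS[tier]})")
    return pairs


def pairs_to_dot_bracket(pairs: dict, length: int) -> str:
    """Serialize a pairing map back to dot-bracket notation.

    Nested pairs go to tier '()'; crossing pairs are pushed to further
    tiers (up to four).
    """
    ordered = sorted({(min(i, j), max(i, j)) for i, j in pairs.items()})
    chars = ["."] * length
    tiers: list[list[tuple[int, int]]] = [[] for _ in _OPENERS]
    for i, j in ordered:
        if not (0 <= i < j < length):
            raise StructureError(f"pair ({i},{j}) outside [0,{length})")
        for tier, assigned in enumerate(tiers):
            if all(not (a < i < b < j or i < a < j < b) for a, b in assigned):
                assigned.append((i, j))
                chars[i] = _OPENERS[tier]
                chars[j] = _CLOSERS[tier]
                break
        else:
            raise StructureError(f"pair ({i},{j}): more than 4 crossing tiers")
    return "".join(chars)


# ---------------------------------------------------------------------------
# doublet encoding

def encode_doublet(a: str, b: str, n_states: int, context: str = "") -> tuple:
    """Doublet state indices compatible with characters ``a``, ``b``.

    6-state: canonical pairs only; a mismatch carries no information and
    maps to full ambiguity.  7-state: every mismatch maps to the single MM
    state.  16-state: every ordered nucleotide pair is a distinct state.
    A gap or N in either member yields full ambiguity in every space.
    """
    if n_states not in (6, 7, 16):
        raise EncodingError(f"doublet state space must be 6, 7 or 16, got {n_states}")
    sa = nucleotide_set(a, context)
    sb = nucleotide_set(b, context)
    if len(sa) == 4 or len(sb) == 4:
        # gap / N in either member: the doublet carries no information
        return tuple(range(n_states))
    states: set[int] = set()
    for x in sa:
        for y in sb:
            d = x + y
            if n_states == 16:
                states.add(STATES16.index(d))
            elif d in CANONICAL_PAIRS:
                states.add(PAIR6.index(d))
            elif n_states == 7:
                states.add(6)
            else:  # mismatch in 6-state space: no information
                states.update(range(6))
        if len(states) == n_states:
            break
    return tuple(sorted(states))


def encode_nucleotide(ch: str, context: str = "") -> tuple:
    """4-state indices (A,C,G,U) compatible with one character."""
    return tuple(_NUC_INDEX[x] for x in nucleotide_set(ch, context))


# ---------------------------------------------------------------------------
# partitioning

@dataclass
class PartitionedData:
    """Column bookkeeping for one structured alignment.

    Invariant: ``n_loop_columns + 2 * n_stem_pairs + len(excluded) == length``
    and no column appears in two partitions.
    """

    alignment: "StructuredAlignment"
    loop_partitions: list          # [(gene_tag, [column, ...]), ...]
    stem_pairs: list               # [(i, j), ...] with i < j
    excluded: frozenset            # effective exclusion (mask + pair spill-over)
    length: int
    dropped_pairs: list = field(default_factory=list)

    @property
    def n_loop_columns(self) -> int:
        return sum(len(cols) for _, cols in self.loop_partitions)

    @property
    def n_stem_pairs(self) -> int:
        return len(self.stem_pairs)

    @property
    def loop_columns(self) -> list:
        return [c for _, cols in self.loop_partitions for c in cols]

    @property
    def stem_columns(self) -> list:
        return sorted(c for pair in self.stem_pairs for c in pair)

    def loop_matrix(self):
        return self.alignment.matrix[:, self.loop_columns]

    def stem_matrix(self):
        """Stem columns as plain nucleotide columns (for DNA-setup use)."""
        return self.alignment.matrix[:, self.stem_columns]

    def combined_matrix(self):
        cols = sorted(self.loop_columns + self.stem_columns)
        return self.alignment.matrix[:, cols]

    def check_invariants(self):
        n = self.n_loop_columns + 2 * self.n_stem_pairs + len(self.excluded)
        if n != self.length:
            raise StructureError(
                f"column accounting broken: {self.n_loop_columns} loops + "
                f"2*{self.n_stem_pairs} stems + {len(self.excluded)} excluded "
                f"!= {self.length}")
        seen = set(self.excluded)
        for c in self.loop_columns + self.stem_columns:
            if c in seen:
                raise StructureError(f"column {c} assigned twice")
            seen.add(c)

    def report(self) -> str:
        """TSV partition report (1-based inclusive column references)."""
        lines = ["partition\tcolumns\tdetail"]
        for tag, cols in self.loop_partitions:
            lines.append(f"loop:{tag}\t{len(cols)}\t"
                         + ",".join(str(c + 1) for c in cols[:20])
                         + ("..." if len(cols) > 20 else ""))
        lines.append(f"stems\t{2 * self.n_stem_pairs}\t"
                     + ",".join(f"{i + 1}-{j + 1}" for i, j in self.stem_pairs[:20])
                     + ("..." if self.n_stem_pairs > 20 else ""))
        lines.append(f"excluded\t{len(self.excluded)}\t"
                     + ",".join(str(c + 1) for c in sorted(self.excluded)[:20])
                     + ("..." if len(self.excluded) > 20 else ""))
        return "\n".join(lines) + "\n"


def partition_alignment(aln: "StructuredAlignment") -> PartitionedData:
    """Split an alignment into loop and stem partitions.

    A pair with one member in the exclusion mask is wholly excluded (the
    partner column joins the effective mask) and logged; loop columns are
    grouped by gene tag when the alignment carries per-column labels.
    """
    length = aln.length
    excluded = set(aln.excluded)
    pairs = sorted({(min(i, j), max(i, j)) for i, j in aln.pairs.items()})
    dropped = []
    stem_pairs = []
    for i, j in pairs:
        if i in excluded or j in excluded:
            dropped.append((i, j))
            excluded.update((i, j))
        else:
            stem_pairs.append((i, j))
    if dropped:
        log.warning("%d stem pair(s) overlap the exclusion mask and were "
                    "wholly excluded", len(dropped))
    paired_cols = {c for pair in stem_pairs for c in pair}
    labels = aln.partition_labels or ["ALL"] * length
    loop_by_tag: dict[str, list[int]] = {}
    for c in range(length):
        if c in excluded or c in paired_cols:
            continue
        loop_by_tag.setdefault(labels[c], []).append(c)
    pd = PartitionedData(alignment=aln,
                         loop_partitions=sorted(loop_by_tag.items()),
                         stem_pairs=stem_pairs,
                         excluded=frozenset(excluded),
                         length=length,
                         dropped_pairs=dropped)
    pd.check_invariants()
    return pd
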