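"""Fragment multiple alignment and consensus calling.

The chain fragments of one protein are multiply aligned with a deterministic
center-star heuristic: the fragment with the greatest summed pairwise global
score against all others becomes the center; every other fragment is aligned
pairwise to the center (end gaps free, since fragments are windows of one
protein) and the pairwise gaps are merged under "once a gap, always a gap".
A per-column residue/gap frequency matrix is tallied from the alignment, and
the consensus emits the most frequent non-gap residue of every column whose
gap fraction does not exceed a threshold (ties broken alphabetically).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .align import GAP, SubstitutionMatrix, default_matrix, needleman_wunsch
from .alphabet import AA, N_AA
from .errors import EmptyConsensusError, EmptyInputError, InvalidInputError
from .fragsim import FragmentSet

#: Columns with a gap fraction above this are dropped from the consensus: a
#: majority-gap column has no meaningful "most prevalent amino acid".
DEFAULT_MAX_GAP_FRACTION = 0.5


@dataclass
class MultipleAlignment:
    """Rows of gapped sequences of equal length."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if not self.rows:
            raise EmptyInputError("alignment has no rows")
        n = len(self.rows[0])
        if any(len(r) != n for r in self.rows):
            raise InvalidInputError("alignment rows must have equal length")
        if len(self.ids) != len(self.rows):
            raise InvalidInputError("one id per row required")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def degapped(self, i: int) -> str:
        return self.rows[i].replace(GAP, "")


@dataclass
class FrequencyMatrix:
    """Per-column residue and gap counts over an alignment."""

    counts: np.ndarray  # (n_columns, 21): 20 residues + gap
    n_rows: int

    GAP_COL = N_AA

    @property
    def n_columns(self) -> int:
        return self.counts.shape[0]

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.n_rows

    def gap_fraction(self, col: int) -> float:
        return self.counts[col, self.GAP_COL] / self.n_rows


@dataclass
class ConsensusSequence:
    """Consensus calls over the gap-filtered alignment columns."""

    sequence: str
    support: list[float] = field(default_factory=list)  # agreeing / non-gap rows per column
    kept_columns: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not (len(self.sequence) == len(self.support) == len(self.kept_columns)):
            raise InvalidInputError("sequence, support and kept_columns must align")

    def __len__(self) -> int:
        return len(self.sequence)


def _pairwise_to_center(center: str, other: str, matrix, gap_open, gap_extend):
    """Align ``other`` to ``center``; return per-center-slot insertions and
    the character (residue or gap) of ``other`` at each center residue."""
    aln = needleman_wunsch(other, center, matrix, gap_open, gap_extend, end_gaps_free=True)
    ins: list[list[str]] = [[] for _ in range(len(center) + 1)]
    at: list[str] = []
    c = 0
    for oc, cc in zip(aln.aligned_query, aln.aligned_subject):
        if cc == GAP:
            ins[c].append(oc)
        else:
            at.append(oc)
            c += 1
    return ins, at


def center_star_align(
    fragments: FragmentSet | list,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> MultipleAlignment:
    """Deterministic center-star multiple alignment of fragments.

    The center maximises the summed pairwise global score (end gaps free);
    ties go to the longest fragment, then the lexicographically smallest id.
    Input row order is preserved in the output.
    """
    frags = list(fragments)
    if not frags:
        raise EmptyInputError("cannot align an empty fragment set")
    matrix = matrix or default_matrix()
    n = len(frags)
    if n == 1:
        return MultipleAlignment([frags[0].id], [frags[0].sequence])

    scores = np.zeros(n)
    for i in range(n):
        for j in range(i + 1, n):
            s = needleman_wunsch(
                frags[i].sequence, frags[j].sequence, matrix, gap_open, gap_extend, True
            ).score
            scores[i] += s
            scores[j] += s
    order = sorted(range(n), key=lambda k: (-scores[k], -len(frags[k]), frags[k].id))
    ci = order[0]
    center = frags[ci].sequence

    per_row = {}
    for k in range(n):
        if k == ci:
            continue
        per_row[k] = _pairwise_to_center(center, frags[k].sequence, matrix, gap_open, gap_extend)

    slots = [0] * (len(center) + 1)
    for ins, _ in per_row.values():
        for c, lst in enumerate(ins):
            slots[c] = max(slots[c], len(lst))

    rows = []
    for k in range(n):
        if k == ci:
            parts = []
            for c in range(len(center)):
                parts.append(GAP * slots[c] + center[c])
            parts.append(GAP * slots[len(center)])
            rows.append("".join(parts))
        else:
            ins, at = per_row[k]
            parts = []
            for c in range(len(center)):
                pad = ins[c] + [GAP] * (slots[c] - len(ins[c]))
                parts.append("".join(pad) + at[c])
            pad = ins[len(center)] + [GAP] * (slots[len(center)] - len(ins[len(center)]))
            parts.append("".join(pad))
            rows.append("".join(parts))
    return MultipleAlignment([f.id for f in frags], rows)


def frequency_matrix(msa: MultipleAlignment) -> FrequencyMatrix:
    """Tally residues and gaps per column; frequencies are counts / n_rows."""
    counts = np.zeros((msa.n_columns, N_AA + 1), dtype=np.int64)
    index = {a: i for i, a in enumerate(AA)}
    index[GAP] = N_AA
    for row in msa.rows:
        for c, ch in enumerate(row):
            if ch not in index:
                raise InvalidInputError(f"unexpected character {ch!r} in alignment")
            counts[c, index[ch]] += 1
    return FrequencyMatrix(counts, msa.n_rows)


def consensus_call(
    freq: FrequencyMatrix,
    max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION,
    tie_break: str = "alphabetical",
) -> ConsensusSequence:
    """Call the most prevalent residue of every sufficiently gap-free column.

    Columns whose gap fraction exceeds ``max_gap_fraction`` are dropped; ties
    between equally frequent residues are broken alphabetically (the only
    supported policy).  Support is the fraction of non-gap rows agreeing
    with the call.
    """
    if not (0.0 <= max_gap_fraction <= 1.0):
        raise InvalidInputError("max_gap_fraction must be in [0, 1]")
    if tie_break != "alphabetical":
        raise InvalidInputError(f"unknown tie_break policy {tie_break!r}")
    seq = []
    support = []
    kept = []
    for c in range(freq.n_columns):
        if freq.gap_fraction(c) > max_gap_fraction:
            continue
        res_counts = freq.counts[c, :N_AA]
        non_gap = int(res_counts.sum())
        if non_gap == 0:
            continue
        best = int(np.argmax(res_counts))  # argmax takes the first (alphabetical) max
        seq.append(AA[best])
        support.append(res_counts[best] / non_gap)
        kept.append(c)
    if not seq:
        raise EmptyConsensusError("every column was gap-dominated; no consensus")
    return ConsensusSequence("".join(seq), support, kept)


def consensus_from_fragments(
    fragments: FragmentSet,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    max_gap_fraction: float = DEFAULT_MAX_GAP_FRACTION,
) -> ConsensusSequence:
    """Convenience pipeline: align → frequency matrix → consensus."""
    return consensus_call(
        frequency_matrix(center_star_align(fragments, matrix, gap_open, gap_extend)),
        max_gap_fraction,
    )
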