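"""Pairwise alignment and local database search.

Global alignment follows the EMBOSS Needle conventions (BLOSUM62, gap open
10.0 / extend 0.5, end gaps free by default; identity and similarity are
percentages over *all* alignment columns, "similar" meaning substitution
score > 0).  Local search uses full Smith–Waterman with BLAST protein
defaults (BLOSUM62, open 11 / extend 1) and Karlin–Altschul statistics
E = K·m·n·exp(−λS) with the published gapped BLOSUM62/11,1 constants.

The unknown residue ``X`` scores 0 against everything and is counted as
neither identical nor similar.  Coordinates are 0-based half-open
internally; the I/O layer converts to 1-based closed in files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np

from . import _dp
from .alphabet import AA, N_AA, X_INDEX, encode
from .errors import InvalidInputError, InvalidParameterError

if TYPE_CHECKING:  # pragma: no cover
    from .fragsim import ProteomeDB

GAP = "-"

#: Published Karlin–Altschul constants for gapped BLOSUM62, open 11 / extend 1.
DEFAULT_LAMBDA = 0.267
DEFAULT_K = 0.041

#: EMBOSS Needle global-alignment defaults.
NEEDLE_GAP_OPEN = 10.0
NEEDLE_GAP_EXTEND = 0.5
#: BLAST protein local-search defaults.
BLAST_GAP_OPEN = 11.0
BLAST_GAP_EXTEND = 1.0
DEFAULT_MAX_EVALUE = 10.0
DEFAULT_TOP_N = 100


class SubstitutionMatrix:
    """A symmetric 20×20 integer residue scoring matrix.

    ``X`` is handled outside the stored matrix: it scores 0 against every
    residue including itself.
    """

    def __init__(self, scores: np.ndarray, name: str = "custom"):
        scores = np.asarray(scores)
        if scores.shape != (N_AA, N_AA):
            raise InvalidParameterError(f"expected a {N_AA}x{N_AA} matrix, got {scores.shape}")
        if not np.array_equal(scores, scores.T):
            raise InvalidParameterError("substitution matrix must be symmetric")
        if np.any(np.diag(scores) <= 0):
            raise InvalidParameterError("diagonal (self) scores must be positive")
        self.scores = scores.astype(np.int64)
        self.name = name
        full = np.zeros((N_AA + 1, N_AA + 1))
        full[:N_AA, :N_AA] = self.scores
        self._full = full  # X row/column stays 0

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load("BLOSUM62")
        scores = np.zeros((N_AA, N_AA), dtype=np.int64)
        for i, a in enumerate(AA):
            for j, b in enumerate(AA):
                scores[i, j] = int(mat[a, b])
        return cls(scores, name="BLOSUM62")

    @classmethod
    def from_ncbi(cls, path, name: str | None = None) -> "SubstitutionMatrix":
        """Read a matrix in NCBI text format (as served with BLAST)."""
        from Bio.Align import substitution_matrices

        with open(path) as fh:
            mat = substitution_matrices.read(fh)
        scores = np.zeros((N_AA, N_AA), dtype=np.int64)
        for i, a in enumerate(AA):
            for j, b in enumerate(AA):
                scores[i, j] = int(mat[a, b])
        return cls(scores, name=name or str(path))

    def full(self) -> np.ndarray:
        """(21, 21) float score table including the neutral X row/column."""
        return self._full

    def score(self, a: str, b: str) -> float:
        ia = encode(a)[0]
        ib = encode(b)[0]
        return float(self._full[ia, ib])

    def __repr__(self) -> str:  # pragma: no cover
        return f"SubstitutionMatrix({self.name!r})"


_DEFAULT_MATRIX: SubstitutionMatrix | None = None


def default_matrix() -> SubstitutionMatrix:
    global _DEFAULT_MATRIX
    if _DEFAULT_MATRIX is None:
        _DEFAULT_MATRIX = SubstitutionMatrix.blosum62()
    return _DEFAULT_MATRIX


@dataclass(frozen=True)
class KarlinAltschulParams:
    """λ (nats per score unit) and K for E = K·m·n·exp(−λS)."""

    lam: float = DEFAULT_LAMBDA
    K: float = DEFAULT_K

    def __post_init__(self):
        if not (self.lam > 0 and self.K > 0):
            raise InvalidParameterError("Karlin–Altschul lambda and K must be positive")


def evalue(raw_score: float, query_len: int, db_len: int, ka: KarlinAltschulParams) -> float:
    """Expected chance hits with score ≥ raw_score: E = K·m·n·exp(−λS)."""
    if query_len < 1 or db_len < 1:
        raise InvalidParameterError("query and database lengths must be ≥ 1")
    return ka.K * query_len * db_len * math.exp(-ka.lam * raw_score)


def bit_score(raw_score: float, ka: KarlinAltschulParams) -> float:
    """Normalised score in bits: (λ·S − ln K) / ln 2."""
    return (ka.lam * raw_score - math.log(ka.K)) / math.log(2.0)


@dataclass
class PairwiseAlignment:
    """A global alignment with EMBOSS-style summary percentages."""

    aligned_query: str
    aligned_subject: str
    score: float
    identity: float  # % of all columns with identical (non-X) residues
    similarity: float  # % of all columns whose residue pair scores > 0
    gaps: float  # % of columns containing a gap

    @property
    def n_columns(self) -> int:
        return len(self.aligned_query)

    def recompute_score(
        self,
        matrix: SubstitutionMatrix,
        gap_open: float,
        gap_extend: float,
        end_gaps_free: bool = True,
    ) -> float:
        """Re-derive the score from the aligned strings (consistency check)."""
        full = matrix.full()
        total = 0.0
        cols = list(zip(self.aligned_query, self.aligned_subject))
        # strip free end gaps
        lo, hi = 0, len(cols)
        if end_gaps_free:
            while lo < hi and GAP in cols[lo]:
                lo += 1
            while hi > lo and GAP in cols[hi - 1]:
                hi -= 1
        in_gap = False
        for a, b in cols[lo:hi]:
            if a == GAP or b == GAP:
                total -= gap_extend + (0.0 if in_gap else gap_open)
                in_gap = True
            else:
                total += full[encode(a)[0], encode(b)[0]]
                in_gap = False
        return total


def _stats(aligned_a: str, aligned_b: str, full: np.ndarray) -> tuple[float, float, float]:
    n = len(aligned_a)
    ident = simil = gapped = 0
    for a, b in zip(aligned_a, aligned_b):
        if a == GAP or b == GAP:
            gapped += 1
            continue
        ia, ib = encode(a)[0], encode(b)[0]
        if ia == ib and ia != X_INDEX:
            ident += 1
        if full[ia, ib] > 0:
            simil += 1
    return 100.0 * ident / n, 100.0 * simil / n, 100.0 * gapped / n


def _traceback_global(a, b, layers, end_i, end_j, end_state):
    M, X, Y, pM, pX, pY = layers
    out_a: list[str] = []
    out_b: list[str] = []
    i, j, state = end_i, end_j, end_state
    ptr = (pM, pX, pY)
    while i > 0 or j > 0:
        if state == 3:
            break
        prev = ptr[state][i, j]
        if state == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif state == 1:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
        state = prev
        if state == 3:
            break
    # leading free end gaps
    while i > 0:
        out_a.append(a[i - 1])
        out_b.append(GAP)
        i -= 1
    while j > 0:
        out_a.append(GAP)
        out_b.append(b[j - 1])
        j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b))


def needleman_wunsch(
    a: str,
    b: str,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = NEEDLE_GAP_OPEN,
    gap_extend: float = NEEDLE_GAP_EXTEND,
    end_gaps_free: bool = True,
) -> PairwiseAlignment:
    """Optimal affine-gap global alignment of two protein sequences."""
    if not a or not b:
        raise InvalidInputError("cannot align an empty sequence")
    if gap_open < 0 or gap_extend < 0:
        raise InvalidParameterError("gap penalties must be ≥ 0")
    matrix = matrix or default_matrix()
    ia, ib = encode(a), encode(b)
    full = matrix.full()
    S = full[ia][:, ib]
    M, X, Y, pM, pX, pY = _dp.fill_global(S, float(gap_open), float(gap_extend), end_gaps_free)
    m, n = len(a), len(b)
    if end_gaps_free:
        # best over last row / last column; strict comparisons keep the
        # earliest candidate in scan order (last row left→right, then last
        # column top→bottom), which fixes ties deterministically.
        best = -math.inf
        end = (m, n, 0)
        candidates = [(m, j) for j in range(n + 1)] + [(i, n) for i in range(m + 1)]
        for i, j in candidates:
            for state, layer in ((0, M), (1, X), (2, Y)):
                if layer[i, j] > best:
                    best = layer[i, j]
                    end = (i, j, state)
        score = best
    else:
        vals = (M[m, n], X[m, n], Y[m, n])
        state = int(np.argmax(vals))
        score = vals[state]
        end = (m, n, state)
    aq, asub = _traceback_global(a, b, (M, X, Y, pM, pX, pY), *end)
    # trailing free end gaps: the end cell sits on the last row or column, so
    # at most one sequence has residues left
    ei, ej, _ = end
    aq += a[ei:] + GAP * (n - ej)
    asub += GAP * (m - ei) + b[ej:]
    ident, simil, gaps = _stats(aq, asub, full)
    return PairwiseAlignment(aq, asub, float(score), ident, simil, gaps)


@dataclass
class Hit:
    """One row of a search result table."""

    subject_id: str
    description: str
    raw_score: float
    bit_score: float
    evalue: float
    query_span: tuple[int, int]  # 0-based half-open
    subject_span: tuple[int, int]


def smith_waterman(
    query: str,
    subject: str,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = BLAST_GAP_OPEN,
    gap_extend: float = BLAST_GAP_EXTEND,
) -> Hit | None:
    """Best local affine-gap alignment; ``None`` when no pair scores > 0."""
    if not query or not subject:
        raise InvalidInputError("cannot align an empty sequence")
    matrix = matrix or default_matrix()
    iq, isub = encode(query), encode(subject)
    S = matrix.full()[iq][:, isub]
    M, X, Y, pM, pX, pY, best, bi, bj = _dp.fill_local(S, float(gap_open), float(gap_extend))
    if best <= 0.0:
        return None
    # traceback from the best cell through the M layer until a fresh start
    i, j, state = bi, bj, 0
    ptr = (pM, pX, pY)
    while True:
        prev = ptr[state][i, j]
        if state == 0:
            i -= 1
            j -= 1
        elif state == 1:
            i -= 1
        else:
            j -= 1
        if prev == 3:
            break
        state = prev
    return Hit(
        subject_id="",
        description="",
        raw_score=float(best),
        bit_score=math.nan,
        evalue=math.nan,
        query_span=(i, bi),
        subject_span=(j, bj),
    )


@dataclass
class HitTable:
    """Ranked search results for one query."""

    query_id: str
    hits: list[Hit] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.hits)

    def __iter__(self):
        return iter(self.hits)

    @staticmethod
    def sort_key(h: Hit):
        return (h.evalue, -h.bit_score, h.subject_id)

    def sorted_truncated(self, top_n: int = DEFAULT_TOP_N) -> "HitTable":
        hits = sorted(self.hits, key=self.sort_key)[:top_n]
        return HitTable(self.query_id, hits)


def search_proteome(
    query: str,
    db: "ProteomeDB",
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = BLAST_GAP_OPEN,
    gap_extend: float = BLAST_GAP_EXTEND,
    ka: KarlinAltschulParams | None = None,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    top_n: int = DEFAULT_TOP_N,
    query_id: str = "query",
) -> HitTable:
    """Smith–Waterman search of ``query`` against every database record.

    One best local hit per subject; hits with E > ``max_evalue`` are
    discarded; results are sorted by ascending E (ties: descending bit
    score, then subject id) and truncated to ``top_n``.
    """
    if not query:
        raise InvalidInputError("query sequence is empty")
    matrix = matrix or default_matrix()
    ka = ka or KarlinAltschulParams()
    m = len(query)
    n = db.size_residues
    table = HitTable(query_id)
    if not db.records:
        return table
    full = matrix.full()
    iq = encode(query)
    for rec in db.records:
        isub = encode(rec.sequence)
        S = full[iq][:, isub]
        hit = None
        raw = float(_dp.local_score(S, float(gap_open), float(gap_extend)))
        if raw <= 0.0:
            continue
        e = evalue(raw, m, n, ka)
        if e > max_evalue:
            continue
        # spans only needed for reported hits
        hit = smith_waterman(query, rec.sequence, matrix, gap_open, gap_extend)
        table.hits.append(
            replace(
                hit,
                subject_id=rec.id,
                description=rec.description,
                bit_score=bit_score(raw, ka),
                evalue=e,
            )
        )
    return table.sorted_truncated(top_n)


def needle_stats(
    reference: str,
    query: str,
    exclude_reference_prefix: int = 0,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = NEEDLE_GAP_OPEN,
    gap_extend: float = NEEDLE_GAP_EXTEND,
    end_gaps_free: bool = True,
) -> PairwiseAlignment:
    """Global identity/similarity of a query against a (truncated) reference.

    ``exclude_reference_prefix`` drops the first N reference residues before
    aligning — the convention used to validate a consensus against a database
    sequence whose N-terminus is unresolved in the map.
    """
    if exclude_reference_prefix < 0 or exclude_reference_prefix >= len(reference):
        raise InvalidParameterError("prefix exclusion must leave a non-empty reference")
    return needleman_wunsch(
        reference[exclude_reference_prefix:], query, matrix, gap_open, gap_extend, end_gaps_free
    )
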