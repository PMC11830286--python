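"""Profile hidden Markov models over chain fragments.

A profile is built either from a fragment multiple alignment (match states =
columns with gap fraction ≤ 0.5; emissions and transitions estimated with a
single background-weighted pseudocount ``alpha``) or directly from a chain's
per-position emission profile.  Scoring uses the forward algorithm in
odds-ratio space against a background null: local alignment is modelled with
uniform entry over match states and a uniform exit point, and residues
outside the matched core score at odds 1 (they are emitted by the null on
both sides of the ratio).  Significance is empirical: each subject's score
is compared with scores of shuffles of itself; when the score exceeds every
null sample the tail is extrapolated with a Gumbel fit of the null scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _dp
from .align import GAP, Hit, HitTable
from .alphabet import N_AA, UNIFORM_BACKGROUND, encode, validate_background
from .consensus import MultipleAlignment
from .errors import EmptyModelError, InvalidInputError, InvalidParameterError
from .fragsim import Fragment, ProteomeDB

DEFAULT_ALPHA = 1.0
DEFAULT_N_SHUFFLES = 200
EULER_GAMMA = 0.5772156649015329


@dataclass
class ProfileHMM:
    """Match/insert/delete profile with local entry/exit.

    ``t_match[j]`` is the core outgoing distribution of match state j over
    (next match, insert, delete); it is scaled by ``1 − exit[j]`` during
    scoring so that every state's outgoing probabilities sum to 1.
    """

    match_emissions: np.ndarray  # (L, 20)
    insert_emissions: np.ndarray  # (20,) shared background
    t_match: np.ndarray  # (L, 3) -> {M, I, D}
    t_insert: np.ndarray  # (L, 2) -> {M, I}
    t_delete: np.ndarray  # (L, 2) -> {M, D}
    background: np.ndarray  # (20,)
    entry: np.ndarray  # (L,) B -> M_j
    exit: np.ndarray  # (L,) M_j -> E
    glocal: bool = False

    def __post_init__(self):
        L = self.length
        if L < 1:
            raise EmptyModelError("profile must have at least one match state")
        for name, arr, axis_sum in (
            ("match_emissions", self.match_emissions, 1),
            ("t_match", self.t_match, 1),
            ("t_insert", self.t_insert, 1),
            ("t_delete", self.t_delete, 1),
        ):
            if not np.allclose(arr.sum(axis=axis_sum), 1.0, atol=1e-9):
                raise InvalidInputError(f"{name} rows must sum to 1")
        if not np.isclose(self.entry.sum(), 1.0, atol=1e-9):
            raise InvalidInputError("entry probabilities must sum to 1")
        if not np.isclose(self.exit[-1], 1.0, atol=1e-9):
            raise InvalidInputError("the last match state must exit with probability 1")

    @property
    def length(self) -> int:
        return self.match_emissions.shape[0]

    def _odds(self) -> np.ndarray:
        odds = np.ones((self.length, N_AA + 1))
        odds[:, :N_AA] = self.match_emissions / self.background
        return odds  # X column stays at neutral odds 1


def _local_entry_exit(L: int, glocal: bool) -> tuple[np.ndarray, np.ndarray]:
    if glocal:
        entry = np.zeros(L)
        entry[0] = 1.0
        exitp = np.zeros(L)
        exitp[-1] = 1.0
    else:
        entry = np.full(L, 1.0 / L)
        # uniform exit point: P(exit at j | entry at i) = 1/(L-i) for j ≥ i
        exitp = np.array([1.0 / (L - j) for j in range(L)])
    return entry, exitp


def build_profile(
    source: MultipleAlignment | Fragment | np.ndarray,
    pseudocount_alpha: float = DEFAULT_ALPHA,
    background: np.ndarray | None = None,
    glocal: bool = False,
    max_gap_fraction: float = 0.5,
) -> ProfileHMM:
    """Estimate a profile HMM from an alignment or per-chain profile columns.

    With an alignment source, match states are the columns with gap fraction
    ≤ ``max_gap_fraction``; emission counts get ``alpha``·background
    pseudocounts, transition counts ``alpha``/k per alternative.  A chain's
    per-position probability profile (or a Fragment carrying one) is treated
    as a single ungapped observation of weight 1 per column.
    """
    if pseudocount_alpha < 0:
        raise InvalidParameterError("pseudocount alpha must be ≥ 0")
    alpha = float(pseudocount_alpha)
    bg = UNIFORM_BACKGROUND if background is None else validate_background(background)

    if isinstance(source, Fragment):
        if source.profile is None:
            source = _indicator_profile(source.sequence)
        else:
            source = source.profile
    if isinstance(source, np.ndarray):
        cols = np.asarray(source, dtype=float)
        if cols.ndim != 2 or cols.shape[1] != N_AA or cols.shape[0] < 1:
            raise EmptyModelError("profile columns must be a non-empty (L, 20) array")
        L = cols.shape[0]
        em = (cols + alpha * bg) / (1.0 + alpha)
        # single ungapped observation: one M->M transition per state;
        # insert/delete states are unobserved (pure pseudocount when alpha>0)
        tm = (np.tile([1.0, 0.0, 0.0], (L, 1)) + alpha / 3.0) / (1.0 + alpha)
        if alpha > 0:
            ti = np.full((L, 2), 0.5)
            td = np.full((L, 2), 0.5)
        else:
            ti = np.tile([1.0, 0.0], (L, 1))
            td = np.tile([1.0, 0.0], (L, 1))
        entry, exitp = _local_entry_exit(L, glocal)
        return ProfileHMM(em, bg.copy(), tm, ti, td, bg.copy(), entry, exitp, glocal)

    msa: MultipleAlignment = source
    n_rows = msa.n_rows
    gap_frac = np.array(
        [sum(r[c] == GAP for r in msa.rows) / n_rows for c in range(msa.n_columns)]
    )
    match_cols = [c for c in range(msa.n_columns) if gap_frac[c] <= max_gap_fraction]
    if not match_cols:
        raise EmptyModelError("no usable match columns (all gap-dominated)")
    L = len(match_cols)
    em_counts = np.zeros((L, N_AA))
    tm_counts = np.zeros((L, 3))
    ti_counts = np.zeros((L, 2))
    td_counts = np.zeros((L, 2))
    col_state = {}  # original column -> match index
    for k, c in enumerate(match_cols):
        col_state[c] = k
    for row in msa.rows:
        # emissions
        for c in match_cols:
            ch = row[c]
            if ch != GAP:
                k = col_state[c]
                if ch == "X":
                    continue  # unknown residues carry no emission evidence
                em_counts[k, encode(ch)[0]] += 1
        # state path: M/D at match columns, I between them
        path = []  # (state, match_index)
        k = 0
        for c in range(msa.n_columns):
            ch = row[c]
            if c in col_state:
                k = col_state[c]
                path.append(("D" if ch == GAP else "M", k))
            elif ch != GAP:
                path.append(("I", k))
        for (s1, k1), (s2, _k2) in zip(path, path[1:]):
            if s1 == "M":
                tm_counts[k1, {"M": 0, "I": 1, "D": 2}[s2]] += 1
            elif s1 == "I":
                ti_counts[k1, 0 if s2 != "I" else 1] += 1
            else:
                td_counts[k1, 0 if s2 != "D" else 1] += 1
    em = (em_counts + alpha * bg) / (em_counts.sum(axis=1, keepdims=True) + alpha)
    tm = (tm_counts + alpha / 3.0) / (tm_counts.sum(axis=1, keepdims=True) + alpha)
    ti = (ti_counts + alpha / 2.0) / (ti_counts.sum(axis=1, keepdims=True) + alpha)
    td = (td_counts + alpha / 2.0) / (td_counts.sum(axis=1, keepdims=True) + alpha)
    if alpha == 0:  # degenerate rows (no observations) fall back to "go to M"
        for arr, default in ((tm, [1, 0, 0]), (ti, [1, 0]), (td, [1, 0])):
            bad = ~np.isfinite(arr.sum(axis=1))
            arr[bad] = default
        bad = ~np.isfinite(em.sum(axis=1))
        em[bad] = bg
    entry, exitp = _local_entry_exit(L, glocal)
    return ProfileHMM(em, bg.copy(), tm, ti, td, bg.copy(), entry, exitp, glocal)


def _indicator_profile(sequence: str) -> np.ndarray:
    idx = encode(sequence, allow_x=False)
    p = np.zeros((len(sequence), N_AA))
    p[np.arange(len(sequence)), idx] = 1.0
    return p


def _placement_norm(hmm: ProfileHMM, n: int) -> float:
    """Forward score of the same architecture with background emissions.

    The local model sums over every entry position and exit point, so even a
    profile that emits pure background accumulates placement entropy that
    grows with sequence length.  Subtracting this term (a function of the
    architecture and the sequence *length* only — background emissions have
    odds 1 everywhere) makes an uninformative profile score exactly 0 bits.
    """
    cache = hmm.__dict__.setdefault("_norm_cache", {})
    if n not in cache:
        ones = np.ones((hmm.length, N_AA + 1))
        dummy = np.zeros(n, dtype=np.int8)
        cache[n] = float(
            _dp.forward_odds(
                ones, hmm.entry, hmm.exit, hmm.t_match, hmm.t_insert, hmm.t_delete, dummy
            )
        )
    return cache[n]


def forward_bitscore(hmm: ProfileHMM, seq: str) -> float:
    """log₂ odds of the sequence under the profile versus the background null
    (including placement entropy), summed over all state paths.  −inf when no
    path has positive probability."""
    if not seq:
        raise InvalidInputError("cannot score an empty sequence")
    idx = encode(seq)
    raw = float(
        _dp.forward_odds(
            hmm._odds(), hmm.entry, hmm.exit, hmm.t_match, hmm.t_insert, hmm.t_delete, idx
        )
    )
    if not math.isfinite(raw):
        return raw
    return raw - _placement_norm(hmm, len(seq))


def _gumbel_tail(null_scores: np.ndarray, score: float) -> float:
    """Upper-tail P(S ≥ score) from a moment-fit Gumbel on the null scores."""
    finite = null_scores[np.isfinite(null_scores)]
    if finite.size < 2:
        return 1.0
    std = float(finite.std(ddof=1))
    if std == 0.0:
        return 1.0 if score <= finite[0] else 0.0
    beta = std * math.sqrt(6.0) / math.pi
    mu = float(finite.mean()) - EULER_GAMMA * beta
    z = (score - mu) / beta
    # P(S >= s) = 1 - exp(-exp(-z)); use expm1 for small tails
    return float(-math.expm1(-math.exp(-z)))


def hmm_search(
    hmm: ProfileHMM,
    db: ProteomeDB,
    n_null_shuffles: int = DEFAULT_N_SHUFFLES,
    seed: int = 0,
    max_evalue: float = 10.0,
    top_n: int = 100,
    query_id: str = "profile",
) -> HitTable:
    """Score every database record with the forward algorithm.

    Each subject's empirical E-value is ``n_records`` times the tail
    frequency of its score among forward scores of ``n_null_shuffles``
    shuffles of the same subject (a Gumbel tail fit extrapolates beyond the
    largest null sample).  Deterministic under a fixed seed.
    """
    if n_null_shuffles < 10:
        raise InvalidParameterError("need at least 10 null shuffles")
    table = HitTable(query_id)
    if not db.records:
        return table
    n_records = len(db.records)
    odds = hmm._odds()
    args = (hmm.entry, hmm.exit, hmm.t_match, hmm.t_insert, hmm.t_delete)
    for ri, rec in enumerate(db.records):
        idx = encode(rec.sequence)
        norm = _placement_norm(hmm, len(idx))
        score = float(_dp.forward_odds(odds, *args, idx)) - norm
        if not math.isfinite(score):
            continue
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), ri]))
        null = np.empty(n_null_shuffles)
        for s in range(n_null_shuffles):
            null[s] = _dp.forward_odds(odds, *args, rng.permutation(idx)) - norm
        exceed = int(np.sum(null >= score))
        if exceed > 0:
            p = exceed / n_null_shuffles
        else:
            p = min(_gumbel_tail(null, score), 1.0 / n_null_shuffles)
        e = n_records * p
        if e > max_evalue:
            continue
        table.hits.append(
            Hit(
                subject_id=rec.id,
                description=rec.description,
                raw_score=score,
                bit_score=score,
                evalue=e,
                query_span=(0, hmm.length),
                subject_span=(0, len(rec.sequence)),
            )
        )
    return table.sorted_truncated(top_n)
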