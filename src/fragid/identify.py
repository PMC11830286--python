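"""The percent-match identification statistic over search hit tables.

Each hit table is trimmed to the (at most) 100 entries with the lowest
E-values; the score is the percentage of those entries whose lowercased
description contains one of the configured key terms as a plain substring.
Ambiguous family-level terms (for example "2-oxo acid dehydrogenase subunit
E2") never count on their own — an entry matches only if a specific key
term is also present.  Tables with zero entries get a missing score,
serialized as the double dash ``--`` and excluded from aggregation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .align import HitTable
from .errors import InvalidInputError, InvalidParameterError, NoDataError

#: Key terms identifying dihydrolipoamide succinyltransferase (DLST)
#: unambiguously, plus the family-level exception term that never counts
#: alone.  Fully overridable for other target proteins.
DLST_MATCH_TERMS = [
    "dihydrolipoamide succinyltransferase",
    "dihydrolipoyllysine-residue succinyltransferase",
    "dihydrolipoyltranssuccinylase",
    "dihydrolipoyltranssuccinate transferase",
    "dihydrolipoyltranssuccinase",
]
DLST_EXCEPTION_TERMS = ["2-oxo acid dehydrogenase subunit e2"]

MISSING_TOKEN = "--"
DEFAULT_TOP_N = 100


@dataclass(frozen=True)
class KeyTermSet:
    """Lowercase match phrases and exception phrases for one target protein."""

    match_terms: tuple[str, ...] = tuple(DLST_MATCH_TERMS)
    exception_terms: tuple[str, ...] = tuple(DLST_EXCEPTION_TERMS)

    def __post_init__(self):
        if not self.match_terms:
            raise InvalidParameterError("at least one match term is required")
        for t in tuple(self.match_terms) + tuple(self.exception_terms):
            if t != t.lower():
                raise InvalidParameterError(f"key terms must be lowercase: {t!r}")


def is_dlst_match(description: str, terms: KeyTermSet | None = None) -> bool:
    """True iff the lowercased description contains a match term.

    Exception terms are family-level phrases that never suffice alone; they
    only document ambiguity — an entry containing both an exception term and
    a match term still matches.
    """
    terms = terms or KeyTermSet()
    text = (description or "").lower()
    return any(t in text for t in terms.match_terms)


@dataclass(frozen=True)
class MatchScore:
    """Percent of the used hit-table entries identifying the target."""

    query_id: str
    value: float | None  # percent to one decimal, or None when missing
    n_entries: int
    n_matched: int

    @classmethod
    def missing(cls, query_id: str) -> "MatchScore":
        return cls(query_id, None, 0, 0)

    @property
    def is_missing(self) -> bool:
        return self.value is None

    def __str__(self) -> str:
        return MISSING_TOKEN if self.is_missing else f"{self.value:.1f}"


def match_score(
    hits: HitTable, terms: KeyTermSet | None = None, top_n: int = DEFAULT_TOP_N
) -> MatchScore:
    """Score a hit table: 100 × matched / used, one decimal.

    Uses the ``min(top_n, available)`` entries with the lowest E-values
    (tables are kept sorted); fewer than ``top_n`` entries simply shrink the
    denominator; zero entries give the missing sentinel.
    """
    terms = terms or KeyTermSet()
    used = hits.sorted_truncated(top_n).hits
    if not used:
        return MatchScore.missing(hits.query_id)
    matched = sum(is_dlst_match(h.description, terms) for h in used)
    value = round(100.0 * matched / len(used), 1)
    return MatchScore(hits.query_id, value, len(used), matched)


@dataclass(frozen=True)
class AggregateScore:
    """Mean percent with a Student-t 95 % confidence interval."""

    mean: float
    ci_low: float
    ci_high: float
    n: int


def aggregate_scores(scores: list[MatchScore]) -> AggregateScore:
    """Mean and 95 % CI of the non-missing scores (t distribution, n−1 df).

    Missing scores are excluded; a single score gives a degenerate interval;
    all-missing input raises :class:`NoDataError`.
    """
    values = np.array([s.value for s in scores if not s.is_missing], dtype=float)
    if values.size == 0:
        raise NoDataError("every score is missing; nothing to aggregate")
    mean = float(values.mean())
    if values.size == 1:
        return AggregateScore(mean, mean, mean, 1)
    sem = float(values.std(ddof=1)) / math.sqrt(values.size)
    half = float(stats.t.ppf(0.975, values.size - 1)) * sem
    return AggregateScore(mean, mean - half, mean + half, int(values.size))


def relative_abundance(counts: dict[str, int]) -> dict[str, float]:
    """Percent of total particle count per species, to two decimals."""
    if not counts or any(c < 0 for c in counts.values()):
        raise InvalidInputError("counts must be non-negative, with at least one species")
    total = sum(counts.values())
    if total == 0:
        raise InvalidInputError("all counts are zero")
    return {k: round(100.0 * v / total, 2) for k, v in counts.items()}
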