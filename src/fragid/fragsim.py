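"""Synthetic stand-in for sequence-agnostic model-building output.

Automated model builders traced into a cryo-EM map without a sequence emit a
collection of chain fragments whose mean length shrinks — roughly inversely
with nominal map resolution — and whose per-residue substitution error rate
grows as the map degrades.  This module emulates that behaviour in sequence
space: fragments are windows of a reference protein with geometric lengths
and independent per-residue substitutions, each carrying a per-position
emission profile ((1−ε) on the emitted residue, ε/19 elsewhere).

It also builds desk-scale decoy proteomes: the target protein under its true
description, a diverged paralog under a confounder description that must not
match the target's key terms, optional labelled homologs emulating database
redundancy, and random decoys.

All randomness flows from one root seed; per-fragment / per-record streams
are derived with ``numpy.random.SeedSequence`` so that changing the number
of fragments never reshuffles earlier ones.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA, N_AA, UNIFORM_BACKGROUND, encode, validate_background
from .errors import EmptyInputError, InvalidInputError, InvalidParameterError

#: Default sequence-space degradation model (see docs/methods.md):
#: mean fragment length = SCALE_K / resolution; substitution error rate
#: = ERROR_BASE + ERROR_SLOPE · (resolution − REFERENCE_RESOLUTION).
DEFAULT_SCALE_K = 150.0  # Å·residues → mean length 60 at 2.5 Å
DEFAULT_ERROR_BASE = 0.10
DEFAULT_ERROR_SLOPE = 0.08  # per Å
DEFAULT_REFERENCE_RESOLUTION = 2.5
MAX_ERROR = 0.95

#: Residue-count bins used for chain-length profiles (1–10, 11–100, >100).
DEFAULT_LENGTH_BINS: list[tuple[int, float]] = [(1, 10), (11, 100), (101, math.inf)]


@dataclass(frozen=True)
class DegradationParams:
    """Sequence-space degradation level standing in for map resolution."""

    resolution: float  # Å, nominal label
    mean_fragment_length: int  # residues
    length_dispersion: float = 1.0  # geometric shape; kept for future mixtures
    substitution_error_rate: float = 0.0
    coverage_fraction: float = 1.0

    def __post_init__(self):
        if not (self.resolution > 0 and math.isfinite(self.resolution)):
            raise InvalidParameterError("resolution must be a positive, finite Å value")
        if self.mean_fragment_length < 1:
            raise InvalidParameterError("mean_fragment_length must be ≥ 1 residue")
        if self.length_dispersion < 0:
            raise InvalidParameterError("length_dispersion must be ≥ 0")
        if not (0.0 <= self.substitution_error_rate < 1.0):
            raise InvalidParameterError("substitution_error_rate must be in [0, 1)")
        if not (0.0 < self.coverage_fraction <= 1.0):
            raise InvalidParameterError("coverage_fraction must be in (0, 1]")


def degradation_from_resolution(
    resolution: float,
    scale_k: float = DEFAULT_SCALE_K,
    error_base: float = DEFAULT_ERROR_BASE,
    error_slope: float = DEFAULT_ERROR_SLOPE,
    reference_resolution: float = DEFAULT_REFERENCE_RESOLUTION,
    coverage_fraction: float = 1.0,
) -> DegradationParams:
    """Map a nominal resolution to degradation parameters.

    Mean fragment length is inversely proportional to resolution
    (``scale_k / resolution``, rounded, minimum 1); the substitution error
    rate rises linearly from ``error_base`` at the reference resolution,
    clamped to [0, 0.95].
    """
    if resolution <= 0 or scale_k <= 0:
        raise InvalidParameterError("resolution and scale_k must be positive")
    mean_len = max(1, int(round(scale_k / resolution)))
    err = error_base + error_slope * (resolution - reference_resolution)
    err = min(max(err, 0.0), MAX_ERROR)
    return DegradationParams(
        resolution=resolution,
        mean_fragment_length=mean_len,
        substitution_error_rate=err,
        coverage_fraction=coverage_fraction,
    )


@dataclass
class Fragment:
    """One putative chain fragment."""

    id: str
    sequence: str
    source_span: tuple[int, int] | None = None  # 0-based half-open on the reference
    profile: np.ndarray | None = None  # (len, 20) per-position emission probabilities

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise InvalidInputError(f"fragment {self.id!r} has an empty sequence")
        if self.profile is not None:
            p = np.asarray(self.profile, dtype=float)
            if p.shape != (len(self.sequence), N_AA):
                raise InvalidInputError(
                    f"fragment {self.id!r}: profile shape {p.shape} does not match "
                    f"sequence length {len(self.sequence)}"
                )
            if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
                raise InvalidInputError(f"fragment {self.id!r}: profile columns must sum to 1")
            self.profile = p

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FragmentSet:
    """A per-map collection of chain fragments with provenance."""

    fragments: list[Fragment]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [f.id for f in self.fragments]
        if len(set(ids)) != len(ids):
            raise InvalidInputError("fragment ids must be unique within a set")

    def __len__(self) -> int:
        return len(self.fragments)

    def __iter__(self):
        return iter(self.fragments)

    @property
    def total_residues(self) -> int:
        return sum(len(f) for f in self.fragments)


@dataclass
class ProteomeRecord:
    id: str
    description: str
    sequence: str


@dataclass
class ProteomeDB:
    """A searchable collection of protein records."""

    records: list[ProteomeRecord]

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise InvalidInputError("proteome record ids must be unique")

    @property
    def size_residues(self) -> int:
        return sum(len(r.sequence) for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def _rng(seed_parts: list[int]) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed_parts))


def _mutate(
    idx: np.ndarray, error_rate: float, background: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Substitute each residue with probability ``error_rate`` by a *different*
    residue drawn from the background renormalised without the original."""
    out = idx.copy()
    if error_rate <= 0:
        return out
    hit = rng.random(idx.size) < error_rate
    for pos in np.flatnonzero(hit):
        orig = out[pos]
        w = background.copy()
        w[orig] = 0.0
        w /= w.sum()
        out[pos] = rng.choice(N_AA, p=w)
    return out


def simulate_fragments(
    reference: str,
    params: DegradationParams,
    n_fragments: int | None = None,
    seed: int = 0,
    background: np.ndarray | None = None,
    reference_id: str = "reference",
) -> FragmentSet:
    """Draw chain fragments from a reference protein under a degradation level.

    Each fragment samples a uniform start and a geometric length with the
    configured mean (truncated at the reference end, minimum 1), then mutates
    residues independently at the substitution error rate.  When
    ``n_fragments`` is omitted it is derived from the coverage fraction:
    ``ceil(coverage · len(reference) / mean_fragment_length)``.
    """
    if len(reference) < 2:
        raise InvalidInputError("reference must be at least 2 residues long")
    ref_idx = encode(reference, allow_x=False)
    background = (
        UNIFORM_BACKGROUND if background is None else validate_background(background)
    )
    if n_fragments is None:
        n_fragments = math.ceil(
            params.coverage_fraction * len(reference) / params.mean_fragment_length
        )
    if n_fragments < 1:
        raise InvalidParameterError("n_fragments must be ≥ 1 (or derived from coverage)")
    L = len(reference)
    p_geom = 1.0 / params.mean_fragment_length
    eps = params.substitution_error_rate
    width = max(4, len(str(n_fragments)))
    fragments = []
    for i in range(n_fragments):
        rng = _rng([int(seed), i])
        start = int(rng.integers(0, L))
        length = int(rng.geometric(p_geom)) if p_geom < 1.0 else 1
        end = min(start + max(1, length), L)
        frag_idx = _mutate(ref_idx[start:end], eps, background, rng)
        n = end - start
        if eps > 0:
            profile = np.full((n, N_AA), eps / (N_AA - 1))
            profile[np.arange(n), frag_idx] = 1.0 - eps
        else:
            profile = np.zeros((n, N_AA))
            profile[np.arange(n), frag_idx] = 1.0
        fragments.append(
            Fragment(
                id=f"frag_{i:0{width}d}",
                sequence="".join(AA[k] for k in frag_idx),
                source_span=(start, end),
                profile=profile,
            )
        )
    return FragmentSet(
        fragments,
        provenance={
            "resolution": params.resolution,
            "seed": int(seed),
            "reference_id": reference_id,
        },
    )


#: Descriptions used for the labelled records of a synthetic proteome.
TARGET_DESCRIPTION = (
    "Dihydrolipoamide succinyltransferase, E2 component of the "
    "2-oxoglutarate dehydrogenase complex"
)
PARALOG_DESCRIPTION = (
    "Dihydrolipoamide acetyltransferase, E2 component of the "
    "pyruvate dehydrogenase complex"
)
HOMOLOG_DESCRIPTION = "Dihydrolipoamide succinyltransferase, partial"


def simulate_proteome(
    n_decoys: int,
    length_range: tuple[int, int],
    target: dict | None = None,
    paralog_divergence: float = 0.3,
    background: np.ndarray | None = None,
    seed: int = 0,
    include_paralog: bool = True,
    n_homologs: int = 0,
    homolog_divergence: float = 0.1,
) -> ProteomeDB:
    """Build a decoy proteome around a target protein.

    The database contains the target under its true description, a diverged
    paralog under a confounder description that does *not* match the
    target's key terms, optionally ``n_homologs`` diverged copies labelled
    like the target (emulating the redundancy of real databases), and
    ``n_decoys`` random background sequences with neutral descriptions.
    """
    lo, hi = length_range
    if lo < 1 or lo > hi:
        raise InvalidParameterError("length_range must satisfy 1 ≤ min ≤ max")
    if not (0.0 <= paralog_divergence < 1.0):
        raise InvalidParameterError("paralog_divergence must be in [0, 1)")
    if n_decoys < 0 or n_homologs < 0:
        raise InvalidParameterError("record counts must be ≥ 0")
    background = (
        UNIFORM_BACKGROUND if background is None else validate_background(background)
    )
    if target is None:
        raise InvalidParameterError("a target {'sequence', 'description'} is required")
    tseq = target["sequence"]
    tdesc = target.get("description", TARGET_DESCRIPTION)
    tidx = encode(tseq, allow_x=False)

    records = [ProteomeRecord("TARGET", tdesc, tseq)]
    if include_paralog:
        rng = _rng([int(seed), 10_000_000])
        pidx = _mutate(tidx, paralog_divergence, background, rng)
        records.append(
            ProteomeRecord("PARALOG", PARALOG_DESCRIPTION, "".join(AA[k] for k in pidx))
        )
    for h in range(n_homologs):
        rng = _rng([int(seed), 20_000_000 + h])
        hidx = _mutate(tidx, homolog_divergence, background, rng)
        records.append(
            ProteomeRecord(
                f"HOMOLOG_{h:03d}",
                f"{HOMOLOG_DESCRIPTION} [synthetic homolog {h}]",
                "".join(AA[k] for k in hidx),
            )
        )
    width = max(4, len(str(max(n_decoys, 1))))
    for d in range(n_decoys):
        rng = _rng([int(seed), 30_000_000 + d])
        length = int(rng.integers(lo, hi + 1))
        seq_idx = rng.choice(N_AA, size=length, p=background)
        records.append(
            ProteomeRecord(
                f"DECOY_{d:0{width}d}",
                f"hypothetical protein D{d:04d}",
                "".join(AA[k] for k in seq_idx),
            )
        )
    return ProteomeDB(records)


def synthetic_reference(
    length: int = 234, seed: int = 2024, background: np.ndarray | None = None
) -> str:
    """A synthetic reference protein (default 234 residues, the size of a
    resolved E2 catalytic-domain segment), drawn iid from the background.

    Synthetic stand-in for a real target sequence; used by the analysis
    drivers and tests so no external accession is ever required.
    """
    if length < 2:
        raise InvalidParameterError("reference length must be ≥ 2")
    background = (
        UNIFORM_BACKGROUND if background is None else validate_background(background)
    )
    rng = _rng([int(seed), 424242])
    return "".join(AA[k] for k in rng.choice(N_AA, size=length, p=background))


def chain_length_profile(
    fragset: FragmentSet,
    bins: list[tuple[int, float]] | None = None,
) -> list[float]:
    """Fraction of all *residues* belonging to chains in each length bin.

    Bins are inclusive ``(lo, hi)`` intervals that must partition [1, ∞);
    the default is 1–10, 11–100, >100.
    """
    if len(fragset) == 0:
        raise EmptyInputError("fragment set is empty")
    bins = DEFAULT_LENGTH_BINS if bins is None else bins
    expect = 1
    for lo, hi in bins:
        if lo != expect:
            raise InvalidParameterError("bins must partition [1, ∞) without gaps or overlap")
        expect = hi + 1 if math.isfinite(hi) else None
        if expect is None:
            break
    if expect is not None:
        raise InvalidParameterError("last bin must be open-ended (hi = inf)")
    counts = [0] * len(bins)
    for frag in fragset:
        n = len(frag)
        for k, (lo, hi) in enumerate(bins):
            if lo <= n <= hi:
                counts[k] += n
                break
    total = fragset.total_residues
    return [c / total for c in counts]
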