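"""The 20-letter protein alphabet and encoding helpers.

Internally sequences are numpy ``int8`` index arrays over the alphabetically
ordered one-letter codes; ``X`` (unknown residue) is tolerated at index 20 and
handled specially by the scoring layers.
"""

from __future__ import annotations

import numpy as np

from .errors import AlphabetError

#: The 20 standard amino acids, alphabetical one-letter order.
AA = "ACDEFGHIKLMNPQRSTVWY"
#: Unknown-residue symbol; scores 0 against everything, never identical/similar.
UNKNOWN = "X"
AA_SET = frozenset(AA)
N_AA = 20
X_INDEX = 20

AA_INDEX = {a: i for i, a in enumerate(AA)}
AA_INDEX[UNKNOWN] = X_INDEX

_LOOKUP = np.full(128, -1, dtype=np.int8)
for _a, _i in AA_INDEX.items():
    _LOOKUP[ord(_a)] = _i

#: Uniform background composition (the generator default).
UNIFORM_BACKGROUND = np.full(N_AA, 1.0 / N_AA)


def encode(seq: str, allow_x: bool = True) -> np.ndarray:
    """Map a protein string to an int8 index array (A=0 ... Y=19, X=20)."""
    raw = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    idx = _LOOKUP[np.minimum(raw, 127)]
    bad = np.flatnonzero(idx < 0)
    if bad.size:
        raise AlphabetError(
            f"character {seq[bad[0]]!r} at position {bad[0] + 1} is not a "
            f"standard amino acid"
        )
    if not allow_x and X_INDEX in idx:
        pos = int(np.flatnonzero(idx == X_INDEX)[0])
        raise AlphabetError(f"unknown residue 'X' at position {pos + 1} not allowed here")
    return idx


def decode(idx: np.ndarray) -> str:
    """Inverse of :func:`encode`."""
    return "".join((AA + UNKNOWN)[i] for i in idx)


def validate_background(background: np.ndarray) -> np.ndarray:
    """Check a 20-vector of residue frequencies sums to 1 and return it as float64."""
    bg = np.asarray(background, dtype=float)
    if bg.shape != (N_AA,):
        raise ValueError(f"background must have shape ({N_AA},), got {bg.shape}")
    if np.any(bg < 0) or not np.isclose(bg.sum(), 1.0, atol=1e-9):
        raise ValueError("background frequencies must be non-negative and sum to 1")
    return bg
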