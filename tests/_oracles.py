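"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package's DP engines: plain
dictionary-based dynamic programming for affine-gap alignment scores, and
explicit path enumeration for profile-HMM forward probabilities.
Gap cost convention matches the package: a gap of length L costs
open + L * extend.
"""

from __future__ import annotations

NEG = float("-inf")


def oracle_global_score(a, b, score_fn, gap_open, gap_extend, free_ends):
    """Optimal affine-gap global alignment score by explicit 3-state DP."""
    m, n = len(a), len(b)
    # best[(i, j, s)]: a[:i] vs b[:j], s in {"M","X","Y"} = last move type
    best = {}
    for s in "MXY":
        best[(0, 0, s)] = 0.0 if s == "M" else NEG
    for i in range(m + 1):
        for j in range(n + 1):
            if i == 0 and j == 0:
                continue
            # X: a[i-1] against a gap
            if i >= 1:
                opens = [best[(i - 1, j, "M")], best[(i - 1, j, "Y")]]
                cand = [v - gap_open - gap_extend for v in opens]
                cand.append(best[(i - 1, j, "X")] - gap_extend)
                if free_ends and j in (0, n):
                    cand += [best[(i - 1, j, s)] for s in "MXY"]
                best[(i, j, "X")] = max(cand)
            else:
                best[(i, j, "X")] = NEG
            # Y: b[j-1] against a gap
            if j >= 1:
                opens = [best[(i, j - 1, "M")], best[(i, j - 1, "X")]]
                cand = [v - gap_open - gap_extend for v in opens]
                cand.append(best[(i, j - 1, "Y")] - gap_extend)
                if free_ends and i in (0, m):
                    cand += [best[(i, j - 1, s)] for s in "MXY"]
                best[(i, j, "Y")] = max(cand)
            else:
                best[(i, j, "Y")] = NEG
            # M: a[i-1] against b[j-1]
            if i >= 1 and j >= 1:
                prev = max(best[(i - 1, j - 1, s)] for s in "MXY")
                best[(i, j, "M")] = prev + score_fn(a[i - 1], b[j - 1])
            else:
                best[(i, j, "M")] = NEG
    return max(best[(m, n, s)] for s in "MXY")


def oracle_local_score(a, b, score_fn, gap_open, gap_extend):
    """Optimal Smith–Waterman affine-gap score (0 when nothing scores > 0)."""
    m, n = len(a), len(b)
    best = {}
    overall = 0.0
    for i in range(m + 1):
        for j in range(n + 1):
            if i == 0 or j == 0:
                best[(i, j, "M")] = NEG
                best[(i, j, "X")] = NEG
                best[(i, j, "Y")] = NEG
                continue
            prev = max(
                0.0,
                best[(i - 1, j - 1, "M")],
                best[(i - 1, j - 1, "X")],
                best[(i - 1, j - 1, "Y")],
            )
            best[(i, j, "M")] = prev + score_fn(a[i - 1], b[j - 1])
            best[(i, j, "X")] = max(
                best[(i - 1, j, "M")] - gap_open - gap_extend,
                best[(i - 1, j, "X")] - gap_extend,
                best[(i - 1, j, "Y")] - gap_open - gap_extend,
            )
            best[(i, j, "Y")] = max(
                best[(i, j - 1, "M")] - gap_open - gap_extend,
                best[(i, j - 1, "X")] - gap_open - gap_extend,
                best[(i, j - 1, "Y")] - gap_extend,
            )
            overall = max(overall, best[(i, j, "M")])
    return overall


def oracle_forward_odds(hmm, seq_indices):
    """Summed path odds by explicit enumeration (tiny models only).

    Mirrors the package's local model: entry at any sequence position into
    any match state (weight entry[j]), uniform-exit, flanking residues at
    odds 1, insert emissions equal to the background (odds 1).
    """
    L = hmm.length
    em = hmm.match_emissions
    bg = hmm.background
    tm, ti, td = hmm.t_match, hmm.t_insert, hmm.t_delete
    exitp = hmm.exit
    N = len(seq_indices)

    def odds(j, i):
        return em[j][seq_indices[i]] / bg[seq_indices[i]]

    def from_match(j, i):
        """Sum of continuation odds after M_j emitted the residue at i-1."""
        total = exitp[j]
        stay = 1.0 - exitp[j]
        if stay <= 0:
            return total
        if j + 1 < L:
            if i < N:
                total += stay * tm[j][0] * odds(j + 1, i) * from_match(j + 1, i + 1)
            total += stay * tm[j][2] * from_delete(j + 1, i)
        if i < N:
            total += stay * tm[j][1] * from_insert(j, i + 1)
        return total

    def from_insert(j, i):
        total = 0.0
        if j + 1 < L and i < N:
            total += ti[j][0] * odds(j + 1, i) * from_match(j + 1, i + 1)
        if i < N:
            total += ti[j][1] * from_insert(j, i + 1)
        return total

    def from_delete(j, i):
        if j == L - 1:
            return 1.0  # D_{L-1} -> E
        total = 0.0
        if i < N:
            total += td[j][0] * odds(j + 1, i) * from_match(j + 1, i + 1)
        total += td[j][1] * from_delete(j + 1, i)
        return total

    total = 0.0
    for i0 in range(N):
        for j in range(L):
            total += hmm.entry[j] * odds(j, i0) * from_match(j, i0 + 1)
    return total
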