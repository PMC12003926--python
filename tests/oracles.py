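"""Independent brute-force oracles used to validate the dynamic programs."""

from __future__ import annotations

import math

import numpy as np

from bacascan.io_formats import X_INDEX
from bacascan.profile_hmm import ProfileHMM


def enumerate_local_paths(hmm: ProfileHMM, seq: np.ndarray) -> tuple[float, float]:
    """(forward_bits, viterbi_bits) by explicit enumeration of state paths.

    Mirrors the scoring model definition: uniform entry 1/K into any match
    state, free exit from any match state, insert emissions at background
    odds (factor 1), delete states silent.  Linear-space path odds are
    summed / maximized; feasible only for tiny models and sequences.
    """
    K = hmm.n_match
    L = len(seq)
    me, bg, tr = hmm.match_emissions, hmm.background, hmm.transitions
    odds = np.ones((K, 21))
    odds[:, :20] = me / bg[None, :]
    odds[:, X_INDEX] = 1.0

    sums: list[float] = []
    best = [0.0]

    def record(acc: float) -> None:
        sums.append(acc)
        if acc > best[0]:
            best[0] = acc

    def extend(state: str, k: int, i: int, acc: float) -> None:
        # state at 1-based match index k, having consumed residues up to i
        if state == "M":
            record(acc)
            if k < K:
                if i + 1 < L:
                    extend("M", k + 1, i + 1, acc * tr[k - 1, 0] * odds[k, seq[i + 1]])
                extend("D", k + 1, i, acc * tr[k - 1, 2])
            if i + 1 < L:
                extend("I", k, i + 1, acc * tr[k - 1, 1])
        elif state == "I":
            if i + 1 < L:
                extend("I", k, i + 1, acc * tr[k - 1, 4])
            if k < K and i + 1 < L:
                extend("M", k + 1, i + 1, acc * tr[k - 1, 3] * odds[k, seq[i + 1]])
        elif state == "D":
            if k < K:
                if i + 1 < L:
                    extend("M", k + 1, i + 1, acc * tr[k - 1, 5] * odds[k, seq[i + 1]])
                extend("D", k + 1, i, acc * tr[k - 1, 6])

    entry = 1.0 / K
    for i0 in range(L):
        for k0 in range(1, K + 1):
            extend("M", k0, i0, entry * odds[k0 - 1, seq[i0]])
    total = float(np.sum(sums))
    return math.log2(total), math.log2(best[0])


def brute_force_local_align(a, b, S, gap_open: int, gap_extend: int) -> int:
    """Optimal local alignment score by exhaustive recursion.

    Every local alignment starts and ends on an aligned residue pair;
    gaps of length k cost gap_open + (k-1) * gap_extend.  Exponential:
    usable only for very short sequences.
    """
    best = 0

    def rec(i: int, j: int, score: int, state: int) -> None:
        nonlocal best
        if score > best:
            best = score
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + int(S[a[i], b[j]]), 0)
        if i < len(a):
            rec(i + 1, j, score - (gap_extend if state == 1 else gap_open), 1)
        if j < len(b):
            rec(i, j + 1, score - (gap_extend if state == 2 else gap_open), 2)

    for i0 in range(len(a)):
        for j0 in range(len(b)):
            rec(i0 + 1, j0 + 1, int(S[a[i0], b[j0]]), 0)
    return best


def memo_local_align(a, b, S, gap_open: int, gap_extend: int) -> int:
    """Optimal local score via top-down memoized recursion over suffixes."""
    from functools import lru_cache

    na, nb = len(a), len(b)

    @lru_cache(maxsize=None)
    def ext(i: int, j: int, state: int) -> int:
        # best continuation score starting at (i, j) in the given gap state;
        # 0 = may stop here
        opts = [0]
        if i < na and j < nb:
            opts.append(int(S[a[i], b[j]]) + ext(i + 1, j + 1, 0))
        if i < na:
            opts.append(-(gap_extend if state == 1 else gap_open) + ext(i + 1, j, 1))
        if j < nb:
            opts.append(-(gap_extend if state == 2 else gap_open) + ext(i, j + 1, 2))
        return max(opts)

    best = 0
    for i0 in range(na):
        for j0 in range(nb):
            s = int(S[a[i0], b[j0]]) + ext(i0 + 1, j0 + 1, 0)
            best = max(best, s)
    return best


class UnionFind:
    """Minimal union-find used as an independent components oracle."""

    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y):
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[rx] = ry

    def components(self):
        groups = {}
        for x in self.parent:
            groups.setdefault(self.find(x), set()).add(x)
        return sorted((sorted(g) for g in groups.values()), key=lambda g: (-len(g), g[0]))
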