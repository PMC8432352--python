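"""Independent brute-force oracles used only by the test suite.

The alignment oracle is a plain O(n·m) three-state Gotoh dynamic program,
written from the recurrences with no shared code with the package's
identity engine.  Besides the optimal global score it computes, by a second
pass over the optimal-path subgraph, the minimum and maximum number of
identical columns achievable by *any* optimal-scoring alignment — the right
yardstick for an implementation that returns one optimal alignment, because
co-optimal alignments can differ in their identical-column count.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

NEG = -1e18
_B62 = substitution_matrices.load("BLOSUM62")


def _score(x: str, y: str) -> float:
    return float(_B62[x, y])


def gotoh_global(a: str, b: str, gap_open: float = 10.0, gap_extend: float = 1.0):
    """(optimal score, min identities, max identities) for global alignment.

    Gap of length L costs gap_open + L*gap_extend; end gaps charged the same.
    States: M (residue pair), X (gap in b, consumes a), Y (gap in a).
    """
    go = gap_open + gap_extend  # cost of the first gapped position
    ge = gap_extend
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)
    Y = np.full((n + 1, m + 1), NEG)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(go + (i - 1) * ge)
    for j in range(1, m + 1):
        Y[0, j] = -(go + (j - 1) * ge)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = _score(a[i - 1], b[j - 1])
            M[i, j] = s + max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            X[i, j] = max(M[i - 1, j] - go, X[i - 1, j] - ge, Y[i - 1, j] - go)
            Y[i, j] = max(M[i, j - 1] - go, X[i, j - 1] - go, Y[i, j - 1] - ge)
    opt = max(M[n, m], X[n, m], Y[n, m])

    # second pass: min/max identical columns along optimal paths
    tables = {"M": M, "X": X, "Y": Y}
    best_ids: dict[tuple[str, int, int], tuple[float, float]] = {}

    def transitions(state: str, i: int, j: int):
        """(prev_state, pi, pj, move score) candidates into (state, i, j)."""
        if state == "M" and i > 0 and j > 0:
            s = _score(a[i - 1], b[j - 1])
            for p in ("M", "X", "Y"):
                yield p, i - 1, j - 1, s
        elif state == "X" and i > 0:
            yield "M", i - 1, j, -go
            yield "X", i - 1, j, -ge
            yield "Y", i - 1, j, -go
        elif state == "Y" and j > 0:
            yield "M", i, j - 1, -go
            yield "X", i, j - 1, -go
            yield "Y", i, j - 1, -ge

    order = [(i, j) for i in range(n + 1) for j in range(m + 1)]
    for i, j in order:
        for state in ("M", "X", "Y"):
            here = tables[state][i, j]
            if here <= NEG / 2:
                continue
            if i == 0 and j == 0:
                best_ids[(state, i, j)] = (0.0, 0.0)
                continue
            lo, hi = None, None
            for pstate, pi, pj, move in transitions(state, i, j):
                if tables[pstate][pi, pj] <= NEG / 2:
                    continue
                if abs(tables[pstate][pi, pj] + move - here) > 1e-6:
                    continue  # not on an optimal sub-path into this cell
                if (pstate, pi, pj) not in best_ids:
                    continue
                plo, phi = best_ids[(pstate, pi, pj)]
                gain = 1.0 if state == "M" and a[i - 1] == b[j - 1] else 0.0
                lo = plo + gain if lo is None else min(lo, plo + gain)
                hi = phi + gain if hi is None else max(hi, phi + gain)
            if lo is not None:
                best_ids[(state, i, j)] = (lo, hi)

    lo = min(
        best_ids[(s, n, m)][0]
        for s in ("M", "X", "Y")
        if abs(tables[s][n, m] - opt) < 1e-6 and (s, n, m) in best_ids
    )
    hi = max(
        best_ids[(s, n, m)][1]
        for s in ("M", "X", "Y")
        if abs(tables[s][n, m] - opt) < 1e-6 and (s, n, m) in best_ids
    )
    return float(opt), int(lo), int(hi)


def scan_motifs(regions: list[str], k_min: int, k_max: int, min_support: float):
    """Exhaustive (motif, support) pairs over all k-mers of the first region."""
    out = {}
    for k in range(k_min, k_max + 1):
        for i in range(len(regions[0]) - k + 1):
            kmer = regions[0][i : i + k]
            support = sum(kmer in r for r in regions) / len(regions)
            if support >= min_support:
                out[kmer] = support
    return out
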