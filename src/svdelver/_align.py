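"""Affine-gap (Gotoh) scoring kernels for the split-read breakpoint search.

The split alignment needs, for every consensus prefix c[1..i], the best
score of fitting that prefix anywhere inside the reference region (free
reference start and end, the consensus fully consumed), plus the reference
column achieving it.  The same kernel applied to the reversed sequences
yields the suffix scores.  Kernels are JIT-compiled with numba; matrices
are filled row-wise so memory stays O(reference length).
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]

NEG_INF = -1e18


@njit(cache=True)
def prefix_scores(query, ref, match, mismatch, gap_open, gap_extend):
    """Best fit of every query prefix inside ``ref``.

    Returns ``(scores, ends)`` of length ``len(query)+1``: ``scores[i]`` is
    the maximum affine-gap alignment score of query[:i] against any
    substring of ``ref`` (query consumed globally, reference ends free) and
    ``ends[i]`` the exclusive reference end column of that optimum (the
    smallest such column on ties).  ``scores[0] = 0`` with ``ends[0] = 0``.
    """
    n = len(query)
    m = len(ref)
    scores = np.empty(n + 1, dtype=np.float64)
    ends = np.zeros(n + 1, dtype=np.int64)
    H = np.zeros(m + 1, dtype=np.float64)  # free reference prefix
    E = np.full(m + 1, NEG_INF, dtype=np.float64)  # gap in query (along ref)
    F = np.full(m + 1, NEG_INF, dtype=np.float64)  # gap in ref (along query)
    scores[0] = 0.0
    prev_diag = 0.0
    for i in range(1, n + 1):
        qi = query[i - 1]
        prev_diag = H[0]
        F[0] = max(H[0] + gap_open, F[0] + gap_extend)
        H[0] = F[0]
        E[0] = NEG_INF
        best = H[0]
        best_j = 0
        for j in range(1, m + 1):
            E[j] = max(H[j - 1] + gap_open, E[j - 1] + gap_extend)
            F[j] = max(H[j] + gap_open, F[j] + gap_extend)
            sub = match if qi == ref[j - 1] else mismatch
            h = prev_diag + sub
            if E[j] > h:
                h = E[j]
            if F[j] > h:
                h = F[j]
            prev_diag = H[j]
            H[j] = h
            if h > best:
                best = h
                best_j = j
        scores[i] = best
        ends[i] = best_j
    return scores, ends


@njit(cache=True)
def global_score(a, b, match, mismatch, gap_open, gap_extend):
    """Plain global affine-gap alignment score of two code arrays."""
    n, m = len(a), len(b)
    H = np.empty(m + 1, dtype=np.float64)
    E = np.full(m + 1, NEG_INF, dtype=np.float64)
    H[0] = 0.0
    for j in range(1, m + 1):
        H[j] = gap_open + gap_extend * (j - 1)
    F = np.full(m + 1, NEG_INF, dtype=np.float64)
    for i in range(1, n + 1):
        prev_diag = H[0]
        H[0] = gap_open + gap_extend * (i - 1)
        F[0] = H[0]
        E[0] = NEG_INF
        for j in range(1, m + 1):
            E[j] = max(H[j - 1] + gap_open, E[j - 1] + gap_extend)
            F[j] = max(H[j] + gap_open, F[j] + gap_extend)
            sub = match if a[i - 1] == b[j - 1] else mismatch
            h = prev_diag + sub
            if E[j] > h:
                h = E[j]
            if F[j] > h:
                h = F[j]
            prev_diag = H[j]
            H[j] = h
    return H[m]
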