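"""Two-stage best-K selection over pose energies.

Selecting the K lowest-energy poses from a population of size N is done
the way a data-parallel device would: stage 1 splits the list into bins
of size B (a power of two, default 1024) and sorts each bin with
Batcher's bitonic merge network — a fixed compare-exchange schedule with
no data-dependent control flow; stage 2 iterates K times, each time
emitting the minimum among the current bin heads and advancing that
bin's cursor.  Exhausted bins present +inf, so K may exceed B safely.

Ordering is ascending by (energy, original index); the index tie-break
makes the selection deterministic.  NaN energies are rejected up front
(a compare-exchange network cannot order them).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ScoredIndex", "bitonic_sort", "k_best"]

_SENTINEL_INDEX = -1


@dataclass(frozen=True)
class ScoredIndex:
    """One energy paired with its position in the original list."""

    energy: float
    index: int


def _next_pow2(n: int) -> int:
    p = 1
    while p < n:
        p <<= 1
    return p


def _bitonic_network_inplace(e: np.ndarray, idx: np.ndarray) -> None:
    """Run the ascending bitonic network on (..., m) arrays, m a power of 2.

    The compare-exchange schedule depends only on m; vectorized over all
    leading axes (all bins sort simultaneously) and over the pairs of
    each stage.  Lexicographic (energy, index) ordering.
    """
    m = e.shape[-1]
    if m < 2:
        return
    pos = np.arange(m)
    k = 2
    while k <= m:
        j = k >> 1
        while j >= 1:
            partner = pos ^ j
            sel = pos[partner > pos]        # each pair handled once
            lo, hi = sel, partner[sel]
            descending = (sel & k).astype(bool)
            a_e, b_e = e[..., lo], e[..., hi]
            a_i, b_i = idx[..., lo], idx[..., hi]
            a_gt_b = (a_e > b_e) | ((a_e == b_e) & (a_i > b_i))
            swap = np.where(descending, ~a_gt_b, a_gt_b)
            new_lo_e = np.where(swap, b_e, a_e)
            new_hi_e = np.where(swap, a_e, b_e)
            new_lo_i = np.where(swap, b_i, a_i)
            new_hi_i = np.where(swap, a_i, b_i)
            e[..., lo], e[..., hi] = new_lo_e, new_hi_e
            idx[..., lo], idx[..., hi] = new_lo_i, new_hi_i
            j >>= 1
        k <<= 1


def bitonic_sort(values: list[ScoredIndex]) -> list[ScoredIndex]:
    """Sort ascending by (energy, index) via a bitonic compare-exchange network.

    Lengths that are not a power of two are padded internally with
    (+inf, -1) sentinels, which sort to the tail and are stripped.
    """
    n = len(values)
    if n == 0:
        return []
    e = np.array([v.energy for v in values], dtype=np.float64)
    if np.any(np.isnan(e)):
        raise ValueError("NaN energy: ordering undefined")
    idx = np.array([v.index for v in values], dtype=np.int64)
    m = _next_pow2(n)
    ep = np.full(m, np.inf)
    ip = np.full(m, _SENTINEL_INDEX, dtype=np.int64)
    ep[:n], ip[:n] = e, idx
    _bitonic_network_inplace(ep, ip)
    return [ScoredIndex(float(ep[i]), int(ip[i])) for i in range(n)]


def k_best(energies, K: int, B: int = 1024) -> list[ScoredIndex]:
    """Return the K lowest energies (with original indices), ascending.

    Equivalent to the first K entries of a full (energy, index) sort,
    computed by the binned-bitonic + K-iteration head-merge algorithm.
    """
    e = np.asarray(energies, dtype=np.float64).ravel()
    n = len(e)
    if not 1 <= K <= n:
        raise ValueError(f"K must be in [1, {n}], got {K}")
    if B < 1 or (B & (B - 1)) != 0:
        raise ValueError(f"bin size B must be a power of two, got {B}")
    if np.any(np.isnan(e)):
        raise ValueError("NaN energy: ordering undefined")

    # stage 1: pad to a whole number of bins and bitonic-sort each bin
    n_bins = -(-n // B)
    m = n_bins * B
    ep = np.full(m, np.inf)
    ip = np.full(m, _SENTINEL_INDEX, dtype=np.int64)
    ep[:n] = e
    ip[:n] = np.arange(n, dtype=np.int64)
    ep = ep.reshape(n_bins, B)
    ip = ip.reshape(n_bins, B)
    _bitonic_network_inplace(ep, ip)

    # stage 2: K iterations of min-over-bin-heads; exhausted cursors read +inf
    cursors = np.zeros(n_bins, dtype=np.int64)
    out: list[ScoredIndex] = []
    for _ in range(K):
        head_e = np.where(cursors < B, ep[np.arange(n_bins),
                                          np.minimum(cursors, B - 1)], np.inf)
        head_i = np.where(cursors < B, ip[np.arange(n_bins),
                                          np.minimum(cursors, B - 1)],
                          np.int64(np.iinfo(np.int64).max))
        # argmin with (energy, index) tie-break
        best = np.lexsort((head_i, head_e))[0]
        out.append(ScoredIndex(float(head_e[best]), int(head_i[best])))
        cursors[best] += 1
    return out
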