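"""Deterministic, seedable per-stream random numbers.

The docking search needs one independent random stream per (generation,
pose-slot) so that results are bit-reproducible and independent of the
order in which poses are evaluated — the same contract a per-work-item
GPU generator provides.  Each stream is a counter-based construction:
the n-th output word is a strong 64-bit mix of (seed, stream_id, n), so
any draw can be computed directly from its coordinates with no carried
state.  The mixer is the SplitMix64 recipe (golden-ratio increment +
MurmurHash3 finalizer), which passes standard statistical batteries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)
_MIX1 = np.uint64(0xFF51AFD7ED558CCD)
_MIX2 = np.uint64(0xC4CEB9FE1A85EC53)
_SHIFT = np.uint64(33)
_U53 = np.float64(1.0 / (1 << 53))

__all__ = ["RandomStream", "make_stream", "hash_label", "derive_seed"]


def _mix64(z: np.ndarray | np.uint64) -> np.ndarray | np.uint64:
    """MurmurHash3 64-bit finalizer: a bijective avalanche on uint64.

    All arithmetic is modulo 2**64 by design; the errstate silences
    numpy's scalar-overflow warning for that intended wraparound.
    """
    with np.errstate(over="ignore"):
        z = (z ^ (z >> _SHIFT)) * _MIX1
        z = (z ^ (z >> _SHIFT)) * _MIX2
        return z ^ (z >> _SHIFT)


def _stream_key(seed: int, stream_id: int) -> np.uint64:
    s = np.uint64(seed & 0xFFFFFFFFFFFFFFFF)
    t = np.uint64(stream_id & 0xFFFFFFFFFFFFFFFF)
    # two dependent mixing rounds keep (seed, id) pairs well separated
    with np.errstate(over="ignore"):
        return _mix64(_mix64(s + _GOLDEN) ^ (t * _MIX2 + _GOLDEN))


def _words(key: np.uint64, counters: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return _mix64(key + (counters + np.uint64(1)) * _GOLDEN)


def hash_label(label: str) -> int:
    """Deterministic 63-bit hash of a text label (for name-keyed streams)."""
    h = np.uint64(0)
    for b in label.encode("utf-8"):
        h = _mix64(h ^ np.uint64(b))
    return int(h & np.uint64(0x7FFFFFFFFFFFFFFF))


def derive_seed(seed: int, *parts: int) -> int:
    """Mix a base seed with integer labels into a fresh 63-bit sub-seed.

    Used to key independent sub-runs (one per ligand conformation) so
    results depend on stable identities, never on processing order.
    """
    with np.errstate(over="ignore"):
        z = _mix64(np.uint64(seed & 0xFFFFFFFFFFFFFFFF) + _GOLDEN)
        for p in parts:
            z = _mix64(z ^ (np.uint64(p & 0xFFFFFFFFFFFFFFFF) * _MIX1 + _GOLDEN))
    return int(z & np.uint64(0x7FFFFFFFFFFFFFFF))


@dataclass
class RandomStream:
    """One independent random sequence, fully determined by (seed, stream_id).

    ``counter`` indexes the next draw; draws are stateless functions of
    (seed, stream_id, counter), so a stream can be forked or replayed by
    value.
    """

    seed: int
    stream_id: int
    counter: int = 0
    _key: np.uint64 = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._key = _stream_key(self.seed, self.stream_id)

    # -- uniforms -----------------------------------------------------

    def next_uniform(self) -> float:
        """One draw in [0, 1); advances the counter by 1."""
        return float(self.uniform(1)[0])

    def uniform(self, n: int) -> np.ndarray:
        """n draws in [0, 1) as float64; advances the counter by n."""
        counters = np.uint64(self.counter) + np.arange(n, dtype=np.uint64)
        self.counter += n
        w = _words(self._key, counters)
        return (w >> np.uint64(11)).astype(np.float64) * _U53

    # -- normals ------------------------------------------------------

    def next_normal(self, mu: float = 0.0, sigma: float = 1.0) -> float:
        return float(self.normal(1, mu, sigma)[0])

    def normal(self, n: int, mu: float = 0.0, sigma: float = 1.0) -> np.ndarray:
        """n Gaussian draws via Box-Muller; sigma == 0 returns mu exactly."""
        if sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {sigma}")
        if sigma == 0:
            self.counter += 2 * n  # keep the counter schedule identical
            return np.full(n, mu, dtype=np.float64)
        u = self.uniform(2 * n)
        u1, u2 = u[:n], u[n:]
        r = np.sqrt(-2.0 * np.log1p(-u1))  # 1-u1 in (0,1], log finite
        z = r * np.cos(2.0 * np.pi * u2)
        return mu + sigma * z


def make_stream(seed: int, stream_id: int) -> RandomStream:
    """Create the stream identified by (seed, stream_id) with counter 0."""
    return RandomStream(seed=seed, stream_id=stream_id)


# -- vectorized cross-stream draws (one draw from each of many streams) --

def streams_uniform(seed: int, stream_ids: np.ndarray, counter: int) -> np.ndarray:
    """Draw number ``counter`` of every stream in ``stream_ids``, in [0, 1).

    Equivalent to ``make_stream(seed, sid)`` advanced to ``counter`` for
    each id, but computed in one vector pass; used by the population
    initializer and mutation step where each pose slot owns a stream.
    """
    sids = np.asarray(stream_ids, dtype=np.uint64)
    with np.errstate(over="ignore"):
        keys = _mix64(_mix64(np.uint64(seed & 0xFFFFFFFFFFFFFFFF) + _GOLDEN)
                      ^ (sids * _MIX2 + _GOLDEN))
    w = _words(keys, np.uint64(counter))
    return (w >> np.uint64(11)).astype(np.float64) * _U53


def streams_normal(seed: int, stream_ids: np.ndarray, counter: int,
                   sigma: float) -> np.ndarray:
    """One N(0, sigma) draw per stream, consuming counters (counter, counter+1)."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    n = len(np.asarray(stream_ids))
    if sigma == 0:
        return np.zeros(n, dtype=np.float64)
    u1 = streams_uniform(seed, stream_ids, counter)
    u2 = streams_uniform(seed, stream_ids, counter + 1)
    r = np.sqrt(-2.0 * np.log1p(-u1))
    return sigma * r * np.cos(2.0 * np.pi * u2)
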