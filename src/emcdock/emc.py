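"""Evolutionary Monte Carlo pose search.

Generation 0 is drawn uniformly over the six-dimensional search space;
each subsequent generation keeps the K_par best poses unchanged
(elitism) and fills the rest with Gaussian mutations of parents chosen
uniformly at random, with the mutation scales decaying geometrically per
generation.  The search runs a fixed number of generations — there is no
early-stopping criterion — and elitism makes the best energy
non-increasing across generations by construction.

Randomness is keyed by (generation, pose-slot): each slot owns a
counter-based stream with stream_id = generation * n_poses + slot, so
results are reproducible from the seed alone and independent of
evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forcefield import ForceFieldTable
from .geometry import SearchSpace, TransformDescriptor
from .kernel import KernelMetrics, MoleculeStruct, PosePopulation, compute_energies
from .prng import streams_normal, streams_uniform
from .selection import ScoredIndex, k_best

__all__ = ["EmcConfig", "EmcTrace", "initial_population", "next_generation",
           "run_emc", "EmcResult"]

_COMPONENTS = ("tx", "ty", "tz", "rx", "ry", "rz")


@dataclass(frozen=True)
class EmcConfig:
    """Search-control parameters.

    Defaults mirror the benchmark operating point (8 generations of
    65,536 poses) and the search resolution the forcefield is built for
    (~1 A translations, ~10 degree rotations), with the mutation scales
    shrinking by ``decay`` each generation to refine around the best
    poses found so far.
    """

    n_poses: int = 65536
    n_generations: int = 8
    n_parents: int = 128
    sigma_t: float = 1.0                      # A
    sigma_r: float = float(np.deg2rad(10.0))  # rad
    decay: float = 0.75
    seed: int = 0
    block: int = 256   # kernel pose-block size; does not affect results
    bin_size: int = 1024

    def __post_init__(self):
        if not (self.n_poses >= self.n_parents >= 1):
            raise ValueError("need n_poses >= n_parents >= 1")
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.sigma_t < 0 or self.sigma_r < 0:
            raise ValueError("mutation sigmas must be >= 0")
        if not (0 < self.decay <= 1):
            raise ValueError("decay must be in (0, 1]")


@dataclass
class EmcTrace:
    """Per-generation observability of convergence."""

    best_energy: list[float] = field(default_factory=list)
    mean_parent_energy: list[float] = field(default_factory=list)
    sigma_t: list[float] = field(default_factory=list)
    sigma_r: list[float] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.best_energy)

    def to_tsv(self) -> str:
        lines = ["generation\tbest_energy\tmean_parent_energy\tsigma_t\tsigma_r"]
        for g in range(len(self)):
            lines.append(f"{g}\t{self.best_energy[g]:.6g}\t"
                         f"{self.mean_parent_energy[g]:.6g}\t"
                         f"{self.sigma_t[g]:.6g}\t{self.sigma_r[g]:.6g}")
        return "\n".join(lines) + "\n"


@dataclass
class EmcResult:
    """Final n_parents poses (ascending energy) plus the search trace."""

    best: list[ScoredIndex]
    descriptors: list[TransformDescriptor]
    trace: EmcTrace
    metrics: KernelMetrics

    @property
    def best_energy(self) -> float:
        return self.best[0].energy

    @property
    def best_descriptor(self) -> TransformDescriptor:
        return self.descriptors[0]


def initial_population(space: SearchSpace, n: int, seed: int) -> PosePopulation:
    """Uniform draw of n poses over the search space (generation 0 streams).

    Slot i uses stream_id i; component c consumes that stream's counter c,
    so the population is a pure function of (seed, n, space).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    sids = np.arange(n, dtype=np.uint64)
    lo = np.concatenate([space.center - space.half_extent, space.angle_lo])
    hi = np.concatenate([space.center + space.half_extent, space.angle_hi])
    cols = []
    for c in range(6):
        u = streams_uniform(seed, sids, counter=c)
        cols.append(lo[c] + u * (hi[c] - lo[c]))
    return PosePopulation(*[col.astype(np.float32) for col in cols])


def next_generation(parent_pop: PosePopulation, parents: list[ScoredIndex],
                    cfg: EmcConfig, gen: int,
                    space: SearchSpace | None = None) -> PosePopulation:
    """Elitist copies of the parents plus Gaussian mutations of them.

    ``gen`` >= 1 indexes the evolution step; mutation scales are
    sigma * decay**(gen - 1).  Slot streams have
    stream_id = gen * n_poses + slot; the child's parent pick consumes
    counter 0, the six normal perturbations counters 1..12.

    When ``space`` is given, child translations are clamped to its box:
    the search-space bounds are hard constraints, so mutation cannot
    carry the population out of the declared docking site.  Angles are
    left unwrapped and unclamped.
    """
    if gen < 1:
        raise ValueError("gen must be >= 1 (generation 0 is the uniform draw)")
    k = len(parents)
    n = cfg.n_poses
    par = np.array([[getattr(parent_pop, comp)[p.index] for comp in _COMPONENTS]
                    for p in parents], dtype=np.float64)  # (k, 6)

    st = cfg.sigma_t * cfg.decay ** (gen - 1)
    sr = cfg.sigma_r * cfg.decay ** (gen - 1)
    new = np.empty((n, 6), dtype=np.float64)
    new[:k] = par  # elitism: parents survive unmutated

    n_child = n - k
    if n_child > 0:
        sids = (np.uint64(gen) * np.uint64(n)
                + np.arange(k, n, dtype=np.uint64))
        pick = (streams_uniform(cfg.seed, sids, counter=0) * k).astype(np.int64)
        pick = np.minimum(pick, k - 1)
        child = par[pick]
        for c in range(6):
            sigma = st if c < 3 else sr
            child[:, c] += streams_normal(cfg.seed, sids, counter=1 + 2 * c,
                                          sigma=sigma)
        if space is not None:
            lo = space.center - space.half_extent
            hi = space.center + space.half_extent
            child[:, :3] = np.clip(child[:, :3], lo, hi)
        new[k:] = child
    return PosePopulation(*[new[:, c].astype(np.float32) for c in range(6)])


def run_emc(ligand: MoleculeStruct, receptor: MoleculeStruct,
            ff: ForceFieldTable, space: SearchSpace,
            cfg: EmcConfig) -> EmcResult:
    """Full generational search; deterministic given cfg.seed.

    Evaluates n_generations populations of n_poses each; returns the
    final generation's best n_parents poses ascending by energy, the
    per-generation trace, and aggregate kernel metrics.
    """
    trace = EmcTrace()
    total_interactions = 0
    total_flops = 0
    total_wall = 0.0
    pop = initial_population(space, cfg.n_poses, cfg.seed)
    parents: list[ScoredIndex] = []
    for gen in range(cfg.n_generations):
        if gen > 0:
            pop = next_generation(pop, parents, cfg, gen, space=space)
        energies, metrics = compute_energies(pop, ligand, receptor, ff,
                                             block=cfg.block)
        total_interactions += metrics.interactions
        total_flops += metrics.flops
        total_wall += metrics.wall_seconds
        parents = k_best(energies, cfg.n_parents, B=cfg.bin_size)
        trace.best_energy.append(parents[0].energy)
        trace.mean_parent_energy.append(
            float(np.mean([p.energy for p in parents])))
        step = max(gen, 1) - 1 if gen > 0 else 0
        trace.sigma_t.append(cfg.sigma_t * cfg.decay ** step if gen > 0 else 0.0)
        trace.sigma_r.append(cfg.sigma_r * cfg.decay ** step if gen > 0 else 0.0)
    descriptors = [pop.descriptor(p.index) for p in parents]
    agg = KernelMetrics(interactions=total_interactions, flops=total_flops,
                        wall_seconds=total_wall)
    return EmcResult(best=parents, descriptors=descriptors, trace=trace,
                     metrics=agg)
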