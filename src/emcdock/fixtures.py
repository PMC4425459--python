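"""Synthetic molecules and worked examples.

Everything the engine needs to be exercised end-to-end is generated here
programmatically: random rigid "ligands" with realistic atom counts
(15-40 non-hydrogen atoms) and minimum separation, planted-optimum
docking scenarios whose global energy minimum is known by construction,
a small default forcefield of eight named atom types, and a hand-sized
worked example whose energies can be checked against the closed-form
term definitions.  None of this is realistic chemistry — no valence or
geometry optimization — which is exactly the point: the scenarios are
oracles for the search and kernel, not models of real complexes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forcefield import (AtomTypeParams, ForceFieldTable, GlobalConstants,
                         HBondClass, pair_energy_reference)
from .geometry import SearchSpace, TransformDescriptor, apply_transform, build_transform
from .kernel import MoleculeStruct
from .prng import RandomStream

__all__ = [
    "default_forcefield", "default_sybyl_mapping", "make_random_ligand",
    "make_benchmark_ligand", "PlantedScenario", "make_planted_scenario",
    "recovery_benchmark", "toy_worked_example",
    "optimal_pair_distance", "make_decoy_library",
]

# name, radius, well_depth, charge, elec_scale, hydrophobicity, hbond, hbond_depth
_DEFAULT_TYPES = [
    ("C.3",  1.80, 0.20,  0.0, 1.0,  0.60, HBondClass.NONE,     0.0),
    ("C.ar", 1.70, 0.25,  0.0, 1.0,  0.50, HBondClass.NONE,     0.0),
    ("N.don", 1.60, 0.16,  0.0, 1.0, -0.40, HBondClass.DONOR,    1.2),
    ("O.acc", 1.50, 0.18,  0.0, 1.0, -0.50, HBondClass.ACCEPTOR, 1.5),
    ("N.plus", 1.60, 0.16,  1.0, 1.0, -0.80, HBondClass.DONOR,    1.2),
    ("O.minus", 1.50, 0.18, -1.0, 1.0, -0.80, HBondClass.ACCEPTOR, 1.5),
    ("O.pol", 1.50, 0.18,  0.0, 1.0, -0.30, HBondClass.BOTH,     1.0),
    ("S",    2.00, 0.35,  0.0, 1.0,  0.20, HBondClass.NONE,     0.0),
]

# SYBYL atom type -> default type name above
_SYBYL_MAP = {
    "C.3": "C.3", "C.2": "C.3", "C.1": "C.3", "C.cat": "C.3",
    "C.ar": "C.ar",
    "N.3": "N.don", "N.2": "N.don", "N.am": "N.don", "N.pl3": "N.don",
    "N.ar": "N.don", "N.1": "N.don",
    "N.4": "N.plus",
    "O.3": "O.pol", "O.2": "O.acc", "O.co2": "O.minus",
    "S.3": "S", "S.2": "S", "S.o": "S", "S.o2": "S",
    "P.3": "S",
}


def default_forcefield() -> ForceFieldTable:
    """Eight-type table spanning apolar, aromatic, donor/acceptor,
    charged and polar chemistry; default global constants."""
    names, types = [], []
    for name, r, w, q, es, h, hb, hd in _DEFAULT_TYPES:
        names.append(name)
        types.append(AtomTypeParams(r, w, q, es, h, hb, hd))
    return ForceFieldTable(types=tuple(types), globals=GlobalConstants(),
                           names=tuple(names))


def default_sybyl_mapping(ff: ForceFieldTable | None = None) -> dict[str, int]:
    ff = ff or default_forcefield()
    return {sybyl: ff.type_id(name) for sybyl, name in _SYBYL_MAP.items()}


def make_random_ligand(n_atoms: int | None = None,
                       type_pool=None, seed: int = 0,
                       radius: float = 5.0,
                       min_sep: float = 1.2,
                       max_tries: int = 10000) -> MoleculeStruct:
    """Random rigid ligand: atoms in a ``radius``-angstrom ball with a
    minimum inter-atom separation, types drawn from ``type_pool``.

    With ``n_atoms`` unspecified, the count is uniform over 15..40 — the
    non-hydrogen size range of typical screening compounds.
    """
    rs = RandomStream(seed=seed, stream_id=0x11A4D)
    if n_atoms is None:
        n_atoms = 15 + int(rs.next_uniform() * 26)
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    if type_pool is None:
        type_pool = list(range(len(_DEFAULT_TYPES)))
    coords: list[np.ndarray] = []
    tries = 0
    while len(coords) < n_atoms:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_atoms} atoms with separation "
                f">= {min_sep} A in a {radius} A ball after {max_tries} tries")
        tries += 1
        p = np.array(rs.uniform(3)) * 2.0 * radius - radius
        if p @ p > radius * radius:
            continue
        if any(np.linalg.norm(p - q) < min_sep for q in coords):
            continue
        coords.append(p)
    type_ids = np.array(
        [type_pool[int(rs.next_uniform() * len(type_pool)) % len(type_pool)]
         for _ in range(n_atoms)], dtype=np.int32)
    return MoleculeStruct.from_coords(np.array(coords), type_ids)


def optimal_pair_distance(type_i: int, type_j: int, ff: ForceFieldTable,
                          step: float = 1e-3) -> tuple[float, float]:
    """(argmin distance, min energy) of one type pair, by dense grid scan.

    Scanning the reference energy keeps planted scenarios consistent
    with the forcefield by construction rather than by re-derivation.
    """
    dmax = ff.max_cutoff()
    ds = np.arange(step, dmax + step, step)
    es = np.array([pair_energy_reference(type_i, type_j, float(d), ff)
                   for d in ds])
    k = int(np.argmin(es))
    return float(ds[k]), float(es[k])


# ligand type -> complementary receptor type (by default-table name).
# Charged ligand atoms get *neutral* H-bond partners: planted
# complementarity is defined through the short-range terms (steric well
# floor, H-bond optimum); bare-monopole Coulomb pairing is long-range
# and clamp-dominated at contact, which would make the planted pose
# non-unique instead of a constructed global optimum.
_PARTNER = {
    "C.3": "C.3", "C.ar": "C.3", "S": "C.3",
    "N.don": "O.acc", "O.acc": "N.don",
    "N.plus": "O.acc", "O.minus": "N.don",
    "O.pol": "N.don",
}

# decoy receptor atoms are drawn from uncharged types for the same reason
_NEUTRAL_DECOY_TYPES = ("C.3", "C.ar", "N.don", "O.acc", "O.pol", "S")


@dataclass
class PlantedScenario:
    """A docking problem whose global minimum is planted by construction.

    Every ligand atom, posed at ``planted_td``, has one complementary
    receptor atom at that pair's optimal distance; decoy receptor atoms
    sit >= 8 A from the pocket and contribute nothing at the planted
    pose.  ``pocket_ids`` are the complementary (non-decoy) receptor
    atom indices.
    """

    receptor: MoleculeStruct
    ligand: MoleculeStruct
    planted_td: TransformDescriptor
    space: SearchSpace
    ff: ForceFieldTable
    pocket_ids: np.ndarray


def make_planted_scenario(ligand: MoleculeStruct,
                          planted_td: TransformDescriptor,
                          n_decoy_receptor_atoms: int = 32,
                          seed: int = 0,
                          ff: ForceFieldTable | None = None) -> PlantedScenario:
    """Build the complementary receptor around the posed ligand."""
    ff = ff or default_forcefield()
    rs = RandomStream(seed=seed, stream_id=0x9CEA2)
    names = ff.names
    partner_ids = {names.index(k): names.index(v) for k, v in _PARTNER.items()
                   if k in names and v in names}

    pivot = ligand.centroid()
    posed = apply_transform(build_transform(planted_td, pivot),
                            ligand.coords.astype(np.float64))
    pocket_center = posed.mean(axis=0)

    rec_coords: list[np.ndarray] = []
    rec_types: list[int] = []
    dist_cache: dict[tuple[int, int], float] = {}
    for a in range(ligand.n_atoms):
        ti = int(ligand.type_ids[a])
        tj = partner_ids.get(ti, ti)
        key = (ti, tj)
        if key not in dist_cache:
            d_best = optimal_pair_distance(ti, tj, ff)[0]
            r_ij = ff.types[ti].radius + ff.types[tj].radius
            # the steric well floor sits on a discontinuity at d = r_ij;
            # nudge strictly into the well so float32 coordinate rounding
            # cannot flip the contact onto the repulsive side
            if abs(d_best - r_ij) < 0.05:
                d_best = r_ij + 0.05
            dist_cache[key] = d_best
        d_opt = dist_cache[key]
        # random direction in the outward hemisphere.  Among many
        # candidates keep the one whose partner is farthest from every
        # *other* posed atom and every placed partner: each designed
        # contact is then isolated (the planted energy is the designed
        # per-pair sum), and the off-radial contact directions make
        # rotations of the planted pose energetically stiff, so the
        # planted descriptor is a genuine energy minimum rather than a
        # soft mode of the smooth desolvation background.
        out_dir = posed[a] - pocket_center
        nrm = np.linalg.norm(out_dir)
        if nrm < 1e-9:
            out_dir = np.array([1.0, 0.0, 0.0])
            nrm = 1.0
        out_dir = out_dir / nrm
        others = np.delete(posed, a, axis=0)
        best_pos, best_clearance = None, -np.inf
        for _ in range(128):
            v = np.array(rs.uniform(3)) * 2.0 - 1.0
            nv = np.linalg.norm(v)
            if nv < 1e-6 or nv > 1.0:
                continue
            v = v / nv
            if v @ out_dir < 0.1:     # outward hemisphere, with margin
                continue
            cand = posed[a] + d_opt * v
            clearance = np.min(np.linalg.norm(others - cand, axis=1)) \
                if len(others) else np.inf
            if rec_coords:
                clearance = min(clearance,
                                np.min(np.linalg.norm(
                                    np.asarray(rec_coords) - cand, axis=1)))
            if clearance > best_clearance:
                best_clearance, best_pos = clearance, cand
        if best_pos is None:          # degenerate RNG run; fall back radial
            best_pos = posed[a] + d_opt * out_dir
        rec_coords.append(best_pos)
        rec_types.append(tj)
    pocket_ids = np.arange(len(rec_coords))

    # decoys: neutral background atoms on a far shell, >= 8 A from every
    # posed atom and >= 5 A from each other — isolated atoms, never a
    # cluster that could form an attractive pseudo-pocket of its own
    decoy_pool = [ff.type_id(nm) for nm in _NEUTRAL_DECOY_TYPES
                  if nm in ff.names] or list(range(ff.n_types))
    decoy_coords: list[np.ndarray] = []
    placed = 0
    guard = 0
    while placed < n_decoy_receptor_atoms and guard < 200000:
        guard += 1
        v = np.array(rs.uniform(3)) * 2.0 - 1.0
        nrm = np.linalg.norm(v)
        if nrm < 1e-6:
            continue
        shell_r = 12.0 + 4.0 * rs.next_uniform()
        p = pocket_center + (v / nrm) * shell_r
        if np.min(np.linalg.norm(posed - p, axis=1)) < 8.0:
            continue
        if decoy_coords and np.min(np.linalg.norm(
                np.asarray(decoy_coords) - p, axis=1)) < 5.0:
            continue
        decoy_coords.append(p)
        rec_coords.append(p)
        rec_types.append(decoy_pool[int(rs.next_uniform() * len(decoy_pool))
                                    % len(decoy_pool)])
        placed += 1

    receptor = MoleculeStruct.from_coords(np.array(rec_coords),
                                          np.array(rec_types, dtype=np.int32))
    space = SearchSpace(
        center=np.array([planted_td.tx, planted_td.ty, planted_td.tz]),
        half_extent=np.array([5.0, 5.0, 5.0]),
        angle_lo=np.array([-np.pi] * 3),
        angle_hi=np.array([np.pi] * 3),
    )
    return PlantedScenario(receptor=receptor, ligand=ligand,
                           planted_td=planted_td, space=space, ff=ff,
                           pocket_ids=pocket_ids)


def make_decoy_library(n_ligands: int = 9, seed: int = 0,
                       n_atoms: int = 15) -> list[MoleculeStruct]:
    """Random ligands with no constructed complement to any receptor."""
    return [make_random_ligand(n_atoms=n_atoms, seed=seed * 1000 + k + 1)
            for k in range(n_ligands)]


def make_benchmark_ligand(n_atoms: int = 35, seed: int = 0,
                          hydrophobic_fraction: float = 0.4,
                          ff: ForceFieldTable | None = None) -> MoleculeStruct:
    """Drug-sized amphiphilic test ligand for pose-recovery benchmarks.

    Atom positions come from :func:`make_random_ligand`; types are then
    assigned by position: the atoms on one side of a random axis form a
    hydrophobic face (apolar C), the rest alternate H-bond donor and
    acceptor.  Rationale: pose recovery is only well-posed for ligands
    whose contacts determine the orientation — small fragments dock
    ambiguously — and an amphiphilic type pattern gives the smooth
    long-range desolvation term a preferred orientation (a funnel), as
    real binding epitopes do, while the donor/acceptor pattern pins the
    pose through short-range complementarity.
    """
    ff = ff or default_forcefield()
    lig = make_random_ligand(n_atoms=n_atoms, seed=seed)
    rs = RandomStream(seed=seed, stream_id=0xA3F)
    u = np.array(rs.uniform(3)) * 2.0 - 1.0
    u /= np.linalg.norm(u)
    proj = (lig.coords.astype(np.float64) - lig.centroid()) @ u
    order = np.argsort(proj)
    nh = int(n_atoms * hydrophobic_fraction)
    tid = np.empty(n_atoms, dtype=np.int32)
    tid[order[:nh]] = ff.type_id("C.3")
    polar = order[nh:]
    tid[polar[::2]] = ff.type_id("N.don")
    tid[polar[1::2]] = ff.type_id("O.acc")
    return MoleculeStruct(lig.x, lig.y, lig.z, tid)


def recovery_benchmark(seed: int) -> tuple[PlantedScenario, TransformDescriptor]:
    """One pose-recovery problem: benchmark ligand + planted scenario.

    The planted descriptor is drawn from the seed (translations within
    +-2 A of the origin, angles over the full circle); the search space
    is the scenario's standard box (planted translation +-5 A, full
    rotation range), so the search never starts centred on the answer.
    """
    rs = RandomStream(seed=seed, stream_id=77)
    lig = make_benchmark_ligand(seed=seed)
    td = TransformDescriptor(*(np.array(rs.uniform(3)) * 4.0 - 2.0),
                             *(np.array(rs.uniform(3)) * 2.0 * np.pi - np.pi))
    return make_planted_scenario(lig, td, seed=seed), td


def toy_worked_example() -> tuple[MoleculeStruct, MoleculeStruct, list[tuple[float, float]]]:
    """One apolar ligand atom vs one apolar receptor atom, with the
    hand-computable energy table at the characteristic distances.

    For the default C.3/C.3 pair (r_ij = 3.6 A, eps = 0.2 EU, S = 10,
    w = 1 A, hydrophobicity 0.6 so the desolvation term is active inside
    6 A): returns [(d, energy), ...] at d in {0, r_ij, r_ij + w/2,
    r_ij + w, 50}.
    """
    ff = default_forcefield()
    t = ff.type_id("C.3")
    lig = MoleculeStruct.from_coords(np.zeros((1, 3)), np.array([t]))
    rec = MoleculeStruct.from_coords(np.zeros((1, 3)), np.array([t]))
    g = ff.globals
    r_ij = 2 * ff.types[t].radius
    table = []
    for d in (0.0, r_ij, r_ij + g.well_width / 2, r_ij + g.well_width, 50.0):
        table.append((d, pair_energy_reference(t, t, d, ff)))
    return lig, rec, table
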