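"""Empirical soft-core forcefield: parameter table and reference energy.

The pairwise interaction energy is a sum of four distance- and type-gated
terms — steric, electrostatic, desolvation and hydrogen bond — each with
compact support and each finite at zero separation (soft core).  With
r_ij = r_i + r_j and eps_ij = sqrt(eps_i * eps_j):

  steric         d <  r_ij          ->  +S * eps_ij * (1 - d/r_ij)
                 r_ij <= d < r_ij+w ->  -eps_ij * (1 - (d - r_ij)/w)
  electrostatic  q_i q_j != 0,
                 d < elec_cutoff    ->  k * es_i es_j q_i q_j
                                         / (dielectric * max(d, 1 A))
                                         * (1 - d/elec_cutoff)
  desolvation    d < desolv_cutoff  ->  -desolv_scale * h_i h_j
                                         * (1 - d/desolv_cutoff)
  hydrogen bond  classes complementary and hb_min <= d <= hb_max ->
                 -sqrt(hbd_i hbd_j) * (1 - |d - d_opt| / ((hb_max-hb_min)/2)),
                 d_opt = (hb_min + hb_max)/2

The steric term is intentionally discontinuous at d = r_ij (repulsive ramp
meets the well floor), tolerant of the coarse geometry of rigid-body
docking.  Energies are in arbitrary units ("EU"): the engine only ranks
poses.  This scalar branched implementation is the oracle for the masked
vectorized kernel.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Callable, TextIO

__all__ = [
    "HBondClass",
    "AtomTypeParams",
    "GlobalConstants",
    "ForceFieldTable",
    "ForceFieldFormatError",
    "load_forcefield",
    "dump_forcefield",
    "pair_energy_reference",
    "specialize_constants",
    "hbond_compatible",
]


class HBondClass(IntEnum):
    NONE = 0
    DONOR = 1
    ACCEPTOR = 2
    BOTH = 3


def hbond_compatible(a: HBondClass, b: HBondClass) -> bool:
    """DONOR pairs with ACCEPTOR; BOTH pairs with DONOR, ACCEPTOR or BOTH."""
    if a == HBondClass.NONE or b == HBondClass.NONE:
        return False
    if a == HBondClass.BOTH or b == HBondClass.BOTH:
        return True
    return a != b


@dataclass(frozen=True)
class AtomTypeParams:
    """Seven per-type parameters of one atom type."""

    radius: float          # A, > 0
    well_depth: float      # EU, >= 0
    charge: float          # e
    elec_scale: float      # dimensionless, >= 0
    hydrophobicity: float  # dimensionless, in [-1, 1]
    hbond_class: HBondClass
    hbond_depth: float     # EU, >= 0

    def __post_init__(self):
        if not (self.radius > 0):
            raise ValueError(f"radius must be > 0, got {self.radius}")
        if self.well_depth < 0 or self.hbond_depth < 0 or self.elec_scale < 0:
            raise ValueError("well_depth, hbond_depth, elec_scale must be >= 0")
        if not (-1.0 <= self.hydrophobicity <= 1.0):
            raise ValueError("hydrophobicity must be in [-1, 1]")


@dataclass(frozen=True)
class GlobalConstants:
    """Constants shared by every atom type (cutoffs, scales)."""

    well_width: float = 1.0       # A
    repulsion_scale: float = 10.0
    elec_cutoff: float = 8.0      # A
    coulomb_k: float = 332.0637   # EU*A/e^2
    dielectric: float = 4.0
    desolv_cutoff: float = 6.0    # A
    desolv_scale: float = 0.2     # EU
    hb_min: float = 2.2           # A
    hb_max: float = 3.5           # A

    def __post_init__(self):
        vals = (self.well_width, self.repulsion_scale, self.elec_cutoff,
                self.coulomb_k, self.dielectric, self.desolv_cutoff,
                self.desolv_scale, self.hb_min, self.hb_max)
        if any(v <= 0 for v in vals):
            raise ValueError("all global constants must be positive")
        if not self.hb_min < self.hb_max:
            raise ValueError("hb_min must be < hb_max")


@dataclass(frozen=True)
class ForceFieldTable:
    """Dense 0..T-1 indexed atom-type table plus global constants.

    The serialized per-type payload is exactly the seven numeric fields;
    at the ~35-type scale of a production table the whole look-up table
    is about a kilobyte.
    """

    types: tuple[AtomTypeParams, ...]
    globals: GlobalConstants = field(default_factory=GlobalConstants)
    names: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.types:
            raise ValueError("forcefield table needs at least one type")
        names = self.names or tuple(f"T{i}" for i in range(len(self.types)))
        if len(names) != len(self.types):
            raise ValueError("names and types length mismatch")
        if len(set(names)) != len(names):
            raise ValueError("duplicate type names")
        object.__setattr__(self, "names", tuple(names))
        object.__setattr__(self, "types", tuple(self.types))

    @property
    def n_types(self) -> int:
        return len(self.types)

    def type_id(self, name: str) -> int:
        return self.names.index(name)

    def max_cutoff(self) -> float:
        """Distance beyond which every term of every pair is zero."""
        g = self.globals
        rmax = max(t.radius for t in self.types)
        return max(2 * rmax + g.well_width, g.elec_cutoff,
                   g.desolv_cutoff, g.hb_max)


class ForceFieldFormatError(ValueError):
    """Raised on malformed forcefield files; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None
                         else f"line {line}: {message}")


_GLOBAL_KEYS = ("well_width", "repulsion_scale", "elec_cutoff", "coulomb_k",
                "dielectric", "desolv_cutoff", "desolv_scale", "hb_min", "hb_max")


def load_forcefield(source: TextIO | str) -> ForceFieldTable:
    """Read a forcefield from delimited text.

    Format: a ``[globals]`` section of ``key = value`` lines, then a
    ``[types]`` section with one whitespace-delimited row per atom type:
    ``name radius well_depth charge elec_scale hydrophobicity hbond_class
    hbond_depth``.  ``#`` starts a comment; blank lines are ignored.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    section = None
    gkwargs: dict[str, float] = {}
    names: list[str] = []
    types: list[AtomTypeParams] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("["):
            section = line.strip("[]").lower()
            if section not in ("globals", "types"):
                raise ForceFieldFormatError(f"unknown section [{section}]", lineno)
            continue
        if section == "globals":
            if "=" not in line:
                raise ForceFieldFormatError("expected key = value", lineno)
            key, _, val = (s.strip() for s in line.partition("="))
            if key not in _GLOBAL_KEYS:
                raise ForceFieldFormatError(f"unknown global '{key}'", lineno)
            try:
                gkwargs[key] = float(val)
            except ValueError:
                raise ForceFieldFormatError(
                    f"non-numeric value '{val}' for global '{key}'", lineno) from None
        elif section == "types":
            fields = line.split()
            if len(fields) != 8:
                raise ForceFieldFormatError(
                    f"type row needs name + 7 fields, got {len(fields)}", lineno)
            name = fields[0]
            if name in names:
                raise ForceFieldFormatError(f"duplicate type name '{name}'", lineno)
            try:
                radius, well, charge, escale, hphob = map(float, fields[1:6])
                hclass = HBondClass[fields[6].upper()]
                hdepth = float(fields[7])
            except KeyError:
                raise ForceFieldFormatError(
                    f"unknown hbond class '{fields[6]}'", lineno) from None
            except ValueError:
                raise ForceFieldFormatError(
                    f"non-numeric field in type row: {line!r}", lineno) from None
            try:
                types.append(AtomTypeParams(radius, well, charge, escale,
                                            hphob, hclass, hdepth))
            except ValueError as e:
                raise ForceFieldFormatError(str(e), lineno) from None
            names.append(name)
        else:
            raise ForceFieldFormatError(
                "content before any [globals]/[types] section", lineno)
    if not types:
        raise ForceFieldFormatError("no atom types defined")
    try:
        g = GlobalConstants(**gkwargs)
    except ValueError as e:
        raise ForceFieldFormatError(str(e)) from None
    return ForceFieldTable(types=tuple(types), globals=g, names=tuple(names))


def dump_forcefield(ff: ForceFieldTable, stream: TextIO | None = None) -> str:
    """Write a table in the format ``load_forcefield`` reads (round-trips)."""
    out = io.StringIO()
    out.write("[globals]\n")
    for key in _GLOBAL_KEYS:
        out.write(f"{key} = {getattr(ff.globals, key)!r}\n")
    out.write("\n[types]\n")
    for name, t in zip(ff.names, ff.types):
        out.write(f"{name} {t.radius!r} {t.well_depth!r} {t.charge!r} "
                  f"{t.elec_scale!r} {t.hydrophobicity!r} "
                  f"{t.hbond_class.name} {t.hbond_depth!r}\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def pair_energy_reference(type_i: int, type_j: int, d: float,
                          ff: ForceFieldTable) -> float:
    """Scalar branched evaluation of one atom-atom interaction at distance d.

    The plain ``if/else`` form of the forcefield, kept as the oracle the
    branch-free kernel is checked against.  Symmetric in (i, j); finite
    for every d >= 0; identically zero beyond the largest cutoff.
    """
    if d < 0 or not math.isfinite(d):
        raise ValueError(f"distance must be finite and >= 0, got {d}")
    pi = ff.types[type_i]   # IndexError on invalid id, as specified
    pj = ff.types[type_j]
    g = ff.globals
    e = 0.0

    # steric: soft-core linear repulsion ramp, then a triangular well
    r_ij = pi.radius + pj.radius
    eps = math.sqrt(pi.well_depth * pj.well_depth)
    if d < r_ij:
        e += g.repulsion_scale * eps * (1.0 - d / r_ij)
    elif d < r_ij + g.well_width:
        e += -eps * (1.0 - (d - r_ij) / g.well_width)

    # electrostatics: screened Coulomb, tapered to zero at the cutoff,
    # distance clamped at 1 A so the term stays finite at contact
    qq = pi.charge * pj.charge
    if qq != 0.0 and d < g.elec_cutoff:
        e += (g.coulomb_k * (pi.elec_scale * pj.elec_scale) * qq
              / (g.dielectric * max(d, 1.0)) * (1.0 - d / g.elec_cutoff))

    # desolvation: pairwise hydrophobic contact preference.  The h_i h_j
    # product is grouped so the term is bit-exactly symmetric in (i, j).
    if d < g.desolv_cutoff:
        e += (-g.desolv_scale * (pi.hydrophobicity * pj.hydrophobicity)
              * (1.0 - d / g.desolv_cutoff))

    # hydrogen bond: triangular well over [hb_min, hb_max] for
    # complementary donor/acceptor classes
    if hbond_compatible(pi.hbond_class, pj.hbond_class) and g.hb_min <= d <= g.hb_max:
        d_opt = 0.5 * (g.hb_min + g.hb_max)
        half = 0.5 * (g.hb_max - g.hb_min)
        e += -math.sqrt(pi.hbond_depth * pj.hbond_depth) * (1.0 - abs(d - d_opt) / half)

    return e


def specialize_constants(ff: ForceFieldTable) -> Callable[[int, int, float], float]:
    """Fold the global constants and type rows into a closed evaluator.

    The returned function captures every parameter by value at call time
    (the runtime analogue of compiling constants into a kernel): mutating
    or replacing the table afterwards cannot change its output, and for
    every (i, j, d) it returns exactly what ``pair_energy_reference``
    returns on the captured table.
    """
    g = ff.globals
    S, w = g.repulsion_scale, g.well_width
    coulomb_k, dielectric = g.coulomb_k, g.dielectric
    elec_cut, desolv_cut, dscale = g.elec_cutoff, g.desolv_cutoff, g.desolv_scale
    hb_min, hb_max = g.hb_min, g.hb_max
    d_opt = 0.5 * (hb_min + hb_max)
    half = 0.5 * (hb_max - hb_min)

    radius = tuple(t.radius for t in ff.types)
    well = tuple(t.well_depth for t in ff.types)
    charge = tuple(t.charge for t in ff.types)
    escale = tuple(t.elec_scale for t in ff.types)
    hphob = tuple(t.hydrophobicity for t in ff.types)
    hclass = tuple(t.hbond_class for t in ff.types)
    hdepth = tuple(t.hbond_depth for t in ff.types)

    def evaluate(type_i: int, type_j: int, d: float) -> float:
        if d < 0 or not math.isfinite(d):
            raise ValueError(f"distance must be finite and >= 0, got {d}")
        e = 0.0
        r_ij = radius[type_i] + radius[type_j]
        eps = math.sqrt(well[type_i] * well[type_j])
        if d < r_ij:
            e += S * eps * (1.0 - d / r_ij)
        elif d < r_ij + w:
            e += -eps * (1.0 - (d - r_ij) / w)
        # op order matches pair_energy_reference exactly (bit-for-bit contract)
        qq = charge[type_i] * charge[type_j]
        if qq != 0.0 and d < elec_cut:
            e += (coulomb_k * (escale[type_i] * escale[type_j]) * qq
                  / (dielectric * max(d, 1.0)) * (1.0 - d / elec_cut))
        if d < desolv_cut:
            e += (-dscale * (hphob[type_i] * hphob[type_j])
                  * (1.0 - d / desolv_cut))
        if hbond_compatible(hclass[type_i], hclass[type_j]) and hb_min <= d <= hb_max:
            e += -math.sqrt(hdepth[type_i] * hdepth[type_j]) * (1.0 - abs(d - d_opt) / half)
        return e

    return evaluate
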