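"""Readers and writers: Tripos Mol2 in, compact binaries out.

Text Mol2 is the exchange format for receptors and ligand libraries;
before docking, molecules are typed against the forcefield and packed
into a compact binary conformation format (BCF) in which each atom is
exactly 16 bytes — three little-endian float32 coordinates plus one
int32 forcefield type id — so the docking kernel can read its inputs
without any parsing.  Best-pose results serialize as a 24-byte
six-float32 transformation descriptor plus a 4-byte ligand identifier
(and a float32 energy extension so rankings are self-contained), with a
human-readable TSV companion.

The Mol2 dialect is deliberately minimal: only @<TRIPOS>MOLECULE and
@<TRIPOS>ATOM are interpreted; BOND and other sections are tolerated and
skipped (rigid-body docking needs no connectivity).
"""

from __future__ import annotations

import io
import struct
from dataclasses import dataclass
from typing import BinaryIO, Iterable, TextIO

import numpy as np

from .forcefield import ForceFieldTable
from .geometry import TransformDescriptor
from .kernel import MoleculeStruct

__all__ = [
    "Mol2Atom", "Mol2Molecule", "Mol2FormatError", "read_mol2", "write_mol2",
    "typify", "read_type_mapping",
    "BcfLigand", "write_bcf", "read_bcf", "BcfFormatError",
    "ResultRecord", "write_results", "read_results", "results_tsv",
    "ATOM_RECORD_BYTES", "TD_BYTES", "LIGAND_ID_BYTES",
]

ATOM_RECORD_BYTES = 16   # 3 x float32 position + 1 x int32 type id
TD_BYTES = 24            # 6 x float32 descriptor
LIGAND_ID_BYTES = 4      # uint32 ligand identifier

_BCF_MAGIC = b"BCF1"
_RES_MAGIC = b"BRR1"


# ---------------------------------------------------------------- Mol2 --

@dataclass(frozen=True)
class Mol2Atom:
    name: str
    x: float
    y: float
    z: float
    sybyl_type: str
    charge: float = 0.0


@dataclass(frozen=True)
class Mol2Molecule:
    name: str
    atoms: tuple[Mol2Atom, ...]
    line_span: tuple[int, int] = (0, 0)   # 1-based first/last source line


class Mol2FormatError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(message if line is None else f"line {line}: {message}")


def read_mol2(source: TextIO | str) -> list[Mol2Molecule]:
    """Parse all molecules of a Mol2 stream, in file order.

    Multi-molecule files (conformation libraries) are supported.  The
    declared atom count in each MOLECULE record is checked against the
    parsed ATOM section.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    lines = source.read().splitlines()
    molecules: list[Mol2Molecule] = []
    i = 0
    n = len(lines)

    def is_section(line: str) -> bool:
        return line.strip().startswith("@<TRIPOS>")

    while i < n:
        line = lines[i].strip()
        if line != "@<TRIPOS>MOLECULE":
            if is_section(line) and molecules == [] and line:
                raise Mol2FormatError(
                    f"expected @<TRIPOS>MOLECULE first, got {line!r}", i + 1)
            i += 1
            continue
        first_line = i + 1
        i += 1
        # record line 1: molecule name (may be blank)
        while i < n and not lines[i].strip():
            i += 1
        if i >= n:
            raise Mol2FormatError("truncated MOLECULE record", first_line)
        mol_name = lines[i].strip()
        i += 1
        # record line 2: counts — first integer is the atom count
        declared = None
        if i < n and lines[i].split():
            try:
                declared = int(lines[i].split()[0])
            except ValueError:
                raise Mol2FormatError(
                    f"bad counts line {lines[i]!r}", i + 1) from None
        i += 1
        # scan forward for the ATOM section of this molecule
        atoms: list[Mol2Atom] = []
        while i < n and lines[i].strip() != "@<TRIPOS>MOLECULE":
            if lines[i].strip() == "@<TRIPOS>ATOM":
                i += 1
                while i < n and not is_section(lines[i]) \
                        and lines[i].strip() != "":
                    fields = lines[i].split()
                    if len(fields) < 6:
                        raise Mol2FormatError(
                            f"ATOM line needs >= 6 fields, got {len(fields)}",
                            i + 1)
                    try:
                        atoms.append(Mol2Atom(
                            name=fields[1],
                            x=float(fields[2]), y=float(fields[3]),
                            z=float(fields[4]), sybyl_type=fields[5],
                            charge=float(fields[8]) if len(fields) > 8 else 0.0))
                    except ValueError:
                        raise Mol2FormatError(
                            f"malformed ATOM line: {lines[i]!r}", i + 1) from None
                    i += 1
            else:
                i += 1
        if declared is not None and declared != len(atoms):
            raise Mol2FormatError(
                f"molecule {mol_name!r} declares {declared} atoms, "
                f"parsed {len(atoms)}", first_line)
        molecules.append(Mol2Molecule(name=mol_name, atoms=tuple(atoms),
                                      line_span=(first_line, i)))
    if not molecules:
        raise Mol2FormatError("no @<TRIPOS>MOLECULE section found")
    return molecules


def write_mol2(molecules: Iterable[Mol2Molecule], stream: TextIO | None = None) -> str:
    """Emit molecules in the minimal Mol2 dialect ``read_mol2`` accepts."""
    out = io.StringIO()
    for mol in molecules:
        out.write("@<TRIPOS>MOLECULE\n")
        out.write(f"{mol.name}\n")
        out.write(f"{len(mol.atoms)} 0 0 0 0\n")
        out.write("SMALL\nUSER_CHARGES\n")
        out.write("@<TRIPOS>ATOM\n")
        for k, a in enumerate(mol.atoms, start=1):
            out.write(f"{k:>7d} {a.name:<8s} {a.x:>10.4f} {a.y:>10.4f} "
                      f"{a.z:>10.4f} {a.sybyl_type:<8s} 1 LIG "
                      f"{a.charge:>8.4f}\n")
    text = out.getvalue()
    if stream is not None:
        stream.write(text)
    return text


def read_type_mapping(source: TextIO | str) -> dict[str, int]:
    """Two-column text: SYBYL type name -> forcefield type id."""
    if isinstance(source, str):
        source = io.StringIO(source)
    mapping: dict[str, int] = {}
    for lineno, raw in enumerate(source, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        fields = line.split()
        if len(fields) != 2:
            raise Mol2FormatError(
                f"mapping row needs 2 columns, got {len(fields)}", lineno)
        try:
            mapping[fields[0]] = int(fields[1])
        except ValueError:
            raise Mol2FormatError(
                f"non-integer type id {fields[1]!r}", lineno) from None
    return mapping


def typify(mol: Mol2Molecule, mapping: dict[str, int],
           drop_hydrogens: bool = True,
           charges_from_mol2: bool = True,
           ff: ForceFieldTable | None = None) -> MoleculeStruct:
    """Map a parsed Mol2 molecule onto dense forcefield type ids.

    Hydrogens (SYBYL type ``H`` or a subtype like ``H.spc``) are dropped
    by default — docking scores non-hydrogen atoms only.  Every retained
    SYBYL type must appear in the mapping; unmapped types raise with the
    full offending list.  When ``charges_from_mol2`` is False the partial
    charge column is ignored (the forcefield type's charge applies).
    """
    retained = [a for a in mol.atoms
                if not (drop_hydrogens
                        and (a.sybyl_type == "H"
                             or a.sybyl_type.startswith("H.")))]
    unmapped = sorted({a.sybyl_type for a in retained
                       if a.sybyl_type not in mapping})
    if unmapped:
        raise KeyError(f"unmapped SYBYL types in {mol.name!r}: {unmapped}")
    coords = np.array([[a.x, a.y, a.z] for a in retained],
                      dtype=np.float32).reshape(-1, 3)
    type_ids = np.array([mapping[a.sybyl_type] for a in retained],
                        dtype=np.int32)
    ms = MoleculeStruct.from_coords(coords, type_ids)
    if ff is not None:
        ms.validate_types(ff)
    return ms


# ---------------------------------------------------- binary conformations --

@dataclass(frozen=True)
class BcfLigand:
    """One conformation in the binary conformation format."""

    ligand_id: int
    mol: MoleculeStruct


class BcfFormatError(ValueError):
    pass


def write_bcf(ligands: Iterable[BcfLigand], stream: BinaryIO | None = None) -> bytes:
    """Serialize conformations: per ligand a 12-byte header (magic,
    ligand_id, n_atoms) then n_atoms 16-byte atom records, little-endian."""
    out = io.BytesIO()
    for lig in ligands:
        m = lig.mol
        out.write(_BCF_MAGIC)
        out.write(struct.pack("<II", lig.ligand_id & 0xFFFFFFFF, m.n_atoms))
        atoms = np.empty((m.n_atoms, 4), dtype="<f4")
        atoms[:, 0] = m.x
        atoms[:, 1] = m.y
        atoms[:, 2] = m.z
        atoms[:, 3] = m.type_ids.astype("<i4").view("<f4")
        out.write(atoms.tobytes())
    data = out.getvalue()
    if stream is not None:
        stream.write(data)
    return data


def read_bcf(data: bytes | BinaryIO) -> list[BcfLigand]:
    """Inverse of :func:`write_bcf`; bit-exact round trip."""
    if not isinstance(data, (bytes, bytearray)):
        data = data.read()
    ligands: list[BcfLigand] = []
    off = 0
    n = len(data)
    while off < n:
        if n - off < 12:
            raise BcfFormatError(f"truncated header at byte {off}")
        if data[off:off + 4] != _BCF_MAGIC:
            raise BcfFormatError(
                f"bad magic {data[off:off + 4]!r} at byte {off}")
        ligand_id, n_atoms = struct.unpack_from("<II", data, off + 4)
        off += 12
        body = n_atoms * ATOM_RECORD_BYTES
        if n - off < body:
            raise BcfFormatError(
                f"truncated atom block for ligand {ligand_id} at byte {off}")
        raw = np.frombuffer(data, dtype="<f4", count=4 * n_atoms,
                            offset=off).reshape(n_atoms, 4)
        off += body
        mol = MoleculeStruct(raw[:, 0].copy(), raw[:, 1].copy(),
                             raw[:, 2].copy(),
                             raw[:, 3].copy().view("<i4"))
        ligands.append(BcfLigand(ligand_id=ligand_id, mol=mol))
    return ligands


# ------------------------------------------------------------- results --

@dataclass(frozen=True)
class ResultRecord:
    """One best pose: 24-byte descriptor + 4-byte ligand id (+ energy)."""

    td: TransformDescriptor
    ligand_id: int
    energy: float
    ligand_name: str = ""

    def td_bytes(self) -> bytes:
        a = np.asarray(self.td.as_array(), dtype="<f4")
        return a.tobytes()

    def ligand_id_bytes(self) -> bytes:
        return struct.pack("<I", self.ligand_id & 0xFFFFFFFF)


def write_results(records: Iterable[ResultRecord],
                  stream: BinaryIO | None = None) -> bytes:
    """Binary result stream: magic + count, then per record the 24-byte
    descriptor block, the 4-byte ligand id, and a float32 energy."""
    records = list(records)
    out = io.BytesIO()
    out.write(_RES_MAGIC)
    out.write(struct.pack("<I", len(records)))
    for r in records:
        out.write(r.td_bytes())
        out.write(r.ligand_id_bytes())
        out.write(struct.pack("<f", r.energy))
    data = out.getvalue()
    if stream is not None:
        stream.write(data)
    return data


def read_results(data: bytes | BinaryIO) -> list[ResultRecord]:
    if not isinstance(data, (bytes, bytearray)):
        data = data.read()
    if len(data) < 8 or data[:4] != _RES_MAGIC:
        raise BcfFormatError("bad result-stream header")
    (count,) = struct.unpack_from("<I", data, 4)
    rec_size = TD_BYTES + LIGAND_ID_BYTES + 4
    if len(data) != 8 + count * rec_size:
        raise BcfFormatError(
            f"result stream length {len(data)} != expected "
            f"{8 + count * rec_size}")
    out: list[ResultRecord] = []
    for k in range(count):
        off = 8 + k * rec_size
        td_vals = np.frombuffer(data, dtype="<f4", count=6, offset=off)
        (ligand_id,) = struct.unpack_from("<I", data, off + TD_BYTES)
        (energy,) = struct.unpack_from("<f", data,
                                       off + TD_BYTES + LIGAND_ID_BYTES)
        out.append(ResultRecord(
            td=TransformDescriptor(*(float(v) for v in td_vals)),
            ligand_id=ligand_id, energy=float(energy)))
    return out


def results_tsv(records: Iterable[ResultRecord]) -> str:
    """Readable companion table; angles reported in degrees."""
    lines = ["ligand_id\tligand_name\tenergy\ttx\tty\ttz\trx_deg\try_deg\trz_deg"]
    for r in records:
        td = r.td
        lines.append("\t".join([
            str(r.ligand_id), r.ligand_name or "-", f"{r.energy:.6g}",
            f"{td.tx:.4f}", f"{td.ty:.4f}", f"{td.tz:.4f}",
            f"{np.rad2deg(td.rx):.3f}", f"{np.rad2deg(td.ry):.3f}",
            f"{np.rad2deg(td.rz):.3f}"]))
    return "\n".join(lines) + "\n"
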