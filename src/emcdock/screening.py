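"""Virtual-screening driver: dock a ligand library, rank by best energy.

Flexible compounds are represented as discrete conformations (grouped by
Mol2 molecule name); every conformation is docked independently by the
EMC search and a ligand's score is the minimum over its conformations.
Each conformation's search is keyed by a sub-seed mixed from (run seed,
ligand-name hash, conformation ordinal), so shuffling the library on
disk changes no energies and no ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .emc import EmcConfig, run_emc
from .forcefield import ForceFieldTable, load_forcefield
from .geometry import SearchSpace, TransformDescriptor
from .io_formats import (ResultRecord, read_bcf, read_mol2,
                         read_type_mapping, results_tsv, typify,
                         write_results)
from .kernel import MoleculeStruct
from .prng import derive_seed, hash_label

logger = logging.getLogger("emcdock")

__all__ = ["ScreeningConfig", "LigandScore", "Conformation",
           "screen_conformations", "screen_library", "load_library"]


@dataclass(frozen=True)
class Conformation:
    """One rigid shape of one ligand, with its stable identity."""

    ligand_name: str
    conf_index: int     # ordinal within the ligand, in library order
    mol: MoleculeStruct


@dataclass(frozen=True)
class LigandScore:
    """Best result of one ligand over all its conformations."""

    ligand_id: int
    ligand_name: str
    best_energy: float
    best_conformation: int
    best_td: TransformDescriptor


@dataclass
class ScreeningConfig:
    """Everything a screen needs; paths may be None for in-memory use."""

    receptor_path: str | Path | None = None
    library_path: str | Path | None = None
    forcefield_path: str | Path | None = None   # None -> packaged default
    mapping_path: str | Path | None = None      # None -> packaged default
    emc: EmcConfig = field(default_factory=EmcConfig)
    top_m: int = 100
    output_prefix: str | Path | None = None
    drop_hydrogens: bool = True
    skip_bad_ligands: bool = False   # False: abort on typify failure
    box_center: np.ndarray | None = None      # None -> receptor centroid
    box_half_extent: float = 5.0              # A per axis
    site_atoms: np.ndarray | None = None      # receptor atom subset (docking site)

    def __post_init__(self):
        if self.top_m < 1:
            raise ValueError("top_m must be >= 1")


def load_library(path: str | Path, mapping: dict[str, int],
                 drop_hydrogens: bool = True,
                 skip_bad: bool = False) -> list[Conformation]:
    """Read a ligand library from Mol2 (text) or BCF (binary).

    Mol2 molecules sharing a name are conformations of one ligand, in
    file order.  BCF conformations are grouped by ligand_id and named
    ``LIG<id>``.
    """
    path = Path(path)
    confs: list[Conformation] = []
    counts: dict[str, int] = {}
    data = path.read_bytes()
    if data[:4] == b"BCF1":
        for rec in read_bcf(data):
            name = f"LIG{rec.ligand_id}"
            k = counts.get(name, 0)
            counts[name] = k + 1
            confs.append(Conformation(name, k, rec.mol))
        return confs
    for mol in read_mol2(data.decode("utf-8")):
        k = counts.get(mol.name, 0)
        counts[mol.name] = k + 1
        try:
            ms = typify(mol, mapping, drop_hydrogens=drop_hydrogens)
        except KeyError:
            if skip_bad:
                logger.warning("skipping conformation %d of %r: "
                               "unmapped atom types", k, mol.name)
                continue
            raise
        confs.append(Conformation(mol.name, k, ms))
    if not confs:
        raise ValueError(f"library {path} contains no usable conformation")
    return confs


def screen_conformations(receptor: MoleculeStruct,
                         conformations: list[Conformation],
                         ff: ForceFieldTable, space: SearchSpace,
                         emc_cfg: EmcConfig, top_m: int = 100,
                         ) -> tuple[list[LigandScore], list[ResultRecord]]:
    """Dock every conformation, aggregate per ligand (min), rank ascending.

    The pure in-memory core of the screen; deterministic and
    library-order invariant.
    """
    if not conformations:
        raise ValueError("empty library")
    # stable ligand ids: order of first appearance
    ligand_ids: dict[str, int] = {}
    for c in conformations:
        ligand_ids.setdefault(c.ligand_name, len(ligand_ids))

    best: dict[str, tuple[float, int, TransformDescriptor]] = {}
    total_interactions = 0
    total_wall = 0.0
    for c in conformations:
        sub_seed = derive_seed(emc_cfg.seed, hash_label(c.ligand_name),
                               c.conf_index)
        result = run_emc(c.mol, receptor, ff, space,
                         replace(emc_cfg, seed=sub_seed))
        total_interactions += result.metrics.interactions
        total_wall += result.metrics.wall_seconds
        e = result.best_energy
        cur = best.get(c.ligand_name)
        if cur is None or (e, c.conf_index) < (cur[0], cur[1]):
            best[c.ligand_name] = (e, c.conf_index, result.best_descriptor)
        logger.info("ligand %-12s conf %2d best energy %10.4f",
                    c.ligand_name, c.conf_index, e)
    if total_wall > 0:
        logger.info("kernel throughput: %.3g interactions/s over %d pairs",
                    total_interactions / total_wall, total_interactions)

    # rank ascending by best energy; ties broken by name for
    # library-order invariance, then by id
    ranked_names = sorted(best, key=lambda nm: (best[nm][0], nm,
                                                ligand_ids[nm]))
    scores = [LigandScore(ligand_id=ligand_ids[nm], ligand_name=nm,
                          best_energy=best[nm][0],
                          best_conformation=best[nm][1],
                          best_td=best[nm][2])
              for nm in ranked_names[:top_m]]
    records = [ResultRecord(td=s.best_td, ligand_id=s.ligand_id,
                            energy=s.best_energy, ligand_name=s.ligand_name)
               for s in scores]
    return scores, records


def screen_library(cfg: ScreeningConfig
                   ) -> tuple[list[LigandScore], list[ResultRecord]]:
    """File-level screen: read inputs, dock, write results + TSV.

    Writes ``<prefix>.results.bin`` and ``<prefix>.results.tsv`` when an
    output prefix is configured.
    """
    from .fixtures import default_forcefield, default_sybyl_mapping

    if cfg.forcefield_path is not None:
        ff = load_forcefield(Path(cfg.forcefield_path).read_text())
    else:
        ff = default_forcefield()
    if cfg.mapping_path is not None:
        mapping = read_type_mapping(Path(cfg.mapping_path).read_text())
    else:
        mapping = default_sybyl_mapping(ff)

    rec_mols = read_mol2(Path(cfg.receptor_path).read_text())
    receptor = typify(rec_mols[0], mapping, drop_hydrogens=cfg.drop_hydrogens)
    if cfg.site_atoms is not None:
        idx = np.asarray(cfg.site_atoms, dtype=np.int64)
        receptor = MoleculeStruct(receptor.x[idx], receptor.y[idx],
                                  receptor.z[idx], receptor.type_ids[idx])

    confs = load_library(cfg.library_path, mapping,
                         drop_hydrogens=cfg.drop_hydrogens,
                         skip_bad=cfg.skip_bad_ligands)

    center = (np.asarray(cfg.box_center, dtype=np.float64)
              if cfg.box_center is not None else receptor.centroid())
    space = SearchSpace(center=center,
                        half_extent=np.full(3, cfg.box_half_extent),
                        angle_lo=np.full(3, -np.pi),
                        angle_hi=np.full(3, np.pi))

    logger.info("screen: %d conformations, %d receptor atoms, seed %d, "
                "%d poses x %d generations",
                len(confs), receptor.n_atoms, cfg.emc.seed,
                cfg.emc.n_poses, cfg.emc.n_generations)
    scores, records = screen_conformations(receptor, confs, ff, space,
                                           cfg.emc, top_m=cfg.top_m)
    if cfg.output_prefix is not None:
        prefix = Path(cfg.output_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        Path(f"{prefix}.results.bin").write_bytes(write_results(records))
        Path(f"{prefix}.results.tsv").write_text(results_tsv(records))
    return scores, records
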