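import numpy as np
import pytest

from emcdock.fixtures import (default_sybyl_mapping,
                              make_benchmark_ligand, make_planted_scenario,
                              make_random_ligand, optimal_pair_distance,
                              recovery_benchmark, toy_worked_example)
from emcdock.forcefield import pair_energy_reference
from emcdock.geometry import TransformDescriptor
from emcdock.kernel import MoleculeStruct, PosePopulation, compute_energies
from emcdock.emc import initial_population


class TestDefaultForcefield:
    def test_eight_named_types(self, ff):
        assert ff.n_types == 8
        assert "C.3" in ff.names and "O.acc" in ff.names

    def test_mapping_covers_common_sybyl_types(self, ff):
        mapping = default_sybyl_mapping(ff)
        for t in ("C.3", "C.ar", "N.3", "N.4", "O.2", "O.3", "O.co2", "S.3"):
            assert 0 <= mapping[t] < ff.n_types


class TestMakeRandomLigand:
    def test_single_atom(self):
        lig = make_random_ligand(n_atoms=1, seed=0)
        assert lig.n_atoms == 1 and np.all(np.isfinite(lig.coords))

    def test_default_size_in_compound_range(self):
        sizes = {make_random_ligand(seed=s).n_atoms for s in range(30)}
        assert all(15 <= n <= 40 for n in sizes)
        assert len(sizes) > 5   # spread, not a constant

    def test_minimum_separation_holds(self):
        for seed in range(100):
            lig = make_random_ligand(n_atoms=12, seed=seed)
            c = lig.coords.astype(np.float64)
            d = np.linalg.norm(c[:, None] - c[None, :], axis=-1)
            np.fill_diagonal(d, np.inf)
            assert d.min() >= 1.2 - 1e-6

    def test_atoms_inside_ball(self):
        lig = make_random_ligand(n_atoms=20, seed=3)
        assert np.all(np.linalg.norm(lig.coords, axis=1) <= 5.0 + 1e-6)

    def test_deterministic(self):
        a = make_random_ligand(n_atoms=10, seed=5)
        b = make_random_ligand(n_atoms=10, seed=5)
        assert np.array_equal(a.coords, b.coords)
        assert np.array_equal(a.type_ids, b.type_ids)

    def test_impossible_packing_raises(self):
        with pytest.raises(RuntimeError):
            make_random_ligand(n_atoms=30, seed=0, radius=1.0, max_tries=500)


class TestOptimalPairDistance:
    def test_apolar_pair_optimum_at_well_floor(self, ff):
        c = ff.type_id("C.3")
        d, e = optimal_pair_distance(c, c, ff)
        assert d == pytest.approx(3.6, abs=2e-3)
        assert e < 0

    def test_hbond_pair_optimum_inside_window(self, ff):
        d, e = optimal_pair_distance(ff.type_id("N.don"), ff.type_id("O.acc"),
                                     ff)
        assert ff.globals.hb_min < d < ff.globals.hb_max
        assert e < -1.0


@pytest.fixture(scope="module")
def scenario():
    lig = make_random_ligand(n_atoms=12, seed=7)
    td = TransformDescriptor(1.0, -0.5, 0.25, 0.3, -0.7, 1.1)
    return make_planted_scenario(lig, td, seed=7), td


class TestPlantedScenario:

    def test_planted_beats_1000_random_poses(self, scenario):
        sc, td = scenario
        pop = initial_population(sc.space, 1000, seed=99)
        e, _ = compute_energies(pop, sc.ligand, sc.receptor, sc.ff, block=256)
        planted = compute_energies(PosePopulation.from_descriptors([td]),
                                   sc.ligand, sc.receptor, sc.ff)[0][0]
        assert planted < e.min()

    def test_ablating_pocket_destroys_planted_signal(self, scenario):
        sc, td = scenario
        keep = np.setdiff1d(np.arange(sc.receptor.n_atoms), sc.pocket_ids)
        bare = MoleculeStruct(sc.receptor.x[keep], sc.receptor.y[keep],
                              sc.receptor.z[keep], sc.receptor.type_ids[keep])
        pop = initial_population(sc.space, 1000, seed=99)
        e, _ = compute_energies(pop, sc.ligand, bare, sc.ff, block=256)
        planted = compute_energies(PosePopulation.from_descriptors([td]),
                                   sc.ligand, bare, sc.ff)[0][0]
        assert planted >= np.median(e)

    def test_reproducible_given_seed(self):
        lig = make_random_ligand(n_atoms=6, seed=8)
        td = TransformDescriptor(0, 0, 0, 0, 0, 0)
        a = make_planted_scenario(lig, td, seed=8)
        b = make_planted_scenario(lig, td, seed=8)
        assert np.array_equal(a.receptor.coords, b.receptor.coords)
        assert np.array_equal(a.receptor.type_ids, b.receptor.type_ids)

    def test_decoys_far_from_pocket(self, scenario):
        sc, td = scenario
        from emcdock.geometry import apply_transform, build_transform
        posed = apply_transform(build_transform(td, sc.ligand.centroid()),
                                sc.ligand.coords.astype(np.float64))
        decoys = np.setdiff1d(np.arange(sc.receptor.n_atoms), sc.pocket_ids)
        dc = sc.receptor.coords[decoys].astype(np.float64)
        dmin = np.min(np.linalg.norm(posed[:, None] - dc[None, :], axis=-1))
        assert dmin >= 8.0 - 1e-6


class TestBenchmarkLigand:
    def test_amphiphilic_composition(self, ff):
        lig = make_benchmark_ligand(n_atoms=35, seed=1)
        counts = np.bincount(lig.type_ids, minlength=ff.n_types)
        assert counts[ff.type_id("C.3")] == 14
        assert counts[ff.type_id("N.don")] + counts[ff.type_id("O.acc")] == 21

    def test_recovery_benchmark_reproducible(self):
        (a, td_a), (b, td_b) = recovery_benchmark(3), recovery_benchmark(3)
        assert td_a == td_b
        assert np.array_equal(a.receptor.coords, b.receptor.coords)


class TestToyWorkedExample:
    def test_table_matches_reference_energies(self, ff):
        lig, rec, table = toy_worked_example()
        assert lig.n_atoms == rec.n_atoms == 1
        t = int(lig.type_ids[0])
        for d, e in table:
            assert e == pair_energy_reference(t, t, d, ff)

    def test_characteristic_values(self):
        _, _, table = toy_worked_example()
        by_d = dict(table)
        assert by_d[50.0] == 0.0
        # repulsion at contact: S * eps (+ the apolar desolvation part)
        assert by_d[0.0] == pytest.approx(2.0 - 0.2 * 0.36)
        # well floor at r_ij = 3.6 A
        assert by_d[3.6] == pytest.approx(-0.2 - 0.2 * 0.36 * (1 - 3.6 / 6))
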