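import numpy as np
import pytest

from emcdock.emc import EmcConfig, initial_population, next_generation, run_emc
from emcdock.fixtures import make_planted_scenario, make_random_ligand
from emcdock.geometry import SearchSpace, TransformDescriptor
from emcdock.selection import ScoredIndex, k_best


def box_space(half=5.0):
    return SearchSpace(np.zeros(3), np.full(3, half),
                       np.full(3, -np.pi), np.full(3, np.pi))


def degenerate_space():
    return SearchSpace(np.array([1.0, 2.0, 3.0]), np.zeros(3),
                       np.full(3, 0.5), np.full(3, 0.5))


class TestInitialPopulation:
    def test_degenerate_space_collapses_to_one_pose(self):
        pop = initial_population(degenerate_space(), 10, seed=0)
        for comp in ("tx", "ty", "tz", "rx", "ry", "rz"):
            assert len(np.unique(getattr(pop, comp))) == 1
        assert pop.tx[0] == 1.0 and pop.rz[0] == np.float32(0.5)

    def test_uniform_coverage_of_box(self):
        pop = initial_population(box_space(5.0), 10000, seed=1)
        for comp in ("tx", "ty", "tz"):
            v = getattr(pop, comp)
            assert v.min() >= -5.0 and v.max() <= 5.0
            assert v.max() - v.min() > 9.0
        assert pop.rx.min() >= -np.pi and pop.rx.max() <= np.pi

    def test_deterministic_under_seed(self):
        a = initial_population(box_space(), 500, seed=7)
        b = initial_population(box_space(), 500, seed=7)
        assert np.array_equal(a.tx, b.tx) and np.array_equal(a.rz, b.rz)


class TestNextGeneration:
    def _parents(self, pop, k):
        return [ScoredIndex(float(i), i) for i in range(k)]

    def test_zero_sigma_children_copy_parents(self):
        cfg = EmcConfig(n_poses=64, n_generations=2, n_parents=4,
                        sigma_t=0.0, sigma_r=0.0, seed=3)
        pop = initial_population(box_space(), 64, seed=3)
        child = next_generation(pop, self._parents(pop, 4), cfg, gen=1)
        parent_set = {tuple(pop.descriptor(i).as_array()) for i in range(4)}
        for i in range(64):
            assert tuple(child.descriptor(i).as_array()) in parent_set

    def test_full_elitism_reproduces_parents(self):
        cfg = EmcConfig(n_poses=16, n_generations=2, n_parents=16, seed=5)
        pop = initial_population(box_space(), 16, seed=5)
        child = next_generation(pop, self._parents(pop, 16), cfg, gen=1)
        assert np.array_equal(child.tx, pop.tx)
        assert np.array_equal(child.rz, pop.rz)

    def test_mutation_scale_matches_sigma(self):
        cfg = EmcConfig(n_poses=10000, n_generations=2, n_parents=1,
                        sigma_t=1.0, sigma_r=0.2, decay=1.0, seed=9)
        pop = initial_population(degenerate_space(), 10000, seed=9)
        child = next_generation(pop, self._parents(pop, 1), cfg, gen=1,
                                space=None)
        dev = child.tx[1:].astype(np.float64) - pop.tx[0]
        assert abs(dev.std() - 1.0) < 0.1
        rdev = child.ry[1:].astype(np.float64) - pop.ry[0]
        assert abs(rdev.std() - 0.2) < 0.02

    def test_decay_shrinks_mutations(self):
        cfg = EmcConfig(n_poses=5000, n_generations=8, n_parents=1,
                        sigma_t=1.0, decay=0.5, seed=2)
        pop = initial_population(degenerate_space(), 5000, seed=2)
        late = next_generation(pop, self._parents(pop, 1), cfg, gen=4)
        dev = late.tx[1:].astype(np.float64) - pop.tx[0]
        assert abs(dev.std() - 0.125) < 0.02   # sigma * decay**3

    def test_children_clamped_to_search_space(self):
        space = box_space(1.0)
        cfg = EmcConfig(n_poses=2000, n_generations=2, n_parents=1,
                        sigma_t=5.0, seed=4)
        pop = initial_population(space, 2000, seed=4)
        child = next_generation(pop, self._parents(pop, 1), cfg, gen=1,
                                space=space)
        for comp in ("tx", "ty", "tz"):
            v = getattr(child, comp)
            assert v.min() >= -1.0 and v.max() <= 1.0


@pytest.fixture(scope="module")
def scenario():
    lig = make_random_ligand(n_atoms=8, seed=100)
    return make_planted_scenario(lig, TransformDescriptor(0, 0, 0, 0, 0, 0),
                                 n_decoy_receptor_atoms=8, seed=100)


class TestRunEmc:

    def test_trace_best_energy_monotone(self, scenario):
        for seed in range(3):
            cfg = EmcConfig(n_poses=256, n_generations=5, n_parents=16,
                            seed=seed, bin_size=64)
            res = run_emc(scenario.ligand, scenario.receptor, scenario.ff,
                          scenario.space, cfg)
            be = res.trace.best_energy
            assert len(be) == 5
            assert all(be[i + 1] <= be[i] + 1e-6 for i in range(4))

    def test_bit_identical_under_same_seed(self, scenario):
        cfg = EmcConfig(n_poses=128, n_generations=3, n_parents=8,
                        seed=11, bin_size=64)
        r1 = run_emc(scenario.ligand, scenario.receptor, scenario.ff,
                     scenario.space, cfg)
        r2 = run_emc(scenario.ligand, scenario.receptor, scenario.ff,
                     scenario.space, cfg)
        assert [s.energy for s in r1.best] == [s.energy for s in r2.best]
        assert [d.as_array().tolist() for d in r1.descriptors] == \
               [d.as_array().tolist() for d in r2.descriptors]
        assert r1.trace.best_energy == r2.trace.best_energy

    def test_single_generation_equals_kbest_of_initial(self, scenario):
        from emcdock.kernel import compute_energies

        cfg = EmcConfig(n_poses=200, n_generations=1, n_parents=10,
                        seed=13, bin_size=64)
        res = run_emc(scenario.ligand, scenario.receptor, scenario.ff,
                      scenario.space, cfg)
        pop = initial_population(scenario.space, 200, seed=13)
        e, _ = compute_energies(pop, scenario.ligand, scenario.receptor,
                                scenario.ff, block=cfg.block)
        expect = k_best(e, 10, B=64)
        assert [(s.energy, s.index) for s in res.best] == \
               [(s.energy, s.index) for s in expect]

    def test_results_sorted_ascending(self, scenario):
        cfg = EmcConfig(n_poses=128, n_generations=2, n_parents=12,
                        seed=17, bin_size=64)
        res = run_emc(scenario.ligand, scenario.receptor, scenario.ff,
                      scenario.space, cfg)
        es = [s.energy for s in res.best]
        assert es == sorted(es)
        assert res.metrics.interactions == \
            2 * 128 * scenario.ligand.n_atoms * scenario.receptor.n_atoms


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        dict(n_poses=4, n_parents=8),
        dict(n_generations=0),
        dict(sigma_t=-1.0),
        dict(decay=0.0),
        dict(decay=1.5),
    ])
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            EmcConfig(**kwargs)
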