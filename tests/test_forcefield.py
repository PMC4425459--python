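import numpy as np
import pytest

from emcdock.forcefield import (AtomTypeParams, ForceFieldFormatError,
                                ForceFieldTable, HBondClass,
                                dump_forcefield, hbond_compatible,
                                load_forcefield, pair_energy_reference,
                                specialize_constants)
from emcdock.fixtures import default_forcefield

TWO_TYPE_FILE = """
[globals]
well_width = 1.0
repulsion_scale = 10.0

[types]
CA 1.8 0.2 0.0 1.0 0.6 NONE 0.0
OD 1.5 0.18 0.0 1.0 -0.5 ACCEPTOR 1.5
"""


def apolar_pair_table():
    t = AtomTypeParams(1.8, 0.2, 0.0, 1.0, 0.6, HBondClass.NONE, 0.0)
    return ForceFieldTable(types=(t, t), names=("A", "B"))


class TestLoadForcefield:
    def test_two_type_file(self):
        ff = load_forcefield(TWO_TYPE_FILE)
        assert ff.n_types == 2
        assert ff.names == ("CA", "OD")
        assert ff.type_id("OD") == 1
        assert ff.types[1].hbond_class == HBondClass.ACCEPTOR
        # unspecified globals fall back to defaults
        assert ff.globals.elec_cutoff == 8.0

    def test_row_with_six_fields_names_the_line(self):
        bad = TWO_TYPE_FILE.replace("OD 1.5 0.18 0.0 1.0 -0.5 ACCEPTOR 1.5",
                                    "OD 1.5 0.18 0.0 1.0 -0.5 ACCEPTOR")
        with pytest.raises(ForceFieldFormatError, match="line 8"):
            load_forcefield(bad)

    @pytest.mark.parametrize("mutation, message", [
        (("CA 1.8", "CA x.8"), "non-numeric"),
        (("OD 1.5", "CA 1.5"), "duplicate"),
        (("ACCEPTOR 1.5", "WEIRD 1.5"), "hbond class"),
    ])
    def test_malformed_rows_rejected(self, mutation, message):
        with pytest.raises(ForceFieldFormatError, match=message):
            load_forcefield(TWO_TYPE_FILE.replace(*mutation))

    def test_default_table_round_trips(self):
        ff = default_forcefield()
        again = load_forcefield(dump_forcefield(ff))
        assert again == ff


class TestPairEnergyReference:
    def test_zero_beyond_all_cutoffs(self):
        ff = default_forcefield()
        for i in range(ff.n_types):
            for j in range(ff.n_types):
                assert pair_energy_reference(i, j, 50.0, ff) == 0.0

    def test_apolar_pair_hand_values(self):
        # r_ij = 3.6 A, eps = 0.2 EU, S = 10, w = 1 A, h_i h_j = 0.36
        ff = apolar_pair_table()
        desolv = lambda d: -0.2 * 0.36 * (1 - d / 6.0)
        assert pair_energy_reference(0, 1, 3.6, ff) == pytest.approx(
            -0.2 + desolv(3.6))
        assert pair_energy_reference(0, 1, 0.0, ff) == pytest.approx(
            2.0 + desolv(0.0))
        assert pair_energy_reference(0, 1, 4.1, ff) == pytest.approx(
            -0.1 + desolv(4.1))
        # well is half-open: at r_ij + w only desolvation remains
        assert pair_energy_reference(0, 1, 4.6, ff) == pytest.approx(desolv(4.6))

    def test_symmetric_in_types(self, rng):
        ff = default_forcefield()
        for d in rng.uniform(0, 12, 100):
            for i in range(ff.n_types):
                for j in range(i, ff.n_types):
                    assert pair_energy_reference(i, j, float(d), ff) == \
                        pair_energy_reference(j, i, float(d), ff)

    def test_soft_core_finite_everywhere(self):
        ff = default_forcefield()
        g = ff.globals
        emax = max(t.well_depth for t in ff.types)
        # closed-form contact bound: repulsion + |Coulomb at the 1 A clamp|
        # + desolvation + H-bond depth ceilings
        bound = (g.repulsion_scale * emax
                 + g.coulomb_k / g.dielectric
                 + g.desolv_scale
                 + max(t.hbond_depth for t in ff.types)) * 1.01
        for d in np.linspace(0, 100, 4001):
            for i in range(ff.n_types):
                e = pair_energy_reference(i, (i * 3) % ff.n_types, float(d), ff)
                assert np.isfinite(e) and abs(e) <= bound

    def test_discontinuity_at_contact(self):
        # hydrophobicity 0 isolates the steric term around d = r_ij
        t = AtomTypeParams(1.8, 0.2, 0.0, 1.0, 0.0, HBondClass.NONE, 0.0)
        ff = ForceFieldTable(types=(t, t), names=("A", "B"))
        eps = 1e-9
        below = pair_energy_reference(0, 1, 3.6 - eps, ff)
        at = pair_energy_reference(0, 1, 3.6, ff)
        # repulsive side tends to 0+ from above, well side jumps to -eps_ij
        assert below > 0 > at
        assert below - at == pytest.approx(0.2, abs=1e-4)

    def test_invalid_type_id_raises_index_error(self):
        ff = default_forcefield()
        with pytest.raises(IndexError):
            pair_energy_reference(0, ff.n_types + 3, 1.0, ff)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            pair_energy_reference(0, 0, -0.1, default_forcefield())


class TestHbondCompatibility:
    def test_truth_table(self):
        N, D, A, B = (HBondClass.NONE, HBondClass.DONOR,
                      HBondClass.ACCEPTOR, HBondClass.BOTH)
        assert hbond_compatible(D, A) and hbond_compatible(A, D)
        assert hbond_compatible(B, D) and hbond_compatible(B, A)
        assert hbond_compatible(B, B)
        assert not hbond_compatible(D, D)
        assert not hbond_compatible(A, A)
        for c in (N, D, A, B):
            assert not hbond_compatible(N, c)


class TestSpecializeConstants:
    def test_bit_identical_to_reference(self, rng):
        ff = default_forcefield()
        ev = specialize_constants(ff)
        for _ in range(1000):
            i = int(rng.integers(ff.n_types))
            j = int(rng.integers(ff.n_types))
            d = float(rng.uniform(0, 12))
            assert ev(i, j, d) == pair_energy_reference(i, j, d, ff)

    def test_capture_semantics(self):
        ff = apolar_pair_table()
        ev = specialize_constants(ff)
        before = ev(0, 1, 3.6)
        # build a different table; the specialized evaluator must not care
        t = AtomTypeParams(2.5, 0.9, 0.0, 1.0, 0.0, HBondClass.NONE, 0.0)
        other = ForceFieldTable(types=(t, t), names=("A", "B"))
        assert specialize_constants(other)(0, 1, 3.6) != before
        assert ev(0, 1, 3.6) == before

    def test_single_type_table(self, rng):
        t = AtomTypeParams(1.5, 0.3, 0.5, 1.0, -0.2, HBondClass.BOTH, 0.8)
        ff = ForceFieldTable(types=(t,), names=("X",))
        ev = specialize_constants(ff)
        for d in rng.uniform(0, 10, 200):
            assert ev(0, 0, float(d)) == pair_energy_reference(0, 0, float(d), ff)


def test_compact_support_bound(rng):
    ff = default_forcefield()
    dmax = ff.max_cutoff()
    for _ in range(200):
        i = int(rng.integers(ff.n_types))
        j = int(rng.integers(ff.n_types))
        d = float(rng.uniform(dmax, dmax + 20))
        assert pair_energy_reference(i, j, d, ff) == 0.0
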