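"""Unit and property tests for the three-allele drive genetics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from suppdrive.genetics import (
    Allele,
    CARRIER_MASK,
    DriveParams,
    GENOTYPE_PAIRS,
    Genotype,
    enumerate_cross,
    expected_inheritance_rate,
    female_fertility,
    fertility_weights,
    gamete_distribution,
    genotype_index,
    offspring_genotype_distribution,
    offspring_tensor,
    apply_embryo_resistance,
)
from conftest import random_drive_params

W, D, R = Allele.W, Allele.D, Allele.R


def _dw(sex=None, **kw):
    return Genotype(D, W, sex=sex, **kw)


def _ww(sex=None, **kw):
    return Genotype(W, W, sex=sex, **kw)


class TestGameteDistribution:
    @pytest.mark.parametrize(
        "c, expected",
        [
            (0.0, {D: 0.5, R: 0.5, W: 0.0}),  # full cutting, no conversion
            (1.0, {D: 1.0, R: 0.0, W: 0.0}),  # perfect homing
            (0.9, {D: 0.95, R: 0.05, W: 0.0}),
        ],
    )
    def test_drive_het_female(self, c, expected):
        dp = DriveParams(c_f=c, c_m=0.0, e=0.0)
        dist = gamete_distribution(_dw(sex="female"), dp)
        for allele, p in expected.items():
            assert dist[allele] == pytest.approx(p, abs=1e-12)

    def test_no_cas9_is_mendelian(self):
        dp = DriveParams(c_f=0.9, c_m=0.9, e=0.5)
        dist = gamete_distribution(_dw(sex="female", cas9_present=False), dp)
        assert dist[D] == pytest.approx(0.5)
        assert dist[W] == pytest.approx(0.5)

    def test_no_drive_allele_is_mendelian(self):
        dp = DriveParams(c_f=0.9, c_m=0.9, e=0.5)
        dist = gamete_distribution(Genotype(W, R, sex="male"), dp)
        assert dist[W] == pytest.approx(0.5)
        assert dist[R] == pytest.approx(0.5)

    def test_partial_cut_rate(self):
        dp = DriveParams(c_f=0.8, c_m=0.0, e=0.0, germline_cut_rate=0.5)
        dist = gamete_distribution(_dw(sex="female"), dp)
        assert dist[W] == pytest.approx(0.25)
        assert dist[D] == pytest.approx(0.5 + 0.5 * 0.8 / 2)
        assert dist[R] == pytest.approx(0.5 * 0.2 / 2)


class TestEmbryoResistance:
    def test_no_deposition_source(self, dp_measured):
        out = apply_embryo_resistance(_ww(), _ww(sex="female"), dp_measured)
        assert out == {_ww(): 1.0}

    def test_single_wildtype_allele(self, dp_measured):
        out = apply_embryo_resistance(_dw(), _dw(sex="female"), dp_measured)
        assert out[Genotype(D, W)] == pytest.approx(0.5)
        assert out[Genotype(D, R)] == pytest.approx(0.5)

    def test_two_independent_alleles(self, dp_measured):
        out = apply_embryo_resistance(_ww(), _dw(sex="female"), dp_measured)
        assert out[Genotype(W, W)] == pytest.approx(0.25)
        assert out[Genotype(W, R)] == pytest.approx(0.5)
        assert out[Genotype(R, R)] == pytest.approx(0.25)


class TestOffspringDistribution:
    def test_wildtype_cross(self, dp_neutral):
        out = offspring_genotype_distribution(_ww(sex="female"), _ww(sex="male"), dp_neutral)
        assert out == {_ww(): 1.0}

    def test_drive_mother_example(self, dp_measured):
        out = offspring_genotype_distribution(_dw(sex="female"), _ww(sex="male"), dp_measured)
        expected = {
            Genotype(D, W): 0.475,
            Genotype(D, R): 0.475,
            Genotype(W, R): 0.025,
            Genotype(R, R): 0.025,
        }
        assert set(out) == set(expected)
        for g, p in expected.items():
            assert out[g] == pytest.approx(p, abs=1e-12)

    def test_drive_father_no_deposition(self, dp_measured):
        out = offspring_genotype_distribution(_ww(sex="female"), _dw(sex="male"), dp_measured)
        assert out[Genotype(D, W)] == pytest.approx(0.9)
        assert out[Genotype(R, W)] == pytest.approx(0.1)

    def test_maternal_cas9_flag_propagates(self, dp_measured):
        out = offspring_genotype_distribution(
            _ww(sex="female", cas9_present=False), _dw(sex="male"), dp_measured
        )
        assert all(not g.maternal_cas9 for g in out)


class TestOracleEquivalence:
    """Closed-form distributions equal exhaustive event-tree enumeration."""

    def test_all_pairs_random_params(self, rng):
        for _ in range(100):
            dp = random_drive_params(rng)
            for (m1, m2), (f1, f2) in itertools.product(GENOTYPE_PAIRS, GENOTYPE_PAIRS):
                mother = Genotype(m1, m2, sex="female")
                father = Genotype(f1, f2, sex="male")
                closed = offspring_genotype_distribution(mother, father, dp)
                brute = enumerate_cross(mother, father, dp)
                keys = set(closed) | set(brute)
                for k in keys:
                    assert closed.get(k, 0.0) == pytest.approx(
                        brute.get(k, 0.0), abs=1e-10
                    )

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        c_f=st.floats(0, 1), c_m=st.floats(0, 1), e=st.floats(0, 1),
        g=st.floats(0, 1),
        mi=st.integers(0, 5), fi=st.integers(0, 5),
    )
    def test_distributions_normalised(self, c_f, c_m, e, g, mi, fi):
        dp = DriveParams(c_f=c_f, c_m=c_m, e=e, germline_cut_rate=g)
        mother = Genotype(*GENOTYPE_PAIRS[mi], sex="female")
        father = Genotype(*GENOTYPE_PAIRS[fi], sex="male")
        out = offspring_genotype_distribution(mother, father, dp)
        assert sum(out.values()) == pytest.approx(1.0, abs=1e-12)
        assert all(p >= 0 for p in out.values())


class TestFertility:
    def test_wildtype_fertile(self, dp_measured):
        assert female_fertility(_ww(sex="female"), dp_measured) == 1.0

    @pytest.mark.parametrize("pair", [(D, R), (D, D), (R, R)])
    def test_no_wildtype_sterile(self, pair, dp_measured):
        g = Genotype(*pair, sex="female")
        assert female_fertility(g, dp_measured) == 0.0

    def test_het_fitness_value(self):
        dp = DriveParams(c_f=0.9, c_m=0.8, e=0.5, f_het=0.205)
        assert female_fertility(_dw(sex="female"), dp) == pytest.approx(0.205)

    def test_maternal_cas9_switch(self):
        dp = DriveParams(c_f=0.9, c_m=0.8, e=0.5, f_het=0.3, f_het_no_maternal_cas9=0.9)
        assert female_fertility(_dw(sex="female", maternal_cas9=True), dp) == 0.3
        assert female_fertility(_dw(sex="female", maternal_cas9=False), dp) == 0.9

    def test_males_unaffected(self, dp_measured):
        assert female_fertility(Genotype(D, R, sex="male"), dp_measured) == 1.0


class TestInheritanceRate:
    def test_mendelian_null(self):
        assert expected_inheritance_rate(0.0) == 0.5
        assert expected_inheritance_rate(0.0, 0.3) == 0.5

    def test_perfect_homing(self):
        assert expected_inheritance_rate(1.0, 1.0) == 1.0

    def test_matches_gamete_distribution(self, rng):
        for _ in range(20):
            c, g = rng.uniform(), rng.uniform()
            dp = DriveParams(c_f=c, c_m=0.0, e=0.0, germline_cut_rate=g)
            dist = gamete_distribution(_dw(sex="female"), dp)
            assert dist[D] == pytest.approx(expected_inheritance_rate(c, g))


class TestEmbryoResistanceEstimand:
    """The sterile fraction of drive daughters equals the parameter e."""

    @pytest.mark.parametrize("e", [0.0, 0.2, 0.5, 0.633, 1.0])
    def test_conditional_sterility_is_e(self, e):
        dp = DriveParams(c_f=0.9, c_m=0.8, e=e)
        out = offspring_genotype_distribution(_dw(sex="female"), _ww(sex="male"), dp)
        carriers = {g: p for g, p in out.items() if g.carries_drive}
        p_carrier = sum(carriers.values())
        p_sterile_carrier = sum(
            p for g, p in carriers.items()
            if female_fertility(Genotype(g.a1, g.a2, sex="female"), dp) == 0.0
        )
        assert p_sterile_carrier / p_carrier == pytest.approx(e, abs=1e-12)


class TestNeutrality:
    def test_inert_locus_mendelian_everywhere(self, dp_neutral):
        for pair in GENOTYPE_PAIRS:
            parent = Genotype(*pair, sex="female")
            dist = gamete_distribution(parent, dp_neutral)
            for allele in (W, D, R):
                expected = sum(0.5 for a in parent.alleles if a is allele)
                assert dist[allele] == pytest.approx(expected)


class TestVectorisedTables:
    def test_tensor_matches_scalar_api(self, dp_measured):
        T = offspring_tensor(dp_measured)
        assert T.shape == (6, 6, 6)
        np.testing.assert_allclose(T.sum(axis=2), 1.0, atol=1e-12)
        mother = _dw(sex="female")
        father = _ww(sex="male")
        row = np.zeros(6)
        for g, p in offspring_genotype_distribution(mother, father, dp_measured).items():
            row[genotype_index(g)] += p
        np.testing.assert_allclose(T[1, 0], row, atol=1e-12)

    def test_fertility_weights_vector(self):
        dp = DriveParams(c_f=0.9, c_m=0.8, e=0.5, f_het=0.25)
        np.testing.assert_allclose(
            fertility_weights(dp), [1.0, 0.25, 1.0, 0.0, 0.0, 0.0]
        )
        assert CARRIER_MASK.tolist() == [False, True, False, True, True, False]


class TestParameterValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"c_f": -0.1, "c_m": 0.5, "e": 0.5},
            {"c_f": 0.5, "c_m": 1.2, "e": 0.5},
            {"c_f": 0.5, "c_m": 0.5, "e": 2.0},
            {"c_f": 0.5, "c_m": 0.5, "e": 0.5, "f_het": -0.5},
        ],
    )
    def test_out_of_domain_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DriveParams(**kwargs)

    def test_genotype_unordered(self):
        assert Genotype(D, W) == Genotype(W, D)
        assert genotype_index(Genotype(W, D)) == 1
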