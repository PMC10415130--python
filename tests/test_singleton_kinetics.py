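"""Four-state kinetics: generator structure, integration, and equilibria."""

import numpy as np
import pytest
from scipy.linalg import expm

from pr2kinetics.rate_model import RATE_KEYS, RateSet, SymmetricRateSet, nsb_expand
from pr2kinetics.singleton_kinetics import (
    BaseComposition,
    DegenerateSystemError,
    EnsemblePropagator,
    LinearPropagator,
    build_rate_matrix,
    evolve,
    evolve_ensemble,
    evolve_nsb,
    gc_equilibrium_curve,
    nsb_equilibrium,
    stationary_composition,
)


def _rate_set(**overrides) -> RateSet:
    rates = {k: 0.0 for k in RATE_KEYS}
    rates.update(overrides)
    return RateSet(rates)


class TestRateMatrix:
    def test_zero_rates_give_zero_matrix(self):
        assert np.all(build_rate_matrix(_rate_set()) == 0)

    def test_single_rate_structure(self):
        # only C->T: entry in T's row, C's column; diagonal -1 in C's column
        M = build_rate_matrix(_rate_set(CT=1.0))
        expected = np.zeros((4, 4))
        expected[3, 1] = 1.0
        expected[1, 1] = -1.0
        assert np.array_equal(M, expected)

    def test_columns_sum_to_zero(self, random_rate_set):
        M = build_rate_matrix(random_rate_set)
        assert np.allclose(M.sum(axis=0), 0, atol=1e-14)

    def test_matrix_reproduces_kinetic_equations(self, random_rate_set):
        # dC_A/dt = k_CA C_C + k_TA C_T + k_GA C_G - (k_AC + k_AT + k_AG) C_A
        r = random_rate_set
        c = np.array([0.1, 0.2, 0.3, 0.4])
        dc = build_rate_matrix(r) @ c
        expected_a = (
            r["CA"] * c[1] + r["TA"] * c[3] + r["GA"] * c[2]
            - (r["AC"] + r["AT"] + r["AG"]) * c[0]
        )
        assert dc[0] == pytest.approx(expected_a, rel=1e-12)


class TestEvolve:
    def test_zero_rates_constant_trajectory(self):
        c0 = BaseComposition(0.1, 0.2, 0.3, 0.4)
        traj = evolve(_rate_set(), c0, horizon=2.0)
        assert np.allclose(traj.compositions, c0.as_array(), atol=1e-12)

    def test_uniform_rates_keep_uniform_composition(self):
        r = RateSet({k: 0.7 for k in RATE_KEYS})
        traj = evolve(r, BaseComposition.uniform(), horizon=4.28)
        assert np.allclose(traj.compositions, 0.25, atol=1e-9)

    def test_matches_matrix_exponential_oracle(self, table1_nsb_rates):
        c0 = BaseComposition.uniform()
        traj = evolve(table1_nsb_rates, c0, horizon=4.28, record_times=[4.28])
        oracle = expm(4.28 * build_rate_matrix(table1_nsb_rates)) @ c0.as_array()
        assert np.allclose(traj.compositions[-1], oracle, atol=1e-8)

    def test_composition_sum_conserved(self, random_rate_set):
        traj = evolve(random_rate_set, BaseComposition(0.4, 0.3, 0.2, 0.1), horizon=10.0)
        assert np.all(np.abs(traj.compositions.sum(axis=1) - 1) < 1e-7)

    def test_general_vs_nsb_formulation_identical(self, table1_symmetric):
        # the 12-rate integrator on an NSB-expanded set must match the
        # dedicated reduced-form integrator along the whole trajectory
        c0 = BaseComposition(0.4, 0.25, 0.15, 0.2)
        times = np.linspace(0, 4.28, 50)[1:]
        general = evolve(nsb_expand(table1_symmetric), c0, 4.28, record_times=times)
        reduced = evolve_nsb(table1_symmetric, c0, 4.28, record_times=times)
        assert np.allclose(general.compositions, reduced.compositions, atol=1e-9)


class TestNsbEquilibrium:
    def test_symmetric_rates_give_uniform(self):
        s = SymmetricRateSet(1, 1, 5, 7, 1, 1)  # k, l irrelevant
        eq = nsb_equilibrium(s)
        assert np.allclose(eq.as_array(), 0.25, atol=1e-15)

    def test_table1_values(self, table1_symmetric):
        eq = nsb_equilibrium(table1_symmetric)
        # (i+m)/(2(i+j+m+n)) with i=0.322, j=0.198, m=1.109, n=0.753
        assert eq.C_A == pytest.approx(1.431 / (2 * 2.382), abs=1e-12)
        assert eq.C_A == pytest.approx(0.3004, abs=5e-5)
        assert eq.C_G == pytest.approx(0.1996, abs=5e-5)

    def test_parity_holds_exactly(self, table1_symmetric):
        eq = nsb_equilibrium(table1_symmetric)
        assert eq.C_A == eq.C_T and eq.C_G == eq.C_C
        assert eq.as_array().sum() == pytest.approx(1.0, abs=1e-15)

    def test_absorbing_at_states(self):
        eq = nsb_equilibrium(SymmetricRateSet(i=1, j=0, k=0, l=1, m=1, n=0))
        assert eq.C_G == eq.C_C == 0.0

    def test_degenerate_rates_rejected(self):
        with pytest.raises(DegenerateSystemError):
            nsb_equilibrium(SymmetricRateSet(0, 0, 1, 1, 0, 0))


class TestGcEquilibriumCurve:
    def test_balanced_ratio_gives_half(self):
        assert gc_equilibrium_curve(SymmetricRateSet(1, 2, 0, 0, 3, 2)) == 0.5

    def test_table1_value(self, table1_symmetric):
        gc = gc_equilibrium_curve(table1_symmetric)
        assert gc == pytest.approx(0.951 / 2.382, abs=1e-12)
        eq = nsb_equilibrium(table1_symmetric)
        assert gc == pytest.approx(eq.C_G + eq.C_C, abs=1e-15)

    def test_no_gc_production(self):
        assert gc_equilibrium_curve(SymmetricRateSet(1, 0, 1, 1, 1, 0)) == 0.0

    def test_no_at_production_limit(self):
        assert gc_equilibrium_curve(SymmetricRateSet(0, 1, 0, 0, 0, 1)) == 1.0

    def test_independent_of_k_and_l(self, table1_symmetric):
        s = table1_symmetric
        other = SymmetricRateSet(s.i, s.j, 9.9, 7.7, s.m, s.n)
        assert gc_equilibrium_curve(other) == gc_equilibrium_curve(s)


class TestStationaryComposition:
    def test_equals_nsb_equilibrium(self, table1_nsb_rates, table1_symmetric):
        stat = stationary_composition(table1_nsb_rates)
        eq = nsb_equilibrium(table1_symmetric)
        assert np.allclose(stat.as_array(), eq.as_array(), atol=1e-12)

    def test_all_rates_equal_gives_uniform(self):
        stat = stationary_composition(RateSet({k: 0.4 for k in RATE_KEYS}))
        assert np.allclose(stat.as_array(), 0.25, atol=1e-12)

    def test_reducible_network_rejected(self):
        # only A->T: states C and G are isolated, the stationary space is
        # multi-dimensional and the limit depends on the initial state
        with pytest.raises(DegenerateSystemError):
            stationary_composition(_rate_set(AT=1.0))

    def test_two_state_chain_limit_via_evolve(self):
        # A->T only, starting from A+T mass only: all of it ends on T
        r = _rate_set(AT=1.0)
        c0 = BaseComposition(0.6, 0.0, 0.0, 0.4)
        traj = evolve(r, c0, horizon=50.0, record_times=[50.0])
        assert traj.compositions[-1] == pytest.approx([0, 0, 0, 1.0], abs=1e-9)

    def test_agrees_with_long_time_evolution(self, random_rate_set):
        stat = stationary_composition(random_rate_set)
        traj = evolve(random_rate_set, BaseComposition.uniform(), horizon=200.0,
                      record_times=[200.0])
        assert np.allclose(traj.compositions[-1], stat.as_array(), atol=1e-6)


class TestPropagators:
    def test_linear_propagator_matches_evolve(self, random_rate_set):
        c0 = BaseComposition(0.3, 0.3, 0.2, 0.2)
        prop = LinearPropagator(random_rate_set, c0)
        traj = evolve(random_rate_set, c0, horizon=4.28, record_times=[1.0, 4.28])
        assert np.allclose(prop.at(np.array([1.0, 4.28])), traj.compositions[1:], atol=1e-8)

    def test_ensemble_matches_single_propagator(self, rng):
        vectors = rng.uniform(0.05, 2.0, size=(5, 12))
        times = np.array([0.0, 0.5, 4.28])
        ens = evolve_ensemble(vectors, np.full(4, 0.25), times)
        for i in range(5):
            prop = LinearPropagator(RateSet.from_vector(vectors[i]), BaseComposition.uniform())
            assert np.allclose(ens[i], prop.at(times), atol=1e-10)

    def test_ensemble_stationary_matches_null_space(self, rng):
        vectors = rng.uniform(0.05, 2.0, size=(4, 12))
        prop = EnsemblePropagator(vectors, np.full(4, 0.25))
        stats = prop.stationary()
        for i in range(4):
            oracle = stationary_composition(RateSet.from_vector(vectors[i]))
            assert np.allclose(stats[i], oracle.as_array(), atol=1e-10)


class TestCompositionValidation:
    def test_sum_must_be_one(self):
        with pytest.raises(ValueError):
            BaseComposition(0.3, 0.3, 0.3, 0.3)

    def test_negative_content_rejected(self):
        with pytest.raises(ValueError):
            BaseComposition(-0.1, 0.4, 0.4, 0.3)
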