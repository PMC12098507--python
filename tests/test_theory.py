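"""Closed-form MFPT predictions, limits, and the quadrature oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from glekinetics import (D1, D2, DoubleWellPotential, MemoryKernel,
                         ed_contribution, mfpt_well_to_top, mfpt_well_to_well,
                         multi_exponential_mfpt, neq_effective_beta,
                         neq_mfpt_well_to_top, od_contribution,
                         overdamped_mfpt_quadrature)

bu = st.floats(min_value=1.0, max_value=8.0)
pos = st.floats(min_value=0.05, max_value=10.0)
nonneg = st.floats(min_value=0.0, max_value=10.0)


class TestInterpolationFormulas:
    def test_overdamped_markovian_limit_term(self):
        # m -> 0, tau -> 0: only the high-friction term survives
        pred = mfpt_well_to_well(5.0, 40.0, 1.0, tau=0.0, mass=0.0)
        assert pred.inertial_term == 0.0
        assert pred.crossover_term == 0.0
        assert pred.total == pytest.approx(math.exp(5.0) * D2 * 1.0 / 40.0)

    def test_tau_squared_dominance(self):
        a = mfpt_well_to_top(3.0, 24.0, 1.0, tau=50.0, mass=0.01)
        b = mfpt_well_to_top(3.0, 24.0, 1.0, tau=100.0, mass=0.01)
        assert b.total / a.total == pytest.approx(4.0, rel=0.01)

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(bu, pos, pos, nonneg, nonneg)
    def test_term_bookkeeping(self, u, l, gamma, tau, mass):
        k = 8.0 * u / l**2
        for f in (mfpt_well_to_well, mfpt_well_to_top):
            pred = f(u, k, gamma, tau, mass)
            assert pred.total == pytest.approx(
                pred.inertial_term + pred.overdamped_term + pred.crossover_term)
            assert min(pred.inertial_term, pred.overdamped_term,
                       pred.crossover_term) >= 0.0

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(pos, pos, nonneg, nonneg)
    def test_monotone_in_barrier_height(self, l, gamma, tau, mass):
        ks = [8.0 * u / l**2 for u in (2.0, 3.0, 4.0)]
        tot = [mfpt_well_to_top(u, k, gamma, tau, mass).total
               for u, k in zip((2.0, 3.0, 4.0), ks)]
        assert tot[0] < tot[1] < tot[2]

    def test_half_ratio_in_overdamped_markovian_limit(self):
        # symmetric well, m = 0, tau = 0: well-to-top is exactly half well-to-well
        for u0, l in [(3.0, 1.0), (5.0, 0.7), (2.0, 2.0)]:
            k = 8 * u0 / l**2
            top = mfpt_well_to_top(u0, k, 1.3, 0.0, 0.0).total
            ww = mfpt_well_to_well(u0, k, 1.3, 0.0, 0.0).total
            assert top / ww == 0.5

    def test_ratio_tends_to_one_at_long_memory(self):
        u0, k, m = 3.0, 24.0, 0.01
        ratios = [mfpt_well_to_top(u0, k, 1.0, tau, m).total
                  / mfpt_well_to_well(u0, k, 1.0, tau, m).total
                  for tau in (10.0, 100.0, 1000.0, 10000.0)]
        assert all(np.diff(ratios) > 0)
        assert ratios[-1] == pytest.approx(1.0, abs=1e-3)

    def test_well_decoupling_is_bit_exact(self):
        p1 = DoubleWellPotential(3.0, 5.0, 1.0, 0.5)
        p2 = DoubleWellPotential(3.0, 7.0, 1.0, 1.4)
        a = mfpt_well_to_top(p1.u_left, p1.curvature_at_minimum("left"),
                             1.0, 0.3, 0.05)
        b = mfpt_well_to_top(p2.u_left, p2.curvature_at_minimum("left"),
                             1.0, 0.3, 0.05)
        assert a == b  # left prediction ignores the right well entirely

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            mfpt_well_to_well(-1.0, 24.0, 1.0)
        with pytest.raises(ValueError):
            mfpt_well_to_top(3.0, 24.0, 0.0)
        with pytest.raises(ValueError):
            mfpt_well_to_top(3.0, 24.0, 1.0, tau=-1.0)


class TestMultiExponential:
    def test_single_component_recovers_base_formula(self):
        u, k, m = 4.0, 32.0, 0.05
        kern = MemoryKernel.exponential(1.0, 0.3)
        assert multi_exponential_mfpt(u, k, kern, m) == \
            mfpt_well_to_top(u, k, 1.0, 0.3, m).total

    def test_od_term_matching(self):
        # N=1 overdamped contribution = overdamped term + half the crossover term
        u, k, m = 3.0, 24.0, 0.05
        pred = mfpt_well_to_top(u, k, 1.0, 0.3, m)
        od = od_contribution(u, k, 1.0, 0.3, m)
        assert od == pytest.approx(pred.overdamped_term
                                   + 0.5 * pred.crossover_term)
        ed = ed_contribution(u, k, 1.0, 0.3, m)
        assert ed == pytest.approx(pred.inertial_term
                                   + 0.5 * pred.crossover_term)

    def test_od_limits(self):
        u, k = 3.0, 24.0
        # tau_i -> large: decays toward the crossover floor
        floor = math.exp(u) * 2 * math.sqrt(2 * 0.05 / k)
        assert od_contribution(u, k, 1.0, 1e6, 0.05) == pytest.approx(
            floor, rel=1e-3)
        # linear in gamma_i at tau_i = 0 (massless)
        assert od_contribution(u, k, 2.0, 0.0, 0.0) == pytest.approx(
            2 * od_contribution(u, k, 1.0, 0.0, 0.0))

    def test_ed_limits(self):
        u, k = 3.0, 24.0
        assert ed_contribution(u, k, 1.0, 0.0, 0.0) == 0.0
        a = ed_contribution(u, k, 1.0, 50.0, 0.0)
        b = ed_contribution(u, k, 1.0, 100.0, 0.0)
        assert b / a == pytest.approx(4.0, rel=1e-3)

    def test_result_bounded_below_by_od_sum(self):
        u, k, m = 3.0, 24.0, 0.05
        kern = MemoryKernel(((0.5, 0.1), (0.5, 1.0), (0.2, 3.0)))
        od_sum = sum(od_contribution(u, k, g, t, m) for g, t in kern.components)
        assert multi_exponential_mfpt(u, k, kern, m) >= od_sum

    def test_split_component_consistency_probe(self):
        # the combination rule is not additive-invariant; document the shift
        u, k, m = 3.0, 24.0, 0.05
        one = multi_exponential_mfpt(u, k, MemoryKernel.exponential(1.0, 0.3), m)
        two = multi_exponential_mfpt(
            u, k, MemoryKernel(((0.5, 0.3), (0.5, 0.3))), m)
        assert two != pytest.approx(one, rel=1e-6)
        assert two == pytest.approx(one, rel=1.0)  # same order of magnitude


class TestNonEquilibrium:
    @pytest.mark.parametrize("tau_r,tau_v,factor", [(1.0, 1.0, 1.0),
                                                    (2.0, 1.0, 4.0),
                                                    (0.5, 1.0, 0.25)])
    def test_effective_beta(self, tau_r, tau_v, factor):
        assert neq_effective_beta(2.0, tau_r, tau_v) == pytest.approx(2.0 * factor)

    def test_equilibrium_recovery_is_exact(self):
        u, k, m = 4.0, 32.0, 0.1
        eq = mfpt_well_to_top(u, k, 1.0, 0.7, m)
        neq = neq_mfpt_well_to_top(u, k, 1.0, tau_v=0.7, tau_r=0.7, mass=m)
        assert neq == eq

    def test_increases_with_noise_decay_time(self):
        u, k, m = 4.0, 32.0, 0.1
        tots = [neq_mfpt_well_to_top(u, k, 1.0, 1.0, r, m).total
                for r in (0.8, 1.0, 1.25, 1.5)]
        assert all(np.diff(tots) > 0)

    def test_width_dependence_minor_next_to_temperature_dependence(self):
        # changing L_R/L_L only moves K_R in the prefactors; the effective
        # temperature in the exponent dominates the ratio dependence
        m, tau_v = 0.1, 1.0

        def total(lr, ratio):
            p = DoubleWellPotential(3.0, 4.0, 1.0, lr)
            return neq_mfpt_well_to_top(
                p.u_right, p.curvature_at_minimum("right"), 1.0,
                tau_v, ratio * tau_v, m).total

        width_spread = max(total(lr, 1.25) for lr in (0.5, 1.0, 1.5)) \
            / min(total(lr, 1.25) for lr in (0.5, 1.0, 1.5))
        ratio_spread = total(1.0, 1.25) / total(1.0, 0.8)
        assert width_spread < ratio_spread


class TestQuadratureOracle:
    def test_flat_potential_reflecting_closed_form(self):
        # free diffusion from a reflecting wall: tau = beta gamma L^2 / 2
        flat = lambda x: np.zeros_like(np.asarray(x, dtype=float))
        val = overdamped_mfpt_quadrature(flat, 0.0, 2.0, beta=1.5, gamma=2.0,
                                         lower=0.0)
        assert val == pytest.approx(1.5 * 2.0 * 2.0**2 / 2.0, rel=1e-6)

    def test_kramers_prefactor_identity(self):
        # 2*sqrt(2)*pi/K equals 2*pi/sqrt(K*|K_b|) with K_b = K/2
        k = 24.0
        kb = k / 2.0
        assert D2 / k == pytest.approx(2 * math.pi / math.sqrt(k * kb))

    def test_formula_approaches_oracle_with_barrier_height(self):
        # well-to-well deviation decreases monotonically and is <= 15% at bU=5
        devs = {}
        for u0 in (2.0, 3.0, 5.0, 8.0):
            p = DoubleWellPotential(u0, u0, 1.0, 1.0)
            oracle = overdamped_mfpt_quadrature(p, -1.0, 1.0)
            formula = mfpt_well_to_well(u0, 8 * u0, 1.0).total
            devs[u0] = abs(formula - oracle) / oracle
        seq = [devs[u] for u in (2.0, 3.0, 5.0, 8.0)]
        assert all(np.diff(seq) < 0)
        assert devs[5.0] <= 0.15

    def test_well_to_top_close_to_oracle_at_high_barrier(self):
        p = DoubleWellPotential(5.0, 5.0, 1.0, 1.0)
        oracle = overdamped_mfpt_quadrature(p, -1.0, 0.0)
        formula = mfpt_well_to_top(5.0, 40.0, 1.0).total
        assert formula == pytest.approx(oracle, rel=0.15)

    def test_top_to_well_ratio_approaches_half(self):
        p = DoubleWellPotential(8.0, 8.0, 1.0, 1.0)
        top = overdamped_mfpt_quadrature(p, -1.0, 0.0)
        ww = overdamped_mfpt_quadrature(p, -1.0, 1.0)
        assert top / ww == pytest.approx(0.5, abs=0.01)

    def test_rejects_bad_interval(self, sym_potential):
        with pytest.raises(ValueError):
            overdamped_mfpt_quadrature(sym_potential, 1.0, -1.0)
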