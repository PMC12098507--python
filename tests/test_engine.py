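"""GLE integrator contracts: stationarity, fluctuation-dissipation, limits."""

import numpy as np
import pytest
from scipy import stats

from glekinetics import (DoubleWellPotential, FlatPotential, HarmonicWell,
                         MemoryKernel, NonEqKernel, SimulationConfig,
                         colored_noise, sample_initial_state,
                         simulate_equilibrium, simulate_langevin_reference,
                         simulate_nonequilibrium)
from glekinetics.engine import _rng


def _acf(f, lag):
    return float((f * f).mean()) if lag == 0 else float((f[:-lag] * f[lag:]).mean())


class TestInitialState:
    def test_deterministic_under_seeding(self, asym_potential, exp_kernel):
        cfg = SimulationConfig(mass=0.1, dt=1e-3, n_steps=10, seed=42)
        a = sample_initial_state(asym_potential, exp_kernel, cfg, _rng(42))
        b = sample_initial_state(asym_potential, exp_kernel, cfg, _rng(42))
        assert a[0] == b[0] and a[1] == b[1]
        np.testing.assert_array_equal(a[2], b[2])

    def test_velocity_moments_are_maxwellian(self, asym_potential, exp_kernel):
        beta, m, n = 2.0, 0.5, 100_000
        cfg = SimulationConfig(mass=m, dt=1e-3, n_steps=10, beta=beta)
        rng = _rng(7)
        v = np.array([sample_initial_state(asym_potential, exp_kernel, cfg,
                                           rng)[1] for _ in range(n)])
        sigma2 = 1.0 / (beta * m)
        assert abs(v.mean()) < 4 * np.sqrt(sigma2 / n)
        se_var = sigma2 * np.sqrt(2.0 / n)
        assert abs(v.var() - sigma2) < 3 * se_var

    def test_positions_resolve_named_minima(self, asym_potential, exp_kernel):
        for name, expect in [("left-minimum", -1.0), ("right-minimum", 0.5)]:
            cfg = SimulationConfig(mass=0.1, dt=1e-3, n_steps=10,
                                   initial_position=name)
            x0, _, _ = sample_initial_state(asym_potential, exp_kernel, cfg,
                                            _rng(0))
            assert x0 == expect

    def test_massless_simulation_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(mass=0.0, dt=1e-3, n_steps=10)


class TestEquilibriumContracts:
    def test_harmonic_equipartition(self):
        k_spring, beta = 10.0, 1.0
        kern = MemoryKernel.exponential(1.0, 0.1)
        cfg = SimulationConfig(mass=0.05, dt=2e-3, n_steps=4_000_000,
                               burn_in=50_000, seed=3, sampling_stride=5)
        tr = simulate_equilibrium(HarmonicWell(k_spring), kern, cfg)
        var = tr.positions.var()
        # effective samples: correlation time ~ gamma/k
        n_eff = len(tr) * (tr.dt / (1.0 / k_spring))
        se = (1 / (beta * k_spring)) * np.sqrt(2.0 / n_eff)
        assert abs(var - 1 / (beta * k_spring)) < 3 * se

    def test_free_diffusion_einstein_relation(self):
        # MSD slope at t >> tau, tau_m equals 2/(beta gamma) per unit time
        kern = MemoryKernel.exponential(1.0, 0.1)
        cfg = SimulationConfig(mass=0.05, dt=2e-3, n_steps=25_000_000,
                               burn_in=1000, seed=4)
        tr = simulate_equilibrium(FlatPotential(), kern, cfg)
        x = tr.positions
        # two-lag slope removes the short-time (inertial + memory) offset
        lags = (5_000, 10_000)  # lag times 10 and 20, both >> tau, tau_m
        msd = [np.var(x[lag:] - x[:-lag]) for lag in lags]
        slope = (msd[1] - msd[0]) / ((lags[1] - lags[0]) * tr.dt)
        assert slope == pytest.approx(2.0, rel=0.05)

    def test_symmetric_double_well_occupancy(self, sym_potential):
        kern = MemoryKernel.exponential(1.0, 0.1)
        cfg = SimulationConfig(mass=0.01, dt=1e-3, n_steps=20_000_000,
                               burn_in=100_000, seed=5, sampling_stride=10)
        tr = simulate_equilibrium(sym_potential, kern, cfg)
        frac = (tr.positions < 0).mean()
        # effective sample = number of well-to-well transitions (~ e^3 scale)
        sign_flips = np.count_nonzero(np.diff(tr.positions > 0))
        se = 0.5 / np.sqrt(max(sign_flips, 1))
        assert abs(frac - 0.5) < 3 * se

    def test_asymmetric_well_occupancy_favours_deep_well(self):
        p = DoubleWellPotential(3.0, 5.0, 1.0, 1.0)
        kern = MemoryKernel.exponential(1.0, 0.01)
        cfg = SimulationConfig(mass=0.01, dt=1e-3, n_steps=20_000_000,
                               burn_in=100_000, seed=6, sampling_stride=10)
        tr = simulate_equilibrium(p, kern, cfg)
        assert (tr.positions > 0).mean() > 0.7

    def test_energy_conservation_without_friction(self):
        p = DoubleWellPotential(3.0, 5.0, 1.0, 0.8)
        kern = MemoryKernel.exponential(1e-12, 1.0)  # vanishing coupling
        m, dt = 0.5, 1e-3
        cfg = SimulationConfig(mass=m, dt=dt, n_steps=100_000, burn_in=1,
                               seed=1, initial_position=-0.4,
                               store_velocities=True)
        tr = simulate_equilibrium(p, kern, cfg)
        energy = 0.5 * m * tr.velocities**2 + p.energy(tr.positions)
        drift = np.ptp(energy) / energy[0]
        assert drift < 1e-4  # O(dt^2) per step, no secular growth

    def test_determinism_and_stride_decimation(self, sym_potential):
        kern = MemoryKernel.exponential(1.0, 0.1)
        base = dict(mass=0.05, dt=2e-3, n_steps=20_000, burn_in=100, seed=9)
        a = simulate_equilibrium(sym_potential, kern,
                                 SimulationConfig(**base))
        b = simulate_equilibrium(sym_potential, kern,
                                 SimulationConfig(**base))
        np.testing.assert_array_equal(a.positions, b.positions)
        c = simulate_equilibrium(sym_potential, kern,
                                 SimulationConfig(**base, sampling_stride=10))
        np.testing.assert_allclose(c.positions, a.positions[::10])

    def test_stability_contract_enforced(self, sym_potential):
        kern = MemoryKernel.exponential(1.0, 0.1)
        cfg = SimulationConfig(mass=1e-4, dt=1e-2, n_steps=1000)
        with pytest.raises(ValueError, match="stability"):
            simulate_equilibrium(sym_potential, kern, cfg)


class TestFluctuationDissipation:
    @pytest.mark.parametrize("kernel,beta", [
        (MemoryKernel.exponential(1.0, 0.1), 1.0),
        (MemoryKernel(((1.0, 0.1), (2.0, 1.0))), 2.0),
    ])
    def test_noise_autocorrelation_matches_kernel(self, kernel, beta):
        dt = 0.005
        n = 4_000_000
        f = colored_noise(kernel, n, dt, beta=beta, seed=77)
        for lag_t in (0.0, kernel.tau_min, 2 * kernel.tau_min):
            lag = int(round(lag_t / dt))
            expect = kernel.noise_autocorrelation(lag * dt, beta=beta)
            assert _acf(f, lag) == pytest.approx(expect, rel=0.05)


class TestMarkovianLimit:
    def test_gle_matches_independent_langevin_reference(self):
        # tau/tau_D = 1e-3: memory is negligible; compare MFPT-scale dynamics
        # via the stationary well population and positional variance
        p = DoubleWellPotential(2.5, 2.5, 1.0, 1.0)
        kern = MemoryKernel.exponential(1.0, 1e-3)
        cfg = SimulationConfig(mass=0.01, dt=5e-5, n_steps=40_000_000,
                               burn_in=200_000, seed=11, sampling_stride=20)
        gle = simulate_equilibrium(p, kern, cfg)
        ref = simulate_langevin_reference(p, 1.0, cfg)
        from glekinetics import well_to_barrier_mfpt
        a = well_to_barrier_mfpt(gle, p, "left")
        b = well_to_barrier_mfpt(ref, p, "left")
        comb = np.hypot(a.sem, b.sem)
        assert abs(a.mean - b.mean) < 2 * comb


class TestNonEquilibrium:
    def test_equal_decay_times_recover_equilibrium_variance(self):
        k_spring = 10.0
        kern = NonEqKernel(gamma=1.0, tau_v=0.2, tau_r=0.2)
        cfg = SimulationConfig(mass=0.05, dt=2e-3, n_steps=4_000_000,
                               burn_in=100_000, seed=13, sampling_stride=5)
        tr = simulate_nonequilibrium(HarmonicWell(k_spring), kern, cfg)
        var = tr.positions.var()
        n_eff = len(tr) * (tr.dt / (1.0 / k_spring))
        se = (1 / k_spring) * np.sqrt(2.0 / n_eff)
        assert abs(var - 1 / k_spring) < 3 * se

    def test_unequal_decay_times_break_boltzmann(self):
        # tau_R/tau_V = 2: stationary density departs from exp(-beta U)
        p = DoubleWellPotential(2.0, 2.0, 1.0, 1.0)
        kern = NonEqKernel(gamma=1.0, tau_v=0.2, tau_r=0.4)
        cfg = SimulationConfig(mass=0.1, dt=2e-3, n_steps=12_000_000,
                               burn_in=200_000, seed=14, sampling_stride=1000)
        tr = simulate_nonequilibrium(p, kern, cfg)
        x = tr.positions  # stride 1000 => samples ~2 tau_D apart
        grid = np.linspace(-2.0, 2.0, 2001)
        w = np.exp(-p.energy(grid))
        cdf_grid = np.cumsum(w)
        cdf_grid /= cdf_grid[-1]
        res = stats.ks_1samp(x, lambda v: np.interp(v, grid, cdf_grid))
        assert res.pvalue < 0.01

        # equilibrium control at tau_R = tau_V passes the same test
        kern_eq = NonEqKernel(gamma=1.0, tau_v=0.2, tau_r=0.2)
        tr_eq = simulate_nonequilibrium(p, kern_eq, cfg)
        res_eq = stats.ks_1samp(tr_eq.positions,
                                lambda v: np.interp(v, grid, cdf_grid))
        assert res_eq.pvalue > 0.01

    def test_noise_stream_autocorrelation(self):
        kern = NonEqKernel(gamma=1.0, tau_v=0.05, tau_r=0.2)
        dt = 0.005
        f = colored_noise(kern, 4_000_000, dt, beta=1.0, seed=21)
        for lag_t in (0.0, 0.2, 0.4):
            lag = int(round(lag_t / dt))
            expect = kern.noise_autocorrelation(lag * dt)
            assert _acf(f, lag) == pytest.approx(expect, rel=0.05)
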