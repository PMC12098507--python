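"""Generalized-Langevin-equation trajectory generation.

Integrates

    m x''(t) = - int_0^t Gamma(t-t') x'(t') dt' - U'(x(t)) + F_R(t)

for multi-exponential memory kernels via a Markovian embedding: each
exponential component is realized as one auxiliary Ornstein--Uhlenbeck
force coupled to the velocity, updated exactly over each timestep.  At
equilibrium the random force obeys the fluctuation--dissipation relation
<F_R(t) F_R(t')> = beta^-1 Gamma(t - t'); the non-equilibrium variant uses
an exponential friction kernel (decay tau_V) and an independent exponential
random force (decay tau_R), which drives the stationary distribution away
from the Boltzmann form whenever tau_V != tau_R.

The memory integral starts at t = 0; startup transients are avoided by
drawing velocity and auxiliary forces from their stationary laws at t = 0
and by an additional configurable burn-in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Union

import numpy as np
from scipy.signal import lfilter

from . import _integrators as _ig
from .kernels import MemoryKernel, NonEqKernel, inertial_time
from .potential import DoubleWellPotential, FlatPotential, HarmonicWell

Potential = Union[DoubleWellPotential, HarmonicWell, FlatPotential]

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "IntegrationError",
    "sample_initial_state",
    "simulate_equilibrium",
    "simulate_nonequilibrium",
    "simulate_langevin_reference",
    "iter_position_chunks",
    "colored_noise",
    "default_timestep",
]

_CHUNK = 1 << 22  # steps per compiled call; bounds memory for normals/output

# stability contract: dt must not exceed this fraction of the fastest scale
_STABILITY_FRACTION = 0.1


class IntegrationError(RuntimeError):
    """Non-finite state encountered during integration."""


@dataclass(frozen=True)
class SimulationConfig:
    """Integrator settings.

    ``n_steps`` counts all steps including ``burn_in``; stored samples start
    at the end of burn-in and are decimated by ``sampling_stride``.
    ``initial_position`` is a coordinate or one of ``"left-minimum"`` /
    ``"right-minimum"``.
    """

    mass: float
    dt: float
    n_steps: int
    beta: float = 1.0
    burn_in: int = 0
    seed: int = 0
    initial_position: Union[float, str] = "left-minimum"
    sampling_stride: int = 1
    store_velocities: bool = False

    def __post_init__(self):
        if self.mass <= 0:
            raise ValueError(
                "mass must be > 0 for simulation; the massless limit exists "
                "only in the closed-form theory")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if not (self.n_steps > self.burn_in >= 0):
            raise ValueError("need n_steps > burn_in >= 0")
        if self.sampling_stride < 1:
            raise ValueError("sampling_stride must be >= 1")


@dataclass
class Trajectory:
    """Uniformly sampled reaction-coordinate time series."""

    t0: float
    dt: float  # spacing of stored samples (config dt * sampling_stride)
    positions: np.ndarray
    velocities: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(len(self.positions))

    def __len__(self) -> int:
        return len(self.positions)


def default_timestep(potential: Potential, kernel, mass: float,
                     beta: float = 1.0, factor: float = 0.01,
                     l_ref: float | None = None) -> float:
    """Timestep from the fastest system scale.

    dt = factor * min(tau_m, min_i tau_i, sqrt(m/K_max), tau_D), skipping
    scales that are infinite or undefined.  ``factor`` defaults to a
    conservative 0.01; the stability contract only requires <= 0.1.
    """
    gamma = kernel.gamma_total
    scales = [inertial_time(mass, gamma), kernel.tau_min]
    kmax = potential.max_curvature
    if kmax > 0:
        scales.append(math.sqrt(mass / kmax))
    if l_ref is None and isinstance(potential, DoubleWellPotential):
        l_ref = potential.l_left
    if l_ref is not None:
        scales.append(beta * l_ref**2 * gamma)
    return factor * min(scales)


def _check_stability(potential: Potential, kernel, config: SimulationConfig):
    gamma = kernel.gamma_total
    named = {"tau_m = m/gamma": inertial_time(config.mass, gamma),
             "min memory time tau_i": kernel.tau_min}
    kmax = potential.max_curvature
    if kmax > 0:
        named["oscillation time sqrt(m/K_max)"] = math.sqrt(config.mass / kmax)
    for name, scale in named.items():
        if config.dt > _STABILITY_FRACTION * scale:
            raise ValueError(
                f"dt = {config.dt:g} violates the stability contract: it must "
                f"be <= {_STABILITY_FRACTION:g} * {name} = "
                f"{_STABILITY_FRACTION * scale:g}")


def _pot_params(potential: Potential):
    if isinstance(potential, DoubleWellPotential):
        return (_ig.DOUBLE_WELL,
                4.0 * potential.u_left / potential.l_left**2,
                1.0 / potential.l_left**2,
                4.0 * potential.u_right / potential.l_right**2,
                1.0 / potential.l_right**2)
    if isinstance(potential, HarmonicWell):
        return (_ig.HARMONIC, potential.k, potential.x0, 0.0, 0.0)
    if isinstance(potential, FlatPotential):
        return (_ig.FLAT, 0.0, 0.0, 0.0, 0.0)
    raise TypeError(f"unsupported potential type {type(potential).__name__}")


def _initial_position(potential: Potential, config: SimulationConfig) -> float:
    pos = config.initial_position
    if isinstance(pos, str):
        if not isinstance(potential, DoubleWellPotential):
            # single-well / flat potentials: start at the rest point
            if pos in ("left-minimum", "right-minimum"):
                return getattr(potential, "x0", 0.0)
            raise ValueError(f"unknown initial position {pos!r}")
        if pos == "left-minimum":
            return -potential.l_left
        if pos == "right-minimum":
            return potential.l_right
        raise ValueError(f"unknown initial position {pos!r}")
    if not np.isfinite(pos):
        raise ValueError("initial position must be finite")
    return float(pos)


def _rng(seed) -> np.random.Generator:
    return np.random.Generator(np.random.SFC64(np.random.SeedSequence(seed)))


def sample_initial_state(potential: Potential, kernel, config: SimulationConfig,
                         rng: np.random.Generator):
    """Draw (position, velocity, auxiliary forces) for the start of a run.

    Velocity is Maxwellian at temperature 1/beta; equilibrium auxiliary
    forces are drawn from their stationary Gaussians N(0, gamma_i/(beta
    tau_i)).  For the non-equilibrium kernel the noise component starts in
    its stationary law N(0, gamma/(beta tau_R)) while the deterministic
    friction convolution starts at zero (its stationary value is tied to
    the velocity history; burn-in removes the transient).
    """
    x0 = _initial_position(potential, config)
    v0 = rng.normal(0.0, math.sqrt(1.0 / (config.beta * config.mass)))
    if isinstance(kernel, MemoryKernel):
        std = np.sqrt(kernel.gammas / (config.beta * kernel.taus))
        aux = rng.standard_normal(kernel.n_components) * std
    elif isinstance(kernel, NonEqKernel):
        r0 = rng.normal(0.0, math.sqrt(kernel.gamma / (config.beta * kernel.tau_r)))
        aux = np.array([0.0, r0])
    else:
        raise TypeError(f"unsupported kernel type {type(kernel).__name__}")
    return x0, v0, aux


def _raise_if_nonfinite(x_chunk, potential, kernel, config):
    if np.all(np.isfinite(x_chunk)):
        return
    gamma = kernel.gamma_total
    tau_m = inertial_time(config.mass, gamma)
    kmax = potential.max_curvature
    osc = math.sqrt(config.mass / kmax) if kmax > 0 else math.inf
    raise IntegrationError(
        "non-finite state during integration; timescale ratios at failure: "
        f"dt/tau_m = {config.dt / tau_m:g}, "
        f"dt/min(tau_i) = {config.dt / kernel.tau_min:g}, "
        f"dt/sqrt(m/K_max) = {config.dt / osc:g}")


def _run(potential: Potential, kernel, config: SimulationConfig,
         chunk_steps: int):
    """Common chunked driver; yields stored-position chunks after burn-in."""
    _check_stability(potential, kernel, config)
    mode, p0, p1, p2, p3 = _pot_params(potential)
    dt = config.dt
    inv_m = 1.0 / config.mass
    rng = _rng(config.seed)
    x0, v0, aux = sample_initial_state(potential, kernel, config, rng)
    st = np.array([x0, v0])

    if isinstance(kernel, MemoryKernel):
        taus = kernel.taus
        gams = kernel.gammas
        th = np.exp(-dt / taus)
        cgam = gams * (1.0 - th)
        sig = np.sqrt(gams / (config.beta * taus) * (1.0 - th * th))
        ncols = kernel.n_components

        def step(n, xi, out_x, out_v, stride, c, store_v):
            return _ig.gle_chunk(st, aux, n, dt, inv_m, mode, p0, p1, p2, p3,
                                 th, cgam, sig, xi, out_x, out_v,
                                 stride, c, store_v)
    else:
        th_v = math.exp(-dt / kernel.tau_v)
        cgam_v = kernel.gamma * (1.0 - th_v)
        th_r = math.exp(-dt / kernel.tau_r)
        sig_r = math.sqrt(kernel.gamma / (config.beta * kernel.tau_r)
                          * (1.0 - th_r * th_r))
        ncols = 1

        def step(n, xi, out_x, out_v, stride, c, store_v):
            return _ig.neq_chunk(st, aux, n, dt, inv_m, mode, p0, p1, p2, p3,
                                 th_v, cgam_v, th_r, sig_r, xi, out_x, out_v,
                                 stride, c, store_v)

    empty = np.empty(0)
    # burn-in: integrate without storing
    done = 0
    while done < config.burn_in:
        n = min(chunk_steps, config.burn_in - done)
        xi = rng.standard_normal((n, ncols))
        step(n, xi, empty, empty, n + 1, 0, False)
        done += n
    if not np.all(np.isfinite(st)):
        _raise_if_nonfinite(st, potential, kernel, config)

    stride = config.sampling_stride
    store_v = config.store_velocities
    # initial sample at the end of burn-in
    yield st[:1].copy(), (st[1:2].copy() if store_v else None)
    remaining = config.n_steps - config.burn_in
    c = 0
    while remaining > 0:
        n = min(chunk_steps, remaining)
        xi = rng.standard_normal((n, ncols))
        nmax = n // stride + 1
        out_x = np.empty(nmax)
        out_v = np.empty(nmax if store_v else 0)
        k, c = step(n, xi, out_x, out_v, stride, c, store_v)
        x_chunk = out_x[:k]
        _raise_if_nonfinite(x_chunk, potential, kernel, config)
        yield x_chunk, (out_v[:k] if store_v else None)
        remaining -= n


def _metadata(potential, kernel, config) -> dict:
    if isinstance(kernel, MemoryKernel):
        kmeta = {"type": "equilibrium", "components": kernel.to_list()}
    else:
        kmeta = {"type": "nonequilibrium", **kernel.to_dict()}
    pmeta = potential.to_dict() if hasattr(potential, "to_dict") else {
        "type": type(potential).__name__}
    return {"potential": pmeta, "kernel": kmeta,
            "config": {"mass": config.mass, "beta": config.beta,
                       "dt": config.dt, "n_steps": config.n_steps,
                       "burn_in": config.burn_in, "seed": config.seed,
                       "sampling_stride": config.sampling_stride}}


def _collect(potential, kernel, config, chunk_steps) -> Trajectory:
    xs, vs = [], []
    for x_chunk, v_chunk in _run(potential, kernel, config, chunk_steps):
        xs.append(x_chunk)
        if v_chunk is not None:
            vs.append(v_chunk)
    positions = np.concatenate(xs)
    velocities = np.concatenate(vs) if vs else None
    return Trajectory(t0=config.burn_in * config.dt,
                      dt=config.dt * config.sampling_stride,
                      positions=positions, velocities=velocities,
                      metadata=_metadata(potential, kernel, config))


def simulate_equilibrium(potential: Potential, kernel: MemoryKernel,
                         config: SimulationConfig,
                         chunk_steps: int = _CHUNK) -> Trajectory:
    """Integrate the equilibrium GLE and return the sampled trajectory."""
    if not isinstance(kernel, MemoryKernel):
        raise TypeError("simulate_equilibrium needs a MemoryKernel")
    return _collect(potential, kernel, config, chunk_steps)


def simulate_nonequilibrium(potential: Potential, kernel: NonEqKernel,
                            config: SimulationConfig,
                            chunk_steps: int = _CHUNK) -> Trajectory:
    """Integrate the non-equilibrium GLE (friction decay tau_V, noise decay tau_R)."""
    if not isinstance(kernel, NonEqKernel):
        raise TypeError("simulate_nonequilibrium needs a NonEqKernel")
    return _collect(potential, kernel, config, chunk_steps)


def iter_position_chunks(potential: Potential, kernel, config: SimulationConfig,
                         chunk_steps: int = _CHUNK) -> Iterator[np.ndarray]:
    """Stream stored-position chunks without holding the full trajectory.

    Used for long first-passage runs: crossing detection consumes each chunk
    and only compact statistics are retained.  The first yielded chunk starts
    with the state at the end of burn-in.
    """
    for x_chunk, _ in _run(potential, kernel, config, chunk_steps):
        yield x_chunk


def simulate_langevin_reference(potential: Potential, gamma: float,
                                config: SimulationConfig,
                                chunk_steps: int = _CHUNK) -> Trajectory:
    """Markovian white-noise Langevin dynamics (BAOAB).

    Independent reference for the memoryless limit of the GLE engine; shares
    no integration code path with the memory-kernel loops.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    mode, p0, p1, p2, p3 = _pot_params(potential)
    kmax = potential.max_curvature
    if kmax > 0 and config.dt > _STABILITY_FRACTION * math.sqrt(config.mass / kmax):
        raise ValueError("dt violates the stability contract on sqrt(m/K_max)")
    dt = config.dt
    inv_m = 1.0 / config.mass
    c1 = math.exp(-gamma * dt / config.mass)
    c2 = math.sqrt((1.0 - c1 * c1) / (config.beta * config.mass))
    rng = _rng(config.seed)
    x0 = _initial_position(potential, config)
    v0 = rng.normal(0.0, math.sqrt(1.0 / (config.beta * config.mass)))
    st = np.array([x0, v0])
    empty = np.empty(0)
    done = 0
    while done < config.burn_in:
        n = min(chunk_steps, config.burn_in - done)
        xi = rng.standard_normal((n, 1))
        _ig.langevin_chunk(st, n, dt, inv_m, mode, p0, p1, p2, p3,
                           c1, c2, xi, empty, empty, n + 1, 0, False)
        done += n
    xs = [st[:1].copy()]
    vs = [st[1:2].copy()]
    stride = config.sampling_stride
    store_v = config.store_velocities
    remaining = config.n_steps - config.burn_in
    c = 0
    while remaining > 0:
        n = min(chunk_steps, remaining)
        xi = rng.standard_normal((n, 1))
        nmax = n // stride + 1
        out_x = np.empty(nmax)
        out_v = np.empty(nmax if store_v else 0)
        k, c = _ig.langevin_chunk(st, n, dt, inv_m, mode, p0, p1, p2, p3,
                                  c1, c2, xi, out_x, out_v, stride, c, store_v)
        if not np.all(np.isfinite(out_x[:k])):
            raise IntegrationError("non-finite state in Langevin reference run")
        xs.append(out_x[:k])
        if store_v:
            vs.append(out_v[:k])
        remaining -= n
    return Trajectory(t0=config.burn_in * dt, dt=dt * stride,
                      positions=np.concatenate(xs),
                      velocities=np.concatenate(vs) if store_v else None,
                      metadata={"integrator": "langevin-baoab", "gamma": gamma})


def colored_noise(kernel, n: int, dt: float, beta: float = 1.0,
                  seed: int = 0) -> np.ndarray:
    """Stationary random-force realization for a kernel.

    For an equilibrium :class:`MemoryKernel` the stream is the sum of
    independent OU components with autocovariance
    (gamma_i/(beta tau_i)) exp(-|dt|/tau_i) (fluctuation--dissipation); for
    a :class:`NonEqKernel` it is the single OU force with decay tau_R.
    """
    rng = _rng(seed)
    if isinstance(kernel, MemoryKernel):
        comps = kernel.components
    elif isinstance(kernel, NonEqKernel):
        comps = ((kernel.gamma, kernel.tau_r),)
    else:
        raise TypeError(f"unsupported kernel type {type(kernel).__name__}")
    out = np.zeros(n)
    for g, tau in comps:
        var = g / (beta * tau)
        th = math.exp(-dt / tau)
        innov = math.sqrt(var * (1.0 - th * th)) * rng.standard_normal(n)
        f0 = rng.normal(0.0, math.sqrt(var))
        innov[0] = f0  # start in the stationary law
        stream, _ = lfilter([1.0], [1.0, -th], innov, zi=np.array([0.0]))
        out += stream
    return out
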