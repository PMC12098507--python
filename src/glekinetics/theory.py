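"""Closed-form mean-first-passage-time predictions.

All formulas interpolate between the Kramers low-friction (energy-diffusion)
and high-friction (overdamped) limits with a heuristic crossover term, for a
piecewise-quartic double well with barrier height U (in absolute energy
units), well curvature K = 8U/L^2, friction gamma, exponential memory time
tau, particle mass m, and inverse temperature beta:

well-to-well (symmetric well, barrier height U0, curvature K)::

    tau_MFP = e^{beta U0} [ (1/(beta U0)) (3 pi/(8 sqrt2)) (m/gamma
                 + 2 K tau^2/(3 gamma))
              + (2 sqrt2 pi gamma/K) / (1 + K beta U0 tau/(4 gamma))
              + 4 sqrt(2 m/K) ]

well-to-barrier-top (asymmetric wells decouple; use the side's own U, K)::

    same expression with the overdamped prefactor halved
    (sqrt2 pi gamma/K instead of 2 sqrt2 pi gamma/K).

For multi-exponential kernels the prediction combines per-component
overdamped contributions additively and per-component energy-diffusion
contributions harmonically.  For the non-equilibrium exponential pair
(friction decay tau_V, noise decay tau_R) the same well-to-top expression
holds with beta -> beta_NEQ = beta tau_R^2/tau_V^2 and tau -> tau_V.

The module also provides the exact overdamped Markovian double-integral
MFPT as an independent quadrature oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_simpson, quad

from .kernels import MemoryKernel
from .potential import DoubleWellPotential

__all__ = [
    "D1",
    "D2",
    "TheoryPrediction",
    "mfpt_well_to_well",
    "mfpt_well_to_top",
    "od_contribution",
    "ed_contribution",
    "multi_exponential_mfpt",
    "neq_effective_beta",
    "neq_mfpt_well_to_top",
    "overdamped_mfpt_quadrature",
]

# Kramers constants of the interpolation formula
D1 = 3.0 * math.pi / (8.0 * math.sqrt(2.0))
D2 = 2.0 * math.sqrt(2.0) * math.pi


@dataclass(frozen=True)
class TheoryPrediction:
    """MFPT prediction with its term-by-term breakdown.

    ``total = inertial_term + overdamped_term + crossover_term`` exactly;
    the inertial term is the low-friction (energy-diffusion) contribution,
    the overdamped term the high-friction contribution, and the crossover
    term the heuristic turnover correction.
    """

    total: float
    inertial_term: float
    overdamped_term: float
    crossover_term: float

    def __post_init__(self):
        for name in ("inertial_term", "overdamped_term", "crossover_term"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _validate(barrier_height, curvature, gamma, tau, mass, beta):
    if barrier_height <= 0:
        raise ValueError("barrier height must be > 0")
    if curvature <= 0:
        raise ValueError("curvature must be > 0")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    if beta <= 0:
        raise ValueError("beta must be > 0")
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if mass < 0:
        raise ValueError("mass must be >= 0")


def _prediction(barrier_height, curvature, gamma, tau, mass, beta,
                od_prefactor: float) -> TheoryPrediction:
    _validate(barrier_height, curvature, gamma, tau, mass, beta)
    bu = beta * barrier_height
    boltzmann = math.exp(bu)
    inertial = boltzmann / bu * D1 * (mass / gamma
                                      + 2.0 * curvature * tau**2 / (3.0 * gamma))
    overdamped = (boltzmann * od_prefactor * gamma / curvature
                  / (1.0 + curvature * bu * tau / (4.0 * gamma)))
    crossover = boltzmann * 4.0 * math.sqrt(2.0 * mass / curvature)
    return TheoryPrediction(total=inertial + overdamped + crossover,
                            inertial_term=inertial,
                            overdamped_term=overdamped,
                            crossover_term=crossover)


def mfpt_well_to_well(barrier_height: float, curvature: float, gamma: float,
                      tau: float = 0.0, mass: float = 0.0,
                      beta: float = 1.0) -> TheoryPrediction:
    """Well-to-well MFPT for a symmetric double well (curvature K = 8 U0/L^2)."""
    return _prediction(barrier_height, curvature, gamma, tau, mass, beta, D2)


def mfpt_well_to_top(barrier_height: float, curvature: float, gamma: float,
                     tau: float = 0.0, mass: float = 0.0,
                     beta: float = 1.0) -> TheoryPrediction:
    """Well-to-barrier-top MFPT using one side's barrier height and curvature.

    The two wells decouple: the prediction depends only on the chosen
    side's U and K = 8U/L^2, never on the other well's shape.
    """
    return _prediction(barrier_height, curvature, gamma, tau, mass, beta, D2 / 2.0)


def mfpt_well_to_top_for(p: DoubleWellPotential, side: str, gamma: float,
                         tau: float = 0.0, mass: float = 0.0,
                         beta: float = 1.0) -> TheoryPrediction:
    """Convenience wrapper picking U_s and K_s from a potential side."""
    u, _ = p._side_params(side)
    return mfpt_well_to_top(u, p.curvature_at_minimum(side), gamma, tau, mass, beta)


def od_contribution(barrier_height: float, curvature: float, gamma_i: float,
                    tau_i: float = 0.0, mass: float = 0.0,
                    beta: float = 1.0) -> float:
    """Per-component overdamped contribution for multi-exponential memory."""
    _validate(barrier_height, curvature, gamma_i, tau_i, mass, beta)
    bu = beta * barrier_height
    return math.exp(bu) * (
        D2 / 2.0 * gamma_i / curvature
        / (1.0 + bu * curvature * tau_i / (4.0 * gamma_i))
        + 2.0 * math.sqrt(2.0 * mass / curvature))


def ed_contribution(barrier_height: float, curvature: float, gamma_i: float,
                    tau_i: float = 0.0, mass: float = 0.0,
                    beta: float = 1.0) -> float:
    """Per-component energy-diffusion contribution for multi-exponential memory."""
    _validate(barrier_height, curvature, gamma_i, tau_i, mass, beta)
    bu = beta * barrier_height
    return math.exp(bu) * (
        D1 / bu * (mass / gamma_i + 2.0 * curvature * tau_i**2 / (3.0 * gamma_i))
        + 2.0 * math.sqrt(2.0 * mass / curvature))


def multi_exponential_mfpt(barrier_height: float, curvature: float,
                           kernel: MemoryKernel, mass: float = 0.0,
                           beta: float = 1.0) -> float:
    """Well-to-top MFPT for an N-component kernel.

    Overdamped contributions add; energy-diffusion contributions combine
    harmonically (inverse of the sum of reciprocals).  N = 1 reproduces
    :func:`mfpt_well_to_top` exactly.
    """
    if kernel.n_components == 1:
        # the combination rule reduces algebraically to the base formula;
        # evaluate it through the same code path so the reduction is exact
        (g, t), = kernel.components
        return mfpt_well_to_top(barrier_height, curvature, g, t, mass,
                                beta).total
    od = sum(od_contribution(barrier_height, curvature, g, t, mass, beta)
             for g, t in kernel.components)
    eds = [ed_contribution(barrier_height, curvature, g, t, mass, beta)
           for g, t in kernel.components]
    if any(e == 0.0 for e in eds):
        ed = 0.0  # massless, memoryless components carry no energy-diffusion cost
    else:
        ed = 1.0 / sum(1.0 / e for e in eds)
    return od + ed


def neq_effective_beta(beta: float, tau_r: float, tau_v: float) -> float:
    """Non-equilibrium effective inverse temperature beta tau_R^2 / tau_V^2."""
    if beta <= 0 or tau_r <= 0 or tau_v <= 0:
        raise ValueError("beta, tau_r and tau_v must be > 0")
    return beta * tau_r**2 / tau_v**2


def neq_mfpt_well_to_top(barrier_height: float, curvature: float, gamma: float,
                         tau_v: float, tau_r: float, mass: float = 0.0,
                         beta: float = 1.0) -> TheoryPrediction:
    """Well-to-top MFPT for the non-equilibrium exponential pair.

    Identical to :func:`mfpt_well_to_top` with beta replaced by
    beta_NEQ = beta tau_R^2/tau_V^2 everywhere and the memory time set to
    tau_V; at tau_R = tau_V it coincides with the equilibrium formula.
    """
    beta_neq = neq_effective_beta(beta, tau_r, tau_v)
    return mfpt_well_to_top(barrier_height, curvature, gamma,
                            tau=tau_v, mass=mass, beta=beta_neq)


# ---------------------------------------------------------------------------
# exact Markovian overdamped oracle

_TRUNCATION = 1e-12  # Boltzmann-weight cutoff for the open lower limit


def overdamped_mfpt_quadrature(potential, start: float, target: float,
                               beta: float = 1.0, gamma: float = 1.0,
                               lower: float | None = None,
                               n_grid: int = 20001) -> float:
    """Exact overdamped Markovian MFPT by double quadrature.

    tau = beta gamma * int_start^target dy e^{beta U(y)}
                      * int_lower^y dz e^{-beta U(z)}

    ``lower`` defaults to the point (left of ``start``) where the Boltzmann
    weight has fallen below 1e-12 of its maximum over the accessible range,
    which truncates the open lower limit; pass an explicit value to impose
    a reflecting boundary instead.  The inner integral is tabulated by
    cumulative Simpson quadrature on ``n_grid`` points and the outer
    integral evaluated adaptively.
    """
    if not target > start:
        raise ValueError("need start < target")
    raw = potential.energy if hasattr(potential, "energy") else potential

    def energy(v):
        out = np.asarray(raw(v), dtype=float)
        if np.shape(out) != np.shape(v):  # scalar-only callable
            out = np.vectorize(raw)(v)
        return out

    if lower is None:
        # scan left from start until the Boltzmann weight is negligible
        span = max(target - start, 1.0)
        xs = start - span * np.linspace(0.0, 100.0, 20001)
        u = beta * energy(xs)
        u0 = u.min()
        below = np.nonzero(u - u0 > -math.log(_TRUNCATION))[0]
        if below.size == 0:
            raise RuntimeError(
                "could not truncate the lower integration limit; the "
                "potential does not confine the particle on the left")
        lower = float(xs[below[0]])

    grid = np.linspace(lower, target, n_grid)
    u_grid = beta * energy(grid)
    u_ref = u_grid.min()
    inner = cumulative_simpson(np.exp(-(u_grid - u_ref)), x=grid, initial=0.0)

    def outer(y):
        iy = np.interp(y, grid, inner)
        return math.exp(beta * float(raw(y)) - u_ref) * iy

    val, err = quad(outer, start, target, limit=200)
    if not np.isfinite(val) or (val > 0 and err / val > 1e-6):
        raise RuntimeError(f"outer quadrature did not converge (err={err:g})")
    return beta * gamma * val
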