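"""Friction memory kernels and the characteristic timescales.

The equilibrium kernel is a sum of exponentials,

    Gamma(t) = sum_i (gamma_i / tau_i) exp(-|t| / tau_i),

with total friction gamma = sum_i gamma_i = integral_0^inf Gamma(t) dt.
Each component is paired (fluctuation--dissipation) with an independent
Ornstein--Uhlenbeck random-force component of covariance
k_BT (gamma_i/tau_i) exp(-|dt|/tau_i).

The non-equilibrium variant breaks fluctuation--dissipation by giving the
friction kernel and the random-force autocorrelation different decay times
tau_V and tau_R (both exponential, both integrating to gamma).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MemoryKernel", "NonEqKernel", "inertial_time", "diffusion_time"]


@dataclass(frozen=True)
class MemoryKernel:
    """Multi-exponential friction kernel; components sorted by decay time."""

    components: tuple[tuple[float, float], ...]  # (gamma_i, tau_i)

    def __post_init__(self):
        comps = tuple((float(g), float(t)) for g, t in self.components)
        if len(comps) < 1:
            raise ValueError("kernel needs at least one component")
        for g, t in comps:
            if not (np.isfinite(g) and g > 0):
                raise ValueError(f"component friction weight must be > 0, got {g}")
            if not (np.isfinite(t) and t > 0):
                raise ValueError(f"component memory time must be > 0, got {t}")
        object.__setattr__(self, "components", tuple(sorted(comps, key=lambda c: c[1])))

    @classmethod
    def exponential(cls, gamma: float, tau: float) -> "MemoryKernel":
        """Single-exponential kernel Gamma(t) = (gamma/tau) exp(-|t|/tau)."""
        return cls(((gamma, tau),))

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def gammas(self) -> np.ndarray:
        return np.array([g for g, _ in self.components])

    @property
    def taus(self) -> np.ndarray:
        return np.array([t for _, t in self.components])

    @property
    def gamma_total(self) -> float:
        """Total friction coefficient, the time integral of the kernel."""
        return float(self.gammas.sum())

    @property
    def tau_min(self) -> float:
        return float(self.taus.min())

    def value(self, t):
        """Kernel value Gamma(t) = sum_i (gamma_i/tau_i) exp(-|t|/tau_i); even in t."""
        t = np.abs(np.asarray(t, dtype=float))
        out = sum(g / tau * np.exp(-t / tau) for g, tau in self.components)
        return out if np.ndim(out) else float(out)

    def noise_autocorrelation(self, t, beta: float = 1.0):
        """Equilibrium random-force autocovariance beta^-1 Gamma(t)."""
        v = self.value(t)
        return v / beta

    def to_list(self) -> list[dict]:
        return [{"gamma": g, "tau": t} for g, t in self.components]

    @classmethod
    def from_list(cls, items) -> "MemoryKernel":
        return cls(tuple((d["gamma"], d["tau"]) for d in items))


@dataclass(frozen=True)
class NonEqKernel:
    """Exponential friction/noise pair with distinct decay times.

    Gamma_V(t) = (gamma/tau_V) exp(-|t|/tau_V) damps the velocity;
    the random force has autocovariance beta^-1 (gamma/tau_R) exp(-|t|/tau_R).
    tau_V = tau_R recovers the equilibrium single-exponential model.
    """

    gamma: float
    tau_v: float
    tau_r: float

    def __post_init__(self):
        for name in ("gamma", "tau_v", "tau_r"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v!r}")

    @property
    def gamma_total(self) -> float:
        return self.gamma

    @property
    def tau_min(self) -> float:
        return min(self.tau_v, self.tau_r)

    def friction_value(self, t):
        t = np.abs(np.asarray(t, dtype=float))
        out = self.gamma / self.tau_v * np.exp(-t / self.tau_v)
        return out if np.ndim(out) else float(out)

    def noise_autocorrelation(self, t, beta: float = 1.0):
        t = np.abs(np.asarray(t, dtype=float))
        out = self.gamma / (beta * self.tau_r) * np.exp(-t / self.tau_r)
        return out if np.ndim(out) else float(out)

    def to_dict(self) -> dict:
        return {"gamma": self.gamma, "tau_v": self.tau_v, "tau_r": self.tau_r}

    @classmethod
    def from_dict(cls, d) -> "NonEqKernel":
        return cls(d["gamma"], d["tau_v"], d["tau_r"])


def inertial_time(mass: float, gamma: float) -> float:
    """Inertial relaxation time tau_m = m / gamma."""
    if mass < 0:
        raise ValueError("mass must be >= 0")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    return mass / gamma


def diffusion_time(beta: float, l_left: float, gamma: float) -> float:
    """Diffusion time tau_D = beta L_L^2 gamma (left well width as length scale)."""
    if beta <= 0 or l_left <= 0 or gamma <= 0:
        raise ValueError("beta, l_left and gamma must be > 0")
    return beta * l_left**2 * gamma
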