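"""Asymmetric double-well potentials and free-energy-profile fitting.

The central object is :class:`DoubleWellPotential`, a piecewise-quartic
double well parameterized by the two barrier heights ``U_L``, ``U_R`` (the
barrier top seen from the left and right wells) and the two well widths
``L_L``, ``L_R`` (distance from each minimum to the barrier top).  The
barrier top sits at ``x = 0``, the minima at ``-L_L`` and ``+L_R``, and the
left-minimum energy is pinned to zero:

    U(x) = U_L [ (x/L_L)^2 - 1 ]^2                      for x <= 0
    U(x) = U_R [ (x/L_R)^2 - 1 ]^2 + (U_L - U_R)        for x  > 0

The potential and its first derivative are continuous at the barrier top;
the second derivative is discontinuous there (one-sided curvatures
``-4 U_s / L_s^2``), which does not perturb the dynamics.

Tabulated one-dimensional free-energy profiles (e.g. along a protein-folding
reaction coordinate such as the fraction of native contacts) can be fitted
by this form with :func:`fit_double_well`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import least_squares

Side = Literal["left", "right"]

__all__ = [
    "DoubleWellPotential",
    "FreeEnergyProfile",
    "HarmonicWell",
    "FlatPotential",
    "DoubleWellFit",
    "ProfileShapeError",
    "fit_double_well",
]


class ProfileShapeError(ValueError):
    """Raised when a free-energy profile lacks two-minima/one-maximum topology."""


def _check_finite(x):
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("positions must be finite")
    return x


@dataclass(frozen=True)
class DoubleWellPotential:
    """Piecewise-quartic asymmetric double well.

    Parameters
    ----------
    u_left, u_right : float
        Barrier heights seen from the left and right well, in units of k_BT
        (or any consistent energy unit).
    l_left, l_right : float
        Distances from the left and right minima to the barrier top.
    """

    u_left: float
    u_right: float
    l_left: float
    l_right: float

    def __post_init__(self):
        for name in ("u_left", "u_right", "l_left", "l_right"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be positive and finite, got {v!r}")

    # -- geometry -----------------------------------------------------------
    @property
    def barrier_top(self) -> float:
        return 0.0

    @property
    def minima(self) -> tuple[float, float]:
        return (-self.l_left, self.l_right)

    def _side_params(self, side: Side) -> tuple[float, float]:
        if side == "left":
            return self.u_left, self.l_left
        if side == "right":
            return self.u_right, self.l_right
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")

    # -- evaluation ---------------------------------------------------------
    def energy(self, x):
        """Potential energy U(x); vectorized."""
        x = _check_finite(x)
        ql = (x / self.l_left) ** 2 - 1.0
        qr = (x / self.l_right) ** 2 - 1.0
        left = self.u_left * ql * ql
        right = self.u_right * qr * qr + (self.u_left - self.u_right)
        out = np.where(x <= 0.0, left, right)
        return out if out.ndim else float(out)

    def force(self, x):
        """Force -dU/dx; continuous at the barrier top (both branches give 0)."""
        x = _check_finite(x)
        fl = -4.0 * self.u_left / self.l_left**2 * x * ((x / self.l_left) ** 2 - 1.0)
        fr = -4.0 * self.u_right / self.l_right**2 * x * ((x / self.l_right) ** 2 - 1.0)
        out = np.where(x <= 0.0, fl, fr)
        return out if out.ndim else float(out)

    def curvature_at_minimum(self, side: Side) -> float:
        """Curvature K_s = U''(minimum) = 8 U_s / L_s^2."""
        u, l = self._side_params(side)
        return 8.0 * u / l**2

    def barrier_curvature(self, side: Side) -> float:
        """One-sided second derivative at the barrier top, -4 U_s / L_s^2.

        The two sides differ for asymmetric parameters: the second derivative
        is discontinuous at the top.
        """
        u, l = self._side_params(side)
        return -4.0 * u / l**2

    @property
    def max_curvature(self) -> float:
        """Largest curvature magnitude over minima and barrier top.

        Sets the fastest harmonic frequency sqrt(K/m) and hence the timestep.
        """
        return max(
            self.curvature_at_minimum("left"),
            self.curvature_at_minimum("right"),
            abs(self.barrier_curvature("left")),
            abs(self.barrier_curvature("right")),
        )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "u_left": self.u_left,
            "u_right": self.u_right,
            "l_left": self.l_left,
            "l_right": self.l_right,
            "energy_unit": "k_BT",
            "length_unit": "L",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DoubleWellPotential":
        return cls(d["u_left"], d["u_right"], d["l_left"], d["l_right"])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "DoubleWellPotential":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class HarmonicWell:
    """Harmonic potential U = k (x - x0)^2 / 2, mainly for simulator checks."""

    k: float
    x0: float = 0.0

    def __post_init__(self):
        if not (np.isfinite(self.k) and self.k > 0):
            raise ValueError("spring constant k must be positive")

    def energy(self, x):
        x = _check_finite(x)
        out = 0.5 * self.k * (x - self.x0) ** 2
        return out if out.ndim else float(out)

    def force(self, x):
        x = _check_finite(x)
        out = -self.k * (x - self.x0)
        return out if out.ndim else float(out)

    @property
    def max_curvature(self) -> float:
        return self.k


@dataclass(frozen=True)
class FlatPotential:
    """Zero potential (free diffusion)."""

    def energy(self, x):
        x = _check_finite(x)
        out = np.zeros_like(x)
        return out if out.ndim else 0.0

    def force(self, x):
        return self.energy(x)

    @property
    def max_curvature(self) -> float:
        return 0.0


@dataclass(frozen=True)
class FreeEnergyProfile:
    """Tabulated 1-D free-energy profile (positions strictly increasing)."""

    positions: np.ndarray
    energies: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.positions, dtype=float)
        e = np.asarray(self.energies, dtype=float)
        if q.ndim != 1 or e.ndim != 1 or q.size != e.size:
            raise ValueError("positions and energies must be matched 1-D sequences")
        if q.size < 5:
            raise ValueError("profile needs at least 5 points")
        if not np.all(np.diff(q) > 0):
            raise ValueError("positions must be strictly increasing")
        if not (np.all(np.isfinite(q)) and np.all(np.isfinite(e))):
            raise ValueError("profile values must be finite")
        object.__setattr__(self, "positions", q)
        object.__setattr__(self, "energies", e)

    def __len__(self) -> int:
        return self.positions.size

    @classmethod
    def from_text(cls, path) -> "FreeEnergyProfile":
        data = np.loadtxt(path, comments="#")
        if data.ndim != 2 or data.shape[1] < 2:
            raise ValueError("profile file must have two columns: position, energy")
        return cls(data[:, 0], data[:, 1])

    def to_text(self, path, header: str = "position energy[k_BT]") -> None:
        np.savetxt(path, np.column_stack([self.positions, self.energies]),
                   header=header)


@dataclass(frozen=True)
class DoubleWellFit:
    """Result of fitting a double-well form to a tabulated profile.

    ``x_shift``/``e_shift`` translate profile coordinates into the fit frame
    (barrier top at 0, left-minimum energy at 0):
    ``x_fit = x_profile - x_shift``, ``e_fit = e_profile - e_shift``.
    """

    potential: DoubleWellPotential
    x_shift: float
    e_shift: float
    residual_norm: float
    minima: tuple[float, float]
    barrier: float
    n_points: int = 0
    extras: dict = field(default_factory=dict)


def _coarse_extrema(profile: FreeEnergyProfile):
    """Locate two well minima and the barrier between them.

    A light moving-average smoothing makes the topology check robust against
    small-amplitude noise; indices returned refer to the raw profile.
    """
    e = profile.energies
    n = e.size
    w = max(1, n // 30)
    if w > 1:
        kern = np.ones(w) / w
        es = np.convolve(e, kern, mode="same")
        # edges of 'same' convolution are biased; patch with raw values
        es[: w] = e[: w]
        es[-w:] = e[-w:]
    else:
        es = e
    interior = np.arange(1, n - 1)
    is_min = (es[interior] <= es[interior - 1]) & (es[interior] < es[interior + 1])
    mins = interior[is_min]
    # merge plateau-adjacent minima
    if mins.size:
        keep = [mins[0]]
        for i in mins[1:]:
            if i - keep[-1] > w:
                keep.append(i)
        mins = np.array(keep)
    if mins.size < 2:
        raise ProfileShapeError(
            "profile does not show two local minima separated by one maximum")
    # the two deepest minima
    order = np.argsort(es[mins])
    i1, i2 = sorted(mins[order[:2]])
    between = np.arange(i1 + 1, i2)
    if between.size == 0:
        raise ProfileShapeError("minima are adjacent; no barrier in between")
    ib = between[np.argmax(es[between])]
    if not (es[ib] > es[i1] and es[ib] > es[i2]):
        raise ProfileShapeError("no maximum separating the two minima")
    return i1, ib, i2


def fit_double_well(profile: FreeEnergyProfile) -> DoubleWellFit:
    """Least-squares fit of the asymmetric double-well form to a profile.

    The fit frame places the barrier top at x = 0 and the left-minimum
    energy at 0; the applied translation is reported in the result.  A
    trust-region nonlinear least-squares solve is initialized from the
    located extrema (minima positions -> L_L, L_R; energy differences ->
    U_L, U_R), which is near-exact for well-shaped profiles.
    """
    i1, ib, i2 = _coarse_extrema(profile)
    q, e = profile.positions, profile.energies
    x0_init = q[ib]
    ul_init = max(e[ib] - e[i1], 1e-6)
    ur_init = max(e[ib] - e[i2], 1e-6)
    ll_init = max(x0_init - q[i1], 1e-9)
    lr_init = max(q[i2] - x0_init, 1e-9)
    e0_init = e[i1]

    def model(theta, x):
        ul, ur, ll, lr, xb, e0 = theta
        xs = x - xb
        ql = (xs / ll) ** 2 - 1.0
        qr = (xs / lr) ** 2 - 1.0
        return np.where(xs <= 0.0, ul * ql * ql,
                        ur * qr * qr + (ul - ur)) + e0

    def resid(theta):
        return model(theta, q) - e

    theta0 = np.array([ul_init, ur_init, ll_init, lr_init, x0_init, e0_init])
    lo = [1e-12, 1e-12, 1e-12, 1e-12, q[i1], -np.inf]
    hi = [np.inf, np.inf, np.inf, np.inf, q[i2], np.inf]
    sol = least_squares(resid, theta0, bounds=(lo, hi), method="trf",
                        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    ul, ur, ll, lr, xb, e0 = sol.x
    pot = DoubleWellPotential(ul, ur, ll, lr)
    return DoubleWellFit(
        potential=pot,
        x_shift=float(xb),
        e_shift=float(e0),
        residual_norm=float(np.linalg.norm(sol.fun)),
        minima=(float(q[i1]), float(q[i2])),
        barrier=float(q[ib]),
        n_points=len(profile),
        extras={"success": bool(sol.success), "cost": float(sol.cost)},
    )


def sample_profile(p: DoubleWellPotential, n: int = 200,
                   span: float = 1.5) -> FreeEnergyProfile:
    """Sample a noise-free profile from a double-well potential.

    The grid spans ``[-span*L_L, +span*L_R]`` on ``n`` points.
    """
    x = np.linspace(-span * p.l_left, span * p.l_right, n)
    return FreeEnergyProfile(x, p.energy(x))
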