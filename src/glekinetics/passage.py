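"""First-passage extraction from trajectories.

Mean first-passage times are computed with the mean all-to-first-passage
convention: every crossing of the start coordinate opens a passage, and all
open passages close at the next arrival (first crossing) of the target
coordinate.  Passages sharing a closing target arrival form one *group*;
the groups are the effectively independent units, so standard errors are
obtained by block bootstrap over groups rather than by treating individual
passages as independent.

Crossings are located with sub-step linear interpolation between bracketing
samples.  A sample exactly on a level is treated as lying on the negative
side (consistent tie-break).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .engine import Trajectory
from .potential import DoubleWellPotential

__all__ = [
    "PassageEnsemble",
    "MFPTEstimate",
    "detect_crossings",
    "all_to_first_passage",
    "well_to_well_mfpt",
    "well_to_barrier_mfpt",
    "AllToFirstAccumulator",
    "MIN_RELIABLE_GROUPS",
]

MIN_RELIABLE_GROUPS = 100


class EmptyEnsembleError(RuntimeError):
    """No target arrival occurred; the run must be extended."""


@dataclass(frozen=True)
class MFPTEstimate:
    """Mean first-passage time with uncertainty.

    ``sem`` comes from a block bootstrap over target-arrival groups, which
    accounts for the serial correlation between passages that share a
    closing arrival.  Estimates with fewer than ``MIN_RELIABLE_GROUPS``
    groups are flagged via :attr:`reliable`.
    """

    mean: float
    sem: float
    n_events: int
    n_groups: int
    start: float = np.nan
    target: float = np.nan

    def __post_init__(self):
        if self.n_events >= 1 and not self.mean > 0:
            raise ValueError("mean passage time must be positive")
        if self.sem < 0:
            raise ValueError("sem must be >= 0")

    @property
    def reliable(self) -> bool:
        return self.n_groups >= MIN_RELIABLE_GROUPS


@dataclass
class PassageEnsemble:
    """All-to-first passages grouped by closing target arrival."""

    start_coordinate: float
    target_coordinate: float
    group_counts: np.ndarray  # passages per target arrival
    group_sums: np.ndarray    # summed durations per target arrival
    durations: np.ndarray | None = None  # individual durations, if retained

    def __post_init__(self):
        self.group_counts = np.asarray(self.group_counts, dtype=np.int64)
        self.group_sums = np.asarray(self.group_sums, dtype=float)
        if self.group_counts.shape != self.group_sums.shape:
            raise ValueError("group arrays must match")
        if np.any(self.group_sums < 0):
            raise ValueError("durations must be >= 0")

    @property
    def n_target_arrivals(self) -> int:
        return len(self.group_counts)

    @property
    def n_events(self) -> int:
        return int(self.group_counts.sum())

    @property
    def passage_durations(self) -> np.ndarray:
        if self.durations is None:
            raise AttributeError("individual durations were not retained")
        return self.durations

    def mean(self) -> float:
        n = self.n_events
        if n == 0:
            raise EmptyEnsembleError(
                "no passage closed by a target arrival; extend the run")
        return float(self.group_sums.sum() / n)

    def estimate(self, seed: int = 0, n_boot: int = 200,
                 n_blocks: int = 50) -> MFPTEstimate:
        """Mean and moving-block-bootstrap SEM over target-arrival groups.

        Consecutive groups are resampled in circular blocks of about
        ``n_groups / n_blocks`` groups each, so the error estimate stays
        honest when neighbouring groups are serially correlated (e.g. many
        barrier recrossings within one well sojourn at long memory times);
        with few groups this reduces to a plain bootstrap over groups.
        """
        mean = self.mean()
        g = self.n_target_arrivals
        if g < 2:
            sem = 0.0
        else:
            rng = np.random.default_rng(seed)
            blk = max(1, int(np.ceil(g / n_blocks)))
            nb = max(1, int(round(g / blk)))
            # circular block sums of counts and durations
            cnt2 = np.concatenate([self.group_counts, self.group_counts[:blk]])
            sum2 = np.concatenate([self.group_sums, self.group_sums[:blk]])
            ccnt = np.concatenate([[0], np.cumsum(cnt2)])
            csum = np.concatenate([[0.0], np.cumsum(sum2)])
            starts = rng.integers(0, g, size=(n_boot, nb))
            cnt = (ccnt[starts + blk] - ccnt[starts]).sum(axis=1)
            tot = (csum[starts + blk] - csum[starts]).sum(axis=1)
            ok = cnt > 0
            sem = float(np.std(tot[ok] / cnt[ok], ddof=1))
        return MFPTEstimate(mean=mean, sem=sem, n_events=self.n_events,
                            n_groups=g, start=self.start_coordinate,
                            target=self.target_coordinate)


# ---------------------------------------------------------------------------
# crossing detection

def _series(traj) -> tuple[np.ndarray, float, float]:
    if isinstance(traj, Trajectory):
        return traj.positions, traj.t0, traj.dt
    raise TypeError("expected a Trajectory")


def _crossings_from_arrays(x: np.ndarray, t0: float, dt: float, level: float,
                           direction: str = "both") -> np.ndarray:
    """Interpolated crossing times of ``level`` in a uniform series."""
    if len(x) == 0:
        raise ValueError("empty trajectory")
    s = x - level
    neg = s <= 0.0  # exact hits count as the negative side
    flip = neg[:-1] != neg[1:]
    if direction == "up":
        flip &= neg[:-1]
    elif direction == "down":
        flip &= ~neg[:-1]
    elif direction != "both":
        raise ValueError("direction must be 'up', 'down' or 'both'")
    idx = np.nonzero(flip)[0]
    if idx.size == 0:
        return np.empty(0)
    s0 = s[idx]
    s1 = s[idx + 1]
    frac = s0 / (s0 - s1)
    return t0 + dt * (idx + frac)


def detect_crossings(traj: Trajectory, level: float,
                     direction: Literal["up", "down", "both"] = "both"
                     ) -> np.ndarray:
    """Times at which the trajectory crosses ``level``.

    Sub-step times are refined by linear interpolation between the two
    bracketing samples.
    """
    x, t0, dt = _series(traj)
    return _crossings_from_arrays(x, t0, dt, level, direction)


# ---------------------------------------------------------------------------
# all-to-first passages

def _group(starts: np.ndarray, targets: np.ndarray,
           pending_cnt: int = 0, pending_sum: float = 0.0):
    """Group start visits by the next target arrival.

    Returns (counts, sums, leftover_cnt, leftover_sum) where leftovers are
    visits after the last target arrival.
    """
    if targets.size == 0:
        return (np.empty(0, np.int64), np.empty(0),
                pending_cnt + starts.size, pending_sum + float(starts.sum()))
    pos = np.searchsorted(starts, targets, side="right")
    cs = np.concatenate([[0.0], np.cumsum(starts)])
    counts = np.diff(np.concatenate([[0], pos])).astype(np.int64)
    sums = np.diff(np.concatenate([[0.0], cs[pos]]))
    counts[0] += pending_cnt
    sums[0] += pending_sum
    dur = counts * targets - sums  # sum_j (t_arrival - t_visit_j) per group
    keep = counts > 0
    left_cnt = int(starts.size - pos[-1])
    left_sum = float(cs[-1] - cs[pos[-1]])
    return counts[keep], dur[keep], left_cnt, left_sum


class AllToFirstAccumulator:
    """Streaming all-to-first passage statistics over position chunks.

    Feed consecutive undecimated chunks (with one overlapping sample handled
    internally); only per-group counts and duration sums are retained, so
    arbitrarily long runs use O(groups) memory.  Produces the same ensemble
    as :func:`all_to_first_passage` on the concatenated series.
    """

    def __init__(self, start: float, target: float):
        if start == target:
            raise ValueError("start and target must differ")
        self.start = start
        self.target = target
        self._counts: list[np.ndarray] = []
        self._sums: list[np.ndarray] = []
        self._pend_cnt = 0
        self._pend_sum = 0.0
        self._x_last: float | None = None
        self._t_next = 0.0
        self._dt = None

    def update(self, x_chunk: np.ndarray, t0: float, dt: float) -> None:
        if len(x_chunk) == 0:
            return
        self._dt = dt
        if self._x_last is None:
            x = x_chunk
            tt0 = t0
        else:
            x = np.concatenate([[self._x_last], x_chunk])
            tt0 = t0 - dt
        starts = _crossings_from_arrays(x, tt0, dt, self.start)
        targets = _crossings_from_arrays(x, tt0, dt, self.target)
        cnts, sums, self._pend_cnt, self._pend_sum = _group(
            starts, targets, self._pend_cnt, self._pend_sum)
        if cnts.size:
            self._counts.append(cnts)
            self._sums.append(sums)
        self._x_last = float(x_chunk[-1])
        self._t_next = t0 + dt * len(x_chunk)

    def to_ensemble(self) -> PassageEnsemble:
        counts = (np.concatenate(self._counts) if self._counts
                  else np.empty(0, np.int64))
        sums = np.concatenate(self._sums) if self._sums else np.empty(0)
        return PassageEnsemble(self.start, self.target, counts, sums)

    def estimate(self, seed: int = 0) -> MFPTEstimate:
        return self.to_ensemble().estimate(seed=seed)


def all_to_first_passage(traj: Trajectory, start: float,
                         target: float) -> PassageEnsemble:
    """All-to-first passage ensemble from a stored trajectory.

    Every crossing of ``start`` opens a passage that closes at the next
    crossing of ``target``; passages left open at the end of the run are
    discarded.  Individual durations are retained on the result.
    """
    if start == target:
        raise ValueError("start and target must differ")
    x, t0, dt = _series(traj)
    starts = _crossings_from_arrays(x, t0, dt, start)
    targets = _crossings_from_arrays(x, t0, dt, target)
    if targets.size == 0:
        raise EmptyEnsembleError("no target arrival in trajectory; extend the run")
    counts, sums, _, _ = _group(starts, targets)
    # individual durations for inspection (small trajectories)
    pos = np.searchsorted(starts, targets, side="right")
    durs = []
    prev = 0
    for j, tt in enumerate(targets):
        if pos[j] > prev:
            durs.append(tt - starts[prev:pos[j]])
            prev = pos[j]
    durations = np.concatenate(durs) if durs else np.empty(0)
    return PassageEnsemble(start, target, counts, sums, durations=durations)


def well_to_well_mfpt(traj: Trajectory, p: DoubleWellPotential,
                      seed: int = 0) -> tuple[MFPTEstimate, MFPTEstimate]:
    """MFPTs between the two well minima (left->right, right->left)."""
    lr = all_to_first_passage(traj, -p.l_left, p.l_right).estimate(seed=seed)
    rl = all_to_first_passage(traj, p.l_right, -p.l_left).estimate(seed=seed)
    return lr, rl


def well_to_barrier_mfpt(traj: Trajectory, p: DoubleWellPotential,
                         side: Literal["left", "right"],
                         seed: int = 0) -> MFPTEstimate:
    """MFPT from a well minimum to the barrier top at x = 0."""
    if side == "left":
        start = -p.l_left
    elif side == "right":
        start = p.l_right
    else:
        raise ValueError("side must be 'left' or 'right'")
    return all_to_first_passage(traj, start, p.barrier_top).estimate(seed=seed)
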