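"""Domain containers for elastic curve analysis.

A repetition of a wrist activity (arm curl, knock) is a scalar angular-velocity
curve beta(t) sampled on a uniform grid.  Time warps gamma are boundary-pinned
strictly increasing reparameterizations of the time axis; the square-root
velocity function (SRVF) q = sign(beta')*sqrt(|beta'|) turns elastic alignment
into an L2 problem.  These classes validate the invariants every downstream
stage relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "Trajectory",
    "WarpingFunction",
    "SrvfCurve",
    "AlignmentResult",
    "GridError",
    "DataError",
    "WarpError",
    "ACTIVITIES",
    "uniform_grid",
    "resample",
]

ACTIVITIES = ("curl", "knock", "other")

_GRID_RTOL = 1e-9
MIN_SAMPLES = 8


class GridError(ValueError):
    """Grid is non-uniform, too short, or mismatched between operands."""


class DataError(ValueError):
    """Sample values are non-finite or otherwise unusable."""


class WarpError(ValueError):
    """A warping function violates monotonicity or boundary pinning."""


def _as_float_array(x: Sequence[float] | np.ndarray) -> np.ndarray:
    return np.asarray(x, dtype=float)


def _check_uniform_grid(grid: np.ndarray) -> None:
    if grid.ndim != 1 or grid.size < MIN_SAMPLES:
        raise GridError(f"grid must be 1-D with >= {MIN_SAMPLES} samples, got shape {grid.shape}")
    d = np.diff(grid)
    if np.any(d <= 0):
        raise GridError("grid must be strictly increasing")
    span = grid[-1] - grid[0]
    if np.any(np.abs(d - d.mean()) > _GRID_RTOL * span):
        raise GridError("grid spacing is not uniform")


def uniform_grid(n: int, T: float = 1.0) -> np.ndarray:
    """Uniform grid of ``n`` samples on [0, T]."""
    return np.linspace(0.0, T, n)


@dataclass
class Trajectory:
    """One repetition of one activity: angular velocity (deg/s) on a uniform grid.

    Parameters
    ----------
    grid : array of sample times on [0, T], strictly increasing, uniform.
    values : angular-velocity samples, all finite, length >= 8.
    subject_id, visit, activity : provenance labels carried through the
        pipeline; ``visit`` is a 1-based integer.
    """

    grid: np.ndarray
    values: np.ndarray
    subject_id: str = ""
    visit: int = 1
    activity: str = "other"

    def __post_init__(self) -> None:
        self.grid = _as_float_array(self.grid)
        self.values = _as_float_array(self.values)
        _check_uniform_grid(self.grid)
        if self.values.shape != self.grid.shape:
            raise DataError("values and grid must have the same length")
        if not np.all(np.isfinite(self.values)):
            raise DataError("trajectory values must be finite")
        if self.activity not in ACTIVITIES:
            raise DataError(f"activity must be one of {ACTIVITIES}, got {self.activity!r}")
        if self.visit < 1:
            raise DataError("visit must be >= 1")

    @property
    def T(self) -> float:
        return float(self.grid[-1])

    @property
    def dt(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def with_values(self, values: np.ndarray) -> "Trajectory":
        return replace(self, values=np.asarray(values, dtype=float))


@dataclass
class WarpingFunction:
    """Boundary-pinned, strictly increasing reparameterization of [0, T].

    ``values[j]`` is gamma(grid[j]); gamma(0) = 0 and gamma(T) = T exactly
    (values within 1e-9 of the boundary are snapped).
    """

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.grid = _as_float_array(self.grid)
        self.values = _as_float_array(self.values).copy()
        _check_uniform_grid(self.grid)
        if self.values.shape != self.grid.shape:
            raise WarpError("warp values and grid must have the same length")
        T = self.grid[-1]
        if abs(self.values[0] - 0.0) > 1e-9 * max(T, 1.0) or abs(self.values[-1] - T) > 1e-9 * max(T, 1.0):
            raise WarpError("warp must satisfy gamma(0)=0 and gamma(T)=T")
        self.values[0] = 0.0
        self.values[-1] = T
        if np.any(np.diff(self.values) <= 0):
            raise WarpError("warp must be strictly increasing")

    @property
    def T(self) -> float:
        return float(self.grid[-1])

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.grid, self.values)

    def inverse(self) -> "WarpingFunction":
        """Inverse diffeomorphism by monotone interpolation."""
        inv = np.interp(self.grid, self.values, self.grid)
        inv[0], inv[-1] = 0.0, self.T
        inv = np.maximum.accumulate(inv)
        # interpolated inverse can locally flatten at float precision; nudge
        eps = 1e-12 * max(self.T, 1.0)
        for j in range(1, inv.size):
            if inv[j] <= inv[j - 1]:
                inv[j] = inv[j - 1] + eps
        inv[-1] = self.T
        return WarpingFunction(self.grid, inv)

    def compose(self, other: "WarpingFunction") -> "WarpingFunction":
        """self after other: (self o other)(t) = self(other(t))."""
        return WarpingFunction(self.grid, self(other.values))

    @classmethod
    def identity(cls, grid: np.ndarray) -> "WarpingFunction":
        grid = _as_float_array(grid)
        return cls(grid, grid.copy())


@dataclass
class SrvfCurve:
    """Square-root velocity representation q(t) of a trajectory.

    ``origin_value`` retains beta(0) so the SRVF map can be inverted.
    """

    grid: np.ndarray
    values: np.ndarray
    origin_value: float = 0.0

    def __post_init__(self) -> None:
        self.grid = _as_float_array(self.grid)
        self.values = _as_float_array(self.values)
        _check_uniform_grid(self.grid)
        if self.values.shape != self.grid.shape:
            raise DataError("values and grid must have the same length")
        if not np.all(np.isfinite(self.values)):
            raise DataError("SRVF values must be finite")
        self.origin_value = float(self.origin_value)

    @property
    def T(self) -> float:
        return float(self.grid[-1])

    @property
    def dt(self) -> float:
        return float(self.grid[1] - self.grid[0])


@dataclass
class AlignmentResult:
    """Outcome of elastically aligning curve 2 to curve 1.

    ``warp`` is the gamma applied to curve 2, ``distance`` the attained
    amplitude distance, ``aligned_curve`` the warped curve beta2 o gamma.
    """

    warp: WarpingFunction
    distance: float
    aligned_curve: Trajectory
    aligned_srvf: SrvfCurve = field(repr=False, default=None)  # type: ignore[assignment]
    dp_cost: float = 0.0  # raw lattice-optimal cost before warp refinement


def resample(grid: np.ndarray, values: np.ndarray, n: int, T: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Linearly resample ``values`` onto ``n`` uniform samples, rescaling time to [0, T]."""
    grid = _as_float_array(grid)
    values = _as_float_array(values)
    src = (grid - grid[0]) / (grid[-1] - grid[0])
    new_grid = np.linspace(0.0, 1.0, n)
    out = np.interp(new_grid, src, values)
    return new_grid * T, out
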