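"""Discretized time grids on which genealogies are encoded.

All genealogies in a study are encoded on one fixed grid of times
(generations before present).  The grid is approximately log-uniform:
spacing grows with age, so recent history — where sweep signal
concentrates — is resolved most finely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_K = 100
DEFAULT_T_MAX = 1e5
DEFAULT_CURVATURE = 1.0


@dataclass(frozen=True)
class TimeGrid:
    """Ordered grid of times in generations before present.

    Attributes
    ----------
    points : np.ndarray
        Strictly increasing times, ``points[0] == 0`` and
        ``points[-1] == t_max``.
    t_max : float
        Oldest grid time, generations.
    curvature : float
        Density parameter; larger values concentrate more points at
        recent times.
    """

    points: np.ndarray
    t_max: float
    curvature: float = field(default=DEFAULT_CURVATURE)

    @property
    def K(self) -> int:
        return len(self.points)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 1 or len(pts) < 2:
            raise ValueError("grid needs at least 2 points")
        if pts[0] != 0.0:
            raise ValueError("grid must start at time 0")
        if np.any(np.diff(pts) <= 0):
            raise ValueError("grid points must be strictly increasing")

    def __len__(self) -> int:
        return self.K


def build_time_grid(
    K: int = DEFAULT_K,
    t_max: float = DEFAULT_T_MAX,
    curvature: float = DEFAULT_CURVATURE,
) -> TimeGrid:
    """Build a log1p-uniform time grid.

    Points are ``t_j = (exp((j/(K-1)) * log(1 + c*t_max)) - 1) / c`` for
    ``j = 0..K-1``, i.e. uniform in ``log(1 + c*t)``.  Spacing is
    non-decreasing with ``j`` (finer discretization of recent times).

    Parameters
    ----------
    K : int
        Number of grid points (>= 2).  Default 100.
    t_max : float
        Oldest time in generations (> 0).
    curvature : float
        Positive density parameter ``c``; as ``c -> 0`` the grid tends to
        uniform spacing.
    """
    if not (isinstance(K, (int, np.integer)) and K >= 2):
        raise ValueError(f"K must be an integer >= 2, got {K!r}")
    if not (np.isfinite(t_max) and t_max > 0):
        raise ValueError(f"t_max must be finite and positive, got {t_max!r}")
    if not (np.isfinite(curvature) and curvature > 0):
        raise ValueError(f"curvature must be finite and positive, got {curvature!r}")
    j = np.arange(K, dtype=float) / (K - 1)
    pts = np.expm1(j * np.log1p(curvature * t_max)) / curvature
    pts[0] = 0.0
    pts[-1] = t_max
    return TimeGrid(points=pts, t_max=float(t_max), curvature=float(curvature))
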