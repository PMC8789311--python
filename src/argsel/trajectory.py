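"""Backward-in-time allele-frequency trajectories conditioned on origin.

The frequency path of the selected (derived) allele is simulated
backward from its present-day frequency ``f`` to its single-copy origin
as a per-generation Wright-Fisher process.  Going into the past the
allele is destined for loss, so each step uses the Wright-Fisher
binomial around the conditioned-on-loss drift of the genic-selection
diffusion,

    E[dx]/dt = -s x (1 - x) coth(2 N(t) s (1 - x)),

which follows from Doob h-transforming the diffusion with drift
``s x (1 - x)`` by its loss probability.  For ``s = 0`` the same formula
degenerates (via the fixation-probability limit) to the neutral
conditioned drift ``-x / (2N)``; for ``2Ns >> 1`` and ``x`` away from 1
it reduces to logistic decay at rate ``s``.

Soft (standing-variation) sweeps: selection acts only while the
frequency exceeds ``f_init``; once the backward path drops below
``f_init`` the allele drifts neutrally back to its origin.  The
generation of that switch is recorded as the selection onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from argsel.demography import DemographyModel, constant_size
from argsel.grid import TimeGrid

__all__ = ["Trajectory", "TrajectorySimulationError", "simulate_trajectory",
           "discretize_trajectory", "conditioned_drift"]


class TrajectorySimulationError(RuntimeError):
    """Conditioning failed after the configured number of attempts."""


@dataclass(frozen=True)
class Trajectory:
    """Per-generation allele frequency, present (index 0) back to origin.

    ``freqs[g]`` is the population frequency ``g`` generations before
    present; the final entry is the single-copy frequency ``1/(2N)`` at
    ``origin_generation = len(freqs) - 1``.  ``onset_generation`` is the
    generation at which selection began acting (equal to the origin for
    hard sweeps).
    """

    freqs: np.ndarray
    onset_generation: int

    @property
    def origin_generation(self) -> int:
        return len(self.freqs) - 1

    def at(self, t: float) -> float:
        """Frequency at time ``t`` (nearest generation; 0 beyond origin)."""
        g = int(round(t))
        if g >= len(self.freqs):
            return 0.0
        return float(self.freqs[g])


def conditioned_drift(x, s: float, N):
    """Per-generation conditioned-on-loss drift of the derived frequency."""
    x = np.asarray(x, dtype=float)
    N = np.asarray(N, dtype=float)
    if s == 0.0:
        return -x / (2.0 * N)
    arg = 2.0 * N * s * (1.0 - x)
    # coth(a) ~ 1/a + a/3 for small a; cap large a to avoid overflow
    safe = np.maximum(arg, 1e-12)
    coth = np.where(
        arg < 1e-4,
        1.0 / safe + safe / 3.0,
        1.0 / np.tanh(np.minimum(safe, 50.0)),
    )
    return -s * x * (1.0 - x) * coth


def simulate_trajectory(
    s: float,
    f: float,
    demography: Optional[DemographyModel] = None,
    mode: str = "hard",
    f_init: Optional[float] = None,
    rng: Optional[np.random.Generator] = None,
    max_generations: int = 2_000_000,
    max_attempts: int = 1_000,
) -> Trajectory:
    """Simulate a conditioned backward Wright-Fisher frequency path.

    Parameters
    ----------
    s : float
        Selection coefficient per generation (>= 0).
    f : float
        Present-day frequency of the derived allele, in (0, 1).
    demography : DemographyModel
        Size history; defaults to constant N = 10,000.
    mode : {"hard", "soft", "neutral"}
        ``hard``: selection from origin to present.  ``soft``: selection
        only above ``f_init``.  ``neutral``: no selection (equivalent to
        ``s = 0``).
    f_init : float
        Standing frequency at which selection began (soft mode only),
        with ``0 < f_init < f``.
    max_generations : int
        Per-attempt cap on trajectory length before the attempt is
        abandoned.
    max_attempts : int
        Rejection cap; exceeding it raises
        :class:`TrajectorySimulationError`.
    """
    if not (0.0 < f < 1.0):
        raise ValueError(f"f must be in (0, 1), got {f}")
    if s < 0:
        raise ValueError(f"s must be >= 0, got {s}")
    if mode not in ("hard", "soft", "neutral"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "soft":
        if f_init is None or not (0.0 < f_init < f):
            raise ValueError("soft mode requires 0 < f_init < f")
    if mode == "neutral":
        s = 0.0
    if demography is None:
        demography = constant_size(10_000)
    if rng is None:
        rng = np.random.default_rng()

    for _ in range(max_attempts):
        freqs = [f]
        x = f
        onset = None
        g = 0
        ok = False
        while g < max_generations:
            N = float(demography.size_at(g))
            two_n = max(int(round(2.0 * N)), 2)
            selected = s > 0 and (mode != "soft" or x >= f_init)
            if mode == "soft" and onset is None and x < f_init:
                onset = g
            s_eff = s if selected else 0.0
            drift = float(conditioned_drift(x, s_eff, N))
            p = min(max(x + drift, 0.0), 1.0)
            copies = rng.binomial(two_n, p)
            g += 1
            if copies <= 1:
                freqs.append(1.0 / two_n)
                ok = True
                break
            # the loss-conditioned path cannot fix
            copies = min(copies, two_n - 1)
            x = copies / two_n
            freqs.append(x)
        if ok:
            arr = np.asarray(freqs)
            onset_gen = len(arr) - 1 if (mode == "hard" and s > 0) else (
                onset if onset is not None else len(arr) - 1
            )
            if mode == "neutral" or s == 0.0:
                onset_gen = len(arr) - 1
            return Trajectory(freqs=arr, onset_generation=int(onset_gen))
    raise TrajectorySimulationError(
        f"no trajectory reached a single-copy origin within "
        f"{max_generations} generations in {max_attempts} attempts "
        f"(s={s}, f={f}, mode={mode})"
    )


def discretize_trajectory(traj: Trajectory, grid: TimeGrid) -> np.ndarray:
    """Per-grid-point frequency labels (nearest generation; 0 pre-origin)."""
    return np.array([traj.at(t) for t in grid.points])
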