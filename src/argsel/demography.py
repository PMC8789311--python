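"""Piecewise-exponential single-population size histories.

A :class:`DemographyModel` is an epoch table: each epoch starts at a time
(generations before present), has an initial diploid size at that start
time, and an exponential growth rate per generation (positive rate means
the population was growing forward in time, i.e. shrinks going into the
past within the epoch).  Three named builders ship with the package:

* ``constant_size(N)`` — the constant-N benchmark model;
* ``ceu_like()`` — a European-style history with an out-of-Africa
  bottleneck followed by two phases of exponential growth, following the
  published Tennessen et al. composite European model (values are the
  conventional ones from that literature; every entry is configurable);
* ``capuchino_like()`` — a piecewise-constant mapping of the southern
  capuchino seedeater history (derived Ne 130,000; ancestral size
  14,380,000 from 44,000 generations ago; root size 1,450,000 from
  1,850,000 generations ago).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Tuple

import numpy as np

__all__ = ["DemographyModel", "constant_size", "ceu_like", "capuchino_like"]


@dataclass(frozen=True)
class Epoch:
    start_time: float  # generations before present
    size: float  # diploid size at start_time
    growth_rate: float = 0.0  # per generation, forward-time convention


@dataclass(frozen=True)
class DemographyModel:
    epochs: Tuple[Epoch, ...]
    name: str = "custom"

    def __post_init__(self):
        eps = tuple(
            e if isinstance(e, Epoch) else Epoch(*e) for e in self.epochs
        )
        object.__setattr__(self, "epochs", eps)
        starts = [e.start_time for e in eps]
        if not eps or starts[0] != 0.0:
            raise ValueError("first epoch must start at time 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("epoch start times must be strictly increasing")
        if any(e.size <= 0 for e in eps):
            raise ValueError("all sizes must be positive")

    def size_at(self, t) -> np.ndarray:
        """Diploid size at time(s) ``t`` generations before present."""
        t = np.asarray(t, dtype=float)
        starts = np.array([e.start_time for e in self.epochs])
        sizes = np.array([e.size for e in self.epochs])
        rates = np.array([e.growth_rate for e in self.epochs])
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, None)
        dt = t - starts[idx]
        return sizes[idx] * np.exp(-rates[idx] * dt)

    def to_msprime(self):
        import msprime

        demo = msprime.Demography()
        e0 = self.epochs[0]
        demo.add_population(
            name="pop0", initial_size=e0.size, growth_rate=e0.growth_rate
        )
        for e in self.epochs[1:]:
            demo.add_population_parameters_change(
                time=e.start_time,
                initial_size=e.size,
                growth_rate=e.growth_rate,
                population="pop0",
            )
        return demo

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "epochs": [
                {"start_time": e.start_time, "size": e.size, "growth_rate": e.growth_rate}
                for e in self.epochs
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DemographyModel":
        return cls(
            epochs=tuple(
                Epoch(e["start_time"], e["size"], e.get("growth_rate", 0.0))
                for e in d["epochs"]
            ),
            name=d.get("name", "custom"),
        )


def constant_size(N: float = 10_000) -> DemographyModel:
    """Constant diploid size ``N``."""
    return DemographyModel(epochs=(Epoch(0.0, N),), name=f"constant-N{N:g}")


def ceu_like() -> DemographyModel:
    """European-style history (Tennessen-style composite, single deme).

    Backward in time: explosive recent growth (to ~512k diploids at
    present), a slower growth phase, the European founding bottleneck,
    the out-of-Africa bottleneck, the ancestral African expansion, and
    the deep ancestral size.
    """
    return DemographyModel(
        epochs=(
            Epoch(0.0, 512_000, growth_rate=0.0195),
            Epoch(205.0, 9_279, growth_rate=0.00307),
            Epoch(920.0, 1_032, growth_rate=0.0),
            Epoch(2_040.0, 1_861, growth_rate=0.0),
            Epoch(5_920.0, 14_474, growth_rate=0.0),
            Epoch(8_800.0, 7_310, growth_rate=0.0),
        ),
        name="CEU-like",
    )


def capuchino_like() -> DemographyModel:
    """Southern-capuchino-style history, as a piecewise-constant size path."""
    return DemographyModel(
        epochs=(
            Epoch(0.0, 130_000),
            Epoch(44_000.0, 14_380_000),
            Epoch(1_850_000.0, 1_450_000),
        ),
        name="capuchino-like",
    )
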