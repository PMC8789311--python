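"""Simulation of labeled training/test regions.

A :class:`SimulatedRegion` bundles what the downstream model consumes:
phased haplotypes, variant positions, the true local genealogies (as a
tskit tree sequence), the focal :class:`~argsel.trees.SiteLabel`, and
the truth record (selection parameters + frequency trajectory).

Neutral regions come from the ordinary coalescent with recombination
(msprime); sweep regions from the package's conditioned-trajectory
structured coalescent (:mod:`argsel.sweepsim`).  Neutral mutations are
placed on the realized genealogies under the infinite-sites model at
rate ``mu`` per bp per generation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import List, Optional, Tuple

import msprime
import numpy as np

from argsel.demography import DemographyModel, constant_size
from argsel.features import channel_names, extract_features
from argsel.grid import TimeGrid, build_time_grid
from argsel.sweepsim import simulate_ancestry_with_sweep
from argsel.trajectory import Trajectory, simulate_trajectory, discretize_trajectory
from argsel.trees import LocalTree, SiteLabel

__all__ = [
    "PriorSpec",
    "SweepParams",
    "SimulatedRegion",
    "NoMatchingSiteError",
    "sample_priors",
    "simulate_region",
    "pick_neutral_focal_site",
    "region_features",
    "make_dataset",
]


class NoMatchingSiteError(RuntimeError):
    """No segregating site within tolerance of the target frequency."""


@dataclass(frozen=True)
class PriorSpec:
    """Uniform prior ranges for the simulation parameters.

    Defaults follow the European-panel study conditions: ``s`` uniform on
    (0.0001, 0.02), present-day frequency ``f`` on (0.01, 0.99), and the
    mutation and recombination rates on (1.25e-8, 2.5e-8) per bp per
    generation.  The soft-sweep standing frequency ``f_init`` is uniform
    on (0.01, 0.05).
    """

    s_range: Tuple[float, float] = (1e-4, 0.02)
    f_range: Tuple[float, float] = (0.01, 0.99)
    mu_range: Tuple[float, float] = (1.25e-8, 2.5e-8)
    rho_range: Tuple[float, float] = (1.25e-8, 2.5e-8)
    f_init_range: Tuple[float, float] = (0.01, 0.05)
    mode: str = "hard"

    def __post_init__(self):
        for name in ("s_range", "f_range", "mu_range", "rho_range", "f_init_range"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"invalid {name}: ({lo}, {hi})")
        if self.mode not in ("neutral", "hard", "soft"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class SweepParams:
    """One draw of the simulation parameters."""

    mode: str
    s: float
    f: float
    mu: float
    rho: float
    f_init: Optional[float] = None
    onset_time: Optional[float] = None

    def __post_init__(self):
        if self.s < 0:
            raise ValueError("s must be >= 0")
        if not (0 < self.f < 1):
            raise ValueError("f must be in (0, 1)")
        if self.mu <= 0 or self.rho <= 0:
            raise ValueError("mu and rho must be positive")
        if self.mode == "soft" and not (
            self.f_init is not None and 0 < self.f_init < self.f
        ):
            raise ValueError("soft mode requires 0 < f_init < f")


def sample_priors(config: PriorSpec, rng: np.random.Generator) -> SweepParams:
    """Draw independent uniform parameters from the configured ranges."""
    u = lambda r: float(rng.uniform(*r))
    mode = config.mode
    f = u(config.f_range)
    f_init = None
    if mode == "soft":
        f_init = min(u(config.f_init_range), 0.5 * f)
    return SweepParams(
        mode=mode,
        s=0.0 if mode == "neutral" else u(config.s_range),
        f=f,
        mu=u(config.mu_range),
        rho=u(config.rho_range),
        f_init=f_init,
    )


@dataclass
class SimulatedRegion:
    """Haplotypes + true genealogies + truth labels for one region."""

    ts: object  # tskit.TreeSequence
    haplotypes: np.ndarray  # n x S, 0 ancestral / 1 derived
    positions: np.ndarray  # S bp coordinates in [0, L)
    L: float
    focal_site: Optional[SiteLabel]
    params: SweepParams
    trajectory: Optional[Trajectory]
    seed: Optional[int] = None

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def is_sweep(self) -> bool:
        return self.params.mode != "neutral" and self.params.s > 0

    def local_trees(self) -> List[LocalTree]:
        return [LocalTree.from_tskit(t) for t in self.ts.trees()]

    def focal_tree_index(self) -> int:
        pos = self.focal_site.position
        for i, tree in enumerate(self.ts.trees()):
            if tree.interval.left <= pos < tree.interval.right:
                return i
        raise ValueError("focal site not covered by any tree")

    def daf(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)


def _site_label_from_matrix(haplotypes, positions, idx) -> SiteLabel:
    carriers = frozenset(np.flatnonzero(haplotypes[:, idx]).tolist())
    return SiteLabel(position=float(positions[idx]), carriers=carriers)


def simulate_region(
    params: SweepParams,
    demography: Optional[DemographyModel] = None,
    L: float = 1e5,
    n: int = 198,
    rng: Optional[np.random.Generator] = None,
) -> SimulatedRegion:
    """Simulate one region of ``n`` haplotypes over ``[0, L)``.

    Sweep/soft modes place the selected site at ``L/2`` with the number
    of derived sample haplotypes binomial in the population frequency
    ``f`` (clamped to keep the site polymorphic).  Neutral regions have
    no focal site until :func:`pick_neutral_focal_site` assigns one.
    """
    if rng is None:
        rng = np.random.default_rng()
    if demography is None:
        demography = constant_size(10_000)
    if n < 2 or L <= 0:
        raise ValueError("need n >= 2 and L > 0")
    seed = int(rng.integers(1, 2**31 - 1))

    if params.mode == "neutral" or params.s == 0.0:
        ts = msprime.sim_ancestry(
            samples=[msprime.SampleSet(n, ploidy=1)],
            ploidy=2,  # sizes are diploid; coalescence rate 1/(2N)
            sequence_length=L,
            recombination_rate=params.rho,
            demography=demography.to_msprime(),
            discrete_genome=False,
            random_seed=seed,
        )
        trajectory = None
        params = SweepParams(
            mode="neutral", s=0.0, f=params.f, mu=params.mu, rho=params.rho
        )
    else:
        trajectory = simulate_trajectory(
            s=params.s,
            f=params.f,
            demography=demography,
            mode=params.mode,
            f_init=params.f_init,
            rng=rng,
        )
        params = SweepParams(
            mode=params.mode,
            s=params.s,
            f=params.f,
            mu=params.mu,
            rho=params.rho,
            f_init=params.f_init,
            onset_time=float(trajectory.onset_generation),
        )
        d = int(np.clip(rng.binomial(n, params.f), 1, n - 1))
        ts = simulate_ancestry_with_sweep(
            n=n,
            L=L,
            recomb_rate=params.rho,
            demography=demography,
            trajectory=trajectory,
            n_derived=d,
            focal_position=L / 2.0,
            rng=rng,
        )

    mts = msprime.sim_mutations(
        ts,
        rate=params.mu,
        model=msprime.BinaryMutationModel(),
        discrete_genome=False,
        keep=True,
        random_seed=seed,
    )
    haplotypes = np.ascontiguousarray(mts.genotype_matrix().T.astype(np.int8))
    positions = np.array([s.position for s in mts.sites()])

    focal = None
    if trajectory is not None:
        focal_idx = int(np.argmin(np.abs(positions - L / 2.0)))
        if positions[focal_idx] != L / 2.0:
            raise RuntimeError("focal site missing from mutated tree sequence")
        focal = _site_label_from_matrix(haplotypes, positions, focal_idx)

    return SimulatedRegion(
        ts=mts,
        haplotypes=haplotypes,
        positions=positions,
        L=L,
        focal_site=focal,
        params=params,
        trajectory=trajectory,
        seed=seed,
    )


def pick_neutral_focal_site(
    region: SimulatedRegion,
    target_daf: float,
    tolerance: float = 0.02,
    rng: Optional[np.random.Generator] = None,
) -> SiteLabel:
    """Uniform choice among segregating sites with DAF near ``target_daf``.

    Raises :class:`NoMatchingSiteError` when no site qualifies (the
    caller is expected to resimulate).
    """
    if region.is_sweep:
        raise ValueError("neutral focal sites are drawn on neutral regions only")
    if rng is None:
        rng = np.random.default_rng()
    daf = region.daf()
    ok = np.flatnonzero(
        (np.abs(daf - target_daf) <= tolerance) & (daf > 0) & (daf < 1)
    )
    if len(ok) == 0:
        raise NoMatchingSiteError(
            f"no segregating site within {tolerance} of DAF {target_daf}"
        )
    idx = int(rng.choice(ok))
    return _site_label_from_matrix(region.haplotypes, region.positions, idx)


def region_features(
    region: SimulatedRegion,
    grid: TimeGrid,
    focal_site: Optional[SiteLabel] = None,
    n_flank_per_side: int = 2,
    normalize: bool = True,
):
    """Extract the lineage-count feature matrix at the region's focal site."""
    site = focal_site if focal_site is not None else region.focal_site
    if site is None:
        raise ValueError("region has no focal site; pass one explicitly")
    trees = region.local_trees()
    focal_idx = None
    for i, tr in enumerate(trees):
        if tr.interval[0] <= site.position < tr.interval[1]:
            focal_idx = i
            break
    if focal_idx is None:
        raise ValueError("site position not covered by the region's trees")
    return extract_features(
        trees,
        focal_idx,
        site,
        grid,
        n_flank_per_side=n_flank_per_side,
        normalize=normalize,
    )


def make_dataset(
    out,
    n_neutral: int,
    n_sweep: int,
    prior: Optional[PriorSpec] = None,
    demography: Optional[DemographyModel] = None,
    L: float = 1e5,
    n: int = 198,
    grid: Optional[TimeGrid] = None,
    n_flank_per_side: int = 2,
    seed: int = 0,
    neutral_daf_tolerance: float = 0.02,
    max_retries: int = 50,
):
    """Simulate a labeled feature dataset and write it to HDF5.

    Neutral records use a DAF-matched focal site: the target frequency is
    drawn from the sweep ``f`` prior and a qualifying segregating site is
    chosen uniformly; regions with no qualifying site are resimulated (up
    to ``max_retries`` per record).

    Returns the in-memory record dict that was written (see
    :func:`argsel.io.save_feature_dataset` for the layout).
    """
    from argsel.io import save_feature_dataset

    if prior is None:
        prior = PriorSpec()
    if demography is None:
        demography = constant_size(10_000)
    if grid is None:
        grid = build_time_grid()
    master = np.random.SeedSequence(seed)
    child_seeds = master.generate_state(n_neutral + n_sweep).astype(np.uint32)

    K = grid.K
    C = 2 + 2 * n_flank_per_side
    N_tot = n_neutral + n_sweep
    feats = np.zeros((N_tot, K, C), dtype=np.float32)
    labels = {
        "is_sweep": np.zeros(N_tot, dtype=np.int8),
        "s": np.zeros(N_tot),
        "f": np.zeros(N_tot),
        "daf": np.zeros(N_tot),
        "onset": np.full(N_tot, np.nan),
        "trajectory": np.zeros((N_tot, K), dtype=np.float32),
        "seed": np.asarray(child_seeds, dtype=np.int64),
    }

    for i in range(N_tot):
        rng = np.random.default_rng(int(child_seeds[i]))
        sweep = i >= n_neutral
        for attempt in range(max_retries):
            params = sample_priors(prior, rng)
            if not sweep:
                params = SweepParams(
                    mode="neutral", s=0.0, f=params.f, mu=params.mu, rho=params.rho
                )
            try:
                region = simulate_region(params, demography, L=L, n=n, rng=rng)
                if sweep:
                    site = region.focal_site
                else:
                    site = pick_neutral_focal_site(
                        region, params.f, tolerance=neutral_daf_tolerance, rng=rng
                    )
                fv = region_features(
                    region, grid, focal_site=site, n_flank_per_side=n_flank_per_side
                )
                break
            except NoMatchingSiteError:
                if attempt == max_retries - 1:
                    raise
        feats[i] = fv.matrix
        labels["is_sweep"][i] = int(sweep)
        labels["s"][i] = region.params.s
        labels["f"][i] = region.params.f
        labels["daf"][i] = site.daf(n)
        if region.trajectory is not None:
            labels["onset"][i] = region.params.onset_time
            labels["trajectory"][i] = discretize_trajectory(region.trajectory, grid)

    meta = {
        "prior": asdict(prior),
        "demography": demography.to_dict(),
        "L": L,
        "n": n,
        "seed": seed,
        "n_neutral": n_neutral,
        "n_sweep": n_sweep,
        "n_flank_per_side": n_flank_per_side,
        "grid": {"K": grid.K, "t_max": grid.t_max, "curvature": grid.curvature},
        "channel_order": list(channel_names(n_flank_per_side)),
        "normalized": True,
    }
    data = {"features": feats, "labels": labels, "grid": grid.points, "metadata": meta}
    if out is not None:
        save_feature_dataset(out, data)
    return data
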