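"""Desk-scale reference experiments.

The full-scale study behind this package trains on a million simulated
100-kb regions; that is far beyond a single workstation.  This module
fixes a scaled-down experimental design — a constant-N(e) = 10,000
population, 32 haplotypes, 50-kb regions, true genealogies, selection
coefficients uniform on (0, 0.02) — whose corpus sizes and network width
are chosen so the whole pipeline (simulate, encode, train, evaluate)
runs on one CPU in minutes while preserving the qualitative behaviour of
the method.  Both the test suite and ``scripts/acceptance.py`` call
these functions, so the reported numbers always come from a fresh run of
the package itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np

from argsel.demography import constant_size
from argsel.grid import TimeGrid, build_time_grid
from argsel.nn.model import NetConfig, SiaModel, predict, predict_with_dropout, train
from argsel.regions import (
    NoMatchingSiteError,
    PriorSpec,
    SweepParams,
    pick_neutral_focal_site,
    region_features,
    sample_priors,
    simulate_region,
)
from argsel.trajectory import discretize_trajectory, simulate_trajectory

__all__ = [
    "ScaledDesign",
    "build_sweep_set",
    "build_neutral_set",
    "run_regression_experiment",
    "run_classification_experiment",
    "trajectory_sojourn",
    "martingale_increments",
    "neutral_coalescent_calibration",
    "interval_width_vs_rate",
]


@dataclass(frozen=True)
class ScaledDesign:
    """Problem sizes of the scaled-down benchmark."""

    n: int = 32
    L: float = 5e4
    N: float = 10_000
    s_range: tuple = (0.0, 0.02)
    f_range: tuple = (0.05, 0.95)
    n_train_sweep: int = 800
    n_train_neutral: int = 400
    n_test_sweep: int = 300
    n_test_neutral: int = 150
    n_per_stratum: int = 80
    units: int = 32
    n_stacks: int = 2
    max_epochs: int = 30
    patience: int = 4
    grid_K: int = 100
    grid_t_max: float = 1e5

    def grid(self) -> TimeGrid:
        return build_time_grid(K=self.grid_K, t_max=self.grid_t_max)

    def prior(self) -> PriorSpec:
        return PriorSpec(s_range=self.s_range, f_range=self.f_range, mode="hard")


def build_sweep_set(
    design: ScaledDesign,
    n_regions: int,
    rng: np.random.Generator,
    s_fixed: Optional[float] = None,
    f_range: Optional[tuple] = None,
    min_daf: float = 0.0,
    max_tries: int = 30,
):
    """Simulate sweep regions and encode their focal sites.

    Returns (features (N,K,C), s, daf, trajectory labels (N,K)).
    ``s_fixed`` pins the selection coefficient (for stratified test
    sets); ``min_daf`` rejects regions whose sampled focal DAF falls
    below the stratum floor.
    """
    demog = constant_size(design.N)
    grid = design.grid()
    prior = design.prior()
    X, s_out, daf, traj = [], [], [], []
    for _ in range(n_regions):
        for attempt in range(max_tries):
            p = sample_priors(prior, rng)
            if f_range is not None:
                p = SweepParams(mode="hard", s=p.s, f=float(rng.uniform(*f_range)),
                                mu=p.mu, rho=p.rho)
            if s_fixed is not None:
                p = SweepParams(mode="hard", s=s_fixed, f=p.f, mu=p.mu, rho=p.rho)
            region = simulate_region(p, demog, L=design.L, n=design.n, rng=rng)
            d = region.focal_site.daf(design.n)
            if d >= min_daf:
                break
        fv = region_features(region, grid)
        X.append(fv.matrix)
        s_out.append(region.params.s)
        daf.append(d)
        traj.append(discretize_trajectory(region.trajectory, grid))
    return (np.asarray(X), np.asarray(s_out), np.asarray(daf), np.asarray(traj))


def build_neutral_set(
    design: ScaledDesign,
    n_regions: int,
    rng: np.random.Generator,
    target_daf_range: Optional[tuple] = None,
    tolerance: float = 0.02,
    max_tries: int = 50,
):
    """Simulate neutral regions with DAF-matched focal sites.

    The target DAF of each region is drawn from the sweep ``f`` prior
    (or ``target_daf_range``), so neutral and sweep focal sites share
    the same frequency distribution and the classifier cannot key on
    frequency alone.  Returns (features, daf).
    """
    demog = constant_size(design.N)
    grid = design.grid()
    lo, hi = target_daf_range if target_daf_range else design.f_range
    X, daf = [], []
    for _ in range(n_regions):
        target = float(rng.uniform(lo, hi))
        site = None
        for _ in range(max_tries):
            p = SweepParams(mode="neutral", s=0.0, f=target,
                            mu=float(rng.uniform(1.25e-8, 2.5e-8)),
                            rho=float(rng.uniform(1.25e-8, 2.5e-8)))
            region = simulate_region(p, demog, L=design.L, n=design.n, rng=rng)
            try:
                site = pick_neutral_focal_site(region, target, tolerance, rng)
                break
            except NoMatchingSiteError:
                continue
        if site is None:
            raise NoMatchingSiteError(
                f"no neutral focal site near DAF {target} after {max_tries} tries"
            )
        fv = region_features(region, grid, focal_site=site)
        X.append(fv.matrix)
        daf.append(site.daf(design.n))
    return np.asarray(X), np.asarray(daf)


def _net_config(design: ScaledDesign, task: str, seed: int) -> NetConfig:
    return NetConfig(
        task=task,
        n_stacks=design.n_stacks,
        units_per_stack=design.units,
        dropout_rate=0.2,
        max_epochs=design.max_epochs,
        patience=design.patience,
        seed=seed,
    )


def run_regression_experiment(
    design: ScaledDesign,
    seed: int,
    train_X: Optional[np.ndarray] = None,
    train_s: Optional[np.ndarray] = None,
    include_trajectory: bool = False,
    train_traj: Optional[np.ndarray] = None,
) -> Dict:
    """Train the s-regressor and measure parameter recovery.

    Returns Spearman correlation between true and predicted s on
    held-out sweeps, the median predicted s on neutral regions, and
    rmse/mae/r2 on the sweep test set.  With ``include_trajectory`` a
    many-to-many model is trained on the same corpus and the Pearson
    correlation of its present-day frequency output against the true
    focal DAF is added.
    """
    from scipy.stats import pearsonr, spearmanr

    from argsel.evalmetrics import regression_metrics

    rng = np.random.default_rng(seed)
    if train_X is None:
        train_X, train_s, _, train_traj = build_sweep_set(
            design, design.n_train_sweep, rng
        )
    test_X, test_s, test_daf, _ = build_sweep_set(design, design.n_test_sweep, rng)
    neut_X, _ = build_neutral_set(design, design.n_test_neutral, rng)

    model = train({"X": train_X, "y": train_s},
                  _net_config(design, "regress_s", seed))
    pred_s = np.array([predict(model, x).s_hat for x in test_X])
    pred_neut = np.array([predict(model, x).s_hat for x in neut_X])
    out = {
        "model": model,
        "spearman_s": float(spearmanr(test_s, pred_s).statistic),
        "median_neutral_s": float(np.median(pred_neut)),
        **regression_metrics(test_s, pred_s),
        "test_s": test_s,
        "pred_s": pred_s,
        "test_daf": test_daf,
    }
    if include_trajectory:
        tmodel = train({"X": train_X, "y": train_traj},
                       _net_config(design, "trajectory", seed + 1))
        pred_now = np.array([predict(tmodel, x).traj_hat[0] for x in test_X])
        out["trajectory_present_af_pearson"] = float(
            pearsonr(test_daf, pred_now).statistic
        )
        out["trajectory_model"] = tmodel
    return out


def run_classification_experiment(
    design: ScaledDesign,
    seed: int,
    train_sweep_X: Optional[np.ndarray] = None,
    train_neutral_X: Optional[np.ndarray] = None,
    s_trend: Sequence[float] = (0.001, 0.005, 0.01),
    stratum_f_range: tuple = (0.7, 0.95),
) -> Dict:
    """Train the sweep classifier and measure stratified power.

    The classifier is trained on the scaled corpus (sweeps vs.
    DAF-matched neutrals) and evaluated against high-frequency test
    strata: a strong-sweep stratum (s uniform on (0.0075, 0.02), focal
    DAF >= 0.7) and fixed-s strata along ``s_trend`` at the same
    frequencies, each scored against DAF-matched neutral regions.
    """
    from argsel.evalmetrics import roc_auroc

    rng = np.random.default_rng(seed)
    if train_sweep_X is None:
        train_sweep_X, _, _, _ = build_sweep_set(design, design.n_train_sweep, rng)
    if train_neutral_X is None:
        train_neutral_X, _ = build_neutral_set(design, design.n_train_neutral, rng)
    X = np.concatenate([train_neutral_X, train_sweep_X])
    y = np.r_[np.zeros(len(train_neutral_X)), np.ones(len(train_sweep_X))]
    model = train({"X": X, "y": y}, _net_config(design, "classify", seed))

    n_per = design.n_per_stratum
    neut_X, _ = build_neutral_set(
        design, n_per, rng, target_daf_range=stratum_f_range
    )
    neut_scores = np.array([predict(model, x).class_prob for x in neut_X])

    def stratum_auroc(sweep_X):
        scores = np.r_[
            neut_scores, [predict(model, x).class_prob for x in sweep_X]
        ]
        labels = np.r_[np.zeros(len(neut_X)), np.ones(len(sweep_X))]
        return roc_auroc(scores, labels)[2]

    from dataclasses import replace

    strong_X, _, _, _ = build_sweep_set(
        replace(design, s_range=(0.0075, 0.02)),
        n_per, rng, f_range=stratum_f_range, min_daf=0.7,
    )
    auroc_strong = stratum_auroc(strong_X)
    auroc_by_s = {}
    for s in s_trend:
        sx, _, _, _ = build_sweep_set(
            design, n_per, rng, s_fixed=s, f_range=stratum_f_range, min_daf=0.7
        )
        auroc_by_s[s] = stratum_auroc(sx)
    return {
        "model": model,
        "auroc_strong": float(auroc_strong),
        "auroc_by_s": {k: float(v) for k, v in auroc_by_s.items()},
    }


def trajectory_sojourn(
    s: float = 0.05,
    N: float = 10_000,
    x_hi: float = 0.95,
    x_lo: float = 0.05,
    n_replicates: int = 500,
    seed: int = 0,
):
    """Mean backward sojourn time from ``x_hi`` down to ``x_lo``.

    Compared against the deterministic logistic duration
    ``ln[(x_hi/(1-x_hi)) * ((1-x_lo)/x_lo)] / s``.  Returns
    (mean, standard error, deterministic duration).
    """
    rng = np.random.default_rng(seed)
    demog = constant_size(N)
    times = []
    for _ in range(n_replicates):
        traj = simulate_trajectory(s=s, f=x_hi, demography=demog, rng=rng)
        below = np.flatnonzero(traj.freqs <= x_lo)
        times.append(int(below[0]))
    times = np.asarray(times, dtype=float)
    t_det = float(
        np.log((x_hi / (1 - x_hi)) * ((1 - x_lo) / x_lo)) / s
    )
    return float(times.mean()), float(times.std(ddof=1) / np.sqrt(len(times))), t_det


def martingale_increments(
    N: float = 10_000,
    f: float = 0.5,
    min_transitions: int = 10_000,
    seed: int = 0,
):
    """Pooled per-generation increments of neutral conditioned paths.

    Returns (mean increment, standard error of the mean, n).  Under
    neutrality the unconditioned frequency process is a martingale; the
    loss-conditioning adds only an O(1/2N) drift, so the pooled mean
    should vanish at that scale.
    """
    rng = np.random.default_rng(seed)
    demog = constant_size(N)
    incs = []
    while len(incs) < min_transitions:
        traj = simulate_trajectory(s=0.0, f=f, demography=demog, mode="neutral",
                                   rng=rng)
        incs.extend(np.diff(traj.freqs).tolist())
    incs = np.asarray(incs)
    return float(incs.mean()), float(incs.std(ddof=1) / np.sqrt(len(incs))), len(incs)


def neutral_coalescent_calibration(
    n: int = 32,
    N: float = 10_000,
    L: float = 2e4,
    mu: float = 1.5e-8,
    rho: float = 1.25e-8,
    n_replicates: int = 2_000,
    seed: int = 0,
):
    """Mean central-tree TMRCA and per-bp diversity of neutral replicates.

    Expected values: E[TMRCA] = 4N(1 - 1/n) generations and
    E[pi] = theta = 4*N*mu per bp.
    """
    rng = np.random.default_rng(seed)
    demog = constant_size(N)
    p = SweepParams(mode="neutral", s=0.0, f=0.5, mu=mu, rho=rho)
    tmrcas, pis = [], []
    for _ in range(n_replicates):
        region = simulate_region(p, demog, L=L, n=n, rng=rng)
        tree = region.ts.at(L / 2)
        tmrcas.append(tree.time(tree.root))
        pis.append(region.ts.diversity())
    tmrcas = np.asarray(tmrcas)
    pis = np.asarray(pis)
    return {
        "tmrca_mean": float(tmrcas.mean()),
        "tmrca_se": float(tmrcas.std(ddof=1) / np.sqrt(n_replicates)),
        "tmrca_expected": 4.0 * N * (1.0 - 1.0 / n),
        "pi_mean": float(pis.mean()),
        "pi_se": float(pis.std(ddof=1) / np.sqrt(n_replicates)),
        "pi_expected": 4.0 * N * mu,
    }


def interval_width_vs_rate(
    model: SiaModel,
    fv,
    rates: Sequence[float] = (0.0, 0.1, 0.3, 0.5),
    n_samples: int = 50,
    n_repeats: int = 20,
    seed: int = 0,
) -> Dict[float, float]:
    """Mean MC-dropout interval width at several dropout rates.

    The trained weights are shared; only the inference-time dropout rate
    changes.  Widths are averaged over ``n_repeats`` resamplings on the
    fixed input.
    """
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    widths = {}
    for rate in rates:
        clone = SiaModel(replace(model.config, dropout_rate=rate),
                         model.n_channels, model.K)
        for p, q in zip(clone.parameters(), model.parameters()):
            p[...] = q
        ws = []
        for _ in range(n_repeats):
            pred = predict_with_dropout(clone, fv, n_samples=n_samples, rng=rng)
            ws.append(float(pred.ci[1] - pred.ci[0]))
        widths[rate] = float(np.mean(ws))
    return widths
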