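import numpy as np
import pytest

from argsel.demography import DemographyModel, capuchino_like, ceu_like, constant_size
from argsel.regions import (
    NoMatchingSiteError,
    PriorSpec,
    SweepParams,
    make_dataset,
    pick_neutral_focal_site,
    sample_priors,
    simulate_region,
)
from argsel.sweepsim import simulate_ancestry_with_sweep
from argsel.trajectory import simulate_trajectory


class TestDemography:
    def test_constant_size_lookup(self):
        d = constant_size(5_000)
        assert np.all(d.size_at([0, 100, 1e6]) == 5_000)

    def test_piecewise_epochs_and_growth(self):
        d = DemographyModel(epochs=((0.0, 1_000, np.log(2) / 100), (100.0, 4_000)))
        assert d.size_at(0) == pytest.approx(1_000)
        assert d.size_at(100 - 1e-9) == pytest.approx(500, rel=1e-3)
        assert d.size_at(150) == 4_000

    def test_named_models_validate(self):
        for model in (ceu_like(), capuchino_like()):
            assert model.size_at(0) > 0
            assert model.epochs[0].start_time == 0.0

    def test_invalid_epoch_tables_rejected(self):
        with pytest.raises(ValueError):
            DemographyModel(epochs=((5.0, 100),))
        with pytest.raises(ValueError):
            DemographyModel(epochs=((0.0, 100), (0.0, 200)))

    def test_roundtrip_dict(self):
        d = ceu_like()
        assert DemographyModel.from_dict(d.to_dict()) == d


class TestPriors:
    def test_draws_stay_in_configured_ranges(self):
        rng = np.random.default_rng(0)
        spec = PriorSpec()
        for _ in range(200):
            p = sample_priors(spec, rng)
            assert 1e-4 <= p.s <= 0.02
            assert 0.01 <= p.f <= 0.99
            assert 1.25e-8 <= p.mu <= 2.5e-8

    def test_same_seed_gives_identical_draws(self):
        spec = PriorSpec(mode="soft")
        a = sample_priors(spec, np.random.default_rng(3))
        b = sample_priors(spec, np.random.default_rng(3))
        assert a == b

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(s_range=(0.02, 0.001))


class TestSweepEngineNeutralLimit:
    """The structured-coalescent engine, run without a sweep, must match
    closed-form neutral coalescent expectations."""

    def test_mean_tmrca_matches_coalescent_expectation(self):
        rng = np.random.default_rng(1)
        n, N = 8, 5_000
        tm = []
        for _ in range(150):
            ts = simulate_ancestry_with_sweep(
                n=n, L=1e3, recomb_rate=1e-9,
                demography=constant_size(N), rng=rng,
            )
            tree = ts.first()
            tm.append(tree.time(tree.root))
        expected = 4 * N * (1 - 1 / n)
        se = np.std(tm, ddof=1) / np.sqrt(len(tm))
        assert abs(np.mean(tm) - expected) < 4 * se

    def test_trees_are_binary_and_fully_coalesced(self):
        rng = np.random.default_rng(2)
        ts = simulate_ancestry_with_sweep(
            n=12, L=2e4, recomb_rate=1e-8,
            demography=constant_size(5_000), rng=rng,
        )
        for tree in ts.trees():
            assert tree.num_roots == 1
            for u in tree.nodes():
                assert tree.num_children(u) in (0, 2)


class TestSweepEngineSweepMode:
    def test_focal_site_carriers_match_requested_count(self):
        rng = np.random.default_rng(3)
        traj = simulate_trajectory(0.02, 0.7, constant_size(5_000), rng=rng)
        ts = simulate_ancestry_with_sweep(
            n=20, L=1e4, recomb_rate=1e-8, demography=constant_size(5_000),
            trajectory=traj, n_derived=14, focal_position=5e3, rng=rng,
        )
        assert ts.num_sites == 1
        var = next(ts.variants())
        assert var.genotypes.sum() == 14

    def test_derived_carriers_coalesce_faster_than_neutral(self):
        """Sweep footprint: derived-class TMRCA shrinks under selection."""
        rng = np.random.default_rng(4)
        N = 5_000
        demog = constant_size(N)
        sweep_t, neut_t = [], []
        for _ in range(40):
            traj = simulate_trajectory(0.01, 0.95, demog, rng=rng)
            ts = simulate_ancestry_with_sweep(
                n=16, L=5e3, recomb_rate=1e-8, demography=demog,
                trajectory=traj, n_derived=15, focal_position=2.5e3, rng=rng,
            )
            tree = ts.at(2.5e3)
            var = next(ts.variants())
            der = np.flatnonzero(var.genotypes == 1)[:2]
            sweep_t.append(tree.tmrca(int(der[0]), int(der[1])))
            neut_t.append(2 * N)  # E[pairwise TMRCA] = 2N generations
        assert np.mean(sweep_t) < 0.5 * np.mean(neut_t)

    def test_focal_mutation_age_matches_trajectory_origin(self):
        rng = np.random.default_rng(5)
        demog = constant_size(5_000)
        traj = simulate_trajectory(0.02, 0.6, demog, rng=rng)
        ts = simulate_ancestry_with_sweep(
            n=10, L=1e4, recomb_rate=1e-8, demography=demog,
            trajectory=traj, n_derived=6, focal_position=5e3, rng=rng,
        )
        mut = ts.mutation(0)
        assert mut.time == pytest.approx(traj.origin_generation, abs=2.0)


class TestSimulateRegion:
    def test_neutral_diversity_matches_theta(self):
        rng = np.random.default_rng(6)
        N, mu = 10_000, 1.5e-8
        p = SweepParams(mode="neutral", s=0.0, f=0.5, mu=mu, rho=1.25e-8)
        pis = [
            simulate_region(p, constant_size(N), L=2e4, n=16, rng=rng).ts.diversity()
            for _ in range(300)
        ]
        theta = 4 * N * mu
        assert np.mean(pis) == pytest.approx(theta, rel=0.05)

    def test_neutral_sfs_follows_one_over_i(self):
        """Expected derived-allele counts at frequency i are proportional
        to 1/i (chi-square goodness of fit not rejected at alpha=0.01)."""
        from scipy.stats import chisquare

        rng = np.random.default_rng(7)
        p = SweepParams(mode="neutral", s=0.0, f=0.5, mu=2e-8, rho=1.25e-8)
        n = 12
        counts = np.zeros(n - 1)
        for _ in range(400):
            region = simulate_region(p, constant_size(10_000), L=5e3, n=n, rng=rng)
            d = region.haplotypes.sum(axis=0)
            for i in range(1, n):
                counts[i - 1] += np.sum(d == i)
        expected = (1.0 / np.arange(1, n)) / np.sum(1.0 / np.arange(1, n))
        stat, pval = chisquare(counts, expected * counts.sum())
        assert pval > 0.01

    def test_sweep_region_truth_consistency(self):
        rng = np.random.default_rng(8)
        p = SweepParams(mode="hard", s=0.01, f=0.8, mu=1.5e-8, rho=1.25e-8)
        region = simulate_region(p, constant_size(5_000), L=2e4, n=32, rng=rng)
        assert region.focal_site.position == 1e4
        daf = region.focal_site.daf(32)
        # sampled DAF is binomial around f
        assert abs(daf - 0.8) < 4 * np.sqrt(0.8 * 0.2 / 32) + 1 / 32
        col = np.argmin(np.abs(region.positions - 1e4))
        assert region.haplotypes[:, col].sum() == len(region.focal_site.carriers)

    def test_sweep_lowers_central_tajimas_d(self):
        """Sweeps depress Tajima's D in the central window vs. neutral."""
        from argsel.sumstats import HaplotypeBlock, basic_stats

        rng = np.random.default_rng(9)
        demog = constant_size(5_000)

        def central_d(params):
            region = simulate_region(params, demog, L=2e4, n=24, rng=rng)
            block = HaplotypeBlock(region.haplotypes, region.positions)
            mid = block.restrict(0.4 * 2e4, 0.6 * 2e4)
            return basic_stats(mid)["tajimas_d"]

        p_sw = SweepParams(mode="hard", s=0.01, f=0.9, mu=2e-8, rho=1.25e-8)
        p_ne = SweepParams(mode="neutral", s=0.0, f=0.5, mu=2e-8, rho=1.25e-8)
        d_sw = [central_d(p_sw) for _ in range(40)]
        d_ne = [central_d(p_ne) for _ in range(40)]
        assert np.nanmean(d_sw) < np.nanmean(d_ne)


class TestPickNeutralFocalSite:
    def _region(self, seed=10):
        rng = np.random.default_rng(seed)
        p = SweepParams(mode="neutral", s=0.0, f=0.5, mu=2e-8, rho=1.25e-8)
        return simulate_region(p, constant_size(10_000), L=2e4, n=16, rng=rng)

    def test_single_qualifying_site_is_returned(self):
        region = self._region()
        daf = region.daf()
        # choose a target hit by exactly one site
        seg = np.flatnonzero((daf > 0) & (daf < 1))
        target = daf[seg[0]]
        exact = np.flatnonzero(np.abs(daf - target) <= 1e-6)
        if len(exact) == 1:
            site = pick_neutral_focal_site(region, target, tolerance=1e-6)
            assert site.position == region.positions[exact[0]]

    def test_degenerate_tolerance_accepts_any_segregating_site(self):
        region = self._region()
        site = pick_neutral_focal_site(
            region, 0.5, tolerance=0.5, rng=np.random.default_rng(0)
        )
        assert 0 < site.daf(region.n) < 1

    def test_no_qualifying_site_raises(self):
        region = self._region()
        # a target between the discrete i/n frequencies cannot match exactly
        with pytest.raises(NoMatchingSiteError):
            pick_neutral_focal_site(region, 0.123456789, tolerance=0.0)

    def test_choice_is_uniform_over_qualifying_sites(self):
        from scipy.stats import chisquare

        region = self._region(11)
        daf = region.daf()
        ok = np.flatnonzero((np.abs(daf - 0.3) <= 0.2) & (daf > 0) & (daf < 1))
        assert len(ok) >= 3
        rng = np.random.default_rng(1)
        picks = [
            pick_neutral_focal_site(region, 0.3, 0.2, rng).position
            for _ in range(600)
        ]
        counts = [picks.count(region.positions[i]) for i in ok]
        assert chisquare(counts).pvalue > 0.01

    def test_sweep_region_rejected(self):
        rng = np.random.default_rng(12)
        p = SweepParams(mode="hard", s=0.01, f=0.5, mu=2e-8, rho=1.25e-8)
        region = simulate_region(p, constant_size(2_000), L=5e3, n=8, rng=rng)
        with pytest.raises(ValueError):
            pick_neutral_focal_site(region, 0.5)


class TestMakeDataset:
    def test_record_counts_labels_and_reproducibility(self, tmp_path):
        from argsel.grid import build_time_grid
        from argsel.io import load_feature_dataset

        grid = build_time_grid(K=16, t_max=4e4)
        prior = PriorSpec(s_range=(0.005, 0.02), f_range=(0.2, 0.8))
        kwargs = dict(
            n_neutral=3, n_sweep=3, prior=prior,
            demography=constant_size(5_000), L=1e4, n=12, grid=grid, seed=123,
        )
        a = make_dataset(tmp_path / "a.h5", **kwargs)
        b = make_dataset(tmp_path / "b.h5", **kwargs)
        assert a["features"].shape == (6, 16, 6)
        assert np.array_equal(a["labels"]["s"], b["labels"]["s"])
        assert np.array_equal(a["features"], b["features"])
        assert a["labels"]["is_sweep"].tolist() == [0, 0, 0, 1, 1, 1]
        sweep_s = a["labels"]["s"][3:]
        assert np.all((sweep_s >= 0.005) & (sweep_s <= 0.02))
        loaded = load_feature_dataset(tmp_path / "a.h5")
        assert np.allclose(loaded["features"], a["features"])
        assert loaded["metadata"]["n"] == 12
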