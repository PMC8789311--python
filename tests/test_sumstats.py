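"""Summary statistics vs. independent brute-force oracles."""

import itertools

import numpy as np
import pytest

from argsel.sumstats import (
    HaplotypeBlock,
    basic_stats,
    ehh_integral,
    garud_h,
    genotype_image,
    haplotype_sort,
    ihs_region,
    ihs_unstandardized,
    omega_max,
    window_features,
    zns,
)

# ---------------------------------------------------------------- oracles


def oracle_pi(matrix):
    n = matrix.shape[0]
    tot = 0
    for i, j in itertools.combinations(range(n), 2):
        tot += int(np.sum(matrix[i] != matrix[j]))
    return tot / (n * (n - 1) / 2)


def oracle_theta_h(matrix):
    n = matrix.shape[0]
    d = matrix.sum(axis=0)
    d = d[(d > 0) & (d < n)]
    return float(np.sum(2.0 * d * d) / (n * (n - 1)))


def oracle_r2(a, b):
    pa, pb = a.mean(), b.mean()
    pab = np.mean(a * b)
    D = pab - pa * pb
    den = pa * (1 - pa) * pb * (1 - pb)
    return np.nan if den == 0 else D * D / den


def oracle_zns(matrix):
    n = matrix.shape[0]
    d = matrix.sum(axis=0)
    seg = matrix[:, (d > 0) & (d < n)]
    S = seg.shape[1]
    if S < 2:
        return np.nan
    vals = [
        oracle_r2(seg[:, i], seg[:, j])
        for i, j in itertools.combinations(range(S), 2)
    ]
    return float(np.mean(vals))


def oracle_omega_max(matrix):
    n = matrix.shape[0]
    d = matrix.sum(axis=0)
    seg = matrix[:, (d > 0) & (d < n)]
    S = seg.shape[1]
    if S < 3:
        return np.nan
    best = -np.inf
    for l in range(1, S):
        within, between = [], []
        for i, j in itertools.combinations(range(S), 2):
            r2 = oracle_r2(seg[:, i], seg[:, j])
            if (i < l) == (j < l):
                within.append(r2)
            else:
                between.append(r2)
        num = np.sum(within) / len(within) if within else None
        if num is None:
            continue
        den = np.mean(between)
        w = np.inf if den == 0 else num / den
        best = max(best, w)
    return float(best)


def oracle_ehh_integral(matrix, positions, core, group, truncate=0.05):
    """Pairwise-identity EHH integral (independent of the prefix-grouping
    algorithm used by the implementation)."""
    g = np.flatnonzero(group)
    if len(g) < 2:
        return np.nan
    pairs = list(itertools.combinations(g.tolist(), 2))
    total = 0.0
    for step in (1, -1):
        prev, ehh_prev = core, 1.0
        while True:
            nxt = prev + step
            if nxt < 0 or nxt >= matrix.shape[1]:
                break
            lo, hi = min(core + step, nxt), max(core + step, nxt)
            ident = sum(
                int(np.array_equal(matrix[i, lo : hi + 1], matrix[j, lo : hi + 1]))
                for i, j in pairs
            )
            ehh = ident / len(pairs)
            total += 0.5 * (ehh_prev + ehh) * abs(positions[nxt] - positions[prev])
            ehh_prev = ehh
            prev = nxt
            if ehh < truncate:
                break
    return total


# ---------------------------------------------------------------- tests


class TestBasicStats:
    def test_two_haplotypes_three_differences(self):
        block = HaplotypeBlock(np.array([[0, 0, 0], [1, 1, 1]]), [1.0, 2.0, 3.0])
        st = basic_stats(block)
        assert st["ss"] == 3
        assert st["pi"] == 3.0
        assert st["theta_w"] == pytest.approx(3.0)  # a1 = 1 for n = 2
        assert st["n_haplotypes"] == 2

    def test_monomorphic_block_flags_tajimas_d(self):
        block = HaplotypeBlock(np.zeros((4, 3), dtype=int), [1.0, 2.0, 3.0])
        st = basic_stats(block)
        assert st["ss"] == 0
        assert st["pi"] == 0.0
        assert np.isnan(st["tajimas_d"])

    def test_identical_haplotypes_collapse_to_one(self):
        block = HaplotypeBlock(np.tile([1, 0, 1], (4, 1)), [1.0, 2.0, 3.0])
        assert basic_stats(block)["n_haplotypes"] == 1


class TestGarudH:
    def test_two_equal_haplotype_classes(self):
        m = np.array([[0, 0], [0, 0], [1, 1], [1, 1]])
        h = garud_h(HaplotypeBlock(m, [1.0, 2.0]))
        assert h["h1"] == pytest.approx(0.5)
        assert h["h12"] == pytest.approx(1.0)

    def test_single_haplotype_class(self):
        h = garud_h(HaplotypeBlock(np.zeros((5, 2), dtype=int), [1.0, 2.0]))
        assert h == {"h1": 1.0, "h12": 1.0, "h2_h1": 0.0}

    def test_frequencies_60_30_10(self):
        m = np.vstack([np.tile([0, 0], (6, 1)), np.tile([1, 0], (3, 1)),
                       np.tile([1, 1], (1, 1))])
        h = garud_h(HaplotypeBlock(m, [1.0, 2.0]))
        assert h["h1"] == pytest.approx(0.46)
        assert h["h12"] == pytest.approx(0.82)
        assert h["h2_h1"] == pytest.approx((0.46 - 0.36) / 0.46)


class TestZns:
    def test_perfectly_correlated_sites(self):
        m = np.array([[1, 1], [1, 1], [0, 0], [0, 0]])
        assert zns(HaplotypeBlock(m, [1.0, 2.0])) == pytest.approx(1.0)

    def test_orthogonal_sites_in_balanced_sample(self):
        m = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
        assert zns(HaplotypeBlock(m, [1.0, 2.0])) == pytest.approx(0.0, abs=1e-12)

    def test_single_site_is_missing(self):
        assert np.isnan(zns(HaplotypeBlock(np.array([[1], [0]]), [1.0])))


class TestOmega:
    def test_two_perfect_ld_groups_give_large_omega(self):
        rng = np.random.default_rng(0)
        left = rng.integers(0, 2, size=(12, 1))
        right = rng.integers(0, 2, size=(12, 1))
        m = np.hstack([left, left, 1 - left, right, 1 - right, right])
        block = HaplotypeBlock(m, np.arange(6, dtype=float))
        w = omega_max(block)
        assert w == pytest.approx(oracle_omega_max(m))
        assert w > 10

    def test_too_few_sites_is_missing(self):
        m = np.array([[1, 0], [0, 1]])
        assert np.isnan(omega_max(HaplotypeBlock(m, [1.0, 2.0])))


class TestIhs:
    def test_symmetric_decay_gives_zero(self):
        # derived and ancestral backgrounds are mirror images
        m = np.array(
            [
                [0, 0, 1, 0, 0],
                [0, 0, 1, 0, 0],
                [1, 1, 1, 1, 1],
                [0, 0, 0, 0, 0],
                [1, 1, 0, 1, 1],
                [1, 1, 0, 1, 1],
            ]
        )
        block = HaplotypeBlock(m, np.arange(5, dtype=float))
        assert ihs_unstandardized(block, core=2) == pytest.approx(0.0, abs=1e-12)

    def test_matches_pairwise_identity_oracle(self, block8):
        matrix, positions = block8
        block = HaplotypeBlock(matrix, positions)
        core = 2
        der = matrix[:, core] == 1
        for group in (der, ~der):
            mine = ehh_integral(matrix, positions, core, group)
            oracle = oracle_ehh_integral(matrix, positions, core, group)
            assert mine == pytest.approx(oracle)

    def test_region_score_standardization(self):
        rng = np.random.default_rng(1)
        m = rng.integers(0, 2, size=(16, 40))
        block = HaplotypeBlock(m, np.sort(rng.uniform(0, 1e4, size=40)))
        score, per_site = ihs_region(block, return_sites=True)
        vals = np.array([v for v in per_site.values() if np.isfinite(v)])
        assert np.isfinite(score)
        assert score == pytest.approx(np.nanmean(list(per_site.values())))
        # standardized scores are centered near zero overall
        assert abs(np.mean(vals)) < 0.5

    def test_no_scoreable_site_is_missing(self):
        m = np.zeros((8, 3), dtype=int)
        m[0] = 1  # every site at DAF 1/8 < 2/8 minor-allele cutoff? 0.125 > 0.05
        m2 = np.zeros((8, 2), dtype=int)
        assert np.isnan(ihs_region(HaplotypeBlock(m2, [1.0, 2.0])))


class TestBruteForceSweep:
    """All scalar statistics agree with naive pairwise-loop oracles on
    random 8 x 20 matrices."""

    @pytest.mark.parametrize("seed", range(4))
    def test_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(25):
            m = rng.integers(0, 2, size=(8, 20))
            positions = np.sort(rng.uniform(0, 2e4, size=20))
            block = HaplotypeBlock(m, positions)
            st = basic_stats(block)
            assert st["pi"] == pytest.approx(oracle_pi(m))
            assert st["theta_h"] == pytest.approx(oracle_theta_h(m))
            d = m.sum(axis=0)
            S = int(np.sum((d > 0) & (d < 8)))
            assert st["ss"] == S
            assert st["theta_w"] == pytest.approx(S / np.sum(1 / np.arange(1, 8)))
            z = zns(block)
            zo = oracle_zns(m)
            assert (np.isnan(z) and np.isnan(zo)) or z == pytest.approx(zo)
            w = omega_max(block)
            wo = oracle_omega_max(m)
            assert (np.isnan(w) and np.isnan(wo)) or w == pytest.approx(wo)


class TestTajimasDNeutrality:
    def test_mean_near_zero_on_neutral_simulations(self):
        from argsel.demography import constant_size
        from argsel.regions import SweepParams, simulate_region

        rng = np.random.default_rng(2)
        p = SweepParams(mode="neutral", s=0.0, f=0.5, mu=2e-8, rho=1.25e-8)
        ds = []
        for _ in range(500):
            region = simulate_region(p, constant_size(10_000), L=5e3, n=16,
                                     rng=rng)
            block = HaplotypeBlock(region.haplotypes, region.positions,
                                   span=(0.0, 5e3))
            ds.append(basic_stats(block)["tajimas_d"])
        assert abs(np.nanmean(ds)) < 0.3


class TestWindowFeatures:
    def _block(self, seed=0, S=60):
        rng = np.random.default_rng(seed)
        m = rng.integers(0, 2, size=(10, S))
        pos = np.sort(rng.uniform(0, 1e5, size=S))
        return HaplotypeBlock(m, pos, span=(0.0, 1e5))

    def test_rows_sum_to_one(self):
        table = window_features(self._block())
        sums = table.sum(axis=1, skipna=False)
        for stat, total in sums.items():
            if np.isfinite(total):
                assert total == pytest.approx(1.0)

    def test_constant_statistic_gives_uniform_row(self):
        m = np.tile(np.array([[0, 1], [1, 0], [1, 1], [0, 0]]), (1, 5))
        pos = np.concatenate([[i * 2e4 + 5e3, i * 2e4 + 1.5e4] for i in range(5)])
        block = HaplotypeBlock(m, pos, span=(0.0, 1e5))
        table = window_features(block)
        assert np.allclose(table.loc["ss"], 0.2)
        assert np.allclose(table.loc["pi"], 0.2)

    def test_diversity_concentrated_in_first_window(self):
        rng = np.random.default_rng(3)
        m = np.hstack([rng.integers(0, 2, size=(10, 30)),
                       np.zeros((10, 5), dtype=int)])
        pos = np.concatenate([np.sort(rng.uniform(0, 2e4, 30)),
                              np.sort(rng.uniform(2e4, 1e5, 5))])
        block = HaplotypeBlock(m, pos, span=(0.0, 1e5))
        table = window_features(block)
        assert table.loc["pi", "window_0"] == pytest.approx(1.0)
        assert np.allclose(table.loc["pi"].iloc[1:], 0.0)

    def test_scale_invariance_of_normalization(self):
        table = window_features(self._block(4))
        row = table.loc["pi"].to_numpy()
        # normalizing c * raw yields the same row for any c > 0
        raw = row * 123.4
        assert np.allclose(raw / raw.sum(), row)


class TestHaplotypeSort:
    def test_identical_rows_keep_original_order(self):
        m = np.tile([1, 0, 1], (4, 1))
        assert np.array_equal(haplotype_sort(m), m)

    def test_hand_worked_three_row_example(self):
        m = np.array([[0, 0, 0], [0, 1, 1], [0, 0, 1]])
        # totals: 3, 3, 2 -> row 001 first; 000 and 011 tie at distance 1
        expected = np.array([[0, 0, 1], [0, 0, 0], [0, 1, 1]])
        assert np.array_equal(haplotype_sort(m), expected)

    def test_output_is_a_permutation_of_input(self):
        rng = np.random.default_rng(5)
        m = rng.integers(0, 2, size=(12, 9))
        out = haplotype_sort(m)
        assert sorted(map(tuple, out)) == sorted(map(tuple, m))


class TestGenotypeImage:
    def test_full_width_image_is_198_by_360(self):
        rng = np.random.default_rng(6)
        m = rng.integers(0, 2, size=(198, 400))
        block = HaplotypeBlock(m, np.arange(400, dtype=float))
        img, pos = genotype_image(block, focal_index=200)
        assert img.shape == (198, 360)
        assert pos.shape == (360,)

    def test_sparse_input_zero_pads_outward(self):
        m = np.ones((4, 10), dtype=int)
        block = HaplotypeBlock(m, np.arange(10, dtype=float) + 1)
        img, pos = genotype_image(block, focal_index=5, half_width=8)
        assert img.shape == (4, 16)
        assert img.sum() == 4 * 10
        assert np.all(img[:, :3] == 0)  # left padding
        assert np.all(pos[:3] == 0)

    def test_focal_variant_is_centered(self):
        m = np.zeros((4, 11), dtype=int)
        m[:, 7] = 1
        block = HaplotypeBlock(m, np.arange(11, dtype=float) + 1)
        img, pos = genotype_image(block, focal_index=7, half_width=5, sort=False)
        assert np.all(img[:, 5] == 1)
        assert pos[5] == 8.0
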