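"""Volume statistics, vertex-wise GLM, clustering, permutation, TFCE, ROIs."""

import numpy as np
import pytest
from scipy import stats as sps

from hippomorph.errors import ValidationError
from hippomorph.stats import (
    DesignMatrix,
    apply_tiv_adjustment,
    clinical_correlation,
    fit_tiv_adjustment,
    flood_fill_clusters,
    group_volume_test,
    permutation_cluster_test,
    roi_cluster_test,
    roi_partition,
    tfce_enhance,
    vertex_glm,
)


# ---------------------------------------------------------------------------
# TIV adjustment
# ---------------------------------------------------------------------------

class TestTivAdjustment:
    def test_exact_linear_relation(self):
        tiv = np.array([1400.0, 1500, 1600, 1450, 1550]) * 1e3
        hv = 2.0 * tiv + 5.0
        model = fit_tiv_adjustment(hv, tiv)
        assert model.alpha == pytest.approx(2.0, abs=1e-9)
        assert model.control_mean_tiv == pytest.approx(tiv.mean())

    def test_uncorrelated_constant_volume(self):
        tiv = np.array([1.4e6, 1.5e6, 1.6e6])
        model = fit_tiv_adjustment(np.full(3, 2500.0), tiv)
        assert model.alpha == pytest.approx(0.0, abs=1e-12)

    def test_slope_recovered_from_noisy_controls(self):
        rng = np.random.default_rng(11)
        tiv = rng.normal(1.5e6, 1e5, 29)
        hv = 0.002 * tiv + rng.normal(0.0, 50.0, 29)
        model = fit_tiv_adjustment(hv, tiv)
        # closed-form OLS standard error of the slope
        resid = hv - (model.alpha * tiv + (hv.mean() - model.alpha * tiv.mean()))
        se = np.sqrt(resid.var(ddof=2) / ((tiv - tiv.mean()) ** 2).sum())
        assert abs(model.alpha - 0.002) < 3 * se

    def test_fixed_point_at_control_mean(self):
        model = fit_tiv_adjustment(np.array([2400.0, 2500, 2600]),
                                   np.array([1.4e6, 1.5e6, 1.6e6]))
        assert apply_tiv_adjustment(model, 2500.0, model.control_mean_tiv) == 2500.0

    def test_worked_example(self):
        from hippomorph.stats import TIVAdjustmentModel

        model = TIVAdjustmentModel(alpha=2.0, control_mean_tiv=1500.0)
        assert apply_tiv_adjustment(model, 2500.0, 1600.0) == pytest.approx(2300.0)

    def test_adjusted_control_slope_is_zero(self):
        rng = np.random.default_rng(5)
        tiv = rng.normal(1.5e6, 1.2e5, 25)
        hv = 0.0017 * tiv + rng.normal(0, 120, 25)
        model = fit_tiv_adjustment(hv, tiv)
        adj = apply_tiv_adjustment(model, hv, tiv)
        slope, _ = np.polyfit(tiv, adj, 1)
        assert abs(slope) < 1e-9
        # centering on the control mean leaves the control mean unchanged
        assert adj.mean() == pytest.approx(hv.mean(), rel=1e-12)

    def test_zero_tiv_variance_rejected(self):
        with pytest.raises(ValidationError, match="variance"):
            fit_tiv_adjustment(np.array([1.0, 2, 3]), np.array([5.0, 5, 5]))


# ---------------------------------------------------------------------------
# volume group test and clinical correlations
# ---------------------------------------------------------------------------

class TestGroupVolumeTest:
    def test_null_when_groups_identical(self):
        vol = np.tile([2500.0, 2600, 2400, 2550], 2)
        group = np.repeat([1, 0], 4)
        age = np.tile([60.0, 62, 58, 65], 2)
        res = group_volume_test(vol, group, age)
        assert res["F"] == pytest.approx(0.0, abs=1e-9)
        assert not res["significant"]

    def test_separated_groups(self):
        rng = np.random.default_rng(0)
        vol = np.concatenate([rng.normal(2000, 10, 15), rng.normal(2100, 10, 15)])
        group = np.repeat([1, 0], 15)
        age = rng.normal(62, 8, 30)
        res = group_volume_test(vol, group, age)
        assert res["p"] < 1e-6
        assert res["significant"]
        assert res["group_coef"] < 0  # patients coded 1 have smaller volumes

    def test_f_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(3)
        n = 10
        group = np.array([1, 1, 1, 1, 1, 0, 0, 0, 0, 0], float)
        age = rng.normal(60, 5, n)
        vol = 2500 - 80 * group + 1.5 * age + rng.normal(0, 40, n)
        res = group_volume_test(vol, group, age)
        # brute-force OLS via lstsq on full and reduced designs
        Xf = np.column_stack([np.ones(n), group, age])
        Xr = np.column_stack([np.ones(n), age])
        rss_f = np.sum((vol - Xf @ np.linalg.lstsq(Xf, vol, rcond=None)[0]) ** 2)
        rss_r = np.sum((vol - Xr @ np.linalg.lstsq(Xr, vol, rcond=None)[0]) ** 2)
        f_expect = (rss_r - rss_f) / (rss_f / (n - 3))
        assert res["F"] == pytest.approx(f_expect, abs=1e-8)
        assert res["p"] == pytest.approx(sps.f.sf(f_expect, 1, n - 3), abs=1e-10)

    def test_small_groups_rejected(self):
        with pytest.raises(ValidationError, match=">= 3"):
            group_volume_test(np.arange(5.0), np.array([1, 1, 0, 0, 0]),
                              np.arange(5.0) + 60)


class TestClinicalCorrelation:
    def test_perfectly_monotone(self):
        res = clinical_correlation(np.arange(8.0), np.arange(8.0) ** 3)
        assert res["rho"] == pytest.approx(1.0)

    def test_reversed_ranks(self):
        res = clinical_correlation(np.arange(8.0), -np.arange(8.0))
        assert res["rho"] == pytest.approx(-1.0)

    def test_matches_rank_formula(self):
        vol = np.array([2400.0, 2550, 2300, 2700, 2500, 2450, 2600, 2350])
        score = np.array([30.0, 41, 28, 44, 39, 35, 38, 45])
        res = clinical_correlation(vol, score)
        d = sps.rankdata(vol) - sps.rankdata(score)
        rho_formula = 1.0 - 6.0 * (d**2).sum() / (8 * (64 - 1))
        assert res["rho"] == pytest.approx(rho_formula, abs=1e-12)

    def test_missing_scores_dropped_pairwise(self):
        vol = np.arange(10.0)
        score = np.arange(10.0)
        score[[2, 5]] = np.nan
        assert clinical_correlation(vol, score)["n"] == 8

    def test_all_tied_scores_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            clinical_correlation(np.arange(6.0), np.full(6, 3.0))


# ---------------------------------------------------------------------------
# vertex-wise GLM
# ---------------------------------------------------------------------------

def _design(group, covs=()):
    cols = [np.ones(len(group)), np.asarray(group, float)]
    cols.extend(np.asarray(c, float) for c in covs)
    contrast = np.zeros(len(cols))
    contrast[1] = 1.0
    names = tuple(["intercept", "group"] + [f"c{i}" for i in range(len(covs))])
    return DesignMatrix(np.column_stack(cols), contrast, names)


class TestVertexGlm:
    def test_identical_maps_give_zero_t(self):
        maps = np.tile(np.random.default_rng(0).normal(3, 0.2, (1, 6, 8)), (10, 1, 1))
        design = _design([1] * 5 + [0] * 5, [np.arange(10.0)])
        res = vertex_glm(maps, design)
        np.testing.assert_allclose(res.t_values, 0.0, atol=1e-8)

    def test_noiseless_patch_separates(self):
        rng = np.random.default_rng(1)
        base = rng.normal(4.0, 0.3, (6, 8))
        maps = np.stack([base] * 12)
        maps[:6, 2:4, 3:6] -= 1.0  # patients deformed inward, zero noise
        res = vertex_glm(maps, _design([1] * 6 + [0] * 6))
        patch = np.zeros((6, 8), bool)
        patch[2:4, 3:6] = True
        assert np.all(res.t_values[patch] <= -1e5)  # capped separation
        np.testing.assert_allclose(res.t_values[~patch], 0.0, atol=1e-8)

    def test_matches_statsmodels_on_random_designs(self):
        """Mass-univariate t equals the independent OLS route (statsmodels)."""
        import statsmodels.api as sm

        rng = np.random.default_rng(42)
        for _ in range(5):
            n = int(rng.integers(9, 16))
            n1 = int(rng.integers(3, n - 5)) if n > 8 else 3
            group = np.zeros(n)
            group[:n1] = 1
            covs = [rng.normal(size=n), rng.normal(size=n)]
            design = _design(group, covs)
            maps = rng.normal(5.0, 1.0, (n, 3, 4))
            res = vertex_glm(maps, design)
            for l in range(3):
                for c in range(4):
                    fit = sm.OLS(maps[:, l, c], design.X).fit()
                    t_ref = fit.tvalues[1]
                    assert res.t_values[l, c] == pytest.approx(t_ref, abs=1e-8)
                    assert res.p_values[l, c] == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_sign_convention_inward_negative(self):
        rng = np.random.default_rng(2)
        maps = rng.normal(4.0, 0.05, (20, 4, 4))
        maps[:10] -= 0.5  # patients first, surface inward
        res = vertex_glm(maps, _design([1] * 10 + [0] * 10))
        assert np.all(res.t_values < 0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            vertex_glm(np.zeros((4, 3, 3)), _design([1, 1, 1, 0, 0, 0]))


# ---------------------------------------------------------------------------
# flood fill
# ---------------------------------------------------------------------------

def dfs_label(mask: np.ndarray, connectivity: int = 4) -> np.ndarray:
    """Brute-force component labelling with circumferential wrap (oracle)."""
    L, C = mask.shape
    labels = np.zeros((L, C), int)
    nxt = 0
    if connectivity == 4:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dl, dc) for dl in (-1, 0, 1) for dc in (-1, 0, 1) if (dl, dc) != (0, 0)]
    for l0 in range(L):
        for c0 in range(C):
            if mask[l0, c0] and labels[l0, c0] == 0:
                nxt += 1
                todo = [(l0, c0)]
                labels[l0, c0] = nxt
                while todo:
                    l, c = todo.pop()
                    for dl, dc in steps:
                        ll, cc = l + dl, (c + dc) % C  # wrap columns, not rows
                        if 0 <= ll < L and mask[ll, cc] and labels[ll, cc] == 0:
                            labels[ll, cc] = nxt
                            todo.append((ll, cc))
    return labels


def partitions_equal(a: np.ndarray, b: np.ndarray) -> bool:
    """Same components irrespective of label numbering."""
    if (a > 0).sum() != (b > 0).sum() or a.max() != b.max():
        return False
    pair = a.astype(np.int64) * (b.max() + 1) + b
    return len(np.unique(pair[a > 0])) == a.max()


class TestFloodFill:
    def test_single_vertex(self):
        mask = np.zeros((5, 6), bool)
        mask[2, 3] = True
        labels, sizes = flood_fill_clusters(mask)
        assert labels[2, 3] == 1 and sizes.tolist() == [1]

    def test_full_row_wraps(self):
        mask = np.zeros((4, 100), bool)
        mask[1] = True
        labels, sizes = flood_fill_clusters(mask)
        assert sizes.tolist() == [100]

    def test_wrap_joins_seam_components(self):
        mask = np.zeros((3, 8), bool)
        mask[1, :2] = True
        mask[1, -2:] = True
        _, sizes = flood_fill_clusters(mask)
        assert sizes.tolist() == [4]

    def test_no_wrap_across_levels(self):
        mask = np.zeros((4, 6), bool)
        mask[0, 2] = True
        mask[3, 2] = True
        _, sizes = flood_fill_clusters(mask)
        assert sizes.tolist() == [1, 1]

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_matches_dfs_oracle_on_random_masks(self, connectivity):
        rng = np.random.default_rng(123)
        for _ in range(200):
            mask = rng.random((20, 20)) < rng.uniform(0.2, 0.7)
            labels, sizes = flood_fill_clusters(mask, connectivity)
            oracle = dfs_label(mask, connectivity)
            assert partitions_equal(labels, oracle)
            assert sorted(sizes, reverse=True) == sizes.tolist()
            assert np.array_equal(np.sort(sizes), np.sort(np.bincount(oracle.ravel())[1:]))


# ---------------------------------------------------------------------------
# permutation cluster test
# ---------------------------------------------------------------------------

def _toy_cohort(n_per=8, effect=0.0, seed=0, shape=(10, 12)):
    rng = np.random.default_rng(seed)
    n = 2 * n_per
    maps = rng.normal(4.0, 0.3, (n, *shape))
    maps[:n_per, 2:5, 3:7] -= effect
    group = np.array([1] * n_per + [0] * n_per, float)
    age = rng.normal(60, 8, n)
    return maps, _design(group, [age])


class TestPermutationClusterTest:
    def test_seed_determinism(self):
        maps, design = _toy_cohort(effect=0.5, seed=4)
        r1 = permutation_cluster_test(maps, design, n_perm=150, seed=9)
        r2 = permutation_cluster_test(maps, design, n_perm=150, seed=9)
        np.testing.assert_array_equal(r1.label_map, r2.label_map)
        np.testing.assert_array_equal(r1.corrected_p, r2.corrected_p)
        np.testing.assert_array_equal(r1.null_max_sizes, r2.null_max_sizes)

    def test_strong_effect_detected(self):
        maps, design = _toy_cohort(n_per=15, effect=1.2, seed=1)
        res = permutation_cluster_test(maps, design, n_perm=300, seed=2)
        assert res.corrected_p.min() <= 0.05
        big = np.argmax(res.cluster_sizes == res.cluster_sizes.max())
        assert res.cluster_signs[big] == -1  # inward deformation

    def test_corrected_p_monotone_in_size(self):
        maps, design = _toy_cohort(n_per=12, effect=0.8, seed=3)
        res = permutation_cluster_test(maps, design, n_perm=200, seed=5)
        order = np.argsort(-res.cluster_sizes)
        p_sorted = res.corrected_p[order]
        assert np.all(np.diff(p_sorted) >= 0)
        assert np.all(res.corrected_p >= 1.0 / (res.n_permutations + 1))

    def test_label_scheme_exhaustive_at_tiny_n(self):
        maps, design = _toy_cohort(n_per=3, seed=6)
        with pytest.warns(UserWarning, match="exhaustively"):
            res = permutation_cluster_test(
                maps, design, n_perm=100, seed=1, scheme="label"
            )
        from math import comb

        assert res.n_permutations == comb(6, 3)

    def test_mask_restricts_clusters(self):
        maps, design = _toy_cohort(n_per=10, effect=1.0, seed=7)
        mask = np.zeros((10, 12), bool)
        mask[7:] = True  # away from the effect patch
        res = permutation_cluster_test(maps, design, n_perm=150, seed=8, mask=mask)
        assert all(
            np.all(mask[res.label_map == k])
            for k in range(1, len(res.cluster_sizes) + 1)
        )

    def test_seed_required(self):
        maps, design = _toy_cohort()
        with pytest.raises(ValueError, match="seed"):
            permutation_cluster_test(maps, design, n_perm=100)


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------

class TestTfce:
    def test_single_vertex_hand_sum(self):
        """Discrete TFCE of an isolated unit vertex: sum_k 1^E (k dh)^H dh."""
        tmap = np.zeros((5, 5))
        tmap[2, 2] = 1.0
        out = tfce_enhance(tmap, E=0.5, H=2.0, dh=0.1)
        expected = sum(1.0**0.5 * (0.1 * k) ** 2 * 0.1 for k in range(1, 11))
        assert expected == pytest.approx(0.385)
        assert out[2, 2] == pytest.approx(expected, rel=1e-12)
        assert np.count_nonzero(out) == 1

    def test_flat_zero_map(self):
        np.testing.assert_array_equal(tfce_enhance(np.zeros((4, 6))), np.zeros((4, 6)))

    def test_negative_values_enhanced_on_negated_map(self):
        tmap = np.zeros((5, 5))
        tmap[1, 1] = 1.0
        tmap[3, 3] = -1.0
        out = tfce_enhance(tmap, dh=0.1)
        assert out[3, 3] == pytest.approx(-out[1, 1], rel=1e-12)

    def test_refinement_convergence(self):
        rng = np.random.default_rng(0)
        from scipy import ndimage

        tmap = ndimage.gaussian_filter(rng.normal(0, 1, (30, 30)), 3.0)
        a = tfce_enhance(tmap, dh=0.05 * np.abs(tmap).max())
        b = tfce_enhance(tmap, dh=0.01 * np.abs(tmap).max())
        denom = np.abs(b).max()
        assert np.abs(a - b).max() / denom < 0.07  # right-sum bias shrinks with dh

    def test_homogeneity_in_scale(self):
        rng = np.random.default_rng(1)
        tmap = rng.normal(0, 1, (10, 10))
        s = 3.0
        base = tfce_enhance(tmap, E=0.5, H=2.0, dh=0.1)
        scaled = tfce_enhance(s * tmap, E=0.5, H=2.0, dh=0.1 * s)
        np.testing.assert_allclose(scaled, s**3 * base, rtol=1e-9)

    def test_invalid_dh_rejected(self):
        with pytest.raises(ValueError):
            tfce_enhance(np.ones((3, 3)), dh=0.0)


# ---------------------------------------------------------------------------
# ROI partition
# ---------------------------------------------------------------------------

class TestRoi:
    def test_equal_thirds(self):
        part = roi_partition(150, 100)
        assert [m.sum() for m in part.masks.values()] == [5000, 5000, 5000]
        assert part.boundaries == (0, 50, 100, 150)

    def test_partition_invariants(self):
        part = roi_partition(17, 9, (0.2, 0.5, 0.3))
        total = np.zeros((17, 9), int)
        for m in part.masks.values():
            total += m.astype(int)
        assert np.all(total == 1)  # union is the grid, pairwise disjoint

    def test_zero_level_band_rejected(self):
        with pytest.raises(ValueError):
            roi_partition(3, 5, (0.01, 0.01, 0.98))

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            roi_partition(10, 5, (0.3, 0.3, 0.3))

    def test_roi_test_targets_band_with_effect(self):
        maps, design = _toy_cohort(n_per=12, effect=1.2, seed=9, shape=(12, 10))
        part = roi_partition(12, 10)
        res = roi_cluster_test(maps, design, part, n_perm=200, seed=3)
        assert set(res) == {"head", "body", "tail"}
        assert res["head"].corrected_p.min() <= 0.05  # effect in rows 2..4
        assert (len(res["tail"].corrected_p) == 0
                or res["tail"].corrected_p.min() > 0.05)
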