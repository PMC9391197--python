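import numpy as np
import pandas as pd
import pytest

import toemorph as tm
from toemorph import shape_stats as ss


def make_design(n, rng, balanced=True):
    if balanced:
        hab = np.tile(np.repeat(["urban", "forest"], n // 4), 2)[:n]
        mun = np.repeat(["Ponce", "Arecibo"], n // 2)
    else:
        hab = rng.choice(["urban", "forest"], n)
        mun = rng.choice(["Ponce", "Arecibo", "San Juan"], n)
    return pd.DataFrame({"habitat": hab, "municipality": mun})


class TestProcrustesAnova:
    def test_balanced_orthogonal_ss_additivity(self, rng):
        """On a balanced crossed design type-II SS partition the total."""
        n = 40
        design = make_design(n, rng, balanced=True)
        y = rng.normal(size=(n, 12))
        res = ss.procrustes_anova(y, design, "habitat * municipality",
                                  n_perm=19, seed=0)
        terms = res.table.drop(index=["Residuals", "Total"])
        total = res.table.loc["Total", "SS"]
        assert terms.SS.sum() + res.table.loc["Residuals", "SS"] == (
            pytest.approx(total, rel=1e-8))

    def test_total_ss_is_n_minus_1_times_variance(self, calib_aligned,
                                                  calib_meta):
        res = ss.procrustes_anova(calib_aligned, calib_meta, n_perm=9, seed=0)
        y = calib_aligned.flat()
        expected = ((y - y.mean(axis=0)) ** 2).sum()
        assert res.table.loc["Total", "SS"] == pytest.approx(expected, rel=1e-10)

    def test_r2_bounds_and_p_range(self, calib_aligned, calib_meta):
        res = ss.procrustes_anova(calib_aligned, calib_meta, n_perm=99, seed=1)
        terms = res.table.drop(index=["Residuals", "Total"])
        assert ((terms.R2 >= 0) & (terms.R2 <= 1)).all()
        assert ((terms.p_perm > 0) & (terms.p_perm <= 1)).all()

    def test_deterministic_given_seed(self, calib_aligned, calib_meta):
        r1 = ss.procrustes_anova(calib_aligned, calib_meta, n_perm=49, seed=7)
        r2 = ss.procrustes_anova(calib_aligned, calib_meta, n_perm=49, seed=7)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_ss_invariant_to_sample_rotation(self, calib_aligned, calib_meta):
        res1 = ss.procrustes_anova(calib_aligned, calib_meta, n_perm=9, seed=0)
        theta = 0.6
        r = np.array([[np.cos(theta), -np.sin(theta)],
                      [np.sin(theta), np.cos(theta)]])
        rotated = calib_aligned.coords @ r.T
        res2 = ss.procrustes_anova(
            rotated.reshape(len(rotated), -1), calib_meta, n_perm=9, seed=0)
        np.testing.assert_allclose(res1.table.SS, res2.table.SS, rtol=1e-9)

    def test_ss_invariant_to_specimen_order(self, calib_aligned, calib_meta):
        y = calib_aligned.flat()
        perm = np.random.default_rng(3).permutation(len(y))
        res1 = ss.procrustes_anova(y, calib_meta, n_perm=9, seed=0)
        res2 = ss.procrustes_anova(y[perm], calib_meta.iloc[perm], n_perm=9,
                                   seed=0)
        np.testing.assert_allclose(res1.table.SS, res2.table.SS, rtol=1e-9)
        np.testing.assert_allclose(res1.table.F.dropna(),
                                   res2.table.F.dropna(), rtol=1e-9)

    def test_habitat_effect_detected_in_calibrated_sample(self, calib_aligned,
                                                          calib_meta):
        res = ss.procrustes_anova(calib_aligned, calib_meta, n_perm=199, seed=5)
        assert res.p_value("habitat") <= 0.05

    def test_constant_shape_rejected(self, calib_meta):
        y = np.ones((len(calib_meta), 10))
        with pytest.raises(ValueError, match="constant"):
            ss.ProcrustesAnova(y, calib_meta)


class TestDisparity:
    def test_mirror_copy_groups_equal_pv(self, rng):
        base = rng.normal(size=(20, 8))
        scatter = base - base.mean(axis=0)
        y = np.vstack([scatter, -scatter])
        groups = ["a"] * 20 + ["b"] * 20
        res = ss.morphological_disparity(y, groups, n_perm=49, seed=0)
        assert res.procrustes_variance["a"] == pytest.approx(
            res.procrustes_variance["b"])
        assert res.relative_excess[("a", "b")] == pytest.approx(0.0, abs=1e-12)

    def test_scaled_deviations_scale_pv_quadratically(self, rng):
        base = rng.normal(size=(30, 8))
        dev = base - base.mean(axis=0)
        y = np.vstack([dev, 1.2 * dev])
        groups = ["a"] * 30 + ["b"] * 30
        res = ss.morphological_disparity(y, groups, n_perm=9, seed=0)
        ratio = res.procrustes_variance["b"] / res.procrustes_variance["a"]
        assert ratio == pytest.approx(1.44, rel=1e-9)

    def test_null_p_not_degenerate(self, rng):
        y = rng.normal(size=(60, 10))
        groups = ["a", "b"] * 30
        res = ss.morphological_disparity(y, groups, n_perm=99, seed=4)
        assert 0 < res.pairwise_p[("a", "b")] <= 1

    def test_small_group_rejected(self, rng):
        y = rng.normal(size=(5, 4))
        with pytest.raises(ValueError, match="3"):
            ss.morphological_disparity(y, ["a", "a", "a", "b", "b"], n_perm=9)


class TestShapePca:
    def test_rank_one_data(self, rng):
        direction = rng.normal(size=10)
        y = np.outer(rng.normal(size=20), direction)
        res = ss.shape_pca(y)
        assert res.percent_variance[0] == pytest.approx(100.0)
        assert res.n_axes == 1

    def test_percent_variance_sums_to_100(self, calib_aligned):
        res = ss.shape_pca(calib_aligned)
        assert res.percent_variance.sum() == pytest.approx(100.0, abs=1e-6)

    def test_scores_centered_and_uncorrelated(self, calib_aligned):
        res = ss.shape_pca(calib_aligned)
        np.testing.assert_allclose(res.scores.mean(axis=0), 0, atol=1e-10)
        k = min(5, res.n_axes)
        corr = np.corrcoef(res.scores[:, :k].T)
        np.testing.assert_allclose(corr - np.eye(k), 0, atol=1e-8)

    def test_full_basis_reconstructs_shapes(self, calib_aligned):
        res = ss.shape_pca(calib_aligned)
        recon = res.center + res.scores @ res.axes
        np.testing.assert_allclose(recon, calib_aligned.flat(), atol=1e-8)

    def test_extreme_shapes_at_observed_scores(self, calib_aligned):
        res = ss.shape_pca(calib_aligned)
        lo, hi = res.extreme_shapes[0]
        expected_lo = res.center + res.scores[:, 0].min() * res.axes[0]
        np.testing.assert_allclose(lo.ravel(), expected_lo, atol=1e-12)
        assert lo.shape == (123, 2) and hi.shape == (123, 2)

    def test_too_few_specimens(self, rng):
        with pytest.raises(ValueError):
            ss.shape_pca(rng.normal(size=(2, 6)))


class TestBetweenGroupPca:
    def test_two_groups_single_axis(self, calib_aligned, calib_meta):
        res = ss.between_group_pca(calib_aligned, calib_meta.habitat)
        assert res.axes.shape[0] == 1

    def test_identical_group_means_zero_variance(self, rng):
        dev = rng.normal(size=(15, 6))
        dev -= dev.mean(axis=0)
        y = np.vstack([dev, dev])
        res = ss.between_group_pca(y, ["a"] * 15 + ["b"] * 15)
        assert res.eigenvalues.max() == pytest.approx(0.0, abs=1e-12)

    def test_specimens_cluster_around_group_mean_scores(self, rng):
        offset = np.zeros(8)
        offset[0] = 5.0
        y = np.vstack([rng.normal(size=(25, 8)),
                       rng.normal(size=(25, 8)) + offset])
        groups = ["a"] * 25 + ["b"] * 25
        res = ss.between_group_pca(y, groups)
        scores = res.scores[:, 0]
        mean_a = res.group_mean_scores.loc["a", "bgPC1"]
        mean_b = res.group_mean_scores.loc["b", "bgPC1"]
        assert abs(scores[:25].mean() - mean_a) < abs(mean_a - mean_b) / 4
        assert abs(scores[25:].mean() - mean_b) < abs(mean_a - mean_b) / 4

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValueError):
            ss.between_group_pca(rng.normal(size=(10, 4)), ["a"] * 10)


class TestGroupMeanShapes:
    def test_identical_shapes_mean_is_that_shape(self, rng):
        shape = rng.normal(size=(6, 2))
        coords = np.stack([shape] * 4)
        means = ss.group_mean_shapes(coords, ["g"] * 4)
        np.testing.assert_allclose(means["g"], shape)

    def test_two_specimens_midpoint(self, rng):
        a, b = rng.normal(size=(2, 6, 2))
        means = ss.group_mean_shapes(np.stack([a, b]), ["g", "g"])
        np.testing.assert_allclose(means["g"], (a + b) / 2)

    def test_pre_alignment_means_preserve_size_ratio(self, calib_configs,
                                                     scheme, calib_meta):
        """Pre-alignment group mean pad lengths keep the simulated 3.61/3.20
        urban/forest ratio (translation-only registration keeps mm units)."""
        coords = np.stack([tm.flatten(c, scheme) for c in calib_configs])
        means = ss.group_mean_shapes(coords, calib_meta.habitat,
                                     space="pre_alignment_mm")
        def pad_len(shape):
            mid34 = (shape[2] + shape[3]) / 2
            mid78 = (shape[6] + shape[7]) / 2
            return np.linalg.norm(mid34 - mid78)

        ratio = pad_len(means["urban"]) / pad_len(means["forest"])
        assert ratio == pytest.approx(3.61 / 3.20, abs=0.05)

    def test_empty_group_rejected(self, rng):
        groups = pd.Series(pd.Categorical(["a", "a", "a"],
                                          categories=["a", "b"]))
        with pytest.raises(ValueError, match="empty group"):
            ss.group_mean_shapes(rng.normal(size=(3, 4, 2)), groups)


class TestCva:
    def test_two_groups_single_axis(self, calib_aligned, calib_meta):
        res = ss.cva(calib_aligned, calib_meta.habitat)
        assert res.scores.shape[1] == 1
        assert res.axes_scorespace.shape[0] == 1

    def test_three_groups_two_axes(self, rng):
        y = rng.normal(size=(60, 20))
        groups = ["a", "b", "c"] * 20
        res = ss.cva(y, groups)
        assert res.scores.shape[1] == 2

    def test_null_groups_small_separation(self, rng):
        y = rng.normal(size=(200, 20))
        groups = ["a", "b"] * 100
        res = ss.cva(y, groups)
        within_sd = 1.0  # axes are scaled to unit within-group variance
        assert res.separation < 2 * within_sd

    def test_strong_effect_separates_groups(self, scheme):
        spec = tm.PopulationSpec.paper_calibrated(n_total=80, seed=31,
                                                  noise_sd_mm=0.005)
        strong = {
            "urban": tm.ToeTemplateParams(pad_len_mm=4.6, pad_width_mm=1.9),
            "forest": tm.ToeTemplateParams(pad_len_mm=3.0, pad_width_mm=1.7),
        }
        object.__setattr__(spec, "habitat_means", strong)
        sample = tm.sample_population(spec, scheme)
        from toemorph.pipeline import prepare_configurations

        configs = prepare_configurations(sample.to_dataset(), scheme)
        aligned = tm.gpa_align(configs, scheme, slide=False)
        meta = sample.metadata.reset_index(drop=True)
        res = ss.cva(aligned, meta.habitat)
        urban = res.scores[(meta.habitat == "urban").to_numpy(), 0]
        forest = res.scores[(meta.habitat == "forest").to_numpy(), 0]
        assert urban.min() > forest.max() or forest.min() > urban.max()

    def test_separation_invariant_to_scorespace_rescaling(self, calib_aligned,
                                                          calib_meta):
        """CVA separation does not depend on an affine re-scoring of the
        retained PC basis (the within-group metric absorbs it)."""
        y = calib_aligned.flat()
        res1 = ss.cva(y, calib_meta.habitat)
        res2 = ss.cva(y * 3.0, calib_meta.habitat)
        assert res1.separation == pytest.approx(res2.separation, rel=1e-6)

    def test_single_group_rejected(self, rng):
        with pytest.raises(ValueError):
            ss.cva(rng.normal(size=(10, 4)), ["a"] * 10)


class TestCvaNull:
    def test_deterministic_given_seed(self, calib_aligned, calib_meta):
        r1 = ss.cva_randomization_null(calib_aligned, calib_meta.habitat,
                                       n_rand=10, seed=3)
        r2 = ss.cva_randomization_null(calib_aligned, calib_meta.habitat,
                                       n_rand=10, seed=3)
        assert r1.null_summary["mean"] == r2.null_summary["mean"]
        assert r1.null_summary["max"] == r2.null_summary["max"]

    def test_calibrated_effect_exceeds_null(self, calib_aligned, calib_meta):
        res = ss.cva_randomization_null(calib_aligned, calib_meta.habitat,
                                        n_rand=50, seed=3)
        ns = res.null_summary
        assert res.separation > ns["mean"] + 2 * ns["sd"]

    def test_too_few_randomizations(self, calib_aligned, calib_meta):
        with pytest.raises(ValueError):
            ss.cva_randomization_null(calib_aligned, calib_meta.habitat,
                                      n_rand=1, seed=0)


class TestAllometry:
    def test_isometric_scaling_shows_no_allometry(self, scheme, rng):
        """Same shape, varied scale: alignment removes size entirely, so
        the shape-size regression finds nothing."""
        stripped = tm.strip_anchor_semilandmarks(
            tm.build_template(tm.ToeTemplateParams(), scheme), scheme)
        configs = []
        for i in range(30):
            c = stripped.copy()
            c.specimen_id = f"s{i}"
            scale = rng.uniform(0.7, 1.5)
            c.fixed_points = c.fixed_points * scale + rng.normal(0, 1e-6,
                                                                 (19, 2))
            c.curve_points = [p * scale for p in c.curve_points]
            configs.append(c)
        aligned = tm.gpa_align(configs, scheme, slide=False)
        res, corrs = ss.allometry_test(aligned, aligned.centroid_sizes,
                                       n_perm=99, seed=0)
        assert res.table.loc["log_size", "R2"] < 0.2

    def test_size_coupled_shape_detected(self, scheme, rng):
        """Pad length grows with size -> significant shape-size association."""
        configs = []
        for i in range(40):
            scale = rng.uniform(0.7, 1.5)
            p = tm.ToeTemplateParams(pad_len_mm=3.2 * scale**2)
            c = tm.build_template(p, scheme, specimen_id=f"s{i}")
            c.fixed_points = c.fixed_points * scale
            c.curve_points = [q * scale for q in c.curve_points]
            configs.append(tm.strip_anchor_semilandmarks(c, scheme))
        aligned = tm.gpa_align(configs, scheme, slide=False)
        res, corrs = ss.allometry_test(aligned, aligned.centroid_sizes,
                                       n_perm=199, seed=0)
        assert res.p_value("log_size") <= 0.05
        assert max(abs(v) for v in corrs.values()) > 0.5

    def test_reports_pc_correlations_for_any_size_definition(
            self, calib_aligned, calib_meta):
        for size in (calib_aligned.centroid_sizes,
                     calib_meta.svl_mm.to_numpy(),
                     calib_meta.measured_pad_area_mm2.to_numpy()):
            _, corrs = ss.allometry_test(calib_aligned, size, n_perm=9, seed=0)
            assert set(corrs) == {"PC1", "PC2", "PC3"}

    def test_nonpositive_size_rejected(self, calib_aligned):
        bad = np.ones(calib_aligned.n_specimens)
        bad[0] = 0.0
        with pytest.raises(ValueError):
            ss.allometry_test(calib_aligned, bad)
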