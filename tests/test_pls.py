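import numpy as np
import pytest

from wgctraj.core_io import VertexMap
from wgctraj.pls import (
    GroupDesign,
    bootstrap_bsr,
    brain_scores,
    bsr_band_ttest,
    conjunction,
    mean_centered_pls,
    orient_to_contrast,
    permutation_test,
    run_pls,
)


def four_group_design(n_per_group=5):
    labels = np.repeat(["ASD_A", "TD_A", "ASD_B", "TD_B"], n_per_group)
    return GroupDesign(labels, ("ASD_A", "TD_A", "ASD_B", "TD_B"))


class TestMeanCenteredPls:
    def test_identical_groups_have_zero_first_singular_value(self):
        rng = np.random.default_rng(0)
        block = rng.standard_normal((4, 6))
        X = np.vstack([block, block])  # two identical groups of 4
        design = GroupDesign(np.repeat(["g1", "g2"], 4))
        res = mean_centered_pls(X, design)
        assert res.singular_values[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_svd_oracle_on_toy(self):
        # 4 groups x 2 vertices with hand-computable means
        X = np.array([
            [1.0, 0.0], [3.0, 2.0],        # g1 means (2, 1)
            [4.0, 1.0], [6.0, 3.0],        # g2 means (5, 2)
            [0.0, 4.0], [2.0, 6.0],        # g3 means (1, 5)
            [7.0, 7.0], [9.0, 9.0],        # g4 means (8, 8)
        ])
        design = GroupDesign(np.repeat(["g1", "g2", "g3", "g4"], 2))
        res = mean_centered_pls(X, design)
        M = np.array([[2.0, 1.0], [5.0, 2.0], [1.0, 5.0], [8.0, 8.0]])
        S_oracle = np.linalg.svd(M - M.mean(axis=0), compute_uv=False)
        np.testing.assert_allclose(res.singular_values, S_oracle, atol=1e-10)

    def test_covariance_explained_sums_to_one(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((20, 9))
        res = mean_centered_pls(X, four_group_design())
        assert res.covariance_explained.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(res.singular_values) <= 1e-12)

    def test_svd_reconstruction(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 12))
        design = four_group_design()
        res = mean_centered_pls(X, design)
        M = np.vstack([X[design.indices(g)].mean(axis=0) for g in design.group_order])
        Mc = M - M.mean(axis=0)
        recon = res.design_vectors @ np.diag(res.singular_values) @ res.vertex_saliences.T
        np.testing.assert_allclose(recon, Mc, atol=1e-8)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty group"):
            GroupDesign(np.repeat(["a", "b"], 3), ("a", "b", "c"))

    def test_degenerate_rank_zero_flagged(self):
        X = np.ones((8, 5))
        res = mean_centered_pls(X, GroupDesign(np.repeat(["a", "b"], 4)))
        assert res.degenerate
        np.testing.assert_array_equal(res.singular_values, 0.0)


class TestPermutation:
    def planted(self, rng, effect=1.0, n=6, V=12):
        X = rng.standard_normal((4 * n, V)) * 0.01
        X[: 2 * n] += effect  # first two groups strongly shifted
        labels = np.repeat(["a", "b", "c", "d"], n)
        return X, GroupDesign(labels)

    def test_strong_effect_reaches_minimum_p(self):
        X, design = self.planted(np.random.default_rng(3))
        p = permutation_test(X, design, n_perm=99, seed=0)
        assert p[0] == pytest.approx(1.0 / 100.0)

    def test_deterministic_for_fixed_seed(self):
        X, design = self.planted(np.random.default_rng(4), effect=0.0)
        p1 = permutation_test(X, design, n_perm=50, seed=7)
        p2 = permutation_test(X, design, n_perm=50, seed=7)
        np.testing.assert_array_equal(p1, p2)

    def test_null_p_values_roughly_uniform(self):
        # smaller version of the calibration suite in the acceptance tests
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(60):
            X, design = self.planted(rng, effect=0.0)
            ps.append(permutation_test(X, design, n_perm=99, seed=rng.integers(2**31))[0])
        grid = np.linspace(0.05, 0.95, 10)
        emp = np.array([(np.array(ps) <= q).mean() for q in grid])
        assert np.abs(emp - grid).max() < 0.18


class TestBootstrap:
    def test_degenerate_groups_mask_bsr_not_infinite(self):
        X = np.vstack([np.tile([1.0, 2.0, 3.0], (4, 1)), np.tile([2.0, 1.0, 0.0], (4, 1))])
        design = GroupDesign(np.repeat(["a", "b"], 4))
        bsr, _ = bootstrap_bsr(X, design, n_boot=20, seed=0)
        assert np.isnan(bsr).all()

    def test_planted_vertices_have_larger_bsr(self):
        rng = np.random.default_rng(6)
        hits = 0
        for rep in range(10):
            X = rng.standard_normal((24, 30))
            X[:12, :10] += 1.5  # effect confined to vertices 0..9
            design = GroupDesign(np.repeat(["a", "b"], 12))
            bsr, _ = bootstrap_bsr(X, design, n_boot=100, seed=rep)
            inside = np.nanmean(np.abs(bsr[:10, 0]))
            outside = np.nanmean(np.abs(bsr[10:, 0]))
            hits += inside > outside
        assert hits >= 9

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((20, 8))
        design = four_group_design()
        a = bootstrap_bsr(X, design, n_boot=30, seed=3)[0]
        b = bootstrap_bsr(X, design, n_boot=30, seed=3)[0]
        np.testing.assert_array_equal(a, b)

    def test_bsr_sign_equals_salience_sign(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((20, 8)) + np.repeat(
            rng.standard_normal((4, 8)), 5, axis=0
        )
        design = four_group_design()
        res = mean_centered_pls(X, design)
        bsr, _ = bootstrap_bsr(X, design, n_boot=80, seed=1)
        ok = np.isfinite(bsr)
        assert np.all(np.sign(bsr[ok]) == np.sign(res.vertex_saliences[ok]))


class TestBrainScores:
    def result_with_bsr(self, X, design):
        res = mean_centered_pls(X, design)
        res.bsr, _ = bootstrap_bsr(X, design, n_boot=40, seed=0)
        return res

    def test_grand_mean_subject_scores_zero(self):
        rng = np.random.default_rng(9)
        X = rng.standard_normal((20, 6))
        design = four_group_design()
        res = self.result_with_bsr(X, design)
        X2 = X.copy()
        # a subject equal to the mean of everyone else IS the grand mean
        X2[0] = X2[1:].mean(axis=0)
        scores = brain_scores(X2, res)
        np.testing.assert_allclose(scores[0], 0.0, atol=1e-10)

    def test_doubling_bsr_doubles_scores(self):
        rng = np.random.default_rng(10)
        X = rng.standard_normal((20, 6))
        res = self.result_with_bsr(X, four_group_design())
        base = brain_scores(X, res)
        res.bsr = 2.0 * res.bsr
        np.testing.assert_allclose(brain_scores(X, res), 2.0 * base, rtol=1e-12)

    def test_groups_separate_on_planted_pattern(self, small_study):
        scores = small_study.pls_lngt.brain_scores[:, 0]
        dx = small_study.lngt_cohort.one_row_per_subject().df["dx"].to_numpy()
        assert scores[dx == "ASD"].mean() * scores[dx == "TD"].mean() < 0

    def test_missing_bsr_is_error(self):
        rng = np.random.default_rng(11)
        X = rng.standard_normal((20, 6))
        res = mean_centered_pls(X, four_group_design())
        with pytest.raises(RuntimeError, match="bootstrap"):
            brain_scores(X, res)


class TestConjunction:
    def test_all_negative_maps(self):
        a = VertexMap(-np.ones(10))
        b = VertexMap(-np.ones(10))
        assert conjunction(a, b).fractions["both_negative"] == 1.0

    def test_swap_symmetry(self):
        rng = np.random.default_rng(12)
        a = VertexMap(rng.standard_normal(200))
        b = VertexMap(rng.standard_normal(200))
        f_ab = conjunction(a, b).fractions
        f_ba = conjunction(b, a).fractions
        assert f_ab["crsc_pos_lngt_neg"] == f_ba["lngt_pos_crsc_neg"]
        assert f_ab["both_negative"] == f_ba["both_negative"]
        assert f_ab["both_positive"] == f_ba["both_positive"]

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(13)
        f = conjunction(
            VertexMap(rng.standard_normal(77)), VertexMap(rng.standard_normal(77))
        ).fractions
        assert sum(f.values()) == pytest.approx(1.0)

    def test_zero_counts_as_negative(self):
        f = conjunction(VertexMap([0.0]), VertexMap([-1.0])).fractions
        assert f["both_negative"] == 1.0


class TestStaticControl:
    def test_static_wgc_pls_is_non_significant_in_most_replicates(self):
        """Single-timepoint WGC (no age-change information) carries no
        diagnostic signal under the default generator: the permutation test
        on the dx/scanner PLS should be non-significant in most replicates."""
        from wgctraj.pls import GroupDesign
        from wgctraj.synthetic_data import (
            SimulationSpec,
            make_effect_template,
            make_mesh,
            simulate_cross_sectional,
        )

        non_sig = 0
        n_rep = 8
        for i in range(n_rep):
            mesh = make_mesh(80, seed=100 + i)
            tpl = make_effect_template(mesh, seed=100 + i)
            spec = SimulationSpec(n_vertices=80, rng_seed=200 + i)
            cohort, wgc = simulate_cross_sectional(spec, tpl)
            design = GroupDesign.from_cohort(cohort, by="dx_scanner")
            p = permutation_test(wgc.values, design, n_perm=49, seed=i)[0]
            non_sig += p > 0.05
        assert non_sig >= n_rep - 2


class TestReportingUtilities:
    def test_bsr_band_ttest_selects_extreme_band(self, small_study):
        out = bsr_band_ttest(
            small_study.pls_lngt.bsr[:, 0],
            small_study.lngt_angles,
            small_study.lngt_cohort.one_row_per_subject(),
            side="min",
        )
        assert 0 < out["n_vertices"] < small_study.lngt_angles.n_vertices
        # in the minimum-BSR band ASD decreases more than TD
        assert out["mean_asd"] < out["mean_td"]

    def test_orient_to_contrast_flips_consistently(self):
        rng = np.random.default_rng(14)
        X = rng.standard_normal((20, 8)) + np.repeat(
            rng.standard_normal((4, 8)), 5, axis=0
        )
        design = four_group_design()
        res = run_pls(X, design, n_perm=20, n_boot=30, seed=0)
        before = res.design_scores[:, 0].copy()
        contrast = -np.sign(before @ np.ones(4)) * np.ones(4) if (before @ np.ones(4)) != 0 else np.ones(4)
        salience_before = res.vertex_saliences[:, 0].copy()
        bsr_before = res.bsr[:, 0].copy()
        res = orient_to_contrast(res, contrast)
        flipped = res.design_scores[:, 0] @ contrast >= 0
        assert flipped
        if not np.allclose(res.design_scores[:, 0], before):
            np.testing.assert_allclose(res.vertex_saliences[:, 0], -salience_before)
            np.testing.assert_allclose(res.bsr[:, 0], -bsr_before, equal_nan=True)
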