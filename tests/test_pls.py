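"""Mean-centered and behavioral PLS: point estimates, permutation,
bootstrap, brain scores, and the algebraic invariants of the SVD."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import megpls as m
from megpls.errors import ConfigError, DataError


def _align_signs(A, B):
    """Flip columns of B to match the sign of A (SVD sign ambiguity)."""
    flips = np.sign(np.einsum("ij,ij->j", A, B))
    flips[flips == 0] = 1
    return B * flips


class TestMeanCenteredPointEstimates:
    def test_identical_group_means_give_zero_singular_values(self):
        X = np.tile([0.3, 0.7], (6, 1))
        res = m.MeanCenteredPLS(X, ["a", "a", "b", "b", "c", "c"]).fit(n_perm=0, n_boot=0)
        assert np.allclose(res.singular_values, 0, atol=1e-12)

    def test_two_groups_one_feature_closed_form(self):
        # group means 0 and 2 -> centered row (-1, 1), singular value sqrt(2)
        X = np.array([[0.0], [0.0], [2.0], [2.0]])
        res = m.MeanCenteredPLS(X, ["a", "a", "b", "b"]).fit(n_perm=0, n_boot=0)
        assert res.singular_values[0] == pytest.approx(np.sqrt(2), abs=1e-12)
        assert np.abs(res.saliences[0, 0]) == pytest.approx(1.0, abs=1e-12)
        assert np.abs(res.contrasts[:, 0]) == pytest.approx(
            [1 / np.sqrt(2)] * 2, abs=1e-12
        )
        # contrast elements of a two-group LV are antisymmetric
        assert res.contrasts[0, 0] == pytest.approx(-res.contrasts[1, 0], abs=1e-12)

    def test_three_group_fixture_matches_dense_svd_oracle(self, toy_brain):
        X, groups = toy_brain
        res = m.MeanCenteredPLS(X, groups).fit(n_perm=0, n_boot=0)
        # oracle: group means, grand-mean centering and SVD, done directly
        means = np.stack([X[groups == g].mean(axis=0) for g in ("ELGA", "VLGA", "Term")], axis=1)
        Mc = means - means.mean(axis=1, keepdims=True)
        U, s, Vt = np.linalg.svd(Mc, full_matrices=False)
        assert np.allclose(res.singular_values, s[:2], atol=1e-10)
        assert np.allclose(_align_signs(res.saliences, U[:, :2]), res.saliences, atol=1e-10)
        assert np.allclose(_align_signs(res.contrasts, Vt[:2].T), res.contrasts, atol=1e-10)

    def test_energy_equals_squared_frobenius_norm(self, toy_brain):
        X, groups = toy_brain
        res = m.MeanCenteredPLS(X, groups).fit(n_perm=0, n_boot=0)
        means = np.stack([X[groups == g].mean(axis=0) for g in ("ELGA", "VLGA", "Term")], axis=1)
        Mc = means - means.mean(axis=1, keepdims=True)
        assert np.sum(res.singular_values**2) == pytest.approx(
            np.sum(Mc**2), abs=1e-10
        )

    def test_invariant_to_subject_order_and_feature_offsets(self, toy_brain):
        X, groups = toy_brain
        base = m.MeanCenteredPLS(X, groups).fit(n_perm=0, n_boot=0)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(X))
        shuffled = m.MeanCenteredPLS(X[perm], groups[perm]).fit(n_perm=0, n_boot=0)
        assert np.allclose(base.singular_values, shuffled.singular_values, atol=1e-12)
        shifted = m.MeanCenteredPLS(X + np.array([5.0, -2.0, 0.25, 100.0]), groups).fit(
            n_perm=0, n_boot=0
        )
        assert np.allclose(base.singular_values, shifted.singular_values, atol=1e-10)
        assert np.allclose(base.saliences, _align_signs(base.saliences, shifted.saliences), atol=1e-10)

    def test_group_of_one_is_rejected(self):
        with pytest.raises(DataError, match="fewer than 2"):
            m.MeanCenteredPLS(np.zeros((3, 2)), ["a", "a", "b"])

    def test_singular_vectors_have_unit_norm(self, toy_brain):
        X, groups = toy_brain
        res = m.MeanCenteredPLS(X, groups).fit(n_perm=0, n_boot=0)
        assert np.allclose(np.linalg.norm(res.saliences, axis=0), 1, atol=1e-12)
        assert np.allclose(np.linalg.norm(res.contrasts, axis=0), 1, atol=1e-12)
        assert np.all(np.diff(res.singular_values) <= 1e-15)


class TestBehavioralPointEstimates:
    def test_orthogonal_behavior_gives_zero_singular_values(self):
        z1 = np.array([1.0, -1.0, 0.0, 0.0]) / np.sqrt(2)
        z2 = np.array([0.0, 0.0, 1.0, -1.0]) / np.sqrt(2)
        res = m.BehavioralPLS(z1[:, None], z2[:, None]).fit(n_perm=0, n_boot=0)
        assert np.allclose(res.singular_values, 0, atol=1e-12)

    def test_exact_planted_correlation_is_the_singular_value(self):
        # y = -0.5 z1 + sqrt(0.75) z2 has sample correlation exactly -0.5
        z1 = np.array([1.0, -1.0, 0.0, 0.0]) / np.sqrt(2)
        z2 = np.array([0.0, 0.0, 1.0, -1.0]) / np.sqrt(2)
        y = -0.5 * z1 + np.sqrt(0.75) * z2
        res = m.BehavioralPLS(z1[:, None], y[:, None]).fit(n_perm=0, n_boot=0)
        assert res.singular_values[0] == pytest.approx(0.5, abs=1e-12)
        assert np.abs(res.contrasts[0, 0]) == pytest.approx(1.0, abs=1e-12)

    def test_copied_variable_dominates_lv1_and_matches_dense_oracle(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((12, 4))
        Y = np.column_stack([X[:, 2], rng.standard_normal(12)])
        res = m.BehavioralPLS(X, Y).fit(n_perm=0, n_boot=0)
        assert np.abs(res.contrasts[0, 0]) > 0.95
        # dense oracle: z-score, correlation matrix, SVD
        Zx = (X - X.mean(0)) / X.std(0)
        Zy = (Y - Y.mean(0)) / Y.std(0)
        R = Zx.T @ Zy / len(X)
        U, s, Vt = np.linalg.svd(R, full_matrices=False)
        assert np.allclose(res.singular_values, s, atol=1e-10)
        assert np.allclose(res.saliences, _align_signs(res.saliences, U), atol=1e-10)
        assert np.allclose(res.contrasts, _align_signs(res.contrasts, Vt.T), atol=1e-10)
        assert np.sum(res.singular_values**2) == pytest.approx(np.sum(R**2), abs=1e-10)

    def test_constant_column_is_named_in_the_error(self):
        X = np.random.default_rng(0).standard_normal((6, 2))
        Y = np.ones((6, 1))
        with pytest.raises(DataError, match="outcome_a"):
            m.BehavioralPLS(X, Y, variable_names=["outcome_a"])

    @given(st.floats(min_value=0.05, max_value=20.0), st.floats(-50, 50))
    def test_invariant_to_affine_rescaling_of_behavior(self, a, b):
        rng = np.random.default_rng(31)
        X = rng.standard_normal((15, 3))
        Y = rng.standard_normal((15, 2))
        base = m.BehavioralPLS(X, Y).fit(n_perm=0, n_boot=0)
        scaled = m.BehavioralPLS(X, np.column_stack([a * Y[:, 0] + b, Y[:, 1]])).fit(
            n_perm=0, n_boot=0
        )
        assert np.allclose(base.singular_values, scaled.singular_values, atol=1e-10)
        assert np.allclose(
            np.abs(base.contrasts), np.abs(scaled.contrasts), atol=1e-10
        )

    def test_misaligned_rows_are_rejected(self):
        with pytest.raises(ConfigError, match="aligned"):
            m.BehavioralPLS(np.zeros((5, 2)), np.zeros((4, 1)))


class TestPermutation:
    def test_counting_rule_with_dominant_effect(self):
        rng = np.random.default_rng(7)
        n = 24
        groups = np.repeat(["a", "b"], n // 2)
        X = rng.standard_normal((n, 3)) * 0.01
        X[groups == "b"] += 10.0  # effect no permutation can reach
        res = m.MeanCenteredPLS(X, groups).fit(n_perm=499, n_boot=0, seed=0)
        assert res.p_values[0] == pytest.approx(1 / 500)

    def test_label_invariant_data_gives_p_one(self):
        X = np.tile([0.2, 0.5, 0.3], (8, 1))
        res = m.MeanCenteredPLS(X, ["a"] * 4 + ["b"] * 4).fit(n_perm=199, n_boot=0, seed=0)
        assert res.p_values[0] == 1.0

    def test_low_permutation_count_warns(self):
        X = np.random.default_rng(0).standard_normal((8, 2))
        with pytest.warns(UserWarning, match="n_perm"):
            m.MeanCenteredPLS(X, ["a"] * 4 + ["b"] * 4).fit(n_perm=50, n_boot=0, seed=0)


class TestBootstrap:
    def test_zero_feature_has_zero_bootstrap_ratio(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((12, 3))
        X[:, 1] = 0.0
        groups = np.repeat(["a", "b"], 6)
        res = m.MeanCenteredPLS(X, groups).fit(n_perm=0, n_boot=150, seed=1)
        assert res.saliences[1, 0] == 0
        assert res.bootstrap_ratios[1, 0] == 0

    def test_degenerate_groups_give_zero_ratios_and_point_cis(self):
        # all subjects within a group identical -> every resample identical
        X = np.array([[1.0, 2.0]] * 4 + [[3.0, 5.0]] * 4)
        res = m.MeanCenteredPLS(X, ["a"] * 4 + ["b"] * 4).fit(n_perm=0, n_boot=120, seed=2)
        assert np.all(res.bootstrap_ratios == 0)
        assert np.allclose(res.contrast_cis[:, :, 0], res.contrasts, atol=1e-12)
        assert np.allclose(res.contrast_cis[:, :, 1], res.contrasts, atol=1e-12)

    def test_planted_effect_sign_recovery_in_top_decile(self, planted_cohort):
        bpm, cohort, truth = planted_cohort
        res = m.MeanCenteredPLS.from_band_power(bpm, cohort).fit(n_perm=0, n_boot=300, seed=5)
        sal = truth.planted_salience.ravel()
        top = np.abs(sal) >= np.quantile(np.abs(sal), 0.9)
        bsr = res.bootstrap_ratios[:, 0]
        orient = np.sign(np.corrcoef(bsr, sal)[0, 1])
        agreement = np.mean(np.sign(orient * bsr[top]) == np.sign(sal[top]))
        assert agreement >= 0.90


class TestBrainScores:
    @pytest.mark.parametrize("case", ["axis", "linearity", "oracle"])
    def test_brain_scores(self, case):
        rng = np.random.default_rng(9)
        if case == "axis":
            X = np.eye(4)
            sal = np.zeros((4, 1))
            sal[0, 0] = 1.0
            assert np.allclose(m.brain_scores(X, sal)[:, 0], X[:, 0])
        elif case == "linearity":
            X = rng.standard_normal((5, 3))
            sal = rng.standard_normal((3, 2))
            doubled = X.copy()
            doubled[2] *= 2
            assert np.allclose(
                m.brain_scores(doubled, sal)[2], 2 * m.brain_scores(X, sal)[2]
            )
        else:
            X = rng.standard_normal((6, 4))
            sal = rng.standard_normal((4, 2))
            scores = m.brain_scores(X, sal)
            oracle = np.zeros((6, 2))
            for i in range(6):
                for k in range(2):
                    acc = 0.0
                    for j in range(4):
                        acc += X[i, j] * sal[j, k]
                    oracle[i, k] = acc
            assert np.allclose(scores, oracle, atol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ConfigError):
            m.brain_scores(np.zeros((3, 4)), np.zeros((5, 1)))

    def test_group_mean_scores_reproduce_contrast_times_singular_value(self):
        # noise-free: every subject sits exactly on its group mean
        rng = np.random.default_rng(15)
        means = rng.standard_normal((6, 3))  # features x groups
        X = np.repeat(means.T, 2, axis=0)    # 2 subjects per group
        groups = np.repeat(["g1", "g2", "g3"], 2)
        res = m.MeanCenteredPLS(X, groups).fit(n_perm=0, n_boot=0)
        scores = res.brain_scores
        g_scores = np.stack([scores[groups == g].mean(axis=0) for g in ("g1", "g2", "g3")])
        centered = g_scores - g_scores.mean(axis=0, keepdims=True)
        expected = res.contrasts * res.singular_values[None, :]
        assert np.allclose(centered, expected, atol=1e-8)


class TestResultsObject:
    def test_summary_and_save_round_trip(self, toy_brain, tmp_path):
        X, groups = toy_brain
        res = m.MeanCenteredPLS(X, groups).fit(n_perm=120, n_boot=120, seed=0)
        text = res.summary()
        assert "MeanCenteredPLS" in text and "LV" in text
        res.save(tmp_path / "out")
        for name in (
            "singular_values.csv", "contrasts.csv", "saliences.csv",
            "bootstrap_ratios.csv", "brain_scores.csv", "p_values.csv", "manifest.json",
        ):
            assert (tmp_path / "out" / name).exists()

    def test_procrustes_alignment_runs(self, toy_brain):
        X, groups = toy_brain
        res = m.MeanCenteredPLS(X, groups).fit(n_perm=0, n_boot=120, seed=3, procrustes=True)
        assert np.isfinite(res.bootstrap_ratios).all()

    def test_within_group_correlation_variant(self):
        rng = np.random.default_rng(18)
        X = rng.standard_normal((18, 4))
        Y = rng.standard_normal((18, 2))
        groups = np.repeat(["a", "b", "c"], 6)
        res = m.BehavioralPLS(
            X, Y, groups=groups, variable_names=["u", "v"], within_group_correlation=True
        ).fit(n_perm=0, n_boot=0)
        assert len(res.contrast_labels) == 6  # 3 groups x 2 variables
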