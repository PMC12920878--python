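"""Rank AUC, DeLong test, fold rule, matrix and sweep mechanics."""

import subprocess
import textwrap

import numpy as np
import pytest
from scipy.stats import norm

from roiaudit.evaluation import (
    AUCMatrix,
    DilationCurve,
    aggregate_significance,
    auc,
    auc_permutation_pvalue,
    cross_masking_evaluation,
    delong_test,
    delong_variance,
    dilation_sweep,
)


def pairwise_auc_oracle(scores, labels):
    """O(n^2) pair-count definition of the AUC."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfectly_ordered_scores(self):
        assert auc(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1])) == 1.0

    def test_all_ties_give_half(self):
        assert auc(np.ones(10), np.array([0, 1] * 5)) == 0.5

    def test_matches_pairwise_oracle_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            n = int(rng.integers(10, 200))
            scores = rng.integers(0, 10, size=n).astype(float)  # many ties
            labels = rng.integers(0, 2, size=n)
            if labels.sum() in (0, n):
                labels[:2] = [0, 1]
            assert auc(scores, labels) == pytest.approx(
                pairwise_auc_oracle(scores, labels), abs=1e-12
            )

    def test_complement_symmetry_for_tie_free_scores(self):
        rng = np.random.default_rng(1)
        scores = rng.permutation(100).astype(float)
        labels = (rng.random(100) < 0.4).astype(int)
        assert auc(scores, labels) + auc(-scores, labels) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auc(np.array([0.1, 0.2]), np.array([1, 1]))


class TestDelong:
    def test_identical_scores_give_p_one(self):
        rng = np.random.default_rng(2)
        s = rng.random(50)
        y = (rng.random(50) < 0.5).astype(int)
        a, b, p = delong_test(s, s, y)
        assert a == b and p == 1.0

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(3)
        y = (rng.random(80) < 0.5).astype(int)
        sa = rng.random(80) + 0.5 * y
        sb = rng.random(80)
        a1, b1, p1 = delong_test(sa, sb, y)
        a2, b2, p2 = delong_test(sb, sa, y)
        assert (a1, b1) == (b2, a2)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            delong_test(np.zeros(5), np.zeros(6), np.array([0, 1, 0, 1, 0]))

    def test_null_calibration_rejection_rate(self):
        """Independent uniform scores: the test should reject at ~alpha."""
        rng = np.random.default_rng(4)
        n, reps = 200, 1000
        rejections = 0
        for _ in range(reps):
            y = np.zeros(n, dtype=int)
            y[: n // 2] = 1
            sa, sb = rng.random(n), rng.random(n)
            _, _, p = delong_test(sa, sb, y)
            rejections += p < 0.05
        assert 0.035 <= rejections / reps <= 0.065

    def test_power_on_separated_binormal_scores(self):
        """AUC 0.9 vs 0.6 at n=200 should be detected almost always."""
        rng = np.random.default_rng(5)
        mu_a = np.sqrt(2) * norm.ppf(0.9)
        mu_b = np.sqrt(2) * norm.ppf(0.6)
        detected = 0
        reps = 200
        for _ in range(reps):
            y = np.zeros(200, dtype=int)
            y[:100] = 1
            sa = rng.standard_normal(200) + mu_a * y
            sb = rng.standard_normal(200) + mu_b * y
            _, _, p = delong_test(sa, sb, y)
            detected += p < 0.001
        assert detected / reps >= 0.95

    def test_single_auc_variance_close_to_empirical(self):
        """DeLong variance of one AUC tracks the Monte-Carlo variance of the
        binormal sampling distribution."""
        rng = np.random.default_rng(6)
        mu = np.sqrt(2) * norm.ppf(0.8)
        aucs, vars_ = [], []
        for _ in range(400):
            y = np.zeros(150, dtype=int)
            y[:75] = 1
            s = rng.standard_normal(150) + mu * y
            aucs.append(auc(s, y))
            vars_.append(delong_variance(s, y))
        assert np.mean(vars_) == pytest.approx(np.var(aucs), rel=0.25)

    def test_matches_r_proc_reference(self, tmp_path):
        """Cross-check one case against the pROC implementation in R."""
        rng = np.random.default_rng(7)
        y = np.zeros(60, dtype=int)
        y[:25] = 1
        sa = rng.random(60) + 0.6 * y
        sb = rng.random(60) + 0.3 * y
        a, b, p = delong_test(sa, sb, y)
        script = tmp_path / "delong.R"
        script.write_text(
            textwrap.dedent(
                f"""
                suppressMessages(library(pROC))
                y <- c({','.join(map(str, y))})
                sa <- c({','.join(f'{v:.17g}' for v in sa)})
                sb <- c({','.join(f'{v:.17g}' for v in sb)})
                r <- roc.test(roc(y, sa, quiet=TRUE), roc(y, sb, quiet=TRUE),
                              method="delong")
                cat(sprintf("%.12f %.12f %.12f", r$estimate[1], r$estimate[2], r$p.value))
                """
            )
        )
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        ref_a, ref_b, ref_p = map(float, out.stdout.split())
        assert a == pytest.approx(ref_a, abs=1e-9)
        assert b == pytest.approx(ref_b, abs=1e-9)
        assert p == pytest.approx(ref_p, abs=1e-9)


class TestFoldRule:
    @pytest.mark.parametrize(
        "p_values,expected",
        [
            ([0.01, 0.02, 0.04, 0.9, 0.9], True),
            ([0.04, 0.04, 0.9, 0.9, 0.9], False),
            ([0.05, 0.05, 0.05, 0.05, 0.05], False),  # strict inequality
            ([0.049, 0.049, 0.049, 0.9, 0.9], True),
        ],
    )
    def test_boundary_cases(self, p_values, expected):
        assert aggregate_significance(p_values) is expected

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            aggregate_significance([])


class TestPermutationNull:
    def test_informative_scores_get_small_p(self):
        rng = np.random.default_rng(8)
        y = np.array([0, 1] * 50)
        scores = y + 0.1 * rng.standard_normal(100)
        p = auc_permutation_pvalue(scores, y, n_permutations=200, rng=9)
        assert p < 0.01

    def test_random_scores_get_large_p(self):
        rng = np.random.default_rng(10)
        y = np.array([0, 1] * 50)
        ps = [
            auc_permutation_pvalue(rng.random(100), y, n_permutations=100, rng=seed)
            for seed in range(20)
        ]
        assert np.mean(np.asarray(ps) < 0.05) <= 0.2


class _ConstantModel:
    """Scores equal to the mean image intensity (deterministic stand-in)."""

    def predict_proba(self, images):
        return np.asarray(images).mean(axis=(1, 2))[:, None]


class TestMatrixAndSweepMechanics:
    def test_matrix_grid_fully_populated(self):
        rng = np.random.default_rng(11)
        images = rng.random((30, 32, 32))
        masks = np.zeros((30, 32, 32), dtype=np.uint8)
        masks[:, 8:24, 8:24] = 1
        labels = (rng.random(30) < 0.5).astype(int)
        labels[:2] = [0, 1]
        models = {
            (s, f): _ConstantModel()
            for s in ["FULL", "NO_ROI", "NO_ROI_BB", "ONLY_ROI", "ONLY_ROI_BB"]
            for f in range(5)
        }
        matrix = cross_masking_evaluation(models, images, masks, labels)
        assert matrix.mean.shape == (5, 5, 1)
        assert np.isfinite(matrix.mean).all()
        df = matrix.to_dataframe()
        assert len(df) == 25

    def test_missing_model_raises(self):
        with pytest.raises(KeyError, match="NO_ROI"):
            cross_masking_evaluation(
                {("FULL", f): _ConstantModel() for f in range(5)},
                np.zeros((4, 8, 8)),
                np.ones((4, 8, 8), dtype=np.uint8),
                np.array([0, 1, 0, 1]),
            )

    def test_sweep_factor_zero_equals_base_evaluation(self):
        rng = np.random.default_rng(12)
        images = rng.random((20, 32, 32))
        masks = np.zeros((20, 32, 32), dtype=np.uint8)
        masks[:, 10:20, 10:20] = 1
        labels = np.array([0, 1] * 10)
        models = [_ConstantModel()]
        curve = dilation_sweep(models, images, masks, labels, "NO_ROI", [0, 3], "all")
        from roiaudit.masking import apply_strategy

        base = np.stack([apply_strategy(i, m, "NO_ROI") for i, m in zip(images, masks)])
        expected = auc(models[0].predict_proba(base)[:, 0], labels)
        assert curve.mean[0, 0] == pytest.approx(expected)

    def test_sweep_to_all_black_hits_chance(self):
        rng = np.random.default_rng(13)
        images = rng.random((30, 16, 16))
        masks = np.zeros((30, 16, 16), dtype=np.uint8)
        masks[:, 6:10, 6:10] = 1
        labels = np.array([0, 1] * 15)
        curve = dilation_sweep(
            [_ConstantModel()], images, masks, labels, "NO_ROI", [0, 23], "all"
        )
        # factor >= image diagonal blacks out everything: AUC is the tie value
        assert curve.mean[1, 0] == pytest.approx(0.5)

    def test_sweep_unsorted_factors_rejected(self):
        with pytest.raises(ValueError):
            dilation_sweep(
                [_ConstantModel()], np.zeros((4, 8, 8)),
                np.ones((4, 8, 8), dtype=np.uint8), np.array([0, 1, 0, 1]),
                "NO_ROI", [5, 0], "all",
            )

    def test_sweep_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            dilation_sweep(
                [_ConstantModel()], np.zeros((4, 8, 8)),
                np.ones((4, 8, 8), dtype=np.uint8), np.zeros(4, dtype=int),
                "NO_ROI", [0], "positives_only",
            )

    def test_dilation_curve_requires_increasing_factors(self):
        with pytest.raises(ValueError):
            DilationCurve(
                factors=[5, 0], mean=np.zeros((2, 1)), sd=np.zeros((2, 1)),
                base="NO_ROI", subset="all", class_names=["disease"],
            )
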