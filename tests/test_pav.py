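"""PAV isotonic calibration and the ECE = ECEmin + ECEcal decomposition."""

import numpy as np
import pytest
from sklearn.isotonic import IsotonicRegression

from ecelab import (
    LRSet,
    PriorSpec,
    apply_pav_as_lrs,
    auc,
    cllr,
    cllr_decomposition,
    ece_decomposition,
    pav_calibrated_set,
    pav_fit,
)

from conftest import random_lr_set


def sklearn_isotonic(scores, labels):
    """Independent isotonic least-squares oracle (convex optimization in
    scikit-learn), evaluated at the training scores."""
    iso = IsotonicRegression(y_min=0, y_max=1, out_of_bounds="clip")
    return iso.fit(scores, labels).predict(scores)


class TestPavFit:
    def test_already_monotone_unchanged(self):
        iso = pav_fit([1.0, 2.0, 3.0], [0, 1, 1])
        np.testing.assert_allclose(iso.block_values, [0, 1, 1])

    def test_single_violator_pools(self):
        iso = pav_fit([1.0, 2.0], [1, 0])
        np.testing.assert_allclose(iso.block_values, [0.5, 0.5])

    def test_four_point_interleaved(self):
        iso = pav_fit([1.0, 2.0, 3.0, 4.0], [0, 1, 0, 1])
        np.testing.assert_allclose(iso.block_values, [0.0, 0.5, 0.5, 1.0])

    def test_ties_pooled_before_fit(self):
        """Equal scores form one block whatever the input order."""
        a = pav_fit([1.0, 1.0, 2.0], [0, 1, 1])
        b = pav_fit([1.0, 2.0, 1.0], [1, 1, 0])
        np.testing.assert_allclose(a.block_values, b.block_values)
        assert a.posterior(1.0) == pytest.approx(0.5)

    def test_block_values_are_label_means_and_monotone(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            s = random_lr_set(rng)
            iso = pav_fit(s.log_lr, s.label)
            assert np.all(np.diff(iso.block_values) >= -1e-15)
            # pooled-block means reproduce the overall label mean
            w = np.array([
                np.sum(s.log_lr == b) for b in iso.breakpoints
            ])
            assert np.average(iso.block_values, weights=w) == pytest.approx(
                s.label.mean(), rel=1e-12
            )

    def test_matches_sklearn_oracle_on_random_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            s = random_lr_set(rng, n_max=25)
            iso = pav_fit(s.log_lr, s.label)
            np.testing.assert_allclose(
                iso.posterior(s.log_lr),
                sklearn_isotonic(s.log_lr, s.label),
                atol=1e-9,
            )

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            s = random_lr_set(rng)
            iso = pav_fit(s.log_lr, s.label)
            refit = pav_fit(iso.posterior(s.log_lr), s.label)
            np.testing.assert_allclose(
                refit.posterior(iso.posterior(s.log_lr)),
                iso.posterior(s.log_lr),
                atol=1e-12,
            )

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            pav_fit([1.0, 2.0], [1, 1])

    def test_infinite_scores_sort_to_ends(self):
        iso = pav_fit([-np.inf, 0.0, np.inf], [0, 1, 1])
        np.testing.assert_allclose(iso.block_values, [0, 1, 1])


class TestApplyAsLrs:
    def test_neutral_block(self):
        iso = pav_fit([0.0, 0.0], [1, 0])  # one block at 0.5, odds 1
        assert apply_pav_as_lrs(iso, [0.0])[0] == pytest.approx(0.0, abs=1e-15)

    def test_odds_arithmetic(self):
        # pcal = 0.8 against empirical prior odds 1 -> LR 4
        scores = [1.0] * 5 + [2.0] * 5
        labels = [1, 0, 0, 0, 0] + [1, 1, 1, 1, 0]  # block means 0.2, 0.8
        iso = pav_fit(scores, labels)
        assert iso.empirical_prior_odds == pytest.approx(1.0)
        np.testing.assert_allclose(
            np.exp(apply_pav_as_lrs(iso, [2.0])), [4.0], rtol=1e-12
        )

    def test_odds_arithmetic_skewed_prior(self):
        # pcal = 0.8 against empirical prior odds 1/3 -> LR 12
        scores = [1.0] * 11 + [2.0] * 5
        labels = [0] * 11 + [1, 1, 1, 1, 0]
        iso = pav_fit(scores, labels)
        assert iso.empirical_prior_odds == pytest.approx(1 / 3)
        np.testing.assert_allclose(
            np.exp(apply_pav_as_lrs(iso, [2.0])), [12.0], rtol=1e-12
        )

    def test_extreme_blocks_give_infinite_lrs(self):
        iso = pav_fit([1.0, 2.0], [0, 1])
        out = apply_pav_as_lrs(iso, [0.5, 3.0])
        assert out[0] == -np.inf and out[1] == np.inf

    def test_out_of_range_clamps(self):
        iso = pav_fit([0.0, 1.0, 2.0, 3.0], [0, 1, 0, 1])
        assert iso.posterior(-10.0) == iso.posterior(0.0)
        assert iso.posterior(10.0) == iso.posterior(3.0)


class TestDecomposition:
    def test_additivity_and_nonnegativity(self):
        rng = np.random.default_rng(1)
        grid = [PriorSpec(p) for p in np.linspace(0.05, 0.95, 19)]
        for _ in range(50):
            s = random_lr_set(rng)
            d = ece_decomposition(s, grid)
            np.testing.assert_allclose(d.ece_min + d.ece_cal_raw, d.ece,
                                       atol=1e-12)
            assert np.all(d.ece_cal >= 0)
            assert np.all(d.ece_cal_raw >= -1e-10)

    def test_pav_output_has_zero_calibration_loss(self):
        rng = np.random.default_rng(2)
        grid = [PriorSpec(p) for p in np.linspace(0.1, 0.9, 9)]
        for _ in range(10):
            s = pav_calibrated_set(random_lr_set(rng))
            d = ece_decomposition(s, grid)
            np.testing.assert_allclose(d.ece_cal, 0.0, atol=1e-10)

    def test_rank_invariance_of_ece_min(self):
        """Strictly monotone distortion changes ECE but never ECEmin."""
        rng = np.random.default_rng(3)
        grid = [PriorSpec(p) for p in np.linspace(0.1, 0.9, 9)]
        for _ in range(20):
            s = random_lr_set(rng)
            warped = LRSet(np.sinh(0.7 * s.log_lr) + 3.0, s.label)
            d0 = ece_decomposition(s, grid)
            d1 = ece_decomposition(warped, grid)
            np.testing.assert_allclose(d1.ece_min, d0.ece_min, atol=1e-10)

    def test_large_calibrated_set_has_tiny_cllr_cal(self, big_calibrated_set):
        _, _, c_cal = cllr_decomposition(big_calibrated_set)
        assert c_cal < 0.01

    def test_same_discrimination_after_pav(self):
        """The PAV reference keeps discrimination up to tie-induced pooling:
        the calibrated scores are a non-decreasing function of the inputs
        (so every surviving ROC operating point is an operating point of the
        original sweep), and on a large set with little pooling the AUC is
        numerically unchanged."""
        rng = np.random.default_rng(4)
        for _ in range(20):
            s = random_lr_set(rng)
            iso = pav_fit(s.log_lr, s.label)
            post = iso.posterior(s.log_lr)
            order = np.argsort(s.log_lr)
            assert np.all(np.diff(post[order]) >= 0)

    def test_auc_preserved_on_large_set(self, big_calibrated_set):
        cal = pav_calibrated_set(big_calibrated_set)
        assert auc(cal) == pytest.approx(auc(big_calibrated_set), abs=5e-4)


class TestCllrDecomposition:
    def test_oracle_all_zero(self, oracle_set):
        assert cllr_decomposition(oracle_set) == (0.0, 0.0, 0.0)

    def test_neutral_two_trial(self):
        s = LRSet([0.0, 0.0], [1, 0])
        c, cmin, ccal = cllr_decomposition(s)
        assert c == pytest.approx(1.0, abs=1e-12)
        assert cmin == pytest.approx(1.0, abs=1e-12)
        assert ccal == pytest.approx(0.0, abs=1e-12)

    def test_four_point_interleaved_hand_value(self):
        """PAV posteriors [0,.5,.5,1] at empirical odds 1 give calibrated
        LRs [0, 1, 1, inf]; Cllr_min follows by direct arithmetic."""
        s = LRSet([-2.0, -1.0, 1.0, 2.0], [0, 1, 0, 1])
        c, cmin, ccal = cllr_decomposition(s)
        expected_min = 0.25 * (np.log2(2) + 0) + 0.25 * (np.log2(1) + np.log2(2))
        # theta1 trials: LR 1 and inf -> log2(1+1/1)=1, 0 ; theta2: LR 0 and 1
        assert cmin == pytest.approx(expected_min, rel=1e-12)
        assert c == pytest.approx(cmin + ccal, rel=1e-12)

    def test_optimal_among_monotone_recalibrations(self):
        """Cllr_min lower-bounds the Cllr of every monotone recalibration
        (randomized search over non-decreasing step functions)."""
        rng = np.random.default_rng(6)
        for _ in range(10):
            s = random_lr_set(rng, n_max=8)
            _, cmin, _ = cllr_decomposition(s)
            uniq = np.unique(s.log_lr)
            pos = np.searchsorted(uniq, s.log_lr)
            best = np.inf
            for _ in range(1000):
                step_vals = np.sort(rng.uniform(-12, 12, uniq.size))
                best = min(best, cllr(LRSet(step_vals[pos], s.label)))
            assert cmin <= best + 1e-9
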