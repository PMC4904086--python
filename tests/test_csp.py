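import numpy as np
import pytest

from _oracles import generalized_csp_eig, random_spd_pair
from mibci import (
    ClassCovariances,
    EpochedTrials,
    SyntheticConfig,
    apply_filters,
    class_mean_covariances,
    csp_filters,
    features_for_trials,
    generate_two_class_trials,
    log_variance_features,
    trial_covariance,
    whitening_transform,
)
from mibci.errors import DegenerateInputError, ValidationError


class TestTrialCovariance:
    def test_single_channel_normalizes_to_one(self):
        assert trial_covariance(np.array([[1.0, 2.0, -3.0]])) == pytest.approx(
            np.array([[1.0]])
        )

    def test_hand_computed_example(self):
        e = np.array([[1.0, -1.0], [1.0, 1.0]])
        # E E^T = [[2,0],[0,2]], trace 4
        assert np.allclose(trial_covariance(e), np.array([[0.5, 0.0], [0.0, 0.5]]))

    def test_unit_trace_for_random_trials(self, rng):
        for _ in range(10):
            r = trial_covariance(rng.normal(size=(4, 30)))
            assert np.trace(r) == pytest.approx(1.0, abs=1e-12)
            assert np.allclose(r, r.T)

    def test_zero_trial_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            trial_covariance(np.zeros((2, 5)))


class TestClassMeanCovariances:
    def test_mean_of_identical_trials(self):
        trial = np.random.default_rng(0).normal(size=(3, 25))
        t = EpochedTrials(
            data=np.stack([trial, trial, trial + 1e-9, trial]),
            labels=[1, 1, 2, 2],
        )
        cov = class_mean_covariances(t)
        assert np.allclose(cov.r1_bar, trial_covariance(trial))

    def test_composite_trace_is_two(self, tiny_trials):
        cov = class_mean_covariances(tiny_trials)
        assert np.trace(cov.rc) == pytest.approx(2.0, abs=1e-10)

    def test_missing_class_rejected(self):
        t = EpochedTrials(data=np.random.default_rng(0).normal(size=(2, 2, 10)), labels=[1, 1])
        with pytest.raises(ValidationError):
            class_mean_covariances(t)


class TestWhitening:
    def test_identity_input_gives_orthogonal_whitener(self):
        p = whitening_transform(np.eye(3))
        assert np.allclose(p @ p.T, np.eye(3), atol=1e-12)

    def test_diagonal_input_closed_form(self):
        # diag(4,1): eigenvalue scaling gives rows diag(0.5, 1) up to order/sign
        p = whitening_transform(np.diag([4.0, 1.0]))
        got = np.sort(np.abs(p[np.abs(p) > 1e-12]))
        assert np.allclose(got, [0.5, 1.0])

    def test_defining_property_on_random_spd(self, rng):
        for n in (2, 4, 7):
            r1, r2 = random_spd_pair(rng, n)
            rc = r1 + r2
            p = whitening_transform(rc)
            assert np.abs(p @ rc @ p.T - np.eye(n)).max() < 1e-8

    def test_rank_deficient_input_names_eigenvalue(self):
        rc = np.diag([1.0, 0.0])
        with pytest.raises(DegenerateInputError, match="eigenvalue"):
            whitening_transform(rc)


class TestCspFilters:
    def test_equal_classes_give_half_eigenvalues(self, rng):
        r, _ = random_spd_pair(rng, 4)
        bank = csp_filters(ClassCovariances(r1_bar=r, r2_bar=r.copy()), 2)
        assert np.allclose(bank.eigvals, 0.5, atol=1e-8)

    def test_diagonal_population_closed_form(self):
        cov = ClassCovariances(
            r1_bar=np.diag([4.0, 1.0]) / 5.0, r2_bar=np.diag([1.0, 4.0]) / 5.0
        )
        bank = csp_filters(cov, 1)
        assert np.allclose(bank.eigvals, [0.8, 0.2], atol=1e-12)
        # filters align with the coordinate axes up to scale
        for row in bank.projection_w:
            assert np.sum(np.abs(row) > 1e-9) == 1

    def test_rayleigh_quotient_matches_eigenvalues(self, rng):
        r1, r2 = random_spd_pair(rng, 6)
        cov = ClassCovariances(r1_bar=r1, r2_bar=r2)
        bank = csp_filters(cov, 3)
        lam_sel = np.concatenate([bank.eigvals[:3], bank.eigvals[-3:]])
        for w, lam in zip(bank.projection_w, lam_sel):
            ratio = (w @ r1 @ w) / (w @ cov.rc @ w)
            assert ratio == pytest.approx(lam, abs=1e-8)

    def test_complementarity_and_simultaneous_diagonalization(self, rng):
        for n in (2, 3, 5, 8):
            r1, r2 = random_spd_pair(rng, n)
            bank = csp_filters(ClassCovariances(r1_bar=r1, r2_bar=r2), 1)
            p, u = bank.whitener_p, bank.eigvecs_u
            s2 = p @ r2 @ p.T
            lam2 = u.T @ s2 @ u
            assert np.abs(lam2 - np.diag(np.diag(lam2))).max() < 1e-8
            assert np.allclose(bank.eigvals + np.diag(lam2), 1.0, atol=1e-8)

    def test_matches_generalized_eigendecomposition_oracle(self, rng):
        for n in (2, 4, 6, 8):
            r1, r2 = random_spd_pair(rng, n)
            bank = csp_filters(ClassCovariances(r1_bar=r1, r2_bar=r2), n // 2)
            lam_oracle, vec_oracle = generalized_csp_eig(r1, r1 + r2)
            assert np.allclose(bank.eigvals, lam_oracle, atol=1e-8)
            # full filter matrix U^T P row k should be collinear with the
            # k-th generalized eigenvector (as a filter: w Rc w = 1 scale)
            w_full = bank.eigvecs_u.T @ bank.whitener_p
            for k in range(n):
                a, b = w_full[k], vec_oracle[:, k]
                cos = abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))
                assert cos == pytest.approx(1.0, abs=1e-8)

    def test_m_pairs_validation(self, rng):
        r1, r2 = random_spd_pair(rng, 3)
        with pytest.raises(ValidationError):
            csp_filters(ClassCovariances(r1_bar=r1, r2_bar=r2), 2)


class TestApplyAndFeatures:
    def test_projection_is_matrix_product(self, rng, tiny_trials):
        bank = csp_filters(class_mean_covariances(tiny_trials), 1)
        e = tiny_trials.data[0]
        assert np.allclose(apply_filters(bank, e), bank.projection_w @ e)

    def test_channel_mismatch_rejected(self, tiny_trials):
        bank = csp_filters(class_mean_covariances(tiny_trials), 1)
        with pytest.raises(ValidationError):
            apply_filters(bank, np.ones((5, 10)))

    def test_log_variance_hand_example(self):
        rng = np.random.default_rng(0)
        y = np.stack([2.0 * rng.normal(size=4000), rng.normal(size=4000)])
        # variance ratio 4:1 -> features approx (log 0.8, log 0.2)
        f = log_variance_features(y)
        assert f[0] == pytest.approx(np.log(0.8), abs=0.05)
        assert f[1] == pytest.approx(np.log(0.2), abs=0.05)

    def test_equal_variances_symmetric_features(self, rng):
        y = rng.normal(size=(4, 1000))
        y = y / y.std(axis=1, keepdims=True)
        f = log_variance_features(y)
        assert np.allclose(f, np.log(1 / 4), atol=1e-9)

    def test_standard_variant_scale_invariant(self, rng):
        y = rng.normal(size=(2, 200))
        assert np.allclose(
            log_variance_features(y), log_variance_features(17.3 * y), atol=1e-12
        )

    def test_as_printed_variant_formula(self, rng):
        y = rng.normal(size=(2, 50)) + 3.0
        var = y.var(axis=1)
        expected = np.log(var) / np.log(var).sum()
        assert np.allclose(log_variance_features(y, "as_printed"), expected)

    def test_zero_variance_row_rejected(self):
        y = np.vstack([np.ones(10), np.arange(10.0)])
        with pytest.raises(DegenerateInputError):
            log_variance_features(y)

    def test_filtered_class1_has_larger_first_row_variance(self, separable_trials):
        train = separable_trials
        bank = csp_filters(class_mean_covariances(train), 1)
        v1 = [apply_filters(bank, t).var(axis=1)[0] for t in train.class_data(1)]
        v2 = [apply_filters(bank, t).var(axis=1)[0] for t in train.class_data(2)]
        assert np.mean(v1) > np.mean(v2)

    def test_midpoint_threshold_separates_heldout_trials(self):
        """On the noise-free 4:1 construction, thresholding the first
        log-variance feature classifies held-out trials > 95% correctly."""
        full = generate_two_class_trials(
            SyntheticConfig(
                n_channels=2,
                n_samples_per_trial=500,
                n_trials_per_class=100,
                variance_ratio=4.0,
                noise_std=0.0,
                mixing_seed=31,
            )
        )
        train = full.subset(np.arange(0, full.n_trials, 2))
        test = full.subset(np.arange(1, full.n_trials, 2))
        bank = csp_filters(class_mean_covariances(train), 1)
        tr = features_for_trials(bank, train)
        mid = 0.5 * (
            tr.features[tr.labels == 1, 0].mean()
            + tr.features[tr.labels == 2, 0].mean()
        )
        te = features_for_trials(bank, test)
        pred = np.where(te.features[:, 0] > mid, 1, 2)
        assert np.mean(pred == te.labels) > 0.95
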