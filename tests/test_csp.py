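"""CSP eigenstructure, log-variance features, filter-bank feature maps."""

import numpy as np
import pytest

from ssafbcsp import (
    EpochSet,
    SynthConfig,
    apply_band,
    class_covariance,
    fit_csp,
    fit_fbcsp,
    generate_epochs,
    logvar_features,
    make_uniform_bank,
    project,
    transform,
)
from ssafbcsp.csp import _trial_covariances
from ssafbcsp.exceptions import ConfigurationError
from ssafbcsp.filterbank import FrequencyBand, bank_from_position


def _spd_pair(rng, dim):
    def spd():
        a = rng.standard_normal((dim, dim))
        c = a @ a.T + dim * np.eye(dim)
        return c / np.trace(c)

    return spd(), spd()


class TestClassCovariance:
    def test_unit_trace(self, rng):
        epochs = EpochSet(data=rng.standard_normal((6, 4, 100)),
                          labels=np.array([0, 0, 0, 1, 1, 1]), fs=100.0)
        C = class_covariance(epochs, 0)
        assert np.trace(C) == pytest.approx(1.0, abs=1e-10)
        np.testing.assert_allclose(C, C.T, atol=1e-12)

    def test_white_noise_approaches_scaled_identity(self, rng):
        n_ch = 4
        epochs = EpochSet(data=rng.standard_normal((40, n_ch, 5000)),
                          labels=np.zeros(40, int), fs=100.0)
        C = class_covariance(epochs, 0)
        np.testing.assert_allclose(C, np.eye(n_ch) / n_ch, atol=0.01)

    def test_single_trial_single_channel(self):
        epochs = EpochSet(data=np.random.default_rng(0).standard_normal((1, 1, 50)),
                          labels=np.zeros(1, int), fs=100.0)
        np.testing.assert_allclose(class_covariance(epochs, 0), [[1.0]])

    def test_empty_class_rejected(self, rng):
        epochs = EpochSet(data=rng.standard_normal((2, 3, 50)),
                          labels=np.zeros(2, int), fs=100.0)
        with pytest.raises(ValueError):
            class_covariance(epochs, 1)


class TestFitCSP:
    def test_symmetric_case_half_eigenvalues(self):
        C = np.eye(3) / 6.0  # C1 = C2, unit-trace pair
        sf = fit_csp(C, C, m=1)
        np.testing.assert_allclose(sf.eigvals, 0.5, atol=1e-12)
        np.testing.assert_allclose(sf.W.T @ (2 * C) @ sf.W, np.eye(2), atol=1e-8)

    def test_diagonal_pair_closed_form(self):
        C1 = np.diag([0.8, 0.2])
        C2 = np.diag([0.2, 0.8])
        sf = fit_csp(C1, C2, m=1)
        np.testing.assert_allclose(sorted(sf.eigvals), [0.2, 0.8], atol=1e-12)
        # top filter selects channel 1, bottom filter channel 2
        top, bottom = np.abs(sf.W[:, 0]), np.abs(sf.W[:, 1])
        assert top[0] > 100 * top[1]
        assert bottom[1] > 100 * bottom[0]

    def test_whitening_and_diagonalization_invariants(self, rng):
        for dim in (4, 8, 22):
            C1, C2 = _spd_pair(rng, dim)
            m = min(3, dim // 2)
            sf = fit_csp(C1, C2, m=m)
            comp = sf.W.T @ (C1 + C2) @ sf.W
            np.testing.assert_allclose(comp, np.eye(2 * m), atol=1e-8)
            D = sf.W.T @ C1 @ sf.W
            off = D - np.diag(np.diag(D))
            assert np.max(np.abs(off)) < 1e-8

    def test_eigenvalue_symmetry_between_classes(self, rng):
        C1, C2 = _spd_pair(rng, 6)
        lam1 = np.sort(fit_csp(C1, C2, m=3).eigvals)
        lam2 = np.sort(fit_csp(C2, C1, m=3).eigvals)
        np.testing.assert_allclose(lam1, np.sort(1.0 - lam2), atol=1e-10)

    def test_too_many_filters_rejected(self, rng):
        C1, C2 = _spd_pair(rng, 4)
        with pytest.raises(ConfigurationError):
            fit_csp(C1, C2, m=3)


class TestProjectAndLogvar:
    def test_identity_projection_returns_rows(self, rng):
        from ssafbcsp.csp import SpatialFilters

        X = rng.standard_normal((4, 100))
        sf = SpatialFilters(W=np.eye(4), eigvals=np.full(4, 0.5), m=2)
        np.testing.assert_array_equal(project(sf, X), X)

    def test_projection_linearity_and_oracle(self, rng):
        from ssafbcsp.csp import SpatialFilters

        W = rng.standard_normal((5, 4))
        sf = SpatialFilters(W=W, eigvals=np.full(4, 0.5), m=2)
        X = rng.standard_normal((5, 80))
        np.testing.assert_allclose(project(sf, 3.0 * X), 3.0 * project(sf, X))
        np.testing.assert_allclose(project(sf, X), W.T @ X, atol=1e-12)

    def test_equal_variances_give_log_half(self):
        Z = np.array([[1.0, -1.0, 1.0, -1.0], [-1.0, 1.0, -1.0, 1.0]])
        np.testing.assert_allclose(logvar_features(Z), np.log(0.5), atol=1e-12)

    def test_known_variance_ratio(self):
        Z = np.array([[3.0, -3.0, 3.0, -3.0], [1.0, -1.0, 1.0, -1.0]])
        np.testing.assert_allclose(
            logvar_features(Z), [np.log(0.9), np.log(0.1)], atol=1e-12
        )

    def test_features_sum_to_one_in_exp_domain(self, rng):
        Z = rng.standard_normal((6, 200))
        assert np.exp(logvar_features(Z)).sum() == pytest.approx(1.0, abs=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            logvar_features(np.zeros((2, 10)))


class TestFBCSP:
    def test_two_class_single_problem(self, mi_epochs_small):
        bank = make_uniform_bank(3, 4.0, 30.0)
        model = fit_fbcsp(mi_epochs_small, bank, m=2)
        assert len(model.problems) == 1
        assert model.n_features == 3 * 1 * 4

    def test_four_class_ovr_dimension(self):
        cfg = SynthConfig(n_classes=4, trials_per_class=5, n_channels=6,
                          fs=128.0, epoch_len=1.0, seed=3,
                          planted_bands=[(8., 12.), (14., 18.), (20., 24.),
                                         (26., 30.)])
        epochs = generate_epochs(cfg)
        bank = make_uniform_bank(10, 4.0, 40.0)
        model = fit_fbcsp(epochs, bank, m=2)
        assert len(model.problems) == 4
        assert model.n_features == 10 * 4 * 4 == 160
        feats = transform(model, epochs)
        assert feats.shape == (20, 160)
        assert np.all(np.isfinite(feats))

    def test_refit_deterministic_up_to_sign(self, mi_epochs_small):
        bank = make_uniform_bank(2, 4.0, 30.0)
        m1 = fit_fbcsp(mi_epochs_small, bank, m=2)
        m2 = fit_fbcsp(mi_epochs_small, bank, m=2)
        for f1, f2 in zip(m1.filters, m2.filters):
            for sf1, sf2 in zip(f1, f2):
                np.testing.assert_allclose(np.abs(sf1.W), np.abs(sf2.W),
                                           atol=1e-10)

    def test_single_class_rejected(self, rng):
        epochs = EpochSet(data=rng.standard_normal((4, 3, 64)),
                          labels=np.zeros(4, int), fs=64.0)
        with pytest.raises(ValueError):
            fit_fbcsp(epochs, make_uniform_bank(2, 4.0, 30.0))


class TestTransform:
    def test_matches_per_trial_recomputation(self, mi_epochs_small):
        bank = make_uniform_bank(2, 4.0, 30.0)
        model = fit_fbcsp(mi_epochs_small, bank, m=2)
        feats = transform(model, mi_epochs_small)
        trial = 5
        for b, band in enumerate(bank):
            filtered = apply_band(mi_epochs_small, band)
            X = filtered.data[trial]
            X = X - X.mean(axis=1, keepdims=True)
            for p, sf in enumerate(model.filters[b]):
                expected = logvar_features(project(sf, X))
                for c in range(2 * model.m):
                    col = model.feature_index(b, p, c)
                    assert feats[trial, col] == pytest.approx(expected[c],
                                                              rel=1e-8)

    def test_row_permutation_equivariance(self, mi_epochs_small):
        bank = make_uniform_bank(2, 4.0, 30.0)
        model = fit_fbcsp(mi_epochs_small, bank, m=1)
        feats = transform(model, mi_epochs_small)
        perm = np.random.default_rng(1).permutation(mi_epochs_small.n_trials)
        permuted = transform(model, mi_epochs_small.select(perm))
        np.testing.assert_allclose(permuted, feats[perm], atol=1e-10)

    def test_invariant_under_filter_sign_flip(self, mi_epochs_small):
        bank = make_uniform_bank(2, 4.0, 30.0)
        model = fit_fbcsp(mi_epochs_small, bank, m=1)
        feats = transform(model, mi_epochs_small)
        from dataclasses import replace

        flipped = [
            [replace(sf, W=-sf.W) for sf in band_filters]
            for band_filters in model.filters
        ]
        model_flipped = replace(model, filters=flipped)
        np.testing.assert_allclose(transform(model_flipped, mi_epochs_small),
                                   feats, atol=1e-12)

    def test_channel_mismatch_rejected(self, mi_epochs_small, rng):
        bank = make_uniform_bank(2, 4.0, 30.0)
        model = fit_fbcsp(mi_epochs_small, bank, m=1)
        other = EpochSet(data=rng.standard_normal((2, 3, 64)),
                         labels=np.array([0, 1]), fs=mi_epochs_small.fs)
        with pytest.raises(ValueError):
            transform(model, other)

    def test_planted_band_separates_better_than_disjoint(self, separable_epochs):
        """The top CSP feature from a band overlapping the planted 10-14 Hz
        rhythm separates the classes better than one from a disjoint band."""
        from scipy import stats

        labels = separable_epochs.labels

        def top_feature_tstat(lo, hi):
            bank = bank_from_position([lo, hi])
            model = fit_fbcsp(separable_epochs, bank, m=1)
            feats = transform(model, separable_epochs)
            t, _ = stats.ttest_ind(feats[labels == 0, 0], feats[labels == 1, 0])
            return abs(t)

        assert top_feature_tstat(9.0, 15.0) > top_feature_tstat(30.0, 36.0)
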