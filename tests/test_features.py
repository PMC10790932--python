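"""Epoch windows, per-window standardization, PCA rules and feature assembly."""

import numpy as np
import pandas as pd
import pytest

from turnintent.features import (
    EpochSet,
    build_features,
    extract_epochs,
    fit_pca,
    retained_after_rules,
    standardize_features,
    standardize_windows,
)
from turnintent.preprocess import ConcentrationSeries
from turnintent.simdata import EventLog


def _conc(n_channels=6, n_samples=600, fs=2.0, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(n_channels, n_samples))
    return ConcentrationSeries(hbo=x * 0.5, hbr=x, sampling_rate=fs,
                               retained_channels=np.arange(n_channels))


def _log(press_times, gaps=None, cars=None):
    n = len(press_times)
    return EventLog(pd.DataFrame({
        "intersection_id": np.arange(n),
        "block_id": np.zeros(n, dtype=int),
        "press_time_s": press_times,
        "gap_size_s": gaps if gaps is not None else np.full(n, 4.0),
        "cars_waited": cars if cars is not None else np.full(n, 3),
        "atypical": np.zeros(n, dtype=bool),
        "noturn_gap_size_s": np.full(n, 2.0),
        "noturn_cars_waited": np.full(n, 1),
    }))


class TestExtractEpochs:
    def test_window_arithmetic(self):
        """Press at t=100 s: turn window [98, 102), no-turn [93.5, 97.5)."""
        conc = _conc()
        ep = extract_epochs(conc, _log([100.0]))
        assert len(ep) == 2
        fs = conc.sampling_rate
        turn = ep.samples[ep.labels == 1][0]
        noturn = ep.samples[ep.labels == 0][0]
        np.testing.assert_array_equal(turn, conc.hbr[:, int(98 * fs):int(102 * fs)])
        np.testing.assert_array_equal(
            noturn, conc.hbr[:, int(93.5 * fs):int(97.5 * fs)])
        assert turn.shape[1] == 8  # 4 s at 2 Hz

    def test_two_epochs_per_intersection(self, default_epochs):
        assert len(default_epochs) == 200
        assert (default_epochs.labels == 1).sum() == 100

    def test_early_press_skipped_with_warning(self):
        conc = _conc()
        with pytest.warns(UserWarning, match="out of bounds"):
            ep = extract_epochs(conc, _log([3.0, 100.0]))
        assert len(ep) == 2  # only the valid intersection remains
        assert set(ep.intersection_ids) == {1}

    def test_phase_specific_context(self):
        ep = extract_epochs(_conc(), _log([100.0], gaps=[5.0], cars=[4]))
        assert ep.gap_size[ep.labels == 1][0] == 5.0
        assert ep.gap_size[ep.labels == 0][0] == 2.0
        assert ep.cars_waited[ep.labels == 0][0] == 1


class TestStandardizeWindows:
    def test_mean_zero_sd_one(self, small_epochs):
        z = standardize_windows(small_epochs.samples)
        np.testing.assert_allclose(z.mean(axis=-1), 0.0, atol=1e-12)
        np.testing.assert_allclose(z.std(axis=-1), 1.0, atol=1e-9)

    def test_flat_window_maps_to_zero(self):
        x = np.ones((1, 2, 8))
        assert np.allclose(standardize_windows(x), 0.0)


class TestPCARules:
    def test_retention_rule_and_first_pc_drop(self):
        """Eigenvalues [2, 1, 0.7, 0.6, 0.1]: cutoff keeps 1-3, dropping the
        first leaves usable components {2, 3}."""
        keep = retained_after_rules(np.array([2.0, 1.0, 0.7, 0.6, 0.1]))
        np.testing.assert_array_equal(keep, [2, 3])

    def test_three_component_model_recovered(self):
        """Data from an exact 3-component linear model + tiny noise puts
        >= 99% of the variance in the first three PCs, and fit_pca matches
        an independent eigendecomposition of the same observations."""
        rng = np.random.default_rng(1)
        n, p = 400, 12
        latents = rng.normal(size=(n, 3)) * np.array([5.0, 3.0, 2.0])
        mixing = rng.normal(size=(3, p))
        x = latents @ mixing + rng.normal(scale=0.01, size=(n, p))
        # plain PCA oracle on the raw matrix: 3 latent directions dominate
        xc = x - x.mean(axis=0)
        eig = np.sort(np.linalg.eigvalsh(xc.T @ xc / (n - 1)))[::-1]
        assert eig[:3].sum() / eig.sum() >= 0.99
        # fit_pca agrees with the eigendecomposition oracle applied to the
        # per-window-standardized observations it actually consumes
        samples = x.T.reshape(p, 50, 8).transpose(1, 0, 2)
        ep = EpochSet(samples=samples, labels=np.zeros(50, dtype=int),
                      intersection_ids=np.arange(50),
                      gap_size=np.zeros(50), cars_waited=np.zeros(50),
                      atypical=np.zeros(50, dtype=bool), sampling_rate=2.0,
                      channel_indices=np.arange(p))
        pca = fit_pca(ep)
        z = standardize_windows(samples)
        flat = np.moveaxis(z, 1, 2).reshape(-1, p)
        flat -= flat.mean(axis=0)
        eig_oracle = np.sort(np.linalg.eigvalsh(
            flat.T @ flat / (flat.shape[0] - 1)))[::-1]
        np.testing.assert_allclose(pca.eigenvalues, eig_oracle, atol=1e-10)

    def test_projection_roundtrip(self, small_epochs):
        pca = fit_pca(small_epochs)
        z = standardize_windows(small_epochs.samples)
        flat = np.moveaxis(z, 1, 2).reshape(-1, z.shape[1])
        scores = (flat - pca.mean) @ pca.eigenvectors
        recon = scores @ pca.eigenvectors.T + pca.mean
        np.testing.assert_allclose(recon, flat, atol=1e-8)
        # eigenvector orthonormality
        gram = pca.eigenvectors.T @ pca.eigenvectors
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)

    def test_eigenvalues_descending(self, small_epochs):
        pca = fit_pca(small_epochs)
        assert np.all(np.diff(pca.eigenvalues) <= 1e-12)
        assert 1 not in pca.model_feature_indices


class TestBuildFeatures:
    def test_instance_counts_full_protocol(self, default_epochs):
        """100 intersections x 2 windows x 8 samples = 1,600 instances."""
        pca = fit_pca(default_epochs)
        for variant, p in (("context", 2), ("fnirs", 7), ("combined", 9)):
            fm = build_features(default_epochs, pca, variant)
            assert fm.n_instances == 1600
            assert fm.n_features == p
        assert (fm.y == 1).mean() == 0.5  # label balance by construction

    def test_too_few_components_instructive_error(self, small_epochs):
        pca = fit_pca(small_epochs)
        pca.eigenvectors = pca.eigenvectors[:, :5]
        with pytest.raises(ValueError, match="retention"):
            build_features(small_epochs, pca, "combined")

    def test_standardization_train_stats_only(self, small_epochs):
        pca = fit_pca(small_epochs)
        fm = build_features(small_epochs, pca, "combined")
        half = fm.n_instances // 2
        tr = _slice_fm(fm, slice(0, half))
        te = _slice_fm(fm, slice(half, None))
        tr_s, te_s = standardize_features(tr, te)
        cont = tr_s.standardization["continuous_mask"]
        np.testing.assert_allclose(tr_s.X[:, cont].mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(tr_s.X[:, cont].std(axis=0), 1.0, atol=1e-9)
        # test split standardized with train stats, not its own
        assert not np.allclose(te_s.X[:, cont].mean(axis=0), 0.0, atol=1e-9)
        # discrete cars_waited untouched
        k = fm.feature_names.index("cars_waited")
        np.testing.assert_array_equal(te_s.X[:, k], te.X[:, k])

    def test_no_leakage_checksum(self, small_epochs):
        """PCA refit on the training epochs alone matches the fold model."""
        train_idx = np.arange(len(small_epochs) // 2)
        pca_fold = fit_pca(small_epochs.subset(train_idx))
        pca_refit = fit_pca(small_epochs.subset(train_idx))
        np.testing.assert_array_equal(pca_fold.eigenvectors, pca_refit.eigenvectors)
        np.testing.assert_array_equal(pca_fold.eigenvalues, pca_refit.eigenvalues)


def _slice_fm(fm, sl):
    from turnintent.features import FeatureMatrix

    return FeatureMatrix(X=fm.X[sl], y=fm.y[sl],
                         feature_names=fm.feature_names, variant=fm.variant,
                         groups=fm.groups[sl], atypical=fm.atypical[sl])
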