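"""Savitzky-Golay, SNV and PCA behaviour against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemocal.preprocess import (
    PreprocessConfig,
    pca_summary,
    preprocess_pipeline,
    savgol,
    snv,
)
from chemocal.spectra import SpectralMatrix, make_grid


def _spectra(values, step=0.2, stage="raw"):
    values = np.atleast_2d(np.asarray(values, float))
    grid = make_grid(200.0, 200.0 + step * (values.shape[1] - 1), step)
    ids = tuple(f"s{i}" for i in range(values.shape[0]))
    return SpectralMatrix(grid, values, ids, stage=stage)


class TestSavgol:
    def test_cubic_filter_reproduces_cubic_everywhere(self):
        grid = make_grid(200, 260, 0.2)
        lam = grid.labels
        x = ((lam - 230) / 30.0) ** 3 + 0.5
        sm = _spectra(x, stage="derivative1")  # may dip negative
        out = savgol(sm, PreprocessConfig(11, 3, 0))
        # a cubic is invariant under an order-3 smoother, edges included
        # (edge values come from the polynomial fitted to the full window)
        np.testing.assert_allclose(out.absorbance[0], x, atol=1e-9)

    def test_first_derivative_of_line_is_slope(self):
        grid = make_grid(200, 210, 0.2)
        x = 0.3 + 0.05 * grid.labels
        out = savgol(_spectra(x), PreprocessConfig(11, 3, 1))
        np.testing.assert_allclose(out.absorbance[0], 0.05, atol=1e-9)
        assert out.stage == "derivative1"

    def test_matches_local_polyfit_oracle_at_every_interior_point(self, rng):
        # brute-force oracle: fit a cubic to each 11-point window by
        # ordinary least squares and evaluate value / derivatives at center
        step = 0.2
        x = rng.random(61)
        sm = _spectra(x, step=step)
        half = 5
        for deriv in (0, 1, 2):
            out = savgol(
                sm, PreprocessConfig(11, 3, deriv)
            ).absorbance[0]
            for i in range(half, len(x) - half):
                window = x[i - half : i + half + 1]
                offsets = np.arange(-half, half + 1) * step
                coeffs = np.polyfit(offsets, window, 3)
                # derivative of the fitted cubic at offset 0
                expected = np.polyder(np.poly1d(coeffs), deriv)(0.0)
                assert out[i] == pytest.approx(expected, abs=1e-8)

    def test_derivative_scaling_is_grid_independent(self):
        # same analog signal sampled at two steps gives the same slope
        for step in (0.1, 0.5):
            grid = make_grid(200, 200 + step * 40, step)
            x = 2.0 * grid.labels
            out = savgol(_spectra(x, step=step), PreprocessConfig(11, 3, 1))
            np.testing.assert_allclose(out.absorbance[0], 2.0, atol=1e-9)

    def test_rejects_bad_windows(self):
        with pytest.raises(ValueError):
            PreprocessConfig(10, 3, 0)
        with pytest.raises(ValueError):
            PreprocessConfig(11, 11, 0)
        with pytest.raises(ValueError):
            savgol(_spectra(np.ones(5)), PreprocessConfig(11, 3, 0))


class TestSNV:
    def test_three_point_example(self):
        out = snv(_spectra([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out.absorbance[0], [-1.0, 0.0, 1.0])
        assert out.stage == "snv"

    def test_row_mean_zero_sd_one(self, rng):
        out = snv(_spectra(rng.random((5, 40))))
        np.testing.assert_allclose(out.absorbance.mean(axis=1), 0, atol=1e-10)
        np.testing.assert_allclose(out.absorbance.std(axis=1, ddof=1), 1, atol=1e-10)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(
        a=st.floats(0.1, 50.0),
        b=st.floats(-5.0, 5.0),
        seed=st.integers(0, 10_000),
    )
    def test_affine_invariance(self, a, b, seed):
        x = np.random.default_rng(seed).random(30)
        base = snv(_spectra(x)).absorbance
        scaled = snv(_spectra(a * x + b, stage="derivative1")).absorbance
        np.testing.assert_allclose(scaled, base, atol=1e-8)

    def test_constant_spectrum_rejected_by_name(self):
        with pytest.raises(ValueError, match="s1"):
            snv(_spectra(np.vstack([np.arange(5.0), np.full(5, 2.0)])))


class TestPipeline:
    def test_empty_step_list_is_identity(self, noise_free_bundle):
        x = noise_free_bundle.calibration_x
        out = preprocess_pipeline(x, [])
        np.testing.assert_array_equal(out.absorbance, x.absorbance)

    def test_composition_matches_sequential_application(self, noisy_bundle):
        x = noisy_bundle.calibration_x
        cfg = PreprocessConfig()
        piped = preprocess_pipeline(x, ["savgol", "derivative1", "snv"], cfg)
        from dataclasses import replace

        manual = snv(
            savgol(
                savgol(x, replace(cfg, derivative_order=0)),
                replace(cfg, derivative_order=1),
            )
        )
        np.testing.assert_array_equal(piped.absorbance, manual.absorbance)

    def test_unknown_step_rejected(self, noise_free_bundle):
        with pytest.raises(ValueError):
            preprocess_pipeline(noise_free_bundle.calibration_x, ["msc"])

    def test_smoothing_recovers_clean_signal(self):
        # paired simulation: the smoothed noisy spectra sit closer to the
        # clean (noise-free) spectra than the raw noisy ones do, at
        # additive noise SD 0.01 AU
        import chemocal as cc

        clean = cc.make_study(seed=11, noise=cc.NoiseSpec(0, 0, 0, False, 0))
        noisy = cc.make_study(
            seed=11,
            noise=cc.NoiseSpec(additive_sd=0.01, scatter_sd=0.0,
                               baseline_slope_sd=0.0, seed=11),
        )
        raw = noisy.calibration_x.absorbance
        smoothed = preprocess_pipeline(noisy.calibration_x, ["savgol"]).absorbance
        target = clean.calibration_x.absorbance
        rms_raw = np.sqrt(np.mean((raw - target) ** 2))
        rms_smoothed = np.sqrt(np.mean((smoothed - target) ** 2))
        assert rms_smoothed < 0.7 * rms_raw


class TestPCA:
    def test_rank_one_data_gives_pc1_100pct(self):
        base = np.linspace(1, 2, 20)
        data = np.outer([1.0, 2.0, 3.0, 4.0], base)
        summary = pca_summary(_spectra(data))
        assert summary.variance_pct[0] == pytest.approx(100.0, abs=1e-8)

    def test_scores_match_covariance_eigendecomposition(self, rng):
        data = rng.random((10, 15))
        summary = pca_summary(_spectra(data))
        centered = data - data.mean(axis=0)
        evals, evecs = np.linalg.eigh(centered.T @ centered)
        order = np.argsort(evals)[::-1]
        for j in range(3):
            expected = centered @ evecs[:, order[j]]
            got = summary.scores[:, j]
            # eigenvectors are sign-ambiguous
            err = min(
                np.abs(got - expected).max(), np.abs(got + expected).max()
            )
            assert err < 1e-8

    def test_variance_percentages_ordered_and_energy_conserving(self, rng):
        data = rng.random((12, 30))
        summary = pca_summary(_spectra(data))
        assert np.all(np.diff(summary.variance_pct) <= 1e-12)
        assert summary.variance_pct.sum() == pytest.approx(100.0, abs=1e-6)
        centered = data - data.mean(axis=0)
        assert np.sum(summary.scores**2) == pytest.approx(
            np.sum(centered**2), rel=1e-10
        )
        # scores of distinct PCs are orthogonal
        gram = summary.scores.T @ summary.scores
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            pca_summary(_spectra(np.ones((1, 5))))
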