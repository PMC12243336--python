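"""Synthetic Beer-Lambert generator: linearity, noise calibration, bundles."""

import numpy as np
import pytest

import chemocal as cc
from chemocal.simulate import (
    ComponentSpec,
    NoiseSpec,
    default_components,
    default_grid,
    make_study,
    pure_spectrum,
    simulate_mixtures,
    write_bundle,
)
from chemocal.spectra import ConcentrationMatrix, read_spectra_csv


class TestPureSpectrum:
    def test_single_band_peak_value(self):
        grid = default_grid()
        spec = ComponentSpec("x", ((230.0, 5.0, 0.8),), molar_scale=0.02)
        s = pure_spectrum(spec, grid)
        i = np.argmin(np.abs(grid.labels - 230.0))
        assert s[i] == pytest.approx(0.02 * 0.8, abs=1e-12)

    def test_symmetry_about_band_center(self):
        grid = default_grid()
        spec = ComponentSpec("x", ((230.0, 6.0, 1.0),), molar_scale=1.0)
        s = pure_spectrum(spec, grid)
        center = np.argmin(np.abs(grid.labels - 230.0))
        for off in (5, 20, 60):
            assert s[center - off] == pytest.approx(s[center + off], rel=1e-12)

    def test_default_components_overlap_strongly(self):
        grid = default_grid()
        a, b = default_components(grid)
        sa, sb = pure_spectrum(a, grid), pure_spectrum(b, grid)
        cosine = sa @ sb / (np.linalg.norm(sa) * np.linalg.norm(sb))
        assert cosine > 0.7

    def test_validation(self):
        with pytest.raises(ValueError):
            ComponentSpec("x", (), 1.0)
        with pytest.raises(ValueError):
            ComponentSpec("x", ((230.0, -1.0, 1.0),), 1.0)


class TestSimulateMixtures:
    def _conc(self, rows):
        rows = np.atleast_2d(rows)
        return ConcentrationMatrix(
            rows, ("a", "b"), tuple(f"s{i}" for i in range(rows.shape[0]))
        )

    def test_noise_off_is_exactly_linear(self):
        grid = default_grid()
        specs = default_components(grid)
        sa, sb = (pure_spectrum(s, grid) for s in specs)
        out = simulate_mixtures(
            self._conc([[10.0, 5.0]]), specs, NoiseSpec.NONE, grid
        )
        np.testing.assert_allclose(
            out.absorbance[0], 10 * sa + 5 * sb, atol=1e-12
        )
        # superposition
        a = simulate_mixtures(self._conc([[7.0, 0.0]]), specs, NoiseSpec.NONE, grid)
        b = simulate_mixtures(self._conc([[0.0, 4.0]]), specs, NoiseSpec.NONE, grid)
        ab = simulate_mixtures(self._conc([[7.0, 4.0]]), specs, NoiseSpec.NONE, grid)
        np.testing.assert_allclose(
            ab.absorbance, a.absorbance + b.absorbance, atol=1e-12
        )

    def test_design_set_supports_exact_pls(self, noise_free_bundle):
        b = noise_free_bundle
        model = cc.fit_pls(b.calibration_x, b.calibration_y, 2)
        fitted = cc.predict(model, b.calibration_x.absorbance)
        rmsec = np.sqrt(np.mean((fitted - b.calibration_y.concentrations) ** 2))
        assert rmsec < 1e-8

    def test_blank_noise_sd_calibrated(self):
        # 200 blank spectra -> empirical SD of the additive noise generator
        grid = default_grid()
        specs = default_components(grid)
        blanks = self._conc(np.zeros((200, 2)))
        out = simulate_mixtures(
            blanks, specs,
            NoiseSpec(additive_sd=0.002, scatter_sd=0.0,
                      baseline_slope_sd=0.0, seed=3),
            grid,
        )
        sd = out.absorbance.std()
        assert 0.0018 <= sd <= 0.0022

    def test_max_mixture_absorbance_in_linear_range(self):
        grid = default_grid()
        specs = default_components(grid)
        out = simulate_mixtures(
            self._conc([[25.0, 25.0]]), specs, NoiseSpec.NONE, grid
        )
        assert out.absorbance.max() < 1.3

    def test_rejects_component_mismatch(self):
        grid = default_grid()
        specs = default_components(grid)
        bad = ConcentrationMatrix(np.ones((1, 3)), ("a", "b", "c"), ("s0",))
        with pytest.raises(ValueError):
            simulate_mixtures(bad, specs, NoiseSpec.NONE, grid)


class TestMakeStudy:
    def test_bundle_sizes_and_ranges(self, noisy_bundle):
        b = noisy_bundle
        assert b.calibration_x.n_samples == 25
        assert b.validation_lhs_x.n_samples == 13
        assert b.validation_mc_x.n_samples == 13
        total = b.calibration_x.n_samples + b.validation_lhs_x.n_samples
        assert total == 38
        for y in (b.calibration_y, b.validation_lhs_y, b.validation_mc_y):
            assert y.concentrations.min() >= 5.0
            assert y.concentrations.max() <= 25.0

    def test_lhs_occupancy_in_bundle(self, noisy_bundle):
        pts = noisy_bundle.validation_lhs_y.concentrations
        for d in range(2):
            bins = np.floor((pts[:, d] - 5.0) / 20.0 * 13).astype(int)
            assert sorted(np.clip(bins, 0, 12)) == list(range(13))

    def test_same_seed_reproduces_bundle_bitwise(self):
        a = make_study(seed=5)
        b = make_study(seed=5)
        np.testing.assert_array_equal(
            a.calibration_x.absorbance, b.calibration_x.absorbance
        )
        np.testing.assert_array_equal(
            a.validation_mc_x.absorbance, b.validation_mc_x.absorbance
        )

    def test_plasma_interferent_biases_recovery(self):
        # a PLS model trained without the matrix band sees biased
        # recoveries on the plasma-surrogate set relative to the clean set
        b = make_study(seed=9, plasma=True)
        model = cc.fit_pls(b.calibration_x, b.calibration_y, 3)
        clean = np.asarray(cc.predict(model, b.validation_lhs_x.absorbance))
        plasma = np.asarray(cc.predict(model, b.plasma_x.absorbance))
        truth = b.validation_lhs_y.concentrations
        dev_clean = np.abs(100 * clean / truth - 100).mean()
        dev_plasma = np.abs(100 * plasma / b.plasma_y.concentrations - 100).mean()
        assert dev_plasma > dev_clean

    def test_write_bundle_roundtrip(self, tmp_path, noisy_bundle):
        write_bundle(noisy_bundle, tmp_path)
        assert (tmp_path / "manifest.json").exists()
        back = read_spectra_csv(tmp_path / "calibration_spectra.csv")
        np.testing.assert_array_equal(
            back.absorbance, noisy_bundle.calibration_x.absorbance
        )
        import json

        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert manifest["synthetic"] is True
        assert manifest["sets"]["calibration"] == 25
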