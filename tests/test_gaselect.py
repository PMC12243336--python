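"""GA wavelength selection: fitness arithmetic, ICOMP, and search behaviour."""

import numpy as np
import pytest

from chemocal.gaselect import (
    GAConfig,
    ga_icomp_pls,
    ga_pls,
    icomp_score,
    penalized_fitness,
    run_ga,
)
from chemocal.pls import loo_residuals


def _planted_data(seed, n=16, p=100, k_inf=5, noise=0.3):
    """Only the first k_inf of p wavelengths carry concentration signal."""
    r = np.random.default_rng(seed)
    y = r.uniform(5, 25, size=(n, 1))
    X = r.standard_normal((n, p)) * noise
    coeffs = r.uniform(0.5, 1.5, k_inf)
    X[:, :k_inf] += y * coeffs
    return X, y


def _planted_necessary(seed, n=16, p=50, k_inf=5):
    """The response needs *every* informative channel: y = X[:, :5] @ w.

    Each informative channel is an independent unit-variance signal, so
    dropping any one leaves an irreducible cross-validation error; the
    remaining channels are lower-variance pure noise.
    """
    r = np.random.default_rng(seed)
    S = r.standard_normal((n, k_inf))
    w = r.uniform(1.0, 2.0, k_inf)
    y = (S @ w)[:, None] + 0.01 * r.standard_normal((n, 1))
    X = np.column_stack([S, 0.3 * r.standard_normal((n, p - k_inf))])
    return X, y


class TestPenalizedFitness:
    def test_hand_arithmetic_of_penalty_term(self, rng):
        # lambda * k/p arithmetic on a fixed RMSECV
        X, y = _planted_data(0, n=12, p=301)
        mask = np.zeros(301, bool)
        mask[:30] = True
        res = loo_residuals(X, y, 2, mask=mask)
        rmsecv = float(np.sqrt(np.mean(res**2)))
        fit = penalized_fitness(mask, X, y, 2, 0.05)
        assert fit == pytest.approx(rmsecv + 0.05 * 30 / 301, abs=1e-12)
        # the spec-level arithmetic check: 0.30 + 0.05*30/301
        assert 0.30 + 0.05 * 30 / 301 == pytest.approx(0.3049834, abs=1e-6)

    def test_lambda_zero_is_plain_rmsecv(self):
        X, y = _planted_data(1, n=12, p=40)
        mask = np.ones(40, bool)
        res = loo_residuals(X, y, 2)
        assert penalized_fitness(mask, X, y, 2, 0.0) == pytest.approx(
            float(np.sqrt(np.mean(res**2))), abs=1e-12
        )

    def test_smaller_mask_strictly_fitter_at_equal_rmsecv(self):
        # monotone penalty: same first-half information duplicated, so the
        # half mask and full mask share RMSECV but not the penalty
        X, y = _planted_data(2, n=12, p=20)
        X = np.column_stack([X[:, :10], X[:, :10]])
        half = np.zeros(20, bool)
        half[:10] = True
        full = np.ones(20, bool)
        f_half = penalized_fitness(half, X, y, 2, 0.05)
        f_full = penalized_fitness(full, X, y, 2, 0.05)
        assert f_half < f_full


class TestICOMP:
    def test_spherical_residuals_have_zero_complexity(self, rng):
        # exactly spherical covariance via symmetric residual pattern
        E = np.array([[1.0, 1.0], [-1.0, 1.0], [1.0, -1.0], [-1.0, -1.0]])
        score = icomp_score(E)
        assert score.complexity == pytest.approx(0.0, abs=1e-12)
        assert score.total == pytest.approx(score.minus2_loglik, abs=1e-9)

    def test_single_response_complexity_vanishes(self, rng):
        score = icomp_score(rng.standard_normal((20, 1)))
        assert score.complexity == pytest.approx(0.0, abs=1e-12)

    def test_diag_1_4_evaluates_to_ln2p5_minus_half_ln4(self):
        # residuals engineered so E'E/n = diag(1, 4)
        n = 8
        a = np.sqrt(1.0) * np.array([1, -1] * 4)
        b = np.sqrt(4.0) * np.array([1, 1, -1, -1] * 2)
        E = np.column_stack([a, b])
        score = icomp_score(E)
        np.testing.assert_allclose(score.residual_cov, np.diag([1.0, 4.0]), atol=1e-12)
        expected = np.log(2.5) - 0.5 * np.log(4.0)
        assert score.complexity == pytest.approx(expected, abs=1e-9)
        assert score.complexity == pytest.approx(0.22314, abs=1e-5)
        # eigenvalue form of the same quantity
        eig = np.linalg.eigvalsh(score.residual_cov)
        alt = (2 / 2) * np.log(eig.mean()) - 0.5 * np.sum(np.log(eig))
        assert score.complexity == pytest.approx(alt, abs=1e-12)

    def test_total_identity_and_positivity_on_random_covariances(self, rng):
        for _ in range(25):
            E = rng.standard_normal((30, 2)) @ rng.random((2, 2))
            score = icomp_score(E)
            assert score.total == pytest.approx(
                score.minus2_loglik + 2 * score.complexity, abs=1e-9
            )
            assert score.complexity >= 0
            # strictly positive unless spherical
            eig = np.linalg.eigvalsh(score.residual_cov)
            if abs(eig[0] - eig[1]) > 1e-9:
                assert score.complexity > 0

    def test_requires_more_rows_than_responses(self):
        with pytest.raises(ValueError):
            icomp_score(np.ones((2, 2)))


class TestRunGA:
    def test_identical_population_is_fixed_point_without_mutation(self):
        # a single window block forces every chromosome to the same
        # one-bit genome (all-zero genomes are repaired to it); with
        # mutation off, crossover of identical parents changes nothing
        def fitness(mask):
            return float(mask.sum())

        cfg = GAConfig(population=6, generations=8, mutation_rate=0.0,
                       window_size=12, seed=0)
        best, hist = run_ga(fitness, 12, cfg)
        assert best.mask.all()
        assert np.all(hist.best == hist.best[0])
        assert np.all(hist.mean == hist.best)

    def test_same_seed_reproduces_history(self):
        def fitness(mask):
            return float(mask.sum()) / mask.size

        cfg = GAConfig(population=8, generations=10, seed=42)
        b1, h1 = run_ga(fitness, 30, cfg)
        b2, h2 = run_ga(fitness, 30, cfg)
        np.testing.assert_array_equal(b1.mask, b2.mask)
        np.testing.assert_array_equal(h1.best, h2.best)
        np.testing.assert_array_equal(h1.mean, h2.mean)

    def test_best_so_far_monotone_non_increasing(self):
        def fitness(mask):
            return float(((mask.astype(int) - (np.arange(mask.size) % 3 == 0)) ** 2).sum())

        cfg = GAConfig(population=10, generations=25, seed=3)
        _, hist = run_ga(fitness, 40, cfg)
        assert np.all(np.diff(hist.best) <= 1e-12)

    def test_planted_informative_wavelengths_recovered(self):
        """>= 4 of 5 planted wavelengths found in >= 90% of 20 seeded runs."""
        hits = 0
        for seed in range(20):
            X, y = _planted_necessary(seed)
            cfg = GAConfig(population=16, generations=18, mutation_rate=0.02,
                           penalty_lambda=0.05, n_lv=5, seed=seed)

            def fitness(mask):
                if mask.sum() < 5:
                    return np.inf
                return penalized_fitness(mask, X, y, 5, cfg.penalty_lambda)

            best, _ = run_ga(fitness, X.shape[1], cfg)
            if best.mask[:5].sum() >= 4:
                hits += 1
        assert hits >= 18

    def test_window_blocks_expand_to_contiguous_mask(self):
        def fitness(mask):
            return -float(mask[:10].sum())  # favor the first block

        cfg = GAConfig(population=8, generations=10, window_size=10, seed=1)
        best, _ = run_ga(fitness, 25, cfg)
        # mask length respects truncated last window
        assert best.mask.size == 25
        # bits act on whole blocks
        blocks = [best.mask[0:10], best.mask[10:20], best.mask[20:25]]
        for blk in blocks:
            assert blk.all() or not blk.any()


class TestGAFrontends:
    def test_ga_pls_restart_minimum(self, noisy_bundle):
        X = noisy_bundle.calibration_x.absorbance[:, ::6]  # thin for speed
        Y = noisy_bundle.calibration_y.concentrations
        cfg = GAConfig(population=8, generations=5, n_lv=2, seed=0, n_restarts=3)
        best, hists = ga_pls(X, Y, cfg)
        assert len(hists) == 3
        singles = []
        for r in range(3):
            single, _ = ga_pls(
                X, Y, GAConfig(population=8, generations=5, n_lv=2,
                               seed=cfg.seed + r, n_restarts=1)
            )
            singles.append(single.fitness)
        assert best.fitness == pytest.approx(min(singles), abs=1e-12)

    def test_selected_count_shrinks_as_lambda_grows(self):
        X, y = _planted_data(5, n=14, p=60)
        counts = []
        for lam in (0.0, 0.05, 0.5):
            cfg = GAConfig(population=16, generations=15, n_lv=2,
                           penalty_lambda=lam, seed=7)
            best, _ = ga_pls(X, y, cfg)
            counts.append(int(best.mask.sum()))
        assert counts[0] >= counts[1] >= counts[2]
        assert counts[2] < counts[0]

    def test_ga_icomp_beats_or_matches_full_spectrum(self, noisy_bundle):
        X = noisy_bundle.calibration_x.absorbance[:, ::6]
        Y = noisy_bundle.calibration_y.concentrations
        cfg = GAConfig(population=10, generations=8, n_lv=3, seed=2)
        best, score, model = ga_icomp_pls(X, Y, cfg)
        full = icomp_score(loo_residuals(X, Y, 3))
        assert best.mask.any()
        assert score.total <= full.total + 1e-9
        assert model.wavelength_mask.sum() == best.mask.sum()

    def test_ga_icomp_reproducible(self, noisy_bundle):
        X = noisy_bundle.calibration_x.absorbance[:, ::10]
        Y = noisy_bundle.calibration_y.concentrations
        cfg = GAConfig(population=8, generations=5, n_lv=2, seed=11)
        b1, s1, _ = ga_icomp_pls(X, Y, cfg)
        b2, s2, _ = ga_icomp_pls(X, Y, cfg)
        np.testing.assert_array_equal(b1.mask, b2.mask)
        assert s1.total == s2.total

    def test_sparser_selection_does_not_wreck_loo_error(self, noisy_bundle):
        # collinear spectra: selection drops variables without degrading
        # leave-one-out RMSE by more than 10% (across a few seeds)
        X = noisy_bundle.calibration_x.absorbance[:, ::6]
        Y = noisy_bundle.calibration_y.concentrations
        full_rmse = float(np.sqrt(np.mean(loo_residuals(X, Y, 3) ** 2)))
        ok = 0
        for seed in range(5):
            cfg = GAConfig(population=10, generations=8, n_lv=3, seed=seed)
            best, _, _ = ga_icomp_pls(X, Y, cfg)
            sel_rmse = float(
                np.sqrt(np.mean(loo_residuals(X, Y, 3, mask=best.mask) ** 2))
            )
            if best.mask.sum() < X.shape[1] and sel_rmse <= 1.10 * full_rmse:
                ok += 1
        assert ok >= 4
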