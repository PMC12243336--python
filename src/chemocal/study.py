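"""End-to-end study orchestration.

``run_study`` reproduces the full workflow on one synthetic bundle:
generate the calibration design and validation sets, optionally
preprocess, fit the requested calibration models (PLS, GA-PLS,
GA-ICOMP-PLS, ANN, MCR-ALS) and tabulate per-model, per-component
figures of merit (RMSEC, RMSEP, %RE, %RSD, r).  ``compare_sampling``
repeats the PLS prediction experiment over many seeds with LHS and
Monte Carlo validation sets to compare error stability and space
coverage of the two strategies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ann as ann_mod
from . import gaselect, mcr, pls
from .design import coverage_report
from .metrics import evaluate_predictions, rmse_family
from .preprocess import PreprocessConfig, preprocess_pipeline
from .simulate import NoiseSpec, StudyBundle, make_study
from .spectra import SpectralMatrix

__all__ = ["StudyConfig", "StudyResult", "run_study", "compare_sampling"]

log = logging.getLogger("chemocal.study")

ALL_MODELS = ("pls", "ga_pls", "ga_icomp_pls", "ann", "mcr_als")


@dataclass(frozen=True)
class StudyConfig:
    seed: int = 0
    noise: NoiseSpec | None = None
    preprocess_steps: tuple[str, ...] = ()
    preprocess: PreprocessConfig = PreprocessConfig()
    models: tuple[str, ...] = ALL_MODELS
    max_lv: int = 8
    n_lv: int | None = None          # fix the LV count; None = pick by RMSECV
    ga: gaselect.GAConfig = gaselect.GAConfig(generations=30, population=20)
    ann_hidden: int = 6
    ann_epochs: int = 500
    ann_goal: float = 1e-10
    mcr_tol: float = 1e-4
    n_validation: int = 13

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError("at least one model must be requested")
        unknown = set(self.models) - set(ALL_MODELS)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")


@dataclass(frozen=True)
class StudyResult:
    config: StudyConfig
    bundle: StudyBundle
    table: pd.DataFrame              # model x component metrics
    models: dict = field(repr=False)
    logs: dict = field(repr=False)


def _prep(x: SpectralMatrix, config: StudyConfig) -> SpectralMatrix:
    if not config.preprocess_steps:
        return x
    return preprocess_pipeline(x, config.preprocess_steps, config.preprocess)


def run_study(config: StudyConfig = StudyConfig()) -> StudyResult:
    """Run every requested model on one synthetic study bundle.

    Deterministic given ``config.seed``.  The table holds one row per
    (model, component) with RMSEC, RMSEP, %R, %RE, %RSD and r computed on
    the LHS validation set.
    """
    bundle = make_study(
        seed=config.seed, noise=config.noise, n_validation=config.n_validation
    )
    Xc = _prep(bundle.calibration_x, config)
    Xv = _prep(bundle.validation_lhs_x, config)
    Yc = bundle.calibration_y
    Yv = bundle.validation_lhs_y
    names = Yc.component_names
    yc, yv = Yc.concentrations, Yv.concentrations

    rows = []
    fitted = {}
    logs = {"seed": config.seed}

    def add_rows(model_name, pred_cal, pred_val, extra=None):
        rep = evaluate_predictions(pred_val, yv, names)
        for j, comp in enumerate(rep.components):
            rows.append(
                {
                    "model": model_name,
                    "component": comp.component,
                    "rmsec": rmse_family(pred_cal[:, j], yc[:, j], "rmsec"),
                    "rmsep": comp.rmsep,
                    "mean_R_pct": comp.stats.mean_R_pct,
                    "re_pct": comp.stats.re_pct,
                    "rsd_pct": comp.stats.rsd_pct,
                    "r": comp.stats.r,
                    **(extra or {}),
                }
            )

    if "pls" in config.models:
        if config.n_lv is None:
            curve = pls.loocv(Xc, Yc, max_lv=config.max_lv)
            n_lv = curve.selected_lv
            logs["pls_rmsecv"] = curve.rmsecv_per_lv.tolist()
        else:
            n_lv = config.n_lv
        log.info("PLS: %d latent variables", n_lv)
        model = pls.fit_pls(Xc, Yc, n_lv)
        fitted["pls"] = model
        logs["pls_n_lv"] = n_lv
        add_rows(
            "pls",
            np.asarray(pls.predict(model, Xc.absorbance)),
            np.asarray(pls.predict(model, Xv.absorbance)),
            {"n_lv": n_lv},
        )
    base_lv = logs.get("pls_n_lv", config.n_lv or config.ga.n_lv)

    if "ga_pls" in config.models:
        cfg = gaselect.GAConfig(
            population=config.ga.population,
            generations=config.ga.generations,
            mutation_rate=config.ga.mutation_rate,
            penalty_lambda=config.ga.penalty_lambda,
            window_size=config.ga.window_size,
            n_lv=min(base_lv, config.ga.n_lv),
            seed=config.seed,
            n_restarts=config.ga.n_restarts,
        )
        best, hist = gaselect.ga_pls(Xc, Yc, cfg)
        model = pls.fit_pls(Xc, Yc, cfg.n_lv, mask=best.mask)
        fitted["ga_pls"] = model
        logs["ga_pls_selected"] = int(best.mask.sum())
        log.info("GA-PLS: %d wavelengths selected", int(best.mask.sum()))
        add_rows(
            "ga_pls",
            np.asarray(pls.predict(model, Xc.absorbance)),
            np.asarray(pls.predict(model, Xv.absorbance)),
            {"n_selected": int(best.mask.sum())},
        )

    if "ga_icomp_pls" in config.models:
        cfg = gaselect.GAConfig(
            population=config.ga.population,
            generations=config.ga.generations,
            mutation_rate=config.ga.mutation_rate,
            window_size=config.ga.window_size,
            n_lv=min(base_lv, config.ga.n_lv),
            seed=config.seed,
            n_restarts=config.ga.n_restarts,
        )
        best, score, model = gaselect.ga_icomp_pls(Xc, Yc, cfg)
        fitted["ga_icomp_pls"] = model
        logs["ga_icomp_selected"] = int(best.mask.sum())
        logs["ga_icomp_total"] = score.total
        log.info(
            "GA-ICOMP-PLS: %d wavelengths, ICOMP %.3f",
            int(best.mask.sum()), score.total,
        )
        add_rows(
            "ga_icomp_pls",
            np.asarray(pls.predict(model, Xc.absorbance)),
            np.asarray(pls.predict(model, Xv.absorbance)),
            {"n_selected": int(best.mask.sum())},
        )

    if "ann" in config.models:
        model, record = ann_mod.fit_ann(
            Xc.absorbance,
            yc,
            n_hidden=config.ann_hidden,
            epochs=config.ann_epochs,
            goal=config.ann_goal,
            seed=config.seed,
        )
        fitted["ann"] = model
        logs["ann_final_mse"] = float(record.mse[-1]) if record.mse.size else None
        logs["ann_stopped"] = record.stopped
        add_rows(
            "ann",
            ann_mod.predict_ann(model, Xc.absorbance),
            ann_mod.predict_ann(model, Xv.absorbance),
        )

    if "mcr_als" in config.models:
        stacked = np.vstack([Xc.absorbance, Xv.absorbance])
        result = mcr.mcr_als(stacked, k=2, tol=config.mcr_tol)
        fitted["mcr_als"] = result
        logs["mcr_lof_pct"] = result.lof_pct
        logs["mcr_n_iter"] = result.n_iter
        log.info("MCR-ALS: lof %.4f%% after %d iterations", result.lof_pct, result.n_iter)
        cal_rows = np.arange(Xc.n_samples)
        val_rows = np.arange(Xc.n_samples, stacked.shape[0])
        pred_cal = mcr.quantify_from_mcr(result, Yc, cal_rows, cal_rows)
        pred_val = mcr.quantify_from_mcr(result, Yc, cal_rows, val_rows)
        add_rows("mcr_als", pred_cal, pred_val, {"lof_pct": result.lof_pct})

    table = pd.DataFrame(rows)
    return StudyResult(config, bundle, table, fitted, logs)


def compare_sampling(
    config: StudyConfig = StudyConfig(),
    n_repeats: int = 50,
    noise_sd: float = 0.005,
    fixed_calibration: bool = False,
) -> pd.DataFrame:
    """LHS vs Monte Carlo validation sets over repeated seeds.

    In the default mode each repeat generates a fresh bundle at additive
    noise *noise_sd*, fits a PLS model on its calibration set and
    predicts both validation sets.  With ``fixed_calibration=True`` one
    calibration model (seed ``config.seed``) is fitted once and only the
    validation sets are re-drawn per repeat, which isolates the effect of
    validation-set placement on the stability of the RMSEP estimate.

    Returns one row per (method, repeat) with the pooled RMSEP and
    coverage statistics (stratum occupancy at ``n_validation`` bins,
    minimum pairwise distance).
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    from .design import lhs_sample, mc_sample
    from .simulate import default_components, default_grid, simulate_mixtures
    from .spectra import ConcentrationMatrix

    rows = []
    n_lv = config.n_lv or 2
    bounds = ((5.0, 25.0), (5.0, 25.0))
    noise = lambda s: NoiseSpec(additive_sd=noise_sd, scatter_sd=0.0,  # noqa: E731
                                baseline_slope_sd=0.0, seed=s)
    grid = default_grid()
    specs = default_components(grid)
    model = None
    if fixed_calibration:
        bundle = make_study(seed=config.seed, noise=noise(config.seed),
                            n_validation=config.n_validation)
        model = pls.fit_pls(bundle.calibration_x, bundle.calibration_y, n_lv)
    for rep in range(n_repeats):
        seed = config.seed + rep
        if not fixed_calibration:
            bundle = make_study(seed=seed, noise=noise(seed),
                                n_validation=config.n_validation)
            model = pls.fit_pls(bundle.calibration_x, bundle.calibration_y, n_lv)
        plans = {
            "lhs": lhs_sample(config.n_validation, 2, bounds,
                              seed=config.seed + 7919 * rep + 1),
            "mc": mc_sample(config.n_validation, 2, bounds,
                            seed=config.seed + 7919 * rep + 2),
        }
        for method, plan in plans.items():
            yv = ConcentrationMatrix(
                plan.points, ("analyte_a", "analyte_b"),
                tuple(f"v{i}" for i in range(plan.n_points)),
            )
            xv = simulate_mixtures(yv, specs, noise(seed + 101), grid)
            pred = np.asarray(pls.predict(model, xv.absorbance))
            rmsep = rmse_family(pred, yv.concentrations)
            cov = coverage_report(plan, config.n_validation)
            rows.append(
                {
                    "method": method,
                    "repeat": rep,
                    "seed": seed,
                    "rmsep": rmsep,
                    "empty_bins_dim0": int(cov.n_empty_bins[0]),
                    "empty_bins_dim1": int(cov.n_empty_bins[1]),
                    "min_distance": cov.min_pairwise_distance,
                }
            )
    return pd.DataFrame(rows)
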