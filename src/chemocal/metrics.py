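"""Figures of merit and method-comparison statistics.

Covers the RMSE family (RMSEC on calibration fits, RMSECV on
cross-validation hold-outs, RMSEP on independent validation predictions),
recovery statistics (%R = 100*found/true with SD, %RSD, %RE), the
predicted-vs-actual regression line and Pearson r, two-sample t and F
method comparisons at runtime-computed critical values, and relative
RMSEP reduction between models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "EvaluationReport",
    "MethodComparison",
    "rmse_family",
    "recovery_stats",
    "evaluate_predictions",
    "compare_methods",
    "rmsep_reduction",
]


def rmse_family(predicted, actual, kind: str = "rmsep") -> float:
    """Root mean square error sqrt(sum((yhat - y)^2) / n).

    *kind* labels which sample set the vectors came from (``rmsec``,
    ``rmsecv`` or ``rmsep``); the formula is shared.
    """
    predicted = np.asarray(predicted, float).ravel()
    actual = np.asarray(actual, float).ravel()
    if predicted.size == 0:
        raise ValueError("empty vectors")
    if predicted.shape != actual.shape:
        raise ValueError(
            f"length mismatch: {predicted.size} predictions for "
            f"{actual.size} actual values"
        )
    if kind not in ("rmsec", "rmsecv", "rmsep"):
        raise ValueError(f"unknown RMSE kind {kind!r}")
    return float(np.sqrt(np.mean((predicted - actual) ** 2)))


@dataclass(frozen=True)
class RecoveryStats:
    mean_R_pct: float
    sd: float
    variance: float
    rsd_pct: float
    re_pct: float
    r: float | None           # None when either vector is constant
    slope: float
    intercept: float
    n: int


def recovery_stats(predicted, actual) -> RecoveryStats:
    """Recovery and regression statistics of predictions against truth.

    %R_i = 100 * yhat_i / y_i; SD uses n-1; %RSD = 100*SD/mean(%R);
    %RE = 100 * mean(|yhat - y| / y); slope/intercept from the ordinary
    least-squares line of predicted on actual; r is the Pearson
    correlation (reported as None, not 0, when undefined).
    """
    predicted = np.asarray(predicted, float).ravel()
    actual = np.asarray(actual, float).ravel()
    if predicted.shape != actual.shape:
        raise ValueError("length mismatch")
    if predicted.size < 2:
        raise ValueError("need at least 2 samples")
    if np.any(actual <= 0):
        raise ValueError("actual concentrations must be strictly positive")
    rec = 100.0 * predicted / actual
    mean_R = float(rec.mean())
    sd = float(rec.std(ddof=1))
    rsd = 100.0 * sd / mean_R if mean_R != 0 else float("inf")
    re = float(100.0 * np.mean(np.abs(predicted - actual) / actual))
    constant = np.ptp(actual) == 0 or np.ptp(predicted) == 0
    r = None if constant else float(np.corrcoef(predicted, actual)[0, 1])
    if np.ptp(actual) == 0:
        slope, intercept = 0.0, float(predicted.mean())
    else:
        slope, intercept = np.polyfit(actual, predicted, 1)
    return RecoveryStats(
        mean_R, sd, sd**2, rsd, re, r, float(slope), float(intercept), predicted.size
    )


@dataclass(frozen=True)
class ComponentReport:
    component: str
    rmsec: float | None
    rmsecv: float | None
    rmsep: float | None
    recoveries_pct: np.ndarray
    stats: RecoveryStats


@dataclass(frozen=True)
class EvaluationReport:
    """Per-component figures of merit for one model."""

    components: tuple[ComponentReport, ...]

    def as_dict(self) -> dict:
        out = {}
        for c in self.components:
            out[c.component] = {
                "rmsec": c.rmsec,
                "rmsecv": c.rmsecv,
                "rmsep": c.rmsep,
                "mean_R_pct": c.stats.mean_R_pct,
                "sd": c.stats.sd,
                "rsd_pct": c.stats.rsd_pct,
                "re_pct": c.stats.re_pct,
                "r": c.stats.r,
                "slope": c.stats.slope,
                "intercept": c.stats.intercept,
                "n": c.stats.n,
            }
        return out


def evaluate_predictions(
    predicted: np.ndarray,
    actual: np.ndarray,
    component_names=None,
    rmsec=None,
    rmsecv=None,
) -> EvaluationReport:
    """Bundle per-component validation metrics into an EvaluationReport.

    *predicted*/*actual* are n x q blocks for the validation set; RMSEP is
    computed here, RMSEC/RMSECV (per component or scalar) may be supplied
    from the calibration stage.
    """
    predicted = np.atleast_2d(np.asarray(predicted, float))
    actual = np.atleast_2d(np.asarray(actual, float))
    q = predicted.shape[1]
    if component_names is None:
        component_names = tuple(f"component_{i + 1}" for i in range(q))

    def _per_comp(value, j):
        if value is None:
            return None
        arr = np.atleast_1d(np.asarray(value, float))
        return float(arr[j]) if arr.size > 1 else float(arr[0])

    reports = []
    for j in range(q):
        st = recovery_stats(predicted[:, j], actual[:, j])
        reports.append(
            ComponentReport(
                component=str(component_names[j]),
                rmsec=_per_comp(rmsec, j),
                rmsecv=_per_comp(rmsecv, j),
                rmsep=rmse_family(predicted[:, j], actual[:, j]),
                recoveries_pct=100.0 * predicted[:, j] / actual[:, j],
                stats=st,
            )
        )
    return EvaluationReport(tuple(reports))


@dataclass(frozen=True)
class MethodComparison:
    t_stat: float
    f_stat: float
    df_t: int
    df_f_num: int
    df_f_den: int
    t_crit: float
    f_crit: float
    alpha: float
    paired: bool = False


def compare_methods(
    recoveries_a, recoveries_b, alpha: float = 0.05, paired: bool = False
) -> MethodComparison:
    """Student t and F comparison of two sets of recoveries.

    Two-sample pooled-variance t by default (a paired t is available);
    F is the larger variance over the smaller so F >= 1.  Critical values
    come from the t and F quantiles at *alpha* (two-tailed t, upper-tail F
    following the analytical-chemistry convention).
    """
    a = np.asarray(recoveries_a, float).ravel()
    b = np.asarray(recoveries_b, float).ravel()
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va >= vb:
        f_stat = va / vb if vb > 0 else float("inf")
        df_num, df_den = a.size - 1, b.size - 1
    else:
        f_stat = vb / va if va > 0 else float("inf")
        df_num, df_den = b.size - 1, a.size - 1
    if paired:
        if a.size != b.size:
            raise ValueError("paired comparison needs equal group sizes")
        d = a - b
        df_t = a.size - 1
        sd = d.std(ddof=1)
        if sd == 0:
            t_stat = 0.0 if d.mean() == 0 else float("inf")
        else:
            t_stat = float(d.mean() / (sd / np.sqrt(a.size)))
    else:
        df_t = a.size + b.size - 2
        pooled = ((a.size - 1) * va + (b.size - 1) * vb) / df_t
        if pooled == 0:
            t_stat = 0.0 if a.mean() == b.mean() else float("inf")
        else:
            t_stat = float(
                (a.mean() - b.mean())
                / np.sqrt(pooled * (1 / a.size + 1 / b.size))
            )
    t_crit = float(stats.t.ppf(1 - alpha / 2, df_t))
    f_crit = float(stats.f.ppf(1 - alpha, df_num, df_den))
    return MethodComparison(
        t_stat, float(f_stat), df_t, df_num, df_den, t_crit, f_crit, alpha, paired
    )


def rmsep_reduction(rmsep_model: float, rmsep_baseline: float) -> float:
    """Relative RMSEP reduction, percent: 100*(baseline - model)/baseline."""
    if rmsep_baseline <= 0:
        raise ValueError("baseline RMSEP must be positive")
    return 100.0 * (rmsep_baseline - rmsep_model) / rmsep_baseline
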