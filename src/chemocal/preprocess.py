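"""Signal enhancement for UV spectra and PCA diagnostics.

The enhancement chain mirrors common chemometric practice: Savitzky-Golay
smoothing (default third-order polynomial over an eleven-point window),
spectral derivatives (first derivative by default; the second is noisier),
and standard normal variate (SNV) normalisation against scatter and
path-length effects.  Mean-centering for PLS/PCA is applied last when
requested.  ``pca_summary`` gives the score plot / explained-variance
diagnostics used to judge dataset homogeneity before calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import savgol_filter

from .spectra import SpectralMatrix, mean_center

__all__ = [
    "PreprocessConfig",
    "PCASummary",
    "savgol",
    "snv",
    "preprocess_pipeline",
    "pca_summary",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Savitzky-Golay / derivative settings.

    window_points must be odd and exceed poly_order; derivative_order must
    not exceed poly_order.  step_nm sets the derivative units (AU per nm^d);
    when None it is taken from the spectral grid.
    """

    window_points: int = 11
    poly_order: int = 3
    derivative_order: int = 0
    apply_snv: bool = False
    step_nm: float | None = None

    def __post_init__(self) -> None:
        if self.window_points % 2 == 0:
            raise ValueError(f"window_points must be odd, got {self.window_points}")
        if self.window_points <= self.poly_order:
            raise ValueError(
                f"window_points ({self.window_points}) must exceed "
                f"poly_order ({self.poly_order})"
            )
        if self.derivative_order not in (0, 1, 2):
            raise ValueError("derivative_order must be 0, 1 or 2")
        if self.derivative_order > self.poly_order:
            raise ValueError("derivative_order cannot exceed poly_order")


_DERIV_STAGE = {0: "smoothed", 1: "derivative1", 2: "derivative2"}


def savgol(spectra: SpectralMatrix, config: PreprocessConfig = PreprocessConfig()) -> SpectralMatrix:
    """Savitzky-Golay smoothing / differentiation along the wavelength axis.

    Output keeps the full grid length: edge points come from the polynomial
    fitted to the nearest complete window.  Derivative values are scaled by
    ``step_nm**-d`` so they are grid-independent (AU nm^-d).
    """
    if config.window_points > spectra.n_wavelengths:
        raise ValueError(
            f"window ({config.window_points}) exceeds spectrum length "
            f"({spectra.n_wavelengths})"
        )
    step = config.step_nm if config.step_nm is not None else spectra.grid.step_nm
    values = savgol_filter(
        spectra.absorbance,
        window_length=config.window_points,
        polyorder=config.poly_order,
        deriv=config.derivative_order,
        delta=step,
        axis=1,
        mode="interp",
    )
    return spectra.with_values(values, _DERIV_STAGE[config.derivative_order])


def snv(spectra: SpectralMatrix) -> SpectralMatrix:
    """Standard normal variate: center and scale each spectrum to unit SD.

    Uses the sample (n-1) standard deviation.  A constant spectrum has no
    scatter information to normalise and is rejected by sample id.
    """
    a = spectra.absorbance
    sd = a.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"constant spectrum cannot be SNV-normalised: sample "
            f"{spectra.sample_ids[bad[0]]!r}"
        )
    values = (a - a.mean(axis=1, keepdims=True)) / sd[:, None]
    return spectra.with_values(values, "snv")


def preprocess_pipeline(
    spectra: SpectralMatrix,
    steps,
    config: PreprocessConfig = PreprocessConfig(),
) -> SpectralMatrix:
    """Apply named steps in order.

    Steps are drawn from ``savgol``, ``derivative1``, ``derivative2``,
    ``snv`` and ``mean_center``; an empty list returns the input unchanged.
    ``derivative1``/``derivative2`` are Savitzky-Golay differentiations with
    the same window/polynomial as smoothing.
    """
    out = spectra
    for step in steps:
        if step == "savgol":
            out = savgol(out, replace(config, derivative_order=0))
        elif step in ("derivative1", "deriv1"):
            out = savgol(out, replace(config, derivative_order=1))
        elif step in ("derivative2", "deriv2"):
            out = savgol(out, replace(config, derivative_order=2))
        elif step == "snv":
            out = snv(out)
        elif step == "mean_center":
            out, _ = mean_center(out)
        else:
            raise ValueError(f"unknown preprocessing step {step!r}")
    return out


@dataclass(frozen=True)
class PCASummary:
    """Scores and explained variance of a principal component analysis."""

    scores: np.ndarray        # n_samples x n_pcs
    variance_pct: np.ndarray  # per-PC percentage of total variance
    set_labels: tuple[str, ...]


def pca_summary(spectra: SpectralMatrix, set_labels=None, n_pcs: int | None = None) -> PCASummary:
    """PCA of the mean-centered spectra via singular value decomposition.

    variance_pct[i] = 100 * s_i^2 / sum(s^2); scores are U * s so their
    total variance equals that of the centered data.
    """
    if spectra.n_samples < 2:
        raise ValueError("PCA requires at least 2 samples")
    centered, _ = mean_center(spectra.absorbance)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    k = len(s) if n_pcs is None else min(n_pcs, len(s))
    total = float((s**2).sum())
    variance_pct = 100.0 * s[:k] ** 2 / total if total > 0 else np.zeros(k)
    scores = u[:, :k] * s[:k]
    if set_labels is None:
        set_labels = ("calibration",) * spectra.n_samples
    set_labels = tuple(set_labels)
    if len(set_labels) != spectra.n_samples:
        raise ValueError("one set label per sample required")
    return PCASummary(scores, variance_pct, set_labels)
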