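"""Partial least squares regression by NIPALS, with leave-one-out CV.

PLS relates the spectral block X (samples x wavelengths) to the
concentration block Y (samples x components) through a small number of
latent variables (LVs): orthogonal score directions t_a = X w_a extracted
by the classical NIPALS deflation.  Both components are modelled jointly
(PLS2) by default; single-response PLS1 falls out of passing a single Y
column.  LV count is chosen by the leave-one-out RMSECV minimum, ties
broken toward the simpler model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import ConcentrationMatrix, SpectralMatrix, check_aligned

__all__ = ["PLSModel", "CVCurve", "fit_pls", "predict", "loocv", "loo_residuals"]

_NIPALS_TOL = 1e-12
_NIPALS_MAX_ITER = 500


@dataclass(frozen=True)
class PLSModel:
    """Fitted NIPALS PLS model on (optionally masked) wavelengths."""

    n_lv: int
    x_weights: np.ndarray      # p_sel x A   (W, unit columns)
    x_loadings: np.ndarray     # p_sel x A   (P)
    y_loadings: np.ndarray     # q x A       (Q)
    x_scores: np.ndarray       # n x A       (T, mutually orthogonal)
    coefficients: np.ndarray   # p_sel x q   (B: centered X -> centered Y)
    x_mean: np.ndarray
    y_mean: np.ndarray
    wavelength_mask: np.ndarray  # boolean over the full grid
    component_names: tuple[str, ...] = ()


@dataclass(frozen=True)
class CVCurve:
    """RMSECV per candidate LV count and the selected count."""

    rmsecv_per_lv: np.ndarray   # index k-1 -> RMSECV at k LVs
    selected_lv: int


def _as_xy(X, Y, mask=None):
    """Coerce inputs to arrays; returns (Xarr, Yarr, mask, names)."""
    names = ()
    if isinstance(X, SpectralMatrix):
        if isinstance(Y, ConcentrationMatrix):
            check_aligned(X, Y)
        Xarr = X.absorbance
    else:
        Xarr = np.atleast_2d(np.asarray(X, float))
    if isinstance(Y, ConcentrationMatrix):
        Yarr = Y.concentrations
        names = Y.component_names
    else:
        Yarr = np.asarray(Y, float)
        if Yarr.ndim == 1:
            Yarr = Yarr[:, None]
    if Xarr.shape[0] != Yarr.shape[0]:
        raise ValueError(
            f"X has {Xarr.shape[0]} samples but Y has {Yarr.shape[0]}"
        )
    p = Xarr.shape[1]
    if mask is None:
        mask = np.ones(p, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (p,):
            raise ValueError(f"mask length {mask.size} != {p} wavelengths")
        if not mask.any():
            raise ValueError("mask selects no wavelengths")
    return Xarr, Yarr, mask, names


def _nipals(X0: np.ndarray, Y0: np.ndarray, n_lv: int, strict: bool = True):
    """Classical NIPALS on centered blocks; returns (W, P, Q, T).

    With ``strict=False`` a rank deficiency truncates the extraction
    instead of raising, returning however many components exist.
    """
    n, p = X0.shape
    q = Y0.shape[1]
    X, Y = X0.copy(), Y0.copy()
    W = np.empty((p, n_lv))
    P = np.empty((p, n_lv))
    Q = np.empty((q, n_lv))
    T = np.empty((n, n_lv))
    # deflation scale: component below this fraction of the original block
    # energy is numerical residue, not signal
    x_scale = np.linalg.norm(X0)
    for a in range(n_lv):
        u = Y[:, int(np.argmax(Y.var(axis=0)))].copy()
        if not np.any(u):
            u = Y[:, 0].copy()
        t = np.zeros(n)
        deficient = False
        for _ in range(_NIPALS_MAX_ITER):
            w = X.T @ u
            norm = np.linalg.norm(w)
            if norm < 1e-13 * max(x_scale, 1e-300):
                deficient = True
                break
            w /= norm
            t_new = X @ w
            tt = t_new @ t_new
            if tt < (1e-13 * max(x_scale, 1e-300)) ** 2:
                deficient = True
                break
            qa = Y.T @ t_new / tt
            if np.linalg.norm(t_new - t) <= _NIPALS_TOL * np.linalg.norm(t_new):
                t = t_new
                break
            t = t_new
            qq = qa @ qa
            u = Y @ qa / qq if qq > 0 else Y[:, 0]
            if Y0.shape[1] == 1:
                break  # single response: weight vector is already converged
        if deficient:
            if strict:
                raise np.linalg.LinAlgError(
                    f"X block is rank deficient below {n_lv} latent "
                    f"variables (failed at LV {a + 1})"
                )
            return W[:, :a], P[:, :a], Q[:, :a], T[:, :a]
        tt = t @ t
        pa = X.T @ t / tt
        qa = Y.T @ t / tt
        X = X - np.outer(t, pa)
        Y = Y - np.outer(t, qa)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, pa, qa, t
    return W, P, Q, T


def _coefficients(W, P, Q, k: int) -> np.ndarray:
    """Regression matrix B_k for the first k latent variables.

    k is capped at the number of components actually extracted (a
    truncated non-strict NIPALS run may hold fewer than requested).
    """
    k = min(k, W.shape[1])
    if k == 0:
        return np.zeros((W.shape[0], Q.shape[0]))
    Wk, Pk, Qk = W[:, :k], P[:, :k], Q[:, :k]
    return Wk @ np.linalg.solve(Pk.T @ Wk, Qk.T)


def fit_pls(X, Y, n_lv: int, mask=None) -> PLSModel:
    """Fit a NIPALS PLS model with *n_lv* latent variables.

    *mask* (boolean over wavelengths) restricts the model to selected
    variables; centering statistics are computed on the masked block.
    """
    Xarr, Yarr, mask, names = _as_xy(X, Y, mask)
    Xs = Xarr[:, mask]
    n, p_sel = Xs.shape
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    if n_lv > min(n - 1, p_sel):
        raise ValueError(
            f"n_lv = {n_lv} exceeds min(n_samples - 1, n_selected) = "
            f"{min(n - 1, p_sel)}"
        )
    if np.any(Yarr.var(axis=0) == 0):
        raise ValueError("Y has a zero-variance column; nothing to model")
    x_mean = Xs.mean(axis=0)
    y_mean = Yarr.mean(axis=0)
    W, P, Q, T = _nipals(Xs - x_mean, Yarr - y_mean, n_lv)
    B = _coefficients(W, P, Q, n_lv)
    return PLSModel(n_lv, W, P, Q, T, B, x_mean, y_mean, mask, names)


def predict(model: PLSModel, X):
    """Predict concentrations for new spectra.

    Returns a :class:`ConcentrationMatrix` when given a
    :class:`SpectralMatrix`, else a plain array.
    """
    if isinstance(X, SpectralMatrix):
        Xarr = X.absorbance
        ids = X.sample_ids
    else:
        Xarr = np.atleast_2d(np.asarray(X, float))
        ids = None
    if Xarr.shape[1] != model.wavelength_mask.size:
        raise ValueError(
            f"spectra have {Xarr.shape[1]} wavelengths; model expects "
            f"{model.wavelength_mask.size}"
        )
    yhat = (Xarr[:, model.wavelength_mask] - model.x_mean) @ model.coefficients
    yhat = yhat + model.y_mean
    if ids is not None:
        names = model.component_names or tuple(
            f"component_{i + 1}" for i in range(yhat.shape[1])
        )
        # predictions may dip fractionally below zero; report them as-is
        # through a plain array if the container would reject them
        if yhat.min() >= 0:
            return ConcentrationMatrix(yhat, names, ids)
    return yhat


def loo_residuals(X, Y, n_lv: int, mask=None) -> np.ndarray:
    """Leave-one-out prediction residuals (yhat - y), n x q.

    One NIPALS fit per held-out sample at the requested LV count.
    """
    Xarr, Yarr, mask, _ = _as_xy(X, Y, mask)
    Xs = Xarr[:, mask]
    n, q = Yarr.shape
    if n_lv > n - 2:
        raise ValueError(f"n_lv = {n_lv} needs at least {n_lv + 2} samples")
    res = np.empty((n, q))
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        Xi, Yi = Xs[keep], Yarr[keep]
        xm, ym = Xi.mean(axis=0), Yi.mean(axis=0)
        W, P, Q, _ = _nipals(Xi - xm, Yi - ym, n_lv, strict=False)
        B = _coefficients(W, P, Q, n_lv)
        res[i] = (Xs[i] - xm) @ B + ym - Yarr[i]
    return res


def loocv(X, Y, max_lv: int, mask=None) -> CVCurve:
    """Leave-one-out RMSECV for 1..max_lv latent variables.

    RMSECV_k pools all responses: sqrt(sum of squared held-out errors /
    (n * q)).  The selected LV count attains the minimum, ties broken
    toward fewer LVs.  Each held-out fit is run once at max_lv and the
    per-k prediction curve extracted from its deflation sequence.
    """
    Xarr, Yarr, mask, _ = _as_xy(X, Y, mask)
    Xs = Xarr[:, mask]
    n, q = Yarr.shape
    if max_lv < 1:
        raise ValueError("max_lv must be >= 1")
    if max_lv > n - 2:
        raise ValueError(f"max_lv = {max_lv} too large for n = {n} samples")
    if max_lv > Xs.shape[1]:
        raise ValueError(
            f"max_lv = {max_lv} exceeds {Xs.shape[1]} selected wavelengths"
        )
    sse = np.zeros(max_lv)
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        Xi, Yi = Xs[keep], Yarr[keep]
        xm, ym = Xi.mean(axis=0), Yi.mean(axis=0)
        W, P, Q, _ = _nipals(Xi - xm, Yi - ym, max_lv, strict=False)
        xc = Xs[i] - xm
        for k in range(1, max_lv + 1):
            err = xc @ _coefficients(W, P, Q, k) + ym - Yarr[i]
            sse[k - 1] += err @ err
    rmsecv = np.sqrt(sse / (n * q))
    selected = int(np.argmin(rmsecv)) + 1  # argmin takes the first (fewest-LV) tie
    return CVCurve(rmsecv, selected)
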