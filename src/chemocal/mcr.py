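"""Multivariate curve resolution by alternating least squares (MCR-ALS).

Factorises an absorbance block ``D (n x p)`` into non-negative
concentration profiles ``C (n x k)`` and spectral profiles ``S (p x k)``
with ``D ~ C S'``.  Both conditional updates are true non-negative least
squares (active-set NNLS per column, not zero-clipping), which makes the
lack of fit monotone non-increasing over iterations.  Convergence is
declared when the relative change in lack of fit between iterations falls
below the tolerance (default 1%, the conventional residual-change
criterion).

Figures of merit: ``lof% = 100 sqrt(sum e^2 / sum d^2)``,
``r2% = 100 (1 - (lof/100)^2)`` and the residual SD
``sqrt(sum e^2 / (n p))``.

The intrinsic scale/permutation ambiguity of bilinear models is resolved
only at quantification time (:func:`quantify_from_mcr`): resolved
components are matched to analytes by spectral correlation against
calibration pure-spectrum estimates, and a univariate regression of the
resolved concentration profile on the known calibration concentrations
converts profile units to ug/mL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import nnls

from .spectra import ConcentrationMatrix, SpectralMatrix

__all__ = ["MCRResult", "init_profiles", "mcr_als", "quantify_from_mcr"]


@dataclass(frozen=True)
class MCRResult:
    C: np.ndarray              # n x k, arbitrary scale, >= 0
    S: np.ndarray              # p x k, >= 0
    lof_pct: float
    r2_pct: float
    residual_sd: float
    n_iter: int
    converged: bool
    lof_history: np.ndarray    # lof after each ALS iteration


def _as_matrix(D) -> np.ndarray:
    if isinstance(D, SpectralMatrix):
        return D.absorbance
    return np.atleast_2d(np.asarray(D, float))


def init_profiles(D, k: int) -> np.ndarray:
    """Initial spectral profiles by maximum dissimilarity (p x k).

    The first profile is the sample spectrum of largest norm; each next
    one maximises the residual after projection onto the span of those
    already chosen.  Deterministic.
    """
    Dm = _as_matrix(D)
    n, p = Dm.shape
    if not 1 <= k <= min(n, p):
        raise ValueError(f"k = {k} outside [1, min(n, p) = {min(n, p)}]")
    chosen = [int(np.argmax(np.linalg.norm(Dm, axis=1)))]
    for _ in range(1, k):
        basis = Dm[chosen].T                     # p x m
        q, _ = np.linalg.qr(basis)
        resid = Dm - (Dm @ q) @ q.T
        scores = np.linalg.norm(resid, axis=1)
        scores[chosen] = -1.0
        chosen.append(int(np.argmax(scores)))
    S0 = Dm[chosen].T.copy()
    return np.maximum(S0, 0.0)


def _nnls_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Solve min ||A x_j - b_j|| s.t. x_j >= 0 for every column b_j of B."""
    out = np.empty((A.shape[1], B.shape[1]))
    for j in range(B.shape[1]):
        out[:, j], _ = nnls(A, B[:, j])
    return out


def mcr_als(
    D,
    k: int = 2,
    tol: float = 0.01,
    max_iter: int = 500,
    S0: np.ndarray | None = None,
) -> MCRResult:
    """Alternating non-negative least squares resolution of D ~ C S'.

    Each iteration solves C given S then S given C, both under exact
    non-negativity.  Stops when the relative lack-of-fit change drops
    below *tol* (default 0.01 = the 1% residual-change criterion) or at
    *max_iter*.
    """
    Dm = _as_matrix(D)
    n, p = Dm.shape
    if k < 1:
        raise ValueError("k must be >= 1")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    ss_total = float(np.sum(Dm**2))
    if ss_total == 0:
        raise ValueError("data matrix is identically zero")
    S = init_profiles(Dm, k) if S0 is None else np.asarray(S0, float).copy()
    if S.shape != (p, k):
        raise ValueError(f"S0 must be {p} x {k}, got {S.shape}")
    lof_hist = []
    prev_lof = None
    converged = False
    C = np.zeros((n, k))
    for it in range(1, max_iter + 1):
        C = _nnls_rows(S, Dm.T).T          # rows of D on the spectral basis
        S = _nnls_rows(C, Dm).T            # columns of D on the conc. basis
        resid = Dm - C @ S.T
        lof = 100.0 * np.sqrt(np.sum(resid**2) / ss_total)
        lof_hist.append(lof)
        if lof < 1e-9:   # exact factorization reached
            converged = True
            break
        if prev_lof is not None:
            if abs(prev_lof - lof) / prev_lof < tol:
                converged = True
                break
        prev_lof = lof
    lof = lof_hist[-1]
    resid = Dm - C @ S.T
    return MCRResult(
        C=C,
        S=S,
        lof_pct=lof,
        r2_pct=100.0 * (1.0 - (lof / 100.0) ** 2),
        residual_sd=float(np.sqrt(np.sum(resid**2) / (n * p))),
        n_iter=it,
        converged=converged,
        lof_history=np.asarray(lof_hist),
    )


def quantify_from_mcr(
    result: MCRResult,
    calibration: ConcentrationMatrix,
    calibration_rows,
    query_rows,
    method: str = "joint",
) -> np.ndarray:
    """Concentrations (ug/mL) for *query_rows* from resolved profiles.

    *calibration_rows*/*query_rows* index rows of the resolved ``C`` that
    correspond to the calibration set and to the samples to quantify.

    ``method="joint"`` (default) regresses each known analyte
    concentration on *all* resolved profiles jointly (OLS with intercept,
    fitted on the calibration rows).  A bilinear factorisation is only
    identified up to an invertible mixing of its factors, and the joint
    map inverts whatever mixing ALS settled on, so noise-free recovery is
    exact even when the resolved profiles are rotated combinations of the
    true ones.

    ``method="univariate"`` assigns each analyte its best-correlated
    resolved profile (the assignment must be unambiguous) and inverts a
    per-analyte straight line; it assumes rotation is negligible.
    """
    cal_rows = np.asarray(calibration_rows, int)
    qry_rows = np.asarray(query_rows, int)
    Ck = result.C[cal_rows]                       # n_cal x k
    known = calibration.concentrations            # n_cal x q
    if Ck.shape[0] != known.shape[0]:
        raise ValueError("calibration rows and concentration table differ in length")
    k, q = Ck.shape[1], known.shape[1]
    if k < q:
        raise ValueError(f"only {k} resolved components for {q} analytes")
    if method == "joint":
        A = np.column_stack([Ck, np.ones(len(cal_rows))])
        coef, *_ = np.linalg.lstsq(A, known, rcond=None)
        Aq = np.column_stack([result.C[qry_rows], np.ones(len(qry_rows))])
        return Aq @ coef
    if method != "univariate":
        raise ValueError(f"unknown method {method!r}")
    corr = np.empty((k, q))
    for i in range(k):
        for j in range(q):
            ci = Ck[:, i]
            if np.ptp(ci) == 0:
                corr[i, j] = -np.inf
            else:
                corr[i, j] = np.corrcoef(ci, known[:, j])[0, 1]
    assignment = {}
    for j in range(q):
        assignment[j] = int(np.argmax(corr[:, j]))
    if len(set(assignment.values())) != q:
        raise ValueError(
            "ambiguous component-to-analyte assignment; correlation matrix:\n"
            f"{np.round(corr, 4)}"
        )
    out = np.empty((len(qry_rows), q))
    for j, comp in assignment.items():
        slope, intercept = np.polyfit(known[:, j], Ck[:, comp], 1)
        if slope == 0:
            raise ValueError(f"flat calibration for analyte {j}")
        out[:, j] = (result.C[qry_rows, comp] - intercept) / slope
    return out
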