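"""Small feed-forward network trained by Levenberg-Marquardt.

The calibration network maps a spectrum (default 301 inputs) through a
single tanh ("tansig") hidden layer (default 6 neurons) to linear
("purelin") concentration outputs.  Inputs and outputs are min-max scaled
to [-1, 1] on the training partition only.  Training follows the classic
LM recipe: solve ``(J'J + mu I) d = -J' e`` with the damping ``mu``
multiplied by 10 on a rejected step and divided by 10 on an accepted one,
so the training MSE over accepted steps is strictly decreasing.  Because
the parameter count usually exceeds the residual count here, the step is
computed through the dual system ``d = -J' (J J' + mu I)^{-1} e``, which
is algebraically identical and much cheaper.

Samples are partitioned 70/15/15 (round-half-up on the train and
validation shares) into training, monitoring-validation and test sets;
validation MSE is recorded but early stopping is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .spectra import ConcentrationMatrix, SpectralMatrix

__all__ = [
    "ANNModel",
    "TrainRecord",
    "partition_70_15_15",
    "init_ann",
    "train_lm",
    "predict_ann",
    "fit_ann",
    "hidden_sweep",
]


@dataclass(frozen=True)
class ANNModel:
    layer_sizes: tuple[int, int, int]
    w1: np.ndarray            # hidden x inputs
    b1: np.ndarray            # hidden
    w2: np.ndarray            # outputs x hidden
    b2: np.ndarray            # outputs
    input_scaling: tuple[np.ndarray, np.ndarray]    # (min, max) per feature
    output_scaling: tuple[np.ndarray, np.ndarray]
    hidden_activation: str = "tansig"
    output_activation: str = "purelin"

    def __post_init__(self) -> None:
        n_in, n_hid, n_out = self.layer_sizes
        if self.w1.shape != (n_hid, n_in) or self.b1.shape != (n_hid,):
            raise ValueError("hidden-layer weight shapes inconsistent")
        if self.w2.shape != (n_out, n_hid) or self.b2.shape != (n_out,):
            raise ValueError("output-layer weight shapes inconsistent")
        omin, omax = self.output_scaling
        if np.any(omax <= omin):
            raise ValueError("output scaling must have max > min per feature")


@dataclass(frozen=True)
class TrainRecord:
    mse: np.ndarray            # training MSE after each epoch (scaled space)
    mu: np.ndarray             # damping value at the end of each epoch
    val_mse: np.ndarray | None
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    seed: int
    stopped: str = "epochs"    # "epochs" | "goal" | "mu_overflow"


def partition_70_15_15(n: int, seed: int = 0):
    """Shuffled 70/15/15 split: round-half-up train and validation sizes.

    n = 25 gives (18, 4, 3); the test set takes the remainder.
    """
    if n < 3:
        raise ValueError("need at least 3 samples to partition")
    n_train = int(np.floor(0.70 * n + 0.5))
    n_val = int(np.floor(0.15 * n + 0.5))
    if n_train + n_val >= n:
        n_val = max(n - n_train - 1, 0)  # keep the test set non-empty
    perm = np.random.default_rng(seed).permutation(n)
    return (
        np.sort(perm[:n_train]),
        np.sort(perm[n_train : n_train + n_val]),
        np.sort(perm[n_train + n_val :]),
    )


def _minmax_fit(block: np.ndarray):
    lo, hi = block.min(axis=0), block.max(axis=0)
    return lo, hi


def _minmax_apply(block: np.ndarray, scaling) -> np.ndarray:
    lo, hi = scaling
    rng = np.where(hi > lo, hi - lo, 1.0)  # constant features map to -1
    return 2.0 * (block - lo) / rng - 1.0


def _minmax_invert(block: np.ndarray, scaling) -> np.ndarray:
    lo, hi = scaling
    return (block + 1.0) / 2.0 * (hi - lo) + lo


def init_ann(n_in: int, n_hidden: int, n_out: int, seed: int,
             input_scaling=None, output_scaling=None,
             hidden_scale: float = 0.5, output_scale: float = 0.5) -> ANNModel:
    """Random network, weights uniform in +-hidden_scale / +-output_scale.

    The generic default is +-0.5 everywhere.  For wide spectral inputs a
    much smaller *hidden_scale* keeps the tanh layer in its linear regime
    at initialisation, which matters for generalisation on near-linear
    calibration maps (see :func:`fit_ann`).
    """
    rng = np.random.default_rng(seed)
    if input_scaling is None:
        input_scaling = (-np.ones(n_in), np.ones(n_in))
    if output_scaling is None:
        output_scaling = (-np.ones(n_out), np.ones(n_out))
    return ANNModel(
        (n_in, n_hidden, n_out),
        rng.uniform(-hidden_scale, hidden_scale, (n_hidden, n_in)),
        rng.uniform(-hidden_scale, hidden_scale, n_hidden),
        rng.uniform(-output_scale, output_scale, (n_out, n_hidden)),
        rng.uniform(-output_scale, output_scale, n_out),
        (np.asarray(input_scaling[0], float), np.asarray(input_scaling[1], float)),
        (np.asarray(output_scaling[0], float), np.asarray(output_scaling[1], float)),
    )


def _forward(theta, shapes, X):
    w1, b1, w2, b2 = _unpack(theta, shapes)
    h = np.tanh(X @ w1.T + b1)
    return h @ w2.T + b2, h


def _pack(w1, b1, w2, b2):
    return np.concatenate([w1.ravel(), b1, w2.ravel(), b2])


def _unpack(theta, shapes):
    (n_in, n_hid, n_out) = shapes
    i = 0
    w1 = theta[i : i + n_hid * n_in].reshape(n_hid, n_in); i += n_hid * n_in
    b1 = theta[i : i + n_hid]; i += n_hid
    w2 = theta[i : i + n_out * n_hid].reshape(n_out, n_hid); i += n_out * n_hid
    b2 = theta[i : i + n_out]
    return w1, b1, w2, b2


def _jacobian(theta, shapes, X):
    """Analytic Jacobian of the residual vector w.r.t. all parameters.

    Residuals are ordered sample-major, output-minor; returns
    (J: (n*o, P), yhat, h).
    """
    n_in, n_hid, n_out = shapes
    w1, b1, w2, b2 = _unpack(theta, shapes)
    h = np.tanh(X @ w1.T + b1)          # n x hid
    yhat = h @ w2.T + b2                # n x out
    n = X.shape[0]
    g = 1.0 - h**2                      # tanh'
    # d y[s,k] / d W1[j,i] = w2[k,j] g[s,j] x[s,i]
    dW1 = np.einsum("kj,sj,si->skji", w2, g, X).reshape(n, n_out, n_hid * n_in)
    dB1 = np.einsum("kj,sj->skj", w2, g)                       # n x out x hid
    dW2 = np.zeros((n, n_out, n_out, n_hid))
    for k in range(n_out):
        dW2[:, k, k, :] = h
    dW2 = dW2.reshape(n, n_out, n_out * n_hid)
    dB2 = np.tile(np.eye(n_out), (n, 1, 1))
    J = np.concatenate([dW1, dB1, dW2, dB2], axis=2).reshape(n * n_out, -1)
    return J, yhat, h


def train_lm(
    model: ANNModel,
    X: np.ndarray,
    Y: np.ndarray,
    epochs: int = 500,
    goal: float = 0.0,
    mu_init: float = 1e-3,
    mu_max: float = 1e10,
    X_val: np.ndarray | None = None,
    Y_val: np.ndarray | None = None,
    partition=None,
    seed: int = 0,
):
    """Train by Levenberg-Marquardt on scaled data.

    *X*, *Y* are raw (unscaled) training blocks; scaling is taken from the
    model.  Stops at *epochs*, when the scaled-space training MSE reaches
    *goal*, or when mu exceeds *mu_max*.  Returns (trained model,
    TrainRecord).
    """
    if epochs < 0:
        raise ValueError("epochs must be >= 0")
    shapes = model.layer_sizes
    Xs = _minmax_apply(np.asarray(X, float), model.input_scaling)
    Ys = _minmax_apply(np.asarray(Y, float), model.output_scaling)
    has_val = X_val is not None and Y_val is not None
    if has_val:
        Xv = _minmax_apply(np.asarray(X_val, float), model.input_scaling)
        Yv = _minmax_apply(np.asarray(Y_val, float), model.output_scaling)
    theta = _pack(model.w1, model.b1, model.w2, model.b2)
    n_res = Xs.shape[0] * shapes[2]
    n_par = theta.size
    mu = mu_init
    mse_hist, mu_hist, val_hist = [], [], []
    stopped = "epochs"

    def mse_of(th):
        yhat, _ = _forward(th, shapes, Xs)
        return float(np.mean((yhat - Ys) ** 2))

    def refine_output(th):
        # the output layer is linear in its weights, so given the hidden
        # activations it has a closed-form least-squares optimum; taking it
        # (only when it lowers the MSE) greatly accelerates convergence
        w1, b1, w2, b2 = _unpack(th, shapes)
        h = np.tanh(Xs @ w1.T + b1)
        Hd = np.column_stack([h, np.ones(h.shape[0])])
        coef, *_ = np.linalg.lstsq(Hd, Ys, rcond=None)
        return _pack(w1, b1, coef[:-1].T, coef[-1])

    current = mse_of(theta)
    for _ in range(epochs):
        candidate = refine_output(theta)
        refined = mse_of(candidate)
        if refined < current:
            theta, current = candidate, refined
        if current <= goal:
            mse_hist.append(current)
            mu_hist.append(mu)
            if has_val:
                yv, _ = _forward(theta, shapes, Xv)
                val_hist.append(float(np.mean((yv - Yv) ** 2)))
            stopped = "goal"
            break
        J, yhat, _ = _jacobian(theta, shapes, Xs)
        if not np.all(np.isfinite(J)):
            raise FloatingPointError("non-finite Jacobian during LM training")
        e = (yhat - Ys).ravel()
        # economy SVD of J: the damped step is
        # delta = -V diag(s/(s^2+mu)) U' e, computed without forming J'J
        # (squaring the condition number is what stalls a naive solve here)
        U, s, Vt = np.linalg.svd(J, full_matrices=False)
        Ue = U.T @ e
        accepted = False
        while mu <= mu_max:
            delta = -(Vt.T * (s / (s**2 + mu))) @ Ue
            candidate = theta + delta
            new = mse_of(candidate)
            if new < current:
                theta, current = candidate, new
                mu = max(mu / 10.0, 1e-20)
                accepted = True
                break
            mu *= 10.0
        mse_hist.append(current)
        mu_hist.append(mu)
        if has_val:
            yv, _ = _forward(theta, shapes, Xv)
            val_hist.append(float(np.mean((yv - Yv) ** 2)))
        if not accepted:
            stopped = "mu_overflow"
            break
        if current <= goal:
            stopped = "goal"
            break
    w1, b1, w2, b2 = _unpack(theta, shapes)
    trained = ANNModel(
        shapes, w1, b1, w2, b2, model.input_scaling, model.output_scaling
    )
    if partition is None:
        n = Xs.shape[0]
        partition = (np.arange(n), np.array([], int), np.array([], int))
    record = TrainRecord(
        np.asarray(mse_hist),
        np.asarray(mu_hist),
        np.asarray(val_hist) if has_val else None,
        *[np.asarray(p) for p in partition],
        seed=seed,
        stopped=stopped,
    )
    return trained, record


def predict_ann(model: ANNModel, X) -> np.ndarray:
    """Deterministic forward pass: unscale(W2 tanh(W1 scale(x) + b1) + b2)."""
    if isinstance(X, SpectralMatrix):
        Xarr = X.absorbance
    else:
        Xarr = np.atleast_2d(np.asarray(X, float))
    if Xarr.shape[1] != model.layer_sizes[0]:
        raise ValueError(
            f"{Xarr.shape[1]} inputs for a {model.layer_sizes[0]}-input network"
        )
    Xs = _minmax_apply(Xarr, model.input_scaling)
    theta = _pack(model.w1, model.b1, model.w2, model.b2)
    ys, _ = _forward(theta, model.layer_sizes, Xs)
    return _minmax_invert(ys, model.output_scaling)


def fit_ann(
    X,
    Y,
    n_hidden: int = 6,
    epochs: int = 500,
    goal: float = 0.0,
    seed: int = 0,
):
    """End-to-end calibration: partition, scale on train, init and train.

    *X* may be a SpectralMatrix and *Y* a ConcentrationMatrix (or plain
    arrays).  Returns (ANNModel, TrainRecord).
    """
    Xarr = X.absorbance if isinstance(X, SpectralMatrix) else np.atleast_2d(np.asarray(X, float))
    Yarr = Y.concentrations if isinstance(Y, ConcentrationMatrix) else np.atleast_2d(np.asarray(Y, float))
    n = Xarr.shape[0]
    train, val, test = partition_70_15_15(n, seed)
    in_scale = _minmax_fit(Xarr[train])
    out_scale = _minmax_fit(Yarr[train])
    if np.any(out_scale[1] <= out_scale[0]):
        raise ValueError("training outputs are constant; cannot scale")
    # calibration maps from absorbance to concentration are close to
    # linear, so the hidden layer starts deep in the linear tanh regime:
    # the trained net then generalises like the linear map it embeds
    # instead of carrying random-saturation wiggle between samples
    model = init_ann(
        Xarr.shape[1], n_hidden, Yarr.shape[1], seed,
        input_scaling=in_scale, output_scaling=out_scale,
        hidden_scale=0.004, output_scale=4.0,
    )
    return train_lm(
        model,
        Xarr[train],
        Yarr[train],
        epochs=epochs,
        goal=goal,
        X_val=Xarr[val] if val.size else None,
        Y_val=Yarr[val] if val.size else None,
        partition=(train, val, test),
        seed=seed,
    )


def hidden_sweep(X, Y, sizes=range(2, 11), epochs: int = 200, seed: int = 0):
    """Validation MSE (raw units) per hidden-layer size.

    Re-runs the full fit at each size with a shared partition seed;
    returns {n_hidden: validation MSE}.
    """
    Xarr = X.absorbance if isinstance(X, SpectralMatrix) else np.atleast_2d(np.asarray(X, float))
    Yarr = Y.concentrations if isinstance(Y, ConcentrationMatrix) else np.atleast_2d(np.asarray(Y, float))
    out = {}
    for k in sizes:
        model, record = fit_ann(Xarr, Yarr, n_hidden=k, epochs=epochs, seed=seed)
        val = record.val_idx
        if val.size:
            pred = predict_ann(model, Xarr[val])
            out[int(k)] = float(np.mean((pred - Yarr[val]) ** 2))
        else:
            out[int(k)] = float("nan")
    return out
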