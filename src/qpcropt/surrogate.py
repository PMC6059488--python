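"""Three-layer feed-forward (back-propagation) network surrogate for Ct.

The surrogate ("model II") maps the five coded reagent concentrations to
the Ct response through a single sigmoid hidden layer.  The Ct vector is
first scaled linearly onto a symmetric band ±h; h defaults to 2.378 so the
scaled response spans the same range as the coded inputs of the rotatable
five-factor design.  Hidden-layer size is selected by k-fold
cross-validation: for each candidate the network is trained on k-1 folds
and scored on the held-out fold; the candidate minimizing the mean
held-out MSE wins, ties going to the smaller network.

Because the scaled target exceeds (0, 1), the default output unit is
linear after the sigmoid hidden layer.  A sigmoid output variant is
available behind ``output_activation="sigmoid"``; its logistic output is
stretched affinely onto the target band so that the extremes remain
reachable.

Training minimizes mean squared error on the scaled response with L-BFGS
on analytically computed gradients; with a fixed seed two runs produce
bit-identical weights.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "ResponseScaler",
    "SurrogateNet",
    "CvReport",
    "DEFAULT_HALFWIDTH",
    "scale_response",
    "train_bpnn",
    "cv_select_nodes",
]

DEFAULT_HALFWIDTH = 2.378  # coded range of the rotatable 5-factor design


@dataclass(frozen=True)
class ResponseScaler:
    """Affine map sending [ct_min, ct_max] onto [-h, +h]."""

    ct_min: float
    ct_max: float
    halfwidth: float = DEFAULT_HALFWIDTH

    def __post_init__(self) -> None:
        if not self.ct_max > self.ct_min:
            raise ValueError(
                "degenerate scaling: response has no spread "
                f"(min {self.ct_min} == max {self.ct_max})"
            )

    @property
    def _mid(self) -> float:
        return 0.5 * (self.ct_min + self.ct_max)

    @property
    def _halfrange(self) -> float:
        return 0.5 * (self.ct_max - self.ct_min)

    def scale(self, ct) -> np.ndarray:
        ct = np.asarray(ct, dtype=float)
        return (ct - self._mid) / self._halfrange * self.halfwidth

    def inverse(self, scaled) -> np.ndarray:
        scaled = np.asarray(scaled, dtype=float)
        return scaled / self.halfwidth * self._halfrange + self._mid


def scale_response(ct_values, target_halfwidth: float = DEFAULT_HALFWIDTH):
    """Scale Ct values onto ±target_halfwidth; returns (scaled, scaler).

    The scaler's :meth:`ResponseScaler.inverse` recovers Ct units exactly.
    """
    ct = np.asarray(ct_values, dtype=float)
    if ct.size < 2:
        raise ValueError("need at least two Ct values to define a scaling")
    scaler = ResponseScaler(float(ct.min()), float(ct.max()), target_halfwidth)
    return scaler.scale(ct), scaler


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class SurrogateNet:
    """Trained three-layer network with its response scaling attached."""

    n_inputs: int
    n_hidden: int
    w1: np.ndarray = field(repr=False)  # (n_hidden, n_inputs)
    b1: np.ndarray = field(repr=False)
    w2: np.ndarray = field(repr=False)  # (n_hidden,)
    b2: float
    scaler: ResponseScaler
    output_activation: str = "linear"
    training_seed: int = 0
    converged: bool = True
    train_mse_scaled: float = float("nan")

    def forward_scaled(self, x) -> np.ndarray:
        """Network output on the scaled-response axis for coded points x."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        h = _sigmoid(x @ self.w1.T + self.b1)
        z = h @ self.w2 + self.b2
        if self.output_activation == "sigmoid":
            # logistic output stretched onto ±h so the band is reachable
            z = self.scaler.halfwidth * (2.0 * _sigmoid(z) - 1.0)
        return z

    def predict(self, x) -> np.ndarray | float:
        """Predicted Ct at coded point(s) x (inverse scaling applied)."""
        arr = np.asarray(x, dtype=float)
        scalar = arr.ndim == 1
        ct = self.scaler.inverse(self.forward_scaled(arr))
        return float(ct[0]) if scalar else ct

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_inputs": self.n_inputs,
                "n_hidden": self.n_hidden,
                "w1": self.w1.tolist(),
                "b1": self.b1.tolist(),
                "w2": self.w2.tolist(),
                "b2": self.b2,
                "scaler": {
                    "ct_min": self.scaler.ct_min,
                    "ct_max": self.scaler.ct_max,
                    "halfwidth": self.scaler.halfwidth,
                },
                "output_activation": self.output_activation,
                "training_seed": self.training_seed,
                "converged": self.converged,
                "train_mse_scaled": self.train_mse_scaled,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "SurrogateNet":
        d = json.loads(text)
        return cls(
            n_inputs=d["n_inputs"],
            n_hidden=d["n_hidden"],
            w1=np.asarray(d["w1"], dtype=float),
            b1=np.asarray(d["b1"], dtype=float),
            w2=np.asarray(d["w2"], dtype=float),
            b2=float(d["b2"]),
            scaler=ResponseScaler(**d["scaler"]),
            output_activation=d["output_activation"],
            training_seed=d["training_seed"],
            converged=d["converged"],
            train_mse_scaled=d.get("train_mse_scaled", float("nan")),
        )


def _unpack(theta: np.ndarray, k: int, h: int):
    i = 0
    w1 = theta[i : i + h * k].reshape(h, k); i += h * k
    b1 = theta[i : i + h]; i += h
    w2 = theta[i : i + h]; i += h
    b2 = theta[i]
    return w1, b1, w2, b2


def _loss_grad(theta, x, t, k, h, output_activation, halfwidth):
    """MSE on the scaled target and its analytic gradient."""
    n = x.shape[0]
    w1, b1, w2, b2 = _unpack(theta, k, h)
    a = _sigmoid(x @ w1.T + b1)  # (n, h)
    z = a @ w2 + b2
    if output_activation == "sigmoid":
        s = _sigmoid(z)
        yhat = halfwidth * (2.0 * s - 1.0)
        dyhat_dz = 2.0 * halfwidth * s * (1.0 - s)
    else:
        yhat = z
        dyhat_dz = np.ones(n)
    err = yhat - t
    loss = float(err @ err / n)
    dz = (2.0 / n) * err * dyhat_dz  # (n,)
    g_b2 = dz.sum()
    g_w2 = a.T @ dz
    da = np.outer(dz, w2) * a * (1.0 - a)  # (n, h)
    g_b1 = da.sum(axis=0)
    g_w1 = da.T @ x
    grad = np.concatenate([g_w1.ravel(), g_b1, g_w2, [g_b2]])
    return loss, grad


def train_bpnn(
    design,
    ct,
    n_hidden: int,
    seed: int = 0,
    tol: float = 1e-8,
    max_epochs: int = 2000,
    output_activation: str = "linear",
    target_halfwidth: float = DEFAULT_HALFWIDTH,
    scaler: ResponseScaler | None = None,
) -> SurrogateNet:
    """Train the network on coded inputs ``design`` (n, k) and Ct vector ``ct``.

    Stops when the gradient norm or the loss change drops below ``tol`` or
    after ``max_epochs`` L-BFGS iterations; in the latter case the
    best-so-far weights are returned with ``converged=False`` and a warning.
    """
    x = np.atleast_2d(np.asarray(design, dtype=float))
    ct = np.asarray(ct, dtype=float)
    n, k = x.shape
    if n_hidden < 1:
        raise ValueError(f"n_hidden must be >= 1, got {n_hidden}")
    if n < n_hidden + 2:
        raise ValueError(
            f"need at least n_hidden + 2 = {n_hidden + 2} rows, got {n}"
        )
    if output_activation not in ("linear", "sigmoid"):
        raise ValueError(f"unknown output activation {output_activation!r}")
    if scaler is None:
        t, scaler = scale_response(ct, target_halfwidth)
    else:
        t = scaler.scale(ct)

    rng = np.random.default_rng(seed)
    n_par = n_hidden * k + n_hidden + n_hidden + 1
    theta0 = rng.uniform(-0.5, 0.5, size=n_par)
    res = minimize(
        _loss_grad,
        theta0,
        args=(x, t, k, n_hidden, output_activation, scaler.halfwidth),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_epochs, "gtol": tol, "ftol": tol},
    )
    converged = bool(res.success) or res.status == 0
    if not converged:
        warnings.warn(
            f"BPNN training stopped without convergence ({res.message}); "
            "returning best-so-far weights",
            stacklevel=2,
        )
    w1, b1, w2, b2 = _unpack(res.x, k, n_hidden)
    return SurrogateNet(
        n_inputs=k,
        n_hidden=n_hidden,
        w1=w1.copy(),
        b1=b1.copy(),
        w2=w2.copy(),
        b2=float(b2),
        scaler=scaler,
        output_activation=output_activation,
        training_seed=seed,
        converged=converged,
        train_mse_scaled=float(res.fun),
    )


@dataclass
class CvReport:
    """Cross-validation summary over hidden-layer size candidates."""

    table: pd.DataFrame  # columns: n_hidden, fit_mean, fit_sd, pred_mean, pred_sd
    selected: int
    fold_seed: int
    fold_assignment: np.ndarray = field(repr=False)

    def to_csv(self, path_or_buf=None):
        return self.table.to_csv(path_or_buf, index=False)


def _fold_indices(n: int, k_folds: int, rng: np.random.Generator) -> np.ndarray:
    """Disjoint exhaustive folds; sizes differ by at most one."""
    assignment = np.array([i % k_folds for i in range(n)])
    rng.shuffle(assignment)
    return assignment


def cv_select_nodes(
    design,
    ct,
    candidates: list[int],
    k_folds: int = 5,
    seed: int = 0,
    output_activation: str = "linear",
    target_halfwidth: float = DEFAULT_HALFWIDTH,
    max_epochs: int = 500,
) -> CvReport:
    """Select the hidden-layer size by k-fold cross-validation.

    Errors (fit = training MSE, prediction = held-out MSE) are computed on
    the scaled response, reported as mean ± sd across folds.  The candidate
    with the smallest mean prediction error is selected; ties break toward
    fewer nodes.  The response scaling is fitted once on the full Ct vector,
    mirroring how the pipeline scales before modelling.
    """
    x = np.atleast_2d(np.asarray(design, dtype=float))
    ct = np.asarray(ct, dtype=float)
    n = x.shape[0]
    if not candidates:
        raise ValueError("candidates must be nonempty")
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if n < k_folds:
        raise ValueError(f"need at least k_folds={k_folds} rows, got {n}")
    _, scaler = scale_response(ct, target_halfwidth)
    rng = np.random.default_rng(seed)
    assignment = _fold_indices(n, k_folds, rng)
    train_seeds = rng.integers(0, 2**31 - 1, size=(len(candidates), k_folds))

    rows = []
    for ci, h in enumerate(sorted(candidates)):
        fit_errs, pred_errs = [], []
        for fold in range(k_folds):
            test = assignment == fold
            train = ~test
            net = train_bpnn(
                x[train],
                ct[train],
                n_hidden=h,
                seed=int(train_seeds[ci, fold]),
                output_activation=output_activation,
                scaler=scaler,
                max_epochs=max_epochs,
            )
            t_train = scaler.scale(ct[train])
            t_test = scaler.scale(ct[test])
            fit_errs.append(
                float(np.mean((net.forward_scaled(x[train]) - t_train) ** 2))
            )
            pred_errs.append(
                float(np.mean((net.forward_scaled(x[test]) - t_test) ** 2))
            )
        rows.append(
            {
                "n_hidden": h,
                "fit_mean": float(np.mean(fit_errs)),
                "fit_sd": float(np.std(fit_errs, ddof=1)),
                "pred_mean": float(np.mean(pred_errs)),
                "pred_sd": float(np.std(pred_errs, ddof=1)),
            }
        )
    table = pd.DataFrame(rows)
    # minimum mean prediction error; ties toward fewer nodes (table is sorted)
    best = int(table.loc[table["pred_mean"].idxmin(), "n_hidden"])
    return CvReport(table=table, selected=best, fold_seed=seed,
                    fold_assignment=assignment)
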