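"""Model-performance metrics and the model I vs model II comparison.

Metrics are the coefficient of determination

    R^2 = 1 - sum (Y_pred - Y_obs)^2 / sum (Y_obs - mean(Y_obs))^2,

the mean absolute error MAE = mean |Y_pred - Y_obs| and the mean squared
error MSE = mean (Y_pred - Y_obs)^2, plus the validation statistic

    relative error = |Ct_pred - Ct_exp| / Ct_exp * 100%.

Every ``FitMetrics`` carries a ``basis`` label naming the response scale it
was computed on (raw Ct vs the scaled band the network trains on).  MAE and
MSE are not comparable across bases — a surrogate scored on a compressed
response axis will show spuriously tiny errors — so ``compare_models``
refuses mixed-basis comparisons unless explicitly overridden, and the
winner is declared on held-out prediction error, not training R^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FitMetrics",
    "ValidationRecord",
    "ComparisonReport",
    "BasisMismatchError",
    "fit_metrics",
    "relative_error",
    "compare_models",
]


class BasisMismatchError(ValueError):
    """Metrics computed on different response scales cannot be compared."""


@dataclass(frozen=True)
class FitMetrics:
    r2: float | None
    mae: float
    mse: float
    n: int
    basis: str = "ct"

    @property
    def rms(self) -> float:
        return float(np.sqrt(self.mse))


@dataclass(frozen=True)
class ValidationRecord:
    ct_predicted: float
    ct_experimental: float
    relative_error_pct: float


def fit_metrics(predicted, observed, basis: str = "ct") -> FitMetrics:
    """R^2, MAE and MSE of ``predicted`` against ``observed``.

    If the observed values have zero variance, R^2 is undefined and
    reported as ``None``.
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape or p.ndim != 1 or p.size == 0:
        raise ValueError("predicted and observed must be equal-length 1-d vectors")
    err = p - o
    mae = float(np.mean(np.abs(err)))
    mse = float(np.mean(err**2))
    ss_tot = float(np.sum((o - o.mean()) ** 2))
    if ss_tot == 0.0:
        r2 = None
    else:
        r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    return FitMetrics(r2=r2, mae=mae, mse=mse, n=p.size, basis=basis)


def relative_error(ct_predicted: float, ct_experimental: float) -> float:
    """|Ct_pred - Ct_exp| / Ct_exp * 100, in percent."""
    if ct_experimental <= 0:
        raise ValueError(
            f"experimental Ct must be positive, got {ct_experimental}"
        )
    return abs(ct_predicted - ct_experimental) / ct_experimental * 100.0


@dataclass
class ComparisonReport:
    """Side-by-side metric table with an explicit decision criterion."""

    table: pd.DataFrame
    winner: str | None
    tie: bool
    criterion: str
    warnings: list[str]

    def to_csv(self, path_or_buf=None):
        return self.table.to_csv(path_or_buf)


def compare_models(
    metrics: dict[str, FitMetrics],
    heldout_mse: dict[str, float] | None = None,
    allow_basis_mismatch: bool = False,
) -> ComparisonReport:
    """Compare named models' metrics (e.g. ``{"model I": ..., "model II": ...}``).

    The decision criterion is held-out prediction error when
    ``heldout_mse`` is supplied (a model can therefore win despite a lower
    training R^2); with training metrics only, no winner is declared.
    Metrics on differing bases raise :class:`BasisMismatchError` unless
    ``allow_basis_mismatch`` is set, in which case the report carries a
    prominent warning.
    """
    if not metrics:
        raise ValueError("no metrics supplied")
    notes: list[str] = []
    bases = {m.basis for m in metrics.values()}
    if len(bases) > 1:
        msg = (
            f"metric bases differ across models ({sorted(bases)}): MAE/MSE "
            "are not comparable across response scales"
        )
        if not allow_basis_mismatch:
            raise BasisMismatchError(msg)
        notes.append(msg)

    rows: dict[str, list] = {"R2": [], "MAE": [], "MSE": [], "n": [], "basis": []}
    for m in metrics.values():
        rows["R2"].append(m.r2)
        rows["MAE"].append(m.mae)
        rows["MSE"].append(m.mse)
        rows["n"].append(m.n)
        rows["basis"].append(m.basis)
    index = ["R2", "MAE", "MSE", "n", "basis"]
    data = {name: [rows[r][i] for r in index] for i, name in enumerate(metrics)}
    table = pd.DataFrame(data, index=index)

    winner: str | None = None
    tie = False
    if heldout_mse is not None:
        if set(heldout_mse) != set(metrics):
            raise ValueError("heldout_mse keys must match metric keys")
        table.loc["heldout_MSE"] = [heldout_mse[name] for name in metrics]
        best = min(heldout_mse.values())
        winners = [name for name, v in heldout_mse.items() if v == best]
        if len(winners) == len(metrics) and len(metrics) > 1:
            tie = True
        else:
            winner = winners[0]
            if len(winners) > 1:
                tie = True
        criterion = "held-out prediction MSE"
    else:
        criterion = "none (training metrics only; no winner declared)"
    if len(metrics) == 1:
        winner, tie = None, False
    return ComparisonReport(
        table=table, winner=winner, tie=tie, criterion=criterion, warnings=notes
    )
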