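"""Second-order response-surface fitting, ANOVA and model reduction.

The response surface is the full quadratic polynomial on coded levels

    Y = b0 + sum_i bi Xi + sum_i bii Xi^2 + sum_{i<j} bij Xi Xj + eps

with Y the cycle-threshold (Ct) response.  For k factors the model has
1 + 2k + k(k-1)/2 parameters (21 for k = 5).  The ANOVA decomposes the
corrected total sum of squares into a 2k + k(k-1)/2 = 20-df model row,
one-df partial (Type-III) rows per term, and a residual that is further
split into lack-of-fit and pure error using runs replicated at identical
coded levels (the n_center center replicates: 8 centers give 7 pure-error
df).  Terms are F-tested against the residual mean square; lack of fit is
tested against pure error.  ``adequate_precision`` reports the conventional
signal-to-noise ratio (prediction range over average prediction standard
error); values above 4 indicate a surface usable for optimization.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignTable

__all__ = [
    "QuadraticModel",
    "AnovaTable",
    "SingularDesignError",
    "term_labels",
    "expand_quadratic",
    "fit_quadratic",
    "anova",
    "adequate_precision",
    "reduce_model",
    "predict",
]


class SingularDesignError(ValueError):
    """The expanded design matrix is rank deficient."""


def term_labels(factor_names: list[str]) -> list[str]:
    """Non-intercept term labels: linear, pairwise interactions (i<j), quadratics.

    For factors A..E: A, B, C, D, E, AB, AC, ..., DE, A^2, ..., E^2.
    """
    k = len(factor_names)
    labels = list(factor_names)
    for i in range(k):
        for j in range(i + 1, k):
            labels.append(f"{factor_names[i]}{factor_names[j]}")
    labels += [f"{n}^2" for n in factor_names]
    return labels


def expand_quadratic(x: np.ndarray) -> np.ndarray:
    """Expand coded points (n, k) to the full quadratic basis incl. intercept.

    Column order matches ``term_labels`` with the intercept prepended.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n, k = x.shape
    cols = [np.ones(n)]
    cols += [x[:, i] for i in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            cols.append(x[:, i] * x[:, j])
    cols += [x[:, i] ** 2 for i in range(k)]
    return np.column_stack(cols)


@dataclass
class QuadraticModel:
    """Fitted (or specified) second-order polynomial on coded levels."""

    factor_names: list[str]
    intercept: float
    linear: np.ndarray
    quadratic: np.ndarray
    interaction: np.ndarray  # i<j row-major, length k(k-1)/2
    term_p: dict[str, float] | None = None
    reduced: bool = False
    kept_terms: list[str] | None = None
    # fit context, populated by fit_quadratic (coded design + response)
    design_coded: np.ndarray | None = field(default=None, repr=False)
    response: np.ndarray | None = field(default=None, repr=False)
    residual_ms: float | None = None
    cov_unscaled: np.ndarray | None = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return len(self.factor_names)

    @property
    def n_params(self) -> int:
        k = self.k
        return 1 + 2 * k + k * (k - 1) // 2

    def coef_vector(self) -> np.ndarray:
        """Coefficients in expand_quadratic column order."""
        return np.concatenate(
            ([self.intercept], self.linear, self.interaction, self.quadratic)
        )

    def coef_by_label(self) -> dict[str, float]:
        labels = term_labels(self.factor_names)
        return dict(zip(labels, self.coef_vector()[1:]))

    def predict(self, x, warn_extrapolation: float | None = None) -> np.ndarray | float:
        """Evaluate the polynomial at coded point(s) ``x``.

        With ``warn_extrapolation=alpha`` a warning is issued when any
        coordinate lies outside ±alpha (predictions there extrapolate).
        """
        arr = np.asarray(x, dtype=float)
        scalar = arr.ndim == 1
        z = expand_quadratic(arr)
        if z.shape[1] != self.n_params:
            raise ValueError(
                f"point has wrong length for a {self.k}-factor model"
            )
        if warn_extrapolation is not None and np.any(
            np.abs(arr) > warn_extrapolation + 1e-12
        ):
            warnings.warn(
                "prediction point lies outside the coded design region "
                f"(±{warn_extrapolation:g}); extrapolating",
                stacklevel=2,
            )
        y = z @ self.coef_vector()
        return float(y[0]) if scalar else y

    @property
    def fitted_values(self) -> np.ndarray:
        if self.design_coded is None or self.response is None:
            raise ValueError("model carries no fit context")
        return np.asarray(self.predict(self.design_coded))

    @property
    def residuals(self) -> np.ndarray:
        return self.response - self.fitted_values

    def r_squared(self) -> float:
        y = self.response
        ss_res = float(np.sum(self.residuals**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - ss_res / ss_tot

    @classmethod
    def from_coefficients(
        cls, factor_names: list[str], coefficients: dict[str, float]
    ) -> "QuadraticModel":
        """Build a model from a {label: value} map (unlisted terms are 0).

        Labels follow ``term_labels`` plus ``"intercept"``.
        """
        k = len(factor_names)
        labels = term_labels(factor_names)
        unknown = set(coefficients) - set(labels) - {"intercept"}
        if unknown:
            raise ValueError(f"unknown term labels: {sorted(unknown)}")
        lin = np.array([coefficients.get(n, 0.0) for n in factor_names])
        inter = []
        for i in range(k):
            for j in range(i + 1, k):
                inter.append(
                    coefficients.get(f"{factor_names[i]}{factor_names[j]}", 0.0)
                )
        quad = np.array([coefficients.get(f"{n}^2", 0.0) for n in factor_names])
        kept = [l for l in labels if coefficients.get(l, 0.0) != 0.0]
        return cls(
            factor_names=list(factor_names),
            intercept=float(coefficients.get("intercept", 0.0)),
            linear=lin,
            quadratic=quad,
            interaction=np.array(inter),
            reduced=len(kept) < len(labels),
            kept_terms=kept,
        )

    def to_json(self) -> str:
        payload = {
            "factor_names": self.factor_names,
            "intercept": self.intercept,
            "linear": self.linear.tolist(),
            "quadratic": self.quadratic.tolist(),
            "interaction": self.interaction.tolist(),
            "term_p": self.term_p,
            "reduced": self.reduced,
            "kept_terms": self.kept_terms,
            "residual_ms": self.residual_ms,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "QuadraticModel":
        d = json.loads(text)
        return cls(
            factor_names=d["factor_names"],
            intercept=d["intercept"],
            linear=np.asarray(d["linear"], dtype=float),
            quadratic=np.asarray(d["quadratic"], dtype=float),
            interaction=np.asarray(d["interaction"], dtype=float),
            term_p=d.get("term_p"),
            reduced=d.get("reduced", False),
            kept_terms=d.get("kept_terms"),
            residual_ms=d.get("residual_ms"),
        )


@dataclass
class AnovaTable:
    """ANOVA with per-term partial SS and a lack-of-fit / pure-error split."""

    table: pd.DataFrame
    adequate_precision: float
    pure_error_defined: bool = True

    def row(self, source: str) -> pd.Series:
        match = self.table.loc[self.table["Source"] == source]
        if match.empty:
            raise KeyError(source)
        return match.iloc[0]

    def term_p_values(self, factor_names: list[str]) -> dict[str, float]:
        labels = term_labels(factor_names)
        return {l: float(self.row(l)["P"]) for l in labels}

    def to_csv(self, path_or_buf=None):
        return self.table.to_csv(path_or_buf, index=False)


def _coef_vector_to_model(
    factor_names: list[str], beta: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    k = len(factor_names)
    n_inter = k * (k - 1) // 2
    intercept = float(beta[0])
    lin = beta[1 : 1 + k].copy()
    inter = beta[1 + k : 1 + k + n_inter].copy()
    quad = beta[1 + k + n_inter :].copy()
    return intercept, lin, quad, inter


def fit_quadratic(design: DesignTable, response) -> QuadraticModel:
    """Least-squares fit of the full second-order polynomial on coded levels.

    ``response`` is the per-run mean Ct vector (one value per design row).
    """
    y = np.asarray(response, dtype=float)
    if y.shape[0] != design.n_runs:
        raise ValueError(
            f"response length {y.shape[0]} != run count {design.n_runs}"
        )
    x = design.coded
    z = expand_quadratic(x)
    n, p = z.shape
    rank = np.linalg.matrix_rank(z)
    if rank < p:
        # identify near-collinear columns via pivoted QR
        from scipy.linalg import qr

        _, r, piv = qr(z, pivoting=True, mode="economic")
        diag = np.abs(np.diag(r))
        bad = piv[diag < diag.max() * 1e-10]
        labels = ["intercept"] + term_labels(design.factor_names)
        raise SingularDesignError(
            "expanded design matrix is rank deficient; collinear terms: "
            + ", ".join(labels[i] for i in sorted(bad))
        )
    beta, _, _, _ = np.linalg.lstsq(z, y, rcond=None)
    resid = y - z @ beta
    df_resid = n - p
    ss_resid = float(resid @ resid)
    ss_total = float(np.sum((y - y.mean()) ** 2))
    if ss_resid <= 1e-16 * max(ss_total, 1.0):
        ss_resid = 0.0  # exact interpolation up to floating dust
    ms_resid = ss_resid / df_resid if df_resid > 0 else float("nan")
    intercept, lin, quad, inter = _coef_vector_to_model(design.factor_names, beta)
    return QuadraticModel(
        factor_names=list(design.factor_names),
        intercept=intercept,
        linear=lin,
        quadratic=quad,
        interaction=inter,
        design_coded=x,
        response=y,
        residual_ms=ms_resid,
        cov_unscaled=np.linalg.inv(z.T @ z),
    )


def _pure_error(coded: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Pure-error SS and df from runs replicated at identical coded levels."""
    groups: dict[bytes, list[int]] = {}
    for idx, row in enumerate(np.round(coded, 10)):
        groups.setdefault(row.tobytes(), []).append(idx)
    ss = 0.0
    df = 0
    for idxs in groups.values():
        if len(idxs) > 1:
            vals = y[idxs]
            ss += float(np.sum((vals - vals.mean()) ** 2))
            df += len(idxs) - 1
    return ss, df


def anova(model: QuadraticModel, design: DesignTable, response=None) -> AnovaTable:
    """Full ANOVA table for a fitted quadratic model.

    Rows: Model (pooled, 2k + k(k-1)/2 df), one partial (Type-III) row per
    term, Residual, Lack of Fit, Pure Error, Cor Total.  Pure error comes
    from design points replicated at identical coded levels (the center
    replicates), computed on the per-run mean responses; with no replicated
    points the lack-of-fit split is omitted with a warning.
    """
    if response is None:
        response = model.response
    y = np.asarray(response, dtype=float)
    x = design.coded
    z = expand_quadratic(x)
    n, p = z.shape
    beta = model.coef_vector()
    resid = y - z @ beta
    ss_resid = float(resid @ resid)
    df_resid = n - p
    ss_total = float(np.sum((y - y.mean()) ** 2))
    ss_model = ss_total - ss_resid
    df_model = p - 1
    ms_resid = ss_resid / df_resid if df_resid > 0 else np.nan

    exact_fit = ss_resid <= 1e-12 * max(ss_total, 1.0)
    cov = model.cov_unscaled
    if cov is None:
        cov = np.linalg.inv(z.T @ z)

    labels = term_labels(model.factor_names)
    rows = []
    f_model = (ss_model / df_model) / ms_resid if not exact_fit else np.inf
    p_model = (
        float(stats.f.sf(f_model, df_model, df_resid)) if np.isfinite(f_model) else 0.0
    )
    rows.append(("Model", df_model, ss_model, ss_model / df_model, f_model, p_model))
    term_p: dict[str, float] = {}
    for j, label in enumerate(labels, start=1):
        ss_j = float(beta[j] ** 2 / cov[j, j])  # partial SS, 1 df
        if exact_fit:
            f_j, p_j = np.inf, 0.0
        else:
            f_j = ss_j / ms_resid
            p_j = float(stats.f.sf(f_j, 1, df_resid))
        term_p[label] = p_j
        rows.append((label, 1, ss_j, ss_j, f_j, p_j))
    rows.append(("Residual", df_resid, ss_resid, ms_resid, np.nan, np.nan))

    ss_pe, df_pe = _pure_error(x, y)
    pe_defined = df_pe > 0
    if pe_defined:
        ss_lof = ss_resid - ss_pe
        df_lof = df_resid - df_pe
        ms_pe = ss_pe / df_pe
        if ms_pe > 0 and df_lof > 0:
            f_lof = (ss_lof / df_lof) / ms_pe
            p_lof = float(stats.f.sf(f_lof, df_lof, df_pe))
        else:
            f_lof, p_lof = np.inf, 0.0
        rows.append(
            ("Lack of Fit", df_lof, ss_lof, ss_lof / df_lof if df_lof else np.nan,
             f_lof, p_lof)
        )
        rows.append(("Pure Error", df_pe, ss_pe, ms_pe, np.nan, np.nan))
    else:
        warnings.warn(
            "no replicated design points: pure error undefined, "
            "lack-of-fit split omitted",
            stacklevel=2,
        )
    rows.append(("Cor Total", n - 1, ss_total, np.nan, np.nan, np.nan))

    table = pd.DataFrame(rows, columns=["Source", "df", "SS", "MS", "F", "P"])
    ap = adequate_precision(model, design)
    model.term_p = term_p
    return AnovaTable(table=table, adequate_precision=ap, pure_error_defined=pe_defined)


def adequate_precision(model: QuadraticModel, design: DesignTable) -> float:
    """Signal-to-noise ratio of the fitted surface over the design points.

    (max prediction - min prediction) / sqrt(p * MS_residual / n).  Values
    above 4 conventionally indicate the surface can guide optimization.
    An exact (zero-residual) fit yields +inf.
    """
    if model.residual_ms is None:
        raise ValueError("model has no residual mean square; fit it first")
    yhat = np.asarray(model.predict(design.coded))
    pred_range = float(yhat.max() - yhat.min())
    n = design.n_runs
    p = model.n_params
    if model.residual_ms <= 0:
        return float("inf")
    return pred_range / float(np.sqrt(p * model.residual_ms / n))


def reduce_model(
    model: QuadraticModel,
    anova_table: AnovaTable,
    p_threshold: float = 0.05,
) -> QuadraticModel:
    """Keep the intercept plus every term with P < p_threshold, then refit.

    Pure thresholding: hierarchy is NOT enforced (an interaction may stay
    while its parent main effect is dropped).  Coefficients of retained
    terms are re-estimated by least squares on the retained columns;
    eliminated terms are stored as exact zeros.
    """
    if model.design_coded is None or model.response is None:
        raise ValueError("model carries no fit context; fit before reducing")
    labels = term_labels(model.factor_names)
    p_values = anova_table.term_p_values(model.factor_names)
    kept = [l for l in labels if p_values[l] < p_threshold]
    z_full = expand_quadratic(model.design_coded)
    keep_idx = [0] + [1 + labels.index(l) for l in kept]
    z = z_full[:, keep_idx]
    y = model.response
    beta_kept, _, _, _ = np.linalg.lstsq(z, y, rcond=None)
    beta = np.zeros(z_full.shape[1])
    beta[keep_idx] = beta_kept
    resid = y - z_full @ beta
    df_resid = len(y) - len(keep_idx)
    intercept, lin, quad, inter = _coef_vector_to_model(model.factor_names, beta)
    return QuadraticModel(
        factor_names=list(model.factor_names),
        intercept=intercept,
        linear=lin,
        quadratic=quad,
        interaction=inter,
        term_p={l: p_values[l] for l in kept},
        reduced=True,
        kept_terms=kept,
        design_coded=model.design_coded,
        response=y,
        residual_ms=float(resid @ resid / df_resid) if df_resid > 0 else None,
    )


def predict(model: QuadraticModel, coded_point) -> float | np.ndarray:
    """Functional alias of :meth:`QuadraticModel.predict`."""
    return model.predict(coded_point)
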