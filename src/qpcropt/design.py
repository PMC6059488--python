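"""Rotatable central composite designs for reaction-condition experiments.

A central composite design (CCD) for k factors combines 2**k factorial
points (all coded levels at ±1), 2k axial ("star") points at coded distance
±alpha along one axis, and n_center replicated center points.  Choosing
alpha = F**(1/4), with F the number of factorial points, makes the design
rotatable: the variance of a fitted second-order prediction depends only on
the distance from the center.  For five factors alpha = 2**(5/4) ≈ 2.378,
which is why coded levels in this package span ±2.378 by default.

Coded and actual concentrations are related by the affine map

    actual = center + coded * step

per factor; ``FactorSpec`` carries the center, step and units.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignTable",
    "DesignValidationError",
    "rotatable_alpha",
    "generate_ccd",
    "code_point",
    "decode_point",
    "read_design_csv",
    "write_design_csv",
]

POINT_FACTORIAL = "factorial"
POINT_AXIAL = "axial"
POINT_CENTER = "center"


class DesignValidationError(ValueError):
    """Raised when a design violates a physical or structural constraint."""


@dataclass(frozen=True)
class FactorSpec:
    """One reagent factor of the reaction mix.

    Parameters
    ----------
    name : str
        Label, e.g. ``"primers"`` or ``"Mg2+"``.
    center : float
        Concentration at coded level 0, in ``units``.
    step : float
        Concentration change per +1 coded unit; must be positive.
    units : str
        e.g. ``"umol/L"``, ``"U/uL"``, ``"mmol/L"``.
    """

    name: str
    center: float
    step: float
    units: str = ""

    def __post_init__(self) -> None:
        if not self.step > 0:
            raise DesignValidationError(
                f"factor {self.name!r}: step must be > 0, got {self.step}"
            )

    def to_actual(self, coded: float) -> float:
        return self.center + coded * self.step

    def to_coded(self, actual: float) -> float:
        return (actual - self.center) / self.step

    def min_actual(self, alpha: float) -> float:
        """Lowest concentration the design reaches (at coded -alpha)."""
        return self.center - alpha * self.step


@dataclass
class DesignTable:
    """A CCD realisation: factors, coded/actual levels and point types."""

    factors: list[FactorSpec]
    frame: pd.DataFrame = field(repr=False)
    alpha: float = 0.0

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_runs(self) -> int:
        return len(self.frame)

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def coded(self) -> np.ndarray:
        """(n_runs, k) coded design matrix."""
        cols = [f"coded_{f.name}" for f in self.factors]
        return self.frame[cols].to_numpy(dtype=float)

    @property
    def actual(self) -> np.ndarray:
        cols = [f"actual_{f.name}" for f in self.factors]
        return self.frame[cols].to_numpy(dtype=float)

    @property
    def point_types(self) -> pd.Series:
        return self.frame["point_type"]

    def validate(self) -> None:
        """Check the structural invariants of a CCD."""
        coded = self.coded
        types = self.point_types.to_numpy()
        for row, ptype in zip(coded, types):
            nz = np.flatnonzero(row != 0.0)
            if ptype == POINT_FACTORIAL:
                if not np.all(np.abs(row) == 1.0):
                    raise DesignValidationError(
                        f"factorial row {row} has a coded level != ±1"
                    )
            elif ptype == POINT_AXIAL:
                if len(nz) != 1 or not np.isclose(abs(row[nz[0]]), self.alpha):
                    raise DesignValidationError(
                        f"axial row {row} must have exactly one entry at ±alpha"
                    )
            elif ptype == POINT_CENTER:
                if len(nz) != 0:
                    raise DesignValidationError(f"center row {row} is not all-zero")
            else:
                raise DesignValidationError(f"unknown point type {ptype!r}")
        # coded <-> actual consistency
        expected = np.array(
            [[f.to_actual(c) for f, c in zip(self.factors, row)] for row in coded]
        )
        if not np.allclose(expected, self.actual, rtol=0, atol=1e-9):
            raise DesignValidationError("coded/actual columns are inconsistent")


def rotatable_alpha(k: int, factorial_fraction: int = 0) -> float:
    """Axial distance making a k-factor CCD rotatable.

    alpha = F**(1/4) with F = 2**(k - factorial_fraction) factorial points.
    For k = 5 (full factorial) this is 2**(5/4) ≈ 2.378, the coded range of
    the five-factor design used throughout this package.
    """
    if not isinstance(k, (int, np.integer)) or isinstance(k, bool):
        raise TypeError(f"k must be an integer, got {k!r}")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if not isinstance(factorial_fraction, (int, np.integer)):
        raise TypeError("factorial_fraction must be an integer")
    n_fact = 2 ** (k - factorial_fraction)
    if n_fact < 4:
        raise ValueError(
            f"factorial fraction too aggressive: 2^{k - factorial_fraction} < 4"
        )
    return float(n_fact) ** 0.25


def generate_ccd(
    factors: list[FactorSpec],
    n_center: int = 8,
    alpha: float | str = "rotatable",
    shuffle_seed: int | None = None,
) -> DesignTable:
    """Generate a central composite design over ``factors``.

    Rows come in a deterministic canonical order: the 2**k factorial points
    in binary counting order (last factor toggling fastest, -1 before +1),
    then axial points grouped per factor (-alpha before +alpha), then the
    center replicates.  Pass ``shuffle_seed`` for a seeded random run order.

    Raises
    ------
    DesignValidationError
        If any actual concentration would be negative (physically invalid),
        naming the offending factor.
    """
    k = len(factors)
    if not 2 <= k <= 8:
        raise ValueError(f"supported factor counts are 2..8, got {k}")
    if n_center < 1:
        raise ValueError("n_center must be >= 1")
    if alpha == "rotatable":
        alpha_val = rotatable_alpha(k)
    else:
        alpha_val = float(alpha)
        if alpha_val <= 0:
            raise ValueError("alpha must be positive")

    for f in factors:
        if f.min_actual(alpha_val) < 0:
            raise DesignValidationError(
                f"factor {f.name!r}: center - alpha*step = "
                f"{f.min_actual(alpha_val):.6g} {f.units} is negative; "
                "shrink the step or raise the center"
            )

    rows: list[np.ndarray] = []
    types: list[str] = []
    # factorial block, binary order
    for i in range(2**k):
        bits = [(i >> (k - 1 - j)) & 1 for j in range(k)]
        rows.append(np.array([2 * b - 1 for b in bits], dtype=float))
        types.append(POINT_FACTORIAL)
    # axial block
    for j in range(k):
        for sign in (-1.0, +1.0):
            row = np.zeros(k)
            row[j] = sign * alpha_val
            rows.append(row)
            types.append(POINT_AXIAL)
    # center block
    for _ in range(n_center):
        rows.append(np.zeros(k))
        types.append(POINT_CENTER)

    coded = np.vstack(rows)
    if shuffle_seed is not None:
        order = np.random.default_rng(shuffle_seed).permutation(len(coded))
        coded = coded[order]
        types = [types[i] for i in order]

    actual = np.array(
        [[f.to_actual(c) for f, c in zip(factors, row)] for row in coded]
    )
    data: dict[str, object] = {
        "run_id": np.arange(1, len(coded) + 1),
        "point_type": types,
    }
    for j, f in enumerate(factors):
        data[f"coded_{f.name}"] = coded[:, j]
    for j, f in enumerate(factors):
        data[f"actual_{f.name}"] = actual[:, j]
    table = DesignTable(factors=list(factors), frame=pd.DataFrame(data), alpha=alpha_val)
    table.validate()
    return table


def code_point(factors: list[FactorSpec], actual) -> np.ndarray:
    """Map an actual-concentration vector to coded levels."""
    actual = np.asarray(actual, dtype=float)
    if actual.shape[-1] != len(factors):
        raise ValueError(
            f"expected {len(factors)} values, got {actual.shape[-1]}"
        )
    centers = np.array([f.center for f in factors])
    steps = np.array([f.step for f in factors])
    return (actual - centers) / steps


def decode_point(factors: list[FactorSpec], coded) -> np.ndarray:
    """Map a coded-level vector to actual concentrations."""
    coded = np.asarray(coded, dtype=float)
    if coded.shape[-1] != len(factors):
        raise ValueError(f"expected {len(factors)} values, got {coded.shape[-1]}")
    centers = np.array([f.center for f in factors])
    steps = np.array([f.step for f in factors])
    return centers + coded * steps


def write_design_csv(design: DesignTable, path_or_buf) -> None:
    """Write the design as UTF-8 CSV (run_id, point_type, coded_*, actual_*)."""
    design.frame.to_csv(path_or_buf, index=False)


def read_design_csv(path_or_buf, factors: list[FactorSpec]) -> DesignTable:
    """Read a design CSV written by :func:`write_design_csv` and validate it."""
    if isinstance(path_or_buf, (str,)) and "\n" in path_or_buf:
        path_or_buf = io.StringIO(path_or_buf)
    frame = pd.read_csv(path_or_buf)
    required = ["run_id", "point_type"] + [f"coded_{f.name}" for f in factors] + [
        f"actual_{f.name}" for f in factors
    ]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise DesignValidationError(f"design CSV missing columns: {missing}")
    axial = frame.loc[frame["point_type"] == POINT_AXIAL]
    if len(axial):
        coded_cols = [f"coded_{f.name}" for f in factors]
        alpha = float(np.abs(axial[coded_cols].to_numpy()).max())
    else:
        alpha = float(
            np.abs(frame[[f"coded_{f.name}" for f in factors]].to_numpy()).max()
        )
    table = DesignTable(factors=list(factors), frame=frame, alpha=alpha)
    table.validate()
    return table
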