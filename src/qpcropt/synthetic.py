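"""Synthetic Ct-surface generator for testing the whole pipeline.

Emulates a 50-run five-factor CCD response table for a multiplex qPCR
panel: the per-run mean Ct follows a known second-order surface dominated
by the Mg2+ effect with curvature, each run carries replicate measurements
(default triplicate) with i.i.d. Gaussian noise, and an optional
third-order term in the Mg2+ coordinate injects lack-of-fit
(model misspecification) at a tunable amplitude.

Three built-in ground-truth profiles (RSV, INF, HMPV) use the reduced
response-surface coefficients of the corresponding multiplex assays; in
all three the Mg2+ linear effect is the largest, matching the consistent
finding that Mg2+ concentration dominates the Ct response.

The generator stands in for real instrument data: it reproduces the
design geometry, replicate noise and curvature structure, not
amplification chemistry (no fluorescence curves, efficiency or
primer-dimer effects).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .design import DesignTable, FactorSpec, generate_ccd, write_design_csv
from .rsm import QuadraticModel

__all__ = [
    "SyntheticSurfaceSpec",
    "DEFAULT_FACTORS",
    "PROFILES",
    "default_spec",
    "simulate_response",
    "make_fixture_bundle",
    "read_runs_csv",
    "write_runs_csv",
    "load_factors_yaml",
]

FACTOR_NAMES = ["A", "B", "C", "D", "E"]

#: Example factor configuration (centers/steps chosen so the rotatable
#: design spans realistic reagent ranges: primers/probes 0.08-0.32 umol/L,
#: polymerase 0.03-0.08 U/uL, Mg2+ 0.8-2.55 mmol/L, dNTPs 0.08-0.16 mmol/L).
DEFAULT_FACTORS = [
    FactorSpec("A", center=0.2, step=0.05, units="umol/L"),      # primers
    FactorSpec("B", center=0.2, step=0.05, units="umol/L"),      # probes
    FactorSpec("C", center=0.055, step=0.0105, units="U/uL"),    # DNA polymerase
    FactorSpec("D", center=1.675, step=0.368, units="mmol/L"),   # Mg2+
    FactorSpec("E", center=0.12, step=0.0168, units="mmol/L"),   # dNTPs
]

#: Reduced-model ground-truth coefficients per virus profile (coded units,
#: Ct scale).  D (Mg2+) carries the largest linear effect in every profile.
PROFILES: dict[str, dict[str, float]] = {
    "RSV": {"intercept": 23.600, "C": -0.420, "D": -1.630, "D^2": 0.950},
    "INF": {"intercept": 23.740, "D": -0.880, "E": 0.370, "AB": -0.460,
            "BE": 0.580},
    "HMPV": {"intercept": 23.600, "A": -0.320, "D": -1.100, "AC": 0.370,
             "D^2": 0.620},
}


@dataclass
class SyntheticSurfaceSpec:
    """Ground truth for a simulated Ct response surface."""

    true_model: QuadraticModel
    noise_sd: float = 0.1  # replicate noise, Ct units
    replicates_per_run: int = 3
    seed: int = 0
    nonquadratic_amplitude: float = 0.0  # cubic-in-D lack-of-fit knob

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates_per_run < 1:
            raise ValueError("replicates_per_run must be >= 1")


def default_spec(
    virus_profile: str,
    noise_sd: float = 0.1,
    replicates_per_run: int = 3,
    seed: int = 0,
    nonquadratic_amplitude: float = 0.0,
) -> SyntheticSurfaceSpec:
    """Ground-truth spec whose surface is the printed reduced model of a profile."""
    if virus_profile not in PROFILES:
        raise ValueError(
            f"unknown profile {virus_profile!r}; choose from {sorted(PROFILES)}"
        )
    model = QuadraticModel.from_coefficients(FACTOR_NAMES, PROFILES[virus_profile])
    return SyntheticSurfaceSpec(
        true_model=model,
        noise_sd=noise_sd,
        replicates_per_run=replicates_per_run,
        seed=seed,
        nonquadratic_amplitude=nonquadratic_amplitude,
    )


def simulate_response(design: DesignTable, spec: SyntheticSurfaceSpec) -> pd.DataFrame:
    """Simulate replicate Ct measurements for every design run.

    Each replicate is (true surface) + amplitude * D^3 + N(0, noise_sd),
    independent across replicates and runs; deterministic under
    ``spec.seed``.  Returns run_id, ct_rep1..R and ct_mean columns.
    """
    if design.k != spec.true_model.k:
        raise ValueError("design and spec have different factor counts")
    rng = np.random.default_rng(spec.seed)
    coded = design.coded
    surface = np.asarray(spec.true_model.predict(coded), dtype=float)
    if spec.nonquadratic_amplitude != 0.0:
        d_idx = design.factor_names.index("D") if "D" in design.factor_names else 0
        surface = surface + spec.nonquadratic_amplitude * coded[:, d_idx] ** 3
    r = spec.replicates_per_run
    noise = rng.normal(0.0, spec.noise_sd, size=(design.n_runs, r))
    reps = surface[:, None] + noise
    data = {"run_id": design.frame["run_id"].to_numpy()}
    for j in range(r):
        data[f"ct_rep{j + 1}"] = reps[:, j]
    data["ct_mean"] = reps.mean(axis=1)
    return pd.DataFrame(data)


def write_runs_csv(design: DesignTable, responses: pd.DataFrame, path) -> None:
    """Design columns joined with replicate/mean Ct columns, one CSV."""
    merged = design.frame.merge(responses, on="run_id", validate="1:1")
    merged.to_csv(path, index=False)


def read_runs_csv(path, factors: list[FactorSpec]):
    """Read a combined design+response CSV; returns (DesignTable, responses)."""
    from .design import read_design_csv

    frame = pd.read_csv(path)
    ct_cols = [c for c in frame.columns if c.startswith("ct_")]
    if "ct_mean" not in ct_cols:
        raise ValueError("runs CSV must contain a ct_mean column")
    bad = frame[ct_cols].apply(lambda s: pd.to_numeric(s, errors="coerce")).isna()
    if bad.to_numpy().any():
        rows = (bad.any(axis=1)[bad.any(axis=1)].index + 2).tolist()  # header is line 1
        raise ValueError(f"non-numeric Ct cells at CSV line(s) {rows}")
    design_cols = [c for c in frame.columns if c not in ct_cols]
    import io

    buf = io.StringIO()
    frame[design_cols].to_csv(buf, index=False)
    buf.seek(0)
    design = read_design_csv(buf, factors)
    return design, frame[["run_id"] + ct_cols]


def make_fixture_bundle(out_dir, seed: int = 0, noise_sd: float = 0.1) -> dict[str, Path]:
    """Write a complete worked fixture: factor config, design, three response tables.

    Deterministic: the same seed produces byte-identical files.  Returns a
    name -> path map (``factors``, ``design``, ``runs_RSV`` ...).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    factors_path = out / "factors.yaml"
    payload = {
        "factors": [
            {"name": f.name, "center": f.center, "step": f.step, "units": f.units}
            for f in DEFAULT_FACTORS
        ]
    }
    factors_path.write_text(yaml.safe_dump(payload, sort_keys=False))
    paths["factors"] = factors_path

    design = generate_ccd(DEFAULT_FACTORS, n_center=8, alpha="rotatable")
    design_path = out / "design.csv"
    write_design_csv(design, design_path)
    paths["design"] = design_path

    for i, profile in enumerate(sorted(PROFILES)):
        spec = default_spec(profile, noise_sd=noise_sd, seed=seed * 1000 + i)
        responses = simulate_response(design, spec)
        p = out / f"runs_{profile}.csv"
        write_runs_csv(design, responses, p)
        paths[f"runs_{profile}"] = p
    return paths


def load_factors_yaml(path) -> list[FactorSpec]:
    """Read a factor configuration written by :func:`make_fixture_bundle`."""
    payload = yaml.safe_load(Path(path).read_text())
    return [
        FactorSpec(f["name"], f["center"], f["step"], f.get("units", ""))
        for f in payload["factors"]
    ]
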