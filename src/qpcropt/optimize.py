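"""Minimizing predicted Ct over the coded factor box.

Three routes:

* :func:`minimize_quadratic` — exact box-constrained minimum of a fitted
  quadratic, by enumerating the 3**k active sets (each coordinate pinned at
  its lower bound, its upper bound, or left free); on each face the reduced
  stationary system is solved and kept when it is feasible and the reduced
  Hessian is positive definite.  Every vertex is a candidate, so the global
  minimum over the compact box is always among the candidates.
* :func:`ga_minimize` — a seeded real-coded genetic algorithm (tournament
  selection, blend crossover, Gaussian mutation clipped to the bounds,
  elitism) for any surrogate exposing ``predict`` on batches, including the
  neural-network surrogate.
* :func:`harmonize_multiplex` — reconciles per-target optima into one set
  of shared-reagent concentrations: in a multiplex reaction the polymerase,
  Mg2+ and dNTP concentrations are common to all targets while each
  target keeps its own primers/probes, so the shared levels are chosen to
  minimize the worst-case (minimax) predicted Ct across targets, after
  which each target re-optimizes its free factors at the shared setting.

Bounds default to the coded design box ±alpha; optimizing a surrogate
outside the region it was trained on extrapolates and is not allowed here.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize as _scipy_minimize

from .design import FactorSpec, decode_point
from .rsm import QuadraticModel

__all__ = [
    "GaConfig",
    "OptimizationResult",
    "HarmonizedResult",
    "minimize_quadratic",
    "ga_minimize",
    "harmonize_multiplex",
]


@dataclass(frozen=True)
class GaConfig:
    """Hyperparameters of the real-coded genetic algorithm."""

    population: int = 60
    generations: int = 200
    crossover_rate: float = 0.9
    mutation_rate: float = 0.1
    mutation_sd: float = 0.2  # coded units, at generation 0
    mutation_sd_final: float = 1e-3  # annealed to this by the last generation
    elitism: int = 2
    seed: int = 0
    tournament: int = 3
    blend_alpha: float = 0.5
    restarts: int = 4  # independent populations; best-ever across all

    @property
    def evaluations(self) -> int:
        return self.restarts * self.population * (self.generations + 1)

    def __post_init__(self) -> None:
        if self.population < 4:
            raise ValueError("population must be >= 4")
        for name in ("crossover_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.elitism < 0 or self.elitism >= self.population:
            raise ValueError("elitism must be in [0, population)")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class OptimizationResult:
    """A located optimum of a Ct surrogate over the coded box."""

    coded_optimum: np.ndarray
    predicted_ct: float
    bounds: np.ndarray  # (k, 2)
    method: str
    surrogate: str = ""
    actual_optimum: np.ndarray | None = None

    def with_actual(self, factors: list[FactorSpec]) -> "OptimizationResult":
        self.actual_optimum = decode_point(factors, self.coded_optimum)
        return self

    def to_json(self) -> str:
        return json.dumps(
            {
                "coded_optimum": self.coded_optimum.tolist(),
                "actual_optimum": (
                    None
                    if self.actual_optimum is None
                    else self.actual_optimum.tolist()
                ),
                "predicted_ct": self.predicted_ct,
                "bounds": self.bounds.tolist(),
                "method": self.method,
                "surrogate": self.surrogate,
            },
            indent=2,
        )


def _as_bounds(bounds, k: int) -> np.ndarray:
    b = np.asarray(bounds, dtype=float)
    if b.shape == (2,):
        b = np.tile(b, (k, 1))
    if b.shape != (k, 2) or np.any(b[:, 0] > b[:, 1]) or not np.all(np.isfinite(b)):
        raise ValueError(f"bounds must be finite (k, 2) intervals, got {bounds!r}")
    return b


def _quadratic_parts(model: QuadraticModel) -> tuple[float, np.ndarray, np.ndarray]:
    """Represent the polynomial as c + g.x + 0.5 x.H x."""
    k = model.k
    h = np.zeros((k, k))
    idx = 0
    for i in range(k):
        for j in range(i + 1, k):
            h[i, j] = h[j, i] = model.interaction[idx]
            idx += 1
    h[np.diag_indices(k)] = 2.0 * model.quadratic
    return model.intercept, model.linear.copy(), h


def minimize_quadratic(
    model: QuadraticModel, bounds=(-2.378, 2.378)
) -> OptimizationResult:
    """Exact minimum of a quadratic surrogate over a coded box.

    Enumerates all 3**k assignments of coordinates to {lower bound, upper
    bound, free}; for each, solves the stationary equations in the free
    coordinates and keeps feasible candidates whose reduced Hessian is
    positive definite.  Vertices (all coordinates pinned) are always
    candidates, so a minimizer is guaranteed to be found.
    """
    k = model.k
    b = _as_bounds(bounds, k)
    const, g, h = _quadratic_parts(model)

    best_x: np.ndarray | None = None
    best_val = np.inf
    for assign in itertools.product((0, 1, 2), repeat=k):
        fixed = [i for i, a in enumerate(assign) if a != 2]
        free = [i for i, a in enumerate(assign) if a == 2]
        x = np.zeros(k)
        for i in fixed:
            x[i] = b[i, assign[i]]
        if free:
            hff = h[np.ix_(free, free)]
            rhs = -(g[free] + h[np.ix_(free, fixed)] @ x[fixed])
            try:
                eig = np.linalg.eigvalsh(hff)
                if eig.min() <= 1e-12:
                    continue  # face minimum lies on its boundary
                x_free = np.linalg.solve(hff, rhs)
            except np.linalg.LinAlgError:
                continue
            if np.any(x_free < b[free, 0] - 1e-12) or np.any(
                x_free > b[free, 1] + 1e-12
            ):
                continue
            x[free] = np.clip(x_free, b[free, 0], b[free, 1])
        val = const + g @ x + 0.5 * x @ h @ x
        if val < best_val - 1e-15:
            best_val = val
            best_x = x.copy()
    assert best_x is not None
    return OptimizationResult(
        coded_optimum=best_x,
        predicted_ct=float(model.predict(best_x)),
        bounds=b,
        method="active-set enumeration",
        surrogate="model I (quadratic)",
    )


def ga_minimize(
    surrogate, bounds=(-2.378, 2.378), config: GaConfig | None = None, k: int | None = None
) -> OptimizationResult:
    """Genetic-algorithm minimum of any surrogate over the coded box.

    ``surrogate`` needs a ``predict`` method accepting an (n, k) batch of
    coded points.  Deterministic under ``config.seed``; returns the best
    individual ever evaluated.
    """
    if config is None:
        config = GaConfig()
    if k is None:
        k = getattr(surrogate, "k", None) or getattr(surrogate, "n_inputs")
    b = _as_bounds(bounds, k)

    best_x: np.ndarray | None = None
    best_val = np.inf
    seed_seq = np.random.SeedSequence(config.seed)
    for child_seq in seed_seq.spawn(config.restarts):
        x, val = _ga_run(surrogate, b, config, np.random.default_rng(child_seq))
        if val < best_val:
            best_x, best_val = x, val

    label = "model I (quadratic)" if isinstance(surrogate, QuadraticModel) else "model II (BPNN)"
    return OptimizationResult(
        coded_optimum=best_x,
        predicted_ct=best_val,
        bounds=b,
        method="genetic algorithm",
        surrogate=label,
    )


def _ga_run(
    surrogate, b: np.ndarray, config: GaConfig, rng: np.random.Generator
) -> tuple[np.ndarray, float]:
    """One GA population to convergence; returns the best individual ever seen."""
    k = b.shape[0]
    lo, hi = b[:, 0], b[:, 1]
    pop = rng.uniform(lo, hi, size=(config.population, k))
    # vertex-seeded initialization: box-constrained response surfaces often
    # attain their minimum at or near a vertex, and the basin around the
    # right vertex can occupy a tiny volume fraction that uniform sampling
    # misses; seeding corners puts every vertex basin in play.
    corners = np.array(list(itertools.product(*zip(lo, hi))))
    n_seed = min(len(corners), config.population // 2)
    if n_seed:
        pick = rng.permutation(len(corners))[:n_seed]
        pop[:n_seed] = corners[pick]
    fitness = np.asarray(surrogate.predict(pop), dtype=float)
    best_i = int(np.argmin(fitness))
    best_x, best_val = pop[best_i].copy(), float(fitness[best_i])

    # exponential annealing of the mutation scale: coarse exploration early,
    # fine refinement late
    if config.generations > 1 and config.mutation_sd_final < config.mutation_sd:
        decay = (config.mutation_sd_final / config.mutation_sd) ** (
            1.0 / (config.generations - 1)
        )
    else:
        decay = 1.0

    for gen in range(config.generations):
        sd = config.mutation_sd * decay**gen
        order = np.argsort(fitness)
        elites = pop[order[: config.elitism]]
        # tournament selection of parents
        n_children = config.population - config.elitism
        idx = rng.integers(0, config.population, size=(n_children, config.tournament))
        winners = idx[np.arange(n_children), np.argmin(fitness[idx], axis=1)]
        parents = pop[winners]
        # blend (BLX-alpha) crossover on consecutive pairs
        children = parents.copy()
        for i in range(0, n_children - 1, 2):
            if rng.random() < config.crossover_rate:
                p, q = parents[i], parents[i + 1]
                d = np.abs(p - q)
                low = np.minimum(p, q) - config.blend_alpha * d
                high = np.maximum(p, q) + config.blend_alpha * d
                children[i] = rng.uniform(low, high)
                children[i + 1] = rng.uniform(low, high)
        # Gaussian mutation, clipped to bounds
        mutate = rng.random(size=children.shape) < config.mutation_rate
        noise = rng.normal(0.0, sd, size=children.shape)
        children = np.clip(children + mutate * noise, lo, hi)
        pop = np.vstack([elites, children])
        fitness = np.asarray(surrogate.predict(pop), dtype=float)
        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_val:
            best_val = float(fitness[gen_best])
            best_x = pop[gen_best].copy()
    return best_x, best_val


def _restrict_quadratic(
    model: QuadraticModel, shared_idx: list[int], shared_vals: np.ndarray
) -> QuadraticModel:
    """The quadratic in the free coordinates with shared ones held fixed."""
    const, g, h = _quadratic_parts(model)
    free = [i for i in range(model.k) if i not in shared_idx]
    s = np.asarray(shared_vals, dtype=float)
    const2 = const + g[shared_idx] @ s + 0.5 * s @ h[np.ix_(shared_idx, shared_idx)] @ s
    g2 = g[free] + h[np.ix_(free, shared_idx)] @ s
    h2 = h[np.ix_(free, free)]
    names = [model.factor_names[i] for i in free]
    kf = len(free)
    inter = []
    for a in range(kf):
        for c in range(a + 1, kf):
            inter.append(h2[a, c])
    return QuadraticModel(
        factor_names=names,
        intercept=float(const2),
        linear=g2,
        quadratic=0.5 * np.diag(h2),
        interaction=np.array(inter),
    )


@dataclass
class HarmonizedResult:
    """Shared-reagent levels plus per-target optima at those levels."""

    shared_idx: list[int]
    shared_coded: np.ndarray
    per_target: list[OptimizationResult]
    target_labels: list[str]
    worst_case_ct: float
    factor_names: list[str] = field(default_factory=list)

    def to_frame(self, factors: list[FactorSpec] | None = None) -> pd.DataFrame:
        """Recommendation table: one column per target, one row per factor."""
        data = {}
        for label, res in zip(self.target_labels, self.per_target):
            if factors is not None:
                res.with_actual(factors)
                vec = res.actual_optimum
            else:
                vec = res.coded_optimum
            col = list(np.asarray(vec)) + [res.predicted_ct]
            data[label] = col
        names = self.factor_names or [f"x{i}" for i in range(len(col) - 1)]
        return pd.DataFrame(data, index=names + ["predicted_ct"])


def harmonize_multiplex(
    per_target_models: list[QuadraticModel],
    shared_idx: list[int],
    bounds=(-2.378, 2.378),
    target_labels: list[str] | None = None,
    grid_points: int | None = None,
) -> HarmonizedResult:
    """Choose one value per shared factor minimizing the worst-case Ct.

    The shared coordinates (typically polymerase, Mg2+ and dNTPs) are set
    by minimax over targets: for a candidate shared vector each target's
    free factors are re-optimized exactly, and the shared vector minimizing
    the maximum of those per-target optima wins.  The outer search is a
    dense grid followed by a Nelder-Mead polish.
    """
    if len(per_target_models) < 1:
        raise ValueError("need at least one model")
    k = per_target_models[0].k
    names = per_target_models[0].factor_names
    for m in per_target_models:
        if m.k != k or m.factor_names != names:
            raise ValueError("all models must share an identical factor space")
    b = _as_bounds(bounds, k)
    if target_labels is None:
        target_labels = [f"target{i + 1}" for i in range(len(per_target_models))]
    shared_idx = sorted(shared_idx)

    if not shared_idx:
        per_target = [minimize_quadratic(m, b) for m in per_target_models]
        worst = max(r.predicted_ct for r in per_target)
        return HarmonizedResult([], np.empty(0), per_target, list(target_labels),
                                worst, names)

    free = [i for i in range(k) if i not in shared_idx]
    b_free = b[free] if free else None

    def inner(shared_vals: np.ndarray) -> list[OptimizationResult]:
        out = []
        for m in per_target_models:
            if free:
                sub = _restrict_quadratic(m, shared_idx, shared_vals)
                r = minimize_quadratic(sub, b_free)
                x = np.zeros(k)
                x[shared_idx] = shared_vals
                x[free] = r.coded_optimum
                val = r.predicted_ct
            else:
                x = np.zeros(k)
                x[shared_idx] = shared_vals
                val = float(m.predict(x))
            out.append(
                OptimizationResult(
                    coded_optimum=x,
                    predicted_ct=float(val),
                    bounds=b,
                    method="harmonized minimax",
                    surrogate="model I (quadratic)",
                )
            )
        return out

    def objective(shared_vals: np.ndarray) -> float:
        s = np.clip(shared_vals, b[shared_idx, 0], b[shared_idx, 1])
        return max(r.predicted_ct for r in inner(s))

    # dense grid over the shared coordinates, then local polish
    if grid_points is None:
        grid_points = {1: 41, 2: 15, 3: 9}.get(len(shared_idx), 5)
    axes = [np.linspace(b[i, 0], b[i, 1], grid_points) for i in shared_idx]
    best_s, best_val = None, np.inf
    for point in itertools.product(*axes):
        v = objective(np.asarray(point))
        if v < best_val:
            best_val, best_s = v, np.asarray(point)
    res = _scipy_minimize(objective, best_s, method="Nelder-Mead",
                          options={"xatol": 1e-6, "fatol": 1e-9})
    s_opt = np.clip(res.x, b[shared_idx, 0], b[shared_idx, 1])
    if objective(s_opt) > best_val:
        s_opt = best_s
    per_target = inner(s_opt)
    return HarmonizedResult(
        shared_idx=shared_idx,
        shared_coded=np.asarray(s_opt, dtype=float),
        per_target=per_target,
        target_labels=list(target_labels),
        worst_case_ct=max(r.predicted_ct for r in per_target),
        factor_names=names,
    )
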