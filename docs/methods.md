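# Methods

## The problem and the model

A multiplex qPCR reaction's cycle threshold Ct is treated as a smooth
response of five reagent concentrations — primers (A), probes (B), DNA
polymerase (C), Mg²⁺ (D), dNTPs (E) — over a bounded experimental region.
Two surrogates of that response are built from the same designed
experiment and compared:

* **Model I**: the full second-order polynomial on coded levels,
  Y = β₀ + ΣβᵢXᵢ + ΣβᵢᵢXᵢ² + Σᵢ<ⱼβᵢⱼXᵢXⱼ + ε, fitted by ordinary least
  squares (21 parameters for k = 5). ε is i.i.d. measurement error.
* **Model II**: a three-layer feed-forward network, 5 inputs → H sigmoid
  hidden units → 1 output, trained on the Ct response after linear scaling
  onto ±2.378.

Both are minimized over the coded box [−α, +α]⁵; predicted-Ct minimization
is the assay-optimization objective (earlier fluorescence crossing =
stronger amplification).

## Experimental design

`generate_ccd` builds the rotatable central composite design: 2ᵏ factorial
points at ±1, 2k axial points at ±α, and n_center center replicates, in a
deterministic canonical order (factorial block in binary counting order,
axial pairs per factor, centers last); a seeded shuffle is optional. With
α = F^(1/4) (F = factorial-point count) the design is rotatable; for k = 5
full factorial α = 2^(5/4) ≈ 2.3784, which is also why the response is
scaled to ±2.378 for the network — inputs and target then share one range.
n_center defaults to 8: eight center replicates give the 7 pure-error
degrees of freedom that the ANOVA's lack-of-fit test rests on.

Coded and actual concentrations are linked per factor by
actual = center + coded·step. Centers and steps are user configuration;
the bundled example values (A, B: 0.2 ± 0.05 μmol/L per coded unit;
C: 0.055 ± 0.0105 U/μL; D: 1.675 ± 0.368 mmol/L; E: 0.12 ± 0.0168 mmol/L)
span practical kit ranges — e.g. Mg²⁺ runs 0.80–2.55 mmol/L across the
±α design — and keep every design concentration non-negative, which the
generator enforces (a negative concentration is a configuration error
naming the offending factor).

## ANOVA

The table carries one-df partial (Type-III) sums of squares per term,
SSⱼ = βⱼ²/(XᵀX)⁻¹ⱼⱼ, a pooled 20-df model row, and the residual split into
lack-of-fit and pure error. Pure error is computed from design points
replicated at identical coded levels, using the **per-run mean** response —
the same response vector that is fitted. Replicate Ct columns exist in the
data model, but the analysis response is the triplicate mean, so the
pure-error df with 8 center runs is 7 (not 8×(3−1)+…): the split measures
run-to-run reproducibility of the analyzed response, and it is what makes
the lack-of-fit F-test well-defined for the fitted model. Term F-ratios
are tested against the residual mean square, lack of fit against pure
error, all with upper-tail F probabilities and no multiplicity correction.

`adequate_precision` is the conventional signal-to-noise summary
(max ŷ − min ŷ over design points) / √(p·MS_resid/n); > 4 is the usual
"surface is usable" convention. Under a flat true surface its null
distribution straddles 4 (both numerator and denominator are noise-driven),
so tests treat it as a strong-vs-null separation statistic, not a sharp
threshold.

`reduce_model` keeps the intercept plus every term with P < 0.05 (pure
thresholding — hierarchy is deliberately not enforced, so an interaction
can outlive its parent main effect) and **refits** the retained columns;
with ~18 inactive terms, about one false inclusion per fit is the expected
cost of the 5% rule. An exactly interpolating fit has its residual mean
square snapped to zero (relative tolerance 1e-16) so F-ratios and the
precision ratio report as infinite rather than floating-point noise.

## Network surrogate and cross-validation

Training minimizes MSE on the scaled response by L-BFGS with analytic
gradients; initial weights ~ U(−0.5, 0.5) from a recorded seed, so a fixed
seed gives bit-identical weights. Because the scaled target exceeds (0,1),
the output unit is linear by default; a sigmoid-output variant
(`output_activation="sigmoid"`) stretches the logistic output affinely
onto the ±h band so the extremes stay reachable. Convergence is declared
at gradient/function tolerance 1e-8 or the epoch cap (default 2000; 500
inside CV), otherwise best-so-far weights return with a warning —
harmless in CV, where all candidates share the same budget.

`cv_select_nodes` partitions the runs into k (default 5) equal folds from
a seeded shuffle, trains each candidate width on k−1 folds and scores MSE
on the held-out fold, reporting mean ± sd across folds for both fit
(training) and prediction (held-out) error on the scaled basis. Selection
minimizes mean prediction error, ties toward fewer nodes. The response
scaling is fitted once on the full Ct vector — mirroring how the pipeline
scales before modelling — rather than per fold; the leakage is a two-
parameter affine map and does not touch the ordering of candidates.

## Optimization

* `minimize_quadratic` is exact: every assignment of each coordinate to
  {lower bound, upper bound, free} (3ᵏ active sets) is enumerated; on each
  face the reduced stationary system is solved and kept when feasible with
  a positive-definite reduced Hessian. Vertices are always candidates, so
  the global box minimum — which for an indefinite quadratic lies on some
  face or vertex — is always among the evaluated points.
* `ga_minimize` is a real-coded GA: tournament selection (size 3), BLX-0.5
  blend crossover, Gaussian mutation clipped to bounds, elitism 2,
  population 60 over 200 generations. Three reliability features are part
  of the default configuration: the mutation sd anneals exponentially from
  0.2 to 1e-3 coded units (coarse search early, refinement late); up to
  half the initial population is seeded with box vertices, because an
  indefinite surrogate's minimum often sits in a vertex basin whose volume
  fraction uniform sampling misses; and 4 independent restarts multiply
  away residual wrong-basin risk. With these defaults the GA matched the
  exact quadratic minimum within 1e-2 Ct on 150/150 random five-factor
  quadratics in the development simulations, and this property is asserted
  (100 quadratics) in the test suite.
* `harmonize_multiplex` formalizes shared-reagent reconciliation as
  minimax: choose one value per shared factor (C, D, E) minimizing the
  worst per-target optimal Ct, each inner optimum computed exactly on the
  restricted quadratic; the outer search is a dense grid over the shared
  coordinates (41/15/9 points per dim for 1/2/3 shared dims) with a
  Nelder-Mead polish. This is a formalization of the practice of picking a
  single compromise concentration by inspection, not a reproduction of any
  particular hand-chosen value; its output guarantees shared-factor
  equality across targets, in-bounds levels, and per-target Ct no better
  than the unconstrained optimum.

## Evaluation and comparison

R², MAE and MSE follow the standard definitions; each `FitMetrics` carries
a `basis` label because MAE/MSE computed on the compressed ±2.378 scaled
axis are numerically tiny and not comparable to Ct-scale errors — a
comparison across bases is refused unless explicitly overridden, and the
winner between surrogates is declared on held-out (cross-validated)
prediction error, never on training R² (a flexible surrogate can hold the
higher R² and still generalize worse).

## Synthetic data: what it does and does not emulate

`simulate_response` draws replicate Ct = true surface + a·D³ + N(0, σ)
per run, i.i.d., deterministic under seed. The built-in profiles use
reduced second-order surfaces for three respiratory-virus assays whose
dominant effect is Mg²⁺ (RSV: 23.600 − 0.420·C − 1.630·D + 0.950·D²; INF:
23.740 − 0.880·D + 0.370·E − 0.460·AB + 0.580·BE; HMPV: 23.600 − 0.320·A −
1.100·D + 0.370·AC + 0.620·D²). Default replicate noise is σ = 0.1 Ct,
loosely calibrated so the pure-error mean square of triplicate means at
8 centers lands in the few-hundredths range typical of replicated qPCR
center points; the cubic-in-D amplitude is a model-misspecification knob
(0 by default, i.e. the surface lies exactly in the quadratic class).

The generator reproduces design geometry, replicate noise and curvature —
enough to exercise estimation, selection, CV and optimization end-to-end —
but not amplification chemistry: no fluorescence-vs-cycle curves,
efficiency saturation, primer-dimer competition, or heteroscedastic noise.
Passing tests therefore certify the statistical machinery, not any claim
about a particular instrument's data.

## Problem sizes and numerical choices

Simulation-based tests use the 50-run design throughout, with 200 seeds
for the parameter-recovery/pure-error checks, 100 random quadratics for
GA-vs-exact equivalence, 50 seeds for the CV optimism property, and
smaller seed counts (12–60) for secondary distributional checks; these
sizes put Monte-Carlo error well inside the asserted tolerances. Exact
identities (SS/df additivity, coded↔actual round-trips, noiseless
coefficient recovery) are asserted at 1e-8 or tighter; statistical
assertions use 4-standard-error bands or generous quantile bounds stated
inline.

## Known limitations

* The ANOVA assumes homoscedastic i.i.d. errors; no robust or mixed-model
  alternative is provided.
* Model reduction is single-pass thresholding; no hierarchy enforcement,
  stepwise search or multiplicity control.
* The GA's reliability guarantees are empirical (simulation-backed), not
  theoretical; pathological surrogates could still defeat 4 restarts.
* Harmonization optimizes worst-case predicted Ct only; cost, specificity
  and primer-dimer considerations that practitioners weigh informally are
  out of scope.
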