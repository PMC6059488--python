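# qpcropt

Reaction-condition optimization for multiplex quantitative PCR (qPCR).

Multiplex qPCR amplifies several targets in one tube; its sensitivity —
read out as the cycle threshold Ct, lower being better — depends jointly
on five reagent concentrations: primers (A), probes (B), DNA polymerase
(C), Mg²⁺ (D) and dNTPs (E). Because these factors interact (Mg²⁺ in
particular both enables the polymerase and binds dNTPs), one-factor-at-a-
time tuning misses the optimum. `qpcropt` implements the full
design-of-experiments workflow an assay developer needs:

1. **Design** — a rotatable central composite design (CCD) over the five
   factors: 2⁵ = 32 factorial points, 10 axial points at coded distance
   α = 2^(5/4) ≈ 2.378, and 8 replicated center points (50 runs), with an
   affine coded↔actual concentration map per factor.
2. **Response-surface model (model I)** — ordinary least squares of the
   full second-order polynomial on coded levels,

   Y = β₀ + Σᵢ βᵢXᵢ + Σᵢ βᵢᵢXᵢ² + ΣΣᵢ<ⱼ βᵢⱼXᵢXⱼ + ε,

   with a complete ANOVA (per-term partial SS, lack-of-fit vs pure-error
   split from the center replicates, adequate-precision signal-to-noise
   ratio) and reduction to the p < 0.05 terms with refitting.
3. **Neural surrogate (model II)** — a three-layer back-propagation
   network (sigmoid hidden layer) on the Ct response scaled to ±2.378,
   hidden-layer size chosen by five-fold cross-validation.
4. **Optimization** — exact box-constrained minimization of the quadratic
   (active-set enumeration) and a seeded real-coded genetic algorithm for
   either surrogate; per-target optima are then *harmonized* into one set
   of shared-reagent concentrations (C, D, E must be common to all targets
   in a single multiplex reaction) by minimax over targets.
5. **Evaluation** — R², MAE and MSE with an explicit response-scale
   ("basis") label, held-out-error model comparison that refuses silent
   cross-basis metric comparisons, and the validation statistic
   |Ct_pred − Ct_exp| / Ct_exp × 100%.

A synthetic-data module generates CCD response tables from built-in
ground-truth surfaces for three respiratory-virus assays (RSV, INF, HMPV)
with triplicate Gaussian replicate noise and a tunable lack-of-fit term,
so the entire pipeline is testable without instrument data.

## Worked example

`examples/01_design_and_fit.py` designs the 50-run CCD, simulates a
triplicate RSV Ct table (noise sd 0.1 Ct) and fits/reduces the surface:

```
design: 50 runs, axial distance 2.378

ANOVA pooled rows (SS, df):
  Model        SS= 174.556  df=20
  Residual     SS=   0.064  df=29
  Lack of Fit  SS=   0.053  df=22
  Pure Error   SS=   0.011  df=7
  Cor Total    SS= 174.621  df=49
adequate precision: 339.7 (above 4 means the surface can guide optimization)

terms kept at p<0.05: ['C', 'D', 'AE', 'D^2']
reduced-model coefficients (coded units, Ct scale):
     C: -0.424
     D: -1.621
    AE: -0.023
   D^2: +0.951
predicted Ct at the center point: 23.591
```

The Mg²⁺ terms (D, D²) dominate: Ct falls by ~1.6 cycles per coded unit of
Mg²⁺ with upward curvature, so an interior Mg²⁺ optimum exists, while the
polymerase effect (C) is smaller and linear. The `AE` term is a
false positive at the 5% threshold — with 20 tested terms, about one is
expected per fit; note its negligible coefficient. The pure-error mean
square (0.011/7 ≈ 0.0016) estimates the variance of a triplicate mean,
consistent with the generating replicate sd 0.1/√3.

`examples/03_optimize_and_harmonize.py` then minimizes each target's
surface and reconciles the shared reagents:

```
independent optima (coded levels; lower Ct = stronger amplification):
  RSV   exact Ct  21.902   GA Ct  21.902   (D at +0.858)
  INF   exact Ct  14.886   GA Ct  14.886   (D at +2.378)
  HMPV  exact Ct  20.259   GA Ct  20.259   (D at +0.887)

harmonized shared levels (C, D, E coded): [ 2.378  0.858 -2.002]
worst-case predicted Ct across targets: 21.902
```

The genetic algorithm reproduces the exact quadratic minima to the printed
precision. Harmonization pins the shared Mg²⁺ near the RSV/HMPV interior
optimum (the worst-off targets) rather than the INF boundary optimum: the
minimax solution protects the weakest assay in the multiplex.

The `qpcropt` command exposes the same stages as subcommands
(`design`, `simulate`, `fit`, `train`, `optimize`, `harmonize`, `compare`,
`run`); see `qpcropt --help`.

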