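"""Design a five-factor CCD, simulate a multiplex Ct table, fit and reduce.

The five reaction factors are primers (A), probes (B), DNA polymerase (C),
Mg2+ (D) and dNTPs (E).  The rotatable design has 50 runs (32 factorial +
10 axial + 8 center) with coded levels spanning ±2.378.
"""

import numpy as np

from qpcropt import anova, default_spec, fit_quadratic, generate_ccd, \
    reduce_model, simulate_response
from qpcropt.synthetic import DEFAULT_FACTORS

design = generate_ccd(DEFAULT_FACTORS, n_center=8, alpha="rotatable")
print(f"design: {design.n_runs} runs, axial distance {design.alpha:.3f}")

# triplicate Ct measurements from the RSV ground-truth surface, sd 0.1 Ct
spec = default_spec("RSV", noise_sd=0.1, seed=1)
responses = simulate_response(design, spec)
y = responses["ct_mean"].to_numpy()

model = fit_quadratic(design, y)
table = anova(model, design, y)
print("\nANOVA pooled rows (SS, df):")
for source in ("Model", "Residual", "Lack of Fit", "Pure Error", "Cor Total"):
    row = table.row(source)
    print(f"  {source:<12} SS={row['SS']:8.3f}  df={row['df']:.0f}")
print(f"adequate precision: {table.adequate_precision:.1f} "
      "(above 4 means the surface can guide optimization)")

reduced = reduce_model(model, table, p_threshold=0.05)
print(f"\nterms kept at p<0.05: {reduced.kept_terms}")
print("reduced-model coefficients (coded units, Ct scale):")
for label, value in reduced.coef_by_label().items():
    if value != 0.0:
        print(f"  {label:>4}: {value:+.3f}")
print(f"predicted Ct at the center point: {reduced.predict(np.zeros(5)):.3f}")
# the D (Mg2+) terms dominate: Mg2+ concentration drives the Ct response
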