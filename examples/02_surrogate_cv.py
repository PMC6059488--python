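"""Select the network surrogate's hidden-layer size by 5-fold CV.

Ct values are scaled onto ±2.378 (the coded range of the design) before
training; fit and prediction errors below are MSEs on that scaled axis.
"""

from qpcropt import cv_select_nodes, default_spec, generate_ccd, \
    simulate_response, train_bpnn
from qpcropt.synthetic import DEFAULT_FACTORS

design = generate_ccd(DEFAULT_FACTORS, n_center=8)
responses = simulate_response(design, default_spec("RSV", noise_sd=0.2, seed=3))
y = responses["ct_mean"].to_numpy()

report = cv_select_nodes(design.coded, y, candidates=[1, 2, 3, 4, 5],
                         k_folds=5, seed=0)
print("hidden-layer size selection (scaled-response MSE, mean ± sd over folds):")
for _, row in report.table.iterrows():
    print(f"  {int(row['n_hidden'])} neurons: "
          f"fit {row['fit_mean']:.4f}±{row['fit_sd']:.4f}  "
          f"prediction {row['pred_mean']:.4f}±{row['pred_sd']:.4f}")
print(f"selected: {report.selected} neurons "
      "(smallest mean held-out prediction error)")

net = train_bpnn(design.coded, y, n_hidden=report.selected, seed=0)
print(f"final net training MSE (scaled): {net.train_mse_scaled:.5f}")
print(f"net prediction at a center point: {net.predict(design.coded[-1]):.3f} Ct")
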