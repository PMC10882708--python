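"""Screen reaction conditions with a 15-run response-surface design.

Generates the default three-factor design (temperature 37-40 degC,
urea 0.4-1.2 M, reaction-enhancing additive 0.1-1 mg/mL; Box-Behnken
layout with 3 center replicates), simulates yield and truncated-mRNA
responses from known quadratic surfaces, prunes non-significant terms
by backward elimination, and finds the joint optimum by maximizing the
composite desirability.
"""

import ivtwin as iv
from ivtwin.synthetic import gen_doe_dataset

design = iv.generate_design(seed=1)
print(f"design: {design.n_runs} runs, "
      f"{int(design.runs['is_center'].sum())} center points")

# synthetic truth: additive drives yield with curvature; truncated mRNA
# rises with temperature and falls toward mid-range urea
yield_truth = {"Intercept": 8.0, "x3": 1.5, "x3^2": -1.0, "x1": 0.5}
trunc_truth = {"Intercept": 60.0, "x1": 5.0, "x3": -4.0, "x3^2": 3.0,
               "x2^2": 4.0}
y_yield, _ = gen_doe_dataset(yield_truth, design, noise_sd=0.05, seed=2)
y_trunc, _ = gen_doe_dataset(trunc_truth, design, noise_sd=0.3, seed=3)

models = {}
for name, y in (("yield_gL", y_yield), ("truncated_pct", y_trunc)):
    reduced = iv.stepwise_reduce(iv.fit_quadratic(design, y, response=name))
    models[name] = reduced
    print(f"\n{name}: adj R^2 = {reduced.adj_R2:.3f}, "
          f"retained terms: {', '.join(reduced.terms)}")
    print(reduced.summary_frame().to_string(float_format=lambda x: f"{x:.3g}"))

opt = iv.desirability_optimize(
    models, {"yield_gL": "maximize", "truncated_pct": "minimize"}, n_grid=41)
print("\njoint optimum (composite desirability "
      f"{opt['desirability']:.3f}):")
for k, v in opt["physical"].items():
    print(f"  {k}: {v:.3g}")
print("predicted there:", {k: round(v, 2) for k, v in opt["predictions"].items()})
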