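"""Diagnostics for the fitted model: correlations, residual normality,
and the network-vs-reference oviposition surface.

Reads the fit artifacts from results/fit_small/, recomputes fitted
half-month series, and writes three tables under results/report/:
correlations.csv (per-city Pearson r), pp_table.csv (standardized-residual
P-P pairs), and surface_comparison.csv (network vs reference expression on
the symbolic-regression training grid).
"""

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import pearsonr

from aedes_ude import oviposition_net as onet
from aedes_ude import symreg as sr
from aedes_ude import training
from aedes_ude.population import ScaleFactors
from aedes_ude.synthetic import load_benchmark
from aedes_ude.vital_rates import VitalParams

ROOT = Path(__file__).resolve().parents[1]
fitdir = ROOT / "results" / "fit_small"
out = ROOT / "results" / "report"
out.mkdir(parents=True, exist_ok=True)

params = VitalParams.from_dict(yaml.safe_load((fitdir / "params.yaml").read_text()))
net = onet.load_net(fitdir / "net.json")
scales_df = pd.read_csv(fitdir / "scales.csv")
scales = ScaleFactors(dict(zip(scales_df.city, scales_df["lambda"])))

_, climate, obs, truth = load_benchmark("small")
data = {s.city_id: (s, obs[s.city_id]) for s in climate}
fitted, problem = training.predict_half_month(data, params, net, scales)

rows = [{"city": c, "pearson_r": training._safe_pearson(fitted[c], problem.obs[i])}
        for i, c in enumerate(problem.cities)]
pd.DataFrame(rows).to_csv(out / "correlations.csv", index=False)
print("per-city fitted-vs-observed Pearson r:")
for r in rows:
    print(f"  {r['city']}: {r['pearson_r']:.4f}")

res = training.FitResult(params=params, net=net, scales=scales,
                         loss_history=np.zeros(1), per_city_r={},
                         fitted=fitted, cities=problem.cities)
pp = training.correlation_diagnostics(res, data)
pp.to_csv(out / "pp_table.csv", index=False)
worst = (pp.assign(gap=np.abs(pp.theoretical_cp - pp.empirical_cp))
         .groupby("city")["gap"].max().max())
print(f"largest P-P deviation from the diagonal: {worst:.3f}")

grid = sr.build_training_grid()
net_surface = onet.forward(net, grid[:, 0], grid[:, 1])
ref_surface = sr.eval_reference(grid[:, 0], grid[:, 1])
pd.DataFrame({"T": grid[:, 0], "R": grid[:, 1],
              "network": net_surface, "reference": ref_surface}
             ).to_csv(out / "surface_comparison.csv", index=False)
r_surf = pearsonr(net_surface, ref_surface)[0]
print(f"network-vs-reference surface Pearson r on the training grid: {r_surf:.4f}")
print(f"tables in {out}")
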