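"""Distill oviposition surfaces into closed-form expressions by GP.

Two demonstrations:
1. Planted recovery — evolve against the surface of a known tree
   (sig(T - 25)) at desk scale (population 500, 20 generations) and report
   the recovered expression and its raw MSE.
2. Network distillation — evolve against the trained oviposition network
   from results/fit_small/net.json on the standard training grid, then
   score the winning expression on the finer validation grid.

Writes expressions and per-generation statistics under results/symreg/.
"""

from pathlib import Path

import pandas as pd

from aedes_ude import oviposition_net as onet
from aedes_ude import symreg as sr

ROOT = Path(__file__).resolve().parents[1]
out = ROOT / "results" / "symreg"
out.mkdir(parents=True, exist_ok=True)

grid = sr.build_training_grid()

# -- planted recovery ------------------------------------------------------
planted = sr.ExprTree(["sig", "sub", 0, 25.0])
targets = planted.evaluate(grid[:, 0], grid[:, 1])
cfg = sr.GPConfig(population_size=500, generations=20, stopping_criteria=1e-6,
                  seed=11)
best, stats = sr.evolve(grid, targets, cfg)
print("planted recovery (truth: sig(T - 25)):")
print(f"  best expression: {best.to_infix()}")
print(f"  raw MSE {stats[-1]['best_raw_mse']:.3g} after {len(stats)} generations")
pd.DataFrame(stats).to_csv(out / "planted_generations.csv", index=False)
(out / "planted_expression.txt").write_text(best.to_sexpr() + "\n")

# -- distillation of the trained network -----------------------------------
net_path = ROOT / "results" / "fit_small" / "net.json"
if net_path.exists():
    net = onet.load_net(net_path)
    net_targets = onet.forward(net, grid[:, 0], grid[:, 1])
    cfg2 = sr.GPConfig(population_size=1000, generations=25, brood_size=16,
                       stopping_criteria=1e-4, seed=11)
    tree, stats2 = sr.evolve(grid, net_targets, cfg2)
    val = sr.validate_against_network(tree, net)
    print("trained-network distillation:")
    print(f"  best expression: {tree.to_infix()}")
    print(f"  training-grid MSE {stats2[-1]['best_raw_mse']:.4g}; "
          f"validation-grid MSE {val:.4g}")
    pd.DataFrame(stats2).to_csv(out / "network_generations.csv", index=False)
    (out / "network_expression.txt").write_text(
        tree.to_sexpr() + "\n" + tree.to_infix() + "\n")
else:
    print(f"{net_path} not found - run analysis/02_fit_model.py first")
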