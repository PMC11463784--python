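"""Generate the packaged synthetic benchmarks with known ground truth.

Writes the `small` benchmark (3 cities x 2 evaluation years plus a burn-in
year; planted oviposition = the closed-form reference expression) under
results/benchmark_small/: one climate CSV per city, the half-month abundance
index CSV, the hidden truth record and a manifest with the generator seed.
"""

from pathlib import Path

from aedes_ude.synthetic import make_benchmark

ROOT = Path(__file__).resolve().parents[1]

out = make_benchmark("small", ROOT / "results" / "benchmark_small")
files = sorted(p.name for p in out.iterdir())
print(f"benchmark 'small' written to {out}")
for f in files:
    print("  ", f)
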