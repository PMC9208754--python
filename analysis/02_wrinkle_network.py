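"""Wrinkle-network quantification of a synthetic timelapse, validated on truth.

Generates one default wrinkling timelapse (6.5 h nucleation stage, 3.5 h
connection stage, 5-min frames), runs the full binarize/clean/thin/label
pipeline, segments the growth stages, and compares N(t) and L(t) against the
generator's ground truth. Writes results/wrinkle_metrics.csv.
"""

from pathlib import Path

import numpy as np

from wrinklekit.synthetic import generate_wrinkle_timelapse
from wrinklekit.wrinkle_network import WrinkleMetrics, segment_stages, wrinkle_metrics

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

stack, truth = generate_wrinkle_timelapse(seed=0)
metrics = wrinkle_metrics(stack)
seg = segment_stages(metrics)

table = metrics.table.copy()
table["stage"] = seg.labels
table["N_true"] = truth.table["N"]
table["L_true_mm"] = truth.table["L_mm"]
table.to_csv(OUT / "wrinkle_metrics.csv", index=False)

n_exact = (table["N"] == table["N_true"]).mean()
with np.errstate(divide="ignore", invalid="ignore"):
    lerr = np.where(table["L_true_mm"] > 0,
                    np.abs(table["L_mm"] - table["L_true_mm"]) / table["L_true_mm"], 0.0)

print(f"frames: {len(table)}, peak wrinkle count N = {table['N'].max()}")
print(f"final longest connected wrinkle L = {table['L_mm'].iloc[-1]:.2f} mm")
print(f"N matches truth exactly on {n_exact:.1%} of frames; median L error {np.median(lerr):.1%}")
truth_table = truth.table.rename(columns={"N": "N", "L_mm": "L_mm"})
seg_truth = segment_stages(WrinkleMetrics(table=truth_table, length_unit="mm"))
print(f"observable stage boundaries (frames): N-peak at {seg.stage2_start} "
      f"(truth curves: {seg_truth.stage2_start}), L-plateau at {seg.stage3_start} "
      f"(truth curves: {seg_truth.stage3_start})")
print(f"process switches (nucleation stop, growth freeze): {truth.stage2_start}, {truth.stage3_start};")
print("merging competes with nucleation, so the observable N-peak precedes the nucleation cut-off.")
print("The pipeline reproduces the three-stage phenomenology: N rises while L stays small,")
print("then merging collapses N while L grows to span the field, then both plateau.")
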