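"""Enrichment-score trajectories over a differentiation time course.

Plants the study-like kinetics — proliferation up and adhesion down at
24 h (progenitor activation), an OxPhos program up from day 4 (metabolic
maturation) — and runs GSEA at every timepoint. Closed markers in the
printed table correspond to FDR q < 0.05.
"""

from britepipe import es_trajectory, split_by_timepoint
from britepipe.scenarios import TRAJECTORY_SCHEDULE, expression_pipeline, trajectory_config

cfg = trajectory_config(seed=0)
matrix, meta, collection, truth = expression_pipeline(cfg)
matrices = split_by_timepoint(matrix, meta)
tracked = ["SET_PROLIFERATION", "SET_ADHESION", "SET_OXPHOS"]
traj = es_trajectory(matrices, meta, collection, tracked, "cPGI2", "Control", seed=0)

timepoints = list(cfg.timepoints)
print(f"{'set':20s} " + " ".join(f"{tp:>9s}" for tp in timepoints))
for name in tracked:
    cells = []
    for tp in timepoints:
        row = traj[(traj["set"] == name) & (traj["timepoint"] == tp)].iloc[0]
        marker = "*" if row["significant"] else " "
        cells.append(f"{row['es']:+.2f}{marker:1s}".rjust(9))
    print(f"{name:20s} " + " ".join(cells))
print("\n(* = FDR q < 0.05)")
print("planted schedule:", {f"{k[0]}@{k[1]}": ("up" if v > 0 else "down")
                            for k, v in TRAJECTORY_SCHEDULE.items()})
print("-> activation signals peak at 24 h and vanish, while the metabolic")
print("   program switches on only at the late timepoints: activation precedes maturation.")
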