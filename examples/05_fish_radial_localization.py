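"""3D DNA-FISH radial localization: segmentation to chi-square.

Renders synthetic nuclei for two conditions with different shell
placement of a diploid locus (treated nuclei more central, like an
activated gene moving inward), runs the full imaging pipeline and
compares the radial distributions.
"""

import numpy as np

from britepipe import (
    SimConfig,
    compare_radial,
    detect_spots,
    equal_area_shells,
    gen_nucleus_images,
    radial_distribution,
    segment_nuclei,
)

cfg = SimConfig(
    n_nuclei=30,  # per condition; the emulated experiments image 30-50
    fish_shell_probs={
        "Control": (0.15, 0.35, 0.50),   # peripheral-dominant
        "cPGI2": (0.433, 0.35, 0.217),   # central-shifted
    },
    seed=0,
)
stacks, truth = gen_nucleus_images(cfg)
print(f"rendered {len(stacks)} one-nucleus fields "
      f"({cfg.image.xy_nm:.0f} nm xy, {cfg.image.z_step_nm:.0f} nm z-step)")

dists = {}
nid = 0
per_condition = {}
for stack, nucleus in zip(stacks, truth.nuclei):
    entry = per_condition.setdefault(nucleus.condition, {"spots": [], "maps": {}, "n": 0})
    for mask in segment_nuclei(stack):
        nid += 1
        mask.nucleus_id = nid
        entry["maps"][nid] = equal_area_shells(mask)
        entry["n"] += 1
        entry["spots"] += detect_spots(stack, mask, "probe1")

for cond, entry in per_condition.items():
    dist = radial_distribution(entry["spots"], entry["maps"], cond, n_nuclei=entry["n"])
    dists[cond] = dist
    pct = dist.format_percent()
    print(f"{cond:8s}: central {pct[0]}, intermediate {pct[1]}, peripheral {pct[2]} "
          f"({dist.n_loci} loci in {dist.n_nuclei} nuclei)")

res = compare_radial(dists["Control"], dists["cPGI2"])
print(f"\nchi-square = {res.statistic:.2f}, df = {res.df}, p = {res.p_value:.2e}")
print("significant at p <= 0.05:", res.significant)
print("-> the locus occupies more central shells under treatment than in control,")
print("   consistent with relocalization of an activated gene away from the periphery.")
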