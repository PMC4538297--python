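"""Relative qPCR quantification with the delta-delta-Ct method.

A planted 16-fold induction of a thermogenic marker is encoded in the
synthetic Ct values and recovered against the Tbp reference gene with
the control group as calibrator.
"""

from britepipe import SimConfig, ddct_relative_expression, gen_qpcr_plate

cfg = SimConfig(qpcr_targets={"Ucp1": 16.0, "Cidea": 4.0}, qpcr_ct_sd=0.1, seed=0)
plate, truth = gen_qpcr_plate(cfg)
print("Ct table head:")
print(plate.head(6).round(2).to_string(index=False))

calibrators = list(plate.loc[plate["group"] == "Control", "sample_id"].unique())
for gene in ("Ucp1", "Cidea"):
    res = ddct_relative_expression(plate, gene, "Tbp", calibrators)
    print(f"\n{gene} fold changes (reference Tbp, calibrator Control):")
    for group in cfg.groups:
        samples = plate.loc[plate["group"] == group, "sample_id"].unique()
        mean_fold = res.loc[[s for s in samples if s in res.index], "fold"].mean()
        print(f"  {group:8s} mean fold = {mean_fold:6.2f}  (planted {truth[gene].get(group, 1.0):.1f})")
print("\n-> fold = 2^(-ddCt); with Ct noise of 0.1 cycles and n = 3 the planted")
print("   inductions are recovered within a few percent.")
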