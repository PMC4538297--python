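"""Gene-set enrichment with exhaustive phenotype permutation at n = 3 + 3.

Plants one coordinated +1 SD gene set, runs the full engine
(Signal2Noise ranking, weighted ES, meandiv NES, permutation FDR) and
shows that the planted set tops the report.
"""

from britepipe import run_gsea
from britepipe.scenarios import expression_pipeline, gsea_planted_config

matrix, meta, collection, truth = expression_pipeline(gsea_planted_config(seed=0))
report = run_gsea(matrix, meta, collection, "cPGI2", "Control", seed=0)

print(report.warning)  # the 3v3 design admits only 20 distinct label assignments
print(f"\n{'gene set':24s} {'size':>4s} {'ES':>6s} {'NES':>6s} {'FDR q':>7s}")
for r in report.records[:6]:
    print(f"{r.name:24s} {r.size:4d} {r.es:6.2f} {r.nes:6.2f} {r.fdr_q:7.4f}")
print("...")
print(f"\nplanted set: SET_UP (100 genes shifted +1 within-group SD in cPGI2)")
top = report.records[0]
print(f"top-ranked set: {top.name}, ES = {top.es:.2f}, FDR q = {top.fdr_q:.4f}")
print("-> the coordinated shift dominates the ranking even though each gene's")
print("   individual shift (0.25 log2 units) is within the noise level.")
le = report.profiles["SET_UP"].leading_edge
print(f"leading edge: {len(le)} genes drive the enrichment, e.g. {list(le[:5])}")
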