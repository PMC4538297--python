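# britepipe

Analysis pipeline for studies of **beige/brite adipocyte differentiation** —
experiments in which white-fat progenitor cells are driven toward a
thermogenic, brown-fat-like phenotype (e.g. by a prostacyclin analog such as
cPGI2) and characterized by bead-array expression profiling, gene-set
enrichment, qPCR, and 3D DNA-FISH of gene-locus position in the nucleus.

The package implements the complete computational chain of such a study,
plus a synthetic-data module that generates every input with known ground
truth so each stage can be validated end to end:

- **Bead-array preprocessing** — bead-level summarization (select beads with
  intensity > 20, remove outliers deviating more than 2.5 raw MAD from the
  median, average the survivors), quantile normalization, log2 transform.
- **Differential expression** — a moderated two-sample t-test with an
  empirical-Bayes variance prior: the posterior variance
  `s̃² = (d₀·s₀² + d·s²) / (d₀ + d)` shrinks each probe's pooled variance
  toward a prior `(d₀, s₀²)` moment-matched on the log variances; the
  statistic is referred to *t* on `d₀ + d` degrees of freedom, with Holm
  step-down adjustment. With `d₀ = 0` it reduces exactly to the classical
  pooled t. A concordance analysis intersects the significant genes of two
  comparisons and reports paired log2 ratios and sign agreement.
- **PCA** — sample-space principal components of median-centered log2
  profiles, with variance-explained fractions.
- **GSEA** — a from-scratch enrichment engine with the canonical
  parameterization: Signal2Noise ranking
  `s2n = (μ_A − μ_B) / (σ_A + σ_B)` with σ floored at `max(0.2·|μ|, 0.2)`;
  weighted running-sum enrichment score (hits weighted by `|s2n|^w`, misses
  by `1/(N − N_h)`, ES = signed maximum deviation); phenotype permutation
  (all distinct label assignments enumerated when fewer exist than requested
  permutations — 20 for a 3 vs 3 design); meandiv normalization
  `NES = ES / mean(same-sign null ES)`; permutation FDR q; per-timepoint ES
  trajectories for time-course designs.
- **qPCR** — ΔΔCt relative quantification: `fold = 2^(−ΔΔCt)` against a
  reference gene (Tbp by default) and calibrator group.
- **3D DNA-FISH radial localization** — DAPI-based nucleus segmentation
  (Otsu + distance-transform watershed), partition of each nucleus footprint
  into **three concentric shells of equal area** eroded from the center
  (shell 1) to the periphery (shell 3) via distance-transform thresholding,
  detection of ≤ 2 allele spots per probe per diploid nucleus
  (Laplacian-of-Gaussian, intensity-ranked, sub-voxel centroids), per-shell
  locus counts, and a chi-square contingency test of the null hypothesis
  that two conditions share one radial distribution (reject at p ≤ 0.05).

## Worked example

`examples/` holds one short script per capability. For instance, planting a
coordinated +1 SD gene set in a 3 vs 3 bead-array experiment and running the
enrichment engine (`python examples/03_gsea_planted_set.py`):

```
only 20 distinct label assignments exist for 3 vs 3; enumerating all of them
instead of 1000 random permutations

gene set                 size     ES    NES   FDR q
SET_UP                     99   0.66   1.75  0.0000
SET_RANDOM_012            120   0.26   1.28  0.1408
SET_RANDOM_000             81  -0.33  -1.37  0.1469
...
```

The planted set (`SET_UP`) tops the report with ES 0.66 and FDR q ≈ 0 — the
coordinated shift is detected although each individual gene moves by only
one within-group standard deviation. And the imaging side
(`python examples/05_fish_radial_localization.py`):

```
Control : central 12.7%, intermediate 32.7%, peripheral 54.5% (55 loci in 30 nuclei)
cPGI2   : central 39.7%, intermediate 29.3%, peripheral 31.0% (58 loci in 30 nuclei)
chi-square = 11.49, df = 2, p = 3.20e-03
```

Treated nuclei show the planted central shift of the locus, and the
chi-square test rejects the shared-distribution null — the imaging pipeline
recovers the radial relocalization from raw voxels.

## Command line

A thin CLI chains the stages into reproducible runs (every output directory
carries the config hash and seed; identical seeds regenerate bit-identical
reports):

```bash
britepipe simulate   --config cfg.yaml --outdir data/          # synthetic study + manifest
britepipe expression --beads data/beads.tsv --metadata data/metadata.tsv \
                     --gmt data/sets.gmt --outdir reports/     # summarize -> DE -> PCA -> GSEA
britepipe fish       --images data/images --outdir reports/    # segment -> shells -> chi-square
britepipe qpcr       --table data/qpcr.csv --target Ucp1 --out folds.csv
```

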