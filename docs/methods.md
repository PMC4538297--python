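# Methods

This note documents the models and procedures implemented in `britepipe`,
the assumptions behind them, the tunable parameters with their defaults,
what the synthetic-data generators do and do not emulate, and the numerical
conventions adopted where the underlying methods leave choices open.

## Bead-array preprocessing

Bead-level intensities are summarized per (probe, sample): beads with
intensity strictly greater than the floor (default **20**, linear scale) are
selected; survivors whose absolute deviation from the median exceeds
**2.5 × MAD** are removed, where the MAD is the *raw* median absolute
deviation with no 1.4826 consistency factor (the rule is stated in MAD
units, so the unscaled statistic is the literal reading; the factor is a
config knob, `mad_k`); the probe signal is the mean of the remainder. The
filter is single-pass. A cell where no bead clears the floor is missing
(NaN), never zero.

Quantile normalization forces every sample column onto the common
distribution (row means of the per-column sorted values). Ties within a
column receive the mean of the reference values at their tied ranks, which
makes the transform deterministic and idempotent. Missing cells are imputed
with the column median for the rank computation and re-masked afterwards,
so they never propagate into statistics. Normalization operates on the
linear scale with log2 applied afterwards (order configurable); intensities
≤ 0 are clamped to 1.0 before log2 while missing cells stay missing.

Caveat worth knowing: quantile normalization slightly compresses genuine
coordinated shifts when a substantial fraction of probes moves in one group
(it equalizes the column distributions by construction). The parameter
recovery benchmark therefore measures fold-change recovery on the
summarized matrix, and probes whose intensities sit near the bead floor in
one arm show survivor-biased (compressed) fold changes — a property of the
floor filter, not of the test statistic.

## Moderated differential expression

The two-group test assumes approximately normal log2 intensities with
probe-specific variances drawn from a scaled-inverse-chi-square population.
Per probe, the pooled variance `s²` on `d = n_A + n_B − 2` degrees of
freedom is shrunk toward a prior:

    s̃² = (d₀·s₀² + d·s²) / (d₀ + d)

`(d₀, s₀²)` are estimated by moment matching on `z = log s²`: with
`e = z − ψ(d/2) + log(d/2)`, the excess variance `Var(e) − ψ′(d/2)` equals
`ψ′(d₀/2)`, solved by Newton inversion of the trigamma function, and
`s₀² = exp(mean(e) + ψ(d₀/2) − log(d₀/2))`. Non-positive excess variance
gives `d₀ = ∞` (fully pooled variance). The moderated statistic
`t̃ = Δmean / (s̃·√(1/n_A + 1/n_B))` is referred to *t* on `d₀ + d` degrees
of freedom (normal when `d₀ = ∞`); `prior_df` can be forced, and `d₀ = 0`
reproduces the classical pooled t exactly (machine precision, verified in
tests). No intensity-dependent variance trend is modeled. Probes with fewer
than two observations in a group, or missing in more than half of either
group's samples (configurable), are excluded from testing and from the Holm
adjustment count.

Holm's step-down adjustment multiplies the *i*-th smallest p-value by
`m − i + 1`, enforces monotonicity by a cumulative maximum over the sorted
order, and caps at 1. Significance selection uses strict `p < α`.

The concordance analysis intersects the probes significant (raw p by
default; the adjusted-p variant is a flag) in two comparisons sharing a
probe universe, and reports the paired log2 ratios, the count significant
in the first comparison alone, and the fraction of selected probes whose
fold changes agree in sign.

ΔΔCt quantification: `ΔCt = Ct_target − Ct_reference` per sample,
`ΔΔCt = ΔCt − mean(ΔCt over calibrator samples)` (the mean-calibrator
convention, deterministic), `fold = 2^(−ΔΔCt)`.

## PCA

Samples are the observations, probes the variables. Rows are median-centered
(each probe's median subtracted); inside the decomposition each probe is
additionally mean-centered so probe-constant offsets cannot influence the
result. Scores come from the SVD of the centered sample × probe matrix;
variance fraction *i* is `λᵢ/Σλ` over all components. Component signs are
fixed by making the largest-magnitude probe loading positive, so outputs are
platform-deterministic. Rows are not scaled to unit variance. Requesting
more components than the numerical rank is an error.

## GSEA engine

**Ranking.** Signal2Noise per gene, `(μ_A − μ_B)/(σ_A + σ_B)`, with each
group's σ floored at `max(0.2·|μ|, 0.2)` — the metric's standard guard,
configurable. Sorting is descending with gene-id tie-break (deterministic).

**Enrichment score.** Walking the ranked list, hits add
`|metric|^w / Σ_set |metric|^w` (weight `w = 1` for the "weighted"
statistic; `w = 0` gives the unweighted KS-type statistic) and misses
subtract `1/(N − N_h)`. The ES is the running-sum value of maximal absolute
deviation; on an exact positive/negative magnitude tie the positive
excursion is taken. The leading edge is the set members at or before the
extremum (positive ES) or at or after it (negative ES). If every in-set
metric is exactly zero under `w = 1`, the hit weights fall back to uniform.

**Phenotype permutation.** Group labels are permuted and the ranking and all
ES recomputed. When the number of distinct label assignments is at most the
requested `n_perm` (e.g. `C(6,3) = 20` for 3 vs 3), **all** distinct
assignments are enumerated exactly once and a warning is recorded;
otherwise `n_perm` assignments are sampled with the run's seed. Gene-set
permutation is available as an explicit alternative mode and is never
substituted silently. Sets are size-filtered to `[15, 500]` members present
in the ranked list by default (configurable); skipped sets are logged with
reasons.

**Normalization and FDR.** NES divides the ES by the mean magnitude of the
same-sign null ES of that set (meandiv); the nominal p is the same-sign
null tail fraction; the FDR q compares the tail fraction of the pooled
normalized null NES with the tail fraction of the observed NES
distribution, clipped to [0, 1].

Small-sample convention (exhaustive enumeration): the enumerated
assignments include the observed labeling itself, whose ES trivially equals
the observed ES. Keeping that column in the null floors the attainable FDR
at roughly `1/n_assignments` (~0.05 at 3 vs 3), which would make the engine
unable to report the near-zero q-values that strongly enriched sets warrant
at this design size. The engine therefore excludes the observed-labeling
column from the null used for NES, nominal p and FDR, and — because only
~19 columns remain — normalizes **leave-one-out**: the observed ES is
divided by the same-sign means of the 19 non-observed columns, and each
null column by the means of the other columns. This keeps observed and null
NES exchangeable under the null (in-sample means systematically shrink the
null extremes and inflate the false-positive rate, which we verified by
simulation), at the cost that a q of exactly 0 is attainable — the standard
behavior of permutation FDR in this regime. With many sampled permutations
the plain pooled means are used, where the in-sample bias is negligible.
Reports are sorted by q, then |NES| descending, then name.

At a 3 vs 3 design the familywise false-positive probability of *any* set
reaching q < 0.05 on null data has an irreducible floor of about 10% (the
observed column "wins" one of the two signed tails among 20 exchangeable
columns with probability ≈ 2/20); the measured clean-run rate of the engine
is ≈ 0.91, at that theoretical ceiling. Likewise, when an up- and a
down-regulated set are planted at the same timepoint they contaminate each
other's permutation nulls, and a single pooled null value above a planted
set's NES puts its q near 0.055; trajectory benchmarks therefore expect
significance at most but not necessarily all planted cells.

**Trajectories.** For time-course designs the engine runs one GSEA per
timepoint (same collection, same parameters) and tabulates (set, timepoint,
ES, NES, q, significance at q < 0.05), skipping timepoints that lack a
group.

## FISH radial localization

**Segmentation.** The DAPI channel is max-projected over z, Gaussian
smoothed (σ = 2 px), thresholded by Otsu with a robust contrast guard
(threshold must exceed the median by 3 robust SDs, so featureless frames
yield zero nuclei), hole-filled, and split by distance-transform watershed.
Masks touching the border or below 200 px² are discarded (both
configurable).

**Equal-area shells.** Footprint pixels are ranked by Euclidean distance
from the boundary (deepest first; flat pixel index as deterministic
tie-break) and split into three consecutive groups whose sizes differ by at
most one pixel: shell 1 is the deepest (central) band, shell 3 the
peripheral band. This distance-transform thresholding realizes "erosion
from the periphery" with exact area control and, on a disc of radius *r*,
reproduces the analytic equal-area boundaries `r·√(1/3)` and `r·√(2/3)`
within a pixel (verified against that oracle). Masks too small to satisfy
the 2% area tolerance (< ~150 px) are rejected with an error naming the
mask. Shells are computed on the 2D z-projection — the quantity of interest
is *area*, not volume — and spots are assigned by their (x, y) centroid
regardless of z; an equal-volume 3D mode is out of scope.

**Spot detection.** Within a nucleus footprint's 3D extent, a
Laplacian-of-Gaussian filter (lateral σ = 1.2 px, axial σ scaled by the
voxel anisotropy xy_nm/z_nm) proposes local maxima above an absolute
intensity floor (channel median + 5 robust SDs by default); candidates are
ranked by integrated background-subtracted intensity, duplicates within one
blob radius suppressed, and the top 2 per nucleus retained (diploid locus —
two alleles). Centroids are refined by intensity-weighted averaging in a
symmetric window, which is exact for symmetric spots on noiseless data.

**Statistics.** Shell counts per condition form a 2 × 3 contingency table;
the chi-square test (no continuity correction, df = 2, expected counts from
pooled margins) evaluates the null hypothesis that both conditions share
one radial distribution, with a warning flag when any expected count drops
below 5 and significance declared at p ≤ 0.05. Replicate experiments are
pooled into one table per comparison; nuclei with no detected spots
contribute no counts but are tallied in the nucleus count.

## Synthetic data generators

The generators emulate the design of a beige/brite differentiation study:
groups Control ("white"), cPGI2-treated, and a BAT reference; 3 biological
replicates; a 0 h–8 d time course; an NE-status metadata column. Baseline
probe intensities are log-normal (log2 mean 8, SD 1.5), matching bead-array
dynamic range so quantile normalization behaves realistically. Planted
signals shift disjoint probe blocks by `effect_size` log2 units in chosen
(group, timepoint) cells; the default schedule mirrors the studied
kinetics (proliferation up and adhesion down at 24 h, an OxPhos program up
from day 4 shared with BAT). Beads scatter multiplicatively (CV 0.08, 20
beads/probe) around each sample's value, which carries within-group log2
noise of SD 0.25; outlier beads (rate 0.01) are 10×/0.1× spikes so the
2.5-MAD rule removes them deterministically. Gene sets are emitted as GMT:
one set per planted signal (drawn from its probes) plus uniform random
sets, sizes within a configurable range (default 15–160).

FISH fields hold ellipsoidal nuclei (semi-axes 18 × 13 px at 100 nm/px,
5 slices at 200 nm z-step — deliberately anisotropic voxels) with
DAPI-bright chromocenter blobs rendered only in the DAPI channel (realistic
distractors that must not trigger spot detection). Each probe channel gets
two allele spots per nucleus placed by sampling a shell from the
condition's placement probabilities and then a uniform pixel within that
shell's region of the *true* footprint, using the same equal-area
construction the analysis applies — the erosion-based definition is
the only well-defined notion of a spot's true shell, and it makes the
configured probabilities exactly the expected shell fractions (the
construction itself is validated against the independent analytic disc
oracle). Spot centers sit on integer voxels so noiseless detection is
exact. A Gaussian PSF blur (σ = 1 px laterally, scaled axially) and
Poisson + Gaussian read noise are applied unless disabled. Default shell
probabilities: Control (0.15, 0.35, 0.50), treated (0.433, 0.35, 0.217) —
a peripheral-dominant locus relocating centrally under treatment; 40
nuclei per condition (within the 30–50 range such experiments image).

qPCR plates encode a planted fold F as a target-gene Ct shift of
−log2 F relative to the calibrator group (reference gene Tbp at Ct 18,
targets at Ct 24+, noise SD 0.1 cycles).

What the generators do **not** emulate: scanner optics and spatial array
artifacts, batch effects, probe-annotation remapping, realistic pathway
topology or inter-gene correlation within sets, chromatic shift, nuclear
texture beyond chromocenters, and z-dependent optical aberrations. Passing
benchmarks therefore demonstrate the correctness and calibration of the
*algorithms* under the stated noise model, not robustness to every artifact
of real arrays or microscopes.

## Benchmark problem sizes

The calibration/recovery benchmarks (tests and `scripts/acceptance.py`) use:
200 random ellipse masks (axis ratio 1–3, random rotation) for the
equal-area property; 10,000 uniform draws for shell calibration; 1,000
replicates of 50 nuclei × 2 loci per condition for the chi-square type-I
rate and 500 for power (counts drawn directly from the placement model —
the statistical property under test — with the image pipeline exercised
end-to-end separately); 1,000 random (list, set) instances at N = 100 for
the ES oracle; bead experiments of 1,000 probes with 15 gene sets of
80–160 genes and a planted set of 100 genes shifted +1 within-group SD at
3 vs 3 for enrichment recovery (the size range of strongly enriched
metabolic pathways; much smaller sets at n = 3 have enrichment-score noise
that makes single-run top-rank recovery unreliable for any implementation);
20 seeds for the null false-positive rate; and a 150-probe, 3-nuclei
configuration for the bit-reproducibility check of the full CLI pipeline.

## Known limitations

- Phenotype permutation at n = 3 + 3 has only 19 informative label
  assignments; FDR estimates are correspondingly coarse and the ~10%
  familywise null floor described above is intrinsic to the design size,
  not to this implementation. Gene-set permutation is offered for designs
  where that is unacceptable.
- The moderated test assumes a common variance population without an
  intensity trend; bead-floor censoring near 20 induces mild heterogeneity
  that makes the test slightly conservative (null rejection ≈ 0.04 at
  α = 0.05 in the benchmark conditions).
- Shell assignment uses the 2D projected footprint; strongly non-convex or
  overlapping nuclei are outside the segmentation model.
- The CLI parses the condition label from the image filename pattern
  `field_<condition>_<index>.tif` written by `simulate`; external data
  must follow that convention or use the library API directly.
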