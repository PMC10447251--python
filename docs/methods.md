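# Methods

`msgp` implements a multimodal mass-spectrometry metabolic-profiling
workflow for stratifying tissues by underlying biology without ion
identification: profile-spectrum preprocessing, unsupervised segmentation of
REIMS cohorts and MSI datacubes, differential-ion (volcano) analysis with
FDR control, compound-database annotation with pathway frequency ranking,
and a replicate-aware SVM classifier evaluated by leave-one-patient-out
cross-validation. This note documents the models, the tunable parameters,
the numerical choices, and what the synthetic-data generators do and do not
emulate.

## Preprocessing

Profile spectra are interpolation-rebinned onto a shared uniform m/z axis
(`build_axis`, default bin width 0.001 Da; length is
`floor((hi-lo)/bin_width)+1` and the spacing is exact to float precision).
Interpolation is linear; points outside the source range are set to 0
rather than extrapolated, because absent MS signal is zero and intensities
are non-negative. Whether the original "interpolation rebinning" was linear
or spline is not determinable; linear is the default and the only
implemented variant.

Mass-window restriction (`SpectrumCohort.restrict`) slices the common axis
before any analysis; typical windows are m/z 600–1500 for lipid-dominated
REIMS cohorts, 50–1200 for clinical REIMS, 700–1200 or 50–250 for MSI.

Row normalization: cohort spectra are l2-normalized (unit Euclidean norm;
idempotent; all-zero rows raise an error naming the sample). MSI pixel
spectra entering the differential test are RMS-normalized (divide by the
root-mean-square intensity). Both remove per-acquisition intensity scale
while preserving spectral shape.

## Peak picking and feature reduction

The cohort (or cube) mean spectrum is peak-picked by a gradient method:
first-difference sign changes from + to − mark local maxima; plateau maxima
report the plateau's centre bin, rounding down on even plateaus (a
deterministic tie-break). An intensity floor (default 0) filters noise
maxima. The top-N peaks by intensity (2000 for REIMS cohorts, 4000 for MSI)
define the feature space; intensity ties break toward lower m/z. Each raw
spectrum/pixel is reduced to peak features by summing bins within ±tol of
each peak m/z, with tol defaulting to half the median inter-peak gap capped
at 0.05 Da; bins claimed by overlapping windows go to the nearest peak
(logged). Peak selection happens after mass-window restriction.

## Segmentation

*Burn (active-acquisition) detection.* REIMS acquisitions alternate
forceps-on (tissue aerosol) and forceps-off (solvent/background) segments.
The cohort is clustered by cosine k-means with k=2 and the cluster with the
higher mean total ion current is kept as active. Cosine k-means is reduced
to Euclidean k-means on unit-normalized rows throughout.

*t-SNE.* Three named presets map the workflow's settings: `cohort`
(cosine metric, perplexity 30, exaggeration 4, auto learning rate, random
init — portable stand-ins for the source tool's defaults), `msi`
(correlation metric, otherwise as cohort), `clinical` (Euclidean,
perplexity 5, learning rate 50, PCA init — the published clinical
hyperparameters). Exaggeration 4 rather than the larger default of some
implementations matters for downstream clustering: strong exaggeration
fragments clusters and strands single spectra, which a k-means pass on
the embedding then mistakes for structure. The exact-gradient
implementation is used so embeddings are deterministic given the seed.
t-SNE implementations differ in exaggeration schedules and tree
approximations, so only topological properties (class separation, cluster
recovery) are asserted, never coordinates.

*k-means.* `kmeans_cluster` returns the best-of-N-replicates labelling and
its within-cluster sum of squares. On tiny instances (k^(n−1) ≤ 40000
partitions) it enumerates all partitions and returns the exact optimum:
Lloyd's fixed points are centroidal-Voronoi partitions, but the true
optimum need not be one (the exact gain of moving a point between clusters
carries size factors n/(n±1) that Lloyd ignores), so no number of restarts
guarantees it. Mid-size instances get Lloyd + a Hartigan-style greedy
single-point polish using that exact gain; very large instances (pixel
cubes) use plain Lloyd restarts. Cohort clustering follows the published
procedure: k-means (Euclidean, 10 replicates, k = number of genotypes) runs
on the 3-D t-SNE embedding, not on the feature matrix.

*Elbow method.* k is chosen to maximize the second difference (discrete
curvature) of the WCSS curve over a candidate range; only interior
candidates are eligible and ties break toward smaller k. A non-monotone
curve (failed fits) triggers one recompute with 4× replicates.

*MSI cubes.* Pixels are segmented by cosine k-means (k=4 by default).
Background is identified either by a user-supplied mask (manual mode,
taking precedence, mirroring labelling against optical images) or
automatically as the cluster with lowest mean total intensity.
"Background-subtract then recluster" is a second k-means pass (k=3 by
default) on tissue pixels only; background pixels carry the sentinel −1.

## Differential analysis

`pairwise_volcano` compares two groups of rows per feature: log2 fold
change of group means on normalized intensities, two-sided two-sample
t-test (pooled-variance Student by default, matching the cited analysis
environment; Welch by flag), Benjamini–Hochberg adjustment across all
*testable* features, and a pass flag requiring |FC| > 1.5, p < 0.05 and
q ≤ 0.05 (cohort preset) or q ≤ 0.1 (MSI preset) simultaneously. MSI mode
first RMS-normalizes pixels and removes zeros per feature (each feature's
test keeps only its nonzero pixels — the minimal reading that keeps sample
sizes maximal). Features with fewer than two usable values in a group, or
zero variance in both groups, are flagged untestable, excluded from the BH
family, and reported with q = NaN. BH adjustment is the step-up rule
q(i) = min over j≥i of p(j)·m/j capped at 1 (delegated to statsmodels and
cross-checked against a brute-force implementation in the tests).

Tests default to the spectrum level; whether technical replicates or
biological samples are the unit of replication is analytically
consequential and left to the caller (replicates can be collapsed upstream).

A compositional caveat: because normalization divides by a whole-spectrum
norm, ions with real effects shift the normalized values of null ions in
the opposite direction. The synthetic MSI design keeps planted-marker
energy a small share of the spectrum (5 marker ions of 150 at 5×) so this
induced shift (~0.4 in log2) stays below the log2(1.5) ≈ 0.585 fold-change
threshold; with many strong markers the filter would flag null ions, as it
would on real data.

## Annotation and pathway ranking

Query m/z values are matched to a local compound table under an inclusive
ppm tolerance, |obs − theo|/theo × 1e6 ≤ tol, default 5 ppm (the
instrument-accuracy figure of the underlying acquisition). Default
negative-mode adducts are deprotonated [M−H]⁻ and chloride [M+Cl]⁻;
ambiguous assignments are all reported, never auto-resolved. Lipid names
are curated to sum compositions — side-chain carbons and double bonds are
summed and double-bond position annotations dropped, e.g.
PC(22:1(13Z)/20:0) → PC(42:1); the transform is idempotent and non-lipid
text passes through. Pathways are ranked by the number of *unique* query
m/z with at least one member compound, after curating pathway names and
merging same-subclass pathways that collapse to the same curated name;
ties sort alphabetically.

## Classification

Leave-one-patient-out folds hold out all technical replicates of one
patient together; fold algebra (no patient on both sides, test sets
partition the cohort) is asserted on every run. The classifier is a
linear-kernel SVM with C = 1 and inverse-class-frequency weights (robust to
the 16/8 imbalance); a test point exactly on the boundary goes to the
lower label id.

Feature refinement is backward elimination: technical replicates are first
averaged to one row per patient (replicate noise cancels and no patient is
over-weighted), then a linear SVM is fitted over 5 inner stratified CV
folds and the 20% of surviving features with smallest mean |weight| are
dropped, repeating until one feature remains. The full elimination order
is computed once and sliced at the target size (50 by default), which
makes selections nested across target sizes. If a batch covariate is
supplied, features whose one-way F statistic against batch exceeds their F
against the label are eliminated first (the "spurious background factor"
filter). Refinement runs inside each training fold by default — never on
the held-out patient — with a `refine_once` flag reproducing the
optimistic refine-before-CV variant; neither mode is claimed to reproduce
any particular published figure.

Patient calls aggregate replicate predictions by majority vote, ties going
to the positive class. Reports carry TP/FN/TN/FP, TPR, TNR, FPR = 1 − TNR
and balanced accuracy = (TPR + TNR)/2; the two identities hold exactly by
construction.

## Synthetic data: what it emulates and what it does not

All generators are pure functions of (spec, seed).

*Cohorts.* Ions are Gaussian profiles (FWHM 0.05 Da) at uniform random
positions with lognormal baseline amplitudes (median 100, log-sd 0.5);
spectrum amplitudes are baseline × group effect × lognormal(0, σ) with
σ = 0.2 by default, plus a uniform additive noise floor (amplitude 0.5)
that is switched off together with σ in the exactly-noiseless limit. The
default design mirrors a five-genotype cohort of 3/4/11/4/5 samples with
10 technical replicates each and 4× effects on 10 group-specific ions out
of 200; the marker blocks are deliberately a minor share of spectral
energy, as genotype effects are on a shared lipidome. Inactive
(forceps-off) segments are 20% of acquisitions: tissue signal scaled by
0.01 plus solvent ions at 25 dedicated m/z positions, giving them a
spectral direction distinct from every genotype — the contrast the k=2
cosine burn detection exploits.

*MSI cubes.* A contiguous compartment map (background border, tumour
core, stroma ring, normal elsewhere) with per-compartment signatures; the
default 40×40 design plants 5 marker ions per tissue compartment at 5×
among 150 ions. Background pixels carry 2% tissue signal plus the same
solvent-ion model; without distinct solvent support, background would be a
scaled copy of tissue and invisible to the cosine metric.

*Clinical cohorts.* Gaussian features (sd 1): 24 patients (16 positive / 8
negative), 3 replicates, 200 features of which 20 shift by ±2 with the
label and 20 by ±2 with a batch variable assigned independently of the
label.

*Compound DB.* 50–1500 Da masses, lipid-style names for ~70% of entries,
1–5 pathways each grouped into subclasses, with lipid tokens embedded in
pathway names so curation has material to work on.

None of this emulates isotope envelopes, adducts beyond the matching
rules, chemical backgrounds with structure, chromatography, spatial
intensity gradients, or patient-level biological heterogeneity beyond mean
shifts. Passing tests therefore demonstrate that the *procedures* are
implemented correctly and are calibrated under their stated noise models —
not that real tissue data would separate this cleanly. No quantitative
description of real REIMS noise or effect sizes was available; the
synthetic parameters are calibration knobs, not estimates.

## Problem sizes and determinism

The shipped tests and the acceptance script run the full designs above
(≈340-spectrum cohorts on 30k-bin axes, 1600-pixel cubes, 20 repetitions
of 1000-ion null cohorts, 20 permutation/refinement seeds), sizes chosen so
a complete run finishes in minutes on one CPU. Every randomized stage
takes an explicit seed; there is no global random state, reruns of a
pipeline with the same config are byte-identical, and the permutation-null
balanced accuracy is assessed by its mean over 20 permutation seeds
(individual 24-patient permuted runs scatter widely around chance, which
no procedure can avoid).

## Known limitations

- Exact t-SNE is O(n²); cohorts beyond a few thousand spectra would need
  the Barnes–Hut path and would lose bitwise determinism guarantees.
- The pooled-variance t-test on lognormal intensities is only
  asymptotically calibrated; the null simulations confirm the empirical
  size at the shipped noise level, not universally.
- Pathway ranking inherits whatever pathway vocabulary the compound table
  provides; no attempt is made to reconcile external taxonomies.
- The feature-refinement criterion (SVM-weight elimination with a
  variance-ratio batch filter) is one member of a family; the selection
  criterion is pluggable by design.
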