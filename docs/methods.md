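# Methods

## The analysis in brief

The pipeline treats bulk lung microarrays as noisy mixtures of cell-type
expression programs and asks whether irradiation (and its modulation by an
anti-CTGF antibody) changes the *proportions* of those programs. It does
so without deconvolution: cell-type distinguishing gene panels are derived
from an independent expression atlas, and their over- or
under-representation in irradiation-responsive gene lists is scored with a
ratio-of-proportions statistic and a 2×2 χ².

## Normalization

Raw intensities are normalized in two steps. First each chip is divided by
the 50th percentile of its own positive measurements; percentiles
interpolate linearly between order statistics, and the convention is fixed
here because different array-analysis suites disagree on it. The per-chip
percentile (rather than a global one across chips) is the standard
behaviour of the software family this analysis descends from. Second,
each probe is divided by the median of its values across the
*timepoint-matched* non-irradiated control arrays, so every value becomes
a ratio to contemporaneous controls; with an even number of control arrays
the median is the mean of the two central values. A probe whose control
median is zero has no defined ratio; such values propagate as missing and
are excluded from every downstream test rather than imputed.

## Low-intensity filter

Probes indistinguishable from background are removed before testing: a
probe is dropped iff its raw signal falls below
`multiplier × coefficient(array)` on at least `min_failing_arrays` arrays
(defaults 3 and 28 — with the default 28-array design, a probe must look
like background everywhere). The per-array coefficient is a documented
robust background scale: 1.4826 × MAD of the array's lowest-decile
intensities, an SD-equivalent of the near-background signal. The original
analysis used a vendor-defined "cross-gene error model" whose form is not
public; this estimator preserves the filter's intent (drop probes whose
signal is within noise of background) with a reproducible statistic, and
the 3× multiplier and array count remain configuration.

## Differential selection

Contrasts compare two disjoint array groups at one timepoint. Welch's
unequal-variance *t* (Welch–Satterthwaite df, two-sided p) is computed on
log2 control ratios — the test scale is not dictated by the source
analysis, and the log scale is chosen for variance symmetry — while fold
changes are reported as linear ratios of group means. A probe is
"altered" when its fold change strictly exceeds 2 (or is strictly below
1/2) *and* p < 0.05, both strict per the defining inequalities. No
multiple-testing correction is applied by default: the published selection
is a raw p < 0.05 screen and the package reproduces it faithfully; a
Benjamini–Hochberg option (`fdr=True`) exists but is off by default. The
"any treatment vs. irradiation alone" list is realized as the union of
the four regimen-specific contrasts (each vs. irradiation alone), since a
pooled construction was equally compatible with the source description; a
pooled mode is available via `PipelineConfig.pooled_treated`. Degenerate
inputs are defined rather than fatal: zero variance in both groups yields
t = 0, p = 1 at equal means and p → 0 (flagged with a warning) otherwise.

## Pattern extraction

PCA runs on the combined altered-probe block with probes as observations
and arrays as variables: each probe's log2-ratio profile is mean-centered
across arrays, and components come from the covariance structure of the
centered block (computed by SVD; covariance, not correlation — arrays are
on a common scale after normalization). Variance fractions are the
squared singular values over their sum and therefore sum to 1.

"Elevated" and "diminished" need a sign convention, since principal
components are defined up to sign: PC1 is oriented so that its mean score
over the 18-week irradiation-alone arrays is positive, making positive
correlation mean "elevated by irradiation". Other components get the
deterministic largest-entry-positive convention. Per-probe correlation
with PC1 uses Pearson's r with the exact t transform
(t = r√((m−2)/(1−r²)), m = number of arrays) for the two-sided p — exact
rather than permutation-based because the array count is small and fixed.
Probes at p < 0.001 are partitioned by the sign of r.

The clustering order for heatmap export is average linkage on
centered-correlation distance (1 − Pearson r between probe profiles).
Probes are pre-sorted lexicographically so linkage ties resolve
deterministically; zero-variance profiles receive the maximal distance 2.

## Marker panels

A gene distinguishes cell type c when its mean linear intensity over c's
atlas samples exceeds 64× the pooled mean of all other samples and the
two-sided Mann–Whitney p is below 0.001. Two open choices are resolved
as follows and kept configurable: the 64× ratio is computed on linear
intensities (the threshold's natural scale; a 10⁻⁹ floor guards the
denominator), and the comparator is the pooled mean of all non-c samples
— the plain reading of "vs. all other samples" — with a stricter
max-over-other-types comparator available (`comparator="max"`). Genes
qualifying for more than one type are removed from every list, so panels
are pairwise disjoint (asserted on every run).

The Mann–Whitney implementation uses midranks for ties; the p-value is
exact by enumeration over all assignments of the pooled midranks when the
pooled sample size is ≤ 12, and otherwise a tie-corrected normal
approximation without continuity correction. Cell types with a single
atlas sample are excluded with a warning, as the rank test has no
resolution there.

Panels travel to the study platform through a (gene → probe) mapping
table. A gene mapping to several probes contributes all of them — the
representation statistic counts probes, so a multiply-probed gene
genuinely occupies more platform slots — and probes shared between panels
after mapping are removed from all panels to restore disjointness.

## Representation scoring

For a query list of t platform probes, a panel with N probes on a
platform of T, n of them in the query: fold enrichment = (n/t)/(N/T),
kept at full precision and rounded only for presentation. Departure from
proportionality is scored by the 2×2 contingency χ² on
[[n, t−n], [N−n, (T−t)−(N−n)]] without continuity correction, df = 1,
upper-tail p. Each panel carries its own platform total T, because panels
may originate from platforms of different sizes. A degenerate table (a
zero margin, e.g. when the query is the whole platform) is recorded as
χ² = 0, p = 1. Published p-values for this table are not reproduced by
this (or any standard) 2×2 construction from the published counts; the
χ² here is therefore validated against an independent contingency-table
implementation, while fold values are validated against the published
numbers, which they reproduce exactly at printed precision.

Per-gene fold-change reporting divides each group's mean control ratio by
the reference (non-irradiated) group's mean ratio at the same timepoint,
so the reference group reports exactly 1.

## Synthetic data: what it emulates and what it does not

The generator is the package's test bed and defines its study conditions.

**Atlas.** Seven lung cell types (macrophage, mast cell, dendritic cell,
mesenchymal, T cell, endothelial, epithelial), six samples per type, 2000
genes with log-normal baseline intensities (median 100, log-sd 0.8).
Thirty genes per type are planted as markers at 128× their baseline in
their own type's samples. Six samples per type gives perfect rank
separation a tie-corrected normal-approximation p of ~1×10⁻⁴, comfortably
inside the p < 0.001 screen; with four or fewer samples per type no gene
could pass that screen at all, so replication at this level is a design
requirement of the derivation procedure itself. Noise is multiplicative
log-normal with coefficient of variation 0.2, the natural intensity-scale
noise model; the atlas has no additive floor so that the planted
marker-to-rest ratio is exactly the configured fold in expectation.

**Study.** The default design is the study's: 7 groups (non-irradiated
IgG and antibody controls; irradiation alone; antibody beginning 2 days
before or 2, 20 or 112 days after irradiation) × 2 timepoints (18 and 30
weeks) × 2 replicates = 28 arrays. Each array is the composition-weighted
mean of the atlas type-mean profiles, times log-normal noise (cv 0.2),
plus a floor intensity of 1. Baseline composition is
parenchyma-dominated (epithelial 0.55, endothelial 0.25, mesenchymal
0.08, macrophage 0.04, T cell 0.05, dendritic 0.02, mast 0.01). At 18
weeks, irradiated groups without late treatment expand macrophage ×8,
mast ×10, dendritic ×6 and mesenchymal ×5 (fractions renormalized);
regimens beginning at day 20 or 112 are fully normalized at 18 weeks, and
every regimen is normalized at 30 weeks, when the untreated response
itself is milder (×4/×5/×3/×2.5) — the schedule dependence the study
reported. Shift magnitudes were set so that, after renormalization, the
bulk marker-intensity ratios of all four expanded types clear the 2-fold
screen (the bulk signal of a marker scales as 1 + 127·f for type fraction
f, so fraction shifts are strongly damped in bulk).

**Pattern plant.** For variance-fraction tests, a separate generator
plants two orthogonal, group-aligned array patterns (an 18-week
irradiation response and a late-regimen contrast) into a raw-scale matrix
with a 70/30 amplitude-variance split, random per-probe signs, Gaussian
log2 noise (sd 0.15, low by construction so the split is identifiable)
and 300 null probes, at 100·2^signal so it flows through the full
normalization chain.

**Not emulated:** probe-level feature extraction, dye or spatial
artifacts, probe–gene multiplicity on the study platform (the synthetic
platform map is one-to-one), biological replicate-to-replicate
composition variability, and correlated noise between genes. Passing
tests therefore demonstrate that the pipeline recovers planted
composition shifts under idealized mixture noise — not that it would be
robust to batch effects or probe-level artifacts in deposited data.

## Problem sizes and determinism

Monte-Carlo checks use 20 seeds for pattern recovery and end-to-end
ranking, 100 seeds (600-gene atlases) for marker sensitivity/FDR in the
test suite, and 20/50/20 seeds in the acceptance script; these sizes give
stable means at the package's chosen precision. All randomness flows
through explicit integer seeds (numpy `default_rng`; child streams are
derived from (seed, stage) pairs), there is no global random state, and
identical configuration + seed reproduces bit-identical run manifests,
which record every probe-count attrition step and SHA-256 checksums of
the stage outputs.

## Known limitations

- The published probe counts (2570/3644/4798, 2754 = 1676 + 1078) and the
  68% PC1 variance fraction depend on the deposited study data and atlas
  and are not recomputable from synthetic data; the package validates the
  procedures that produced them (union bookkeeping, variance-fraction
  recovery, partition recall) rather than those numbers.
- The background estimator is a stand-in for an undocumented vendor
  model; absolute retained-probe counts on real data would differ even
  though the filter's monotonicity and intent are preserved.
- With two replicates per cell, Welch's test has ~2 degrees of freedom;
  the selection is a screen, not an inference, and is used as such.
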