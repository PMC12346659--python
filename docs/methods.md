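# Methods

This note documents the models, parameter choices, numerical decisions
and known limitations of `crcmeth`. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate and missing-value conventions

All internal intervals are 0-based half-open (BED convention). Bismark
cytosine reports carry 1-based positions; they are converted on
ingestion (pos − 1 as start). A CpG at 1-based position 1000 therefore
falls in tile [0, 1000). Strand is parsed and carried but ignored by
all region arithmetic — the analyses are strand-agnostic at region
level; per-strand reports can be merged upstream if desired. Missing
matrix cells are NaN in memory and empty strings on disk, never 0: a
zero beta is a biological observation, a missing one is not.

## Beta values and the two DMR callers

β = m/(m+u) is the exact count ratio with no smoothing; zero coverage
yields a missing value rather than 0.

**Tile caller** (1000 bp tiles, step = size). CpGs with per-sample
coverage < 4 are dropped before summing; a tile missing in a sample is
excluded from that sample, and a tile is tested only when both groups
retain at least one sample with data. The test is a binomial GLM of
(methylated, unmethylated) per sample on group plus biological sex; the
sex covariate is dropped automatically when constant. The p-value is
the likelihood-ratio test of the group term against the chi-square(1)
reference — for the group-only model this is checked in the tests
against the closed-form LRT with pooled-proportion MLEs. Multiple
testing uses Benjamini–Hochberg across tested tiles (a standard,
monotone FDR procedure; the SLIM variant some tools default to is not
reimplemented). Significance: q < 0.01 and |Δβ| ≥ 25 percentage points,
where Δβ is the difference of group mean per-sample betas (HGD − LGD).
Degenerate fits (separation, singular design) skip the tile with a
warning rather than aborting a genome-wide run.

**Bin caller** (100 bp bins, step = size). Counts are pooled within
group per CpG; a CpG qualifies when its pooled coverage is ≥ 4 in both
groups, and a bin is tested only with ≥ 4 qualifying CpGs. The test is
the two-sided Fisher exact test on the pooled 2×2 table — deterministic
and exactly checkable against hypergeometric enumeration, which the
acceptance suite does exhaustively for group margins up to 30. The
filter is on raw p < 0.01 (BH q-values are stored for reference only),
matching the bin-level calling convention this caller mirrors.

**Consensus geometry.** The published notion of "intersection of both
pipelines" leaves the geometry open. Here a consensus region is every
maximal run of adjacent (gap 0) significant bins with a common
direction that overlaps at least one significant tile of the same
direction by ≥ 1 bp. This keeps the 100 bp caller's resolution while
requiring both callers to agree; direction-discordant overlaps are
dropped. The consensus record carries the merged interval, a
coverage-weighted mean of the member-bin methylation differences, and
the minimum member p/q.

## Region annotation

Feature precedence when a region overlaps several classes:
promoter > 5'UTR > exon > intron > enhancer > upstream_1to5kb >
intergenic; a region overlapping nothing is intergenic. Promoters and
upstream windows come from the supplied annotation BED, not recomputed
from TSSs. CpG-context: island on overlap, shore within 2 kb of an
island edge (the standard shore convention), open sea otherwise. Gene
linking uses the gap between half-open intervals, max(0, s2−e1, s1−e2),
with genes linked at gap ≤ 5000 bp (a gene 5001 bp away is not linked).

## Bin matrices and preprocessing

Probe-to-bin aggregation takes the mean of non-missing probe betas per
bin per sample (a probe exactly at a bin start belongs to the bin;
half-open rule); bins with no contributing probe are dropped.
Gain/loss classification uses strict thresholds as printed: diff > +20
percentage points is gain, < −20 loss, otherwise unchanged (a bin at
exactly +20 is unchanged). Missingness filtering drops rows then
columns with strictly > 50 % missing, repeating the row/column pass
until stable so the output never violates the rule. Row z-scores use
the sample SD (n − 1); constant rows are set to zero and flagged
rather than propagating NaNs.

## Consensus clustering and cluster assignment

Consensus clustering resamples 80 % of samples (and optionally a
feature fraction) per iteration, clusters each resample with
average-linkage hierarchical clustering on Euclidean distance, cuts the
same tree at every k, and defines consensus as co-assignment count over
co-sampling count. Per-k labels cut an average-linkage tree on
(1 − consensus); k selection is reported by the delta-area of the
consensus CDF. The headline assignment for downstream contrasts is
Ward/Euclidean on the z-matrix at k = 4 (both tools are exposed; the
published heatmap clustering is Ward-based and k = 4 mirrors the
four-cluster structure, though the elbow criterion is reported rather
than claimed to reproduce that choice). Cluster labels are renumbered
by increasing mean methylation over the signature rows, so CL1 is the
normal-like low end and CL4 the hypermethylated extreme. Linkage ties
follow scipy's deterministic lower-index convention. Desk-scale
defaults in the tests and drivers use 200 resamples and k up to 8; the
library defaults remain 1000 resamples, k 3–20.

## CIMP classification

Probe Z-scores use the normal-reference mean and sample SD per probe;
probes with fewer than two informative normals are dropped, and a zero
normal SD is floored at 0.01 and flagged (otherwise a constant
reference probe would generate infinite Z). "At least one-third of
probes at Z ≥ 3" is read inclusively on both counts, with the
denominator the probes that have a non-missing Z for that sample. The
Ogino thresholds are as printed (H ≥ 5, L 3–4, N < 3). The published
Weisenberger sentence is internally inconsistent ("CIMP-L as 2
methylated genes, non-CIMP if 2 or less"); the implementation uses the
only reading that yields three disjoint classes — H ≥ 3, L 1–2, N 0 —
and exposes both thresholds as parameters. Normal-tissue samples are
CIMP-N by definition. Summary percentages use the tumor-only
denominator rounded to one decimal; with-normals totals add normals to
CIMP-N.

## Scores, tests, survival

EMT scores average per-gene cohort z-scores (sample SD) over the
19-gene panel; genes missing from the matrix or with zero SD are
skipped and reported (an error is raised only when nothing remains).
Whether normals join the cohort statistics is the caller's choice; the
default is every sample in the supplied matrix. Group contrasts use
tie-corrected Kruskal–Wallis plus pairwise two-sided Wilcoxon rank-sum
tests — exact for group sizes ≤ 10 without ties, normal approximation
with continuity and tie correction otherwise — BH-adjusted within the
pairwise family at α = 0.05. Over-representation is the upper-tail
hypergeometric test on user-supplied gene sets intersected with the
universe, BH-adjusted; no live pathway databases are queried.

Follow-up is truncated at 1000 days: later times become censored
observations at the limit, events at or before the limit are untouched.
Kaplan–Meier estimation delegates to lifelines (deaths precede
censorings at ties). The log-rank statistic is computed directly from
the observed/expected tabulation with hypergeometric variance so that
per-group O and E are part of the result; with G groups the statistic
is the quadratic form over the first G − 1 groups against
chi-square(G − 1); the implementation is cross-checked against
lifelines in the tests. Pairwise cluster contrasts run CL2/CL3,
CL2/CL4 and CL3/CL4, with normal samples excluded by the caller.

## TF networks

TF activity is a mode-signed mean of target z-scores (activity = mean
over targets of mode × z). This is a deliberately transparent surrogate
for rank-enrichment activity inference: the analyses downstream consume
the activity *profiles*, and a linear surrogate keeps the planted-truth
recovery exact and testable. TFs with fewer than three present targets
are excluded and reported. Networks connect node profiles at
|Pearson r| ≥ 0.4 (edges carry r and its sign; no self-edges);
centralities are computed on the unweighted skeleton, with normalized
betweenness and harmonic closeness (well-defined on disconnected
graphs). Hubs and bottlenecks are the top decile of degree and
betweenness respectively, ties at the quantile flagged inclusively —
"bottleneck" is operationalized as top-decile betweenness. A hub's
regulatory sign is the sign of the mean correlation between its
activity profile and its targets' expression.

## The synthetic cohorts

The generator encodes the study conditions as defaults and is the
source of every test input.

* **Count data** — 6 LGD vs 9 HGD samples (the tissue cohort's sizes;
  recovery benchmarks use 6 vs 6), 1000 CpGs over fifty 1 kb regions.
  CpGs sit on a regular grid inside a 400 bp island-like core of each
  region (≈ 5 CpGs per 100 bp), the density regime in which a 100 bp
  bin caller with a 4-CpG rule is applicable at all. Background
  methylation per CpG is a bimodal Beta mixture (70 % Beta(1,10),
  30 % Beta(10,1)), mimicking the genome-wide low/high methylation
  split around regulatory regions. 5 % of regions carry a planted
  shift of 0.4 in the HGD group, clipped to [0,1]; the direction is
  hyper when the region's mean background is below 0.5 and hypo
  otherwise — a shift away from the nearer boundary would be erased by
  clipping, and biologically hypermethylation arises at unmethylated
  island-like loci. Coverage is Poisson with mean 30 (floored at 1);
  methylated counts are Binomial.
* **Beta matrix** — 300 probes × 4 clusters × 40 samples plus 20 normal
  reference samples. A 60 % signature-probe subset carries the stepwise
  shifts (0, 0.15, 0.25, 0.40) over a Uniform(0.05, 0.35) base with
  Gaussian noise (SD 0.05), clipped to [0,1]; cluster 1 is the normal
  end of the gradient.
* **Expression** — log-scale; per-sample TF activity = cluster mean
  (default N(0, 1.5) per TF per cluster) + a shared latent factor for
  half the TFs + N(0, 0.5); target genes follow mode × activity with
  N(0, 0.5) noise; EMT panel genes get a +1 shift in cluster 3 (the
  published inverse-to-methylation EMT pattern has its peak in the
  intermediate cluster). The latent factor is what gives the
  per-cluster TF networks their within-cluster correlation structure.
* **Clinical** — exponential survival with per-cluster hazards
  (2, 5, 10, 20) × 10⁻⁴ per day, so the hypermethylated cluster is the
  poor-prognosis arm; each subject is independently censored with
  probability 0.3 at a Uniform(0, T) time (censor rate 1 yields zero
  events); mutation counts are Poisson with per-cluster means
  (0, 2, 2, 8).

All generators are deterministic given the seed (numpy PCG64), which
the property tests assert byte-for-byte.

**What passing tests do and do not show.** The generator plants clean,
well-separated structure: independent CpGs (no spatial autocorrelation
of methylation beyond the planted regions), homogeneous coverage, no
batch or composition effects, binary shift sets rather than graded
per-probe effects, and regulons with disjoint targets. Recovery and
calibration results on these cohorts validate the implementation logic
— they do not establish power or error rates on real EM-seq or array
data, where dispersion, probe cross-reactivity and cellular
heterogeneity matter. One visible consequence: because every signature
probe shifts by the full cluster offset, all tumor clusters saturate
the CIMP Z ≥ 3 rule in the demo drivers, whereas real cohorts spread
across CIMP-H/L/N.

## Problem sizes

The drivers and test suites run desk-scale versions of each analysis:
1000 CpGs / 50 tiles per simulated cohort, 20 seeds for recovery
benchmarks, 50 seeds for the null tile-caller calibration, 1000
replicates for the type-I error checks, 200 consensus resamples at
k ≤ 8, and exhaustive oracle sweeps at margins ≤ 30 (Fisher), ≤ 25
(ORA) and ≤ 8 nodes (centralities). These sizes were chosen so the
whole pipeline re-runs from scratch in minutes while every statistical
claim is still measured rather than assumed.

## Known limitations

* The bin caller tests pooled counts, so sample-level overdispersion
  inflates its significance on real data; the tile caller's per-sample
  GLM is the guard. No beta-binomial dispersion model is provided.
* BH replaces the SLIM q-value procedure of the tile caller this
  mirrors; q-values are comparable but not identical.
* TF activity is a linear surrogate, not rank-enrichment inference;
  hub lists from real cohorts will differ from enrichment-based tools.
* No probe-level array preprocessing, imputation, cfDNA deconvolution,
  Cox regression, or live GO/KEGG queries — annotations, gene sets and
  regulons are inputs.
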