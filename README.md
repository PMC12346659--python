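# crcmeth

Consensus differential-methylation signature (DMS) calling and
methylation-based tumor subtyping along the colorectal
adenoma–carcinoma continuum.

Colorectal cancer develops through a well-characterized progression
from normal epithelium to low-grade dysplasia (LGD), high-grade
dysplasia (HGD), and invasive carcinoma. `crcmeth` implements the
computational pipeline for studying the DNA-methylation side of that
progression: it calls a consensus set of differentially methylated
regions between dysplasia grades from per-cytosine methylation counts,
projects probe-level beta matrices onto those regions, stratifies a
tumor cohort into methylation clusters, and characterizes the clusters
by CIMP status, EMT expression scores, mutation burden, survival, and
transcription-factor network topology. A synthetic-data module
generates every input with planted ground truth, so the full analysis
runs and is tested without any external download.

## The core computations

**Beta values.** For each CpG, β = m / (m + u), the fraction of
methylated read counts (undefined, not zero, at zero coverage).

**Two independent DMR callers, intersected.**

* *Tile caller*: 1000 bp non-overlapping tiles; CpGs under 4× coverage
  are dropped per sample; per tile, a binomial logistic regression of
  the methylated proportion on group (plus a sex covariate) gives a
  likelihood-ratio p-value; Benjamini–Hochberg q-values across tiles;
  tiles pass at q < 0.01 and |Δβ| ≥ 25 percentage points.
* *Bin caller*: 100 bp bins with counts pooled within group; a bin is
  tested only with ≥ 4 CpGs each covered by ≥ 4 pooled reads per group;
  two-sided Fisher exact test on the pooled 2×2 table at p < 0.01.
* *Consensus DMS*: maximal runs of adjacent significant bins that
  overlap a significant tile with the same direction
  (hyper = higher methylation in HGD).

**Cluster analysis.** Probe betas are averaged into genomic bins, rows
and columns with > 50 % missing values are dropped, rows are z-scored
(sample SD), and samples are clustered by resampling consensus
clustering (hierarchical, Euclidean, 80 % item sampling) and by
Ward/Euclidean assignment at k = 4. Clusters are renumbered along the
methylation gradient so CL1 is the lowest (normal-like) and CL4 the
most hypermethylated.

**CIMP classification.** Probe Z-scores against a normal-tissue
reference, Z = (β − μ_normal)/σ_normal; a panel gene is methylated in
a sample when ≥ 1/3 of its informative probes reach Z ≥ 3; samples are
labeled by methylated-gene counts on the Weisenberger panel (CACNA1G,
IGF2, NEUROG1, RUNX3, SOCS1; H ≥ 3, L 1–2, N 0) or the Ogino panel
(those plus CDKN2A, MLH1, CRABP1; H ≥ 5, L 3–4, N < 3). Normal samples
are CIMP-N by definition.

**Downstream contrasts.** EMT score = per-sample mean cohort z-score
over a 19-gene epithelial–mesenchymal-transition panel;
Kruskal–Wallis + pairwise BH-adjusted Wilcoxon rank-sum contrasts;
Kaplan–Meier curves and log-rank tests with follow-up truncated at
1000 days; regulon-based TF activity, |r| ≥ 0.4 correlation networks,
and degree/betweenness/closeness centralities with top-decile
hub/bottleneck flags.

## Worked example

The analysis is organized as numbered drivers over the library:

```bash
python analysis/01_simulate_cohort.py     # synthetic inputs -> scratch/data/
python analysis/02_call_dms.py            # consensus DMS    -> results/
python analysis/03_cluster_cohort.py      # clustering
python analysis/04_clinical_contrasts.py  # EMT, burden, survival
python analysis/05_tf_networks.py         # TF networks
python analysis/06_cimp_calls.py          # CIMP classification
```

Driver 02 prints, for the simulated 6 LGD vs 9 HGD tissue cohort:

```
significant tiles: 2; significant bins: 11; consensus DMS regions: 2
planted-DMR recovery: recall 1.00, precision 1.00
```

— both planted differentially methylated regions are recovered by the
intersection of the two callers with no false consensus region.
Driver 03 reports `Ward assignment ARI vs planted truth: 1.000` with
per-cluster mean methylation 0.199 / 0.289 / 0.349 / 0.438 (the planted
stepwise gradient), and driver 04:

```
pairwise log-rank over tumor clusters (1000-day truncation):
group_a group_b  statistic      p
    CL2     CL3     2.4353 0.1186
    CL2     CL4    28.9079 0.0000
    CL3     CL4    12.5077 0.0004
```

i.e. the most hypermethylated cluster (CL4, planted hazard 4–10× the
other tumor clusters) has significantly worse survival, the highest
mutation burden (8.1 vs ≈ 2.2 mean mutations), while the EMT score
peaks in CL3 where the panel shift was planted. Driver 06 ends with the
summary arithmetic applied to the published TCGA COAD-READ tumor-only
label counts:

```
weisenberger: {'CIMP-H': 9.0, 'CIMP-L': 27.1, 'CIMP-N': 63.9} | with normals, CIMP-N = 307 of 455
ogino:        {'CIMP-H': 7.6, 'CIMP-L': 18.0, 'CIMP-N': 74.4} | with normals, CIMP-N = 350 of 455
```

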