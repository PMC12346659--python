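"""Synthetic cohorts with planted ground truth for every pipeline stage.

The generator emulates the statistical structure the analysis assumes:

* **count data** — two dysplasia groups (LGD/HGD) of per-CpG
  methylated/unmethylated counts over a one-chromosome genome of 1 kb
  regions, each with an island-like CpG-dense core; a fraction of
  regions carries a planted methylation shift (the DMRs the consensus
  caller must recover);
* **beta matrix** — probe-level betas for a 4-cluster cohort with a
  stepwise hypermethylation gradient on a designated signature-probe
  subset, one cluster playing "normal", plus held-out normal reference
  samples;
* **expression** — log-scale expression with planted TF-regulon activity
  and a cluster-specific EMT-panel shift;
* **clinical** — exponential survival with per-cluster hazards, uniform
  censoring, and Poisson mutation burden.

Everything is deterministic given the config seed (numpy PCG64).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io_formats import ClinicalRecord, CytosineRecord, GenomicInterval

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_count_data",
    "simulate_beta_matrix",
    "simulate_expression",
    "simulate_clinical",
    "make_regulons",
]

CHROM = "chr1"


@dataclass
class SimulationConfig:
    """Study conditions for all generators (defaults mirror the cohort
    the analysis assumes; see docs/methods.md for the rationale)."""

    seed: int = 0
    # count data (tissue cohort: 6 LGD vs 9 HGD)
    n_samples_per_group: Sequence[int] = (6, 9)
    n_cpgs: int = 1000
    n_regions: int = 50
    region_size_bp: int = 1000
    planted_dmr_fraction: float = 0.05
    effect_delta: float = 0.4
    coverage_mean: float = 30.0
    background_low_weight: float = 0.7  # mixture weight of the low mode
    # beta matrix (TCGA-like cohort)
    n_probes: int = 300
    signature_fraction: float = 0.6
    n_clusters: int = 4
    n_samples_per_cluster: int = 40
    n_normal_ref: int = 20
    cluster_shift_steps: Sequence[float] = (0.0, 0.15, 0.25, 0.40)
    beta_noise_sd: float = 0.05
    # expression
    expr_noise_sd: float = 0.5
    tf_activity_sd: float = 0.5  # per-sample activity noise around cluster mean
    tf_shared_factor_fraction: float = 0.5  # TFs loading on a latent co-factor
    emt_shift: float = 1.0
    emt_shift_cluster: int = 3  # 1-based cluster index with highest EMT score
    # clinical
    hazard_per_cluster: Sequence[float] = (0.0002, 0.0005, 0.001, 0.002)
    censor_rate: float = 0.3
    mutation_rate_per_cluster: Sequence[float] = (0.0, 2.0, 2.0, 8.0)

    def __post_init__(self) -> None:
        if not (0.0 <= self.planted_dmr_fraction <= 1.0):
            raise ValueError("planted_dmr_fraction must be in [0, 1]")
        if not (0.0 <= self.effect_delta <= 1.0):
            raise ValueError("effect_delta must be in [0, 1]")
        if not (0.0 <= self.censor_rate <= 1.0):
            raise ValueError("censor_rate must be in [0, 1]")
        if self.coverage_mean <= 0:
            raise ValueError("coverage_mean must be positive")
        for name in ("cluster_shift_steps", "hazard_per_cluster",
                     "mutation_rate_per_cluster"):
            if len(getattr(self, name)) != self.n_clusters:
                raise ValueError(f"{name} must have n_clusters entries")
        if any(h <= 0 for h in self.hazard_per_cluster):
            raise ValueError("hazards must be positive")


@dataclass
class GroundTruth:
    """Planted structure the tests recover."""

    planted_dmrs: list = field(default_factory=list)  # (GenomicInterval, direction)
    cluster_labels: Optional[pd.Series] = None  # sample -> 1..k (1 = normal)
    normal_ref_samples: list = field(default_factory=list)
    signature_probes: list = field(default_factory=list)
    tf_activities: Optional[pd.DataFrame] = None  # tf x cluster means
    sample_activities: Optional[pd.DataFrame] = None  # tf x sample
    emt_cluster: Optional[int] = None
    hazard_group: Optional[pd.Series] = None


# ---------------------------------------------------------------------------
# count data
# ---------------------------------------------------------------------------

def _cpg_positions(config: SimulationConfig) -> np.ndarray:
    """Deterministic island-like placement: CpGs on a regular grid inside
    a 400 bp core of each region (0-based starts)."""
    per_region = config.n_cpgs // config.n_regions
    core_len = min(400, config.region_size_bp)
    spacing = max(core_len // max(per_region, 1), 2)
    offset = (config.region_size_bp - core_len) // 2
    starts = []
    for r in range(config.n_regions):
        base = r * config.region_size_bp + offset
        starts.extend(base + i * spacing for i in range(per_region))
    return np.array(starts[: config.n_cpgs], dtype=int)


def simulate_count_data(config: SimulationConfig):
    """Two-group per-CpG count tables with planted DMRs.

    Background methylation per CpG is a bimodal Beta mixture
    (low ~ Beta(1,10), high ~ Beta(10,1)); inside planted DMRs the HGD
    fraction is shifted by effect_delta towards the far side of the
    methylation scale (hyper when the region is mostly unmethylated,
    hypo otherwise), clipped to [0, 1].  Coverage ~ max(1, Poisson);
    methylated counts ~ Binomial(coverage, fraction).

    Returns (records_per_sample dict, GroundTruth).
    """
    rng = np.random.default_rng(config.seed)
    starts = _cpg_positions(config)
    n = len(starts)

    low = rng.random(n) < config.background_low_weight
    base = np.where(low, rng.beta(1, 10, size=n), rng.beta(10, 1, size=n))

    n_planted = int(round(config.planted_dmr_fraction * config.n_regions))
    planted_regions = rng.choice(config.n_regions, size=n_planted, replace=False)
    region_of = starts // config.region_size_bp

    planted, shifted = [], base.copy()
    for r in sorted(planted_regions):
        mask = region_of == r
        direction = "hyper" if base[mask].mean() < 0.5 else "hypo"
        delta = config.effect_delta if direction == "hyper" else -config.effect_delta
        shifted[mask] = np.clip(base[mask] + delta, 0.0, 1.0)
        planted.append((
            GenomicInterval(CHROM, r * config.region_size_bp,
                            (r + 1) * config.region_size_bp,
                            name=f"dmr_{r}"),
            direction,
        ))

    n_lgd, n_hgd = config.n_samples_per_group
    records_per_sample = {}
    for g, (n_s, frac) in enumerate([(n_lgd, base), (n_hgd, shifted)]):
        label = "LGD" if g == 0 else "HGD"
        for i in range(n_s):
            coverage = np.maximum(rng.poisson(config.coverage_mean, size=n), 1)
            meth = rng.binomial(coverage, frac)
            records_per_sample[f"{label}_{i + 1}"] = [
                CytosineRecord(
                    chrom=CHROM, pos=int(s) + 1, strand="+",
                    count_methylated=int(mc), count_unmethylated=int(c - mc),
                    context="CpG",
                )
                for s, c, mc in zip(starts, coverage, meth)
            ]
    truth = GroundTruth(planted_dmrs=planted)
    return records_per_sample, truth


# ---------------------------------------------------------------------------
# beta matrix
# ---------------------------------------------------------------------------

def simulate_beta_matrix(config: SimulationConfig):
    """Probe x sample beta matrix with a stepwise 4-cluster gradient.

    Signature probes: beta = clip(base + shift[cluster] + N(0, sd));
    other probes carry base + noise for every sample.  Cluster 1 uses
    shift 0 (the "normal" end); ``n_normal_ref`` extra normal reference
    samples are drawn from the cluster-1 distribution.

    Returns (beta DataFrame, probe_coords DataFrame, GroundTruth).
    """
    rng = np.random.default_rng(config.seed + 1)
    n_sig = int(round(config.signature_fraction * config.n_probes))
    probes = [f"probe_{i}" for i in range(config.n_probes)]
    signature = probes[:n_sig]
    base = rng.uniform(0.05, 0.35, size=config.n_probes)

    samples, labels = [], []
    for c in range(config.n_clusters):
        for i in range(config.n_samples_per_cluster):
            samples.append(f"S_c{c + 1}_{i + 1}")
            labels.append(c + 1)
    normals = [f"NREF_{i + 1}" for i in range(config.n_normal_ref)]

    columns = {}
    for sample, cluster in zip(samples, labels):
        shift = np.zeros(config.n_probes)
        shift[:n_sig] = config.cluster_shift_steps[cluster - 1]
        noise = rng.normal(0.0, config.beta_noise_sd, size=config.n_probes)
        columns[sample] = np.clip(base + shift + noise, 0.0, 1.0)
    for sample in normals:
        noise = rng.normal(0.0, config.beta_noise_sd, size=config.n_probes)
        columns[sample] = np.clip(base + noise, 0.0, 1.0)

    beta = pd.DataFrame(columns, index=probes)
    coords = pd.DataFrame(
        {
            "chrom": CHROM,
            "start": np.arange(config.n_probes) * 200,
            "end": np.arange(config.n_probes) * 200 + 2,
        },
        index=probes,
    )
    truth = GroundTruth(
        cluster_labels=pd.Series(labels, index=samples),
        normal_ref_samples=normals,
        signature_probes=signature,
    )
    return beta, coords, truth


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def make_regulons(n_tfs: int = 10, targets_per_tf: int = 30,
                  activator_fraction: float = 0.7, seed: int = 0) -> pd.DataFrame:
    """A synthetic regulon table (tf, target, mode) with disjoint targets."""
    rng = np.random.default_rng(seed)
    rows = []
    for t in range(n_tfs):
        mode = 1 if rng.random() < activator_fraction else -1
        for j in range(targets_per_tf):
            rows.append((f"TF{t + 1}", f"G_{t + 1}_{j + 1}", mode))
    return pd.DataFrame(rows, columns=["tf", "target", "mode"])


def simulate_expression(config: SimulationConfig, regulons: pd.DataFrame,
                        truth: GroundTruth,
                        tf_activities: Optional[pd.DataFrame] = None):
    """Log-scale expression with planted regulon and EMT structure.

    Per-sample TF activity = cluster mean + (latent co-factor for a
    subset of TFs) + N(0, tf_activity_sd); target expression (z-space) =
    mode * activity[tf, sample] + N(0, expr_noise_sd).  The co-factor
    induces within-cluster TF-TF correlation (the structure the network
    stage summarizes).  EMT panel genes get +emt_shift in the designated
    cluster.  ``tf_activities``: tf x cluster mean activity levels;
    default drawn ~ N(0, 1.5).  Returns (expression DataFrame, truth
    updated with tf_activities, sample_activities and emt_cluster).
    """
    from .scores import EMT_PANEL

    if truth.cluster_labels is None:
        raise ValueError("truth must carry cluster labels (run simulate_beta_matrix)")
    rng = np.random.default_rng(config.seed + 2)
    tfs = sorted(regulons["tf"].unique().tolist())
    clusters = sorted(truth.cluster_labels.unique().tolist())
    if tf_activities is None:
        tf_activities = pd.DataFrame(
            rng.normal(0.0, 1.5, size=(len(tfs), len(clusters))),
            index=tfs, columns=clusters,
        )

    samples = list(truth.cluster_labels.index)
    cluster_of = truth.cluster_labels
    loading = (rng.random(len(tfs)) < config.tf_shared_factor_fraction)
    factor = rng.normal(0.0, 1.0, size=len(samples))
    means = np.array(
        [[tf_activities.loc[tf, cluster_of[s]] for s in samples] for tf in tfs]
    )
    sample_activities = pd.DataFrame(
        means
        + loading[:, None] * factor[None, :]
        + rng.normal(0.0, config.tf_activity_sd, size=(len(tfs), len(samples))),
        index=tfs, columns=samples,
    )

    targets = regulons.set_index("target")
    genes = sorted(set(targets.index)) + sorted(EMT_PANEL) + \
        [f"BG_{i}" for i in range(50)]

    data = np.empty((len(genes), len(samples)))
    for gi, gene in enumerate(genes):
        noise = rng.normal(0.0, config.expr_noise_sd, size=len(samples))
        signal = np.zeros(len(samples))
        if gene in targets.index:
            row = targets.loc[gene]
            mode, tf = int(row["mode"]), str(row["tf"])
            signal += mode * sample_activities.loc[tf].to_numpy()
        if gene in EMT_PANEL:
            signal += np.where(
                np.array([cluster_of[s] for s in samples]) == config.emt_shift_cluster,
                config.emt_shift, 0.0,
            )
        data[gi] = signal + noise
    expression = pd.DataFrame(data, index=genes, columns=samples) + 8.0
    truth.tf_activities = tf_activities
    truth.sample_activities = sample_activities
    truth.emt_cluster = config.emt_shift_cluster
    return expression, truth


# ---------------------------------------------------------------------------
# clinical
# ---------------------------------------------------------------------------

def simulate_clinical(config: SimulationConfig, truth: GroundTruth) -> list:
    """Exponential survival per cluster + uniform censoring + Poisson
    mutation burden.

    Each subject is independently censored with probability
    ``censor_rate`` at a Uniform(0, T) time (censor_rate=1 => no events).
    """
    if truth.cluster_labels is None:
        raise ValueError("truth must carry cluster labels")
    rng = np.random.default_rng(config.seed + 3)
    records = []
    hazard_group = {}
    for sample, cluster in truth.cluster_labels.items():
        lam = config.hazard_per_cluster[cluster - 1]
        t = rng.exponential(1.0 / lam)
        event = 1
        if rng.random() < config.censor_rate:
            t = rng.uniform(0.0, t)
            event = 0
        mut = int(rng.poisson(config.mutation_rate_per_cluster[cluster - 1]))
        records.append(
            ClinicalRecord(
                sample_id=sample, time=float(t), event=event,
                group=f"CL{cluster}", mutation_count=mut,
            )
        )
        hazard_group[sample] = cluster
    truth.hazard_group = pd.Series(hazard_group)
    return records
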