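"""CpG Island Methylator Phenotype (CIMP) classification.

Tumor beta values are z-scored against a normal-tissue reference per
probe; a panel gene counts as methylated in a sample when at least
one-third of its informative probes reach Z >= 3; samples are then
labeled CIMP-H / CIMP-L / CIMP-N by panel-specific gene-count
thresholds.  Two canonical panels are built in:

* Weisenberger — CACNA1G, IGF2, NEUROG1, RUNX3, SOCS1
  (H: >=3 genes, L: 1-2, N: 0)
* Ogino — the five above plus CDKN2A, MLH1, CRABP1
  (H: >=5, L: 3-4, N: <3)

Normal-tissue samples are CIMP-N by definition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelDefinition",
    "WEISENBERGER",
    "OGINO",
    "CimpCall",
    "probe_zscores",
    "call_gene_methylation",
    "classify_cimp",
    "cimp_summary",
    "summary_from_counts",
]

SD_FLOOR = 0.01  # floor for degenerate (constant) normal-reference probes


@dataclass(frozen=True)
class PanelDefinition:
    """A CIMP gene panel with (h_min, l_min) methylated-gene thresholds."""

    name: str
    genes: tuple
    h_min: int  # CIMP-H when count >= h_min
    l_min: int  # CIMP-L when l_min <= count < h_min; else CIMP-N


WEISENBERGER = PanelDefinition(
    name="weisenberger",
    genes=("CACNA1G", "IGF2", "NEUROG1", "RUNX3", "SOCS1"),
    h_min=3,
    l_min=1,
)
OGINO = PanelDefinition(
    name="ogino",
    genes=("CACNA1G", "IGF2", "NEUROG1", "RUNX3", "SOCS1",
           "CDKN2A", "MLH1", "CRABP1"),
    h_min=5,
    l_min=3,
)


@dataclass
class CimpCall:
    sample_id: str
    panel: str
    n_methylated_genes: int
    label: str  # CIMP-H | CIMP-L | CIMP-N
    gene_calls: dict  # gene -> bool (informative genes only)


def probe_zscores(tumor_betas: pd.DataFrame, normal_betas: pd.DataFrame,
                  min_normals: int = 2):
    """Z = (beta_tumor - mean_normal) / SD_normal per probe (sample SD).

    Probes with fewer than ``min_normals`` non-missing normal values are
    dropped; probes with zero normal SD get the SD floored at
    ``SD_FLOOR`` and are reported in the returned ``flagged`` list.
    Returns (z_matrix, flagged_probes).
    """
    common = tumor_betas.index.intersection(normal_betas.index)
    normals = normal_betas.loc[common]
    enough = normals.notna().sum(axis=1) >= min_normals
    common = common[enough.to_numpy()]
    normals = normals.loc[common]

    mu = normals.mean(axis=1, skipna=True)
    sd = normals.std(axis=1, ddof=1, skipna=True)
    flagged = list(common[(sd == 0).to_numpy()])
    sd = sd.clip(lower=SD_FLOOR)
    z = tumor_betas.loc[common].sub(mu, axis=0).div(sd, axis=0)
    return z, flagged


def call_gene_methylation(z_matrix: pd.DataFrame, probe_to_gene: dict,
                          z_threshold: float = 3.0,
                          min_fraction: float = 1.0 / 3.0) -> pd.DataFrame:
    """Gene x sample booleans: methylated iff the fraction of informative
    probes with Z >= z_threshold is >= min_fraction (both inclusive).

    Genes with zero informative probes in a sample get NaN (excluded
    from downstream counts).
    """
    genes = sorted(set(probe_to_gene.values()))
    rows = {}
    for gene in genes:
        probes = [p for p, g in probe_to_gene.items() if g == gene]
        probes = [p for p in probes if p in z_matrix.index]
        if not probes:
            rows[gene] = pd.Series(np.nan, index=z_matrix.columns)
            continue
        sub = z_matrix.loc[probes]
        informative = sub.notna().sum(axis=0)
        exceeding = (sub >= z_threshold).sum(axis=0)
        with np.errstate(invalid="ignore"):
            frac = exceeding / informative
        call = (frac >= min_fraction).astype(float)
        call[informative == 0] = np.nan
        rows[gene] = call
    return pd.DataFrame(rows).T  # genes x samples


def classify_cimp(gene_calls: pd.DataFrame, panel: PanelDefinition,
                  normal_samples: Optional[Sequence[str]] = None) -> list:
    """Panel-count classification; normal samples forced CIMP-N."""
    normal_samples = set(normal_samples or [])
    panel_genes = [g for g in panel.genes if g in gene_calls.index]
    calls = []
    for sample in gene_calls.columns:
        col = gene_calls.loc[panel_genes, sample] if panel_genes else pd.Series(dtype=float)
        informative = col.dropna()
        count = int(informative.sum())
        if sample in normal_samples:
            label = "CIMP-N"
        elif count >= panel.h_min:
            label = "CIMP-H"
        elif count >= panel.l_min:
            label = "CIMP-L"
        else:
            label = "CIMP-N"
        calls.append(
            CimpCall(
                sample_id=sample,
                panel=panel.name,
                n_methylated_genes=count,
                label=label,
                gene_calls={g: bool(v) for g, v in informative.items()},
            )
        )
    return calls


def summary_from_counts(n_h: int, n_l: int, n_n: int, n_normals: int = 0) -> dict:
    """Percentages (tumor-only denominator, 1 decimal) and with-normals
    totals from label counts."""
    total_tumor = n_h + n_l + n_n
    if total_tumor == 0:
        return {}
    pct = lambda c: round(100.0 * c / total_tumor, 1)
    return {
        "counts_tumor": {"CIMP-H": n_h, "CIMP-L": n_l, "CIMP-N": n_n},
        "percent_tumor": {
            "CIMP-H": pct(n_h), "CIMP-L": pct(n_l), "CIMP-N": pct(n_n),
        },
        "counts_with_normals": {
            "CIMP-H": n_h, "CIMP-L": n_l, "CIMP-N": n_n + n_normals,
        },
        "n_tumor": total_tumor,
        "n_total": total_tumor + n_normals,
    }


def cimp_summary(calls: list, sample_types: Optional[dict] = None) -> dict:
    """Summaries per panel from CimpCall objects.

    ``sample_types``: sample -> 'tumor' | 'normal'; unlisted samples are
    tumors.  Normals contribute only to the with-normals CIMP-N total.
    """
    if not calls:
        return {}
    sample_types = sample_types or {}
    out = {}
    for panel in sorted({c.panel for c in calls}):
        sub = [c for c in calls if c.panel == panel]
        tumors = [c for c in sub if sample_types.get(c.sample_id, "tumor") == "tumor"]
        n_normals = len(sub) - len(tumors)
        n = {lab: sum(1 for c in tumors if c.label == lab)
             for lab in ("CIMP-H", "CIMP-L", "CIMP-N")}
        out[panel] = summary_from_counts(
            n["CIMP-H"], n["CIMP-L"], n["CIMP-N"], n_normals
        )
    return out
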