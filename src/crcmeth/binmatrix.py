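"""Probe-to-bin aggregation and beta-matrix preprocessing.

Probe-level beta matrices (450K-style, probes x samples) are aggregated
onto a bin grid (typically the consensus DMS intervals): per bin per
sample the mean of non-missing probe betas.  Bins are classified as
methylation gain/loss by a strict +-20 percentage-point rule, matrices
are filtered at >50% missingness (rows first, then columns), and rows
are z-scored ahead of clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import GenomicInterval

__all__ = [
    "BinMatrix",
    "aggregate_probes",
    "classify_bins",
    "filter_missing",
    "zscore_rows",
]


@dataclass
class BinMatrix:
    """Bin x sample beta matrix with provenance (probes per bin)."""

    values: pd.DataFrame  # index: bin ids "chrom:start-end"
    bins: list  # GenomicInterval per retained row
    n_probes: pd.Series = field(default=None)  # probes contributing per bin


def aggregate_probes(beta_matrix: pd.DataFrame, probe_coords: pd.DataFrame,
                     bins) -> BinMatrix:
    """Mean beta of probes falling in each (non-overlapping) bin.

    ``probe_coords``: frame indexed by probe id with chrom/start columns
    (half-open convention; a probe exactly at a bin start is included).
    Probes without coordinates are excluded with a warning; bins with no
    contributing probe are dropped.
    """
    missing_coords = beta_matrix.index.difference(probe_coords.index)
    if len(missing_coords):
        warnings.warn(
            f"{len(missing_coords)} probe(s) without coordinates excluded: "
            f"{list(missing_coords[:5])}..."
        )
    probes = beta_matrix.index.intersection(probe_coords.index)
    coords = probe_coords.loc[probes]

    kept_bins, rows, counts = [], [], []
    for b in bins:
        mask = (
            (coords["chrom"] == b.chrom)
            & (coords["start"] >= b.start)
            & (coords["start"] < b.end)
        )
        members = probes[mask.to_numpy()]
        if len(members) == 0:
            continue
        sub = beta_matrix.loc[members]
        kept_bins.append(b)
        rows.append(sub.mean(axis=0, skipna=True))
        counts.append(len(members))

    if not kept_bins:
        return BinMatrix(
            values=pd.DataFrame(columns=beta_matrix.columns),
            bins=[],
            n_probes=pd.Series(dtype=int),
        )
    ids = [b.id for b in kept_bins]
    values = pd.DataFrame(rows, index=ids)
    return BinMatrix(values=values, bins=kept_bins,
                     n_probes=pd.Series(counts, index=ids))


def classify_bins(matrix: pd.DataFrame, group_a_ids, group_b_ids,
                  threshold: float = 20.0) -> pd.DataFrame:
    """gain / loss / unchanged by strict +-threshold (percent) on
    (mean_B - mean_A) over non-missing entries."""
    mean_a = matrix[list(group_a_ids)].mean(axis=1, skipna=True)
    mean_b = matrix[list(group_b_ids)].mean(axis=1, skipna=True)
    diff = (mean_b - mean_a) * 100.0
    label = pd.Series("unchanged", index=matrix.index)
    label[diff > threshold] = "gain"
    label[diff < -threshold] = "loss"
    return pd.DataFrame({"diff_percent": diff, "label": label})


def filter_missing(matrix: pd.DataFrame,
                   max_missing_fraction: float = 0.5) -> pd.DataFrame:
    """Drop rows then columns with strictly more than the allowed
    fraction of missing values.

    Order is fixed: rows first, then columns, repeated until stable
    (a column drop can push a row back over the threshold), so the
    result never contains a row or column exceeding the rule.
    """
    out = matrix
    while True:
        row_frac = out.isna().mean(axis=1)
        out2 = out.loc[row_frac <= max_missing_fraction]
        col_frac = out2.isna().mean(axis=0)
        out2 = out2.loc[:, col_frac <= max_missing_fraction]
        if out2.shape == out.shape:
            return out2
        out = out2


def zscore_rows(matrix: pd.DataFrame):
    """Row-wise z-scores with sample SD (ddof=1) over non-missing entries.

    Returns (z_matrix, flagged) where ``flagged`` lists constant rows
    (SD 0 or a single observation), which are set to all zeros.
    """
    mean = matrix.mean(axis=1, skipna=True)
    sd = matrix.std(axis=1, ddof=1, skipna=True)
    degenerate = (sd == 0) | sd.isna()
    safe_sd = sd.where(~degenerate, 1.0)
    z = matrix.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[degenerate] = z.loc[degenerate].where(matrix.loc[degenerate].isna(), 0.0)
    return z, list(matrix.index[degenerate])
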