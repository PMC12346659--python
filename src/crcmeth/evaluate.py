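"""End-to-end pipeline helpers and planted-truth evaluation metrics."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .dmr import (
    SampleDesign,
    call_dmrs_bins,
    call_dmrs_tiles,
    intersect_dms,
    tile_counts,
)

__all__ = [
    "design_from_samples",
    "run_consensus_pipeline",
    "dmr_recovery",
    "adjusted_rand_index",
]


def design_from_samples(records_per_sample: dict, rng=None) -> SampleDesign:
    """Build a SampleDesign from LGD_* / HGD_* sample names.

    Sexes alternate F/M within groups (a covariate with variation, as the
    tile caller expects).
    """
    samples = sorted(records_per_sample)
    groups = ["HGD" if s.startswith("HGD") else "LGD" for s in samples]
    sexes = ["F" if i % 2 == 0 else "M" for i in range(len(samples))]
    return SampleDesign(sample_ids=samples, group=groups, sex=sexes,
                        group_b="HGD")


def run_consensus_pipeline(records_per_sample: dict, design: SampleDesign = None,
                           tile_size: int = 1000, bin_size: int = 100,
                           q_cutoff: float = 0.01, diff_cutoff: float = 25.0,
                           p_cutoff: float = 0.01):
    """Tiles + bins + consensus in one call.

    Returns dict with 'tiles', 'bins', 'consensus' DmrRecord lists.
    """
    if design is None:
        design = design_from_samples(records_per_sample)
    tiled = tile_counts(records_per_sample, tile_size=tile_size, step=tile_size)
    tiles = call_dmrs_tiles(tiled, design, q_cutoff=q_cutoff,
                            diff_cutoff=diff_cutoff)
    bins = call_dmrs_bins(records_per_sample, design, bin_size=bin_size,
                          step=bin_size, p_cutoff=p_cutoff)
    consensus = intersect_dms(tiles, bins)
    return {"tiles": tiles, "bins": bins, "consensus": consensus}


def dmr_recovery(consensus: list, planted: list) -> dict:
    """Recall/precision of consensus regions against planted DMRs.

    A planted DMR is recovered when some consensus region overlaps it
    with matching direction; a consensus region is a true positive when
    it overlaps a planted DMR of the same direction.
    """
    if not planted:
        return {"recall": np.nan, "precision": np.nan,
                "n_consensus": len(consensus)}
    recovered = 0
    for interval, direction in planted:
        if any(c.direction == direction and c.interval.overlaps(interval)
               for c in consensus):
            recovered += 1
    recall = recovered / len(planted)
    if consensus:
        tp = sum(
            1 for c in consensus
            if any(c.direction == d and c.interval.overlaps(iv)
                   for iv, d in planted)
        )
        precision = tp / len(consensus)
    else:
        precision = np.nan
    return {"recall": recall, "precision": precision,
            "n_consensus": len(consensus)}


def adjusted_rand_index(labels_a, labels_b) -> float:
    """ARI between two partitions (delegates to scikit-learn)."""
    from sklearn.metrics import adjusted_rand_score

    a = pd.Series(labels_a)
    b = pd.Series(labels_b).reindex(a.index)
    return float(adjusted_rand_score(a.to_numpy(), b.to_numpy()))
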