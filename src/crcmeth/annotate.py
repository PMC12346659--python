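"""Genomic-feature and CpG-context annotation of DMS regions.

Each region gets exactly one feature label (precedence: promoter >
5'UTR > exon > intron > enhancer > upstream_1to5kb > intergenic) and one
CpG-context label (island / shore / open_sea, shore = within 2 kb of an
island).  Regions are linked to genes within a 5 kb window.
"""

from __future__ import annotations

from collections import defaultdict

import pandas as pd
from intervaltree import IntervalTree

from .io_formats import GenomicInterval

__all__ = [
    "FEATURE_PRECEDENCE",
    "annotate_features",
    "annotate_cpg_context",
    "link_genes",
    "feature_distribution",
]

# most regulatory-specific class wins when a region overlaps several
FEATURE_PRECEDENCE = [
    "promoter",
    "5'UTR",
    "exon",
    "intron",
    "enhancer",
    "upstream_1to5kb",
    "intergenic",
]
_RANK = {name: i for i, name in enumerate(FEATURE_PRECEDENCE)}

SHORE_WIDTH = 2000  # bp from an island edge that still counts as shore


def _build_trees(intervals) -> dict:
    trees: dict = defaultdict(IntervalTree)
    for iv in intervals:
        trees[iv.chrom].addi(iv.start, iv.end, iv)
    return trees


def annotate_features(regions, feature_intervals) -> pd.DataFrame:
    """Assign one feature class per region by overlap + precedence.

    ``feature_intervals``: GenomicIntervals whose ``name`` is the feature
    class.  Unknown classes raise; non-overlapping regions are intergenic.
    """
    unknown = sorted(
        {iv.name for iv in feature_intervals} - set(FEATURE_PRECEDENCE)
    )
    if unknown:
        raise ValueError(f"unknown feature classes in annotation: {unknown}")
    trees = _build_trees(feature_intervals)
    rows = []
    for region in regions:
        hits = trees[region.chrom].overlap(region.start, region.end)
        classes = {h.data.name for h in hits}
        feature = min(classes, key=_RANK.get) if classes else "intergenic"
        rows.append({"region": region.id, "feature": feature})
    return pd.DataFrame(rows)


def annotate_cpg_context(regions, islands, shore_width: int = SHORE_WIDTH) -> pd.DataFrame:
    """island if overlapping an island, shore if within ``shore_width`` bp,
    else open_sea."""
    trees = _build_trees(islands)
    rows = []
    for region in regions:
        tree = trees.get(region.chrom)
        if tree is not None and tree.overlap(region.start, region.end):
            context = "island"
        elif tree is not None and tree.overlap(
            region.start - shore_width, region.end + shore_width
        ):
            context = "shore"
        else:
            context = "open_sea"
        rows.append({"region": region.id, "cpg_context": context})
    return pd.DataFrame(rows)


def link_genes(regions, gene_intervals, window: int = 5000) -> pd.DataFrame:
    """Link every gene within ``window`` bp (gap between half-open
    intervals; 0 when overlapping) of each region."""
    trees = _build_trees(gene_intervals)
    rows = []
    for region in regions:
        tree = trees.get(region.chrom)
        if tree is None:
            continue
        for hit in tree.overlap(region.start - window, region.end + window):
            gene: GenomicInterval = hit.data
            gap = region.gap_to(gene)
            if gap is not None and gap <= window:
                rows.append(
                    {"region": region.id, "gene": gene.name, "distance": gap}
                )
    df = pd.DataFrame(rows, columns=["region", "gene", "distance"])
    return df.sort_values(["region", "distance", "gene"]).reset_index(drop=True)


def feature_distribution(annotations: pd.DataFrame, direction_labels) -> pd.DataFrame:
    """Percent of regions per feature per direction (rows sum to 100).

    ``annotations``: frame with region/feature columns (from
    :func:`annotate_features`); ``direction_labels``: mapping or Series
    region id -> hyper/hypo.
    """
    if annotations.empty:
        return pd.DataFrame()
    df = annotations.copy()
    df["direction"] = df["region"].map(dict(direction_labels))
    counts = df.groupby(["direction", "feature"]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0) * 100.0
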