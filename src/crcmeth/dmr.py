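"""Consensus differential-methylation-signature (DMS) calling.

Two independent region callers over per-CpG methylation counts from two
sample groups (LGD vs HGD dysplasia in the motivating analysis):

* **tile caller** — 1000 bp non-overlapping tiles; per-sample counts
  summed per tile after dropping CpGs below a minimum coverage; binomial
  logistic regression of methylated proportion on group (+ sex
  covariate), likelihood-ratio p-value for the group term,
  Benjamini-Hochberg q-values; tiles pass at q < 0.01 and
  |methylation difference| >= 25 percentage points.
* **bin caller** — 100 bp bins with counts pooled within group; bins kept
  only with >= 4 CpGs each covered by >= 4 reads in both groups; two-sided
  Fisher exact test on the pooled 2x2 table at p < 0.01.

The consensus DMS keeps runs of adjacent significant bins that overlap a
significant tile with the same direction.  Direction convention:
``hyper`` = hypermethylated in group B (HGD) relative to group A (LGD);
``meth_diff`` = (mean beta B - mean beta A) x 100.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .io_formats import GenomicInterval

__all__ = [
    "DmrRecord",
    "SampleDesign",
    "compute_beta",
    "tile_counts",
    "call_dmrs_tiles",
    "call_dmrs_bins",
    "intersect_dms",
]


@dataclass(frozen=True)
class DmrRecord:
    """One differentially methylated region from one caller."""

    interval: GenomicInterval
    meth_diff: float  # percent, group B - group A
    p_value: float
    q_value: float
    direction: str  # hyper | hypo, group B relative to group A
    caller: str  # tile | bin | consensus
    coverage: int = 0  # pooled reads (bin caller; used for weighting)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0) or not (0.0 <= self.q_value <= 1.0):
            raise ValueError("p and q must be in [0, 1]")
        if self.direction not in {"hyper", "hypo"}:
            raise ValueError(f"direction must be hyper/hypo, got {self.direction}")
        expected = "hyper" if self.meth_diff >= 0 else "hypo"
        if self.meth_diff != 0 and self.direction != expected:
            raise ValueError("direction inconsistent with sign of meth_diff")


@dataclass
class SampleDesign:
    """Sample-to-group assignment with a sex covariate for the tile caller."""

    sample_ids: Sequence[str]
    group: Sequence[str]  # two levels, e.g. LGD / HGD; second level = "B"
    sex: Optional[Sequence[str]] = None
    group_b: Optional[str] = None  # which level plays HGD; default: sorted()[-1]

    def __post_init__(self) -> None:
        if len(self.sample_ids) != len(self.group):
            raise ValueError("sample_ids and group length mismatch")
        levels = sorted(set(self.group))
        if len(levels) != 2:
            raise ValueError(f"exactly two groups required, got {levels}")
        if self.group_b is None:
            self.group_b = levels[-1]
        counts = pd.Series(list(self.group)).value_counts()
        if (counts < 2).any():
            raise ValueError("need >=2 samples per group for the tile caller")

    def is_group_b(self, sample: str) -> bool:
        idx = list(self.sample_ids).index(sample)
        return list(self.group)[idx] == self.group_b


def compute_beta(count_methylated: int, count_unmethylated: int) -> Optional[float]:
    """beta = methylated / (methylated + unmethylated); None at zero coverage."""
    coverage = count_methylated + count_unmethylated
    if coverage == 0:
        return None
    return count_methylated / coverage


def _records_frame(records) -> pd.DataFrame:
    """CpG records -> frame with 0-based start and counts (CpG context only)."""
    rows = [
        (r.chrom, r.start, r.count_methylated, r.coverage)
        for r in records
        if r.is_cpg
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "meth", "cov"])


def _window_counts(records_per_sample, size, step, cpg_filter) -> pd.DataFrame:
    """Sum per-sample counts into windows anchored at 0 per chromosome.

    ``cpg_filter(frame) -> bool mask`` decides per-sample CpG inclusion.
    Returns a frame indexed by (chrom, win_start) with per-sample
    (meth, total) column MultiIndex; windows absent for a sample are NaN.
    """
    if step != size:
        raise NotImplementedError("only non-overlapping windows (step == size)")
    pieces = {}
    for sample, records in records_per_sample.items():
        df = _records_frame(records)
        df = df[cpg_filter(df)]
        if df.empty:
            pieces[sample] = pd.DataFrame(columns=["meth", "total"])
            continue
        win = (df["start"] // size) * size
        grouped = df.groupby([df["chrom"], win]).agg(
            meth=("meth", "sum"), total=("cov", "sum")
        )
        grouped.index.names = ["chrom", "win_start"]
        pieces[sample] = grouped
    out = pd.concat(pieces, axis=1)  # columns: (sample, meth/total)
    out.index.names = ["chrom", "win_start"]
    return out.sort_index()


def tile_counts(records_per_sample: dict, tile_size: int = 1000,
                step: int = 1000, min_coverage: int = 4) -> pd.DataFrame:
    """Aggregate per-sample CpG counts into tiles.

    CpGs with per-sample coverage < ``min_coverage`` are excluded before
    summing; a tile with no surviving CpG in a sample is missing (NaN)
    for that sample.
    """
    return _window_counts(
        records_per_sample, tile_size, step,
        cpg_filter=lambda df: df["cov"] >= min_coverage,
    )


def _lrt_group_pvalue(meth, unmeth, group, sex):
    """Likelihood-ratio p for the group term in a binomial GLM."""
    endog = np.column_stack([meth, unmeth])
    exog_cols = [np.ones_like(group, dtype=float), group.astype(float)]
    if sex is not None and len(np.unique(sex)) > 1:
        exog_cols.append(pd.factorize(sex)[0].astype(float))
    exog_full = np.column_stack(exog_cols)
    exog_null = np.delete(exog_full, 1, axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = sm.GLM(endog, exog_full, family=sm.families.Binomial()).fit()
        null = sm.GLM(endog, exog_null, family=sm.families.Binomial()).fit()
    lr = 2.0 * (full.llf - null.llf)
    lr = max(lr, 0.0)
    return stats.chi2.sf(lr, df=1)


def call_dmrs_tiles(tiled_counts: pd.DataFrame, design: SampleDesign,
                    q_cutoff: float = 0.01, diff_cutoff: float = 25.0) -> list:
    """Call DMRs on tiled counts via binomial regression + BH.

    Tiles are tested only when every group has >=1 sample with data; the
    sex covariate is dropped automatically when constant.  Degenerate
    fits are skipped with a warning.  Returned records pass q < q_cutoff
    and |meth_diff| >= diff_cutoff (percent).
    """
    samples = list(design.sample_ids)
    group_b = np.array([design.is_group_b(s) for s in samples])
    sex = np.array(list(design.sex)) if design.sex is not None else None

    tested = []  # (index key, meth_diff, p)
    for key, row in tiled_counts.iterrows():
        meth = np.array([row.get((s, "meth"), np.nan) for s in samples], dtype=float)
        total = np.array([row.get((s, "total"), np.nan) for s in samples], dtype=float)
        have = ~np.isnan(total) & (total > 0)
        if not (have & group_b).any() or not (have & ~group_b).any():
            continue
        m, t, g = meth[have], total[have], group_b[have]
        s = sex[have] if sex is not None else None
        betas = m / t
        diff = 100.0 * (betas[g].mean() - betas[~g].mean())
        try:
            p = _lrt_group_pvalue(m, t - m, g, s)
        except (PerfectSeparationError, np.linalg.LinAlgError, ValueError) as exc:
            warnings.warn(f"tile {key}: degenerate fit skipped ({exc})")
            continue
        if not np.isfinite(p):
            warnings.warn(f"tile {key}: non-finite p, skipped")
            continue
        tested.append((key, diff, p))

    if not tested:
        return []
    pvals = np.array([t[2] for t in tested])
    qvals = multipletests(pvals, method="fdr_bh")[1]

    records = []
    tile_size = None
    for (key, diff, p), q in zip(tested, qvals):
        chrom, start = key
        if tile_size is None:
            starts = tiled_counts.index.get_level_values("win_start")
            diffs = np.diff(np.unique(starts))
            tile_size = int(diffs.min()) if len(diffs) else 1000
        if q < q_cutoff and abs(diff) >= diff_cutoff:
            records.append(
                DmrRecord(
                    interval=GenomicInterval(chrom, int(start), int(start) + tile_size),
                    meth_diff=float(diff),
                    p_value=float(p),
                    q_value=float(q),
                    direction="hyper" if diff >= 0 else "hypo",
                    caller="tile",
                )
            )
    return records


def call_dmrs_bins(records_per_sample: dict, design: SampleDesign,
                   bin_size: int = 100, step: int = 100,
                   min_cytosines: int = 4, min_reads: int = 4,
                   p_cutoff: float = 0.01) -> list:
    """Call DMRs on pooled 100 bp bins via two-sided Fisher exact tests.

    Counts are pooled within group per CpG; a CpG qualifies when its
    pooled coverage is >= ``min_reads`` in *both* groups, and a bin is
    tested only with >= ``min_cytosines`` qualifying CpGs.  All tested
    bins with p < p_cutoff are returned (BH q stored for reference; the
    filter is on raw p).
    """
    if step != bin_size:
        raise NotImplementedError("only non-overlapping bins (step == bin_size)")
    samples = list(design.sample_ids)
    pooled = {}
    for grp_is_b in (False, True):
        members = [s for s in samples if design.is_group_b(s) == grp_is_b]
        frames = [_records_frame(records_per_sample[s]) for s in members]
        allf = pd.concat(frames, ignore_index=True)
        pooled[grp_is_b] = allf.groupby(["chrom", "start"]).sum()

    both = pooled[False].join(pooled[True], lsuffix="_a", rsuffix="_b", how="inner")
    both = both[(both["cov_a"] >= min_reads) & (both["cov_b"] >= min_reads)]
    if both.empty:
        return []
    both = both.reset_index()
    both["bin"] = (both["start"] // bin_size) * bin_size

    tested = []
    for (chrom, bin_start), sub in both.groupby(["chrom", "bin"]):
        if len(sub) < min_cytosines:
            continue
        ma, ca = int(sub["meth_a"].sum()), int(sub["cov_a"].sum())
        mb, cb = int(sub["meth_b"].sum()), int(sub["cov_b"].sum())
        table = [[mb, cb - mb], [ma, ca - ma]]
        p = stats.fisher_exact(table, alternative="two-sided")[1]
        diff = 100.0 * (mb / cb - ma / ca)
        tested.append((chrom, int(bin_start), diff, p, ca + cb))

    if not tested:
        return []
    qvals = multipletests(np.array([t[3] for t in tested]), method="fdr_bh")[1]
    records = []
    for (chrom, bin_start, diff, p, cov), q in zip(tested, qvals):
        if p < p_cutoff:
            records.append(
                DmrRecord(
                    interval=GenomicInterval(chrom, bin_start, bin_start + bin_size),
                    meth_diff=float(diff),
                    p_value=float(p),
                    q_value=float(min(q, 1.0)),
                    direction="hyper" if diff >= 0 else "hypo",
                    caller="bin",
                    coverage=int(cov),
                )
            )
    return records


def intersect_dms(tile_dmrs: list, bin_dmrs: list) -> list:
    """Intersect the two callers into the consensus DMS.

    A consensus region is each maximal run of adjacent (gap 0)
    significant bins with a common direction that overlaps >= 1
    significant tile of the same direction by >= 1 bp.  The record
    carries the merged interval, a coverage-weighted mean of bin
    methylation differences, and the minimum bin p/q.
    Direction-discordant overlaps are dropped (counted via the returned
    records' complement; see the driver reports).
    """
    if not tile_dmrs or not bin_dmrs:
        return []
    tiles_by_chrom: dict = {}
    for t in tile_dmrs:
        tiles_by_chrom.setdefault(t.interval.chrom, []).append(t)

    # merge adjacent same-direction bins
    runs = []
    key = lambda r: (r.interval.chrom, r.direction, r.interval.start)
    for (chrom, direction), group in _groupby_sorted(bin_dmrs, key):
        current = [group[0]]
        for b in group[1:]:
            if b.interval.start == current[-1].interval.end:
                current.append(b)
            else:
                runs.append((chrom, direction, current))
                current = [b]
        runs.append((chrom, direction, current))

    consensus = []
    for chrom, direction, bins in runs:
        merged = GenomicInterval(chrom, bins[0].interval.start, bins[-1].interval.end)
        hit = any(
            t.direction == direction and t.interval.overlaps(merged)
            for t in tiles_by_chrom.get(chrom, [])
        )
        if not hit:
            continue
        weights = np.array([max(b.coverage, 1) for b in bins], dtype=float)
        diffs = np.array([b.meth_diff for b in bins])
        meth_diff = float(np.average(diffs, weights=weights))
        if (meth_diff >= 0) != (direction == "hyper"):
            # weighted mean flipped sign relative to member bins; keep the
            # member direction (all bins in a run agree) and clamp the diff
            meth_diff = math.copysign(abs(meth_diff), 1 if direction == "hyper" else -1)
        consensus.append(
            DmrRecord(
                interval=merged,
                meth_diff=meth_diff,
                p_value=float(min(b.p_value for b in bins)),
                q_value=float(min(b.q_value for b in bins)),
                direction=direction,
                caller="consensus",
                coverage=int(weights.sum()),
            )
        )
    consensus.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return consensus


def _groupby_sorted(records, key):
    """Group DmrRecords by (chrom, direction), sorted by start within."""
    from itertools import groupby

    ordered = sorted(records, key=key)
    for (chrom, direction), grp in groupby(ordered, key=lambda r: key(r)[:2]):
        yield (chrom, direction), list(grp)
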