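"""Tile caller, bin caller, and consensus intersection.

Oracles: the tile caller's likelihood-ratio p-value is checked against a
closed-form binomial LRT (group-only model has pooled-proportion MLEs);
the bin caller's Fisher p against direct hypergeometric enumeration.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from crcmeth.dmr import (
    DmrRecord,
    SampleDesign,
    call_dmrs_bins,
    call_dmrs_tiles,
    compute_beta,
    intersect_dms,
    tile_counts,
)
from crcmeth.evaluate import run_consensus_pipeline
from crcmeth.io_formats import CytosineRecord, GenomicInterval


def rec(pos, meth, unmeth, chrom="chr1", context="CpG"):
    return CytosineRecord(chrom, pos, "+", meth, unmeth, context)


# ---------------------------------------------------------------------------
# beta
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("m,u,expected", [(3, 1, 0.75), (0, 5, 0.0), (5, 0, 1.0)])
def test_compute_beta_examples(m, u, expected):
    assert compute_beta(m, u) == expected


def test_compute_beta_zero_coverage_is_missing():
    assert compute_beta(0, 0) is None


@given(st.integers(0, 10_000), st.integers(0, 10_000))
@settings(deadline=None, max_examples=200)
def test_compute_beta_in_unit_interval(m, u):
    beta = compute_beta(m, u)
    if m + u == 0:
        assert beta is None
    else:
        assert 0.0 <= beta <= 1.0


# ---------------------------------------------------------------------------
# tiling
# ---------------------------------------------------------------------------

def test_tile_window_arithmetic():
    records = {"s1": [rec(10, 3, 1), rec(990, 2, 2)]}
    tiled = tile_counts(records, min_coverage=1)
    assert list(tiled.index) == [("chr1", 0)]
    assert tiled.loc[("chr1", 0), ("s1", "meth")] == 5
    assert tiled.loc[("chr1", 0), ("s1", "total")] == 8


def test_tile_minimum_coverage_excludes_cpg():
    records = {"s1": [rec(10, 2, 1), rec(20, 3, 1)]}  # coverage 3 and 4
    tiled = tile_counts(records, min_coverage=4)
    assert tiled.loc[("chr1", 0), ("s1", "total")] == 4  # only the second CpG


def test_tile_boundary_position_1000_lands_in_first_tile():
    # 1-based pos 1000 -> internal start 999 -> tile [0, 1000)
    records = {"s1": [rec(1000, 4, 0)], "s2": [rec(1001, 4, 0)]}
    tiled = tile_counts(records, min_coverage=1)
    assert tiled.loc[("chr1", 0), ("s1", "total")] == 4
    assert tiled.loc[("chr1", 1000), ("s2", "total")] == 4


def make_design(n_a=6, n_b=6, sex=None):
    ids = [f"LGD_{i}" for i in range(n_a)] + [f"HGD_{i}" for i in range(n_b)]
    groups = ["LGD"] * n_a + ["HGD"] * n_b
    return SampleDesign(sample_ids=ids, group=groups, sex=sex, group_b="HGD")


def tiled_frame(meth_a, tot_a, meth_b, tot_b):
    """One tile; per-sample counts for groups A (LGD) and B (HGD)."""
    design = make_design(len(meth_a), len(meth_b))
    data = {}
    for i, (m, t) in enumerate(zip(meth_a, tot_a)):
        data[(f"LGD_{i}", "meth")], data[(f"LGD_{i}", "total")] = m, t
    for i, (m, t) in enumerate(zip(meth_b, tot_b)):
        data[(f"HGD_{i}", "meth")], data[(f"HGD_{i}", "total")] = m, t
    frame = pd.DataFrame(data, index=pd.MultiIndex.from_tuples(
        [("chr1", 0)], names=["chrom", "win_start"]))
    return frame, design


def binomial_lrt_oracle(meth_a, tot_a, meth_b, tot_b):
    """Closed-form LRT for group-only binomial regression: group MLEs are
    the pooled within-group proportions."""
    def loglik(ms, ts, p):
        if p <= 0 or p >= 1:
            p = min(max(p, 1e-12), 1 - 1e-12)
        return sum(m * math.log(p) + (t - m) * math.log(1 - p)
                   for m, t in zip(ms, ts))

    pa = sum(meth_a) / sum(tot_a)
    pb = sum(meth_b) / sum(tot_b)
    p0 = (sum(meth_a) + sum(meth_b)) / (sum(tot_a) + sum(tot_b))
    lr = 2 * (loglik(meth_a, tot_a, pa) + loglik(meth_b, tot_b, pb)
              - loglik(meth_a + meth_b, tot_a + tot_b, p0))
    return stats.chi2.sf(max(lr, 0.0), df=1)


def test_tile_caller_identical_groups_not_significant():
    meth, tot = [10] * 6, [30] * 6
    frame, design = tiled_frame(meth, tot, meth, tot)
    assert call_dmrs_tiles(frame, design) == []


def test_tile_caller_pvalue_matches_likelihood_ratio_oracle():
    meth_a, tot_a = [6] * 6, [30] * 6    # beta 0.2
    meth_b, tot_b = [18] * 6, [30] * 6   # beta 0.6
    frame, design = tiled_frame(meth_a, tot_a, meth_b, tot_b)
    records = call_dmrs_tiles(frame, design)
    assert len(records) == 1
    r = records[0]
    assert r.direction == "hyper" and r.q_value < 0.01
    assert r.meth_diff == pytest.approx(40.0)
    expected_p = binomial_lrt_oracle(meth_a, tot_a, meth_b, tot_b)
    assert r.p_value == pytest.approx(expected_p, rel=1e-6)


def test_tile_caller_effect_size_filter():
    # strong evidence but only ~13% difference -> filtered by the 25% rule
    meth_a, tot_a = [100] * 6, [500] * 6   # 0.20
    meth_b, tot_b = [165] * 6, [500] * 6   # 0.33
    frame, design = tiled_frame(meth_a, tot_a, meth_b, tot_b)
    assert call_dmrs_tiles(frame, design) == []
    assert call_dmrs_tiles(frame, design, diff_cutoff=10.0) != []


# ---------------------------------------------------------------------------
# bin caller
# ---------------------------------------------------------------------------

def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by direct enumeration of the hypergeometric
    distribution with fixed margins."""
    n1, n2, k = a + b, c + d, a + c
    total = math.comb(n1 + n2, k)
    obs = math.comb(n1, a) * math.comb(n2, c)
    p = 0
    for x in range(max(0, k - n2), min(k, n1) + 1):
        mass = math.comb(n1, x) * math.comb(n2, k - x)
        if mass <= obs * (1 + 1e-9):
            p += mass
    return p / total


def cohort_from_pooled(meth_a, cov_a, meth_b, cov_b, n_cpgs=4, start=101):
    """Per-sample records realizing the pooled per-group 2x2 table:
    each group = one sample holding the pooled counts, split over
    ``n_cpgs`` CpGs (pooling is what the bin caller tests)."""
    def split(total, parts):
        base, remainder = divmod(total, parts)
        return [base + (1 if i < remainder else 0) for i in range(parts)]

    records = {}
    for label, meth, cov in (("LGD", meth_a, cov_a), ("HGD", meth_b, cov_b)):
        ms, cs = split(meth, n_cpgs), split(cov, n_cpgs)
        recs = [rec(start + i * 10, m, c - m) for i, (m, c) in enumerate(zip(ms, cs))]
        records[f"{label}_0"] = recs
        records[f"{label}_1"] = [rec(r.pos, 0, 0, context="CHH") for r in recs]
    return records


def bins_design():
    return SampleDesign(
        sample_ids=["LGD_0", "LGD_1", "HGD_0", "HGD_1"],
        group=["LGD", "LGD", "HGD", "HGD"], group_b="HGD",
    )


def test_bin_caller_balanced_table_p_one():
    records = cohort_from_pooled(50, 100, 50, 100)
    out = call_dmrs_bins(records, bins_design(), p_cutoff=1.1)
    assert len(out) == 1
    assert out[0].p_value == pytest.approx(1.0)
    assert out[0].meth_diff == pytest.approx(0.0)


def test_bin_caller_p_matches_hypergeometric_enumeration():
    records = cohort_from_pooled(50, 100, 90, 100)
    out = call_dmrs_bins(records, bins_design(), p_cutoff=1.1)
    assert len(out) == 1
    expected = fisher_oracle(90, 10, 50, 50)
    assert out[0].p_value == pytest.approx(expected, rel=1e-9)
    assert out[0].direction == "hyper"


def test_bin_caller_min_cytosine_rule():
    records = cohort_from_pooled(90, 100, 50, 100, n_cpgs=3)
    assert call_dmrs_bins(records, bins_design(), p_cutoff=1.1) == []


def test_bin_caller_min_reads_per_cytosine():
    # 4 CpGs but one has pooled coverage 3 in group A -> bin has only 3
    records = cohort_from_pooled(40, 100, 40, 100)
    weak = records["LGD_0"][0]
    records["LGD_0"][0] = rec(weak.pos, 1, 2)  # pooled coverage 3 < 4
    assert call_dmrs_bins(records, bins_design(), p_cutoff=1.1) == []


# ---------------------------------------------------------------------------
# consensus intersection
# ---------------------------------------------------------------------------

def dmr(chrom, start, end, diff, direction, caller, p=1e-6, cov=100):
    return DmrRecord(
        interval=GenomicInterval(chrom, start, end), meth_diff=diff,
        p_value=p, q_value=p, direction=direction, caller=caller, coverage=cov,
    )


def test_consensus_merges_adjacent_concordant_bins():
    tiles = [dmr("chr1", 0, 1000, 40.0, "hyper", "tile")]
    bins = [
        dmr("chr1", 100, 200, 35.0, "hyper", "bin"),
        dmr("chr1", 200, 300, 45.0, "hyper", "bin"),
    ]
    out = intersect_dms(tiles, bins)
    assert len(out) == 1
    region = out[0]
    assert (region.interval.start, region.interval.end) == (100, 300)
    assert region.caller == "consensus" and region.direction == "hyper"
    assert region.meth_diff == pytest.approx(40.0)  # equal-coverage mean


def test_consensus_drops_discordant_direction():
    tiles = [dmr("chr1", 0, 1000, 40.0, "hyper", "tile")]
    bins = [dmr("chr1", 100, 200, -35.0, "hypo", "bin")]
    assert intersect_dms(tiles, bins) == []


def test_consensus_empty_without_tiles():
    bins = [dmr("chr1", 100, 200, 35.0, "hyper", "bin")]
    assert intersect_dms([], bins) == []
    assert intersect_dms(bins, []) == []


def test_consensus_subset_and_disjoint_on_simulated_cohort(count_cohort):
    _, records, _ = count_cohort
    result = run_consensus_pipeline(records)
    consensus = result["consensus"]
    # every consensus region overlaps a significant tile and a significant bin
    for region in consensus:
        assert any(region.interval.overlaps(t.interval) for t in result["tiles"])
        assert any(region.interval.overlaps(b.interval) for b in result["bins"])
    # consensus regions never overlap each other
    for i, a in enumerate(consensus):
        for b in consensus[i + 1:]:
            assert not a.interval.overlaps(b.interval)


def test_group_mean_beta_equals_pooled_ratio_with_shared_coverage():
    # equal per-sample coverage -> mean of per-sample betas == pooled ratio
    meth_a, tot_a = [5, 10, 15], [30, 30, 30]
    mean_beta = np.mean([m / t for m, t in zip(meth_a, tot_a)])
    pooled = sum(meth_a) / sum(tot_a)
    assert mean_beta == pytest.approx(pooled)
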