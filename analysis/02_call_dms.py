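#!/usr/bin/env python
"""Call the consensus differential methylation signature (DMS) on the
tissue cohort: 1 kb logistic-regression tiles (q<0.01, |diff|>=25%) and
100 bp Fisher-exact bins (p<0.01) intersected with direction agreement,
then annotate the consensus regions and report recovery of the planted
DMRs.
"""

import warnings
from pathlib import Path

import pandas as pd

from crcmeth.annotate import annotate_cpg_context, feature_distribution
from crcmeth.evaluate import dmr_recovery, run_consensus_pipeline
from crcmeth.io_formats import read_bed, read_cytosine_report, write_bed

DATA = Path("scratch/data")
OUT = Path("results")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    reports = sorted((DATA / "cytosine_reports").glob("*.CpG_report.txt"))
    records = {p.name.split(".")[0]: read_cytosine_report(p) for p in reports}
    planted_bed = read_bed(DATA / "planted_dmrs.bed")
    planted = [(iv, extra) for iv, extra in zip(
        planted_bed,
        pd.read_csv(DATA / "planted_dmrs.bed", sep="\t", header=None).iloc[:, 6],
    )]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_consensus_pipeline(records)
    tiles, bins, consensus = result["tiles"], result["bins"], result["consensus"]
    print(f"significant tiles: {len(tiles)}; significant bins: {len(bins)}; "
          f"consensus DMS regions: {len(consensus)}")

    write_bed(
        [r.interval for r in consensus], OUT / "dms_regions.bed",
        extra_columns=[
            (f"{r.meth_diff:.2f}", f"{r.p_value:.3g}", f"{r.q_value:.3g}",
             r.direction, r.caller)
            for r in consensus
        ],
    )

    metrics = dmr_recovery(consensus, planted)
    print(f"planted-DMR recovery: recall {metrics['recall']:.2f}, "
          f"precision {metrics['precision']:.2f}")

    # CpG-context annotation against the island-like region cores
    islands = [iv for iv, _ in planted]
    regions = [r.interval for r in consensus]
    ctx = annotate_cpg_context(regions, islands)
    directions = {r.interval.id: r.direction for r in consensus}
    table = feature_distribution(
        ctx.rename(columns={"cpg_context": "feature"}), directions
    )
    table.to_csv(OUT / "dms_context_distribution.tsv", sep="\t")
    print("context distribution (% per direction):")
    print(table.round(1).to_string())


if __name__ == "__main__":
    main()
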