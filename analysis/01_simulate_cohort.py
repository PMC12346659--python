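#!/usr/bin/env python
"""Generate the synthetic study inputs and write them in their on-disk
dialects: per-sample Bismark-style cytosine reports for the 6 LGD / 9
HGD tissue cohort, a probe-level beta matrix with coordinates for the
4-cluster TCGA-like cohort (plus normal reference samples), a regulon
table, log-scale expression, and a clinical table.

Everything downstream (02-06) reads these files, so the whole analysis
runs without any external download.
"""

from pathlib import Path

import pandas as pd

from crcmeth.io_formats import (
    write_bed,
    write_clinical,
    write_cytosine_report,
    write_matrix,
    write_regulons,
)
from crcmeth.synthetic import (
    SimulationConfig,
    make_regulons,
    simulate_beta_matrix,
    simulate_clinical,
    simulate_count_data,
    simulate_expression,
)

SEED = 20260101
OUT = Path("scratch/data")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimulationConfig(seed=SEED)

    records, truth = simulate_count_data(config)
    reports = OUT / "cytosine_reports"
    reports.mkdir(exist_ok=True)
    for sample, recs in records.items():
        write_cytosine_report(recs, reports / f"{sample}.CpG_report.txt")
    write_bed(
        [iv for iv, _ in truth.planted_dmrs], OUT / "planted_dmrs.bed",
        extra_columns=[(d,) for _, d in truth.planted_dmrs],
    )
    print(f"wrote {len(records)} cytosine reports "
          f"({len(truth.planted_dmrs)} planted DMRs)")

    beta, coords, truth_beta = simulate_beta_matrix(config)
    write_matrix(beta, OUT / "beta_matrix.tsv")
    coords.reset_index(names="probe").to_csv(
        OUT / "probe_coords.tsv", sep="\t", index=False
    )
    truth_beta.cluster_labels.rename("cluster").to_csv(
        OUT / "true_clusters.tsv", sep="\t"
    )
    pd.Series(truth_beta.signature_probes, name="probe").to_csv(
        OUT / "signature_probes.tsv", sep="\t", index=False
    )
    print(f"wrote beta matrix {beta.shape} "
          f"({len(truth_beta.normal_ref_samples)} normal references)")

    regulons = make_regulons(n_tfs=10, targets_per_tf=30, seed=SEED)
    write_regulons(regulons, OUT / "regulons.tsv")
    expression, truth_beta = simulate_expression(config, regulons, truth_beta)
    write_matrix(expression, OUT / "expression.tsv")
    print(f"wrote expression {expression.shape} "
          f"(EMT shift planted in cluster {truth_beta.emt_cluster})")

    clinical = simulate_clinical(config, truth_beta)
    write_clinical(clinical, OUT / "clinical.tsv")
    print(f"wrote clinical table for {len(clinical)} samples")


if __name__ == "__main__":
    main()
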