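import numpy as np
import pandas as pd
import pytest

from crcmeth.scores import EMT_PANEL
from crcmeth.synthetic import (
    SimulationConfig,
    make_regulons,
    simulate_beta_matrix,
    simulate_clinical,
    simulate_count_data,
    simulate_expression,
)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(effect_delta=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(coverage_mean=0)
    with pytest.raises(ValueError):
        SimulationConfig(hazard_per_cluster=(0.1, 0.1, 0.1))  # length mismatch
    with pytest.raises(ValueError):
        SimulationConfig(hazard_per_cluster=(0.1, 0.1, 0.1, 0.0))


def test_count_data_deterministic():
    a, _ = simulate_count_data(SimulationConfig(seed=42))
    b, _ = simulate_count_data(SimulationConfig(seed=42))
    assert a.keys() == b.keys()
    for sample in a:
        assert a[sample] == b[sample]


def test_count_data_structure():
    config = SimulationConfig(seed=1)
    records, truth = simulate_count_data(config)
    n_lgd, n_hgd = config.n_samples_per_group
    assert len(records) == n_lgd + n_hgd
    span = config.n_regions * config.region_size_bp
    for sample, recs in records.items():
        assert len(recs) == config.n_cpgs
        for r in recs:
            assert r.coverage >= 1
            assert 1 <= r.pos <= span
    for interval, direction in truth.planted_dmrs:
        assert 0 <= interval.start < interval.end <= span
        assert direction in {"hyper", "hypo"}


def test_planted_shift_moves_group_means():
    config = SimulationConfig(seed=3, n_samples_per_group=(6, 6))
    records, truth = simulate_count_data(config)
    interval, direction = truth.planted_dmrs[0]
    betas = {"LGD": [], "HGD": []}
    for sample, recs in records.items():
        grp = sample.split("_")[0]
        inside = [r for r in recs if interval.start <= r.start < interval.end]
        betas[grp].append(
            sum(r.count_methylated for r in inside)
            / sum(r.coverage for r in inside)
        )
    diff = np.mean(betas["HGD"]) - np.mean(betas["LGD"])
    assert (diff > 0.2) if direction == "hyper" else (diff < -0.2)


def test_beta_matrix_stepwise_gradient():
    config = SimulationConfig(seed=9)
    beta, coords, truth = simulate_beta_matrix(config)
    assert beta.to_numpy().min() >= 0 and beta.to_numpy().max() <= 1
    assert list(coords.index) == list(beta.index)
    signature = beta.loc[truth.signature_probes, truth.cluster_labels.index]
    means = signature.mean(axis=0).groupby(truth.cluster_labels).mean()
    assert means.is_monotonic_increasing  # shifts 0 < .15 < .25 < .40
    assert len(truth.normal_ref_samples) == config.n_normal_ref


def test_beta_matrix_deterministic():
    a, ca, _ = simulate_beta_matrix(SimulationConfig(seed=5))
    b, cb, _ = simulate_beta_matrix(SimulationConfig(seed=5))
    pd.testing.assert_frame_equal(a, b)
    pd.testing.assert_frame_equal(ca, cb)


def test_flat_shifts_remove_cluster_structure():
    config = SimulationConfig(seed=13, cluster_shift_steps=(0.0, 0.0, 0.0, 0.0))
    beta, _, truth = simulate_beta_matrix(config)
    signature = beta.loc[truth.signature_probes, truth.cluster_labels.index]
    means = signature.mean(axis=0).groupby(truth.cluster_labels).mean()
    assert means.max() - means.min() < 0.02  # only noise left


def test_expression_planted_regulon_correlation():
    config = SimulationConfig(seed=17)
    _, _, truth = simulate_beta_matrix(config)
    regulons = make_regulons(n_tfs=3, targets_per_tf=30, seed=17)
    activities = pd.DataFrame(
        {c: [2.0, 0.0, -1.0] for c in (1, 2, 3, 4)},
        index=["TF1", "TF2", "TF3"],
    )
    expr, truth = simulate_expression(config, regulons, truth,
                                      tf_activities=activities)
    # activator with constant positive activity: targets track each other
    t1 = regulons[regulons["tf"] == "TF1"]["target"]
    sub = expr.loc[t1]
    # per-cluster activity is constant here, so check the planted EMT shift
    emt = expr.loc[list(EMT_PANEL)]
    shifted = truth.cluster_labels[truth.cluster_labels == config.emt_shift_cluster].index
    others = truth.cluster_labels[truth.cluster_labels != config.emt_shift_cluster].index
    assert emt[shifted].mean().mean() - emt[others].mean().mean() > 0.5


def test_expression_tf_target_correlation_exceeds_threshold():
    """Planted activator with 30 targets: mean correlation between the
    TF's per-sample activity and its targets' expression exceeds 0.4 at
    expression noise SD 0.5."""
    config = SimulationConfig(seed=19)
    _, _, truth = simulate_beta_matrix(config)
    regulons = make_regulons(n_tfs=1, targets_per_tf=30, activator_fraction=1.0, seed=19)
    activities = pd.DataFrame([[2.0, -1.0, 0.5, 3.0]], index=["TF1"],
                              columns=[1, 2, 3, 4])
    expr, truth = simulate_expression(config, regulons, truth,
                                      tf_activities=activities)
    activity = truth.sample_activities.loc["TF1"]
    corrs = [
        np.corrcoef(activity, expr.loc[g, activity.index])[0, 1]
        for g in regulons["target"]
    ]
    assert np.mean(corrs) > 0.4


def test_clinical_censoring_extremes():
    config = SimulationConfig(seed=21, censor_rate=1.0)
    _, _, truth = simulate_beta_matrix(config)
    records = simulate_clinical(config, truth)
    assert all(r.event == 0 for r in records)

    config2 = SimulationConfig(seed=21, censor_rate=0.0)
    records2 = simulate_clinical(config2, truth)
    assert all(r.event == 1 for r in records2)


def test_clinical_hazard_ordering():
    config = SimulationConfig(seed=25, censor_rate=0.0,
                              n_samples_per_cluster=200)
    _, _, truth = simulate_beta_matrix(config)
    records = simulate_clinical(config, truth)
    times = pd.Series({r.sample_id: r.time for r in records})
    mean_by_cluster = times.groupby(truth.cluster_labels).mean()
    # higher hazard -> shorter mean survival, cluster 1 longest
    assert mean_by_cluster.is_monotonic_decreasing


def test_clinical_deterministic_and_mutations():
    config = SimulationConfig(seed=29)
    _, _, truth = simulate_beta_matrix(config)
    a = simulate_clinical(config, truth)
    b = simulate_clinical(config, truth)
    assert a == b
    muts = pd.Series({r.sample_id: r.mutation_count for r in a})
    by_cluster = muts.groupby(truth.cluster_labels).mean()
    assert by_cluster[4] > by_cluster[2]  # planted burden in cluster 4
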