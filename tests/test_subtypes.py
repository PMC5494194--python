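"""Subtype analysis: labels, F-test, patient-aware LOOCV, ROC, signature,
clustering, PCA."""

import numpy as np
import pandas as pd
import pytest

import atacohort as a
from atacohort.subtypes import SmallCohortError


def _sheet(rows):
    return pd.DataFrame(rows, columns=["sample_id", "patient_id", "ighv_homology_percent"])


def test_ighv_label_boundaries():
    sheet = _sheet(
        [("s1", "p1", 97.5), ("s2", "p2", 99.2), ("s3", "p3", 98.0), ("s4", "p4", None)]
    )
    labels = a.ighv_labels(sheet)
    assert labels["s1"] == "mutated"
    assert labels["s2"] == "unmutated"
    assert labels["s3"] == "mutated"  # strict > 98 for unmutated
    assert labels["s4"] == "unknown"


def test_ighv_out_of_range_rejected():
    with pytest.raises(ValueError):
        a.ighv_labels(_sheet([("s1", "p1", 101.0)]))


def _frame(rows, samples):
    return pd.DataFrame(rows, index=[f"r{i}" for i in range(len(rows))], columns=samples)


def test_f_test_closed_form_f22():
    """3-vs-3 groups give df (2,2), where P(F > x) = 1/(1+x) exactly."""
    samples = list("abcdef")
    values = _frame([[1, 5, 9, 4, 5, 6]], samples)
    labels = pd.Series(["mutated"] * 3 + ["unmutated"] * 3, index=samples)
    dv = a.differential_variability(values, labels)
    row = dv.table.iloc[0]
    assert row["F"] == pytest.approx(16.0)
    assert row["p_value"] == pytest.approx(2 / 17)
    assert row["higher_variance_group"] == "mutated"


def test_f_test_flags_degenerate_rows():
    samples = list("abcdef")
    values = _frame([[2, 2, 2, 2, 2, 2], [1, 1, 1, 2, 5, 8]], samples)
    labels = pd.Series(["mutated"] * 3 + ["unmutated"] * 3, index=samples)
    dv = a.differential_variability(values, labels)
    assert dv.table.iloc[0]["flag_both_zero"] and not dv.table.iloc[0]["significant"]
    assert dv.table.iloc[1]["flag_one_zero"] and dv.table.iloc[1]["p_value"] == 0
    assert dv.n_tested == 1


def test_f_test_significance_requires_mean_above_cutoff():
    rng = np.random.default_rng(2)
    samples = [f"s{i}" for i in range(12)]
    labels = pd.Series(["mutated"] * 6 + ["unmutated"] * 6, index=samples)
    low = np.concatenate([rng.normal(0.5, 2.0, 6), rng.normal(0.5, 0.01, 6)])
    values = _frame([low], samples)
    dv = a.differential_variability(values, labels)
    assert not dv.table.iloc[0]["significant"]  # mean below 1 blocks the call


def test_bonferroni_uses_tested_count():
    samples = list("abcdef")
    values = _frame([[1, 5, 9, 4, 5, 6], [3, 3, 3, 3, 3, 3]], samples)
    labels = pd.Series(["mutated"] * 3 + ["unmutated"] * 3, index=samples)
    dv = a.differential_variability(values, labels)
    assert dv.n_tested == 1
    assert dv.table.iloc[0]["p_bonferroni"] == pytest.approx(2 / 17)


def test_roc_examples():
    scores = pd.Series([0.9, 0.8, 0.85, 0.1], index=["p1", "p2", "n1", "n2"])
    labels = pd.Series(["unmutated", "unmutated", "mutated", "mutated"],
                       index=scores.index)
    _, auc, _ = a.roc_and_auc(scores, labels)
    assert auc == pytest.approx(3 / 4)  # 3 concordant of 4 pairs

    perfect = pd.Series([0.9, 0.8, 0.2, 0.1], index=scores.index)
    roc, auc, op = a.roc_and_auc(perfect, labels)
    assert auc == pytest.approx(1.0)
    assert op["sensitivity"] == 1.0 and op["specificity"] == 1.0
    assert (roc.iloc[0]["fpr"], roc.iloc[0]["tpr"]) == (0, 0)
    assert (roc.iloc[-1]["fpr"], roc.iloc[-1]["tpr"]) == (1, 1)

    ties = pd.Series([0.5] * 4, index=scores.index)
    _, auc, _ = a.roc_and_auc(ties, labels)
    assert auc == pytest.approx(0.5)


def test_roc_single_class_rejected():
    scores = pd.Series([0.1, 0.9], index=["s1", "s2"])
    labels = pd.Series(["mutated", "mutated"], index=scores.index)
    with pytest.raises(ValueError):
        a.roc_and_auc(scores, labels)


def test_auc_matches_concordance_oracle_randomized():
    """Trapezoidal sweep AUC equals the Mann-Whitney pairwise statistic."""
    rng = np.random.default_rng(23)
    for _ in range(100):
        n_pos, n_neg = rng.integers(2, 8, size=2)
        ids = [f"x{i}" for i in range(n_pos + n_neg)]
        # coarse grid makes ties frequent
        scores = pd.Series(rng.integers(0, 5, size=n_pos + n_neg) / 4, index=ids)
        labels = pd.Series(["unmutated"] * n_pos + ["mutated"] * n_neg, index=ids)
        _, auc, _ = a.roc_and_auc(scores, labels)
        pos, neg = scores[:n_pos].to_numpy(), scores[n_pos:].to_numpy()
        oracle = (
            (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
        ) / (n_pos * n_neg)
        assert auc == pytest.approx(oracle)


def _toy_classification(n_per_class=6, n_regions=30, effect=3.0, seed=0):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(2 * n_per_class)]
    labels = pd.Series(["mutated"] * n_per_class + ["unmutated"] * n_per_class,
                       index=samples)
    x = rng.normal(10, 1, size=(n_regions, len(samples)))
    x[:5, n_per_class:] += effect  # first regions carry the signal
    values = pd.DataFrame(x, index=[f"r{i}" for i in range(n_regions)], columns=samples)
    patients = pd.Series([f"p{i // 2}" for i in range(len(samples))], index=samples)
    return values, labels, patients


def test_loocv_excludes_same_patient_samples():
    values, labels, patients = _toy_classification()
    res = a.patient_aware_loocv(
        values, labels, patients, model_config={"n_estimators": 20}, seed=0
    )
    for test_sample, train in res.fold_map.items():
        assert test_sample not in train
        test_patient = patients[test_sample]
        assert all(patients[t] != test_patient for t in train)
    assert len(res.scores) == len(labels)


def test_loocv_single_class_rejected():
    values, labels, patients = _toy_classification()
    labels[:] = "mutated"
    with pytest.raises(ValueError):
        a.patient_aware_loocv(values, labels, patients)


def test_loocv_small_cohort_error_names_fold():
    # both unmutated samples share a patient: the fold testing s2 excludes
    # s3 as well and loses the class from training
    samples = ["s0", "s1", "s2", "s3"]
    values = pd.DataFrame(
        np.random.default_rng(0).normal(size=(5, 4)), columns=samples
    )
    labels = pd.Series(["mutated", "mutated", "unmutated", "unmutated"], index=samples)
    patients = pd.Series(["p0", "p1", "p2", "p2"], index=samples)
    with pytest.raises(SmallCohortError, match="s2"):
        a.patient_aware_loocv(values, labels, patients,
                              model_config={"n_estimators": 5}, seed=0)


def test_loocv_separates_planted_signal():
    values, labels, patients = _toy_classification()
    res = a.patient_aware_loocv(
        values, labels, patients, model_config={"n_estimators": 50}, seed=1
    )
    assert res.auc >= 0.9
    sig = a.extract_signature(res, values, labels, importance_threshold=1e-4)
    assert set(f"r{i}" for i in range(5)) <= set(sig.region_ids)


def test_shuffled_null_length_and_range():
    values, labels, patients = _toy_classification()
    null = a.shuffled_label_null(
        values, labels, patients, n_permutations=1,
        seed=0, model_config={"n_estimators": 10},
    )
    assert len(null.auc_values) == 1
    assert 0 <= null.auc_values[0] <= 1


def test_extract_signature_threshold_and_directions():
    values, labels, _ = _toy_classification()
    imp = pd.Series(0.0, index=values.index)
    imp["r0"], imp["r1"] = 2e-4, 5e-5
    res = a.ClassifierResult(
        scores=pd.Series(dtype=float), labels=labels, positive_label="unmutated",
        roc=pd.DataFrame(), auc=0.5, operating_point={}, importances=imp,
        fold_map={},
    )
    sig = a.extract_signature(res, values, labels)
    assert list(sig.region_ids) == ["r0"]
    assert sig.directions["r0"] == "unmutated"  # signal planted upward there
    assert sig.clusters["r0"] == 2

    res.importances[:] = 0.0
    empty = a.extract_signature(res, values, labels)
    assert len(empty.region_ids) == 0


def test_cluster_recovers_blocks_and_duplicates():
    rng = np.random.default_rng(4)
    block1 = rng.normal(0, 1, size=(20, 1)) + rng.normal(0, 0.01, size=(20, 4))
    block2 = rng.normal(5, 1, size=(20, 1)) + rng.normal(0, 0.01, size=(20, 4))
    values = pd.DataFrame(
        np.hstack([block1, block2]),
        columns=[f"a{i}" for i in range(4)] + [f"b{i}" for i in range(4)],
    )
    assign, order = a.cluster_samples(values, k=2)
    assert len(set(assign[:4])) == 1 and len(set(assign[4:])) == 1
    assert assign["a0"] != assign["b0"]
    # a duplicated sample has distance 0 to its twin
    dup = values.copy()
    dup["a0_twin"] = dup["a0"]
    assign2, _ = a.cluster_samples(dup, k=2)
    assert assign2["a0"] == assign2["a0_twin"]


def test_cluster_constant_profile_rejected():
    values = pd.DataFrame({"s1": [1.0, 1.0], "s2": [1.0, 2.0], "s3": [0, 3], "s4": [2, 0]})
    with pytest.raises(ValueError, match="s1"):
        a.cluster_samples(values, k=2)


def test_intermediates_form_own_cluster():
    """Cohorts with midpoint-mean intermediates at signature regions
    separate into mutated / unmutated / intermediate at k=3."""
    hits = 0
    for seed in range(10):
        spec = a.CohortSpec(
            n_samples=18, n_patients=18,
            genome=(("chr1", 10_000_000), ("chr2", 8_000_000)),
            n_core_regions=120, n_variable_regions=30,
            n_sample_specific_regions_per_sample=0,
            n_signature_regions=30, signature_log2_effect=2.5,
            n_diffvar_regions=5, intermediate_fraction=0.34,
            dispersion=0.05, seed=100 + seed,
        )
        cohort = a.generate_cohort(spec)
        cons = a.merge_peak_sets(cohort.peak_sets)
        m = a.quantify_regions(cons, cohort.fragments)
        a.add_normalized_layer(m)
        norm = m.normalized_frame()
        sig_ids = [r for r in cohort.ground_truth["signature_regions"] if r in norm.index]
        assign, _ = a.cluster_samples(norm.loc[sig_ids], k=3)
        truth = pd.Series(cohort.ground_truth["labels"]).reindex(assign.index)
        inter_clusters = set(assign[truth == "intermediate"])
        others = set(assign[truth != "intermediate"])
        if len(inter_clusters) == 1 and not (inter_clusters & others):
            hits += 1
    assert hits >= 9


def test_pca_single_direction_and_group_separation(default_matrix, default_cohort,
                                                   default_labels):
    rng = np.random.default_rng(6)
    direction = rng.normal(size=10)
    coeffs = rng.normal(size=6)
    values = pd.DataFrame(
        np.outer(direction, coeffs), columns=[f"s{i}" for i in range(6)]
    )
    _, evr = a.pca_projection(values)
    assert evr[0] == pytest.approx(1.0)
    assert np.all(np.diff(evr) <= 1e-12)

    # two-subtype cohort: PC1 separates the ground-truth groups
    norm = default_matrix.normalized_frame()
    coords, _ = a.pca_projection(norm)
    truth = pd.Series(default_cohort.ground_truth["labels"]).reindex(coords.index)
    pc1 = coords["PC1"]
    if pc1[truth == "unmutated"].mean() < pc1[truth == "mutated"].mean():
        pc1 = -pc1
    _, auc, _ = a.roc_and_auc(pc1, truth, positive_label="unmutated")
    assert auc >= 0.9


def test_pca_degenerate_input_rejected():
    values = pd.DataFrame(np.ones((5, 3)), columns=["a", "b", "c"])
    with pytest.raises(ValueError):
        a.pca_projection(values)
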