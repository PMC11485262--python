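"""Metric oracles, averaging identities, co-occurrence rule, sweeps, fusion."""

import numpy as np
import pytest

from mmdx.evaluate import (augment_confidence, average_metrics,
                           binary_curve_metrics, confusion_metrics,
                           cooccurrence_report, metric_report,
                           min_positive_samples, missingness_sweep)
from mmdx.schema import LABELS, UNKNOWN


def auroc_pairwise(scores, labels):
    """Mann-Whitney oracle: fraction of positive-negative pairs correctly
    ordered, ties counting one half."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


def test_auroc_worked_example_and_conventions():
    m = binary_curve_metrics(np.array([0.1, 0.4, 0.35, 0.8]), np.array([0, 0, 1, 1]))
    assert m["auroc"] == pytest.approx(0.75)
    perfect = binary_curve_metrics(np.array([0.1, 0.2, 0.8, 0.9]), np.array([0, 0, 1, 1]))
    assert perfect["auroc"] == 1.0 and perfect["aupr"] == 1.0
    ties = binary_curve_metrics(np.full(6, 0.5), np.array([0, 1, 0, 1, 0, 1]))
    assert ties["auroc"] == pytest.approx(0.5)
    with pytest.raises(ValueError):
        binary_curve_metrics(np.array([0.1, 0.2]), np.array([1, 1]))


def test_auroc_equals_pairwise_oracle_on_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(50):
        n = int(rng.integers(4, 50))
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        labels = rng.integers(0, 2, n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        got = binary_curve_metrics(scores, labels)["auroc"]
        assert got == pytest.approx(auroc_pairwise(scores, labels), abs=1e-12)


def test_macro_and_weighted_averaging_arithmetic():
    # label A: AUROC 1.0 with 10 positives; label B: AUROC 0.5 with 30 positives
    sA = np.concatenate([np.full(10, 0.9), np.full(10, 0.1)])
    yA = np.concatenate([np.ones(10, dtype=int), np.zeros(10, dtype=int)])
    sB = np.full(60, 0.5)
    yB = np.concatenate([np.ones(30, dtype=int), np.zeros(30, dtype=int)])
    n = 80
    probs = np.zeros((n, 2))
    labels = np.full((n, 2), UNKNOWN)
    probs[:20, 0], labels[:20, 0] = sA, yA
    probs[20:, 1], labels[20:, 1] = sB, yB
    assert average_metrics(probs, labels, "macro")["auroc"] == pytest.approx(0.75)
    # weighted by positive counts: (10*1.0 + 30*0.5) / 40
    assert average_metrics(probs, labels, "weighted")["auroc"] == pytest.approx(0.625)


def test_micro_pooling_identity():
    rng = np.random.default_rng(1)
    probs = rng.random((40, 3))
    labels = rng.integers(0, 2, (40, 3))
    micro = average_metrics(probs, labels, "micro")
    pooled = binary_curve_metrics(probs.ravel(), labels.ravel())
    assert micro["auroc"] == pytest.approx(pooled["auroc"], abs=1e-12)
    assert micro["aupr"] == pytest.approx(pooled["aupr"], abs=1e-12)


def test_weighted_average_is_convex_combination():
    rng = np.random.default_rng(2)
    probs = rng.random((60, 4))
    labels = rng.integers(0, 2, (60, 4))
    per = [binary_curve_metrics(probs[:, i], labels[:, i])["auroc"] for i in range(4)]
    w = average_metrics(probs, labels, "weighted")["auroc"]
    assert min(per) - 1e-12 <= w <= max(per) + 1e-12


def test_single_label_all_schemes_collapse():
    rng = np.random.default_rng(3)
    probs = rng.random((30, 1))
    labels = rng.integers(0, 2, (30, 1))
    ref = binary_curve_metrics(probs[:, 0], labels[:, 0])["auroc"]
    for scheme in ("micro", "macro", "weighted"):
        assert average_metrics(probs, labels, scheme)["auroc"] == pytest.approx(ref)


def test_confusion_metrics_worked_example():
    # TP=6, FP=1, TN=3, FN=0 at threshold 0.5
    scores = np.array([0.9] * 6 + [0.8] + [0.2] * 3)
    labels = np.array([1] * 6 + [0] + [0] * 3)
    m = confusion_metrics(scores, labels, threshold=0.5)
    assert m["mcc"] == pytest.approx((6 * 3 - 1 * 0) / np.sqrt(7 * 6 * 4 * 3), abs=1e-4)
    assert m["accuracy"] == pytest.approx(0.9)
    assert m["sensitivity"] == 1.0
    assert m["specificity"] == pytest.approx(0.75)
    perfect = confusion_metrics(np.array([0.9, 0.9, 0.1]), np.array([1, 1, 0]))
    assert perfect["mcc"] == 1.0 and perfect["sensitivity"] == 1.0
    inverted = confusion_metrics(np.array([0.1, 0.1, 0.9]), np.array([1, 1, 0]))
    assert inverted["mcc"] == -1.0
    degenerate = confusion_metrics(np.array([0.9, 0.9]), np.array([1, 1]))
    assert np.isnan(degenerate["mcc"])


def test_min_positive_samples_rule():
    assert min_positive_samples(0.01) == 25
    assert min_positive_samples(0.25) == 1
    assert min_positive_samples(0.005) == 50
    bounds = [0.25, 0.1, 0.05, 0.01, 0.005, 0.001]
    ns = [min_positive_samples(b) for b in bounds]
    assert ns == sorted(ns)  # monotone non-increasing in the bound
    with pytest.raises(ValueError):
        min_positive_samples(0.0)


def test_cooccurrence_admission_and_scoring():
    rng = np.random.default_rng(4)
    n = 200
    labels = np.zeros((n, 13), dtype=int)
    iAD, iVD, iFTD = LABELS.index("AD"), LABELS.index("VD"), LABELS.index("FTD")
    labels[:30, [iAD]] = 1
    labels[:30, [iVD]] = 1          # 30 joint AD+VD positives -> admitted
    labels[30:40, [iAD]] = 1
    labels[30:40, [iFTD]] = 1       # 10 joint AD+FTD positives -> excluded
    labels[:, LABELS.index("DE")] = 1
    probs = rng.random((n, 13)) * 0.3
    probs[:30, iAD] = probs[:30, iVD] = 0.9  # model confident on joint positives
    rep = cooccurrence_report(probs, labels, variance_bound=0.01)
    assert rep.min_positives == 25
    assert rep.combinations[("AD", "VD")]["admitted"]
    assert rep.combinations[("AD", "VD")]["auroc"] > 0.9
    assert not rep.combinations[("AD", "FTD")]["admitted"]
    assert "auroc" not in rep.combinations[("AD", "FTD")]


def test_cooccurrence_unknown_labels_dropped():
    labels = np.zeros((60, 13), dtype=int)
    iAD, iVD = LABELS.index("AD"), LABELS.index("VD")
    labels[:30, iAD] = labels[:30, iVD] = 1
    labels[30:40, iAD] = UNKNOWN
    probs = np.full((60, 13), 0.5)
    probs[:30, iAD] = probs[:30, iVD] = 0.9
    rep = cooccurrence_report(probs, labels)
    entry = rep.combinations[("AD", "VD")]
    assert entry["n_pos"] == 30
    assert entry["n_neg"] == 20  # the 10 UNKNOWN rows are dropped


def test_augment_confidence_arithmetic_and_properties():
    assert augment_confidence([100.0], [1.0])[0] == 1.0
    assert augment_confidence([80.0], [0.6])[0] == pytest.approx(0.7)
    assert augment_confidence([0.0], [0.0])[0] == 0.0
    # symmetric in rescaled arguments, idempotent when equal
    a, b = 64.0, 0.37
    assert augment_confidence([a], [b])[0] == pytest.approx(
        augment_confidence([b * 100], [a / 100])[0])
    assert augment_confidence([50.0], [0.5])[0] == 0.5
    with pytest.raises(ValueError):
        augment_confidence([101.0], [0.5])
    with pytest.raises(ValueError):
        augment_confidence([50.0], [1.5])


def test_metric_report_with_strata(small_records):
    rng = np.random.default_rng(5)
    records = small_records * 10
    probs = rng.random((len(records), 13))
    labels = np.stack([r.labels for r in records])
    rep = metric_report(probs, labels, records)
    assert set(rep.averaged) == {"micro", "macro", "weighted"}
    assert any(k.startswith("gender=") for k in rep.strata)
    assert rep.per_label["PRD"]["auroc"] is None  # single-class label reported as such


def test_missingness_sweep_baseline_and_knockouts(small_catalog, small_records,
                                                  small_checkpoint):
    records = small_records * 15
    labels = np.stack([r.labels for r in records])
    scenarios = {"baseline": [], "no_np": ["NP tests"], "no_all": ["NP tests", "FAQ",
                                                                   "demographics"]}
    table = missingness_sweep(small_checkpoint, records, scenarios,
                              label_subset=("NC", "DE"))
    assert set(table) == set(scenarios)
    from mmdx.training import predict

    preds = predict(small_checkpoint, records)
    base = table["baseline"]["NC"]
    i = LABELS.index("NC")
    expected = binary_curve_metrics(preds.probs[:, i], labels[:, i])["auroc"]
    assert base == pytest.approx(expected, abs=1e-12)
    with pytest.raises(KeyError):
        missingness_sweep(small_checkpoint, records, {"bad": ["NOPE"]})
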