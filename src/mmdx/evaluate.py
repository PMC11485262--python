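"""Evaluation protocols for the 13-head diagnostic model.

Covers per-label ROC/PR metrics with micro / macro / weighted averaging,
confusion-table statistics at a threshold, subgroup stratification, the
co-occurring-dementia evaluation with its minimum-positive-count admission
rule, test-time missingness sweeps over feature groups, and AI-augmented
clinician score fusion.

AUROC uses the midrank tie convention (equivalently the tie-corrected
Mann-Whitney statistic); AUPR is average precision.  The co-occurrence rule
admits a label combination only when its joint-positive count n satisfies
1/(4n) <= variance_bound, the distribution-free upper bound on the variance
of empirical AUROC in terms of the limiting class count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from sklearn import metrics as skm

from .schema import ETIOLOGIES, LABELS, MISSING, UNKNOWN

__all__ = [
    "MetricReport", "CooccurrenceReport", "binary_curve_metrics", "average_metrics",
    "confusion_metrics", "min_positive_samples", "cooccurrence_report",
    "missingness_sweep", "augment_confidence", "metric_report",
]


# ------------------------------------------------------------------ primitives

def binary_curve_metrics(scores, labels) -> dict:
    """AUROC, AUPR and the underlying ROC/PR curve points for one binary task.

    Raises on single-class input: the quantities are undefined there, and
    reporting 0 would silently poison averages.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    classes = np.unique(labels)
    if not np.array_equal(np.sort(classes), [0, 1]):
        raise ValueError(f"need both classes present, got {classes.tolist()}")
    fpr, tpr, roc_thr = skm.roc_curve(labels, scores)
    prec, rec, pr_thr = skm.precision_recall_curve(labels, scores)
    return {
        "auroc": float(skm.roc_auc_score(labels, scores)),
        "aupr": float(skm.average_precision_score(labels, scores)),
        "roc": {"fpr": fpr, "tpr": tpr, "thresholds": roc_thr},
        "pr": {"precision": prec, "recall": rec, "thresholds": pr_thr},
    }


def _scoreable(probs, labels):
    """Per-label (scores, binary labels) with UNKNOWN entries dropped,
    keeping only labels where both classes remain."""
    out = {}
    for i in range(probs.shape[1]):
        known = labels[:, i] != UNKNOWN
        y = labels[known, i]
        if known.sum() and 0 in y and 1 in y:
            out[i] = (probs[known, i], y)
    return out

def average_metrics(probs, labels, scheme: str) -> dict:
    """Averaged AUROC/AUPR across the label columns.

    micro pools every (score, label) pair into one curve; macro is the
    unweighted mean of per-label values; weighted weights each label by its
    positive count.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    per = _scoreable(probs, labels)
    if not per:
        raise ValueError("no label with both classes present")
    if scheme == "micro":
        s = np.concatenate([v[0] for v in per.values()])
        y = np.concatenate([v[1] for v in per.values()])
        m = binary_curve_metrics(s, y)
        return {"auroc": m["auroc"], "aupr": m["aupr"]}
    vals = {i: binary_curve_metrics(s, y) for i, (s, y) in per.items()}
    aurocs = np.array([vals[i]["auroc"] for i in per])
    auprs = np.array([vals[i]["aupr"] for i in per])
    if scheme == "macro":
        w = np.ones(len(per))
    elif scheme == "weighted":
        w = np.array([float((y == 1).sum()) for _, y in per.values()])
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    w = w / w.sum()
    return {"auroc": float(w @ aurocs), "aupr": float(w @ auprs)}


def confusion_metrics(scores, labels, threshold: float = 0.5) -> dict:
    """Accuracy, sensitivity, specificity and MCC at the given threshold.

    MCC is NaN when any confusion-table margin is zero (undefined, not 0).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    n = tp + tn + fp + fn
    out = {
        "accuracy": (tp + tn) / n if n else float("nan"),
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    out["mcc"] = (tp * tn - fp * fn) / math.sqrt(denom) if denom else float("nan")
    return out


# --------------------------------------------------------------- full report

@dataclass
class MetricReport:
    per_label: dict[str, dict]
    averaged: dict[str, dict]        # scheme -> {auroc, aupr}
    strata: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {"per_label": self.per_label, "averaged": self.averaged,
                "strata": self.strata}


def metric_report(probs, labels, records=None, threshold: float = 0.5,
                  strata_keys=("age_bin", "gender", "race")) -> MetricReport:
    """Per-label and averaged metrics, optionally stratified by subgroup."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    per_label = {}
    for i, lab in enumerate(LABELS[: probs.shape[1]]):
        known = labels[:, i] != UNKNOWN
        y = labels[known, i]
        if known.sum() == 0 or 0 not in y or 1 not in y:
            per_label[lab] = {"auroc": None, "aupr": None, "note": "single-class"}
            continue
        m = binary_curve_metrics(probs[known, i], y)
        entry = {"auroc": m["auroc"], "aupr": m["aupr"]}
        entry.update(confusion_metrics(probs[known, i], y, threshold))
        per_label[lab] = entry
    averaged = {}
    for scheme in ("micro", "macro", "weighted"):
        try:
            averaged[scheme] = average_metrics(probs, labels, scheme)
        except ValueError:
            averaged[scheme] = {"auroc": None, "aupr": None}
    strata: dict[str, dict] = {}
    if records is not None:
        for key in strata_keys:
            groups: dict[str, list[int]] = {}
            for idx, rec in enumerate(records):
                v = rec.strata.get(key, MISSING)
                if v is not MISSING:
                    groups.setdefault(str(v), []).append(idx)
            for gval, idxs in sorted(groups.items()):
                sel = np.asarray(idxs)
                try:
                    strata[f"{key}={gval}"] = {
                        "n": len(idxs),
                        **{s: average_metrics(probs[sel], labels[sel], s)
                           for s in ("micro", "macro", "weighted")},
                    }
                except ValueError:
                    strata[f"{key}={gval}"] = {"n": len(idxs), "note": "not scoreable"}
    return MetricReport(per_label=per_label, averaged=averaged, strata=strata)


# --------------------------------------------------------- co-occurrence rule

def min_positive_samples(variance_bound: float) -> int:
    """Smallest class count n whose distribution-free maximum AUROC variance
    1/(4n) is at most ``variance_bound``: ceil(1 / (4 * bound))."""
    if not variance_bound > 0:
        raise ValueError("variance bound must be positive")
    return math.ceil(1.0 / (4.0 * variance_bound))


@dataclass
class CooccurrenceReport:
    variance_bound: float
    min_positives: int
    score_statistic: str
    combinations: dict[tuple[str, ...], dict]

    def to_json(self) -> dict:
        return {
            "variance_bound": self.variance_bound,
            "min_positives": self.min_positives,
            "score_statistic": self.score_statistic,
            "combinations": {"+".join(k): v for k, v in self.combinations.items()},
        }


def cooccurrence_report(probs, labels, variance_bound: float = 0.01,
                        score_statistic: str = "mean") -> CooccurrenceReport:
    """Evaluate every etiology combination (>= 2 labels jointly positive)
    that meets the minimum-positive-count rule.

    Positives are subjects with ALL combination labels 1; negatives are all
    other subjects with every combination label known; subjects with an
    UNKNOWN combination label are dropped.  The combination's scalar score
    is the mean (default; alternatives: min, product) of the model
    probabilities of its labels.
    """
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels)
    floor = min_positive_samples(variance_bound)
    etio_idx = {lab: LABELS.index(lab) for lab in ETIOLOGIES}
    reducers = {"mean": np.mean, "min": np.min, "product": np.prod}
    if score_statistic not in reducers:
        raise ValueError(f"unknown score statistic {score_statistic!r}")
    reduce_ = reducers[score_statistic]

    # candidate combinations: subsets (size >= 2) of observed positive sets
    seen: set[tuple[str, ...]] = set()
    for row in labels:
        pos = [lab for lab in ETIOLOGIES if row[etio_idx[lab]] == 1]
        for r in range(2, len(pos) + 1):
            seen.update(combinations(pos, r))

    out: dict[tuple[str, ...], dict] = {}
    for combo in sorted(seen):
        cols = [etio_idx[lab] for lab in combo]
        known = np.all(labels[:, cols] != UNKNOWN, axis=1)
        joint_pos = known & np.all(labels[:, cols] == 1, axis=1)
        n_pos = int(joint_pos.sum())
        n_neg = int((known & ~joint_pos).sum())
        admitted = n_pos >= floor
        entry = {"n_pos": n_pos, "n_neg": n_neg, "admitted": admitted}
        if admitted and n_neg > 0:
            score = reduce_(probs[:, cols], axis=1)
            y = joint_pos.astype(int)[known]
            m = binary_curve_metrics(score[known], y)
            entry.update(auroc=m["auroc"], aupr=m["aupr"])
        out[combo] = entry
    return CooccurrenceReport(variance_bound=variance_bound, min_positives=floor,
                              score_statistic=score_statistic, combinations=out)


# -------------------------------------------------------- missingness sweep

def missingness_sweep(ckpt, records, scenarios: dict[str, list[str]],
                      label_subset=("NC", "MCI", "DE")) -> dict[str, dict]:
    """Re-score under test-time removal of feature groups.

    ``scenarios`` maps a scenario name to a list of catalog group tags whose
    features are masked for every record; an empty list is the unmasked
    baseline.  Returns per-scenario per-label AUROC (None when a label is
    not scoreable after masking).
    """
    from .training import predict

    catalog = ckpt.catalog
    labels = np.stack([np.asarray(r.labels) for r in records])
    results: dict[str, dict] = {}
    for name, groups in scenarios.items():
        hidden = set(catalog.features_in_groups(groups)) if groups else set()
        mask = np.array([[nm not in hidden for nm in catalog.names]] * len(records))
        preds = predict(ckpt, records, feature_mask=mask, allow_empty=True)
        entry: dict[str, float | None] = {}
        for lab in label_subset:
            i = LABELS.index(lab)
            known = labels[:, i] != UNKNOWN
            y = labels[known, i]
            if known.sum() and 0 in y and 1 in y:
                entry[lab] = binary_curve_metrics(preds.probs[known, i], y)["auroc"]
            else:
                entry[lab] = None
        results[name] = entry
    return results


# ----------------------------------------------------------- score fusion

def augment_confidence(clinician_scores, model_probs) -> np.ndarray:
    """AI-augmented confidence: mean of the clinician's 0-100 score
    (rescaled to [0,1]) and the model's predicted probability."""
    c = np.asarray(clinician_scores, dtype=float)
    p = np.asarray(model_probs, dtype=float)
    if c.shape != p.shape:
        raise ValueError("clinician scores and model probabilities must align")
    if np.any((c < 0) | (c > 100)):
        raise ValueError("clinician confidence scores must lie in [0, 100]")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("model probabilities must lie in [0, 1]")
    return (c / 100.0 + p) / 2.0
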