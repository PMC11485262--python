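"""Synthetic multimodal cohort generator.

Emulates the statistical structure the diagnostic framework assumes, so that
every component can be exercised without access-restricted clinical cohorts:

* 13 partially co-occurring labels: a three-way cognitive status (NC / MCI /
  DE) and, for dementia cases, one or more of ten etiologies drawn with
  conditional prevalences and pairwise co-occurrence boosts (e.g. AD with
  VD, LBD with PSY).  NC cases carry no etiology; every DE case carries at
  least one.
* label-dependent feature distributions: each numeric feature is a baseline
  plus a linear label effect plus Gaussian noise; categoricals use a
  logistic link; optional 256-dimensional image embeddings are label-shifted
  Gaussians.  The true effect matrix is returned for recovery tests.
* block missingness: per-group MCAR feature removal at configurable rates,
  with named sparsity profiles mimicking a well-characterized reference
  cohort (low missingness), a cohort with roughly 69% feature absence, and a
  very sparse cohort with roughly 94% absence; plus per-label UNKNOWN
  injection.

The generator never removes a subject's last observed feature, and identical
config + seed reproduces the cohort exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from pydantic import BaseModel, model_validator

from .schema import (ETIOLOGIES, LABELS, MISSING, UNKNOWN, FeatureCatalog,
                     FeatureSpec, SubjectRecord)

__all__ = ["SyntheticConfig", "SimulatedCohort", "simulate_cohort",
           "apply_missingness", "MISSINGNESS_PROFILES", "default_catalog"]

#: Named per-group MCAR rates emulating the sparsity contrast between a
#: reference cohort and two progressively sparser external cohorts.
MISSINGNESS_PROFILES = {
    "reference_like": 0.05,
    "sparse69_like": 0.69,
    "sparse94_like": 0.94,
}

GROUPS = ("demographics", "NP tests", "FAQ", "GDS", "NPIQ", "UPDRS", "MRI", "noise")

# (name, group, baseline, noise sd, {label: effect}) — effects add to the mean
_NUMERIC_FEATURES = [
    ("age", "demographics", 70.0, 8.0, {"MCI": 3.0, "DE": 6.0}),
    ("moca", "NP tests", 27.0, 1.8, {"MCI": -3.0, "DE": -8.0}),
    ("mmse", "NP tests", 29.0, 1.2, {"MCI": -2.0, "DE": -6.0}),
    ("memory_delayed", "NP tests", 12.0, 2.5, {"AD": -5.0, "DE": -2.0}),
    ("trails_b", "NP tests", 80.0, 25.0, {"VD": 60.0, "DE": 30.0}),
    ("faq_total", "FAQ", 1.0, 2.0, {"MCI": 2.0, "DE": 8.0}),
    ("adl_score", "FAQ", 1.0, 1.5, {"DE": 4.0}),
    ("gds_total", "GDS", 2.0, 2.0, {"PSY": 6.0}),
    ("npiq_total", "NPIQ", 1.0, 2.0, {"DE": 3.0, "LBD": 2.0, "PSY": 3.0}),
    ("updrs", "UPDRS", 5.0, 4.0, {"LBD": 14.0}),
    ("wmh_volume", "MRI", 4.0, 2.5, {"VD": 8.0}),
    ("hippocampal_volume", "MRI", 7.0, 0.8, {"AD": -2.0, "DE": -0.8}),
    ("noise_marker", "noise", 0.0, 1.0, {}),
]


def default_catalog(include_image: bool = False) -> FeatureCatalog:
    entries = [FeatureSpec(name=n, modality="numeric", group=g)
               for n, g, _, _, _ in _NUMERIC_FEATURES]
    entries.insert(1, FeatureSpec(name="sex", modality="categorical",
                                  categories=["female", "male"], group="demographics"))
    if include_image:
        entries.append(FeatureSpec(name="mri_t1", modality="image_embedding",
                                   embedding_width=256, group="MRI"))
    return FeatureCatalog(entries=entries, allowed_groups=list(GROUPS))


class SyntheticConfig(BaseModel):
    n_subjects: int = 1000
    status_prevalence: dict[str, float] = {"NC": 0.3, "MCI": 0.3, "DE": 0.4}
    etiology_given_de: dict[str, float] = {
        "AD": 0.55, "LBD": 0.12, "VD": 0.18, "PRD": 0.02, "FTD": 0.08,
        "NPH": 0.04, "SEF": 0.06, "PSY": 0.12, "TBI": 0.04, "ODE": 0.08,
    }
    cooccurrence_boost: dict[str, float] = {"AD+VD": 2.0, "LBD+PSY": 1.8}
    mci_ad_prob: float = 0.25       # fraction of MCI cases carrying an AD etiology label
    effect_scale: float = 1.0       # global multiplier on all planted effects
    noise_scale: float = 1.0        # global multiplier on feature noise
    include_image: bool = False
    image_effect_scale: float = 3.0
    feature_missing_rates: dict[str, float] = {}   # group tag -> MCAR rate
    missingness_profile: str | None = None          # key of MISSINGNESS_PROFILES
    label_missing_rates: dict[str, float] = {}      # label -> UNKNOWN rate
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        sp = self.status_prevalence
        if set(sp) != {"NC", "MCI", "DE"}:
            raise ValueError("status_prevalence needs exactly NC, MCI, DE")
        if abs(sum(sp.values()) - 1.0) > 1e-9:
            raise ValueError("status prevalences must sum to 1")
        for d in (sp, self.etiology_given_de, self.feature_missing_rates,
                  self.label_missing_rates):
            for k, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"rate/prevalence {k}={v} outside [0, 1]")
        if all(v == 0.0 for v in self.etiology_given_de.values()):
            raise ValueError("at least one etiology must have nonzero prevalence given DE")
        if self.missingness_profile is not None \
                and self.missingness_profile not in MISSINGNESS_PROFILES:
            raise ValueError(f"unknown profile {self.missingness_profile!r}; "
                             f"choose from {sorted(MISSINGNESS_PROFILES)}")
        bad = [k for k in self.cooccurrence_boost if len(k.split("+")) != 2
               or any(e not in ETIOLOGIES for e in k.split("+"))]
        if bad:
            raise ValueError(f"co-occurrence keys must be 'ETIO+ETIO': {bad}")
        return self


@dataclass
class SimulatedCohort:
    records: list[SubjectRecord]
    catalog: FeatureCatalog
    effects: dict[str, np.ndarray]      # feature -> true 13-vector of mean shifts
    signal_labels: list[str]            # labels with substantial planted signal
    config: SyntheticConfig
    realized_missingness: dict[str, float]
    image_directions: dict[str, np.ndarray] | None = None


def _draw_labels(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    labels = np.zeros(13, dtype=np.int64)
    status = rng.choice(["NC", "MCI", "DE"],
                        p=[cfg.status_prevalence[s] for s in ("NC", "MCI", "DE")])
    labels[LABELS.index(status)] = 1
    if status == "MCI" and rng.random() < cfg.mci_ad_prob:
        labels[LABELS.index("AD")] = 1
    if status == "DE":
        boosts = {tuple(k.split("+")): v for k, v in cfg.cooccurrence_boost.items()}
        drawn: list[str] = []
        for e in ETIOLOGIES:
            p = cfg.etiology_given_de.get(e, 0.0)
            for d in drawn:
                if (d, e) in boosts:
                    p *= boosts[(d, e)]
            if rng.random() < min(p, 0.95):
                drawn.append(e)
                labels[LABELS.index(e)] = 1
        if not drawn:  # every dementia case carries at least one etiology
            base = np.array([cfg.etiology_given_de.get(e, 0.0) for e in ETIOLOGIES])
            pick = rng.choice(len(ETIOLOGIES), p=base / base.sum())
            labels[LABELS.index(ETIOLOGIES[pick])] = 1
    return labels


def simulate_cohort(cfg: SyntheticConfig) -> SimulatedCohort:
    """Generate a cohort with planted label effects; returns the ground truth.

    Labels are drawn hierarchically (status, then etiologies with
    co-occurrence boosts), numeric features are linear in the label vector
    plus Gaussian noise, the optional image embedding is a label-shifted
    Gaussian 256-vector, and missingness configured in ``cfg`` is applied at
    the end.
    """
    rng = np.random.default_rng(cfg.seed)
    catalog = default_catalog(cfg.include_image)

    effects: dict[str, np.ndarray] = {}
    for name, _, _, _, eff in _NUMERIC_FEATURES:
        vec = np.zeros(13)
        for lab, v in eff.items():
            vec[LABELS.index(lab)] = v * cfg.effect_scale
        effects[name] = vec
    effects["sex"] = np.zeros(13)

    image_dirs = None
    if cfg.include_image:
        image_dirs = {}
        vec = np.zeros(13)
        for lab in ("DE", "AD"):
            d = rng.normal(size=256)
            image_dirs[lab] = d / np.linalg.norm(d)
            vec[LABELS.index(lab)] = cfg.image_effect_scale
        effects["mri_t1"] = vec  # magnitude of the mean shift along each direction

    records: list[SubjectRecord] = []
    width = len(str(max(cfg.n_subjects - 1, 1)))
    for k in range(cfg.n_subjects):
        labels = _draw_labels(cfg, rng)
        values: dict[str, object] = {}
        for name, _, base, sd, _ in _NUMERIC_FEATURES:
            mu = base + float(effects[name] @ labels)
            values[name] = float(mu + rng.normal(0.0, sd * cfg.noise_scale))
        values["sex"] = "male" if rng.random() < 0.5 else "female"
        if cfg.include_image:
            mu = np.zeros(256)
            for lab, d in image_dirs.items():
                mu += labels[LABELS.index(lab)] * cfg.image_effect_scale * d
            values["mri_t1"] = mu + rng.normal(0.0, cfg.noise_scale, size=256)
        age = values["age"]
        strata = {
            "age_bin": "<65" if age < 65 else ("65-75" if age < 75 else ">75"),
            "gender": values["sex"],
            "race": str(rng.choice(["white", "black", "asian", "other"],
                                   p=[0.7, 0.15, 0.1, 0.05])),
        }
        records.append(SubjectRecord(subject_id=f"S{k:0{width}d}", values=values,
                                     labels=labels, strata=strata))

    signal = [lab for i, lab in enumerate(LABELS)
              if sum(abs(v[i]) for v in effects.values()) >= 1.0 * cfg.effect_scale]
    if "NC" not in signal and cfg.effect_scale > 0:
        signal.insert(0, "NC")  # NC is identified by the absence of impairment effects

    rates = dict(cfg.feature_missing_rates)
    if cfg.missingness_profile is not None:
        base = MISSINGNESS_PROFILES[cfg.missingness_profile]
        for g in catalog.groups:
            rates.setdefault(g, base)
    realized: dict[str, float] = {}
    if rates or cfg.label_missing_rates:
        records, realized = apply_missingness(
            records, catalog, rates, cfg.label_missing_rates,
            rng=np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0]),
        )
    return SimulatedCohort(records=records, catalog=catalog, effects=effects,
                           signal_labels=signal, config=cfg,
                           realized_missingness=realized, image_directions=image_dirs)


def apply_missingness(
    records: list[SubjectRecord],
    catalog: FeatureCatalog,
    group_rates: dict[str, float],
    label_rates: dict[str, float] | float | None = None,
    rng: np.random.Generator | None = None,
    mar: tuple[str, float] | None = None,
) -> tuple[list[SubjectRecord], dict[str, float]]:
    """Inject MCAR feature missingness per group and UNKNOWN labels per label.

    ``mar`` optionally makes feature missingness informative: a (label,
    multiplier) pair scales every group rate for subjects positive for that
    label (rates clipped to 1).  Never removes a subject's last observed
    feature.  Returns new records plus the realized per-group missing
    fractions.
    """
    if rng is None:
        rng = np.random.default_rng()
    for g, r in group_rates.items():
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"rate for group {g!r} outside [0, 1]: {r}")
        if g not in catalog.groups:
            raise KeyError(f"unknown group tag {g!r}")
    if label_rates is None:
        label_rates = {}
    elif isinstance(label_rates, (int, float)):
        label_rates = {lab: float(label_rates) for lab in LABELS}

    feat_group = {e.name: e.group for e in catalog}
    dropped = {g: 0 for g in group_rates}
    total = {g: 0 for g in group_rates}
    if mar is not None and mar[0] not in LABELS:
        raise ValueError(f"unknown label in MAR hook: {mar[0]!r}")
    out: list[SubjectRecord] = []
    for rec in records:
        values = dict(rec.values)
        scale = 1.0
        if mar is not None and rec.labels[LABELS.index(mar[0])] == 1:
            scale = mar[1]
        rates_here = {g: min(r * scale, 1.0) for g, r in group_rates.items()}
        observed = [n for n in catalog.names if values.get(n, MISSING) is not MISSING]
        for name in observed:
            g = feat_group.get(name)
            if g in group_rates:
                total[g] += 1
        drop = [n for n in observed
                if feat_group.get(n) in rates_here
                and rng.random() < rates_here[feat_group[n]]]
        if len(drop) == len(observed) and observed:
            keep = observed[int(rng.integers(len(observed)))]
            drop = [n for n in drop if n != keep]
        for n in drop:
            values[n] = MISSING
            dropped[feat_group[n]] += 1
        labels = np.asarray(rec.labels).copy()
        for lab, r in label_rates.items():
            if labels[LABELS.index(lab)] != UNKNOWN and rng.random() < r:
                labels[LABELS.index(lab)] = UNKNOWN
        out.append(SubjectRecord(subject_id=rec.subject_id, values=values,
                                 labels=labels, strata=dict(rec.strata)))
    realized = {g: (dropped[g] / total[g] if total[g] else 0.0) for g in group_rates}
    return out, realized
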