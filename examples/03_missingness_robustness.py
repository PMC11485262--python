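"""Missingness sweep: how much performance survives when feature groups vanish.

Trains a small model, then re-scores the test split with entire feature
groups masked at inference time (the same operation the model saw during
random feature masking in training).  AUROC near the baseline means the
remaining features carry the signal; a drop toward 0.5 means the masked
group was essential for that label.
"""

import numpy as np

from mmdx import (LossConfig, ModelConfig, SyntheticConfig, TrainConfig,
                  missingness_sweep, simulate_cohort, train_model)

cohort = simulate_cohort(SyntheticConfig(n_subjects=1200, seed=13))
recs = cohort.records
ckpt = train_model(
    recs[:800], recs[800:1000], cohort.catalog,
    ModelConfig(d_model=32, n_layers=2, n_heads=4),
    LossConfig(), TrainConfig(epochs=10, first_restart=10, seed=2),
)

scenarios = {
    "baseline": [],
    "no NP tests": ["NP tests"],
    "no MRI": ["MRI"],
    "no noise group": ["noise"],      # planted pure-noise group: should not matter
    "NP+FAQ+MRI gone": ["NP tests", "FAQ", "MRI"],
}
table = missingness_sweep(ckpt, recs[1000:], scenarios, label_subset=("NC", "MCI", "DE"))

print(f"{'scenario':18s}  NC     MCI    DE")
for name, row in table.items():
    print(f"{name:18s}  " + "  ".join(f"{row[lab]:.3f}" for lab in ("NC", "MCI", "DE")))
print("\nMasking the pure-noise group leaves AUROC essentially unchanged;")
print("removing the cognitive-test groups costs the most for MCI/DE detection.")
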