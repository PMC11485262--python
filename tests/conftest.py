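import numpy as np
import pytest

from mmdx.backbone import ModelConfig, init_backbone_params
from mmdx.embedding import init_embedding_params, fit_feature_stats, FeatureStats
from mmdx.schema import (FeatureCatalog, FeatureSpec, SubjectRecord, UNKNOWN)
from mmdx.training import Checkpoint, LossConfig, TrainConfig


@pytest.fixture
def small_catalog() -> FeatureCatalog:
    return FeatureCatalog(entries=[
        FeatureSpec(name="age", modality="numeric", group="demographics"),
        FeatureSpec(name="sex", modality="categorical",
                    categories=["female", "male"], group="demographics"),
        FeatureSpec(name="moca", modality="numeric", group="NP tests"),
        FeatureSpec(name="faq", modality="numeric", group="FAQ"),
    ])


@pytest.fixture
def small_records(small_catalog) -> list[SubjectRecord]:
    from mmdx.schema import MISSING

    labels0 = np.array([1, 0, 0] + [0] * 10)
    labels1 = np.array([0, 0, 1, 1] + [UNKNOWN] * 9)
    return [
        SubjectRecord("s0", {"age": 71.0, "sex": "female", "moca": 28.0, "faq": 0.0},
                      labels0, {"age_bin": "65-75", "gender": "female", "race": "white"}),
        SubjectRecord("s1", {"age": 80.0, "sex": "male", "moca": 17.0, "faq": MISSING},
                      labels1, {"age_bin": ">75", "gender": "male", "race": "black"}),
    ]


def make_checkpoint(catalog, seed=0, d_model=16, n_layers=1, n_heads=2,
                    pooling="learned_cls_token", records=None) -> Checkpoint:
    """Random-weight checkpoint for inference-path tests (no training)."""
    rng = np.random.default_rng(seed)
    cfg = ModelConfig(d_model=d_model, n_layers=n_layers, n_heads=n_heads,
                      pooling=pooling, dropout_rate=0.0, seed=seed)
    params = {**init_embedding_params(catalog, d_model, rng),
              **init_backbone_params(cfg, rng)}
    stats = (fit_feature_stats(records, catalog) if records
             else FeatureStats(mean={}, std={}))
    return Checkpoint(
        model_config=cfg, loss_config=LossConfig(alpha=[0.5] * 13),
        train_config=TrainConfig(epochs=1, first_restart=1, seed=seed),
        catalog=catalog, params=params, stats=stats, alpha=np.full(13, 0.5),
    )


@pytest.fixture
def small_checkpoint(small_catalog, small_records) -> Checkpoint:
    return make_checkpoint(small_catalog, records=small_records)
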