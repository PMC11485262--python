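"""Loss functions, masking strategies, and the training loop.

The composite objective is

    L = L_FL + lambda * L_RL + beta * ||w||^2

where L_FL is a class-balanced focal loss over the 13 binary heads
(focusing exponent gamma, per-label balance alpha_i set to the squared
complement of the label's positive fraction on the training split), L_RL is
a pairwise margin ranking loss pushing sigmoid outputs of positive labels
above negative ones by a margin epsilon within each subject, and ||w||^2
sums squared trainable weights excluding normalization parameters and
biases.  Both loss sums are normalized by the batch size N, with masked
(UNKNOWN) label terms zeroed — exactly the written equations, not an average
over unmasked counts (the alternative is available behind a flag).

Robustness to missing data is trained in by *random feature masking*: for a
record with observed feature set S, draw a uniform permutation sigma of S
and an integer i uniform on [1, |S|], then hide sigma_{i+1..|S|} from the
attention mechanism.  The number of features kept is uniform on {1..|S|}, at
least one feature always survives, and the mask is redrawn every batch.

Missing labels never contribute loss or gradient: a binary label mask zeroes
their terms before backpropagation.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from pydantic import BaseModel, model_validator

from .autodiff import Tensor, as_tensor
from .backbone import ModelConfig, N_LABELS, forward, init_backbone_params
from .embedding import (FeatureStats, TokenBatch, assemble_tokens,
                        fit_feature_stats, init_embedding_params)
from .optim import AdamW, CosineWarmRestarts
from .schema import UNKNOWN, FeatureCatalog, LabelSchema, SubjectRecord

__all__ = [
    "LossConfig", "TrainConfig", "Checkpoint", "compute_alpha", "focal_loss",
    "ranking_loss", "total_loss", "sample_feature_mask", "label_loss_mask",
    "train_model", "predict",
]

_PROB_EPS = 1e-7  # probabilities clamped to [eps, 1-eps] before logs


class LossConfig(BaseModel):
    gamma: float = 2.0
    epsilon: float = 0.25
    lam: float = 0.005
    beta: float = 0.0005
    alpha: list[float] | None = None  # 13-vector; computed from data when None
    batch_size: int = 128
    normalize_by: str = "batch"  # or "unmasked": divide by the unmasked-term count

    @model_validator(mode="after")
    def _check(self):
        if self.gamma < 0 or self.epsilon < 0:
            raise ValueError("gamma and epsilon must be non-negative")
        if self.alpha is not None:
            a = np.asarray(self.alpha)
            if a.shape != (N_LABELS,) or np.any((a < 0) | (a > 1)):
                raise ValueError("alpha must be 13 values in [0, 1]")
        if self.normalize_by not in ("batch", "unmasked"):
            raise ValueError("normalize_by must be 'batch' or 'unmasked'")
        return self


class TrainConfig(BaseModel):
    lr: float = 0.001
    epochs: int = 256
    first_restart: int = 64
    period_multiplier: int = 2
    selection_metric: str = "micro_auroc"  # or "macro_auroc", "loss"
    feature_masking: bool = True
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.epochs < 1 or self.first_restart < 1:
            raise ValueError("epochs and first_restart must be >= 1")
        return self


# ----------------------------------------------------------------------- losses

def compute_alpha(labels: np.ndarray) -> np.ndarray:
    """Per-label balance alpha_i = (1 - f_i)^2 with f_i the positive fraction
    among known (non-UNKNOWN) entries of the training split."""
    labels = np.asarray(labels)
    known = labels != UNKNOWN
    n_known = known.sum(axis=0)
    if np.any(n_known == 0):
        bad = [int(i) for i in np.where(n_known == 0)[0]]
        raise ValueError(f"label column(s) {bad} have no known entries")
    f = (labels == 1).sum(axis=0) / n_known
    return (1.0 - f) ** 2


def _prep(probs, labels, label_mask, cfg: LossConfig):
    p = as_tensor(probs)
    labels = np.asarray(labels)
    mask = np.asarray(label_mask, dtype=bool)
    y = np.where(labels == 1, 1.0, 0.0)
    alpha = np.asarray(cfg.alpha if cfg.alpha is not None else np.full(N_LABELS, 0.5))
    n = p.shape[0]
    return p, y, mask.astype(float), alpha, n


def focal_loss(probs, labels, label_mask, cfg: LossConfig):
    """Class-balanced focal loss; UNKNOWN-label terms contribute exactly zero.

    Accepts numpy arrays (returns float) or autodiff tensors (returns a
    Tensor on the tape).
    """
    p, y, m, alpha, n = _prep(probs, labels, label_mask, cfg)
    pc = p.clamp(_PROB_EPS, 1.0 - _PROB_EPS)
    pos = pc.log() * ((1.0 - pc) ** cfg.gamma) * Tensor(-y * alpha * m)
    neg = (1.0 - pc).log() * (pc ** cfg.gamma) * Tensor(-(1.0 - y) * (1.0 - alpha) * m)
    denom = float(m.sum()) if cfg.normalize_by == "unmasked" else n
    out = (pos + neg).sum() * (1.0 / max(denom, 1))
    return out if isinstance(probs, Tensor) else out.item()


def ranking_loss(probs, labels, label_mask, cfg: LossConfig):
    """Pairwise margin ranking loss over label pairs i < j within each subject.

    Only pairs with both labels known contribute; equal-label pairs
    contribute the constant margin epsilon exactly as written (their
    gradient is zero since (y_j - y_i) = 0).
    """
    p, y, m, _, n = _prep(probs, labels, label_mask, cfg)
    diff = p.reshape(n, N_LABELS, 1) - p.reshape(n, 1, N_LABELS)      # p_i - p_j
    ydiff = y[:, None, :] - y[:, :, None]                             # y_j - y_i
    hinge = (diff * Tensor(ydiff) + cfg.epsilon).maximum(0.0)
    upper = np.triu(np.ones((N_LABELS, N_LABELS)), k=1)
    pair_mask = m[:, :, None] * m[:, None, :] * upper
    denom = float(pair_mask.sum()) if cfg.normalize_by == "unmasked" else n
    out = (hinge * Tensor(pair_mask)).sum() * (1.0 / max(denom, 1))
    return out if isinstance(probs, Tensor) else out.item()


def l2_penalty(params: dict[str, Tensor]):
    """Sum of squared trainable weights, excluding norm parameters and biases."""
    terms = [(p * p).sum() for name, p in params.items() if AdamW.decays(name)]
    out = terms[0]
    for t in terms[1:]:
        out = out + t
    return out


def total_loss(probs, labels, label_mask, weights: dict[str, Tensor] | None, cfg: LossConfig):
    """L = L_FL + lambda * L_RL + beta * ||w||^2."""
    fl = focal_loss(as_tensor(probs), labels, label_mask, cfg)
    rl = ranking_loss(as_tensor(probs), labels, label_mask, cfg)
    out = fl + cfg.lam * rl
    if weights and cfg.beta:
        out = out + cfg.beta * l2_penalty(weights)
    return out if isinstance(probs, Tensor) else out.item()


# ---------------------------------------------------------------------- masking

def sample_feature_mask(observed_features: Sequence, rng: np.random.Generator) -> set:
    """Features to hide for one record: permute the observed set S, draw i
    uniform on [1, |S|], mask the last |S| - i permuted features.

    At least one feature always survives (|S| = 1 never masks anything)."""
    s = list(observed_features)
    if not s:
        raise ValueError("observed feature set is empty")
    sigma = [s[j] for j in rng.permutation(len(s))]
    i = int(rng.integers(1, len(s) + 1))
    return set(sigma[i:])


def label_loss_mask(labels: np.ndarray) -> np.ndarray:
    """True where a label is known (0/1), false where UNKNOWN."""
    return np.asarray(labels) != UNKNOWN


def _draw_train_masks(observed: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = observed.copy()
    for r in range(observed.shape[0]):
        idx = np.where(observed[r])[0]
        if idx.size <= 1:
            continue
        drop = sample_feature_mask(idx.tolist(), rng)
        if drop:
            out[r, list(drop)] = False
    return out


# --------------------------------------------------------------------- training

@dataclass
class Checkpoint:
    """Trained model state: configs, parameters, and training statistics."""

    model_config: ModelConfig
    loss_config: LossConfig
    train_config: TrainConfig
    catalog: FeatureCatalog
    params: dict[str, Tensor]
    stats: FeatureStats
    alpha: np.ndarray
    best_epoch: int = -1
    best_score: float = float("nan")
    log: list[dict] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        meta = {
            "model_config": self.model_config.model_dump(),
            "loss_config": self.loss_config.model_dump(),
            "train_config": self.train_config.model_dump(),
            "catalog": [e.model_dump(exclude_none=True) for e in self.catalog.entries],
            "stats": {"mean": self.stats.mean, "std": self.stats.std},
            "alpha": list(map(float, self.alpha)),
            "best_epoch": self.best_epoch,
            "best_score": self.best_score,
            "log": self.log,
        }
        arrays = {f"param::{k}": v.data for k, v in self.params.items()}
        np.savez(path, __meta__=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        from .schema import FeatureSpec

        with np.load(Path(path), allow_pickle=False) as z:
            meta = json.loads(str(z["__meta__"]))
            params = {
                k[len("param::"):]: Tensor(z[k], requires_grad=True)
                for k in z.files if k.startswith("param::")
            }
        return cls(
            model_config=ModelConfig(**meta["model_config"]),
            loss_config=LossConfig(**meta["loss_config"]),
            train_config=TrainConfig(**meta["train_config"]),
            catalog=FeatureCatalog(entries=[FeatureSpec(**e) for e in meta["catalog"]]),
            params=params,
            stats=FeatureStats(**meta["stats"]),
            alpha=np.asarray(meta["alpha"]),
            best_epoch=meta["best_epoch"],
            best_score=meta["best_score"],
            log=meta["log"],
        )


def predict(ckpt: Checkpoint, records: list[SubjectRecord], feature_mask=None,
            allow_empty: bool = False):
    """Score records with a trained checkpoint (optionally hiding features)."""
    from .backbone import score_records

    return score_records(records, ckpt.catalog, ckpt.params, ckpt.model_config,
                         ckpt.stats, feature_mask=feature_mask, allow_empty=allow_empty)


def _labels_matrix(records: list[SubjectRecord]) -> np.ndarray:
    return np.stack([np.asarray(r.labels) for r in records])


def _validation_score(ckpt_like, records, metric: str) -> float:
    from .evaluate import average_metrics

    preds = predict(ckpt_like, records)
    labels = _labels_matrix(records)
    scheme = "micro" if metric == "micro_auroc" else "macro"
    try:
        return average_metrics(preds.probs, labels, scheme)["auroc"]
    except ValueError:
        return float("nan")


def train_model(
    train_records: list[SubjectRecord],
    val_records: list[SubjectRecord],
    catalog: FeatureCatalog,
    model_cfg: ModelConfig,
    loss_cfg: LossConfig,
    train_cfg: TrainConfig,
) -> Checkpoint:
    """Mini-batch AdamW training with cosine warm restarts and epoch-best selection.

    Per batch: redraw each record's feature dropout mask, embed, run the
    masked encoder, and minimize the composite loss with UNKNOWN labels
    masked out.  After every epoch the model is scored on the validation
    split; the checkpoint returned is the epoch with the best validation
    score.  A fixed master seed fans out to weight init, shuffling, feature
    masking and dropout, so runs are exactly reproducible.
    """
    train_ids = {r.subject_id for r in train_records}
    if train_ids & {r.subject_id for r in val_records}:
        raise ValueError("train and validation splits must be subject-disjoint")

    master = np.random.SeedSequence(train_cfg.seed)
    init_rng, shuffle_rng, mask_rng, drop_rng = (
        np.random.default_rng(s) for s in master.spawn(4)
    )

    stats = fit_feature_stats(train_records, catalog)
    labels_all = _labels_matrix(train_records)
    loss_cfg = loss_cfg.model_copy()
    if loss_cfg.alpha is None:
        loss_cfg.alpha = [float(a) for a in compute_alpha(labels_all)]

    params = {
        **init_embedding_params(catalog, model_cfg.d_model, init_rng),
        **init_backbone_params(model_cfg, init_rng),
    }
    opt = AdamW(params, lr=train_cfg.lr)
    sched = CosineWarmRestarts(train_cfg.lr, train_cfg.first_restart,
                               train_cfg.period_multiplier)

    ckpt = Checkpoint(model_cfg, loss_cfg, train_cfg, catalog, params, stats,
                      np.asarray(loss_cfg.alpha))
    best_params: dict[str, Tensor] | None = None
    best_score = -np.inf
    n = len(train_records)
    bs = loss_cfg.batch_size

    for epoch in range(train_cfg.epochs):
        opt.lr = sched.lr_at(epoch)
        order = shuffle_rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, bs):
            idx = order[start:start + bs]
            recs = [train_records[i] for i in idx]
            labels_b = labels_all[idx]
            lmask = label_loss_mask(labels_b)
            batch = assemble_tokens(recs, catalog, params, stats=stats)
            if train_cfg.feature_masking:
                tm = _draw_train_masks(batch.observed_mask, mask_rng)
                batch = TokenBatch(batch.tokens, batch.observed_mask, tm)
            preds = forward(batch, model_cfg, params, training=True, rng=drop_rng)
            probs_t = preds.logits_t.sigmoid()
            loss = total_loss(probs_t, labels_b, lmask, params, loss_cfg)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch {n_batches}; lr={opt.lr:.3g}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            n_batches += 1

        val = _validation_score(ckpt, val_records, train_cfg.selection_metric)
        mean_loss = epoch_loss / max(n_batches, 1)
        score = -mean_loss if train_cfg.selection_metric == "loss" else val
        ckpt.log.append({
            "epoch": epoch, "lr": opt.lr, "train_loss": mean_loss,
            "val_score": None if np.isnan(val) else val,
        })
        if np.isfinite(score) and score > best_score:
            best_score = score
            ckpt.best_epoch = epoch
            best_params = {k: Tensor(p.data.copy(), requires_grad=True)
                           for k, p in params.items()}

    if best_params is not None:
        ckpt.params = best_params
        ckpt.best_score = float(best_score)
    return ckpt
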