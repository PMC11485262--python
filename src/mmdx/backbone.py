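"""Masked transformer encoder over feature tokens with 13 binary heads.

The central contract is *masking soundness*: the logits depend only on tokens
whose ``train_mask`` entry is true.  Masked tokens are removed from attention
as keys/values in every layer (additive mask before the softmax) and excluded
from pooling, so no value stored at a masked position can influence any
output — for any weights.  This is what lets training-time feature dropout
faithfully emulate missing data, and what makes Shapley coalitions cheap to
evaluate at inference time.

Pooling is a learned classification token by default (it attends to the
visible feature tokens; nothing attends back to it as a query destination for
features is irrelevant — it participates as both query and key).  A
masked-mean alternative averages the visible tokens' final representations.
The pooled vector feeds one affine layer producing 13 logits; probabilities
are independent sigmoids (labels may co-occur, so there is no softmax
coupling across heads).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from pydantic import BaseModel, model_validator

from .autodiff import Tensor, concat, masked_softmax, no_grad
from .embedding import TokenBatch

__all__ = ["ModelConfig", "PredictionSet", "init_backbone_params", "forward",
           "predict_proba", "N_LABELS"]

N_LABELS = 13


class ModelConfig(BaseModel):
    d_model: int = 256
    n_layers: int = 4
    n_heads: int = 4
    feedforward_width: int | None = None  # defaults to 4 * d_model
    pooling: str = "learned_cls_token"    # or "masked_mean"
    dropout_rate: float = 0.1
    seed: int = 0

    @model_validator(mode="after")
    def _check(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.pooling not in ("learned_cls_token", "masked_mean"):
            raise ValueError(f"unknown pooling {self.pooling!r}")
        if self.feedforward_width is None:
            object.__setattr__(self, "feedforward_width", 4 * self.d_model)
        return self


@dataclass
class PredictionSet:
    """Logits and elementwise-sigmoid probabilities, one column per label."""

    logits: np.ndarray  # [N, 13]
    probs: np.ndarray   # [N, 13]
    logits_t: Tensor | None = field(default=None, repr=False)  # kept when training


def init_backbone_params(config: ModelConfig, rng: np.random.Generator) -> dict[str, Tensor]:
    d = config.d_model
    ff = config.feedforward_width
    params: dict[str, Tensor] = {}

    def xavier(n_in, n_out):
        return Tensor(rng.normal(0.0, math.sqrt(1.0 / n_in), size=(n_in, n_out)),
                      requires_grad=True)

    if config.pooling == "learned_cls_token":
        params["cls_token"] = Tensor(rng.normal(0.0, 0.02, size=(d,)), requires_grad=True)
    for layer in range(config.n_layers):
        p = f"layer{layer}"
        for proj in ("q", "k", "v", "o"):
            params[f"{p}.attn.{proj}"] = xavier(d, d)
            params[f"{p}.attn.{proj}_bias"] = Tensor(np.zeros(d), requires_grad=True)
        params[f"{p}.norm1.gain"] = Tensor(np.ones(d), requires_grad=True)
        params[f"{p}.norm1.bias"] = Tensor(np.zeros(d), requires_grad=True)
        params[f"{p}.ffn.w1"] = xavier(d, ff)
        params[f"{p}.ffn.w1_bias"] = Tensor(np.zeros(ff), requires_grad=True)
        params[f"{p}.ffn.w2"] = xavier(ff, d)
        params[f"{p}.ffn.w2_bias"] = Tensor(np.zeros(d), requires_grad=True)
        params[f"{p}.norm2.gain"] = Tensor(np.ones(d), requires_grad=True)
        params[f"{p}.norm2.bias"] = Tensor(np.zeros(d), requires_grad=True)
    params["final_norm.gain"] = Tensor(np.ones(d), requires_grad=True)
    params["final_norm.bias"] = Tensor(np.zeros(d), requires_grad=True)
    params["head.weight"] = xavier(d, N_LABELS)
    params["head.bias"] = Tensor(np.zeros(N_LABELS), requires_grad=True)
    return params


def _layer_norm(x: Tensor, gain: Tensor, bias: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc / ((var + eps) ** 0.5) * gain + bias


def _attention(x: Tensor, visible: np.ndarray, params, prefix: str,
               n_heads: int, dropout, rng) -> Tensor:
    n, t, d = x.shape
    dh = d // n_heads

    def split(z):  # [N,T,d] -> [N,H,T,dh]
        return z.reshape(n, t, n_heads, dh).transpose(0, 2, 1, 3)

    q = split(x @ params[f"{prefix}.q"] + params[f"{prefix}.q_bias"])
    k = split(x @ params[f"{prefix}.k"] + params[f"{prefix}.k_bias"])
    v = split(x @ params[f"{prefix}.v"] + params[f"{prefix}.v_bias"])
    scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(dh))  # [N,H,T,T]
    key_vis = visible[:, None, None, :]  # masked keys hidden from every query
    weights = masked_softmax(scores, key_vis)
    if dropout is not None:
        weights = weights * Tensor(dropout(rng, weights.shape))
    ctx = (weights @ v).transpose(0, 2, 1, 3).reshape(n, t, d)
    return ctx @ params[f"{prefix}.o"] + params[f"{prefix}.o_bias"]


def forward(
    batch: TokenBatch,
    config: ModelConfig,
    params: dict[str, Tensor],
    *,
    training: bool = False,
    rng: np.random.Generator | None = None,
    allow_empty: bool = False,
) -> PredictionSet:
    """Run the masked encoder; logits depend only on ``train_mask``-visible tokens.

    ``allow_empty`` permits records with no visible feature (used to evaluate
    the empty coalition in Shapley attribution); otherwise such rows are an
    error because a diagnosis from zero features is meaningless in training.
    """
    vis = batch.train_mask
    if not allow_empty and np.any(~vis.any(axis=1)):
        raise ValueError("record with all features masked; nothing visible to the model")

    n, f = vis.shape
    x = batch.tokens
    use_cls = config.pooling == "learned_cls_token"
    if use_cls:
        cls = params["cls_token"].reshape(1, 1, -1) * Tensor(np.ones((n, 1, 1)))
        x = concat([cls, x], axis=1)
        vis = np.concatenate([np.ones((n, 1), dtype=bool), vis], axis=1)

    drop = None
    if training and config.dropout_rate > 0:
        if rng is None:
            raise ValueError("training mode with dropout requires an rng")
        rate = config.dropout_rate

        def drop(r, shape):  # inverted dropout
            return (r.random(shape) >= rate) / (1.0 - rate)

    for layer in range(config.n_layers):
        p = f"layer{layer}"
        h = _layer_norm(x, params[f"{p}.norm1.gain"], params[f"{p}.norm1.bias"])
        a = _attention(h, vis, params, f"{p}.attn", config.n_heads, drop, rng)
        if drop is not None:
            a = a * Tensor(drop(rng, a.shape))
        x = x + a
        h = _layer_norm(x, params[f"{p}.norm2.gain"], params[f"{p}.norm2.bias"])
        h = (h @ params[f"{p}.ffn.w1"] + params[f"{p}.ffn.w1_bias"]).gelu()
        h = h @ params[f"{p}.ffn.w2"] + params[f"{p}.ffn.w2_bias"]
        if drop is not None:
            h = h * Tensor(drop(rng, h.shape))
        x = x + h

    x = _layer_norm(x, params["final_norm.gain"], params["final_norm.bias"])
    if use_cls:
        pooled = x[:, 0, :]
    else:
        w = vis.astype(float)
        denom = np.maximum(w.sum(axis=1, keepdims=True), 1.0)
        pooled = (x * Tensor(w[:, :, None])).sum(axis=1) * Tensor(1.0 / denom)

    logits_t = pooled @ params["head.weight"] + params["head.bias"]
    logits = logits_t.data.copy()
    return PredictionSet(logits=logits, probs=predict_proba(logits), logits_t=logits_t)


def predict_proba(logits: np.ndarray) -> np.ndarray:
    """Elementwise sigmoid; the 13 heads are independent (labels can co-occur)."""
    z = np.asarray(logits, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("logits must be finite")
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def score_records(records, catalog, params, config, stats, *, feature_mask=None,
                  allow_empty=False) -> PredictionSet:
    """Convenience inference path: assemble tokens (no dropout) and run the encoder.

    ``feature_mask`` optionally hides additional observed features (a boolean
    [N, F] visibility matrix), e.g. for missingness sweeps or Shapley coalitions.
    """
    from .embedding import assemble_tokens

    with no_grad():
        batch = assemble_tokens(records, catalog, params, stats=stats)
        if feature_mask is not None:
            batch = TokenBatch(
                tokens=batch.tokens,
                observed_mask=batch.observed_mask,
                train_mask=batch.observed_mask & np.asarray(feature_mask, dtype=bool),
            )
        return forward(batch, config, params, training=False, allow_empty=allow_empty)
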