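"""Modality-specific feature embeddings and token assembly.

Every observed feature becomes one fixed-length token:

* numeric values pass through a single affine map (``value * w + b``) after
  z-scoring with training-split statistics;
* categorical codes index a per-feature lookup table;
* imaging inputs arrive either as a precomputed 256-vector (projected
  linearly to the token width) or as an encoder-output grid of shape
  768 x 4 x 4 x 4 that a small learnable downsampler of four convolutional
  blocks reduces to a 256-vector first.

Unobserved features yield a zero-filled token plus a ``False`` entry in the
observation mask; the backbone's attention mask guarantees the zero filler is
never read.  The token sequence is a *set*: there are no positional
encodings, each feature is identified solely by its own embedding parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, stack
from .schema import MISSING, FeatureCatalog, SubjectRecord

__all__ = [
    "TokenBatch", "FeatureStats", "fit_feature_stats", "init_embedding_params",
    "embed_numeric", "embed_categorical", "embed_image_grid", "assemble_tokens",
    "count_parameters", "GRID_CHANNELS", "GRID_SPATIAL", "IMAGE_VECTOR_WIDTH",
]

GRID_CHANNELS = 768
GRID_SPATIAL = 4
IMAGE_VECTOR_WIDTH = 256

# channel progression of the four downsampling blocks; the first two halve the
# 4x4x4 spatial grid with stride-2 kernels, the last two are 1x1x1 convolutions
_DS_CHANNELS = (GRID_CHANNELS, 512, 384, 320, IMAGE_VECTOR_WIDTH)


@dataclass
class TokenBatch:
    """Embedded tokens plus observation and training-dropout masks.

    ``train_mask`` is always a subset of ``observed_mask``: training-time
    feature dropout can only hide features that exist, never resurrect
    missing ones.
    """

    tokens: Tensor              # [N, F, d_model]
    observed_mask: np.ndarray   # bool [N, F]
    train_mask: np.ndarray      # bool [N, F]

    def __post_init__(self):
        if np.any(self.train_mask & ~self.observed_mask):
            raise ValueError("train_mask must be a subset of observed_mask")


@dataclass
class FeatureStats:
    """Per-feature z-scoring statistics, frozen at fit time from the training split."""

    mean: dict[str, float]
    std: dict[str, float]


def fit_feature_stats(records: list[SubjectRecord], catalog: FeatureCatalog) -> FeatureStats:
    mean, std = {}, {}
    for spec in catalog:
        if spec.modality != "numeric":
            continue
        vals = [float(r.values[spec.name]) for r in records
                if r.values.get(spec.name, MISSING) is not MISSING]
        m = float(np.mean(vals)) if vals else 0.0
        s = float(np.std(vals)) if len(vals) > 1 else 1.0
        mean[spec.name] = m
        std[spec.name] = s if s > 1e-12 else 1.0
    return FeatureStats(mean=mean, std=std)


def init_embedding_params(
    catalog: FeatureCatalog, d_model: int, rng: np.random.Generator
) -> dict[str, Tensor]:
    """One parameter block per catalog feature, all producing width-``d_model`` tokens."""
    params: dict[str, Tensor] = {}

    def xavier(shape):
        fan_in = shape[0] if len(shape) > 1 else 1
        scale = np.sqrt(1.0 / max(fan_in, 1))
        return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)

    for spec in catalog:
        key = f"emb.{spec.name}"
        if spec.modality == "numeric":
            params[f"{key}.weight"] = xavier((d_model,))
            params[f"{key}.bias"] = Tensor(np.zeros(d_model), requires_grad=True)
        elif spec.modality == "categorical":
            params[f"{key}.table"] = Tensor(
                rng.normal(0.0, 1.0 / np.sqrt(d_model), size=(len(spec.categories), d_model)),
                requires_grad=True,
            )
        else:
            for i in range(4):
                c_in, c_out = _DS_CHANNELS[i], _DS_CHANNELS[i + 1]
                k = 8 if i < 2 else 1  # stride-2 kernel covers 2x2x2 = 8 cells
                params[f"{key}.ds{i}.weight"] = xavier((c_in * k, c_out))
                params[f"{key}.ds{i}.bias"] = Tensor(np.zeros(c_out), requires_grad=True)
            if spec.embedding_width == d_model:
                proj = np.eye(d_model)  # identity-initialized projection
            else:
                proj = rng.normal(0.0, 1.0 / np.sqrt(spec.embedding_width),
                                  size=(spec.embedding_width, d_model))
            params[f"{key}.proj"] = Tensor(proj, requires_grad=True)
            params[f"{key}.proj_bias"] = Tensor(np.zeros(d_model), requires_grad=True)
    return params


def count_parameters(params: dict[str, Tensor]) -> int:
    return int(sum(p.size for p in params.values()))


# ------------------------------------------------------------------ embeddings

def embed_numeric(value: float, weight: Tensor, bias: Tensor) -> Tensor:
    """Affine map of a (standardized) scalar: ``value * weight + bias``."""
    v = float(value)
    if not np.isfinite(v):
        raise ValueError("numeric value must be finite")
    return weight * v + bias


def embed_categorical(code: int, table: Tensor) -> Tensor:
    """Row ``code`` of the lookup table; distinct codes are independent parameters."""
    n = table.shape[0]
    if not (0 <= code < n):
        raise IndexError(f"category code {code} out of range [0, {n})")
    return table[int(code)]


def _downsample(grids: Tensor, params: dict[str, Tensor], key: str) -> Tensor:
    """Four convolutional blocks: [N,768,4,4,4] -> [N,256].

    The stride-2 blocks are expressed as a reshape of non-overlapping 2x2x2
    neighborhoods followed by a matmul, which is exactly a strided convolution.
    """
    n = grids.shape[0]
    x = grids  # [N, C, D, H, W]
    for i in range(4):
        c_in = x.shape[1]
        d = x.shape[2]
        w = params[f"{key}.ds{i}.weight"]
        b = params[f"{key}.ds{i}.bias"]
        if i < 2:
            # gather 2x2x2 blocks: [N,C,d/2,2,d/2,2,d/2,2] -> [N,d/2,d/2,d/2,C*8]
            x = x.reshape(n, c_in, d // 2, 2, d // 2, 2, d // 2, 2)
            x = x.transpose(0, 2, 4, 6, 1, 3, 5, 7)
            x = x.reshape(n, d // 2, d // 2, d // 2, c_in * 8)
            x = x @ w + b
            x = x.transpose(0, 4, 1, 2, 3)  # back to [N, C_out, d/2, d/2, d/2]
        else:
            # 1x1x1 convolution on the collapsed spatial grid
            s = x.shape[2] * x.shape[3] * x.shape[4]
            x = x.reshape(n, c_in, s).transpose(0, 2, 1) @ w + b
            x = x.transpose(0, 2, 1).reshape(n, w.shape[1], 1, 1, 1)
        if i < 3:
            x = x.relu()
    return x.reshape(n, IMAGE_VECTOR_WIDTH)


def embed_image_grid(grid, params: dict[str, Tensor], feature_name: str) -> Tensor:
    """Embed one imaging input: a 768x4x4x4 encoder grid (downsample + project)
    or a precomputed 256-vector (projection only)."""
    key = f"emb.{feature_name}"
    arr = grid.data if isinstance(grid, Tensor) else np.asarray(grid, dtype=float)
    if arr.shape == (IMAGE_VECTOR_WIDTH,):
        vec = Tensor(arr[None, :])
    elif arr.shape == (GRID_CHANNELS, GRID_SPATIAL, GRID_SPATIAL, GRID_SPATIAL):
        vec = _downsample(Tensor(arr[None]), params, key)
    else:
        raise ValueError(
            f"imaging input must be a ({IMAGE_VECTOR_WIDTH},) vector or a "
            f"({GRID_CHANNELS},{GRID_SPATIAL},{GRID_SPATIAL},{GRID_SPATIAL}) grid, got {arr.shape}"
        )
    return (vec @ params[f"{key}.proj"] + params[f"{key}.proj_bias"]).reshape(-1)


# -------------------------------------------------------------- token assembly

def assemble_tokens(
    records: list[SubjectRecord],
    catalog: FeatureCatalog,
    params: dict[str, Tensor],
    train_masks: np.ndarray | None = None,
    stats: FeatureStats | None = None,
) -> TokenBatch:
    """Embed a batch of records into a :class:`TokenBatch` in catalog order.

    When no dropout mask is supplied, ``train_mask`` equals the observation
    mask (all observed features visible).
    """
    n, f = len(records), len(catalog)
    observed = np.zeros((n, f), dtype=bool)
    columns: list[Tensor] = []

    for j, spec in enumerate(catalog):
        key = f"emb.{spec.name}"
        raw = [r.values.get(spec.name, MISSING) for r in records]
        obs = np.array([v is not MISSING for v in raw], dtype=bool)
        observed[:, j] = obs
        obs_col = obs[:, None].astype(float)

        if spec.modality == "numeric":
            vals = np.array([float(v) if o else 0.0 for v, o in zip(raw, obs)])
            if stats is not None and spec.name in stats.mean:
                vals = np.where(obs, (vals - stats.mean[spec.name]) / stats.std[spec.name], 0.0)
            w, b = params[f"{key}.weight"], params[f"{key}.bias"]
            if w.shape[0] != b.shape[0]:
                raise ValueError(f"width mismatch in embedding block for {spec.name!r}")
            col = (w * Tensor(vals[:, None]) + b) * Tensor(obs_col)
        elif spec.modality == "categorical":
            table = params[f"{key}.table"]
            codes = np.array(
                [spec.categories.index(v) if o else 0 for v, o in zip(raw, obs)], dtype=int
            )
            col = table[codes] * Tensor(obs_col)
        else:
            proj, pb = params[f"{key}.proj"], params[f"{key}.proj_bias"]
            vecs = np.zeros((n, spec.embedding_width))
            grid_rows = [i for i, (v, o) in enumerate(zip(raw, obs))
                         if o and np.asarray(v).ndim == 4]
            for i, (v, o) in enumerate(zip(raw, obs)):
                if o and i not in grid_rows:
                    vecs[i] = np.asarray(v, dtype=float)
            col = Tensor(vecs) @ proj
            if grid_rows:
                grids = Tensor(np.stack([np.asarray(raw[i], dtype=float) for i in grid_rows]))
                ds = _downsample(grids, params, key) @ proj
                sel = np.zeros((n, len(grid_rows)))
                sel[grid_rows, np.arange(len(grid_rows))] = 1.0
                col = col + Tensor(sel) @ ds
            col = (col + pb) * Tensor(obs_col)
        columns.append(col)

    widths = {c.shape[1] for c in columns}
    if len(widths) > 1:
        raise ValueError(f"embedding blocks disagree on token width: {sorted(widths)}")
    tokens = stack(columns, axis=1)  # [N, F, d]
    if train_masks is None:
        train_masks = observed.copy()
    else:
        train_masks = np.asarray(train_masks, dtype=bool)
    return TokenBatch(tokens=tokens, observed_mask=observed, train_mask=train_masks)
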