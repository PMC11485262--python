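"""Permutation-sampling Shapley attribution under the model's masking semantics.

Each subject is one "game": the players are the subject's *observed* features
and the payoff of a coalition is the model's output for the chosen label when
exactly those features are visible to the attention mechanism (no retraining,
no imputation — hiding a feature is the same operation the model was trained
to be robust to).  The Shapley value of feature j is the average of its
marginal contribution payoff(prefix + {j}) - payoff(prefix) over feature
orderings, sampled uniformly; enumerating all orderings gives the exact
value.  Features missing from the record are assigned a Shapley value of
exactly zero.

The empty coalition is evaluated in a dedicated no-feature mode in which only
the pooled/CLS pathway is active, so payoff(empty) is a record-independent
constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations
from math import factorial

import numpy as np

from .autodiff import Tensor, no_grad
from .backbone import forward
from .embedding import TokenBatch, assemble_tokens
from .schema import FeatureCatalog, SubjectRecord

__all__ = ["ShapleyResult", "shapley_estimate", "rank_global_features"]


@dataclass
class ShapleyResult:
    subject_id: str
    label: str
    values: dict[str, float]   # feature -> estimated Shapley value (absent -> 0.0)
    n_permutations: int
    payoff: str                # "prob" or "logit"
    exact: bool


class _CoalitionPayoff:
    """Memoized payoff oracle: coalition (frozenset of feature indices) -> payoff."""

    def __init__(self, ckpt, record: SubjectRecord, label_index: int, payoff: str):
        self.ckpt = ckpt
        self.label_index = label_index
        self.payoff = payoff
        with no_grad():
            batch = assemble_tokens([record], ckpt.catalog, ckpt.params, stats=ckpt.stats)
        self._tokens = batch.tokens.data  # (1, F, d)
        self._observed = batch.observed_mask  # (1, F)
        self.cache: dict[frozenset, float] = {}

    def evaluate(self, coalitions: list[frozenset], chunk: int = 512) -> None:
        todo = [c for c in dict.fromkeys(coalitions) if c not in self.cache]
        f = self._tokens.shape[1]
        for start in range(0, len(todo), chunk):
            batch_cs = todo[start:start + chunk]
            m = len(batch_cs)
            vis = np.zeros((m, f), dtype=bool)
            for r, c in enumerate(batch_cs):
                vis[r, list(c)] = True
            tb = TokenBatch(
                tokens=Tensor(np.broadcast_to(self._tokens, (m,) + self._tokens.shape[1:]).copy()),
                observed_mask=np.broadcast_to(self._observed, (m, f)).copy(),
                train_mask=vis,
            )
            with no_grad():
                preds = forward(tb, self.ckpt.model_config, self.ckpt.params,
                                allow_empty=True)
            out = preds.probs if self.payoff == "prob" else preds.logits
            for r, c in enumerate(batch_cs):
                self.cache[c] = float(out[r, self.label_index])

    def __getitem__(self, coalition: frozenset) -> float:
        return self.cache[coalition]


def shapley_estimate(
    ckpt,
    record: SubjectRecord,
    label_index: int,
    n_perms: int = 128,
    rng: np.random.Generator | None = None,
    *,
    payoff: str = "prob",
    exact: bool = False,
) -> ShapleyResult:
    """Estimate per-feature Shapley values for one record and one label head.

    With ``exact=True`` all |S|! orderings are enumerated (feasible for small
    feature sets) and the result is the exact Shapley value; otherwise
    ``n_perms`` orderings are sampled uniformly, giving an unbiased estimate.
    """
    if payoff not in ("prob", "logit"):
        raise ValueError("payoff must be 'prob' or 'logit'")
    catalog: FeatureCatalog = ckpt.catalog
    observed = record.observed(catalog)
    if not observed:
        raise ValueError(f"subject {record.subject_id}: no observed features")
    name_to_idx = {n: i for i, n in enumerate(catalog.names)}
    obs_idx = [name_to_idx[n] for n in observed]

    if exact:
        perms = list(permutations(obs_idx))
    else:
        if n_perms < 1:
            raise ValueError("n_perms must be >= 1")
        if rng is None:
            rng = np.random.default_rng()
        perms = [tuple(np.array(obs_idx)[rng.permutation(len(obs_idx))]) for _ in range(n_perms)]

    oracle = _CoalitionPayoff(ckpt, record, label_index, payoff)
    needed = [frozenset()]
    for perm in perms:
        for t in range(1, len(perm) + 1):
            needed.append(frozenset(perm[:t]))
    oracle.evaluate(needed)

    totals = dict.fromkeys(obs_idx, 0.0)
    for perm in perms:
        prev = oracle[frozenset()]
        prefix: set[int] = set()
        for j in perm:
            prefix.add(j)
            cur = oracle[frozenset(prefix)]
            totals[j] += cur - prev
            prev = cur
    n_used = len(perms)
    values = {n: 0.0 for n in catalog.names}  # absent features stay exactly 0
    for j, tot in totals.items():
        values[catalog.names[j]] = tot / n_used

    from .schema import LABELS

    return ShapleyResult(
        subject_id=record.subject_id,
        label=LABELS[label_index],
        values=values,
        n_permutations=n_used if not exact else factorial(len(obs_idx)),
        payoff=payoff,
        exact=exact,
    )


def rank_global_features(
    ckpt,
    records: list[SubjectRecord],
    label: str,
    n_cases: int = 500,
    n_perms: int = 128,
    rng: np.random.Generator | None = None,
    *,
    payoff: str = "prob",
) -> list[tuple[str, float]]:
    """Rank features by mean Shapley value over confidently-predicted cases.

    Cases with a positive logit for ``label`` are filtered in, the ``n_cases``
    with the most observed features are kept (ties broken by subject_id), and
    per-feature Shapley values are averaged with absent features contributing
    their zero value to the mean.  Returns (feature, mean value) sorted
    descending.
    """
    from .schema import LABELS
    from .training import predict

    if rng is None:
        rng = np.random.default_rng()
    li = LABELS.index(label)
    preds = predict(ckpt, records)
    qualifying = [(r, preds.logits[i, li]) for i, r in enumerate(records)
                  if preds.logits[i, li] > 0]
    if not qualifying:
        raise ValueError(f"no qualifying cases: no record has logit > 0 for {label}")
    ordered = sorted(qualifying, key=lambda t: (-t[0].n_observed(ckpt.catalog),
                                                t[0].subject_id))
    selected = [r for r, _ in ordered[:n_cases]]

    sums = dict.fromkeys(ckpt.catalog.names, 0.0)
    for rec in selected:
        res = shapley_estimate(ckpt, rec, li, n_perms=n_perms, rng=rng, payoff=payoff)
        for name, v in res.values.items():
            sums[name] += v
    means = {name: s / len(selected) for name, s in sums.items()}
    return sorted(means.items(), key=lambda kv: -kv[1])
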