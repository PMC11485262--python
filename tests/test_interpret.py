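"""Shapley estimator: exactness, efficiency, symmetry, and ranking protocol."""

from itertools import combinations
from math import factorial

import numpy as np
import pytest

from mmdx.interpret import _CoalitionPayoff, rank_global_features, shapley_estimate
from mmdx.schema import (LABELS, MISSING, FeatureCatalog, FeatureSpec,
                         SubjectRecord)

from conftest import make_checkpoint


@pytest.fixture
def three_feature_setup():
    catalog = FeatureCatalog(entries=[
        FeatureSpec(name=f"f{i}", modality="numeric") for i in range(3)
    ])
    rec = SubjectRecord("s0", {"f0": 0.7, "f1": -1.2, "f2": 0.3},
                        np.zeros(13, dtype=int))
    ckpt = make_checkpoint(catalog, seed=3, d_model=8, n_heads=2, records=[rec])
    return ckpt, rec


def brute_force_shapley(payoff, players):
    """Exact Shapley values from the 2^F coalition formula."""
    n = len(players)
    values = {}
    for j in players:
        others = [p for p in players if p != j]
        total = 0.0
        for r in range(n):
            for coal in combinations(others, r):
                w = factorial(len(coal)) * factorial(n - len(coal) - 1) / factorial(n)
                total += w * (payoff(frozenset(coal) | {j}) - payoff(frozenset(coal)))
        values[j] = total
    return values


def test_exact_enumeration_matches_coalition_brute_force(three_feature_setup):
    ckpt, rec = three_feature_setup
    label = 2
    res = shapley_estimate(ckpt, rec, label, exact=True)
    oracle = _CoalitionPayoff(ckpt, rec, label, "prob")
    all_coals = [frozenset(c) for r in range(4) for c in combinations(range(3), r)]
    oracle.evaluate(all_coals)
    expected = brute_force_shapley(lambda c: oracle[c], [0, 1, 2])
    for j, name in enumerate(["f0", "f1", "f2"]):
        assert res.values[name] == pytest.approx(expected[j], abs=1e-10)


def test_efficiency_in_exact_mode(three_feature_setup):
    ckpt, rec = three_feature_setup
    res = shapley_estimate(ckpt, rec, 5, exact=True)
    oracle = _CoalitionPayoff(ckpt, rec, 5, "prob")
    oracle.evaluate([frozenset(), frozenset({0, 1, 2})])
    grand = oracle[frozenset({0, 1, 2})] - oracle[frozenset()]
    assert sum(res.values.values()) == pytest.approx(grand, abs=1e-8)


def test_additive_payoff_recovers_coefficients(monkeypatch, three_feature_setup):
    """For a payoff additive over visible features, every marginal contribution
    of feature j equals c_j regardless of order, so any number of sampled
    permutations returns c_j exactly."""
    ckpt, rec = three_feature_setup
    c = np.array([0.5, -0.2, 0.3])

    def fake_evaluate(self, coalitions, chunk=512):
        for coal in coalitions:
            self.cache[coal] = float(sum(c[j] for j in coal))

    monkeypatch.setattr(_CoalitionPayoff, "evaluate", fake_evaluate)
    res = shapley_estimate(ckpt, rec, 0, n_perms=2, rng=np.random.default_rng(0))
    for j, name in enumerate(["f0", "f1", "f2"]):
        assert res.values[name] == pytest.approx(c[j], abs=1e-12)


def test_missing_feature_gets_exactly_zero(three_feature_setup):
    ckpt, _ = three_feature_setup
    rec = SubjectRecord("s1", {"f0": 0.4, "f1": MISSING, "f2": 1.0},
                        np.zeros(13, dtype=int))
    res = shapley_estimate(ckpt, rec, 0, exact=True)
    assert res.values["f1"] == 0.0


def test_symmetry_for_identically_parameterized_features():
    catalog = FeatureCatalog(entries=[
        FeatureSpec(name="a", modality="numeric"),
        FeatureSpec(name="b", modality="numeric"),
        FeatureSpec(name="c", modality="numeric"),
    ])
    rec = SubjectRecord("s", {"a": 0.9, "b": 0.9, "c": -0.4}, np.zeros(13, dtype=int))
    ckpt = make_checkpoint(catalog, seed=4, d_model=8, n_heads=2)
    # tie the parameters of a and b; identical value + identical parameters
    # make them interchangeable players
    ckpt.params["emb.b.weight"].data[:] = ckpt.params["emb.a.weight"].data
    ckpt.params["emb.b.bias"].data[:] = ckpt.params["emb.a.bias"].data
    res = shapley_estimate(ckpt, rec, 1, exact=True)
    assert res.values["a"] == pytest.approx(res.values["b"], abs=1e-10)


def test_monte_carlo_estimate_converges_to_exact(three_feature_setup):
    ckpt, rec = three_feature_setup
    exact = shapley_estimate(ckpt, rec, 2, exact=True).values
    est = shapley_estimate(ckpt, rec, 2, n_perms=400,
                           rng=np.random.default_rng(11)).values
    for name in exact:
        assert est[name] == pytest.approx(exact[name], abs=0.02)


def test_rank_global_features_protocol(three_feature_setup):
    ckpt, rec = three_feature_setup
    recs = [
        SubjectRecord("p0", {"f0": 2.0, "f1": 0.1, "f2": 0.1}, np.zeros(13, dtype=int)),
        SubjectRecord("p1", {"f0": 1.5, "f1": MISSING, "f2": 0.2}, np.zeros(13, dtype=int)),
        SubjectRecord("p2", {"f0": -1.0, "f1": 0.3, "f2": 0.4}, np.zeros(13, dtype=int)),
    ]
    from mmdx.training import predict

    preds = predict(ckpt, recs)
    label = "NC"
    li = LABELS.index(label)
    qualifying = (preds.logits[:, li] > 0).sum()
    if qualifying == 0:
        with pytest.raises(ValueError, match="no qualifying"):
            rank_global_features(ckpt, recs, label, n_cases=2, n_perms=6,
                                 rng=np.random.default_rng(0))
    else:
        ranking = rank_global_features(ckpt, recs, label, n_cases=2, n_perms=6,
                                       rng=np.random.default_rng(0))
        assert len(ranking) == 3
        vals = [v for _, v in ranking]
        assert vals == sorted(vals, reverse=True)


def test_rank_global_zero_inclusion_mean(monkeypatch, three_feature_setup):
    """Absent features contribute their zero value to the mean."""
    ckpt, _ = three_feature_setup
    recs = [
        SubjectRecord("q0", {"f0": 1.0, "f1": 0.5, "f2": 0.5}, np.zeros(13, dtype=int)),
        SubjectRecord("q1", {"f0": 1.0, "f1": MISSING, "f2": 0.5}, np.zeros(13, dtype=int)),
    ]

    def fake_evaluate(self, coalitions, chunk=512):
        for coal in coalitions:
            self.cache[coal] = float(sum(0.4 for j in coal if j == 1))

    import mmdx.training as training

    monkeypatch.setattr(_CoalitionPayoff, "evaluate", fake_evaluate)

    class FakePreds:
        logits = np.ones((2, 13))

    monkeypatch.setattr(training, "predict", lambda *a, **k: FakePreds())
    import mmdx.interpret as interpret

    monkeypatch.setattr(interpret, "predict", lambda *a, **k: FakePreds(), raising=False)
    ranking = dict(rank_global_features(ckpt, recs, "DE", n_cases=2, n_perms=1,
                                        rng=np.random.default_rng(0)))
    # f1 is worth 0.4 when present, absent in one of two cases -> mean 0.2
    assert ranking["f1"] == pytest.approx(0.2, abs=1e-12)
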