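"""Confusion metrics, consensus, split validation, nulls, prioritization."""

import math

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score

from zebratox.evalx import (
    Confusion,
    confusion_from_calls,
    consensus_and,
    cross_validate,
    metrics,
    prioritization_estimate,
    random_search,
    shuffle_null,
)
from zebratox.toxdata import ActivityCall


def _calls(actives, n, prefix="c"):
    return [
        ActivityCall(chemical_id=f"{prefix}{i}", agg_entropy=20.0 if i in actives else 1.0, active=i in actives)
        for i in range(n)
    ]


def test_metrics_reproduce_printed_test_set_values():
    r = metrics(Confusion(tp=5, fn=2, fp=4, tn=45))
    assert (round(r.se, 1), round(r.sp, 1), round(r.ppv, 1)) == (71.4, 91.8, 55.6)
    assert round(r.kappa, 3) == 0.564
    assert round(r.auroc, 3) == 0.816
    rc = metrics(Confusion(tp=5, fn=2, fp=2, tn=47))
    assert (round(rc.sp, 1), round(rc.ppv, 1)) == (95.9, 71.4)
    assert round(rc.kappa, 3) == 0.673
    assert round(rc.auroc, 3) == 0.837


def test_perfect_classifier():
    r = metrics(Confusion(tp=7, fn=0, fp=0, tn=49))
    assert r.se == r.sp == r.ppv == 100.0
    assert r.kappa == 1.0 and r.auroc == 1.0


def test_metrics_match_bruteforce_recount(rng):
    for _ in range(20):
        n = int(rng.integers(10, 200))
        pred = rng.random(n) < 0.3
        truth = rng.random(n) < 0.2
        # explicit label loop as the oracle
        tp = sum(1 for p, t in zip(pred, truth) if p and t)
        fn = sum(1 for p, t in zip(pred, truth) if not p and t)
        fp = sum(1 for p, t in zip(pred, truth) if p and not t)
        tn = sum(1 for p, t in zip(pred, truth) if not p and not t)
        c = confusion_from_calls(pred, truth)
        assert (c.tp, c.fn, c.fp, c.tn) == (tp, fn, fp, tn)
        r = metrics(c)
        if truth.any() and (~truth).any() and pred.any() and (~pred).any():
            assert r.kappa == pytest.approx(cohen_kappa_score(truth, pred), abs=1e-12)
        assert r.auroc == pytest.approx((r.se + r.sp) / 200.0, abs=1e-12)


def test_single_class_truth_gives_undefined_kappa():
    r = metrics(Confusion(tp=5, fn=0, fp=0, tn=0))
    assert math.isnan(r.kappa)
    assert math.isnan(r.sp)  # no negatives to be specific about


def test_consensus_reproduces_reported_overlap():
    # test set of 56 with 7 actives; model A calls 9 active (5 true);
    # model B agrees on 5 true actives and 2 of A's false positives
    n = 56
    truth = set(range(7))
    a_active = set(range(5)) | {10, 11, 12, 13}
    b_active = set(range(5)) | {10, 11, 20, 30, 40, 5}
    a = _calls(a_active, n)
    b = _calls(b_active, n)
    cons = consensus_and(a, b)
    c = confusion_from_calls(cons, [i in truth for i in range(n)])
    assert (c.tp, c.fp, c.fn, c.tn) == (5, 2, 2, 47)
    r = metrics(c)
    assert round(r.ppv, 1) == 71.4 and round(r.sp, 1) == 95.9


def test_consensus_idempotent_and_never_adds_positives():
    a = _calls({0, 1, 2}, 10)
    b = _calls({2, 3}, 10)
    assert [c.active for c in consensus_and(a, a)] == [c.active for c in a]
    cons = consensus_and(a, b)
    assert sum(c.active for c in cons) <= min(sum(c.active for c in a), sum(c.active for c in b))
    disjoint = consensus_and(_calls({0, 1}, 10), _calls({5, 6}, 10))
    assert not any(c.active for c in disjoint)


def test_consensus_id_mismatch_raises():
    with pytest.raises(ValueError):
        consensus_and(_calls({0}, 5), _calls({0}, 5, prefix="other"))


def test_cross_validate_constant_classifier():
    truth = np.zeros(50, dtype=bool)
    truth[:10] = True
    data = list(range(50))
    res = cross_validate(
        data, lambda train, val: [False] * len(val), truth, k=5, seed=0
    )
    assert res["summary"]["se"]["mean"] == 0.0
    assert res["summary"]["sp"]["mean"] == 100.0


def test_cross_validate_split_determinism_and_summary_recompute():
    truth = np.zeros(60, dtype=bool)
    truth[:12] = True
    rng = np.random.default_rng(3)
    preds = {}

    def trainer(train, val):
        return [bool(rng.random() < 0.5) for _ in val]

    res1 = cross_validate(list(range(60)), trainer, truth, k=4, seed=9)
    res2 = cross_validate(list(range(60)), lambda tr, va: [True] * len(va), truth, k=4, seed=9)
    for s1, s2 in zip(res1["splits"], res2["splits"]):
        assert np.array_equal(s1, s2)
    # summary equals independent recomputation from the per-fold reports
    kappas = [r.kappa for r in res1["reports"] if math.isfinite(r.kappa)]
    assert res1["summary"]["kappa"]["mean"] == pytest.approx(np.mean(kappas))
    assert res1["summary"]["kappa"]["sd"] == pytest.approx(np.std(kappas, ddof=1))


def test_shuffle_null_centers_on_chance(rng):
    pred = rng.random(56) < 0.16
    truth = rng.random(56) < 0.125
    res = shuffle_null(pred, truth, n=500, seed=7)
    assert abs(res["kappa_mean"]) < 0.05
    assert abs(res["auroc_mean"] - 0.5) < 0.05
    assert res == shuffle_null(pred, truth, n=500, seed=7)


def test_random_search_single_point_space():
    res = random_search({"lr": [0.1]}, lambda cfg, s: 1.0 - cfg["lr"], n_trials=3, seed=0)
    assert res["best"]["config"] == {"lr": 0.1}
    assert len(res["trials"]) == 3


def test_random_search_log_matches_recompute_and_is_deterministic():
    def evaluate(cfg, seed):
        return cfg["width"] * 0.01 + (seed % 7) * 0.001

    space = {"width": [16, 32, 64], "lr": (0.01, 10.0)}
    res1 = random_search(space, evaluate, n_trials=5, seed=42)
    res2 = random_search(space, evaluate, n_trials=5, seed=42)
    assert res1 == res2
    for t in res1["trials"][:2]:
        assert evaluate(t["config"], t["seed"]) == t["kappa"]


def test_random_search_empty_space_raises():
    with pytest.raises(ValueError):
        random_search({}, lambda c, s: 0.0, n_trials=1)


def test_prioritization_arithmetic():
    expected, list_size = prioritization_estimate(80_000, 166 / 1059, 5 / 7)
    assert expected == 12_540
    assert list_size == 17_556
    assert prioritization_estimate(1000, 1.0, 1.0) == (1000, 1000)
    with pytest.raises(ValueError):
        prioritization_estimate(1000, 0.5, 0.0)
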