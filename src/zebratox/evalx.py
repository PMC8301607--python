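"""Evaluation of activity calls on imbalanced data.

The headline metrics follow the screening-evaluation conventions for a
~16%-active class balance: sensitivity, specificity and positive
predictive value in percent, Cohen's kappa, and a binary-call AUROC equal
to balanced accuracy (SE + SP)/2 — the ROC area of a single operating
point, which is what thresholded AggE calls admit (no score sweep is
offered, deliberately). Undefined ratios are reported as NaN with the
metric flagged, never silently as 0.

Also here: the AND-consensus of two models' calls, repeated randomized
80:20 train/validation evaluation, a label-shuffle null, random-search
hyperparameter tuning, and the screening-prioritization arithmetic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .toxdata import ActivityCall

log = logging.getLogger(__name__)

__all__ = [
    "Confusion",
    "EvalReport",
    "confusion_from_calls",
    "metrics",
    "consensus_and",
    "cross_validate",
    "shuffle_null",
    "random_search",
    "prioritization_estimate",
]


@dataclass(frozen=True)
class Confusion:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.n == 0:
            raise ValueError("empty confusion matrix")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class EvalReport:
    """SE/SP/PPV in percent; kappa in [-1, 1]; auroc in [0, 1] (balanced
    accuracy of the binary calls)."""

    se: float
    sp: float
    ppv: float
    kappa: float
    auroc: float
    confusion: Confusion

    def as_dict(self) -> dict:
        return {
            "SE": self.se,
            "SP": self.sp,
            "PPV": self.ppv,
            "kappa": self.kappa,
            "auroc": self.auroc,
            "confusion": {"TP": self.confusion.tp, "FN": self.confusion.fn,
                          "FP": self.confusion.fp, "TN": self.confusion.tn},
        }


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def metrics(c: Confusion) -> EvalReport:
    """All metrics from a confusion matrix.

    kappa uses the standard chance-agreement marginals; it is NaN when the
    truth (or the predictions) contain a single class, since chance
    agreement is then 1.
    """
    se = _ratio(c.tp, c.tp + c.fn)
    sp = _ratio(c.tn, c.tn + c.fp)
    ppv = _ratio(c.tp, c.tp + c.fp)
    n = c.n
    p_o = (c.tp + c.tn) / n
    p_e = ((c.tp + c.fp) * (c.tp + c.fn) + (c.fn + c.tn) * (c.fp + c.tn)) / (n * n)
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else math.nan
    auroc = (se + sp) / 2.0
    return EvalReport(se=100.0 * se, sp=100.0 * sp, ppv=100.0 * ppv, kappa=kappa, auroc=auroc, confusion=c)


def confusion_from_calls(
    pred: Sequence[bool] | Sequence[ActivityCall],
    truth: Sequence[bool] | Sequence[ActivityCall],
) -> Confusion:
    p = _to_bool(pred)
    t = _to_bool(truth)
    if len(p) != len(t):
        raise ValueError("prediction and truth lengths differ")
    return Confusion(
        tp=int(np.sum(p & t)),
        fn=int(np.sum(~p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
    )


def _to_bool(calls) -> np.ndarray:
    if len(calls) and isinstance(calls[0], ActivityCall):
        return np.array([c.active for c in calls], dtype=bool)
    return np.asarray(calls, dtype=bool)


def consensus_and(calls_a: list[ActivityCall], calls_b: list[ActivityCall]) -> list[ActivityCall]:
    """AND-consensus: active only where both models call active.

    Requires identical chemical sets; the consensus AggE is the min of the
    two models' values (the binding constraint of the AND rule).
    """
    b_by_id = {c.chemical_id: c for c in calls_b}
    if {c.chemical_id for c in calls_a} != set(b_by_id):
        raise ValueError("consensus requires the same chemical set in both call lists")
    out = []
    for a in calls_a:
        b = b_by_id[a.chemical_id]
        out.append(
            ActivityCall(
                chemical_id=a.chemical_id,
                agg_entropy=min(a.agg_entropy, b.agg_entropy),
                active=a.active and b.active,
                threshold=a.threshold,
            )
        )
    return out


# ---------------------------------------------------------------------------
# repeated randomized-split validation


def cross_validate(
    data: list,
    trainer: Callable[[list, list], Sequence[bool]],
    truth: Sequence[bool],
    k: int = 10,
    test_fraction: float = 0.2,
    seed: int = 0,
    stratified: bool = True,
) -> dict:
    """k repeats of a randomized train/validation split (80:20 by default).

    ``trainer(train_items, val_items)`` returns boolean predictions for the
    validation items; ``truth`` aligns with ``data``. Splits are stratified
    by class unless disabled; a split whose validation set is single-class
    is resampled (logged), up to 100 attempts. Returns per-split reports
    plus mean/SD per metric.
    """
    truth = np.asarray(truth, dtype=bool)
    n = len(data)
    if n < 10:
        raise ValueError("need at least 10 items for split validation")
    if not (truth.any() and (~truth).any()):
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    n_val = max(1, int(round(test_fraction * n)))
    reports: list[EvalReport] = []
    splits: list[np.ndarray] = []
    for fold in range(k):
        for attempt in range(100):
            if stratified:
                pos = np.flatnonzero(truth)
                neg = np.flatnonzero(~truth)
                n_pos = max(1, int(round(test_fraction * len(pos))))
                n_neg = n_val - n_pos
                val = np.concatenate(
                    [rng.choice(pos, n_pos, replace=False), rng.choice(neg, n_neg, replace=False)]
                )
            else:
                val = rng.choice(n, n_val, replace=False)
            if truth[val].any() and (~truth[val]).any():
                break
            log.info("fold %d attempt %d: single-class validation set, resampling", fold, attempt)
        else:
            raise RuntimeError("could not draw a two-class validation set in 100 attempts")
        val = np.sort(val)
        train = np.setdiff1d(np.arange(n), val)
        pred = trainer([data[i] for i in train], [data[i] for i in val])
        reports.append(metrics(confusion_from_calls(np.asarray(pred, bool), truth[val])))
        splits.append(val)
    summary = {}
    for name in ("se", "sp", "ppv", "kappa", "auroc"):
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        ok = vals[np.isfinite(vals)]
        summary[name] = {
            "mean": float(ok.mean()) if ok.size else math.nan,
            "sd": float(ok.std(ddof=1)) if ok.size > 1 else math.nan,
            "n_defined": int(ok.size),
        }
    return {"reports": reports, "summary": summary, "splits": splits}


def shuffle_null(
    predictions: Sequence[bool], truth: Sequence[bool], n: int = 1000, seed: int = 0
) -> dict:
    """Label-shuffle null: permute the truth n times against fixed calls.

    Returns mean/SD of kappa and binary-call AUROC over the permutations.
    Under permutation the expectation of kappa is 0 and of AUROC 1/2.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pred = _to_bool(predictions)
    t = _to_bool(truth)
    rng = np.random.default_rng(seed)
    kappas, aurocs = [], []
    for _ in range(n):
        perm = rng.permutation(len(t))
        r = metrics(confusion_from_calls(pred, t[perm]))
        kappas.append(r.kappa)
        aurocs.append(r.auroc)
    kappas = np.asarray(kappas)
    aurocs = np.asarray(aurocs)
    return {
        "n": n,
        "kappa_mean": float(np.nanmean(kappas)),
        "kappa_sd": float(np.nanstd(kappas, ddof=1)),
        "auroc_mean": float(np.nanmean(aurocs)),
        "auroc_sd": float(np.nanstd(aurocs, ddof=1)),
    }


def random_search(
    space: dict[str, list | tuple],
    evaluate: Callable[[dict, int], float],
    n_trials: int,
    seed: int = 0,
    objective: str = "kappa",
) -> dict:
    """Random hyperparameter search maximizing ``evaluate(config, trial_seed)``.

    ``space`` maps parameter names to either a list of discrete choices or
    a (low, high) tuple sampled uniformly (log-uniform when both ends are
    positive and differ by >= 100x). Returns the best config plus the full
    trial log.
    """
    if not space:
        raise ValueError("empty search space")
    rng = np.random.default_rng(seed)
    trials = []
    best = None
    for trial in range(n_trials):
        cfg = {}
        for name, spec in space.items():
            if isinstance(spec, list):
                cfg[name] = spec[int(rng.integers(len(spec)))]
            else:
                lo, hi = float(spec[0]), float(spec[1])
                if lo > 0 and hi / lo >= 100:
                    cfg[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                else:
                    cfg[name] = float(rng.uniform(lo, hi))
        trial_seed = int(rng.integers(2**31 - 1))
        score = evaluate(cfg, trial_seed)
        entry = {"trial": trial, "config": cfg, "seed": trial_seed, objective: score}
        trials.append(entry)
        if best is None or (np.isfinite(score) and score > best[objective]):
            best = entry
    return {"best": best, "trials": trials}


def prioritization_estimate(
    n_registered: float, active_fraction: float, ppv: float
) -> tuple[int, int]:
    """Screening-prioritization arithmetic.

    Expected untested actives = n_registered * active_fraction, rounded to
    the nearest 10; the screening list that must be tested to capture them
    at the given PPV is expected_actives / ppv.
    """
    if not 0.0 < active_fraction <= 1.0:
        raise ValueError("active_fraction must lie in (0, 1]")
    if ppv <= 0.0 or ppv > 1.0:
        raise ValueError("ppv must lie in (0, 1]")
    expected = int(round(n_registered * active_fraction / 10.0) * 10)
    list_size = int(round(expected / ppv))
    return expected, list_size
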