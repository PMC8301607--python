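"""Toxicity matrices, aggregate entropy (AggE) and activity calls.

A chemical's phenotype is an 18-endpoint vector of incidence proportions
p_e in [0, 1], measured over replicate embryos (32 by default) at the
highest tested concentration. AggE collapses the vector to a single
bits-scale summary; chemicals with AggE >= 9.35 (the default,
concentration-dependent threshold) are called *active*.

AggE here pools endpoints within correlation groups by max (default: 18
singleton groups) and scores each pooled incidence q with

    s(q) = H2(q)        for q <= 1/2
    s(q) = 2 - H2(q)    for q >  1/2

where H2 is the binary Shannon entropy in bits. s is continuous, monotone
non-decreasing with s(0) = 0, s(1/2) = 1, s(1) = 2, so AggE over 18
singleton groups ranges over [0, 36] and the 9.35 threshold is attainable.
Plain entropy is not monotone in incidence (it peaks at 1/2), so it cannot
rank uniformly-affected chemicals above partially-affected ones; the
folded form restores monotonicity while keeping entropy units. The formula
is isolated in :func:`entropy_score` so an alternative aggregate can be
swapped in without touching callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import xlogy

__all__ = [
    "N_ENDPOINTS",
    "DEFAULT_THRESHOLD",
    "ToxicityMatrix",
    "EndpointPanel",
    "ActivityCall",
    "entropy_score",
    "agg_entropy",
    "classify",
    "incidence_from_binary",
    "read_toxicity_csv",
    "write_toxicity_csv",
]

N_ENDPOINTS = 18
DEFAULT_THRESHOLD = 9.35
DEFAULT_LABELS = tuple(f"E{i:02d}" for i in range(1, N_ENDPOINTS + 1))


@dataclass
class ToxicityMatrix:
    """Incidence proportions for one chemical at one concentration."""

    chemical_id: str
    incidence: np.ndarray  # 18 values in [0, 1]
    n_replicates: int = 32
    concentration_label: str = "64 uM"

    def __post_init__(self) -> None:
        self.incidence = np.asarray(self.incidence, dtype=float)
        if self.incidence.shape != (N_ENDPOINTS,):
            raise ValueError(
                f"{self.chemical_id}: expected {N_ENDPOINTS} endpoint incidences, "
                f"got shape {self.incidence.shape}"
            )
        if np.any(~np.isfinite(self.incidence)) or np.any(
            (self.incidence < 0) | (self.incidence > 1)
        ):
            raise ValueError(f"{self.chemical_id}: incidences must lie in [0, 1]")


@dataclass
class EndpointPanel:
    """Endpoint labels plus their partition into correlation groups.

    The default panel is 18 singleton groups; supplying a coarser
    partition pools correlated endpoints (by max) so they are not
    double-counted in AggE.
    """

    labels: tuple[str, ...] = DEFAULT_LABELS
    grouping: tuple[tuple[int, ...], ...] | None = None

    def __post_init__(self) -> None:
        if len(self.labels) != N_ENDPOINTS:
            raise ValueError(f"panel must name {N_ENDPOINTS} endpoints")
        if self.grouping is None:
            self.grouping = tuple((i,) for i in range(N_ENDPOINTS))
        seen = sorted(i for g in self.grouping for i in g)
        if seen != list(range(N_ENDPOINTS)):
            raise ValueError("grouping must partition all 18 endpoints")


@dataclass
class ActivityCall:
    chemical_id: str
    agg_entropy: float
    active: bool
    threshold: float = DEFAULT_THRESHOLD


def entropy_score(q) -> np.ndarray:
    """Folded binary-entropy score s(q), elementwise, in bits."""
    q = np.asarray(q, dtype=float)
    if np.any((q < 0) | (q > 1)):
        raise ValueError("incidence outside [0, 1]")
    h2 = -(xlogy(q, q) + xlogy(1.0 - q, 1.0 - q)) / np.log(2.0)
    return np.where(q <= 0.5, h2, 2.0 - h2)


def agg_entropy(tm: ToxicityMatrix, panel: EndpointPanel | None = None) -> float:
    """Aggregate entropy of a toxicity matrix, in bits."""
    panel = panel or EndpointPanel()
    pooled = np.array([max(tm.incidence[list(g)]) for g in panel.grouping])
    return float(entropy_score(pooled).sum())


def classify(
    agg: float, threshold: float = DEFAULT_THRESHOLD, chemical_id: str = ""
) -> ActivityCall:
    """Active/inactive call: active iff AggE >= threshold."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if agg < 0:
        raise ValueError("aggregate entropy cannot be negative")
    return ActivityCall(
        chemical_id=chemical_id, agg_entropy=float(agg), active=bool(agg >= threshold), threshold=threshold
    )


def incidence_from_binary(
    table: np.ndarray | pd.DataFrame, chemical_id: str = "", labels=DEFAULT_LABELS
) -> ToxicityMatrix:
    """Collapse a replicate x endpoint binary table to incidence proportions.

    Missing entries (NaN) are excluded from both numerator and denominator.
    An endpoint with no evaluable replicate raises, naming the endpoint.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != N_ENDPOINTS:
        raise ValueError(f"expected a replicate x {N_ENDPOINTS} table, got {arr.shape}")
    ok = ~np.isnan(arr)
    vals = np.where(ok, arr, 0.0)
    if np.any((vals != 0) & (vals != 1)):
        raise ValueError("binary incidence table may contain only 0, 1 or missing")
    evaluable = ok.sum(axis=0)
    for e, n in enumerate(evaluable):
        if n == 0:
            raise ValueError(f"endpoint {labels[e]} has zero evaluable replicates")
    p = vals.sum(axis=0) / evaluable
    return ToxicityMatrix(chemical_id=chemical_id, incidence=p, n_replicates=int(arr.shape[0]))


# ---------------------------------------------------------------------------
# CSV I/O — wide (one row per chemical) and long (replicate-resolved) forms


def write_toxicity_csv(mats: list[ToxicityMatrix], path: str | Path, labels=DEFAULT_LABELS) -> None:
    rows = []
    for tm in mats:
        row = {"chemical_id": tm.chemical_id, "n_replicates": tm.n_replicates}
        row.update({lab: tm.incidence[i] for i, lab in enumerate(labels)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.12g")


def read_toxicity_csv(path: str | Path, labels=DEFAULT_LABELS) -> list[ToxicityMatrix]:
    """Read toxicity matrices from wide or long CSV.

    Wide: ``chemical_id`` + 18 endpoint columns of proportions (optional
    ``n_replicates``). Long: ``chemical_id, replicate, endpoint, value``
    with binary values, pivoted and collapsed per chemical.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"chemical_id", "replicate", "endpoint", "value"} <= cols:
        out = []
        for cid, sub in df.groupby("chemical_id", sort=False):
            pivot = sub.pivot(index="replicate", columns="endpoint", values="value")
            missing = [lab for lab in labels if lab not in pivot.columns]
            if missing:
                raise ValueError(f"{cid}: long-form file lacks endpoints {missing}")
            pivot = pivot.reindex(columns=list(labels))
            out.append(incidence_from_binary(pivot.to_numpy(), chemical_id=str(cid), labels=labels))
        return out
    endpoint_cols = [c for c in df.columns if c not in ("chemical_id", "n_replicates", "concentration_label")]
    if len(endpoint_cols) != N_ENDPOINTS:
        raise ValueError(
            f"expected {N_ENDPOINTS} endpoint columns, found {len(endpoint_cols)}"
        )
    out = []
    for _, row in df.iterrows():
        out.append(
            ToxicityMatrix(
                chemical_id=str(row["chemical_id"]),
                incidence=row[endpoint_cols].to_numpy(dtype=float),
                n_replicates=int(row.get("n_replicates", 32)),
            )
        )
    return out
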