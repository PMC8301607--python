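"""Weighted-set-of-views vectorization of 3D molecules.

A molecule is recast as a set of *views*: local coordinate frames, one per
center atom, in which every atom appears as a row
``[period, group, x, y, z]``. The frame is canonical — center at the
origin, the designated nearest neighbour on the +x axis, the nearest
non-collinear atom in the y > 0 half-plane — so the representation is
invariant to rigid motion of the input coordinates and to atom order in
the file.

When k atoms tie (within ``tie_tol``) for the nearest-neighbour position
of a center, that center's view is split into k views, one per tied atom
designated as nearest, and the center's unit weight is divided equally
among them. All weights are then normalized to sum to one over the
molecule, so the downstream weighted sum over view features is scale-free
across molecules of different sizes.

Reflection is quotiented out: each view is built in both mirror images and
the lexicographically smaller row matrix is kept, so enantiomers produce
identical views. This is a known representational limit, not an accident.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .chemio import Molecule

log = logging.getLogger(__name__)

__all__ = ["View", "ViewSet", "ViewConfig", "build_views", "canonical_frame", "pad_to_tensor"]

_COLLINEAR_EPS = 1e-8  # squared-cross-product threshold for collinearity
_COORD_ROUND = 6  # decimals used when coordinates act as sort keys


@dataclass
class ViewConfig:
    """Vectorization settings.

    centers_mode
        ``all_atoms`` starts a view from every atom; ``carbon_only`` gives
        preference to carbons, falling back to all atoms for carbon-free
        molecules.
    max_atoms_per_view
        Rows kept per view (center + nearest neighbours).
    tie_tol
        Distance tolerance (Angstrom) within which nearest-neighbour
        candidates count as tied and trigger view splitting.
    """

    centers_mode: str = "all_atoms"
    max_atoms_per_view: int = 16
    tie_tol: float = 1e-3

    def __post_init__(self) -> None:
        if self.centers_mode not in ("all_atoms", "carbon_only"):
            raise ValueError(f"unknown centers_mode {self.centers_mode!r}")
        if self.max_atoms_per_view < 1:
            raise ValueError("max_atoms_per_view must be >= 1")
        if self.tie_tol < 0:
            raise ValueError("tie_tol must be non-negative")


@dataclass
class View:
    center_index: int
    designated_nearest: int  # atom index fixing the +x axis; -1 if single-atom
    rows: np.ndarray  # (n_rows, 5): [period, group, x, y, z], row 0 = center


@dataclass
class ViewSet:
    molecule_id: str
    views: list[View]
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.views) or len(self.views) == 0:
            raise ValueError("weights must align with a non-empty view list")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError(f"weights sum to {self.weights.sum()}, expected 1")


def canonical_frame(
    center: np.ndarray, nearest: np.ndarray, reference: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Rigid transform (R, t) of the canonical view frame.

    Maps ``center`` to the origin and ``nearest`` onto the +x axis; when a
    ``reference`` point is given it lands in the y > 0 half-plane. Local
    coordinates of a point p are ``R @ p + t``. Raises on a zero-length
    axis vector.
    """
    center = np.asarray(center, dtype=float)
    u = np.asarray(nearest, dtype=float) - center
    norm = np.linalg.norm(u)
    if norm < 1e-12:
        raise ValueError("designated nearest atom coincides with the center")
    u = u / norm
    if reference is None:
        # collinear molecule: any perpendicular pair completes the frame;
        # all local y and z will be zero for points on the axis.
        p = _safe_perp(u)
        y = p
    else:
        r = np.asarray(reference, dtype=float) - center
        perp = r - (r @ u) * u
        pn = np.linalg.norm(perp)
        if pn < 1e-12:
            raise ValueError("reference atom is collinear with the view axis")
        y = perp / pn
    z = np.cross(u, y)
    rot = np.vstack([u, y, z])
    return rot, -rot @ center


def _safe_perp(v: np.ndarray) -> np.ndarray:
    idx = int(np.argmin(np.abs(v)))
    e = np.zeros(3)
    e[idx] = 1.0
    p = np.cross(v, e)
    return p / np.linalg.norm(p)


def _view_rows(
    mol: Molecule,
    coords: np.ndarray,
    pg: np.ndarray,
    center: int,
    nearest: int,
    tie_tol: float,
    max_rows: int,
) -> View:
    """Construct one view: canonical frame, deterministic row order.

    The reference atom (fixing the y > 0 half-plane) is the nearest
    non-collinear atom; when several candidates tie on every frame-free
    invariant (distance group, element, axial projection, axial offset),
    each candidate frame is built in both reflections and the
    lexicographically smallest rounded row matrix wins. This keeps the
    view independent of atom order in the file and of rigid motion, and
    quotients out reflection (enantiomers vectorize identically).
    """
    c = coords[center]
    others = [i for i in range(len(mol)) if i != center]
    dists = {i: float(np.linalg.norm(coords[i] - c)) for i in others}

    def dist_bin(i: int):
        # tie-group index: exact ties share a bin regardless of float noise
        return round(dists[i] / tie_tol) if tie_tol > 0 else dists[i]

    u = (coords[nearest] - c) / dists[nearest]

    def frame_free_key(i: int):
        r = coords[i] - c
        return (
            dist_bin(i),
            int(pg[i, 0]),
            int(pg[i, 1]),
            round(float(r @ u), _COORD_ROUND),
            round(float(np.sqrt(max(np.sum(np.cross(r, u) ** 2), 0.0))), _COORD_ROUND),
        )

    noncollinear = [
        i
        for i in others
        if i != nearest
        and np.sum(np.cross(coords[i] - c, u) ** 2) > _COLLINEAR_EPS * (dists[i] ** 2)
    ]
    if not noncollinear:
        candidates: list[int | None] = [None]
    else:
        best_key = min(frame_free_key(i) for i in noncollinear)
        candidates = [i for i in noncollinear if frame_free_key(i) == best_key]

    def build(reference: int | None, flip: bool) -> np.ndarray:
        rot, trans = canonical_frame(
            c, coords[nearest], coords[reference] if reference is not None else None
        )
        local = coords @ rot.T + trans
        if reference is None:
            local[:, 1:] = 0.0  # fully collinear molecule
        if flip:
            local[:, 2] = -local[:, 2]

        def key(i: int):
            return (
                dist_bin(i),
                int(pg[i, 0]),
                int(pg[i, 1]),
                tuple(np.round(local[i], _COORD_ROUND)),
            )

        rest = sorted((i for i in others if i != nearest), key=key)
        order = ([center, nearest] + rest)[:max_rows]
        rows = np.empty((len(order), 5))
        rows[:, 0] = pg[order, 0]
        rows[:, 1] = pg[order, 1]
        rows[:, 2:] = local[order]
        rows[0, 2:] = 0.0  # center is the origin exactly
        return rows

    variants = [build(ref, flip) for ref in candidates for flip in ((False, True) if candidates != [None] else (False,))]
    rows = min(variants, key=lambda r: tuple(map(tuple, np.round(r, _COORD_ROUND))))
    return View(center_index=center, designated_nearest=nearest, rows=rows)


def build_views(mol: Molecule, cfg: ViewConfig | None = None) -> ViewSet:
    """Vectorize a molecule into its weighted set of canonical views.

    One base view per center atom; a k-way nearest-neighbour tie at a
    center splits its view into k (weight divided equally); weights are
    normalized to sum to 1 over the molecule.
    """
    cfg = cfg or ViewConfig()
    coords = mol.coords()
    pg = np.array([[a.period, a.group] for a in mol.atoms], dtype=float)

    centers = list(range(len(mol)))
    if cfg.centers_mode == "carbon_only":
        carbons = [i for i, a in enumerate(mol.atoms) if a.element == "C"]
        if carbons:
            centers = carbons
        else:
            log.info("%s has no carbon; carbon_only falls back to all atoms", mol.id)

    views: list[View] = []
    weights: list[float] = []
    for c in centers:
        if len(mol) == 1:
            rows = np.array([[pg[c, 0], pg[c, 1], 0.0, 0.0, 0.0]])
            views.append(View(center_index=c, designated_nearest=-1, rows=rows))
            weights.append(1.0)
            continue
        d = np.linalg.norm(coords - coords[c], axis=1)
        d[c] = np.inf
        dmin = d.min()
        tied = np.nonzero(d <= dmin + cfg.tie_tol)[0]
        for t in tied:
            views.append(
                _view_rows(mol, coords, pg, c, int(t), cfg.tie_tol, cfg.max_atoms_per_view)
            )
            weights.append(1.0 / len(tied))
    w = np.asarray(weights)
    return ViewSet(molecule_id=mol.id, views=views, weights=w / w.sum())


@dataclass
class ViewTensor:
    """Fixed-shape bundle: views (n_views, max_atoms, 5) + weights (n_views,)."""

    molecule_id: str
    views: np.ndarray
    weights: np.ndarray


def pad_to_tensor(vs: ViewSet, max_atoms: int) -> ViewTensor:
    """Emit every view as exactly ``max_atoms`` rows x 5 columns.

    Short views are zero-padded (period = group = 0 sentinel rows); long
    views are truncated to the center plus its nearest neighbours. The
    weight vector is untouched.
    """
    if max_atoms < 1:
        raise ValueError("max_atoms must be >= 1")
    out = np.zeros((len(vs.views), max_atoms, 5))
    for k, v in enumerate(vs.views):
        n = min(v.rows.shape[0], max_atoms)
        out[k, :n] = v.rows[:n]
    return ViewTensor(molecule_id=vs.molecule_id, views=out, weights=vs.weights.copy())
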