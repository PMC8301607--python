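"""Idealized molecular geometry construction.

Fixture and synthetic molecules are embedded with textbook bond lengths and
exact tetrahedral / linear angles so that symmetry-induced distance ties
(e.g. the three methyl hydrogens seen from their carbon) are *exact*, which
makes the tie-splitting step of the views representation deterministic.
"""

from __future__ import annotations

import numpy as np

from .periodic import bond_length

# The four exact tetrahedral directions (unit vectors); pairwise angle
# arccos(-1/3) = 109.471 deg. Using these keeps methyl H distances tied
# to the last bit.
TETRAHEDRAL = np.array(
    [[1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0]]
) / np.sqrt(3.0)


def zigzag_backbone(elements: list[str]) -> np.ndarray:
    """Embed a chain of atoms as an all-anti zigzag in the xy-plane.

    Consecutive bond lengths come from the element pair; the bond angle is
    the exact tetrahedral angle.
    """
    n = len(elements)
    coords = np.zeros((n, 3))
    if n == 1:
        return coords
    # alternate between two unit directions with tetrahedral angle between
    # consecutive bonds: theta/2 from the x axis, alternating +/- y.
    half = np.arccos(-1.0 / 3.0) / 2.0
    up = np.array([np.sin(half), np.cos(half), 0.0])
    down = np.array([np.sin(half), -np.cos(half), 0.0])
    for i in range(1, n):
        d = bond_length(elements[i - 1], elements[i])
        step = up if i % 2 == 1 else down
        coords[i] = coords[i - 1] + d * step
    return coords


def backbone_substituent_dirs(i: int, n: int) -> list[np.ndarray]:
    """Two out-of-plane unit directions available at zigzag backbone atom i.

    The backbone consumes two tetrahedral slots (one for a terminal atom);
    the remaining slots point symmetrically out of the xy-plane.
    """
    half = np.arccos(-1.0 / 3.0) / 2.0
    up = np.array([np.sin(half), np.cos(half), 0.0])
    down = np.array([np.sin(half), -np.cos(half), 0.0])
    if i == 0:
        b = up  # direction toward the next atom
        prev = None
    elif i == n - 1:
        b = (up if (i % 2 == 1) else down) * -1.0  # toward previous atom
        prev = None
    else:
        b = up if (i + 1) % 2 == 1 else down
        prev = -(up if i % 2 == 1 else down)
    # Build an orthonormal frame around the occupied directions and place
    # the free slots at exact tetrahedral angles.
    if prev is None:
        # terminal atom: three free slots around -b; use a methyl-like tripod
        axis = -b
        perp1 = np.array([axis[1], -axis[0], 0.0])
        perp1 /= np.linalg.norm(perp1)
        perp2 = np.cross(axis, perp1)
        out = []
        for k in range(3):
            ang = 2.0 * np.pi * k / 3.0
            d = axis * (1.0 / 3.0) + (np.cos(ang) * perp1 + np.sin(ang) * perp2) * (
                np.sqrt(8.0) / 3.0
            )
            out.append(d / np.linalg.norm(d))
        return out
    bisector = -(b + prev)
    bisector /= np.linalg.norm(bisector)
    # free slots lie in the plane spanned by bisector and z
    z = np.array([0.0, 0.0, 1.0])
    halfang = np.arccos(-1.0 / 3.0) / 2.0
    d1 = bisector * np.cos(halfang) + z * np.sin(halfang)
    d2 = bisector * np.cos(halfang) - z * np.sin(halfang)
    return [d1, d2]


def methyl_positions(center: np.ndarray, along: np.ndarray, h_len: float) -> np.ndarray:
    """Three H positions of a methyl group whose fourth bond points `along`.

    The three hydrogens are exactly equidistant from `center` and from the
    `along` axis by construction.
    """
    axis = -np.asarray(along, dtype=float)
    axis = axis / np.linalg.norm(axis)
    perp1 = _any_perp(axis)
    perp2 = np.cross(axis, perp1)
    out = np.empty((3, 3))
    for k in range(3):
        ang = 2.0 * np.pi * k / 3.0
        d = axis * (1.0 / 3.0) + (np.cos(ang) * perp1 + np.sin(ang) * perp2) * (
            np.sqrt(8.0) / 3.0
        )
        out[k] = center + h_len * d / np.linalg.norm(d)
    return out


def _any_perp(v: np.ndarray) -> np.ndarray:
    """A unit vector perpendicular to v (deterministic choice)."""
    v = np.asarray(v, dtype=float)
    if abs(v[0]) <= abs(v[1]) and abs(v[0]) <= abs(v[2]):
        p = np.array([0.0, -v[2], v[1]])
    elif abs(v[1]) <= abs(v[2]):
        p = np.array([-v[2], 0.0, v[0]])
    else:
        p = np.array([-v[1], v[0], 0.0])
    return p / np.linalg.norm(p)


def random_rigid_motion(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniformly random proper rotation and a random translation."""
    # QR of a Gaussian matrix gives a Haar-distributed orthogonal matrix.
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    t = rng.uniform(-10.0, 10.0, size=3)
    return q, t
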