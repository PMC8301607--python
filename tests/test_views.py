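"""The weighted-set-of-views vectorization."""

import numpy as np
import pytest

from zebratox.chemio import Atom, Molecule, fixture_molecule
from zebratox.geometry import random_rigid_motion
from zebratox.periodic import periodic_position
from zebratox.views import ViewConfig, build_views, canonical_frame, pad_to_tensor


def test_methyl_isothiocyanate_all_atom_views(mitc):
    vs = build_views(mitc, ViewConfig(centers_mode="all_atoms"))
    assert len(vs.views) == 9  # methyl C splits 3-way on its tied hydrogens
    assert abs(vs.weights.sum() - 1.0) < 1e-9
    # the three split views carry a third of a center's share each
    methyl_views = [w for v, w in zip(vs.views, vs.weights) if v.center_index == 0]
    assert len(methyl_views) == 3
    assert np.allclose(methyl_views, (1.0 / 3.0) / 7.0)


def test_methane_tie_splitting_weights(methane):
    # hand enumeration: C's 4-way tie -> 4 views at 1/20 after
    # normalization; each H has a unique nearest (C) -> 4 views at 1/5
    vs = build_views(methane)
    assert len(vs.views) == 8
    assert np.allclose(sorted(vs.weights), [0.05] * 4 + [0.2] * 4)


def test_single_atom_molecule_single_view():
    mol = Molecule(id="he", atoms=[Atom.make("He", (1.0, 2.0, 3.0))])
    vs = build_views(mol)
    assert len(vs.views) == 1
    assert vs.weights[0] == 1.0
    assert np.allclose(vs.views[0].rows, [[1, 18, 0, 0, 0]])


def test_view_rows_start_at_center_and_sort_by_distance(mitc):
    vs = build_views(mitc)
    coords = mitc.coords()
    for v in vs.views:
        assert np.allclose(v.rows[0, 2:], 0.0)
        p, g = periodic_position(mitc.atoms[v.center_index].element)
        assert tuple(v.rows[0, :2]) == (p, g)
        d = np.linalg.norm(v.rows[1:, 2:], axis=1)
        assert np.all(np.diff(d) >= -1e-9)
        # designated nearest lies on the +x axis at its true distance
        true_d = np.linalg.norm(coords[v.designated_nearest] - coords[v.center_index])
        assert np.allclose(v.rows[1, 2:], [true_d, 0.0, 0.0], atol=1e-9)


def test_row_columns_match_periodic_position(mitc):
    vs = build_views(mitc)
    for v in vs.views:
        for row in v.rows:
            if row[0] == 0:
                continue
            assert (int(row[0]), int(row[1])) in {
                periodic_position(e) for e in set(mitc.elements())
            }


def test_collinear_molecule_views_are_planar():
    co2 = fixture_molecule("co2")
    vs = build_views(co2)
    for v in vs.views:
        assert np.abs(v.rows[:, 3:]).max() < 1e-9


def test_carbon_only_mode_and_fallback(mitc):
    vs = build_views(mitc, ViewConfig(centers_mode="carbon_only"))
    assert all(mitc.atoms[v.center_index].element == "C" for v in vs.views)
    assert abs(vs.weights.sum() - 1.0) < 1e-9
    # no carbon -> silently falls back to all atoms
    water_like = Molecule(
        id="h2o",
        atoms=[
            Atom.make("O", (0, 0, 0)),
            Atom.make("H", (0.96, 0, 0)),
            Atom.make("H", (-0.24, 0.93, 0)),
        ],
    )
    vs2 = build_views(water_like, ViewConfig(centers_mode="carbon_only"))
    assert len(vs2.views) >= 3


@pytest.mark.parametrize("name", ["methyl_isothiocyanate", "methanol", "glycine_betaine", "chain_C6"])
def test_rigid_motion_invariance_on_fixtures(name, rng):
    mol = fixture_molecule(name)
    base = build_views(mol)
    rot, t = random_rigid_motion(rng)
    moved = build_views(mol.transformed(rot, t))
    assert np.allclose(base.weights, moved.weights)
    for a, b in zip(base.views, moved.views):
        assert np.abs(a.rows - b.rows).max() < 1e-6


def test_atom_order_invariance(mitc, rng):
    base = build_views(mitc)
    perm = rng.permutation(len(mitc))
    shuffled = Molecule(id=mitc.id, atoms=[mitc.atoms[i] for i in perm])
    other = build_views(shuffled)
    # same multiset of (weight, rows) regardless of file order
    def canon(vs):
        return sorted(
            (round(w, 12), np.round(v.rows, 6).tobytes())
            for v, w in zip(vs.views, vs.weights)
        )

    assert canon(base) == canon(other)


def test_tie_splitting_monotone_in_tolerance(mitc):
    counts = [
        len(build_views(mitc, ViewConfig(tie_tol=t)).views)
        for t in (0.0, 1e-3, 0.05, 0.3)
    ]
    assert counts == sorted(counts)


def test_canonical_frame_maps_nearest_to_x_axis():
    rot, t = canonical_frame(
        np.array([1.0, 1.0, 1.0]), np.array([2.0, 1.0, 1.0]), np.array([1.0, 3.0, 1.0])
    )
    assert np.allclose(rot @ np.array([1.0, 1.0, 1.0]) + t, 0.0)
    mapped = rot @ np.array([2.0, 1.0, 1.0]) + t
    assert np.allclose(mapped, [1.0, 0.0, 0.0])
    ref = rot @ np.array([1.0, 3.0, 1.0]) + t
    assert ref[1] > 0 and abs(ref[2]) < 1e-12


def test_canonical_frame_zero_axis_raises():
    with pytest.raises(ValueError):
        canonical_frame(np.zeros(3), np.zeros(3))


def test_pad_to_tensor_shapes_and_truncation(mitc):
    vs = build_views(mitc)
    t10 = pad_to_tensor(vs, 10)
    assert t10.views.shape == (9, 10, 5)
    # padded rows carry the zero sentinel
    assert np.all(t10.views[:, 7:, :] == 0.0)
    t4 = pad_to_tensor(vs, 4)
    assert t4.views.shape == (9, 4, 5)
    for k, v in enumerate(vs.views):
        # truncation keeps the center + 3 nearest (recomputed from distances)
        d = np.linalg.norm(v.rows[1:, 2:], axis=1)
        keep = np.concatenate([[0.0], np.sort(d)[:3]])
        got = np.linalg.norm(t4.views[k, :, 2:], axis=1)
        assert np.allclose(np.sort(got), np.sort(keep), atol=1e-9)
    assert np.array_equal(t10.weights, vs.weights)
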