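"""Structure loading, ring adjacency and Calpha-distance assessment."""

import math

import numpy as np
import pytest

from oligoxl import (
    CrosslinkCandidate,
    StructureModel,
    assess_candidate,
    dms_profile,
    load_structure,
    ring_adjacency,
    site_pair_distances,
    write_ca_pdb,
)
from oligoxl.digest import N_TERMINUS


def make_ring(n=5, radius=30.0, residue_offsets=None, n_frames=1):
    """Ring of rotational copies; residue r of chain 0 sits at
    (radius,0,0) + residue_offsets[r], chain k is rotated by 360k/n."""
    residue_offsets = residue_offsets or {1: np.zeros(3)}
    chain_ids = tuple("ABCDEFGH"[:n])
    coords = {}
    for k, cid in enumerate(chain_ids):
        t = 2.0 * math.pi * k / n
        rot = np.array(
            [
                [math.cos(t), -math.sin(t), 0.0],
                [math.sin(t), math.cos(t), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        coords[cid] = {
            r: np.tile(rot @ (np.array([radius, 0.0, 0.0]) + off), (n_frames, 1))
            for r, off in residue_offsets.items()
        }
    return StructureModel(chain_ids=chain_ids, coords=coords, n_frames=n_frames)


# ---------------------------------------------------------------- loading


TOY_PDB = """\
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ATOM      2  CA  ALA A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      3  CA  ALA A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""


def test_load_single_chain_toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    model = load_structure(path)
    assert model.chain_ids == ("A",)
    assert model.resolved("A") == (1, 2, 3)
    assert model.n_frames == 1
    np.testing.assert_allclose(model.coords["A"][2][0], [3.8, 0.0, 0.0])


def test_numbering_offset_applied(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    model = load_structure(path, numbering_offset=186)
    assert model.resolved("A") == (187, 188, 189)


def test_missing_ca_recorded(tmp_path):
    pdb = TOY_PDB.replace(
        "ATOM      2  CA  ALA A   2", "ATOM      2  CB  ALA A   2"
    )
    path = tmp_path / "toy.pdb"
    path.write_text(pdb)
    model = load_structure(path)
    assert ("A", 2) in model.missing_ca
    assert model.resolved("A") == (1, 3)


def test_multi_model_pdb_roundtrip(tmp_path):
    model = make_ring(n=5, residue_offsets={1: np.zeros(3), 2: np.array([1.0, 0, 0])},
                      n_frames=4)
    path = tmp_path / "ring.pdb"
    write_ca_pdb(model, path)
    back = load_structure(path)
    assert back.n_frames == 4
    assert back.chain_ids == model.chain_ids
    np.testing.assert_allclose(
        back.coords["B"][1], model.coords["B"][1], atol=1e-3
    )


# ---------------------------------------------------------------- adjacency


def off_plane():
    # N-terminal residue lifted off the ring plane fixes the axis direction
    return {1: np.array([0.0, 0.0, 2.0]), 2: np.zeros(3)}


def test_pentagon_adjacency_cycle():
    adj = ring_adjacency(make_ring(n=5, residue_offsets=off_plane()))
    assert len(adj.cycle) == 5
    assert set(adj.cycle) == set("ABCDE")
    # consecutive chains in the construction are ring neighbours
    idx = {c: i for i, c in enumerate(adj.cycle)}
    for a, b in zip("ABCDE", "BCDEA"):
        assert (idx[b] - idx[a]) % 5 in (1, 4)


def test_mirror_flips_orientation_tag():
    model = make_ring(n=5, residue_offsets=off_plane())
    mirrored = StructureModel(
        chain_ids=model.chain_ids,
        coords={
            ch: {r: xyz * np.array([-1.0, 1.0, 1.0]) for r, xyz in resmap.items()}
            for ch, resmap in model.coords.items()
        },
        n_frames=1,
    )
    a, b = ring_adjacency(model), ring_adjacency(mirrored)
    assert a.cycle == b.cycle
    assert {a.orientation, b.orientation} == {"ccw", "cw"}


def test_two_chains_is_not_a_ring():
    with pytest.raises(ValueError, match="3 chains"):
        ring_adjacency(make_ring(n=2))


# ---------------------------------------------------------------- distances


def test_coincident_sites_have_zero_distance():
    model = make_ring(n=5, residue_offsets={1: np.zeros(3), 2: np.zeros(3)})
    assessment = site_pair_distances(model, 1, 2)
    assert assessment.intra.mean == pytest.approx(0.0, abs=1e-12)


def test_pentagon_chord_closed_form():
    """Adjacent inter-subunit distance on a radius-10 pentagon is
    2 r sin(36 deg)."""
    model = make_ring(n=5, radius=10.0)
    assessment = site_pair_distances(model, 1, 1)
    expected = 2.0 * 10.0 * math.sin(math.radians(36.0))
    for stats in assessment.inter.values():
        assert stats.mean == pytest.approx(expected, abs=1e-6)
        assert stats.n == 5
    # i and j identical within one chain: zero
    assert assessment.intra.mean == pytest.approx(0.0, abs=1e-12)


def test_rigid_translation_leaves_distances_unchanged():
    model = make_ring(n=5, residue_offsets=off_plane())
    shifted = model.transformed(shift=(12.0, -7.0, 3.0))
    a = site_pair_distances(model, 1, 2)
    b = site_pair_distances(shifted, 1, 2)
    assert a.intra.mean == pytest.approx(b.intra.mean, abs=1e-9)
    for key in a.inter:
        assert a.inter[key].mean == pytest.approx(b.inter[key].mean, abs=1e-9)


def test_scaling_scales_every_distance():
    model = make_ring(n=5, residue_offsets=off_plane())
    doubled = model.transformed(scale=2.0)
    a = site_pair_distances(model, 1, 2)
    b = site_pair_distances(doubled, 1, 2)
    for key in a.inter:
        assert b.inter[key].mean == pytest.approx(2.0 * a.inter[key].mean, abs=1e-9)


def test_nterm_pseudo_site_uses_first_resolved_residue():
    model = make_ring(n=5, residue_offsets=off_plane())
    via_pseudo = site_pair_distances(model, N_TERMINUS, 2)
    via_resnum = site_pair_distances(model, 1, 2)
    assert via_pseudo.intra.mean == pytest.approx(via_resnum.intra.mean)


# ---------------------------------------------------------------- assessment


def candidate(pairs=((1, 2),)):
    return CrosslinkCandidate.from_intervals(1000.0, ((1, 1), (2, 2)), pairs)


def rotate_z(point, degrees):
    t = math.radians(degrees)
    return np.array(
        [
            point[0] * math.cos(t) - point[1] * math.sin(t),
            point[0] * math.sin(t) + point[1] * math.cos(t),
            point[2],
        ]
    )


def test_inter_only_geometry():
    """Intra distance ~35 A exceeds the 24 A span, but site 2 of each chain
    sits on the neighbouring vertex, so the inter distance is ~0."""
    offsets = {
        1: np.zeros(3),
        2: rotate_z(np.array([30.0, 0.0, 0.0]), -72.0) - np.array([30.0, 0.0, 0.0]),
    }
    model = make_ring(n=5, radius=30.0, residue_offsets=offsets)
    assert assess_candidate(candidate(), model, dms_profile()) == "inter"


def test_intra_only_geometry():
    """Site 2 is 10 A above site 1 within each chain; across chains the
    separation is the ~35 A chord."""
    offsets = {1: np.zeros(3), 2: np.array([0.0, 0.0, 10.0])}
    model = make_ring(n=5, radius=30.0, residue_offsets=offsets)
    assert assess_candidate(candidate(), model, dms_profile()) == "intra"


def test_neither_geometry():
    offsets = {1: np.zeros(3), 2: np.array([0.0, 0.0, 30.0])}
    model = make_ring(n=5, radius=30.0, residue_offsets=offsets)
    assert assess_candidate(candidate(), model, dms_profile()) == "neither"


def test_ambiguous_sites_satisfiable_if_any_member_is():
    offsets = {
        1: np.zeros(3),
        2: np.array([0.0, 0.0, 30.0]),  # unreachable partner
        3: np.array([0.0, 0.0, 10.0]),  # reachable partner
    }
    model = make_ring(n=5, radius=30.0, residue_offsets=offsets)
    ambiguous = candidate(pairs=((1, 2), (1, 3)))
    assert assess_candidate(ambiguous, model, dms_profile()) == "intra"


def test_unresolved_site_warns_and_excludes():
    model = make_ring(n=5, residue_offsets=off_plane())
    with pytest.warns(UserWarning, match="unresolved"):
        assessment = site_pair_distances(model, 1, 99)
    assert assessment.intra is None
    assert assessment.satisfiable_as(24.0) == "neither"
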