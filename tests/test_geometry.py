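"""Distances, lysine reach, duplex kink angle, SASA, buried fractions."""

import numpy as np
import pytest

from trajnet.geometry import (
    AtomSelection,
    buried_fraction,
    duplex_kink_angle,
    lysine_reach_scan,
    pair_distance,
    residue_sasa,
    sasa,
)
from trajnet.io import StructureModel, TrajectoryEnsemble

from conftest import bead_model, make_atom


# ---------------------------------------------------------------------------
# pair distances

def test_same_atom_distance_is_zero():
    model = bead_model([[1.0, 2.0, 3.0]])
    assert pair_distance(model, "A:1:CA", "A:1:CA") == 0.0


def test_three_four_five_triangle():
    model = bead_model([[0, 0, 0], [3.0, 4.0, 0]], resseqs=[1, 2])
    assert pair_distance(model, "A:1:CA", "A:2:CA") == pytest.approx(5.0)


def test_ensemble_distance_summary():
    model = bead_model([[0, 0, 0], [1.0, 0, 0]], resseqs=[1, 2])
    frames = np.zeros((3, 2, 3))
    frames[:, 1, 0] = [1.0, 2.0, 3.0]
    d, summary = pair_distance(
        TrajectoryEnsemble(model, frames), "A:1:CA", "A:2:CA"
    )
    np.testing.assert_allclose(d, [1.0, 2.0, 3.0])
    assert summary == {"min": 1.0, "mean": 2.0, "max": 3.0}


def test_ambiguous_and_empty_selections_raise():
    atoms = [make_atom("CA", resseq=1), make_atom("CA", resseq=1, icode="B")]
    model = StructureModel(atoms, np.zeros((2, 3)))
    with pytest.raises(ValueError, match="ambiguous"):
        AtomSelection("A", 1, "CA").resolve(model)
    with pytest.raises(ValueError, match="no atom"):
        AtomSelection("Z", 9, "CA").resolve(model)


# ---------------------------------------------------------------------------
# lysine reach

def _lysine_field(distances, chain="C"):
    """Reference CA at origin plus LYS NZ atoms at given distances."""
    atoms = [make_atom("CA", chain="E", resseq=85, resname="CYS")]
    coords = [[0.0, 0.0, 0.0]]
    for k, d in enumerate(distances):
        atoms.append(
            make_atom("NZ", chain=chain, resseq=k + 1, resname="LYS",
                      element="N")
        )
        coords.append([d, 0.0, 0.0])
    return StructureModel(atoms, np.array(coords))


def test_reach_boundary_is_strictly_below_cutoff():
    model = _lysine_field([5.0, 11.9, 12.1])
    report = lysine_reach_scan(model, {"C"}, "E:85:CA", cutoff=12.0)
    found = {e.residue_id[1] for e in report.union}
    assert found == {1, 2}  # 12.1 Å excluded; 12.0 itself would be too


def test_union_semantics_across_conformers():
    model = _lysine_field([5.0, 20.0])
    frames = np.broadcast_to(model.coords, (3, 3, 3)).copy()
    frames[1, 2, 0] = 9.0  # second lysine dips into range in frame 2 only
    report = lysine_reach_scan(
        TrajectoryEnsemble(model, frames), {"C"}, "E:85:CA"
    )
    assert len(report.per_frame[0]) == 1
    assert len(report.per_frame[1]) == 2
    entry = [e for e in report.union if e.residue_id[1] == 2][0]
    assert entry.min_distance == pytest.approx(9.0)


def test_seven_planted_lysines_are_recovered_exactly():
    rng = np.random.default_rng(5)
    inside = rng.uniform(3.0, 11.5, size=7)
    outside = rng.uniform(12.5, 40.0, size=6)
    model = _lysine_field(np.concatenate([inside, outside]))
    report = lysine_reach_scan(model, {"C"}, "E:85:CA")
    assert len(report.union) == 7
    # brute-force check against plain distance enumeration
    expected = {k + 1 for k, d in enumerate(np.concatenate([inside, outside]))
                if d < 12.0}
    assert {e.residue_id[1] for e in report.union} == expected


def test_missing_nz_falls_back_to_ca_with_warning(caplog):
    atoms = [
        make_atom("CA", chain="E", resseq=85, resname="CYS"),
        make_atom("CA", chain="C", resseq=1, resname="LYS"),
    ]
    model = StructureModel(atoms, np.array([[0.0, 0, 0], [5.0, 0, 0]]))
    with caplog.at_level("WARNING"):
        report = lysine_reach_scan(model, {"C"}, "E:85:CA")
    assert report.union[0].atom_used == "CA"


def test_no_lysines_gives_empty_report_with_warning(caplog):
    model = bead_model([[0, 0, 0]])
    with caplog.at_level("WARNING"):
        report = lysine_reach_scan(model, {"A"}, "A:1:CA")
    assert report.union == []
    assert any("no LYS" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# duplex kink angle

def _two_arm_model(angle_deg, n=6, spacing=3.0, rotate=None, shift=None):
    """Two straight arms meeting at the origin with the given angle between
    their away-from-junction directions."""
    a = np.radians(angle_deg)
    dir_a = np.array([-1.0, 0.0, 0.0])
    dir_b = np.array([-np.cos(a), np.sin(a), 0.0])  # angle(dir_a, dir_b) = a
    atoms, coords = [], []
    for chain, direction in (("D", dir_a), ("E", dir_b)):
        for i in range(n):
            atoms.append(
                make_atom("P", chain=chain, resseq=i + 1, resname="DA",
                          element="P")
            )
            coords.append(direction * (i + 1) * spacing)
    coords = np.array(coords)
    if rotate is not None:
        coords = coords @ rotate.T
    if shift is not None:
        coords = coords + shift
    return StructureModel(atoms, coords)


def _arms(n=6):
    return [("D", i) for i in range(1, n + 1)], [("E", i) for i in range(1, n + 1)]


@pytest.mark.parametrize("angle", [180.0, 140.0, 90.0])
def test_constructed_kink_angles_are_recovered(angle):
    model = _two_arm_model(angle)
    arm_a, arm_b = _arms()
    got = duplex_kink_angle(model, arm_a, arm_b)
    assert got == pytest.approx(angle, abs=0.5)


def test_kink_angle_is_rigid_motion_invariant():
    rng = np.random.default_rng(9)
    # random rotation via QR
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    ref = duplex_kink_angle(_two_arm_model(140.0), *_arms())
    moved = duplex_kink_angle(
        _two_arm_model(140.0, rotate=q, shift=np.array([10.0, -5.0, 3.0])),
        *_arms(),
    )
    assert abs(moved - ref) < 1e-6


def test_short_arm_is_rejected():
    model = _two_arm_model(140.0, n=2)
    with pytest.raises(ValueError, match="at least 3"):
        duplex_kink_angle(model, *_arms(n=2))


# ---------------------------------------------------------------------------
# SASA

def test_single_carbon_matches_closed_form():
    model = bead_model([[0, 0, 0]], name="C")
    area = sasa(model)[0]
    assert area == pytest.approx(4 * np.pi * 3.1**2, rel=1e-6)
    assert area == pytest.approx(120.76, abs=0.01)


def test_far_apart_atoms_are_additive():
    model = bead_model([[0, 0, 0], [50.0, 0, 0]], name="C", resseqs=[1, 2])
    areas = sasa(model)
    assert areas.sum() == pytest.approx(2 * 4 * np.pi * 3.1**2, rel=1e-9)


def test_two_close_carbons_match_dense_point_oracle():
    """Shrake–Rupley at 960 points vs a 10⁵-point evaluation within 1%."""
    model = bead_model([[0, 0, 0], [2.0, 0, 0]], name="C", resseqs=[1, 2])
    coarse = sasa(model, n_points=960)
    dense = sasa(model, n_points=100_000)
    assert dense.sum() > 0
    np.testing.assert_allclose(coarse, dense, rtol=0.01)


def test_sasa_decreases_monotonically_as_partners_crowd_in():
    positions = [[0.0, 0, 0]]
    areas = []
    shells = [[3.5, 0, 0], [-3.5, 0, 0], [0, 3.5, 0], [0, -3.5, 0]]
    for k in range(len(shells) + 1):
        model = bead_model(
            positions + shells[:k], name="C",
            resseqs=list(range(1, k + 2)),
        )
        areas.append(sasa(model)[0])
    assert all(a1 >= a2 - 1e-9 for a1, a2 in zip(areas, areas[1:]))
    assert areas[-1] < areas[0]


def test_residue_sasa_aggregates_atoms():
    atoms = [make_atom("CA", resseq=1), make_atom("CB", resseq=1)]
    model = StructureModel(atoms, np.array([[0.0, 0, 0], [50.0, 0, 0]]))
    per_res = residue_sasa(model, sasa(model))
    assert per_res[("A", 1, " ")] == pytest.approx(2 * 4 * np.pi * 3.1**2, rel=1e-6)


# ---------------------------------------------------------------------------
# buried fractions

def _cage_model(r=2.8, n_cage=60):
    """A carbon atom enclosed by a dense cage of partner atoms."""
    from trajnet.geometry import _fibonacci_sphere

    atoms = [make_atom("C", chain="X", resseq=1)]
    coords = [[0.0, 0.0, 0.0]]
    for k, p in enumerate(_fibonacci_sphere(n_cage)):
        atoms.append(make_atom("C", chain="Y", resseq=k + 1, serial=k + 2))
        coords.append((r * p).tolist())
    return StructureModel(atoms, np.array(coords))


def test_component_with_no_neighbours_has_zero_buried_fraction():
    model = bead_model(
        [[0, 0, 0], [100.0, 0, 0]], chains=["X", "Y"], resseqs=[1, 1]
    )
    result = buried_fraction(model, {"X"})
    assert result.fraction == pytest.approx(0.0, abs=1e-12)


def test_fully_caged_atom_is_fully_buried():
    result = buried_fraction(_cage_model(), {"X"})
    assert result.fraction == pytest.approx(1.0, abs=1e-9)
    assert result.partner_shares == {"Y": 1.0}


def test_partner_shares_are_normalized_and_ranked():
    """Component flanked by a close partner and a grazing one."""
    atoms = [
        make_atom("C", chain="X", resseq=1),
        make_atom("C", chain="Y", resseq=1),
        make_atom("C", chain="Z", resseq=1),
    ]
    model = StructureModel(
        atoms, np.array([[0.0, 0, 0], [2.0, 0, 0], [-5.5, 0, 0]])
    )
    result = buried_fraction(model, {"X"})
    assert 0 < result.fraction < 1
    assert sum(result.partner_shares.values()) == pytest.approx(1.0)
    assert result.partner_shares["Y"] > result.partner_shares["Z"]
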