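import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from digembody.annotation import CDR_SPANS, ChainAnnotation, FrameworkMap, ImgtPos
from digembody.errors import GeometryError
from digembody.geometry import (angle_between, axis_vector,
                                interface_contacts, intra_digb_angle,
                                residue_min_distance, wobble_angles,
                                wobble_series)
from digembody.structure_io import AtomRecord, AtomSet
from digembody.superpose import RigidTransform, apply_transform
from digembody.synthetic import assemble_digb, make_toy_gb, make_wobble_series
from conftest import make_atoms


def _mini_chain(coords, elements, hinge_index):
    """Single-atom residues with the hinge residue labeled IMGT 12."""
    records = [
        AtomRecord(chain_id="A", residue_number=i + 1, insertion_code="",
                   residue_name="GLY", atom_name="CA", element=el,
                   x=float(c[0]), y=float(c[1]), z=float(c[2]))
        for i, (c, el) in enumerate(zip(coords, elements))]
    atoms = AtomSet(records)
    labels = {i: ImgtPos(i + 1) for i in range(len(records))}
    labels[hinge_index] = ImgtPos(12)
    fmap = FrameworkMap("G" * len(records), labels, CDR_SPANS, 1.0)
    keys = [(i + 1, "") for i in range(len(records))]
    return ChainAnnotation("A", atoms, fmap, keys)


def test_axis_vector_hand_case():
    # uniform com of the three atoms is (1, 4/3, 0); tip is CA(12) at (1,4,0)
    ann = _mini_chain([[0, 0, 0], [2, 0, 0], [1, 4, 0]], "CCC", hinge_index=2)
    av = axis_vector(ann, weighting="uniform")
    np.testing.assert_allclose(av.d, [0, 8.0 / 3.0, 0], atol=1e-12)


def test_axis_vector_mass_weighting_shifts_origin():
    ann = _mini_chain([[0, 0, 0], [2, 0, 0], [1, 4, 0]], "COC", hinge_index=2)
    m_c, m_o = 12.0107, 15.9994
    com = (np.array([0.0, 0, 0]) * m_c + np.array([2.0, 0, 0]) * m_o
           + np.array([1.0, 4, 0]) * m_c) / (2 * m_c + m_o)
    av = axis_vector(ann, weighting="atomic_mass")
    np.testing.assert_allclose(av.d, np.array([1.0, 4, 0]) - com, atol=1e-9)


def test_axis_vector_translation_invariant(toy_gb):
    d0 = axis_vector(toy_gb).d
    moved = toy_gb.atoms.with_coords(toy_gb.atoms.coords + [5.0, 5.0, 5.0])
    ann = ChainAnnotation("A", moved, toy_gb.fmap, toy_gb.residue_keys)
    np.testing.assert_allclose(axis_vector(ann).d, d0, atol=1e-9)


def test_missing_hinge_ca_is_named_in_error(toy_gb):
    i12 = toy_gb.fmap.index_of(12)
    resnum = toy_gb.residue_keys[i12][0]
    pruned = toy_gb.atoms.subset([
        not (r.residue_number == resnum and r.atom_name == "CA")
        for r in toy_gb.atoms])
    ann = ChainAnnotation("A", pruned, toy_gb.fmap, toy_gb.residue_keys)
    with pytest.raises(GeometryError, match="12"):
        axis_vector(ann)


@pytest.mark.parametrize("v,expected", [
    ([1, 0, 0], 0.0), ([-1, 0, 0], 180.0), ([0, 1, 0], 90.0)])
def test_intra_angle_special_cases(v, expected):
    assert intra_digb_angle([1, 0, 0], v) == pytest.approx(expected)


def test_intra_angle_zero_vector_is_error():
    with pytest.raises(GeometryError):
        angle_between([0, 0, 0], [1, 0, 0])


@pytest.mark.parametrize("angle", [71.3, 85.0, 100.7])
def test_assembled_digb_returns_requested_angle(toy_gb, angle):
    scene = assemble_digb(toy_gb, intra_angle=angle)
    measured = intra_digb_angle(axis_vector(scene.annotations["A"]),
                                axis_vector(scene.annotations["B"]))
    assert measured == pytest.approx(angle, abs=0.1)


def test_identical_frames_have_zero_wobble(digb_scene):
    frames = [digb_scene.atoms, digb_scene.atoms, digb_scene.atoms]
    series = wobble_series(frames, "A", "B",
                           annotations=(digb_scene.annotations["A"],
                                        digb_scene.annotations["B"]))
    assert series.wobble_max <= 1e-6
    # deviations from the mean vector sum to zero identically
    np.testing.assert_allclose(
        (series.d_mobile - series.d_a_mobile).sum(axis=0), 0, atol=1e-9)


def test_two_frame_symmetric_wobble_is_exact(digb_scene):
    series_scene = make_wobble_series(digb_scene, amplitude=10.0, n_frames=2,
                                      seed=0)
    series = wobble_series(series_scene.frames, "A", "B",
                           annotations=(digb_scene.annotations["A"],
                                        digb_scene.annotations["B"]))
    np.testing.assert_allclose(series.beta, [10.0, 10.0], atol=1e-9)


def test_wobble_matches_direct_formula(digb_scene):
    scene = make_wobble_series(digb_scene, amplitude=8.0, n_frames=60, seed=4)
    series = wobble_series(scene.frames, "A", "B",
                           annotations=(digb_scene.annotations["A"],
                                        digb_scene.annotations["B"]))
    d = series.d_mobile
    d_a = d.mean(axis=0)
    expected = np.degrees(np.arccos(np.clip(
        d @ d_a / (np.linalg.norm(d, axis=1) * np.linalg.norm(d_a)),
        -1.0, 1.0)))
    np.testing.assert_allclose(series.beta, expected, atol=1e-6)
    assert series.wobble_max == pytest.approx(8.0, abs=0.5)


def test_wobble_angles_helper_bounds():
    d = np.array([[1.0, 0, 0], [0.0, 1, 0], [-1.0, 0, 0]])
    beta = wobble_angles(d)
    assert np.all((beta >= 0) & (beta <= 180))


def test_angles_invariant_under_global_rigid_motion(digb_scene):
    scene = make_wobble_series(digb_scene, amplitude=5.0, n_frames=10, seed=2)
    anns = (digb_scene.annotations["A"], digb_scene.annotations["B"])
    base = wobble_series(scene.frames, "A", "B", annotations=anns)
    t = RigidTransform(
        Rotation.from_euler("zyx", [70, -10, 25], degrees=True).as_matrix(),
        np.array([-4.0, 9.0, 2.0]), 0.0)
    moved = [apply_transform(fr, t) for fr in scene.frames]
    series = wobble_series(moved, "A", "B", annotations=anns)
    np.testing.assert_allclose(series.beta, base.beta, atol=1e-6)
    assert series.intra_digb_angle == pytest.approx(base.intra_digb_angle,
                                                    abs=1e-6)


def test_series_errors():
    with pytest.raises(GeometryError):
        wobble_series([], "A", "B")


def test_residue_min_distance_conventions():
    a = make_atoms([[0, 0, 0]])
    b = make_atoms([[2.5, 0, 0]])
    assert residue_min_distance(a, b) == pytest.approx(2.5)
    assert residue_min_distance(b, a) == pytest.approx(2.5)
    # a nearer hydrogen is ignored
    b_with_h = b.concat(make_atoms([[1.0, 0, 0]], element="H", atom_name="H"))
    assert residue_min_distance(a, b_with_h) == pytest.approx(2.5)
    with pytest.raises(GeometryError):
        residue_min_distance(a, make_atoms([[0, 0, 0]], element="H"))


def test_residue_min_distance_matches_brute_force(rng):
    a = make_atoms(rng.uniform(0, 5, size=(8, 3)))
    b = make_atoms(rng.uniform(3, 8, size=(8, 3)))
    brute = min(np.linalg.norm(ra.xyz - rb.xyz) for ra in a for rb in b)
    assert residue_min_distance(a, b) == pytest.approx(brute, abs=1e-12)


def test_contacts_empty_when_far_apart():
    a = make_atoms([[0, 0, 0]])
    b = make_atoms([[20, 0, 0]], chain="B")
    assert interface_contacts(a, b) == []


def test_backbone_hydrogen_bond_detected():
    donor = AtomSet([AtomRecord("A", 1, "", "GLY", "N", "N", 0, 0, 0)])
    acceptor = AtomSet([AtomRecord("B", 5, "", "ALA", "O", "O", 2.9, 0, 0)])
    recs = interface_contacts(donor, acceptor)
    assert len(recs) == 1
    rec = recs[0]
    assert rec.is_hbond and rec.hbond_atoms == ("N", "O")
    assert rec.min_heavy_distance == pytest.approx(2.9)


def test_carbon_contact_is_not_hydrogen_bond():
    a = make_atoms([[0, 0, 0]])
    b = make_atoms([[3.0, 0, 0]], chain="B")
    recs = interface_contacts(a, b)
    assert len(recs) == 1 and not recs[0].is_hbond


def test_digb_interface_contacts_have_imgt_labels(digb_scene):
    recs = interface_contacts(
        digb_scene.parts["A"], digb_scene.parts["B"],
        ann_a=digb_scene.annotations["A"], ann_b=digb_scene.annotations["B"])
    assert recs, "assembled dimer should have interface contacts"
    assert all(r.min_heavy_distance <= 4.0 for r in recs)
    assert any(r.imgt_a is not None and r.imgt_b is not None for r in recs)
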