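import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from digembody.errors import CorrespondenceError, DegenerateGeometryError
from digembody.structure_io import AtomSet
from digembody.superpose import (RigidTransform, apply_transform,
                                 kabsch_superpose, match_framework_atoms,
                                 superpose_chains)
from digembody.synthetic import make_toy_gb
from digembody.annotation import ChainAnnotation

TETRAHEDRON = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])


def test_self_superposition_is_identity():
    t = kabsch_superpose(TETRAHEDRON, TETRAHEDRON)
    np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-9)
    np.testing.assert_allclose(t.translation, 0, atol=1e-9)
    assert t.rmsd <= 1e-9


def test_recovers_planted_rotation_and_translation():
    rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
    moved = TETRAHEDRON @ rot.T + np.array([1.0, 2.0, 3.0])
    t = kabsch_superpose(TETRAHEDRON, moved)
    np.testing.assert_allclose(t.rotation, rot, atol=1e-9)
    np.testing.assert_allclose(t.translation, [1, 2, 3], atol=1e-9)
    assert t.rmsd <= 1e-9


def test_beats_random_rotation_oracle(rng):
    """Kabsch rmsd <= min rmsd over 10,000 sampled rotations."""
    x = rng.uniform(-10, 10, size=(50, 3))
    rot = Rotation.random(rng=rng)
    y = rot.apply(x) + rng.normal(scale=0.1, size=(50, 3))
    best = kabsch_superpose(x, y).rmsd
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    samples = Rotation.random(10_000, rng=rng).as_matrix()
    moved = np.einsum("rij,nj->rni", samples, xc)
    oracle = np.sqrt(((moved - yc) ** 2).sum(axis=(1, 2)) / 50).min()
    assert best <= oracle + 1e-12


def test_degenerate_and_invalid_inputs():
    line = np.outer(np.arange(5.0), [1.0, 0, 0])
    with pytest.raises(DegenerateGeometryError):
        kabsch_superpose(line, line)
    with pytest.raises(ValueError):
        kabsch_superpose(TETRAHEDRON[:2], TETRAHEDRON[:2])
    with pytest.raises(ValueError):
        kabsch_superpose(TETRAHEDRON, TETRAHEDRON[:3])


def test_apply_transform_round_trip(toy_gb):
    t = RigidTransform(
        Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix(),
        np.array([1.0, -2.0, 3.0]), 0.0)
    moved = apply_transform(toy_gb.atoms, t)
    identity = apply_transform(toy_gb.atoms, RigidTransform.identity())
    np.testing.assert_array_equal(identity.coords, toy_gb.atoms.coords)
    back = apply_transform(moved, t.inverse())
    np.testing.assert_allclose(back.coords, toy_gb.atoms.coords, atol=1e-9)
    assert [r.atom_name for r in moved] == [r.atom_name for r in toy_gb.atoms]


@settings(derandomize=True, max_examples=20)
@given(st.integers(0, 2 ** 31 - 1))
def test_transform_is_an_isometry(seed):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(-20, 20, size=(15, 3))
    t = RigidTransform(Rotation.random(rng=rng).as_matrix(),
                       rng.uniform(-5, 5, size=3), 0.0)
    moved = t.apply(coords)
    d0 = np.linalg.norm(coords[:, None] - coords[None], axis=-1)
    d1 = np.linalg.norm(moved[:, None] - moved[None], axis=-1)
    np.testing.assert_allclose(d1, d0, atol=1e-9)


def test_transform_serialization_round_trip(rng):
    t = RigidTransform(Rotation.random(rng=rng).as_matrix(),
                       rng.normal(size=3), 0.5)
    t2 = RigidTransform.from_flat(t.to_flat())
    np.testing.assert_array_equal(t2.rotation, t.rotation)
    np.testing.assert_array_equal(t2.translation, t.translation)


def test_framework_pairing_identical_chains(toy_gb):
    m, f, pos = match_framework_atoms(toy_gb, toy_gb)
    assert len(pos) == 92            # all framework positions carry a CA
    np.testing.assert_array_equal(m, f)


def test_framework_pairing_robust_to_cdr_length(toy_gb):
    longer = make_toy_gb(seed=1, n_res=124)   # 6 extra CDR3 residues
    m, f, pos = match_framework_atoms(toy_gb, longer)
    assert len(pos) == 92
    assert all(not (27 <= p.number <= 38 or 56 <= p.number <= 65
                    or 105 <= p.number <= 117) for p in pos)


def test_missing_ca_drops_position(toy_gb):
    i12 = toy_gb.fmap.index_of(12)
    resnum = toy_gb.residue_keys[i12][0]
    pruned = toy_gb.atoms.subset([
        not (r.residue_number == resnum and r.atom_name == "CA")
        for r in toy_gb.atoms])
    ann = ChainAnnotation("A", pruned, toy_gb.fmap, toy_gb.residue_keys)
    _m, _f, pos = match_framework_atoms(ann, toy_gb)
    assert len(pos) == 91
    assert all(p.number != 12 for p in pos)


def test_too_few_shared_positions_is_an_error(toy_gb):
    keep_ca_of = {toy_gb.residue_keys[toy_gb.fmap.index_of(p)][0]
                  for p in (1, 7, 12, 14, 20)}
    pruned = toy_gb.atoms.subset([
        r.atom_name != "CA" or r.residue_number in keep_ca_of
        for r in toy_gb.atoms])
    ann = ChainAnnotation("A", pruned, toy_gb.fmap, toy_gb.residue_keys)
    with pytest.raises(CorrespondenceError):
        match_framework_atoms(ann, toy_gb)


def test_superpose_chains_recovers_planted_motion(toy_gb):
    rot = Rotation.from_euler("y", 40, degrees=True)
    moved = toy_gb.atoms.with_coords(rot.apply(toy_gb.atoms.coords) + 7.0)
    ann = ChainAnnotation("A", moved, toy_gb.fmap, toy_gb.residue_keys)
    t = superpose_chains(ann, toy_gb)
    assert t.rmsd <= 1e-9
    np.testing.assert_allclose(
        apply_transform(moved, t).coords, toy_gb.atoms.coords, atol=1e-8)
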