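import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from digembody.clash import (ClashReport, count_clash_atoms,
                             screen_on_scaffold, survey_library)
from digembody.errors import SurveyError
from digembody.structure_io import AtomSet
from digembody.superpose import RigidTransform, apply_transform
from digembody.synthetic import (make_clash_scene, make_screen_library,
                                 make_screen_scene, make_toy_gb)
from conftest import make_atoms


@pytest.mark.parametrize("env_x,expected", [
    (5.0, 0),      # outside the sphere
    (3.9, 1),      # inside
    (4.0, 1),      # boundary is inclusive
])
def test_single_pair_boundary_convention(env_x, expected):
    probe = make_atoms([[0, 0, 0]], chain="P")
    env = make_atoms([[env_x, 0, 0]], chain="E")
    assert count_clash_atoms(probe, env, cutoff=4.0) == expected


def test_counts_probe_atoms_not_pairs():
    # one probe atom near two environment atoms still counts once
    probe = make_atoms([[0, 0, 0]], chain="P")
    env = make_atoms([[1, 0, 0], [0, 1, 0]], chain="E")
    assert count_clash_atoms(probe, env, cutoff=4.0) == 1


def test_matches_all_pairs_oracle_on_random_cube(rng):
    probe = make_atoms(rng.uniform(0, 20, size=(200, 3)), chain="P")
    env = make_atoms(rng.uniform(0, 20, size=(200, 3)), chain="E")
    brute = int((cdist(probe.coords, env.coords).min(axis=1) <= 4.0).sum())
    assert count_clash_atoms(probe, env, 4.0) == brute


def test_monotone_in_cutoff(rng):
    probe = make_atoms(rng.uniform(0, 15, size=(80, 3)), chain="P")
    env = make_atoms(rng.uniform(0, 15, size=(80, 3)), chain="E")
    counts = [count_clash_atoms(probe, env, c)
              for c in (1.0, 2.0, 4.0, 6.0, 10.0)]
    assert counts == sorted(counts)


def test_invalid_cutoff():
    probe = make_atoms([[0, 0, 0]])
    with pytest.raises(ValueError):
        count_clash_atoms(probe, probe, cutoff=0.0)


def test_report_classification_consistency():
    assert ClashReport(0, 100, 4.0).classification == "no_clash"
    assert ClashReport(4, 100, 4.0).classification == "under_5pct"
    assert ClashReport(5, 100, 4.0).classification == "over_5pct"
    assert ClashReport(100, 100, 4.0).score == 1.0


def test_planted_scene_counts_recovered():
    for k in (0, 5, 100):
        scene = make_clash_scene(100, k, cutoff=4.0, seed=3)
        got = count_clash_atoms(scene.parts["probe"],
                                scene.parts["environment"], 4.0)
        assert got == scene.truth["n_clash_planted"] == k


def test_screen_no_clash_when_target_far():
    scene = make_screen_scene(seed=5, k_clash=0)
    report = screen_on_scaffold(scene.parts["complex"],
                                scene.parts["scaffold"])
    assert report.n_clash == 0
    assert report.classification == "no_clash"
    assert max(report.placement_rmsds) < 1e-6


def test_screen_recovers_planted_fraction():
    scene = make_screen_scene(seed=5, k_clash=6, n_target=100)
    report = screen_on_scaffold(scene.parts["complex"],
                                scene.parts["scaffold"])
    assert report.n_clash == 6 and report.n_total == 200
    assert report.score == pytest.approx(0.03)
    assert report.classification == "under_5pct"


def test_screen_symmetric_under_copy_swap():
    scene = make_screen_scene(seed=5, k_clash=20)
    a = screen_on_scaffold(scene.parts["complex"], scene.parts["scaffold"],
                           gb_chains=("A", "B"))
    b = screen_on_scaffold(scene.parts["complex"], scene.parts["scaffold"],
                           gb_chains=("B", "A"))
    assert a.n_clash == b.n_clash == 20


def test_degenerate_coincident_scaffold_gives_total_overlap():
    gb = make_toy_gb(seed=2)
    # both "Gb" chains at identical coordinates: the two placed copies of
    # the complex coincide, so every target atom clashes
    scaffold = gb.atoms.concat(gb.atoms.relabel_chain("A", "B"))
    target = make_atoms(np.array([[100.0, i * 8.0, 0.0] for i in range(10)]),
                        chain="T")
    complex_atoms = gb.atoms.relabel_chain("A", "N").concat(target)
    report = screen_on_scaffold(complex_atoms, scaffold,
                                gb_chains=("A", "B"))
    assert report.score == 1.0


def test_screen_invariant_under_global_rigid_motion():
    scene = make_screen_scene(seed=9, k_clash=6)
    t = RigidTransform(
        Rotation.from_euler("xyz", [15, -25, 40], degrees=True).as_matrix(),
        np.array([3.0, -8.0, 12.0]), 0.0)
    before = screen_on_scaffold(scene.parts["complex"],
                                scene.parts["scaffold"])
    after = screen_on_scaffold(apply_transform(scene.parts["complex"], t),
                               apply_transform(scene.parts["scaffold"], t))
    assert (before.n_clash, before.n_total) == (after.n_clash, after.n_total)


def test_survey_closure_and_skips():
    entries, scaffold = make_screen_library(
        seed=11, plantings=[0, 0, 0, 0, 6, 6, 6, 20, 20, 20])
    # an unscreenable entry (no nanobody chain) must be skipped, not fatal
    entries["broken"] = make_atoms(np.zeros((4, 3)), chain="T")
    summary = survey_library(entries, scaffold)
    assert summary.n_screened == 10
    assert list(summary.skipped) == ["broken"]
    assert summary.fraction_no_clash == pytest.approx(0.4)
    assert summary.fraction_under_5pct == pytest.approx(0.7)
    assert summary.fraction_under_5pct >= summary.fraction_no_clash


def test_survey_with_no_screenable_entries_fails():
    entries = {"bad": make_atoms(np.zeros((4, 3)), chain="T")}
    scaffold = make_toy_gb(seed=1).atoms
    with pytest.raises(SurveyError):
        survey_library(entries, scaffold)
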