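"""Deterministic synthetic structures with planted ground truth.

Every pipeline stage (annotation through clash screening and wobble
analysis) is exercised on generated scenes whose true parameters are known
by construction:

* :func:`make_toy_gb` — a rigid, chirality-bearing backbone "toy Gembody"
  whose residues carry IMGT framework labels (a labeled rigid body, not a
  physically realistic immunoglobulin fold);
* :func:`assemble_digb` — a two-chain dimer hinged at the IMGT-12 C-alpha
  with an exact requested inter-axis (intra-DiGb) angle and C12-C12
  separation;
* :func:`make_wobble_series` — a frame series whose maximum wobble angle
  equals a planted amplitude;
* :func:`make_clash_scene` — two atom sets with an exact planted number of
  within-cutoff contacts;
* :func:`make_screen_scene` — a complex + scaffold pair that, after
  framework superposition, yields an exact planted clash count.

All generators are pure functions of (seed, parameters): same inputs, bit
identical output.  Randomness goes through one ``numpy`` Generator created
per call; there is no global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation
from Bio.SeqUtils import seq3

from .annotation import (CDR_SPANS, ChainAnnotation, FrameworkMap, ImgtPos,
                         is_cdr_position, reference_positions,
                         reference_sequence)
from .errors import AssemblyError
from .geometry import axis_vector, intra_digb_angle
from .structure_io import AtomRecord, AtomSet, write_structure

GENERATOR_VERSION = "1.0"

#: IMGT positions that must be labeled on every toy Gb
REQUIRED_POSITIONS = (7, 12, 14, 44, 46, 47, 84, 120, 123, 125)


@dataclass
class SyntheticScene:
    """Generated coordinates plus the planted parameters that predict them."""

    parts: dict[str, AtomSet] = field(default_factory=dict)
    frames: list[AtomSet] = field(default_factory=list)
    annotations: dict[str, ChainAnnotation] = field(default_factory=dict)
    truth: dict = field(default_factory=dict)
    seed: int | None = None
    generator_version: str = GENERATOR_VERSION

    @property
    def atoms(self) -> AtomSet:
        sets = list(self.parts.values())
        out = sets[0]
        for s in sets[1:]:
            out = out.concat(s)
        return out

    def write(self, directory, prefix: str = "scene") -> list[Path]:
        """Write the scene through the real PDB output path.

        Frame series become one file per frame; a truth sidecar records the
        planted parameters as tab-separated text.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths: list[Path] = []
        if self.frames:
            for i, fr in enumerate(self.frames):
                p = directory / f"{prefix}_frame{i:03d}.pdb"
                write_structure(fr, p, format="pdb")
                paths.append(p)
        else:
            p = directory / f"{prefix}.pdb"
            write_structure(self.atoms, p, format="pdb")
            paths.append(p)
        sidecar = directory / f"{prefix}_truth.tsv"
        with open(sidecar, "w") as fh:
            fh.write("key\tvalue\n")
            fh.write(f"seed\t{self.seed}\n")
            fh.write(f"generator_version\t{self.generator_version}\n")
            for k, v in self.truth.items():
                if isinstance(v, (int, float, str)):
                    fh.write(f"{k}\t{v}\n")
        paths.append(sidecar)
        return paths


# ---------------------------------------------------------------------------
# toy Gembody

def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perpendicular(u: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to ``u``."""
    e = np.zeros(3)
    e[int(np.argmin(np.abs(u)))] = 1.0
    return _unit(np.cross(u, e))


def _toy_labels(n_res: int) -> tuple[str, list[ImgtPos]]:
    """Sequence and IMGT labels for a toy Gb of ``n_res`` residues.

    At the reference length (118) the labels are the full reference
    numbering; longer toys gain insertion-coded CDR3 residues, shorter ones
    lose CDR residues first and then keep an evenly thinned framework subset
    that always includes the interface-critical positions.
    """
    ref_pos = list(reference_positions())
    ref_seq = reference_sequence()
    n_ref = len(ref_pos)
    if n_res == n_ref:
        return ref_seq, [ImgtPos(p.number) for p in ref_pos]
    if n_res > n_ref:
        extra = n_res - n_ref
        # splice glycine insertions after the first half of CDR3 (IMGT 109)
        cut = ref_pos.index(ImgtPos(109)) + 1
        seq = ref_seq[:cut] + "G" * extra + ref_seq[cut:]
        labels = ([ImgtPos(p.number) for p in ref_pos[:cut]]
                  + [ImgtPos(109, chr(ord("A") + i)) for i in range(extra)]
                  + [ImgtPos(p.number) for p in ref_pos[cut:]])
        return seq, labels
    # shorter: drop CDR residues from the loop tails first
    keep = list(range(n_ref))
    droppable = [i for i, p in enumerate(ref_pos) if is_cdr_position(p)]
    for i in reversed(droppable[: n_ref - n_res]):
        keep.remove(i)
    if len(keep) > n_res:
        # all CDRs gone and still too long: thin the framework evenly,
        # preserving the interface-critical positions
        required = {i for i in keep
                    if ref_pos[i].number in REQUIRED_POSITIONS}
        optional = [i for i in keep if i not in required]
        n_opt = n_res - len(required)
        sel = [optional[int(round(k * (len(optional) - 1) / max(n_opt - 1, 1)))]
               for k in range(n_opt)]
        keep = sorted(required | set(sel))
    seq = "".join(ref_seq[i] for i in keep)
    labels = [ImgtPos(ref_pos[i].number) for i in keep]
    return seq, labels


def make_toy_gb(seed: int, n_res: int = 118, chain_id: str = "A"
                ) -> ChainAnnotation:
    """Generate a rigid toy Gembody with labeled IMGT positions.

    The backbone is a seeded self-avoiding-ish random C-alpha walk (3.8 A
    steps, 30-90 degree turns) decorated with N, C and O atoms in a local
    chiral frame.  Two different seeds give folds differing by well over
    1 A RMSD, so superposition tests are non-degenerate.

    Returns a :class:`ChainAnnotation` carrying the atoms, the framework
    map, and the author residue numbering (1..n_res).
    """
    if not 30 <= n_res <= 140:
        raise ValueError(f"n_res must be in [30, 140], got {n_res}")
    seq, labels = _toy_labels(n_res)
    rng = np.random.default_rng(seed)

    # C-alpha random walk
    ca = np.zeros((n_res, 3))
    v = _unit(rng.normal(size=3))
    for i in range(1, n_res):
        axis = _unit(rng.normal(size=3))
        angle = np.radians(rng.uniform(30.0, 90.0))
        v = Rotation.from_rotvec(axis * angle).apply(v)
        ca[i] = ca[i - 1] + 3.8 * v

    records: list[AtomRecord] = []
    for i in range(n_res):
        t = _unit(ca[min(i + 1, n_res - 1)] - ca[max(i - 1, 0)])
        u = _perpendicular(t)
        b = np.cross(t, u)
        resname = seq3(seq[i]).upper()
        for name, element, pos in (
            ("N", "N", ca[i] - 1.46 * t + 0.40 * u),
            ("CA", "C", ca[i]),
            ("C", "C", ca[i] + 1.52 * t + 0.30 * u),
            ("O", "O", ca[i] + 1.52 * t + 0.30 * u + 1.23 * b),
        ):
            records.append(AtomRecord(
                chain_id=chain_id, residue_number=i + 1, insertion_code="",
                residue_name=resname, atom_name=name, element=element,
                x=float(pos[0]), y=float(pos[1]), z=float(pos[2])))

    fmap = FrameworkMap(
        query_sequence=seq,
        index_to_imgt={i: p for i, p in enumerate(labels)},
        cdr_spans=CDR_SPANS,
        framework_identity=1.0,
    )
    atoms = AtomSet(records, provenance=f"make_toy_gb(seed={seed}, n_res={n_res})")
    keys = [(i + 1, "") for i in range(n_res)]
    return ChainAnnotation(chain_id, atoms, fmap, keys)


# ---------------------------------------------------------------------------
# DiGb assembly

def _digb_geometry(gb: ChainAnnotation, intra_angle: float,
                   c12_separation: float):
    """Rotation axis, separation direction and copy-1 -> copy-2 map."""
    av = axis_vector(gb)
    u = _unit(av.d)
    pivot = av.tip
    axis = _perpendicular(u)
    rot = Rotation.from_rotvec(axis * np.radians(intra_angle))
    u2 = rot.apply(u)
    m = u + u2
    if np.linalg.norm(m) < 1e-9:      # antiparallel: any direction in plane
        sep_dir = _unit(np.cross(axis, u))
    else:
        sep_dir = _unit(m)
    shift = c12_separation * sep_dir
    return av, pivot, axis, rot, shift


def assemble_digb(gb: ChainAnnotation, intra_angle: float,
                  c12_separation: float = 6.0,
                  chain_ids: tuple[str, str] = ("A", "B")) -> SyntheticScene:
    """Build a two-chain dimer with an exact planted inter-axis angle.

    The second copy is the first rotated about an axis through its IMGT-12
    C-alpha (perpendicular to the axis vector) by ``intra_angle``, then
    displaced by ``c12_separation`` along the bisector of the two axis
    vectors — emulating two domains splaying from adjacent covalent hinge
    residues.

    The scene records the copy-1 -> copy-2 rigid map and verifies closure:
    the measured intra-DiGb angle matches the request to 0.1 degree and the
    C12-C12 distance to 0.01 A.
    """
    if not 0.0 < intra_angle <= 180.0:
        raise ValueError(f"intra_angle must be in (0, 180], got {intra_angle}")
    if not 4.0 <= c12_separation <= 8.0:
        raise ValueError("c12_separation must be in [4, 8] A "
                         f"(disulfide-span-like), got {c12_separation}")
    av, pivot, axis, rot, shift = _digb_geometry(gb, intra_angle,
                                                 c12_separation)
    id_a, id_b = chain_ids
    atoms_a = gb.atoms if gb.chain_id == id_a else \
        gb.atoms.relabel_chain(gb.chain_id, id_a)
    coords_b = rot.apply(gb.atoms.coords - pivot) + pivot + shift
    atoms_b = atoms_a.relabel_chain(id_a, id_b).with_coords(coords_b)

    ann_a = ChainAnnotation(id_a, atoms_a, gb.fmap, gb.residue_keys)
    ann_b = ChainAnnotation(id_b, atoms_b, gb.fmap, gb.residue_keys)

    measured = intra_digb_angle(axis_vector(ann_a), axis_vector(ann_b))
    c12_dist = float(np.linalg.norm(
        ann_b.ca_record(12).xyz - ann_a.ca_record(12).xyz))
    if abs(measured - intra_angle) > 0.1 or \
            abs(c12_dist - c12_separation) > 0.01:
        raise AssemblyError(
            f"closure failed: angle {measured:.3f} vs {intra_angle}, "
            f"C12 distance {c12_dist:.3f} vs {c12_separation}")

    rot_mat = rot.as_matrix()
    return SyntheticScene(
        parts={id_a: atoms_a, id_b: atoms_b},
        annotations={id_a: ann_a, id_b: ann_b},
        truth={
            "intra_angle": float(intra_angle),
            "c12_separation": float(c12_separation),
            "measured_intra_angle": measured,
            "hinge_axis": axis,
            "pivot": pivot,
            "copy_map_rotation": rot_mat,
            "copy_map_translation": pivot + shift - rot_mat @ pivot,
        },
    )


# ---------------------------------------------------------------------------
# wobble series

def _wobble_deltas(amplitude: float, n_frames: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Signed in-plane deviations with max |delta| == amplitude exactly.

    Deviations come in +/- pairs so that their mean direction is the rest
    direction, making the planted amplitude exactly recoverable as the
    maximum wobble angle.
    """
    if amplitude == 0.0:
        return np.zeros(n_frames)
    deltas = [amplitude, -amplitude]
    n_extra = n_frames - 2
    for _ in range(n_extra // 2):
        x = float(rng.uniform(0.0, amplitude))
        deltas.extend([x, -x])
    if n_extra % 2:
        deltas.append(0.0)
    return np.array(deltas)


def make_wobble_series(digb: SyntheticScene, amplitude: float,
                       n_frames: int = 60, seed: int = 0,
                       static_chain: str = "A", mobile_chain: str = "B"
                       ) -> SyntheticScene:
    """Frame series in which the mobile Gb wobbles about its rest axis.

    Each frame rotates the mobile chain about an axis through its hinge
    C-alpha, perpendicular to its axis vector, by a signed deviation; the
    deviations are drawn so their maximum magnitude equals ``amplitude``
    (degrees) exactly and their mean direction is the rest direction.  The
    static chain is identical in every frame.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(seed)
    deltas = _wobble_deltas(amplitude, n_frames, rng)

    ann_b = digb.annotations[mobile_chain]
    d_b = axis_vector(ann_b).d
    pivot = ann_b.ca_record(12).xyz
    wobble_axis = _perpendicular(d_b)

    static_atoms = digb.parts[static_chain]
    mobile_atoms = digb.parts[mobile_chain]
    frames: list[AtomSet] = []
    for delta in deltas:
        rot = Rotation.from_rotvec(wobble_axis * np.radians(delta))
        coords = rot.apply(mobile_atoms.coords - pivot) + pivot
        frames.append(static_atoms.concat(mobile_atoms.with_coords(coords)))

    return SyntheticScene(
        parts=dict(digb.parts),
        frames=frames,
        annotations=dict(digb.annotations),
        truth={**digb.truth,
               "wobble_amplitude": float(amplitude),
               "wobble_deltas": deltas},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# planted clash scenes

def make_clash_scene(n_atoms: int, k_clash: int, cutoff: float = 4.0,
                     seed: int = 0) -> SyntheticScene:
    """Probe/environment atom sets with exactly ``k_clash`` planted contacts.

    Exactly ``k_clash`` probe atoms have an environment atom within
    ``cutoff``; every other probe atom is farther than ``cutoff`` + 1 A from
    all environment atoms.
    """
    if n_atoms < 1:
        raise ValueError("n_atoms must be >= 1")
    if not 0 <= k_clash <= n_atoms:
        raise ValueError(f"k_clash must be in [0, {n_atoms}], got {k_clash}")
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    rng = np.random.default_rng(seed)
    spacing = 2.0 * cutoff + 4.0

    env_pos = np.zeros((n_atoms, 3))
    env_pos[:, 0] = np.arange(n_atoms) * spacing
    env_pos += rng.uniform(-0.3, 0.3, size=env_pos.shape)

    probe_pos = np.zeros((n_atoms, 3))
    for j in range(k_clash):
        direction = _unit(rng.normal(size=3))
        probe_pos[j] = env_pos[j] + 0.75 * cutoff * direction
    far_y = 10.0 * (cutoff + 1.0)
    for i, j in enumerate(range(k_clash, n_atoms)):
        probe_pos[j] = [i * spacing, far_y, 0.0]
    probe_pos[k_clash:] += rng.uniform(-0.3, 0.3,
                                       size=probe_pos[k_clash:].shape)

    def _carbon_chain(chain_id: str, pos: np.ndarray) -> AtomSet:
        return AtomSet([
            AtomRecord(chain_id=chain_id, residue_number=i + 1,
                       insertion_code="", residue_name="GLY", atom_name="CA",
                       element="C", x=float(p[0]), y=float(p[1]),
                       z=float(p[2]))
            for i, p in enumerate(pos)
        ], provenance=f"make_clash_scene(seed={seed})")

    probe = _carbon_chain("P", probe_pos)
    environment = _carbon_chain("E", env_pos)

    dmin = cdist(probe_pos, env_pos).min(axis=1)
    if int((dmin <= cutoff).sum()) != k_clash or \
            np.any(dmin[k_clash:] <= cutoff + 1.0):
        raise AssemblyError("planted clash construction failed self-check")
    return SyntheticScene(
        parts={"probe": probe, "environment": environment},
        truth={"n_clash_planted": int(k_clash), "cutoff": float(cutoff)},
        seed=seed,
    )


# ---------------------------------------------------------------------------
# end-to-end screening scenes

def make_screen_scene(seed: int, k_clash: int, n_target: int = 100,
                      intra_angle: float = 85.0, c12_separation: float = 6.0,
                      cutoff: float = 4.0,
                      gb: ChainAnnotation | None = None) -> SyntheticScene:
    """Complex + scaffold pair with an exact planted screening clash count.

    The complex holds one nanobody chain N (coincident with scaffold chain A,
    so its placements on the scaffold are exact) and a C-alpha target chain
    T.  Target atoms sit along the scaffold's hinge axis far from both Gb
    bodies; ``k_clash`` of them (``k_clash`` must be even) are arranged in
    pairs such that after placing both complex copies each pair member lies
    exactly 0.75 * cutoff from an atom of the other copy.  The planted
    truth therefore predicts ``n_clash = k_clash`` out of
    ``n_total = 2 * n_target``.
    """
    if k_clash % 2:
        raise ValueError("k_clash must be even (clashes plant in pairs)")
    if k_clash > n_target:
        raise ValueError("k_clash cannot exceed n_target")
    if not 40.0 <= intra_angle <= 140.0:
        raise AssemblyError(
            "planted screening scenes need an intra angle in [40, 140] "
            "degrees to keep incidental contacts away from the cutoff")
    if gb is None:
        gb = make_toy_gb(seed)
    scaffold = assemble_digb(gb, intra_angle, c12_separation)
    axis = scaffold.truth["hinge_axis"]
    pivot = scaffold.truth["pivot"]
    rot = Rotation.from_matrix(scaffold.truth["copy_map_rotation"])
    tvec = scaffold.truth["copy_map_translation"]

    def copy_map(x: np.ndarray) -> np.ndarray:
        return rot.apply(x) + tvec

    n_pairs = k_clash // 2
    n_far = n_target - k_clash
    target_pos = np.zeros((n_target, 3))
    h0 = 120.0
    for i in range(n_far):
        target_pos[i] = pivot + (h0 + 8.0 * i) * axis
    h1 = h0 + 8.0 * n_far + 60.0
    for j in range(n_pairs):
        q = pivot + (h1 + 16.0 * j) * axis
        p = copy_map(q) + 0.75 * cutoff * axis
        target_pos[n_far + 2 * j] = q
        target_pos[n_far + 2 * j + 1] = p

    target = AtomSet([
        AtomRecord(chain_id="T", residue_number=i + 1, insertion_code="",
                   residue_name="GLY", atom_name="CA", element="C",
                   x=float(p[0]), y=float(p[1]), z=float(p[2]))
        for i, p in enumerate(target_pos)
    ], provenance=f"make_screen_scene(seed={seed}, k={k_clash})")
    nanobody = scaffold.parts["A"].relabel_chain("A", "N")
    complex_atoms = nanobody.concat(target)

    # independent all-pairs self-check of the planted count
    nb_coords = scaffold.parts["A"].coords
    placed = [np.vstack([target_pos, nb_coords]),
              np.vstack([copy_map(target_pos), copy_map(nb_coords)])]
    n_a = int((cdist(target_pos, placed[1]).min(axis=1) <= cutoff).sum())
    n_b = int((cdist(copy_map(target_pos), placed[0]).min(axis=1)
               <= cutoff).sum())
    if n_a + n_b != k_clash:
        raise AssemblyError(
            f"planted screening scene self-check failed: "
            f"{n_a}+{n_b} != {k_clash}")

    return SyntheticScene(
        parts={"complex": complex_atoms, "scaffold": scaffold.atoms},
        annotations=scaffold.annotations,
        truth={"n_clash_planted": int(k_clash),
               "n_total": 2 * n_target,
               "score": k_clash / (2 * n_target),
               "intra_angle": float(intra_angle),
               "cutoff": float(cutoff)},
        seed=seed,
    )


def make_screen_library(seed: int, plantings: list[int], n_target: int = 100,
                        intra_angle: float = 85.0
                        ) -> tuple[dict[str, AtomSet], AtomSet]:
    """A library of complexes sharing one scaffold, with planted clash counts.

    Returns ``(entries, scaffold_atoms)`` ready for
    :func:`digembody.clash.survey_library`; entry ``i`` plants
    ``plantings[i]`` clashing target atoms out of ``2 * n_target``.
    """
    gb = make_toy_gb(seed)
    scaffold_atoms = None
    entries: dict[str, AtomSet] = {}
    for i, k in enumerate(plantings):
        scene = make_screen_scene(seed, k, n_target=n_target,
                                  intra_angle=intra_angle, gb=gb)
        entries[f"entry_{i:02d}"] = scene.parts["complex"]
        scaffold_atoms = scene.parts["scaffold"]
    return entries, scaffold_atoms
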