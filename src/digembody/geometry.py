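"""Geometry of the DiGb interface: axis vectors, wobble, and contacts.

Each Gembody in a dimer is reduced to an axis vector ``D`` running from its
heavy-atom center of mass to the C-alpha of the cysteine at IMGT position 12
(the covalent hinge).  Over a series of docked coordinate models the motion
of the mobile Gb relative to a static (reference-aligned) Gb is quantified
as per-frame wobble angles

    beta_i = arccos( D_a . D_i / (|D_a| |D_i|) ),   D_a = mean_i D_i,

with ``D_a`` the arithmetic mean of the *unnormalized* per-frame vectors.
The intra-DiGb angle is the angle between the average axis vectors of the
two Gbs.  Contact analysis reports residue pairs across the interface by
minimum heavy-atom distance, flagging nitrogen/oxygen pairs within
hydrogen-bonding distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist

from .annotation import ChainAnnotation, ImgtPos, annotate_chain
from .errors import GeometryError
from .structure_io import AtomSet, center_of_mass
from .superpose import apply_transform, superpose_chains

HINGE_IMGT_POSITION = 12


@dataclass(frozen=True)
class AxisVector:
    """Gb axis: center of mass -> C-alpha of the IMGT-12 hinge residue."""

    origin: np.ndarray  # center of mass, A
    tip: np.ndarray     # CA of IMGT 12, A

    @property
    def d(self) -> np.ndarray:
        return self.tip - self.origin


def axis_vector(gb: ChainAnnotation, weighting: str = "atomic_mass"
                ) -> AxisVector:
    """Axis vector of one annotated Gb chain.

    Raises :class:`GeometryError` if the hinge residue has no C-alpha.
    """
    ca = gb.ca_record(HINGE_IMGT_POSITION)
    if ca is None:
        raise GeometryError(
            f"chain {gb.chain_id!r}: no C-alpha at IMGT position "
            f"{HINGE_IMGT_POSITION}")
    origin = center_of_mass(gb.atoms, weighting=weighting)
    return AxisVector(origin=origin, tip=ca.xyz)


def angle_between(u, v) -> float:
    """Angle in degrees between two vectors, cosine clamped to [-1, 1]."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise GeometryError("angle undefined for a zero-length vector")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def intra_digb_angle(static_d, mobile_d) -> float:
    """Angle (degrees, [0, 180]) between the two Gbs' axis vectors.

    Accepts :class:`AxisVector` instances or plain 3-vectors; by convention
    both vectors point from the center of mass toward the hinge C-alpha.
    """
    if isinstance(static_d, AxisVector):
        static_d = static_d.d
    if isinstance(mobile_d, AxisVector):
        mobile_d = mobile_d.d
    return angle_between(static_d, mobile_d)


@dataclass
class GeometrySeries:
    """Axis vectors and wobble statistics over a model series."""

    n_frames: int
    d_static: np.ndarray     # (n, 3) per-frame static-Gb axis vectors
    d_mobile: np.ndarray     # (n, 3) per-frame mobile-Gb axis vectors
    beta: np.ndarray         # (n,) wobble angles of the mobile Gb, degrees

    @property
    def d_a_static(self) -> np.ndarray:
        return self.d_static.mean(axis=0)

    @property
    def d_a_mobile(self) -> np.ndarray:
        return self.d_mobile.mean(axis=0)

    @property
    def intra_digb_angle(self) -> float:
        return angle_between(self.d_a_static, self.d_a_mobile)

    @property
    def wobble_max(self) -> float:
        return float(self.beta.max())

    @property
    def wobble_range(self) -> float:
        return float(self.beta.max() - self.beta.min())

    def as_tsv(self) -> str:
        lines = ["frame\tbeta_deg"]
        for i, b in enumerate(self.beta):
            lines.append(f"{i}\t{b:.4f}")
        lines.append(f"# intra_digb_angle_deg: {self.intra_digb_angle:.1f}")
        lines.append(f"# wobble_max_deg: {self.wobble_max:.1f}")
        lines.append(f"# wobble_range_deg: {self.wobble_range:.1f}")
        return "\n".join(lines) + "\n"


def wobble_angles(d_vectors: np.ndarray) -> np.ndarray:
    """beta_i = arccos(D_a . D_i / (|D_a||D_i|)) in degrees, D_a = mean D_i."""
    d = np.asarray(d_vectors, dtype=float)
    d_a = d.mean(axis=0)
    na = np.linalg.norm(d_a)
    ni = np.linalg.norm(d, axis=1)
    if na == 0 or np.any(ni == 0):
        raise GeometryError("zero-length axis vector in series")
    cos = np.clip(d @ d_a / (ni * na), -1.0, 1.0)
    return np.degrees(np.arccos(cos))


def wobble_series(frames: list[AtomSet], static_chain: str, mobile_chain: str,
                  annotations: tuple[ChainAnnotation, ChainAnnotation] | None
                  = None,
                  weighting: str = "atomic_mass") -> GeometrySeries:
    """Wobble analysis of a mobile Gb over a series of docked models.

    Every frame is first superposed onto the static Gb of the first frame
    (framework C-alpha correspondence), then per-frame axis vectors are
    extracted for both Gbs and the wobble angles computed for the mobile
    one.  ``annotations`` may supply precomputed (static, mobile) chain
    annotations from the first frame; residue numbering must then be
    consistent across frames.

    Raises
    ------
    GeometryError
        listing the frame, if any frame lacks one of the two chains.
    """
    if len(frames) < 2:
        raise GeometryError("need at least 2 frames for a series")
    for i, fr in enumerate(frames):
        missing = {static_chain, mobile_chain} - set(fr.chain_ids())
        if missing:
            raise GeometryError(f"frame {i}: missing chain(s) {sorted(missing)}")

    if annotations is None:
        ann_static = annotate_chain(frames[0], static_chain)
        ann_mobile = annotate_chain(frames[0], mobile_chain)
    else:
        ann_static, ann_mobile = annotations

    d_static: list[np.ndarray] = []
    d_mobile: list[np.ndarray] = []
    ref = ChainAnnotation(static_chain, frames[0].chain(static_chain),
                          ann_static.fmap, ann_static.residue_keys)
    for fr in frames:
        fs = ChainAnnotation(static_chain, fr.chain(static_chain),
                             ann_static.fmap, ann_static.residue_keys)
        transform = superpose_chains(fs, ref)
        aligned = apply_transform(fr, transform)
        for chain, ann, out in ((static_chain, ann_static, d_static),
                                (mobile_chain, ann_mobile, d_mobile)):
            ca = ChainAnnotation(chain, aligned.chain(chain), ann.fmap,
                                 ann.residue_keys)
            out.append(axis_vector(ca, weighting=weighting).d)

    d_mobile_arr = np.array(d_mobile)
    return GeometrySeries(
        n_frames=len(frames),
        d_static=np.array(d_static),
        d_mobile=d_mobile_arr,
        beta=wobble_angles(d_mobile_arr),
    )


# ---------------------------------------------------------------------------
# contacts

def residue_min_distance(res_a: AtomSet, res_b: AtomSet) -> float:
    """Minimum heavy-atom distance (A) between two residues.

    Hydrogens are ignored; a residue without heavy atoms is an error.
    """
    a = res_a.heavy()
    b = res_b.heavy()
    if len(a) == 0 or len(b) == 0:
        raise GeometryError("residue with no heavy atoms")
    return float(cdist(a.coords, b.coords).min())


@dataclass(frozen=True)
class ContactRecord:
    """One residue pair across the interface."""

    chain_a: str
    residue_a: tuple[int, str, str]   # (author number, icode, residue name)
    imgt_a: ImgtPos | None
    chain_b: str
    residue_b: tuple[int, str, str]
    imgt_b: ImgtPos | None
    min_heavy_distance: float
    is_hbond: bool
    hbond_atoms: tuple[str, str] | None   # atom names on a and b sides


_HBOND_ELEMENTS = {"N", "O"}


def interface_contacts(atoms_a: AtomSet, atoms_b: AtomSet,
                       ann_a: ChainAnnotation | None = None,
                       ann_b: ChainAnnotation | None = None,
                       contact_cutoff: float = 4.0,
                       hbond_cutoff: float = 3.5) -> list[ContactRecord]:
    """Residue pairs across an interface with min heavy distance <= cutoff.

    Hydrogen bonds are flagged on a pure distance criterion (N/O against N/O
    within ``hbond_cutoff``): deposited cryo-EM models usually carry no
    hydrogens, so no angle term is applied.
    """
    heavy_a = atoms_a.heavy()
    heavy_b = atoms_b.heavy()
    if len(heavy_a) == 0 or len(heavy_b) == 0:
        return []
    res_a = heavy_a.residues()
    res_b = heavy_b.residues()
    tree_b = cKDTree(heavy_b.coords)

    # map each b-atom index to its residue index for the prefilter
    b_res_index = []
    for i, (_key, ratoms) in enumerate(res_b):
        b_res_index.extend([i] * len(ratoms))
    b_res_index = np.array(b_res_index)
    # residues() preserves atom order within residues but the flat heavy_b
    # order may interleave; rebuild coordinates residue-wise to stay aligned
    b_coords = np.concatenate([r.coords for _k, r in res_b])
    tree_b = cKDTree(b_coords)

    contacts: list[ContactRecord] = []
    for key_a, ratoms_a in res_a:
        idx = tree_b.query_ball_point(ratoms_a.coords, r=contact_cutoff)
        near_res = sorted({int(b_res_index[j]) for lst in idx for j in lst})
        for ib in near_res:
            key_b, ratoms_b = res_b[ib]
            dmat = cdist(ratoms_a.coords, ratoms_b.coords)
            dmin = float(dmat.min())
            if dmin > contact_cutoff:
                continue
            hb_atoms = None
            is_hb = False
            pol_a = [i for i, r in enumerate(ratoms_a)
                     if r.element.upper() in _HBOND_ELEMENTS]
            pol_b = [j for j, r in enumerate(ratoms_b)
                     if r.element.upper() in _HBOND_ELEMENTS]
            if pol_a and pol_b:
                sub = dmat[np.ix_(pol_a, pol_b)]
                if sub.min() <= hbond_cutoff:
                    is_hb = True
                    ia, jb = np.unravel_index(sub.argmin(), sub.shape)
                    hb_atoms = (ratoms_a[pol_a[ia]].atom_name,
                                ratoms_b[pol_b[jb]].atom_name)
            contacts.append(ContactRecord(
                chain_a=key_a[0],
                residue_a=(key_a[1], key_a[2], key_a[3]),
                imgt_a=_imgt_of(ann_a, key_a),
                chain_b=key_b[0],
                residue_b=(key_b[1], key_b[2], key_b[3]),
                imgt_b=_imgt_of(ann_b, key_b),
                min_heavy_distance=dmin,
                is_hbond=is_hb,
                hbond_atoms=hb_atoms,
            ))
    contacts.sort(key=lambda c: c.min_heavy_distance)
    return contacts


def _imgt_of(ann: ChainAnnotation | None, key) -> ImgtPos | None:
    if ann is None or key[0] != ann.chain_id:
        return None
    try:
        i = ann.residue_keys.index((key[1], key[2]))
    except ValueError:
        return None
    return ann.fmap.index_to_imgt.get(i)
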