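"""Least-squares rigid-body superposition (Kabsch) and its application.

Scaffold placement and frame alignment both reduce to superposing matched
framework C-alpha atoms: CDR loops are excluded because their conformation
differs between a target-bound nanobody and a scaffold Gembody, while
framework regions deviate by only about 1 A RMSD across nanobodies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .annotation import ChainAnnotation, ImgtPos, is_cdr_position
from .errors import CorrespondenceError, DegenerateGeometryError
from .structure_io import AtomSet

#: minimum number of shared framework C-alpha positions for a placement
MIN_SHARED_POSITIONS = 20


@dataclass(frozen=True)
class RigidTransform:
    """x -> R @ x + t, with the RMSD of the fit that produced it."""

    rotation: np.ndarray      # (3, 3), orthonormal, det +1
    translation: np.ndarray   # (3,)
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T \
            + self.translation

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation, self.rmsd)

    def compose(self, first: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``first`` then ``self``."""
        return RigidTransform(self.rotation @ first.rotation,
                              self.rotation @ first.translation
                              + self.translation, float("nan"))

    def to_flat(self) -> np.ndarray:
        """12 numbers: row-major rotation then translation."""
        return np.concatenate([self.rotation.ravel(), self.translation])

    @classmethod
    def from_flat(cls, values, rmsd: float = float("nan")) -> "RigidTransform":
        v = np.asarray(values, dtype=float).ravel()
        if v.size != 12:
            raise ValueError("expected 12 numbers (rotation row-major + t)")
        return cls(v[:9].reshape(3, 3), v[9:], rmsd)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3), 0.0)


def kabsch_superpose(mobile: np.ndarray, fixed: np.ndarray) -> RigidTransform:
    """Optimal rigid transform mapping ``mobile`` onto ``fixed``.

    Closed-form SVD solution minimizing the coordinate RMSD; reflections are
    excluded by the usual determinant sign correction.

    Raises
    ------
    ValueError
        on length mismatch or fewer than 3 points.
    DegenerateGeometryError
        when either point set is (near-)collinear, which leaves a rotation
        degree of freedom undetermined.
    """
    mobile = np.asarray(mobile, dtype=float)
    fixed = np.asarray(fixed, dtype=float)
    if mobile.shape != fixed.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError(
            f"point sets must both be (n, 3); got {mobile.shape} and "
            f"{fixed.shape}")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 points, got {n}")

    mc = mobile.mean(axis=0)
    fc = fixed.mean(axis=0)
    x = mobile - mc
    y = fixed - fc
    for pts, name in ((x, "mobile"), (y, "fixed")):
        s = np.linalg.svd(pts, compute_uv=False)
        if s[1] <= 1e-8 * max(s[0], 1.0):
            raise DegenerateGeometryError(
                f"{name} points are collinear; rotation is underdetermined")

    h = x.T @ y
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.diag([1.0, 1.0, d])
    rotation = vt.T @ corr @ u.T
    translation = fc - rotation @ mc
    moved = x @ rotation.T + fc
    rmsd = float(np.sqrt(((moved - fixed) ** 2).sum() / n))
    return RigidTransform(rotation, translation, rmsd)


def apply_transform(atoms: AtomSet, transform: RigidTransform) -> AtomSet:
    """Return a new AtomSet with every coordinate mapped through ``transform``."""
    return atoms.with_coords(transform.apply(atoms.coords), note="transformed")


def match_framework_atoms(mobile: ChainAnnotation, fixed: ChainAnnotation
                          ) -> tuple[np.ndarray, np.ndarray, list[ImgtPos]]:
    """Paired C-alpha coordinates at shared framework IMGT positions.

    CDR positions are excluded; positions lacking a C-alpha in either chain
    simply drop out of the pairing.

    Raises
    ------
    CorrespondenceError
        if fewer than ``MIN_SHARED_POSITIONS`` pairs remain.
    """
    mobile_pts: list[np.ndarray] = []
    fixed_pts: list[np.ndarray] = []
    positions: list[ImgtPos] = []
    shared = [p for p, _ in mobile.fmap.framework_items()
              if fixed.fmap.index_of(p) is not None]
    for pos in shared:
        if is_cdr_position(pos):
            continue
        ca_m = mobile.ca_record(pos)
        ca_f = fixed.ca_record(pos)
        if ca_m is None or ca_f is None:
            continue
        mobile_pts.append(ca_m.xyz)
        fixed_pts.append(ca_f.xyz)
        positions.append(pos)
    if len(positions) < MIN_SHARED_POSITIONS:
        raise CorrespondenceError(
            f"only {len(positions)} shared framework C-alpha positions "
            f"(need >= {MIN_SHARED_POSITIONS})")
    return np.array(mobile_pts), np.array(fixed_pts), positions


def superpose_chains(mobile: ChainAnnotation, fixed: ChainAnnotation,
                     reject_outliers: bool = False,
                     outlier_cutoff: float = 2.0,
                     max_cycles: int = 5) -> RigidTransform:
    """Superpose one annotated nanobody chain onto another.

    The fit uses uniform weights over the shared framework C-alphas.  With
    ``reject_outliers`` the fit is iterated, dropping pairs deviating by more
    than ``outlier_cutoff`` A, for at most ``max_cycles`` cycles (useful for
    structures with locally deformed framework segments).
    """
    m, f, _pos = match_framework_atoms(mobile, fixed)
    transform = kabsch_superpose(m, f)
    if not reject_outliers:
        return transform
    for _ in range(max_cycles):
        dev = np.linalg.norm(transform.apply(m) - f, axis=1)
        keep = dev <= outlier_cutoff
        if keep.all() or keep.sum() < MIN_SHARED_POSITIONS:
            break
        m, f = m[keep], f[keep]
        transform = kabsch_superpose(m, f)
    return transform
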