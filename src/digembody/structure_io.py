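"""Reading, selecting and writing protein coordinates.

The in-memory container is :class:`AtomSet`, an ordered, immutable collection
of :class:`AtomRecord` entries plus a provenance string.  Parsing and
serialization are delegated to :mod:`gemmi`; this module fixes the package's
conventions on top of it:

* alternate locations are resolved to the highest-occupancy conformer
  (first-listed on ties) at read time;
* only the first model of a multi-model file is used;
* hydrogens are retained on read but excluded from mass and distance
  defaults throughout the package.

Coordinates are in Angstrom, residue numbering is the author numbering of the
source file.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np

from .errors import EmptyStructureError, GeometryError

logger = logging.getLogger(__name__)

_HYDROGEN_ELEMENTS = {"H", "D", "T"}

#: residue key: (chain_id, residue_number, insertion_code, residue_name)
ResidueKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class AtomRecord:
    """One atom with its chain/residue identity and Cartesian coordinates (A)."""

    chain_id: str
    residue_number: int
    insertion_code: str
    residue_name: str
    atom_name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    altloc: str = ""

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in _HYDROGEN_ELEMENTS

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def residue_key(self) -> ResidueKey:
        return (self.chain_id, self.residue_number, self.insertion_code,
                self.residue_name)


class AtomSet(Sequence):
    """Ordered collection of :class:`AtomRecord` with vectorized coordinate access."""

    def __init__(self, records: Iterable[AtomRecord], provenance: str = ""):
        self._records: tuple[AtomRecord, ...] = tuple(records)
        self.provenance = provenance
        self._coords: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self._records)

    def __getitem__(self, i):
        if isinstance(i, slice):
            return AtomSet(self._records[i], self.provenance)
        return self._records[i]

    def __iter__(self) -> Iterator[AtomRecord]:
        return iter(self._records)

    def __repr__(self) -> str:
        return f"AtomSet({len(self)} atoms, provenance={self.provenance!r})"

    @property
    def records(self) -> tuple[AtomRecord, ...]:
        return self._records

    @property
    def coords(self) -> np.ndarray:
        """(n, 3) array of coordinates in A; cached, do not mutate."""
        if self._coords is None:
            self._coords = np.array(
                [[r.x, r.y, r.z] for r in self._records], dtype=float
            ).reshape(len(self._records), 3)
        return self._coords

    def with_coords(self, coords: np.ndarray, note: str = "") -> "AtomSet":
        """Same labels, new coordinates (used by rigid transforms)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self), 3):
            raise ValueError(f"coords shape {coords.shape} != ({len(self)}, 3)")
        recs = [replace(r, x=float(c[0]), y=float(c[1]), z=float(c[2]))
                for r, c in zip(self._records, coords)]
        prov = self.provenance + (f" | {note}" if note else "")
        return AtomSet(recs, prov)

    def subset(self, mask) -> "AtomSet":
        return AtomSet((r for r, m in zip(self._records, mask) if m),
                       self.provenance)

    def heavy(self) -> "AtomSet":
        return self.subset([not r.is_hydrogen for r in self._records])

    def chain(self, chain_id: str) -> "AtomSet":
        return self.subset([r.chain_id == chain_id for r in self._records])

    def chain_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self._records:
            seen.setdefault(r.chain_id, None)
        return tuple(seen)

    def relabel_chain(self, old: str, new: str) -> "AtomSet":
        recs = [replace(r, chain_id=new) if r.chain_id == old else r
                for r in self._records]
        return AtomSet(recs, self.provenance)

    def residues(self) -> list[tuple[ResidueKey, "AtomSet"]]:
        """Residues in order of first appearance, each as its own AtomSet."""
        order: dict[ResidueKey, list[AtomRecord]] = {}
        for r in self._records:
            order.setdefault(r.residue_key, []).append(r)
        return [(k, AtomSet(v, self.provenance)) for k, v in order.items()]

    def find_atom(self, chain_id: str, residue_number: int, atom_name: str,
                  insertion_code: str = "") -> AtomRecord | None:
        for r in self._records:
            if (r.chain_id == chain_id and r.residue_number == residue_number
                    and r.insertion_code == insertion_code
                    and r.atom_name == atom_name):
                return r
        return None

    def concat(self, other: "AtomSet") -> "AtomSet":
        return AtomSet(self._records + other.records,
                       f"{self.provenance}+{other.provenance}")


# ---------------------------------------------------------------------------
# parsing

_FORMATS = {
    "pdb": gemmi.CoorFormat.Pdb,
    "mmcif": gemmi.CoorFormat.Mmcif,
    "auto": gemmi.CoorFormat.Detect,
}


def read_structure(path, format: str = "auto") -> AtomSet:
    """Read a PDB or mmCIF file into an :class:`AtomSet`.

    All ATOM/HETATM records of the first model are returned with altlocs
    resolved (highest occupancy wins, first-listed on ties).  Additional
    models are ignored with a logged notice.

    Raises
    ------
    OSError
        if the file cannot be read.
    ValueError
        if the file cannot be parsed in the requested dialect.
    EmptyStructureError
        if parsing succeeds but yields zero atoms.
    """
    path = Path(path)
    if format not in _FORMATS:
        raise ValueError(f"unknown format {format!r}; expected pdb/mmcif/auto")
    try:
        st = gemmi.read_structure(str(path), format=_FORMATS[format])
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"could not parse {path}: {exc}") from exc
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    if len(st) > 1:
        logger.info("%s: %d models present, using model 1 only", path, len(st))

    records: list[AtomRecord] = []
    for chain in st[0]:
        for res in chain:
            icode = res.seqid.icode.strip()
            for atom in res:
                records.append(AtomRecord(
                    chain_id=chain.name,
                    residue_number=res.seqid.num,
                    insertion_code=icode,
                    residue_name=res.name,
                    atom_name=atom.name,
                    element=atom.element.name,
                    x=atom.pos.x, y=atom.pos.y, z=atom.pos.z,
                    occupancy=atom.occ,
                    altloc=atom.altloc if atom.altloc else "",
                ))
    records = _resolve_altlocs(records)
    if not records:
        raise EmptyStructureError(f"{path}: no atoms parsed")
    return AtomSet(records, provenance=str(path))


def _resolve_altlocs(records: list[AtomRecord]) -> list[AtomRecord]:
    """Keep one conformer per atom: highest occupancy, first-listed on ties."""
    best: dict[tuple, tuple[int, AtomRecord]] = {}
    order: list[tuple] = []
    for i, r in enumerate(records):
        key = (r.chain_id, r.residue_number, r.insertion_code,
               r.residue_name, r.atom_name)
        if key not in best:
            best[key] = (i, r)
            order.append(key)
        elif r.occupancy > best[key][1].occupancy:
            best[key] = (best[key][0], r)
    return [best[k][1] for k in order]


# ---------------------------------------------------------------------------
# selection

def _is_water(residue_name: str) -> bool:
    info = gemmi.find_tabulated_residue(residue_name)
    return info is not None and info.is_water()


def _is_polymer_residue(residue_name: str) -> bool:
    info = gemmi.find_tabulated_residue(residue_name)
    if info is None:
        return False
    return info.is_amino_acid() or info.is_nucleic_acid()


def select_atoms(atoms: AtomSet, chain: str | None = None,
                 residue_range: tuple[int, int] | None = None,
                 heavy_only: bool = False,
                 polymer_only: bool = False) -> AtomSet:
    """Conjunctive atom selection; an empty result is valid, not an error.

    ``residue_range`` is an inclusive ``(first, last)`` interval in author
    numbering.  ``polymer_only`` drops waters and residues that are neither
    amino acids nor nucleotides.
    """
    if len(atoms) == 0:
        raise ValueError("select_atoms: input AtomSet is empty")
    if residue_range is not None:
        try:
            lo, hi = residue_range
            lo, hi = int(lo), int(hi)
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed residue_range {residue_range!r}") from exc
        if lo > hi:
            raise ValueError(f"residue_range {residue_range!r}: first > last")

    mask = []
    for r in atoms:
        keep = True
        if chain is not None:
            keep &= r.chain_id == chain
        if residue_range is not None:
            keep &= lo <= r.residue_number <= hi
        if heavy_only:
            keep &= not r.is_hydrogen
        if polymer_only:
            keep &= (not _is_water(r.residue_name)
                     and _is_polymer_residue(r.residue_name))
        mask.append(keep)
    return atoms.subset(mask)


# ---------------------------------------------------------------------------
# center of mass

def center_of_mass(atoms: AtomSet, weighting: str = "atomic_mass") -> np.ndarray:
    """Weighted mean position of the heavy atoms, in A.

    Hydrogens are excluded regardless of ``weighting`` ("atomic_mass" or
    "uniform").
    """
    if weighting not in ("atomic_mass", "uniform"):
        raise ValueError(f"unknown weighting {weighting!r}")
    heavy = atoms.heavy()
    if len(heavy) == 0:
        raise ValueError("center_of_mass: no heavy atoms")
    if weighting == "uniform":
        w = np.ones(len(heavy))
    else:
        w = np.array([gemmi.Element(r.element).weight for r in heavy])
        if np.any(w <= 0):
            bad = [r.element for r, wi in zip(heavy, w) if wi <= 0]
            raise GeometryError(f"unknown element(s) for mass weighting: {bad}")
    return (heavy.coords * w[:, None]).sum(axis=0) / w.sum()


# ---------------------------------------------------------------------------
# writing

def write_structure(atoms: AtomSet, path, format: str = "pdb") -> None:
    """Write an AtomSet as PDB or mmCIF.

    Coordinates survive a PDB round trip to 3 decimals (format precision) and
    an mmCIF round trip unchanged at the printed precision.  Chain ids wider
    than the PDB field (2 characters with gemmi's extended convention) are
    rejected for ``format="pdb"``.
    """
    if len(atoms) == 0:
        raise ValueError("write_structure: empty AtomSet")
    if format not in ("pdb", "mmcif"):
        raise ValueError(f"unknown format {format!r}")
    if format == "pdb":
        wide = sorted({r.chain_id for r in atoms if len(r.chain_id) > 2})
        if wide:
            raise ValueError(
                f"chain id(s) {wide} exceed the PDB chain-id field; "
                "use mmcif format")

    # gemmi's add_* methods copy their argument, so build bottom-up:
    # group records by chain and residue in order of appearance first.
    chains: dict[str, list[tuple[tuple, list[AtomRecord]]]] = {}
    for r in atoms:
        groups = chains.setdefault(r.chain_id, [])
        rkey = (r.residue_number, r.insertion_code, r.residue_name)
        if not groups or groups[-1][0] != rkey:
            groups.append((rkey, []))
        groups[-1][1].append(r)

    st = gemmi.Structure()
    st.name = "digembody"
    model = gemmi.Model("1")
    for chain_id, groups in chains.items():
        chain = gemmi.Chain(chain_id)
        for (num, icode, resname), recs in groups:
            res = gemmi.Residue()
            res.name = resname
            res.seqid = gemmi.SeqId(num, icode or " ")
            res.het_flag = "A" if _is_polymer_residue(resname) else "H"
            for r in recs:
                atom = gemmi.Atom()
                atom.name = r.atom_name
                atom.element = gemmi.Element(r.element)
                atom.pos = gemmi.Position(r.x, r.y, r.z)
                atom.occ = r.occupancy
                atom.altloc = r.altloc if r.altloc else "\0"
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    path = Path(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if format == "pdb":
            st.write_pdb(str(path))
        else:
            st.make_mmcif_document().write_file(str(path))
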