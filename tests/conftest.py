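import numpy as np
import pytest

from digembody import assemble_digb, make_toy_gb
from digembody.structure_io import AtomRecord, AtomSet


def pdb_line(serial, name, resname, chain, resnum, x, y, z, element,
             occ=1.0, altloc=" ", record="ATOM"):
    pad_name = f" {name:<3}" if len(name) < 4 else f"{name:<4}"
    return (f"{record:<6}{serial:>5} {pad_name}{altloc}{resname:>3} "
            f"{chain:1}{resnum:>4}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{occ:6.2f}{0.0:6.2f}          {element:>2}")


@pytest.fixture(scope="session")
def gly_pdb_text():
    """A single glycine: N, CA, C at hand-listed coordinates."""
    lines = [
        pdb_line(1, "N", "GLY", "A", 1, 1.0, 2.0, 3.0, "N"),
        pdb_line(2, "CA", "GLY", "A", 1, 2.5, 2.0, 3.0, "C"),
        pdb_line(3, "C", "GLY", "A", 1, 3.25, 3.25, 3.0, "C"),
        "END",
    ]
    return "\n".join(lines) + "\n"


@pytest.fixture(scope="session")
def two_chain_pdb_text():
    """Chains A (ala with 2 hydrogens) and B (gly), plus one water."""
    lines = [
        pdb_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, "N"),
        pdb_line(2, "CA", "ALA", "A", 1, 1.5, 0.0, 0.0, "C"),
        pdb_line(3, "CB", "ALA", "A", 1, 2.0, 1.4, 0.0, "C"),
        pdb_line(4, "HB1", "ALA", "A", 1, 2.5, 1.5, 0.9, "H"),
        pdb_line(5, "HB2", "ALA", "A", 1, 2.5, 1.5, -0.9, "H"),
        pdb_line(6, "N", "GLY", "B", 1, 10.0, 0.0, 0.0, "N"),
        pdb_line(7, "CA", "GLY", "B", 1, 11.5, 0.0, 0.0, "C"),
        pdb_line(8, "O", "HOH", "B", 100, 20.0, 20.0, 20.0, "O",
                 record="HETATM"),
        "END",
    ]
    return "\n".join(lines) + "\n"


def make_atoms(coords, chain="A", element="C", atom_name="CA",
               resname="GLY"):
    """One single-atom residue per coordinate."""
    return AtomSet([
        AtomRecord(chain_id=chain, residue_number=i + 1, insertion_code="",
                   residue_name=resname, atom_name=atom_name, element=element,
                   x=float(c[0]), y=float(c[1]), z=float(c[2]))
        for i, c in enumerate(np.atleast_2d(coords))
    ])


@pytest.fixture(scope="session")
def toy_gb():
    return make_toy_gb(seed=1)


@pytest.fixture(scope="session")
def digb_scene(toy_gb):
    return assemble_digb(toy_gb, intra_angle=85.0, c12_separation=6.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
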