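"""Nanobody framework annotation and Gembody substitution design.

Nanobodies (VHH single-domain antibodies) share a highly conserved
beta-sandwich framework; only the three CDR loops vary substantially in
length.  This module maps an arbitrary nanobody sequence onto IMGT positions
by global alignment against an embedded, IMGT-pre-numbered VHH consensus
framework (``data/vhh_reference.tsv``).  Framework positions — all that the
Gembody design scheme requires — transfer exactly through aligned columns;
numbering of residues inside CDR loops of non-reference length is
approximate (insertion-coded) and documented as such.

The Gembody ("Gb") substitution sets turn a plain nanobody into a dimerizable
module: the core set S7N;L12C;Q14K;T125M installs the reactive cysteine at
IMGT position 12 plus the residues that predispose the nanobody-to-nanobody
interface.  Named variant sets used for particular scaffolds are shipped as
data.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, NamedTuple

import gemmi
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import DesignError, NotANanobodyError
from .structure_io import AtomRecord, AtomSet

#: IMGT CDR spans (inclusive) for the V domain.
CDR_SPANS: tuple[tuple[int, int], ...] = ((27, 38), (56, 65), (105, 117))

_VALID_AA = set("ACDEFGHIKLMNPQRSTVWYX")


class ImgtPos(NamedTuple):
    """An IMGT position; ``ins`` is an insertion letter for CDR insertions."""

    number: int
    ins: str = ""

    def __str__(self) -> str:  # e.g. "12" or "111A"
        return f"{self.number}{self.ins}"


def is_cdr_position(pos: int | ImgtPos) -> bool:
    num = pos.number if isinstance(pos, ImgtPos) else pos
    return any(lo <= num <= hi for lo, hi in CDR_SPANS)


# ---------------------------------------------------------------------------
# embedded reference

@functools.lru_cache(maxsize=1)
def _load_reference() -> tuple[tuple[ImgtPos, ...], str]:
    """(imgt positions, sequence) of the embedded VHH framework reference."""
    text = (resources.files("digembody") / "data" / "vhh_reference.tsv") \
        .read_text()
    positions: list[ImgtPos] = []
    seq: list[str] = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pos, _region, aa = line.split("\t")
        positions.append(ImgtPos(int(pos)))
        seq.append(aa)
    return tuple(positions), "".join(seq)


def reference_sequence() -> str:
    return _load_reference()[1]


def reference_positions() -> tuple[ImgtPos, ...]:
    return _load_reference()[0]


# ---------------------------------------------------------------------------
# framework map

@dataclass
class FrameworkMap:
    """Bidirectional map between a query sequence and IMGT positions."""

    query_sequence: str
    index_to_imgt: dict[int, ImgtPos]
    cdr_spans: tuple[tuple[int, int], ...]
    framework_identity: float
    imgt_to_index: dict[ImgtPos, int] = field(init=False)

    def __post_init__(self) -> None:
        self.imgt_to_index = {p: i for i, p in self.index_to_imgt.items()}

    def index_of(self, pos: int | ImgtPos) -> int | None:
        if isinstance(pos, int):
            pos = ImgtPos(pos)
        return self.imgt_to_index.get(pos)

    def residue_at(self, pos: int | ImgtPos) -> str | None:
        i = self.index_of(pos)
        return None if i is None else self.query_sequence[i]

    def framework_items(self) -> list[tuple[ImgtPos, int]]:
        """(imgt, query index) pairs outside the CDR spans, in IMGT order."""
        items = [(p, i) for i, p in self.index_to_imgt.items()
                 if not is_cdr_position(p)]
        items.sort(key=lambda t: (t[0].number, t[0].ins))
        return items


def _make_aligner(open_gap: float = -10.0, extend_gap: float = -1.0
                  ) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    # terminal overhangs are free: queries may start/end off-reference
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    return aligner


def align_to_reference(query: str, open_gap: float = -10.0,
                       extend_gap: float = -1.0,
                       min_framework_identity: float = 0.5) -> FrameworkMap:
    """Number a nanobody sequence by alignment to the embedded VHH reference.

    Parameters
    ----------
    query:
        Amino-acid sequence (one-letter codes, X allowed), length 90-160.
    open_gap, extend_gap:
        Affine gap scores for the BLOSUM62 global alignment.  Framework
        regions are conserved enough that the mapping is insensitive to the
        exact values.
    min_framework_identity:
        Below this fraction of identical framework columns the query is
        rejected as not a nanobody.

    Raises
    ------
    ValueError
        on non-amino-acid characters or out-of-range length.
    NotANanobodyError
        if framework identity falls below ``min_framework_identity``.
    """
    query = query.strip().upper()
    bad = set(query) - _VALID_AA
    if bad:
        raise ValueError(f"non-amino-acid characters in query: {sorted(bad)}")
    if not 90 <= len(query) <= 160:
        raise ValueError(
            f"query length {len(query)} outside the nanobody range 90-160")

    ref_pos, ref_seq = _load_reference()
    aligner = _make_aligner(open_gap, extend_gap)
    alignment = aligner.align(ref_seq, query)[0]
    ref_blocks, query_blocks = alignment.aligned

    ref_to_q: dict[int, int] = {}
    index_to_imgt: dict[int, ImgtPos] = {}
    prev_q_end = 0
    prev_imgt: ImgtPos | None = None
    for (t0, t1), (q0, q1) in zip(ref_blocks, query_blocks):
        # query residues between blocks: insertions relative to the reference
        _assign_insertions(index_to_imgt, prev_q_end, q0, prev_imgt,
                           ref_pos[t0] if t0 < len(ref_pos) else None)
        for k in range(t1 - t0):
            ref_to_q[t0 + k] = q0 + k
            index_to_imgt[q0 + k] = ref_pos[t0 + k]
        prev_q_end = q1
        prev_imgt = ref_pos[t1 - 1]
    # trailing query overhang stays unmapped

    n_fw = matches = 0
    for i, pos in enumerate(ref_pos):
        if is_cdr_position(pos):
            continue
        n_fw += 1
        j = ref_to_q.get(i)
        if j is not None and query[j] == ref_seq[i]:
            matches += 1
    identity = matches / n_fw
    if identity < min_framework_identity:
        raise NotANanobodyError(
            f"framework identity {identity:.2f} below "
            f"{min_framework_identity:.2f}; query does not look like a "
            "nanobody VHH domain")
    return FrameworkMap(query, index_to_imgt, CDR_SPANS, identity)


def _assign_insertions(index_to_imgt: dict[int, ImgtPos], q_start: int,
                       q_end: int, prev_imgt: ImgtPos | None,
                       next_imgt: ImgtPos | None) -> None:
    """Insertion-code query residues that fall between aligned blocks.

    Only insertions flanked by a CDR span receive codes (letters appended to
    the preceding numbered position, 111A-style); framework insertions and
    terminal overhangs stay unmapped.
    """
    if q_start >= q_end or prev_imgt is None:
        return
    in_cdr = is_cdr_position(prev_imgt) or (
        next_imgt is not None and is_cdr_position(next_imgt))
    if not in_cdr:
        return
    for n, j in enumerate(range(q_start, q_end)):
        # wraps to AA, AB... beyond 26 insertions, which IMGT never reaches
        code = chr(ord("A") + n % 26) * (1 + n // 26)
        index_to_imgt[j] = ImgtPos(prev_imgt.number, code)


# ---------------------------------------------------------------------------
# structure-linked annotation

@dataclass
class ChainAnnotation:
    """A chain's atoms plus its FrameworkMap and per-residue author ids."""

    chain_id: str
    atoms: AtomSet                       # the chain's atoms only
    fmap: FrameworkMap
    residue_keys: list[tuple[int, str]]  # (author number, icode) per seq index

    def ca_record(self, pos: int | ImgtPos) -> AtomRecord | None:
        i = self.fmap.index_of(pos)
        if i is None:
            return None
        num, icode = self.residue_keys[i]
        return self.atoms.find_atom(self.chain_id, num, "CA", icode)

    def residue_atoms(self, pos: int | ImgtPos) -> AtomSet | None:
        i = self.fmap.index_of(pos)
        if i is None:
            return None
        num, icode = self.residue_keys[i]
        return self.atoms.subset([
            r.residue_number == num and r.insertion_code == icode
            for r in self.atoms])


def chain_sequence(atoms: AtomSet, chain_id: str
                   ) -> tuple[str, list[tuple[int, str]]]:
    """One-letter sequence of the CA-bearing amino-acid residues of a chain."""
    chain = atoms.chain(chain_id)
    seq: list[str] = []
    keys: list[tuple[int, str]] = []
    for (cid, num, icode, name), res in chain.residues():
        info = gemmi.find_tabulated_residue(name)
        if info is None or not info.is_amino_acid():
            continue
        if res.find_atom(cid, num, "CA", icode) is None:
            continue
        one = info.one_letter_code.upper()
        seq.append(one if one.isalpha() else "X")
        keys.append((num, icode))
    return "".join(seq), keys


def annotate_chain(atoms: AtomSet, chain_id: str, **align_kwargs
                   ) -> ChainAnnotation:
    """Build a ChainAnnotation for one chain of a structure."""
    seq, keys = chain_sequence(atoms, chain_id)
    if not seq:
        raise NotANanobodyError(f"chain {chain_id!r}: no amino-acid residues")
    fmap = align_to_reference(seq, **align_kwargs)
    return ChainAnnotation(chain_id, atoms.chain(chain_id), fmap, keys)


def detect_nanobody_chains(atoms: AtomSet, exclude: Iterable[str] = ()
                           ) -> dict[str, ChainAnnotation]:
    """Annotate every chain that aligns to the VHH reference.

    Returns successfully annotated chains keyed by chain id, ordered by
    decreasing framework identity.  Chains that fail annotation (targets,
    non-protein chains) are silently omitted.
    """
    out: dict[str, ChainAnnotation] = {}
    for cid in atoms.chain_ids():
        if cid in exclude:
            continue
        try:
            out[cid] = annotate_chain(atoms, cid)
        except (ValueError, NotANanobodyError):
            continue
    return dict(sorted(out.items(),
                       key=lambda kv: -kv[1].fmap.framework_identity))


# ---------------------------------------------------------------------------
# substitution design

#: Named Gembody substitution sets: (imgt position, wild type, replacement).
#: "core" is the minimal set that enables covalent dimerization at C12.
VARIANT_SETS: dict[str, tuple[tuple[int, str, str], ...]] = {
    "core": ((7, "S", "N"), (12, "L", "C"), (14, "Q", "K"), (125, "T", "M")),
    "Gb5-006": ((7, "S", "N"), (12, "L", "C"), (14, "Q", "K"),
                (40, "G", "T"), (49, "Q", "E"), (52, "L", "W"),
                (84, "K", "E"), (101, "I", "V"), (125, "T", "M")),
    "GbD12": ((7, "S", "N"), (12, "L", "C"), (14, "Q", "K"),
              (84, "K", "E"), (123, "P", "Q"), (125, "T", "M")),
    "GbS2A4": ((5, "Q", "V"), (7, "S", "N"), (12, "L", "C"), (14, "Q", "K"),
               (44, "Q", "R"), (125, "T", "M")),
    "GbH12": ((2, "L", "V"), (7, "S", "N"), (12, "L", "C"), (14, "Q", "K"),
              (84, "K", "E"), (123, "P", "Q"), (125, "T", "M")),
    "GbRBD3": ((7, "S", "N"), (12, "L", "C"), (14, "Q", "K"),
               (84, "K", "E"), (125, "T", "M")),
    "GbC4": ((2, "L", "G"), (7, "S", "N"), (12, "L", "C"), (14, "Q", "K"),
             (125, "T", "M")),
    "Gb113": ((7, "S", "N"), (12, "L", "C"), (14, "Q", "K"), (125, "T", "M")),
}


@dataclass(frozen=True)
class Substitution:
    imgt_position: int
    wild_type: str       # expected wild-type residue of the set definition
    found: str           # residue actually present in the query
    replacement: str
    status: str          # "apply" | "already_present" | "wt_mismatch"

    def __str__(self) -> str:
        return f"{self.found}{self.imgt_position}{self.replacement}"


@dataclass
class MutationSpec:
    """A substitution set instantiated against one query sequence."""

    label: str
    entries: list[Substitution]
    mutant_sequence: str

    @property
    def applied(self) -> list[Substitution]:
        return [e for e in self.entries if e.status != "already_present"]

    @property
    def already_present(self) -> list[Substitution]:
        return [e for e in self.entries if e.status == "already_present"]

    def as_tsv(self) -> str:
        lines = ["imgt_position\twild_type\tfound\treplacement\tstatus"]
        for e in self.entries:
            lines.append(f"{e.imgt_position}\t{e.wild_type}\t{e.found}\t"
                         f"{e.replacement}\t{e.status}")
        return "\n".join(lines) + "\n"


def design_gb_substitutions(fmap: FrameworkMap,
                            variant: str = "core",
                            custom: Iterable[tuple[int, str, str]] | None = None
                            ) -> MutationSpec:
    """Instantiate a Gembody substitution set against an annotated query.

    Positions already bearing the replacement residue are omitted from the
    applied list and reported as ``already_present`` (this makes the design
    idempotent).  A residue that matches neither the expected wild type nor
    the replacement is still substituted but flagged ``wt_mismatch``.

    Raises
    ------
    DesignError
        if the set references an IMGT position absent from the map.
    """
    if custom is not None:
        subs, label = tuple(custom), variant or "custom"
    else:
        try:
            subs, label = VARIANT_SETS[variant], variant
        except KeyError:
            raise DesignError(
                f"unknown variant {variant!r}; known: "
                f"{', '.join(VARIANT_SETS)}") from None
    seen: set[int] = set()
    entries: list[Substitution] = []
    seq = list(fmap.query_sequence)
    for pos, wt, new in sorted(subs):
        if pos in seen:
            raise DesignError(f"duplicate IMGT position {pos} in set {label!r}")
        seen.add(pos)
        idx = fmap.index_of(pos)
        if idx is None:
            raise DesignError(
                f"IMGT position {pos} not present in the query map; "
                f"cannot design {label!r}")
        found = fmap.query_sequence[idx]
        if found == new:
            status = "already_present"
        elif found == wt:
            status = "apply"
        else:
            status = "wt_mismatch"
        if status != "already_present":
            seq[idx] = new
        entries.append(Substitution(pos, wt, found, new, status))
    return MutationSpec(label, entries, "".join(seq))


# ---------------------------------------------------------------------------
# conservation advisories

#: Expected identities at interface-critical framework positions.  These are
#: the positions that form the predisposed Gb-Gb interface; residue 12 is
#: leucine in most nanobodies but serine in roughly 30% of them.
_EXPECTED_INTERFACE = {
    7: ("S",), 12: ("L",), 14: ("Q",),
    120: ("Q",), 123: ("Q",), 125: ("T",),
}


@dataclass(frozen=True)
class Advisory:
    imgt_position: int
    found: str | None
    expected: tuple[str, ...]
    level: str   # "info" | "warning"
    message: str


def check_interface_conservation(fmap: FrameworkMap) -> list[Advisory]:
    """Advisory (never fatal) check of the interface-critical positions.

    Deviations at 120/123 have been observed to shift the dimer interface;
    serine at 12 is a common natural variant and only noted.
    """
    advisories: list[Advisory] = []
    for pos, expected in sorted(_EXPECTED_INTERFACE.items()):
        found = fmap.residue_at(pos)
        if found is None:
            advisories.append(Advisory(
                pos, None, expected, "warning",
                f"IMGT {pos} is not covered by the query map"))
            continue
        if found in expected:
            continue
        if pos == 12 and found == "S":
            level, note = "info", "serine at 12 is a common natural variant"
        elif pos in (120, 123):
            level = "warning"
            note = (f"non-canonical residue at interface position {pos}; "
                    "may shift the dimer interface geometry")
        else:
            level = "warning"
            note = f"non-canonical residue at interface position {pos}"
        advisories.append(Advisory(
            pos, found, expected, level,
            f"IMGT {pos}: found {found}, expected "
            f"{'/'.join(expected)} — {note}"))
    return advisories
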