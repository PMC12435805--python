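"""Applicability screening of target:nanobody complexes on DiGb scaffolds.

A DiGb displays two nanobody (Gembody) copies at a fixed inter-domain
geometry.  Whether an existing target:nanobody complex is compatible with a
given scaffold is estimated purely sterically: two copies of the complex are
superposed, via their nanobody framework C-alphas, onto the scaffold's two
Gb chains, and every target heavy atom lying within a 4 A sphere of any
heavy atom of the *other* placed copy is scored as clashed.

The clash score normalizes the clashed-atom count by the total number of
target heavy atoms across both copies ("maximal clash" = every target atom
clashing); complexes divide into no-clash, under-5%-of-maximal, and above.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .annotation import ChainAnnotation, annotate_chain, detect_nanobody_chains
from .errors import DigembodyError, SurveyError
from .structure_io import AtomSet, select_atoms
from .superpose import RigidTransform, apply_transform, superpose_chains

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 4.0      # A, the clash sphere radius
DEFAULT_THRESHOLD = 0.05  # fraction of maximal clash


def count_clash_atoms(probe: AtomSet, environment: AtomSet,
                      cutoff: float = DEFAULT_CUTOFF) -> int:
    """Number of probe atoms with >= 1 environment atom within ``cutoff`` A.

    The boundary is inclusive: an atom pair at exactly ``cutoff`` counts.
    Uses a k-d tree; the result is identical to all-pairs counting.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if len(probe) == 0 or len(environment) == 0:
        raise ValueError("probe and environment must be nonempty")
    tree = cKDTree(environment.coords)
    # count_neighbors semantics differ; query the nearest distance per probe
    dist, _ = tree.query(probe.coords, k=1)
    return int(np.count_nonzero(dist <= cutoff))


@dataclass(frozen=True)
class ClashReport:
    """Clash counts and classification for one complex on one scaffold."""

    n_clash: int
    n_total: int
    cutoff: float
    threshold: float = DEFAULT_THRESHOLD
    placement_rmsds: tuple[float, float] = (float("nan"), float("nan"))

    @property
    def score(self) -> float:
        return self.n_clash / self.n_total

    @property
    def classification(self) -> str:
        if self.n_clash == 0:
            return "no_clash"
        if self.score < self.threshold:
            return "under_5pct"
        return "over_5pct"


def _target_and_environment(complex_atoms: AtomSet, nb_chain: str
                            ) -> tuple[AtomSet, AtomSet]:
    """Heavy polymer atoms split into target chains and the whole copy."""
    heavy = select_atoms(complex_atoms, heavy_only=True, polymer_only=True)
    target = heavy.subset([r.chain_id != nb_chain for r in heavy])
    return target, heavy


def screen_on_scaffold(complex_atoms: AtomSet, scaffold_atoms: AtomSet,
                       nb_chain: str | None = None,
                       gb_chains: tuple[str, str] | None = None,
                       cutoff: float = DEFAULT_CUTOFF,
                       threshold: float = DEFAULT_THRESHOLD) -> ClashReport:
    """Screen one target:nanobody complex against a two-Gb scaffold.

    Copy A of the complex is superposed via its nanobody framework onto the
    first Gb chain, copy B onto the second; target heavy atoms of each copy
    within ``cutoff`` A of any heavy atom of the other copy are counted as
    clashed.  Waters, non-polymer heteroatoms, and hydrogens are excluded
    from both probe and environment.

    ``nb_chain``/``gb_chains`` override the automatic detection (the chain
    with the highest VHH framework identity, resp. the two best-scoring
    scaffold chains).
    """
    if nb_chain is None:
        candidates = detect_nanobody_chains(complex_atoms)
        if not candidates:
            raise DigembodyError("no annotatable nanobody chain in complex")
        nb_chain, nb_ann = next(iter(candidates.items()))
    else:
        nb_ann = annotate_chain(complex_atoms, nb_chain)
    target_chains = [c for c in complex_atoms.chain_ids() if c != nb_chain]
    if not target_chains:
        raise DigembodyError("complex has no target chain besides the nanobody")

    if gb_chains is None:
        gb_anns = detect_nanobody_chains(scaffold_atoms)
        if len(gb_anns) < 2:
            raise DigembodyError(
                f"scaffold must contain two annotatable Gb chains; "
                f"found {list(gb_anns)}")
        gb_pair = list(gb_anns.values())[:2]
        # keep the scaffold's own chain order deterministic
        gb_pair.sort(key=lambda a: scaffold_atoms.chain_ids().index(a.chain_id))
    else:
        gb_pair = [annotate_chain(scaffold_atoms, c) for c in gb_chains]

    placements: list[RigidTransform] = [
        superpose_chains(nb_ann, gb) for gb in gb_pair]
    target, whole = _target_and_environment(complex_atoms, nb_chain)
    if len(target) == 0:
        raise DigembodyError("no target heavy atoms to screen")

    placed_targets = [apply_transform(target, t) for t in placements]
    placed_wholes = [apply_transform(whole, t) for t in placements]
    n_a = count_clash_atoms(placed_targets[0], placed_wholes[1], cutoff)
    n_b = count_clash_atoms(placed_targets[1], placed_wholes[0], cutoff)
    return ClashReport(
        n_clash=n_a + n_b,
        n_total=2 * len(target),
        cutoff=cutoff,
        threshold=threshold,
        placement_rmsds=(placements[0].rmsd, placements[1].rmsd),
    )


@dataclass
class SurveySummary:
    """Aggregate of per-entry ClashReports over a complex library."""

    scaffold_id: str
    reports: dict[str, ClashReport]
    skipped: dict[str, str] = field(default_factory=dict)

    @property
    def n_screened(self) -> int:
        return len(self.reports)

    @property
    def fraction_no_clash(self) -> float:
        ok = sum(1 for r in self.reports.values()
                 if r.classification == "no_clash")
        return ok / self.n_screened

    @property
    def fraction_under_5pct(self) -> float:
        """Cumulative: includes the no-clash entries."""
        ok = sum(1 for r in self.reports.values()
                 if r.classification in ("no_clash", "under_5pct"))
        return ok / self.n_screened

    def as_tsv(self) -> str:
        lines = ["entry\tn_clash\tn_total\tscore\tclass\trmsd_a\trmsd_b"]
        for name, r in self.reports.items():
            lines.append(
                f"{name}\t{r.n_clash}\t{r.n_total}\t{r.score:.4f}\t"
                f"{r.classification}\t{r.placement_rmsds[0]:.3f}\t"
                f"{r.placement_rmsds[1]:.3f}")
        for name, reason in self.skipped.items():
            lines.append(f"{name}\tskipped: {reason}")
        lines.append(f"# scaffold: {self.scaffold_id}")
        lines.append(f"# fraction_no_clash: {self.fraction_no_clash:.3f}")
        lines.append(f"# fraction_under_5pct: {self.fraction_under_5pct:.3f}")
        return "\n".join(lines) + "\n"


def survey_library(entries: dict[str, AtomSet], scaffold_atoms: AtomSet,
                   scaffold_id: str = "scaffold",
                   cutoff: float = DEFAULT_CUTOFF,
                   threshold: float = DEFAULT_THRESHOLD,
                   nb_chains: dict[str, str] | None = None,
                   gb_chains: tuple[str, str] | None = None) -> SurveySummary:
    """Screen a library of complexes against one scaffold.

    Entries failing annotation or superposition are recorded as skipped with
    the failure reason; fractions are computed over the successes only.

    Raises
    ------
    SurveyError
        if no entry could be screened at all.
    """
    if not entries:
        raise SurveyError("empty library")
    reports: dict[str, ClashReport] = {}
    skipped: dict[str, str] = {}
    for name, atoms in entries.items():
        nb = (nb_chains or {}).get(name)
        try:
            reports[name] = screen_on_scaffold(
                atoms, scaffold_atoms, nb_chain=nb, gb_chains=gb_chains,
                cutoff=cutoff, threshold=threshold)
        except (DigembodyError, ValueError) as exc:
            logger.warning("survey: skipping %s: %s", name, exc)
            skipped[name] = str(exc)
    if not reports:
        raise SurveyError(
            f"no entry could be screened; reasons: {skipped}")
    return SurveySummary(scaffold_id, reports, skipped)
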