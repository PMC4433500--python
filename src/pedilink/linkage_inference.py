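"""Carrier status, marker-disease phase, and recombination detection.

Phase logic for a dominant disease allele linked to a biallelic marker:

* a carrier homozygous for the marker mutation must hold the disease
  allele on a mutant-marker chromosome (coupling, certain);
* a carrier with two wild-type marker alleles must hold it on a wild-type
  chromosome (repulsion, certain);
* a marker-heterozygous carrier is ambiguous on its own genotype, but if
  its carrier parent is marker-homozygous the transmitted marker allele is
  forced, so the parent's phase propagates (a crossover in a
  marker-homozygous parent swaps the disease allele between two identical
  marker alleles and is invisible, so the propagated phase cannot be
  broken by recombination in that meiosis).

A phase switch between a propagated-phase, marker-heterozygous parent and
a homozygosity-certain child pins a crossover to that single meiosis and
is graded ``certain``.  Switches across longer chains (untyped or
unresolvable heterozygous intermediates) cannot be localised and are
graded ``possible`` against the whole path.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional

from pedilink.assoc_stats import GenotypeCounts
from pedilink.descent_tracing import LineAssignment, RiskClass, TransmitterCall
from pedilink.pedigree_core import Affection, MarkerGenotype, Pedigree


class CarrierStatus(enum.Enum):
    OBLIGATE_CARRIER = "obligate_carrier"
    INFERRED_CARRIER = "inferred_carrier"
    CLEAR = "clear"
    UNKNOWN = "unknown"


@dataclass
class CarrierAssignment:
    """Per-dog disease-locus status with its evidential provenance."""

    status: dict[str, CarrierStatus] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def is_carrier(self, iid: str) -> bool:
        return self.status.get(iid) in (
            CarrierStatus.OBLIGATE_CARRIER,
            CarrierStatus.INFERRED_CARRIER,
        )

    def carriers(self) -> set[str]:
        return {i for i in self.status if self.is_carrier(i)}

    def to_dict(self) -> dict:
        return {
            i: {"status": s.value, "provenance": self.provenance.get(i, "")}
            for i, s in self.status.items()
        }


class Phase(enum.Enum):
    COUPLING = "coupling"
    REPULSION = "repulsion"
    AMBIGUOUS = "ambiguous"


class PhaseCertainty(enum.Enum):
    CERTAIN_BY_HOMOZYGOSITY = "certain_by_homozygosity"
    PROPAGATED = "propagated"
    NONE = "none"


@dataclass(frozen=True)
class PhaseCall:
    phase: Phase
    certainty: PhaseCertainty

    @property
    def is_resolved(self) -> bool:
        return self.phase is not Phase.AMBIGUOUS


@dataclass(frozen=True)
class RecombinationEvent:
    """A detected (or suspected) crossover between marker and disease loci.

    ``certain`` events are pinned to the single meiosis parent_id ->
    child_id; ``possible`` events name the endpoints of the unresolvable
    path, listed in ``path`` from ancestor to descendant.
    """

    parent_id: str
    child_id: str
    parent_phase: PhaseCall
    child_phase: PhaseCall
    grade: str  # "certain" | "possible"
    path: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "parent": self.parent_id,
            "child": self.child_id,
            "parent_phase": self.parent_phase.phase.value,
            "child_phase": self.child_phase.phase.value,
            "grade": self.grade,
            "path": list(self.path),
        }


def assign_carriers(
    ped: Pedigree,
    risk: RiskClass,
    transmitters: Iterable[TransmitterCall],
    bridges: Iterable[str] = (),
) -> CarrierAssignment:
    """affected -> obligate; transmitters/bridges -> inferred; clear-by-pedigree
    -> clear; everyone else unknown.  The marker genotype never vetoes carrier
    status (affected dogs may be HOM, HET or WT)."""
    ca = CarrierAssignment()
    tids = {t.id for t in transmitters if t.is_transmitter}
    bridge_set = set(bridges)
    for iid in ped.ids():
        if ped[iid].is_affected:
            ca.status[iid] = CarrierStatus.OBLIGATE_CARRIER
            ca.provenance[iid] = "affected"
        elif iid in tids:
            ca.status[iid] = CarrierStatus.INFERRED_CARRIER
            ca.provenance[iid] = "transmitter"
        elif iid in bridge_set:
            ca.status[iid] = CarrierStatus.INFERRED_CARRIER
            ca.provenance[iid] = "bridge"
        elif risk.is_clear(iid):
            ca.status[iid] = CarrierStatus.CLEAR
            ca.provenance[iid] = "clear_by_pedigree"
        else:
            ca.status[iid] = CarrierStatus.UNKNOWN
            ca.provenance[iid] = ""
    return ca


def _own_genotype_phase(geno: MarkerGenotype) -> PhaseCall:
    if geno is MarkerGenotype.HOM:
        return PhaseCall(Phase.COUPLING, PhaseCertainty.CERTAIN_BY_HOMOZYGOSITY)
    if geno is MarkerGenotype.WT:
        return PhaseCall(Phase.REPULSION, PhaseCertainty.CERTAIN_BY_HOMOZYGOSITY)
    return PhaseCall(Phase.AMBIGUOUS, PhaseCertainty.NONE)


def assign_phase(
    ped: Pedigree, carriers: CarrierAssignment
) -> dict[str, PhaseCall]:
    """Phase every carrier: homozygosity rule first, then forced-transmission
    propagation from marker-homozygous carrier parents to marker-heterozygous
    carrier children.  Propagation never overwrites a homozygosity call."""
    phases: dict[str, PhaseCall] = {}
    carrier_set = carriers.carriers()
    for iid in carrier_set:
        phases[iid] = _own_genotype_phase(ped[iid].marker_genotype)

    links_by_child: dict[str, str] = {
        c: p for p, c in _carrier_parent_links(ped, carrier_set)
    }
    for iid in carrier_set:
        call = phases[iid]
        if call.certainty is PhaseCertainty.CERTAIN_BY_HOMOZYGOSITY:
            continue
        if ped[iid].marker_genotype is not MarkerGenotype.HET:
            continue  # untyped dogs stay ambiguous
        pid = links_by_child.get(iid)
        if pid is None:
            continue
        pcall = phases[pid]
        if (pcall.certainty is PhaseCertainty.CERTAIN_BY_HOMOZYGOSITY
                and ped[pid].marker_genotype.is_homozygous):
            phases[iid] = PhaseCall(pcall.phase, PhaseCertainty.PROPAGATED)

    # the homozygosity rule must never be contradicted
    for iid, call in phases.items():
        geno = ped[iid].marker_genotype
        if geno is MarkerGenotype.HOM:
            assert call.phase is Phase.COUPLING
        elif geno is MarkerGenotype.WT:
            assert call.phase is Phase.REPULSION
    return phases


def _carrier_parent_links(
    ped: Pedigree, carrier_set: set[str]
) -> list[tuple[str, str]]:
    """Parent->child meioses along which the disease allele must have
    travelled.  When both parents are carriers the transmitting side is
    ambiguous (and a disease homozygote possible), so neither link is used."""
    links = []
    for child in carrier_set:
        parents = [p for p in ped.parents_of(child) if p is not None]
        carrier_parents = [p for p in parents if p in carrier_set]
        if len(carrier_parents) == 1:
            links.append((carrier_parents[0], child))
    return links


def detect_recombination(
    ped: Pedigree, phases: dict[str, PhaseCall]
) -> list[RecombinationEvent]:
    """Emit recombination events from phase switches along carrier chains.

    Certain events (single-meiosis):
      * a forced-phase (propagated), marker-heterozygous carrier parent
        whose homozygosity-certain carrier child shows the opposite phase —
        the crossover can only have happened in that parent's meiosis;
      * two homozygosity-certain calls that differ across one direct meiosis
        (only possible with inconsistent genotype data, but reported rather
        than suppressed).

    Possible events: any other phase switch between resolved calls on a
    carrier parent path; reported against the whole path.
    """
    carrier_set = set(phases)
    events: list[RecombinationEvent] = []
    links = _carrier_parent_links(ped, carrier_set)
    children_by_parent: dict[str, list[str]] = {}
    for pid, cid in links:
        children_by_parent.setdefault(pid, []).append(cid)

    # direct parent -> child meioses
    for pid, cid in links:
        pcall, ccall = phases[pid], phases[cid]
        if not (pcall.is_resolved and ccall.is_resolved):
            continue
        if pcall.phase is ccall.phase:
            continue
        both_certain = (
            pcall.certainty is PhaseCertainty.CERTAIN_BY_HOMOZYGOSITY
            and ccall.certainty is PhaseCertainty.CERTAIN_BY_HOMOZYGOSITY
        )
        forced_het_parent = (
            pcall.certainty is PhaseCertainty.PROPAGATED
            and ped[pid].marker_genotype is MarkerGenotype.HET
            and ccall.certainty is PhaseCertainty.CERTAIN_BY_HOMOZYGOSITY
        )
        grade = "certain" if (both_certain or forced_het_parent) else "possible"
        events.append(
            RecombinationEvent(
                parent_id=pid,
                child_id=cid,
                parent_phase=pcall,
                child_phase=ccall,
                grade=grade,
                path=(pid, cid),
            )
        )

    # multi-meiosis paths between resolved calls through unresolved carriers
    for top in carrier_set:
        if not phases[top].is_resolved:
            continue
        stack: list[list[str]] = [[top]]
        while stack:
            path = stack.pop()
            cur = path[-1]
            for child in children_by_parent.get(cur, ()):
                if phases[child].is_resolved:
                    if len(path) >= 2:  # >=1 unresolved intermediate
                        if phases[child].phase is not phases[top].phase:
                            events.append(
                                RecombinationEvent(
                                    parent_id=top,
                                    child_id=child,
                                    parent_phase=phases[top],
                                    child_phase=phases[child],
                                    grade="possible",
                                    path=tuple(path) + (child,),
                                )
                            )
                else:
                    stack.append(path + [child])
    return events


def informative_meioses(
    ped: Pedigree, phases: dict[str, PhaseCall]
) -> list[tuple[str, str]]:
    """Meioses where recombination is detectable with certainty: carrier
    parent marker-heterozygous with a resolved (forced) phase, carrier child
    marker-homozygous."""
    out = []
    for pid, cid in _carrier_parent_links(ped, set(phases)):
        if (ped[pid].marker_genotype is MarkerGenotype.HET
                and phases[pid].is_resolved
                and ped[cid].marker_genotype.is_homozygous):
            out.append((pid, cid))
    return out


def genotype_tables_by_group(
    ped: Pedigree,
    lines: LineAssignment,
    risk: RiskClass,
    extra_groups: Optional[dict[str, Iterable[str]]] = None,
) -> dict[str, GenotypeCounts]:
    """Per-group HOM/HET/WT counts over typed dogs.

    Automatic groups: one ``<line>_cases`` row per line (affected dogs whose
    membership is exactly that line), a ``mixed_cases`` row for affected
    dogs belonging to several lines, and ``normal_by_pedigree`` (unaffected,
    clear by pedigree).  ``extra_groups`` adds user-defined rosters (e.g. an
    externally sampled cohort); their members are excluded from the
    automatic groups.  Untyped dogs are always excluded from counts.
    """
    extra_groups = {k: set(v) for k, v in (extra_groups or {}).items()}
    reserved: set[str] = set().union(*extra_groups.values()) if extra_groups else set()

    def counts_for(ids: Iterable[str]) -> GenotypeCounts:
        hom = het = wt = 0
        for iid in ids:
            g = ped[iid].marker_genotype
            if g is MarkerGenotype.HOM:
                hom += 1
            elif g is MarkerGenotype.HET:
                het += 1
            elif g is MarkerGenotype.WT:
                wt += 1
        return GenotypeCounts(hom=hom, het=het, wt=wt)

    tables: dict[str, GenotypeCounts] = {}
    line_labels = sorted(lines.sources)
    for label in line_labels:
        ids = [
            i for i in ped.ids()
            if i not in reserved
            and ped[i].is_affected
            and lines.membership.get(i) == frozenset({label})
        ]
        tables[f"{label}_cases"] = counts_for(ids)
    mixed = [
        i for i in ped.ids()
        if i not in reserved
        and ped[i].is_affected
        and len(lines.membership.get(i, frozenset())) > 1
    ]
    if mixed:
        tables["mixed_cases"] = counts_for(mixed)
    normals = [
        i for i in ped.ids()
        if i not in reserved
        and risk.is_clear(i)
        and ped[i].affection is Affection.UNAFFECTED
    ]
    tables["normal_by_pedigree"] = counts_for(normals)
    for name in sorted(extra_groups):
        tables[name] = counts_for(extra_groups[name])
    return tables
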