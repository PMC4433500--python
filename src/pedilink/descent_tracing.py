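"""Transmitter identification, line-of-descent tracing and risk classification.

Under a dominant model, an affected dog proves it carries the disease
allele, and so does an unaffected dog that has produced affected offspring
with several different mates (one-litter coincidences are excluded by the
mate-count threshold).  Tracing those proven carriers upward through the
pedigree groups them into lines of descent, each anchored on one or more
source dogs with no transmitting ancestor of their own; everything outside
the sources' descendant closures is clear by pedigree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from pedilink.pedigree_core import Pedigree, Sex


@dataclass(frozen=True)
class TransmitterCall:
    """Carrier-by-production verdict for one dog.

    basis:
      * ``affected_self`` — the dog is itself affected (proven carrier).
      * ``multi_mate_producer`` — affected offspring with >= min_mates
        distinct co-parents.
      * ``single_mate_producer`` — affected offspring but only one mate;
        not a transmitter on its own (could be the other parent's allele).
    """

    id: str
    n_affected_offspring: int
    n_distinct_mates_with_affected: int
    is_transmitter: bool
    basis: str


@dataclass
class LineAssignment:
    """Lines of descent: label -> source ids, and per-dog label membership.

    ``bridges`` are non-transmitter dogs lying on a parent path between two
    transmitters — carriers by inference (generation skipping).
    """

    sources: dict[str, frozenset[str]] = field(default_factory=dict)
    membership: dict[str, frozenset[str]] = field(default_factory=dict)
    bridges: frozenset[str] = frozenset()

    def all_sources(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.sources.values():
            out |= s
        return frozenset(out)

    def to_dict(self) -> dict:
        return {
            "sources": {k: sorted(v) for k, v in self.sources.items()},
            "membership": {
                k: sorted(v) for k, v in self.membership.items() if v
            },
            "bridges": sorted(self.bridges),
        }


@dataclass
class RiskClass:
    """Per-dog label: ``at_risk`` or ``clear_by_pedigree``.

    Affected dogs classified clear are data inconsistencies; they stay
    clear but are reported in ``warnings``.
    """

    labels: dict[str, str] = field(default_factory=dict)
    warnings: list[tuple[str, str, str]] = field(default_factory=list)

    def is_clear(self, iid: str) -> bool:
        return self.labels.get(iid) == "clear_by_pedigree"

    def is_at_risk(self, iid: str) -> bool:
        return self.labels.get(iid) == "at_risk"

    def to_dict(self) -> dict:
        return {
            "labels": dict(self.labels),
            "warnings": [
                {"code": c, "id": i, "message": m} for c, i, m in self.warnings
            ],
        }


def identify_transmitters(ped: Pedigree, min_mates: int = 2) -> list[TransmitterCall]:
    """One call per affected dog and per parent of >= 1 affected dog.

    Mate counting is over distinct co-parents on affected offspring; a
    missing co-parent counts as one anonymous mate per affected offspring's
    missing side (conservative: cannot be pooled with any named mate).
    """
    if min_mates < 2:
        raise ValueError("min_mates must be >= 2")
    affected = [i for i in ped.ids() if ped[i].is_affected]
    mates: dict[str, set[str]] = {}
    n_aff_off: dict[str, int] = {}
    for child in affected:
        sire, dam = ped.parents_of(child)
        for pid, co in ((sire, dam), (dam, sire)):
            if pid is None:
                continue
            n_aff_off[pid] = n_aff_off.get(pid, 0) + 1
            mates.setdefault(pid, set()).add(
                co if co is not None else f"__anon_mate_of_{child}"
            )

    calls: list[TransmitterCall] = []
    seen: set[str] = set()
    for iid in ped.ids():
        is_aff = ped[iid].is_affected
        n_off = n_aff_off.get(iid, 0)
        n_mates = len(mates.get(iid, ()))
        if not is_aff and n_off == 0:
            continue
        if is_aff:
            basis = "affected_self"
            is_tr = True
        elif n_mates >= min_mates:
            basis = "multi_mate_producer"
            is_tr = True
        else:
            basis = "single_mate_producer"
            is_tr = False
        calls.append(
            TransmitterCall(
                id=iid,
                n_affected_offspring=n_off,
                n_distinct_mates_with_affected=n_mates,
                is_transmitter=is_tr,
                basis=basis,
            )
        )
        seen.add(iid)
    return calls


def _transmitter_ids(transmitters: Iterable[TransmitterCall]) -> set[str]:
    return {t.id for t in transmitters if t.is_transmitter}


def trace_to_sources(
    ped: Pedigree, transmitters: Iterable[TransmitterCall]
) -> LineAssignment:
    """Group transmitters into lines of descent anchored on source dogs.

    Each transmitter is traced upward to its sources: the flagged import
    ancestors when any exist (the allele is presumed to have entered with
    the imports, whose own foreign ancestry is not traced), otherwise its
    maximal transmitting ancestors (transmitters with no transmitting
    ancestor of their own).  Lines are the connected components of the
    graph linking transmitters to their transmitting ancestors and
    sources, labelled ``line1``, ``line2``, ... in order of their
    lexicographically smallest source id.  Per-dog membership is the set
    of lines whose sources appear in the dog's ancestor closure (or are
    the dog itself).
    """
    tset = _transmitter_ids(transmitters)
    anc: dict[str, set[str]] = {t: ped.ancestors(t) for t in tset}

    # per-transmitter source candidates: flagged import ancestors when any
    # exist (tracing truncates at imports), otherwise the maximal
    # transmitting ancestors (no transmitting ancestor of their own)
    src_of: dict[str, set[str]] = {}
    for t in tset:
        imports = {
            a for a in (anc[t] | {t}) if ped[a].is_import
        }
        if imports:
            src_of[t] = imports
            continue
        chain = (anc[t] & tset) | {t}
        src_of[t] = {a for a in chain if not (ped.ancestors(a) & tset)}

    # lines = connected components of transmitters linked to their
    # transmitting ancestors and their sources
    nodes = set(tset)
    for t in tset:
        nodes |= src_of[t]
    parent_uf: dict[str, str] = {n: n for n in nodes}

    def find(x: str) -> str:
        while parent_uf[x] != x:
            parent_uf[x] = parent_uf[parent_uf[x]]
            x = parent_uf[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent_uf[ra] = rb

    for t in tset:
        for s in src_of[t]:
            union(t, s)
        if not ped[t].is_import:
            for a in anc[t] & tset:
                union(t, a)

    comps: dict[str, set[str]] = {}
    for n in nodes:
        comps.setdefault(find(n), set()).add(n)

    all_source_ids = set().union(*src_of.values()) if src_of else set()
    line_source_sets = [
        frozenset(comp & all_source_ids)
        for comp in comps.values()
        if comp & all_source_ids
    ]
    line_source_sets.sort(key=lambda s: min(s))
    labelled = {f"line{k + 1}": s for k, s in enumerate(line_source_sets)}

    membership: dict[str, frozenset[str]] = {}
    src_desc: dict[str, set[str]] = {}
    for label, srcs in labelled.items():
        covered: set[str] = set(srcs)
        for s in srcs:
            covered |= ped.descendants(s)
        src_desc[label] = covered
    for iid in ped.ids():
        labels = frozenset(
            lab for lab, covered in src_desc.items() if iid in covered
        )
        membership[iid] = labels

    # bridge dogs: unaffected non-transmitters carrying the allele through a
    # skipped generation.  Conservative rule: x must lie below a transmitter
    # AND have a carrier child whose other parental side is clear (no line
    # membership), so the child's allele can only have come through x.
    bridges: set[str] = set()
    carrier_like = set(tset)
    changed = True
    while changed:
        changed = False
        for x in ped.ids():
            if x in carrier_like or ped[x].is_affected:
                continue
            if not (ped.ancestors(x) & tset):
                continue
            for c in ped.children_of(x):
                if c not in carrier_like:
                    continue
                sire, dam = ped.parents_of(c)
                other = dam if sire == x else sire
                if other is None or not membership.get(other):
                    bridges.add(x)
                    carrier_like.add(x)
                    changed = True
                    break

    return LineAssignment(
        sources=labelled, membership=membership, bridges=frozenset(bridges)
    )


def classify_risk(ped: Pedigree, assignment: LineAssignment) -> RiskClass:
    """at_risk = sources plus their descendant closure; rest clear_by_pedigree."""
    rc = RiskClass()
    for iid in ped.ids():
        at_risk = bool(assignment.membership.get(iid))
        rc.labels[iid] = "at_risk" if at_risk else "clear_by_pedigree"
        if not at_risk and ped[iid].is_affected:
            rc.warnings.append(
                ("W_AFFECTED_CLEAR", iid,
                 "affected dog has no traced source ancestor; "
                 "data inconsistency, left clear_by_pedigree")
            )
    return rc


def inheritance_mode_report(
    ped: Pedigree,
    assignment: LineAssignment,
    risk: Optional[RiskClass] = None,
) -> dict:
    """Descriptive evidence for the mode of inheritance.

    Counts affected dogs by how many parental sides are at risk (a dominant
    gene needs only one; both sides at risk is compatible with a recessive
    but also with inbreeding), tallies sexes among the affected, and counts
    affected dogs per litter.  A missing parent counts as a clear side.
    """
    if risk is None:
        risk = classify_risk(ped, assignment)
    single_side = both_sides = no_side = founder_affected = 0
    for iid in ped.ids():
        if not ped[iid].is_affected:
            continue
        sire, dam = ped.parents_of(iid)
        if sire is None and dam is None:
            founder_affected += 1
            continue
        sides = sum(
            1 for p in (sire, dam) if p is not None and risk.is_at_risk(p)
        )
        if sides == 0:
            no_side += 1
        elif sides == 1:
            single_side += 1
        else:
            both_sides += 1

    sex_counts = {s.value: 0 for s in Sex}
    for iid in ped.ids():
        if ped[iid].is_affected:
            sex_counts[ped[iid].sex.value] += 1
    n_affected = sum(sex_counts.values())

    per_litter: dict[str, int] = {}
    litters_with_case = 0
    litters_multi_case = 0
    for key, members in ped.litters().items():
        n_aff = sum(1 for m in members if ped[m].is_affected)
        label = f"{key[0] or '0'}x{key[1] or '0'}" + (
            f".{key[2]}" if key[2] else ""
        )
        per_litter[label] = n_aff
        if n_aff >= 1:
            litters_with_case += 1
        if n_aff >= 2:
            litters_multi_case += 1

    return {
        "n_affected": n_affected,
        "affected_single_at_risk_side": single_side,
        "affected_both_at_risk_sides": both_sides,
        "affected_no_at_risk_side": no_side,
        "affected_founders": founder_affected,
        "sex_counts_affected": sex_counts,
        "pct_male_affected": (
            100.0 * sex_counts["male"] / n_affected if n_affected else None
        ),
        "litters_with_at_least_one_case": litters_with_case,
        "litters_with_multiple_cases": litters_multi_case,
        "affected_per_litter": per_litter,
    }
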