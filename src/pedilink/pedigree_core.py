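"""Pedigree data model, PED/CSV I/O, validation and kinship arithmetic.

The on-disk dialect is PLINK-style PED (whitespace-delimited columns
``family id sire dam sex phenotype``; missing parent ``0``; sex 1=male,
2=female, 0=unknown; phenotype 1=unaffected, 2=affected, 0/-9=unknown)
plus a phenotype/genotype sidecar CSV with header
``id,affection,onset_age,severity,strn`` and optional ``litter`` and
``import`` columns.  PED column 6 cannot carry genotype, severity and
onset jointly, hence the sidecar.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional


class PedigreeError(ValueError):
    """Hard pedigree defect: duplicate id, cycle, bad sex code, ..."""


class Sex(enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    UNKNOWN = "unknown"


class Severity(enum.Enum):
    """Clinical severity category (1 = arrhythmia only, 3 = CHF-like)."""

    CAT1 = "cat1"
    CAT2 = "cat2"
    CAT3 = "cat3"
    UNASSESSED = "unassessed"


class MarkerGenotype(enum.Enum):
    """Biallelic marker genotype: HOM/HET for the mutant allele, WT, or untyped."""

    HOM = "HOM"
    HET = "HET"
    WT = "WT"
    UNTYPED = "untyped"

    @property
    def is_typed(self) -> bool:
        return self is not MarkerGenotype.UNTYPED

    @property
    def is_homozygous(self) -> bool:
        return self in (MarkerGenotype.HOM, MarkerGenotype.WT)


@dataclass
class Individual:
    """One dog: identity, parents, sex, phenotype and marker genotype.

    ``birth_order_key`` groups full-sib offspring into litters; offspring of
    the same (sire, dam) pair with equal keys belong to one litter.
    ``is_import`` flags a founder brought in from an external population,
    which truncates upward line tracing.
    """

    id: str
    sire_id: Optional[str] = None
    dam_id: Optional[str] = None
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN
    onset_age_years: Optional[float] = None
    severity: Severity = Severity.UNASSESSED
    marker_genotype: MarkerGenotype = MarkerGenotype.UNTYPED
    birth_order_key: Optional[str] = None
    is_import: bool = False

    @property
    def is_founder(self) -> bool:
        return self.sire_id is None and self.dam_id is None

    @property
    def is_affected(self) -> bool:
        return self.affection is Affection.AFFECTED


@dataclass
class ValidationReport:
    """Hard errors and advisory warnings as (code, individual id, message)."""

    errors: list[tuple[str, str, str]] = field(default_factory=list)
    warnings: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def to_dict(self) -> dict:
        return {
            "ok": self.ok,
            "errors": [
                {"code": c, "id": i, "message": m} for c, i, m in self.errors
            ],
            "warnings": [
                {"code": c, "id": i, "message": m} for c, i, m in self.warnings
            ],
        }


class Pedigree:
    """Acyclic multi-generation family graph over :class:`Individual`."""

    def __init__(self, individuals: Iterable[Individual] = ()):
        self._individuals: dict[str, Individual] = {}
        self._children: dict[str, list[str]] = {}
        for ind in individuals:
            self.add(ind)

    # -- construction ----------------------------------------------------

    def add(self, ind: Individual) -> None:
        if ind.id in self._individuals:
            raise PedigreeError(f"duplicate individual id {ind.id!r}")
        if ind.sire_id == ind.id or ind.dam_id == ind.id:
            raise PedigreeError(f"{ind.id!r} listed as its own parent")
        self._individuals[ind.id] = ind
        self._invalidate_caches()

    def _invalidate_caches(self) -> None:
        self._children = {}

    # -- mapping-style access -------------------------------------------

    def __len__(self) -> int:
        return len(self._individuals)

    def __iter__(self) -> Iterator[str]:
        return iter(self._individuals)

    def __contains__(self, iid: str) -> bool:
        return iid in self._individuals

    def __getitem__(self, iid: str) -> Individual:
        try:
            return self._individuals[iid]
        except KeyError:
            raise KeyError(f"unknown individual id {iid!r}") from None

    @property
    def individuals(self) -> dict[str, Individual]:
        return dict(self._individuals)

    def ids(self) -> list[str]:
        return list(self._individuals)

    # -- graph structure -------------------------------------------------

    def parents_of(self, iid: str) -> tuple[Optional[str], Optional[str]]:
        ind = self[iid]
        return ind.sire_id, ind.dam_id

    def children_of(self, iid: str) -> list[str]:
        if not self._children:
            ch: dict[str, list[str]] = {i: [] for i in self._individuals}
            for ind in self._individuals.values():
                for pid in (ind.sire_id, ind.dam_id):
                    if pid is not None and pid in ch:
                        ch[pid].append(ind.id)
            self._children = ch
        return list(self._children.get(iid, []))

    def founders(self) -> set[str]:
        return {i for i, ind in self._individuals.items() if ind.is_founder}

    def ancestors(self, iid: str) -> set[str]:
        """Transitive closure over parent edges, excluding ``iid`` itself."""
        self[iid]
        out: set[str] = set()
        stack = [p for p in self.parents_of(iid) if p in self]
        while stack:
            cur = stack.pop()
            if cur in out:
                continue
            out.add(cur)
            stack.extend(p for p in self.parents_of(cur) if p in self)
        return out

    def descendants(self, iid: str) -> set[str]:
        """Transitive closure over child edges, excluding ``iid`` itself."""
        self[iid]
        out: set[str] = set()
        stack = list(self.children_of(iid))
        while stack:
            cur = stack.pop()
            if cur in out:
                continue
            out.add(cur)
            stack.extend(self.children_of(cur))
        return out

    def litters(self) -> dict[tuple[Optional[str], Optional[str], Optional[str]], list[str]]:
        """Group non-founders by (sire, dam, litter key).

        Offspring without an explicit ``birth_order_key`` collapse to one
        litter per (sire, dam) pair.
        """
        out: dict[tuple, list[str]] = {}
        for ind in self._individuals.values():
            if ind.is_founder:
                continue
            key = (ind.sire_id, ind.dam_id, ind.birth_order_key)
            out.setdefault(key, []).append(ind.id)
        return out

    def find_cycle(self) -> Optional[list[str]]:
        """Return one cycle of ids over child->parent edges, or None."""
        WHITE, GREY, BLACK = 0, 1, 2
        colour = {i: WHITE for i in self._individuals}
        for start in self._individuals:
            if colour[start] != WHITE:
                continue
            stack: list[tuple[str, Iterator[str]]] = [
                (start, iter([p for p in self.parents_of(start) if p in self]))
            ]
            colour[start] = GREY
            path = [start]
            while stack:
                node, it = stack[-1]
                advanced = False
                for nxt in it:
                    if colour[nxt] == GREY:
                        return path[path.index(nxt):] + [nxt]
                    if colour[nxt] == WHITE:
                        colour[nxt] = GREY
                        path.append(nxt)
                        stack.append(
                            (nxt, iter([p for p in self.parents_of(nxt) if p in self]))
                        )
                        advanced = True
                        break
                if not advanced:
                    colour[node] = BLACK
                    path.pop()
                    stack.pop()
        return None

    # -- validation ------------------------------------------------------

    def validate(self) -> ValidationReport:
        rep = ValidationReport()
        cyc = self.find_cycle()
        if cyc is not None:
            rep.errors.append(
                ("E_CYCLE", cyc[0], "pedigree cycle: " + " -> ".join(cyc))
            )
        for ind in self._individuals.values():
            for pid, role in ((ind.sire_id, "sire"), (ind.dam_id, "dam")):
                if pid is None:
                    continue
                if pid not in self:
                    rep.errors.append(
                        ("E_PARENT_MISSING", ind.id,
                         f"{role} {pid!r} not present in pedigree")
                    )
                    continue
                psex = self[pid].sex
                if role == "sire" and psex is Sex.FEMALE:
                    rep.errors.append(
                        ("E_SIRE_FEMALE", pid,
                         f"{pid!r} is female but recorded as sire of {ind.id!r}")
                    )
                if role == "dam" and psex is Sex.MALE:
                    rep.errors.append(
                        ("E_DAM_MALE", pid,
                         f"{pid!r} is male but recorded as dam of {ind.id!r}")
                    )
            if ind.onset_age_years is not None and not ind.is_affected:
                rep.errors.append(
                    ("E_ONSET_UNAFFECTED", ind.id,
                     "onset age recorded for a dog not marked affected")
                )
            if ind.onset_age_years is not None and ind.onset_age_years < 0:
                rep.errors.append(
                    ("E_ONSET_NEGATIVE", ind.id, "negative onset age")
                )
            if ind.severity is not Severity.UNASSESSED and not ind.is_affected:
                rep.errors.append(
                    ("E_SEVERITY_UNAFFECTED", ind.id,
                     "severity category recorded for a dog not marked affected")
                )
            if (ind.sire_id is None) != (ind.dam_id is None):
                rep.warnings.append(
                    ("W_SINGLE_PARENT", ind.id,
                     "only one parent recorded; missing side treated as anonymous founder")
                )
        return rep


# ---------------------------------------------------------------------------
# Module-level operations (thin wrappers over Pedigree methods)
# ---------------------------------------------------------------------------

def founders(ped: Pedigree) -> set[str]:
    """Ids with both parents missing."""
    return ped.founders()


def ancestors(ped: Pedigree, iid: str) -> set[str]:
    return ped.ancestors(iid)


def descendants(ped: Pedigree, iid: str) -> set[str]:
    return ped.descendants(iid)


def _depths(ped: Pedigree) -> dict[str, int]:
    depth: dict[str, int] = {}

    def d(i: str) -> int:
        if i in depth:
            return depth[i]
        ind = ped[i]
        parents = [p for p in (ind.sire_id, ind.dam_id) if p in ped]
        depth[i] = 0 if not parents else 1 + max(d(p) for p in parents)
        return depth[i]

    for i in ped:
        d(i)
    return depth


def kinship(ped: Pedigree, a: Optional[str], b: Optional[str]) -> float:
    """Malécot kinship coefficient phi(a, b) by the recursive tabular method.

    A missing parent contributes 0 (anonymous unrelated founder).
    """
    depth = _depths(ped)
    memo: dict[tuple[str, str], float] = {}

    def phi(x: Optional[str], y: Optional[str]) -> float:
        if x is None or y is None or x not in ped or y not in ped:
            return 0.0
        if x == y:
            s, d = ped[x].sire_id, ped[x].dam_id
            return 0.5 * (1.0 + phi(s, d))
        key = (x, y) if x <= y else (y, x)
        if key in memo:
            return memo[key]
        # recurse on the individual farther from the founders so the other
        # can never be its descendant
        if depth[x] < depth[y]:
            x, y = y, x
        s, d = ped[x].sire_id, ped[x].dam_id
        val = 0.5 * (phi(s, y) + phi(d, y))
        memo[key] = val
        return val

    return phi(a, b)


def inbreeding_coefficient(ped: Pedigree, iid: str) -> float:
    """Wright's F: the kinship of the parents; 0 when a parent is missing."""
    ind = ped[iid]
    if ind.sire_id is None or ind.dam_id is None:
        return 0.0
    return kinship(ped, ind.sire_id, ind.dam_id)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_SEX_FROM_PED = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN}
_SEX_TO_PED = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_AFF_FROM_PED = {
    "1": Affection.UNAFFECTED,
    "2": Affection.AFFECTED,
    "0": Affection.UNKNOWN,
    "-9": Affection.UNKNOWN,
}
_AFF_TO_PED = {
    Affection.UNAFFECTED: "1",
    Affection.AFFECTED: "2",
    Affection.UNKNOWN: "0",
}
_SEVERITY_FROM_STR = {
    "1": Severity.CAT1, "2": Severity.CAT2, "3": Severity.CAT3,
    "cat1": Severity.CAT1, "cat2": Severity.CAT2, "cat3": Severity.CAT3,
    "": Severity.UNASSESSED, "unassessed": Severity.UNASSESSED,
}
_SEVERITY_TO_STR = {
    Severity.CAT1: "1", Severity.CAT2: "2", Severity.CAT3: "3",
    Severity.UNASSESSED: "",
}
_MARKER_FROM_STR = {
    "HOM": MarkerGenotype.HOM, "HET": MarkerGenotype.HET,
    "WT": MarkerGenotype.WT, "": MarkerGenotype.UNTYPED,
    "untyped": MarkerGenotype.UNTYPED,
}
_AFF_FROM_STR = {
    "affected": Affection.AFFECTED, "unaffected": Affection.UNAFFECTED,
    "unknown": Affection.UNKNOWN, "": Affection.UNKNOWN,
}

PHENO_COLUMNS = ["id", "affection", "onset_age", "severity", "strn"]


def read_pedigree(
    ped_path: str | Path,
    pheno_path: str | Path | None = None,
    report: ValidationReport | None = None,
) -> Pedigree:
    """Read a PLINK-style PED file plus optional phenotype/genotype CSV.

    Hard defects (duplicate id, cycle, unknown sex code) raise
    :class:`PedigreeError`.  Advisory findings (unreferenced phenotype rows,
    implicit founders materialised for referenced-but-undefined parents) go
    to ``report.warnings`` when a report is supplied.
    """
    if report is None:
        report = ValidationReport()
    ped = Pedigree()
    referenced: list[tuple[str, str, Sex]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise PedigreeError(
                    f"{ped_path}:{lineno}: expected 6 columns "
                    f"(family id sire dam sex phenotype), got {len(parts)}"
                )
            _fam, iid, sire, dam, sex_code, aff_code = parts[:6]
            if sex_code not in _SEX_FROM_PED:
                raise PedigreeError(
                    f"{ped_path}:{lineno}: unknown sex code {sex_code!r} for {iid!r}"
                )
            if aff_code not in _AFF_FROM_PED:
                raise PedigreeError(
                    f"{ped_path}:{lineno}: unknown phenotype code {aff_code!r} for {iid!r}"
                )
            ind = Individual(
                id=iid,
                sire_id=None if sire == "0" else sire,
                dam_id=None if dam == "0" else dam,
                sex=_SEX_FROM_PED[sex_code],
                affection=_AFF_FROM_PED[aff_code],
            )
            ped.add(ind)
            if ind.sire_id is not None:
                referenced.append((iid, ind.sire_id, Sex.MALE))
            if ind.dam_id is not None:
                referenced.append((iid, ind.dam_id, Sex.FEMALE))

    for child, pid, sex in referenced:
        if pid not in ped:
            ped.add(Individual(id=pid, sex=sex))
            report.warnings.append(
                ("W_IMPLICIT_FOUNDER", pid,
                 f"parent of {child!r} had no PED row; added as anonymous founder")
            )

    cyc = ped.find_cycle()
    if cyc is not None:
        raise PedigreeError("pedigree cycle: " + " -> ".join(cyc))

    if pheno_path is not None:
        _merge_phenotypes(ped, pheno_path, report)

    return ped


def _parse_onset(raw: str) -> Optional[float]:
    raw = raw.strip()
    if not raw:
        return None
    if raw.startswith("<"):  # "<1" dialect: encode as midpoint 0.5
        return float(raw[1:]) / 2.0
    return float(raw)


def _merge_phenotypes(
    ped: Pedigree, pheno_path: str | Path, report: ValidationReport
) -> None:
    with open(pheno_path, newline="") as fh:
        reader = csv.DictReader(fh)
        missing = [c for c in PHENO_COLUMNS if c not in (reader.fieldnames or [])]
        if missing:
            raise PedigreeError(
                f"{pheno_path}: phenotype CSV missing columns {missing}"
            )
        for row in reader:
            iid = row["id"].strip()
            if iid not in ped:
                report.warnings.append(
                    ("W_UNREFERENCED_PHENO", iid,
                     "phenotype row has no matching PED individual")
                )
                continue
            ind = ped[iid]
            aff_raw = row["affection"].strip().lower()
            if aff_raw not in _AFF_FROM_STR:
                raise PedigreeError(
                    f"{pheno_path}: unknown affection value {row['affection']!r} for {iid!r}"
                )
            aff = _AFF_FROM_STR[aff_raw]
            if (aff is not Affection.UNKNOWN
                    and ind.affection is not Affection.UNKNOWN
                    and aff is not ind.affection):
                report.warnings.append(
                    ("W_AFFECTION_CONFLICT", iid,
                     f"PED says {ind.affection.value}, phenotype CSV says {aff.value}; "
                     "CSV value kept")
                )
            if aff is not Affection.UNKNOWN:
                ind.affection = aff
            ind.onset_age_years = _parse_onset(row["onset_age"])
            sev_raw = row["severity"].strip().lower()
            if sev_raw not in _SEVERITY_FROM_STR:
                raise PedigreeError(
                    f"{pheno_path}: unknown severity value {row['severity']!r} for {iid!r}"
                )
            ind.severity = _SEVERITY_FROM_STR[sev_raw]
            strn_raw = row["strn"].strip()
            if strn_raw not in _MARKER_FROM_STR:
                raise PedigreeError(
                    f"{pheno_path}: unknown marker genotype {row['strn']!r} for {iid!r}"
                )
            ind.marker_genotype = _MARKER_FROM_STR[strn_raw]
            if "litter" in row and row["litter"] is not None and row["litter"].strip():
                ind.birth_order_key = row["litter"].strip()
            if "import" in row and row["import"] is not None:
                ind.is_import = row["import"].strip() in ("1", "true", "True", "yes")


def write_pedigree(
    ped: Pedigree,
    ped_path: str | Path,
    pheno_path: str | Path | None = None,
    family_id: str = "FAM1",
) -> None:
    """Write PED (and optionally the phenotype CSV) in the dialect read back
    by :func:`read_pedigree`; the pair round-trips field-for-field."""
    with open(ped_path, "w") as fh:
        for ind in ped.individuals.values():
            fh.write(
                " ".join(
                    [
                        family_id,
                        ind.id,
                        ind.sire_id or "0",
                        ind.dam_id or "0",
                        _SEX_TO_PED[ind.sex],
                        _AFF_TO_PED[ind.affection],
                    ]
                )
                + "\n"
            )
    if pheno_path is None:
        return
    with open(pheno_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(PHENO_COLUMNS + ["litter", "import"])
        for ind in ped.individuals.values():
            writer.writerow(
                [
                    ind.id,
                    ind.affection.value if ind.affection is not Affection.UNKNOWN else "",
                    "" if ind.onset_age_years is None else repr(ind.onset_age_years),
                    _SEVERITY_TO_STR[ind.severity],
                    ind.marker_genotype.value if ind.marker_genotype.is_typed else "",
                    ind.birth_order_key or "",
                    "1" if ind.is_import else "",
                ]
            )
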