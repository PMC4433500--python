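"""Gene-dropping simulator for a dominant, late-onset, incompletely
penetrant disease locus linked to a biallelic marker.

Two loci on one chromosome, a single recombination interval with crossover
probability ``theta`` per meiosis.  The disease allele enters only through
designated founder "imports"; founder marker genotypes are drawn at
Hardy-Weinberg proportions.  Breeding follows a popular-sire scheme (each
generation a few sires are each mated to several dams) so that
multi-mate transmitters are observable; litter sizes are Poisson truncated
at one.  Carriers develop disease with probability ``penetrance`` at a
log-normal onset age; a dog censored before onset is recorded unaffected.

Full ground truth (haplotypes, per-meiosis crossover indicators, carrier
flags, uncensored onsets) is logged so downstream inference can be scored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from pedilink.descent_tracing import RiskClass
from pedilink.pedigree_core import (
    Affection,
    Individual,
    MarkerGenotype,
    Pedigree,
    Severity,
    Sex,
)

MUT, WT_ALLELE = 1, 0  # marker alleles
D, PLUS = 1, 0  # disease-locus alleles

Haplotype = tuple[int, int]  # (marker allele, disease allele)


@dataclass(frozen=True)
class SimConfig:
    """Simulator parameters.

    Defaults follow the published cohort description: mean litter size 6.5,
    median onset 7 years, a handful of import founders carrying the disease
    allele, and a marker mutation common in the background population.
    """

    seed: int = 0
    n_founders: int = 40
    n_import_carriers: int = 2
    generations: int = 4
    mean_litter_size: float = 6.5
    theta: float = 0.0
    penetrance: float = 0.25
    marker_mut_freq: float = 0.4
    onset_median_years: float = 7.0
    onset_sigma: float = 0.55
    censor_age_years: float = 12.0
    prop_genotyped: float = 1.0
    import_phase: str = "coupling"  # coupling | repulsion | per_import
    mating_scheme: str = "popular_sire"  # popular_sire | monogamy
    n_sires_per_generation: int = 4
    dams_per_sire: int = 3
    avoid_carrier_x_carrier: bool = True
    severity_weights: tuple[float, float, float] = (0.5, 0.3, 0.2)
    severity_hom_cat3_boost: float = 2.0

    def __post_init__(self):
        if not 0.0 <= self.theta <= 0.5:
            raise ValueError("theta must lie in [0, 0.5]")
        for name in ("penetrance", "marker_mut_freq", "prop_genotyped"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.mean_litter_size <= 0:
            raise ValueError("mean_litter_size must be positive")
        if self.n_import_carriers > self.n_founders:
            raise ValueError("n_import_carriers cannot exceed n_founders")
        if self.n_founders < 2 or self.generations < 1:
            raise ValueError("need >= 2 founders and >= 1 generation")
        if self.import_phase not in ("coupling", "repulsion", "per_import"):
            raise ValueError(f"unknown import_phase {self.import_phase!r}")
        if self.mating_scheme not in ("popular_sire", "monogamy"):
            raise ValueError(f"unknown mating_scheme {self.mating_scheme!r}")
        if self.onset_median_years <= 0 or self.onset_sigma <= 0:
            raise ValueError("onset parameters must be positive")


@dataclass(frozen=True)
class Meiosis:
    parent_id: str
    child_id: str
    start_hap: int  # which parental haplotype supplied the marker allele
    crossover: bool  # loci exchanged between parental haplotypes

    def gamete(self, parent_haps: tuple[Haplotype, Haplotype]) -> Haplotype:
        marker = parent_haps[self.start_hap][0]
        disease_src = 1 - self.start_hap if self.crossover else self.start_hap
        return (marker, parent_haps[disease_src][1])


@dataclass
class SimTruth:
    """Ground truth: haplotypes, meioses, carrier flags, uncensored onsets."""

    haplotypes: dict[str, tuple[Haplotype, Haplotype]] = field(default_factory=dict)
    meioses: list[Meiosis] = field(default_factory=list)
    carrier: dict[str, bool] = field(default_factory=dict)
    true_onset: dict[str, Optional[float]] = field(default_factory=dict)
    observed_affected: dict[str, bool] = field(default_factory=dict)
    founder_ids: list[str] = field(default_factory=list)
    import_ids: list[str] = field(default_factory=list)

    def marker_genotype(self, iid: str) -> MarkerGenotype:
        n_mut = sum(h[0] for h in self.haplotypes[iid])
        return {0: MarkerGenotype.WT, 1: MarkerGenotype.HET, 2: MarkerGenotype.HOM}[n_mut]

    def is_marker_het(self, iid: str) -> bool:
        h = self.haplotypes[iid]
        return h[0][0] != h[1][0]

    def to_dict(self) -> dict:
        return {
            "haplotypes": {k: [list(h) for h in v] for k, v in self.haplotypes.items()},
            "meioses": [
                {
                    "parent": m.parent_id,
                    "child": m.child_id,
                    "start_hap": m.start_hap,
                    "crossover": m.crossover,
                }
                for m in self.meioses
            ],
            "carrier": dict(self.carrier),
            "true_onset": dict(self.true_onset),
            "observed_affected": dict(self.observed_affected),
            "founder_ids": list(self.founder_ids),
            "import_ids": list(self.import_ids),
        }


def _draw_phenotype(
    iid: str,
    haps: tuple[Haplotype, Haplotype],
    cfg: SimConfig,
    rng: np.random.Generator,
    truth: SimTruth,
) -> tuple[Affection, Optional[float], Severity, MarkerGenotype]:
    carrier = any(h[1] == D for h in haps)
    truth.carrier[iid] = carrier
    onset: Optional[float] = None
    if carrier and rng.random() < cfg.penetrance:
        onset = float(
            rng.lognormal(mean=math.log(cfg.onset_median_years), sigma=cfg.onset_sigma)
        )
    truth.true_onset[iid] = onset
    observed = onset is not None and onset < cfg.censor_age_years
    truth.observed_affected[iid] = observed

    n_mut = haps[0][0] + haps[1][0]
    true_geno = {0: MarkerGenotype.WT, 1: MarkerGenotype.HET, 2: MarkerGenotype.HOM}[n_mut]
    typed = rng.random() < cfg.prop_genotyped
    geno = true_geno if typed else MarkerGenotype.UNTYPED

    severity = Severity.UNASSESSED
    if observed:
        w = np.array(cfg.severity_weights, dtype=float)
        if true_geno is MarkerGenotype.HOM:
            w = w.copy()
            w[2] *= cfg.severity_hom_cat3_boost
        w /= w.sum()
        severity = [Severity.CAT1, Severity.CAT2, Severity.CAT3][
            int(rng.choice(3, p=w))
        ]
    affection = Affection.AFFECTED if observed else Affection.UNAFFECTED
    return affection, (onset if observed else None), severity, geno


def _transmit(
    parent_id: str,
    child_id: str,
    parent_haps: tuple[Haplotype, Haplotype],
    theta: float,
    rng: np.random.Generator,
) -> tuple[Haplotype, Meiosis]:
    m = Meiosis(
        parent_id=parent_id,
        child_id=child_id,
        start_hap=int(rng.integers(2)),
        crossover=bool(rng.random() < theta),
    )
    return m.gamete(parent_haps), m


def simulate(cfg: SimConfig) -> tuple[Pedigree, pd.DataFrame, SimTruth]:
    """Run a gene drop; returns the pedigree (phenotypes attached to
    individuals), a phenotype table, and the ground-truth log."""
    rng = np.random.default_rng(cfg.seed)
    ped = Pedigree()
    truth = SimTruth()

    # founders, imports first (males, carrying one disease allele)
    founders: list[str] = []
    for i in range(cfg.n_founders):
        iid = f"F{i + 1:03d}"
        is_import = i < cfg.n_import_carriers
        sex = Sex.MALE if (is_import or i % 2 == 0) else Sex.FEMALE
        hap0 = (int(rng.random() < cfg.marker_mut_freq), PLUS)
        hap1 = (int(rng.random() < cfg.marker_mut_freq), PLUS)
        if is_import:
            phase = cfg.import_phase
            if phase == "per_import":
                phase = "coupling" if i % 2 == 0 else "repulsion"
            hap0 = (MUT if phase == "coupling" else WT_ALLELE, D)
        haps = (hap0, hap1)
        truth.haplotypes[iid] = haps
        aff, onset, sev, geno = _draw_phenotype(iid, haps, cfg, rng, truth)
        ped.add(
            Individual(
                id=iid, sex=sex, affection=aff, onset_age_years=onset,
                severity=sev, marker_genotype=geno, is_import=is_import,
            )
        )
        founders.append(iid)
        if is_import:
            truth.import_ids.append(iid)
    truth.founder_ids = founders

    prev_gen = founders
    counter = 0
    for g in range(1, cfg.generations + 1):
        males = [i for i in prev_gen if ped[i].sex is Sex.MALE]
        females = [i for i in prev_gen if ped[i].sex is Sex.FEMALE]
        if not males or not females:
            break
        matings = _plan_matings(ped, truth, males, females, cfg, rng)
        new_gen: list[str] = []
        for litter_idx, (sire, dam) in enumerate(matings):
            size = 0
            while size == 0:
                size = int(rng.poisson(cfg.mean_litter_size))
            litter_key = f"G{g}L{litter_idx + 1}"
            for _ in range(size):
                counter += 1
                iid = f"G{g}_{counter:04d}"
                pat, m1 = _transmit(sire, iid, truth.haplotypes[sire], cfg.theta, rng)
                mat, m2 = _transmit(dam, iid, truth.haplotypes[dam], cfg.theta, rng)
                truth.meioses.extend([m1, m2])
                haps = (pat, mat)
                truth.haplotypes[iid] = haps
                aff, onset, sev, geno = _draw_phenotype(iid, haps, cfg, rng, truth)
                ped.add(
                    Individual(
                        id=iid, sire_id=sire, dam_id=dam,
                        sex=Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
                        affection=aff, onset_age_years=onset, severity=sev,
                        marker_genotype=geno, birth_order_key=litter_key,
                    )
                )
                new_gen.append(iid)
        prev_gen = new_gen

    return ped, phenotype_table(ped), truth


def _plan_matings(
    ped: Pedigree,
    truth: SimTruth,
    males: list[str],
    females: list[str],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    if cfg.mating_scheme == "monogamy":
        males = list(males)
        females = list(females)
        rng.shuffle(males)
        rng.shuffle(females)
        return list(zip(males, females))

    # popular-sire scheme: keep carrier males in the stud pool so the
    # disease allele persists, fill the rest at random
    carrier_males = [m for m in males if truth.carrier[m]]
    other_males = [m for m in males if not truth.carrier[m]]
    rng.shuffle(carrier_males)
    rng.shuffle(other_males)
    n_sires = min(cfg.n_sires_per_generation, len(males))
    n_carrier = min(len(carrier_males), max(1, n_sires // 2))
    sires = carrier_males[:n_carrier] + other_males[: n_sires - n_carrier]
    sires = sires[:n_sires]

    clear_females = [f for f in females if not truth.carrier[f]]
    carrier_females = [f for f in females if truth.carrier[f]]
    rng.shuffle(clear_females)
    rng.shuffle(carrier_females)

    matings: list[tuple[str, str]] = []
    pool = clear_females + carrier_females  # prefer clear dams
    cursor = 0
    for sire in sires:
        for _ in range(cfg.dams_per_sire):
            if cursor >= len(pool):
                cursor = 0
            dam = pool[cursor]
            cursor += 1
            if (
                cfg.avoid_carrier_x_carrier
                and truth.carrier[sire]
                and truth.carrier[dam]
                and clear_females
            ):
                dam = clear_females[int(rng.integers(len(clear_females)))]
            matings.append((sire, dam))
    return matings


def phenotype_table(ped: Pedigree) -> pd.DataFrame:
    """Phenotype/genotype sidecar table for a pedigree (CSV dialect)."""
    rows = []
    for ind in ped.individuals.values():
        rows.append(
            {
                "id": ind.id,
                "affection": (
                    ind.affection.value
                    if ind.affection is not Affection.UNKNOWN
                    else ""
                ),
                "onset_age": ind.onset_age_years,
                "severity": {
                    Severity.CAT1: "1", Severity.CAT2: "2",
                    Severity.CAT3: "3", Severity.UNASSESSED: "",
                }[ind.severity],
                "strn": ind.marker_genotype.value if ind.marker_genotype.is_typed else "",
                "litter": ind.birth_order_key or "",
                "import": "1" if ind.is_import else "",
            }
        )
    return pd.DataFrame(
        rows, columns=["id", "affection", "onset_age", "severity", "strn", "litter", "import"]
    )


def truth_recombination_count(truth: SimTruth, informative_only: bool = False) -> int:
    """Number of crossover meioses; optionally only those observable in
    principle (parent marker-heterozygous and a disease carrier)."""
    n = 0
    for m in truth.meioses:
        if not m.crossover:
            continue
        if informative_only:
            if not (truth.is_marker_het(m.parent_id) and truth.carrier[m.parent_id]):
                continue
        n += 1
    return n


def truth_carrier_assignment(ped: Pedigree, truth: SimTruth):
    """Oracle carrier/risk assignments straight from ground truth.

    Useful for scoring inference and for unconfounded parameter recovery
    (inference-based carrier calls are ascertained through affected
    offspring, which biases segregation ratios upward).
    """
    from pedilink.linkage_inference import CarrierAssignment, CarrierStatus

    ca = CarrierAssignment()
    rc = RiskClass()
    for iid in ped.ids():
        if truth.carrier[iid]:
            ca.status[iid] = CarrierStatus.OBLIGATE_CARRIER
            ca.provenance[iid] = "truth"
            rc.labels[iid] = "at_risk"
        else:
            ca.status[iid] = CarrierStatus.CLEAR
            ca.provenance[iid] = "truth"
            rc.labels[iid] = "clear_by_pedigree"
    return ca, rc


# ---------------------------------------------------------------------------
# Deterministic genotype-count fixture
# ---------------------------------------------------------------------------

#   group               HOM  HET  WT   total
_FIXTURE_ROWS = {
    "line1_cases": (10, 13, 0),       # 23
    "line2_cases": (6, 8, 10),        # 24
    "normal_by_pedigree": (5, 16, 10),  # 31
    "holter_cases": (5, 14, 7),       # 26
    "holter_normals": (6, 3, 4),      # 13
}


@dataclass
class Table1Fixture:
    pedigree: Pedigree
    phenotypes: pd.DataFrame
    extra_groups: dict[str, list[str]]


def _genotype_sequence(hom: int, het: int, wt: int) -> list[MarkerGenotype]:
    return (
        [MarkerGenotype.HOM] * hom
        + [MarkerGenotype.HET] * het
        + [MarkerGenotype.WT] * wt
    )


def make_table1_fixture() -> Table1Fixture:
    """Minimal deterministic pedigree reproducing the published genotype
    table: one single-import line (source A), one two-import line with
    joined chains (sources G and H), a clear-by-pedigree normal section,
    and two externally sampled Holter cohorts carried as extra groups."""
    ped = Pedigree()

    def add(iid, sire=None, dam=None, sex=Sex.UNKNOWN, aff=Affection.UNKNOWN,
            geno=MarkerGenotype.UNTYPED, imp=False, litter=None):
        ped.add(
            Individual(
                id=iid, sire_id=sire, dam_id=dam, sex=sex, affection=aff,
                marker_genotype=geno, is_import=imp, birth_order_key=litter,
            )
        )

    # ---- line 1: single imported source A --------------------------------
    add("A", sex=Sex.MALE, aff=Affection.UNAFFECTED, geno=MarkerGenotype.HET, imp=True)
    for dam in ("DAM1", "DAM2"):
        add(dam, sex=Sex.FEMALE)
    l1_genos = _genotype_sequence(*_FIXTURE_ROWS["line1_cases"])
    line1_cases = []
    for k, geno in enumerate(l1_genos):
        dam = "DAM1" if k < 12 else "DAM2"
        iid = f"C1{k + 1:02d}"
        add(iid, sire="A", dam=dam, sex=Sex.MALE if k % 2 else Sex.FEMALE,
            aff=Affection.AFFECTED, geno=geno, litter=f"L1-{1 + k // 6}")
        line1_cases.append(iid)

    # ---- line 2: imported sources G and H, chains joined through J x K ---
    for imp in ("G", "H"):
        add(imp, sex=Sex.MALE, aff=Affection.UNAFFECTED, geno=MarkerGenotype.WT, imp=True)
    for dam in ("DAM3", "DAM4", "DAM5", "DAM6"):
        add(dam, sex=Sex.FEMALE)
    add("J", sire="G", dam="DAM3", sex=Sex.MALE, aff=Affection.UNAFFECTED)
    add("K", sire="H", dam="DAM5", sex=Sex.FEMALE, aff=Affection.UNAFFECTED)
    l2_genos = _genotype_sequence(*_FIXTURE_ROWS["line2_cases"])
    parents = (
        [("G", "DAM3"), ("G", "DAM4")] * 4    # 8 cases from G
        + [("H", "DAM5"), ("H", "DAM6")] * 4  # 8 cases from H
        + [("J", "K")] * 8                     # 8 cases of joined descent
    )
    line2_cases = []
    for k, ((sire, dam), geno) in enumerate(zip(parents, l2_genos)):
        iid = f"C2{k + 1:02d}"
        add(iid, sire=sire, dam=dam, sex=Sex.MALE if k % 2 else Sex.FEMALE,
            aff=Affection.AFFECTED, geno=geno, litter=f"L2-{1 + k // 4}")
        line2_cases.append(iid)

    # ---- clear-by-pedigree normal section --------------------------------
    for k, geno in enumerate(_genotype_sequence(*_FIXTURE_ROWS["normal_by_pedigree"])):
        add(f"N{k + 1:02d}", sex=Sex.MALE if k % 2 else Sex.FEMALE,
            aff=Affection.UNAFFECTED, geno=geno)

    # ---- externally sampled Holter cohorts (extra groups) ----------------
    holter_cases = []
    add("DAM7", sex=Sex.FEMALE)
    add("DAM8", sex=Sex.FEMALE)
    for k, geno in enumerate(_genotype_sequence(*_FIXTURE_ROWS["holter_cases"])):
        sire, dam = ("A", "DAM7") if k < 13 else ("H", "DAM8")
        iid = f"HC{k + 1:02d}"
        add(iid, sire=sire, dam=dam, sex=Sex.MALE if k % 2 else Sex.FEMALE,
            aff=Affection.AFFECTED, geno=geno, litter=f"LH-{1 + k // 7}")
        holter_cases.append(iid)
    holter_normals = []
    for k, geno in enumerate(_genotype_sequence(*_FIXTURE_ROWS["holter_normals"])):
        iid = f"HN{k + 1:02d}"
        add(iid, sex=Sex.MALE if k % 2 else Sex.FEMALE,
            aff=Affection.UNAFFECTED, geno=geno)
        holter_normals.append(iid)

    extra_groups = {"holter_cases": holter_cases, "holter_normals": holter_normals}
    return Table1Fixture(
        pedigree=ped,
        phenotypes=phenotype_table(ped),
        extra_groups=extra_groups,
    )
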