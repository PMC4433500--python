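import pytest

from pedilink.descent_tracing import classify_risk, identify_transmitters, trace_to_sources
from pedilink.linkage_inference import (
    CarrierStatus,
    Phase,
    PhaseCertainty,
    assign_carriers,
    assign_phase,
    detect_recombination,
    genotype_tables_by_group,
    informative_meioses,
)
from pedilink.pedigree_core import MarkerGenotype
from pedilink.synthetic_data import make_table1_fixture

from conftest import AFF, F, HET, HOM, M, UNAFF, WT, build_pedigree


def full_pipeline(ped, min_mates=2):
    tr = identify_transmitters(ped, min_mates=min_mates)
    lines = trace_to_sources(ped, tr)
    risk = classify_risk(ped, lines)
    carriers = assign_carriers(ped, risk, tr, bridges=lines.bridges)
    phases = assign_phase(ped, carriers)
    return tr, lines, risk, carriers, phases


# ---------------------------------------------------------------------------
# carrier assignment
# ---------------------------------------------------------------------------

def carrier_family():
    return build_pedigree(
        [
            {"id": "imp", "sex": M, "affection": UNAFF, "is_import": True,
             "marker_genotype": WT},
            {"id": "d1", "sex": F},
            {"id": "d2", "sex": F},
            {"id": "a1", "sire_id": "imp", "dam_id": "d1", "affection": AFF,
             "marker_genotype": WT},
            {"id": "a2", "sire_id": "imp", "dam_id": "d2", "affection": AFF,
             "marker_genotype": HET},
            {"id": "n1", "sex": F, "affection": UNAFF, "marker_genotype": HOM},
        ]
    )


def test_affected_wt_dog_is_obligate_carrier():
    ped = carrier_family()
    _, _, _, carriers, _ = full_pipeline(ped)
    # the marker genotype never vetoes carrier status
    assert carriers.status["a1"] is CarrierStatus.OBLIGATE_CARRIER
    assert carriers.provenance["a1"] == "affected"


def test_clear_hom_dog_stays_clear():
    ped = carrier_family()
    _, _, _, carriers, _ = full_pipeline(ped)
    assert carriers.status["n1"] is CarrierStatus.CLEAR
    assert carriers.provenance["n1"] == "clear_by_pedigree"


def test_untyped_affected_obligate_ambiguous_phase():
    ped = build_pedigree([{"id": "x", "affection": AFF}])
    _, _, _, carriers, phases = full_pipeline(ped)
    assert carriers.status["x"] is CarrierStatus.OBLIGATE_CARRIER
    assert phases["x"].phase is Phase.AMBIGUOUS
    assert phases["x"].certainty is PhaseCertainty.NONE


def test_transmitter_is_inferred_carrier():
    ped = carrier_family()
    _, _, _, carriers, _ = full_pipeline(ped)
    assert carriers.status["imp"] is CarrierStatus.INFERRED_CARRIER
    assert carriers.provenance["imp"] == "transmitter"


# ---------------------------------------------------------------------------
# phase assignment
# ---------------------------------------------------------------------------

def test_hom_carrier_coupling_certain():
    ped = build_pedigree([{"id": "x", "affection": AFF, "marker_genotype": HOM}])
    _, _, _, _, phases = full_pipeline(ped)
    assert phases["x"] .phase is Phase.COUPLING
    assert phases["x"].certainty is PhaseCertainty.CERTAIN_BY_HOMOZYGOSITY


def test_wt_carrier_repulsion_certain():
    ped = build_pedigree([{"id": "x", "affection": AFF, "marker_genotype": WT}])
    _, _, _, _, phases = full_pipeline(ped)
    assert phases["x"].phase is Phase.REPULSION
    assert phases["x"].certainty is PhaseCertainty.CERTAIN_BY_HOMOZYGOSITY


def propagation_family(parent_geno, child_geno):
    """WT (or HOM) carrier dam with a carrier child; sire clear."""
    return build_pedigree(
        [
            {"id": "dam", "sex": F, "affection": AFF, "marker_genotype": parent_geno},
            {"id": "sire", "sex": M, "affection": UNAFF},
            {"id": "kid", "sire_id": "sire", "dam_id": "dam", "affection": AFF,
             "marker_genotype": child_geno},
        ]
    )


def test_het_child_of_wt_carrier_dam_propagates_repulsion():
    ped = propagation_family(WT, HET)
    _, _, _, _, phases = full_pipeline(ped)
    assert phases["kid"].phase is Phase.REPULSION
    assert phases["kid"].certainty is PhaseCertainty.PROPAGATED


def test_propagation_never_overwrites_homozygosity():
    ped = propagation_family(HOM, WT)  # genotype-inconsistent data
    _, _, _, _, phases = full_pipeline(ped)
    assert phases["kid"].phase is Phase.REPULSION
    assert phases["kid"].certainty is PhaseCertainty.CERTAIN_BY_HOMOZYGOSITY


def test_phase_never_contradicts_homozygosity_rule(small_sim):
    ped, _, _ = small_sim
    _, _, _, _, phases = full_pipeline(ped)
    for iid, call in phases.items():
        g = ped[iid].marker_genotype
        if g is MarkerGenotype.HOM:
            assert call.phase is Phase.COUPLING
        elif g is MarkerGenotype.WT:
            assert call.phase is Phase.REPULSION


# ---------------------------------------------------------------------------
# recombination detection
# ---------------------------------------------------------------------------

def test_same_phase_no_event():
    ped = propagation_family(HOM, HOM)
    _, _, _, _, phases = full_pipeline(ped)
    assert detect_recombination(ped, phases) == []


def test_direct_certain_mismatch_reported():
    # HOM dam with WT affected child is only possible with a genotype error,
    # but the phase conflict is reported, graded certain, not suppressed
    ped = propagation_family(HOM, WT)
    _, _, _, _, phases = full_pipeline(ped)
    events = detect_recombination(ped, phases)
    assert len(events) == 1
    assert events[0].grade == "certain"
    assert (events[0].parent_id, events[0].child_id) == ("dam", "kid")


def test_forced_het_parent_event_certain():
    # grandparent HOM (coupling) -> HET parent (forced coupling) -> WT child
    # (repulsion): the switch is pinned to the parent's meiosis
    ped = build_pedigree(
        [
            {"id": "gp", "sex": M, "affection": AFF, "marker_genotype": HOM},
            {"id": "gd", "sex": F},
            {"id": "par", "sire_id": "gp", "dam_id": "gd", "sex": F,
             "affection": AFF, "marker_genotype": HET},
            {"id": "sire2", "sex": M},
            {"id": "kid", "sire_id": "sire2", "dam_id": "par", "affection": AFF,
             "marker_genotype": WT},
        ]
    )
    _, _, _, _, phases = full_pipeline(ped)
    assert phases["par"].certainty is PhaseCertainty.PROPAGATED
    events = [e for e in detect_recombination(ped, phases) if e.grade == "certain"]
    assert [(e.parent_id, e.child_id) for e in events] == [("par", "kid")]


def test_untyped_bridge_gives_possible_path_event():
    ped = build_pedigree(
        [
            {"id": "gp", "sex": M, "affection": AFF, "marker_genotype": HOM},
            {"id": "gd", "sex": F},
            {"id": "par", "sire_id": "gp", "dam_id": "gd", "sex": F,
             "affection": AFF},  # untyped carrier in between
            {"id": "sire2", "sex": M},
            {"id": "kid", "sire_id": "sire2", "dam_id": "par", "affection": AFF,
             "marker_genotype": WT},
        ]
    )
    _, _, _, _, phases = full_pipeline(ped)
    events = detect_recombination(ped, phases)
    assert len(events) == 1
    assert events[0].grade == "possible"
    assert events[0].path == ("gp", "par", "kid")


def test_line1_pattern_no_events():
    # all cases marker-HOM/HET in coupling: nothing to report
    rows = [
        {"id": "src", "sex": M, "affection": AFF, "marker_genotype": HOM,
         "is_import": True},
        {"id": "d1", "sex": F},
        {"id": "d2", "sex": F},
    ]
    for k, geno in enumerate([HOM, HET, HET, HOM]):
        rows.append(
            {"id": f"c{k}", "sire_id": "src", "dam_id": "d1" if k % 2 else "d2",
             "affection": AFF, "marker_genotype": geno}
        )
    ped = build_pedigree(rows)
    _, _, _, _, phases = full_pipeline(ped)
    assert detect_recombination(ped, phases) == []


@pytest.mark.parametrize("seed", range(8))
def test_no_events_without_crossover(seed, sim_factory):
    ped, _, _ = sim_factory(
        seed=seed, theta=0.0, penetrance=1.0, censor_age_years=1e9,
        marker_mut_freq=0.5,
    )
    _, _, _, _, phases = full_pipeline(ped)
    assert detect_recombination(ped, phases) == []


@pytest.mark.parametrize("seed", range(5))
def test_certain_events_match_true_crossovers(seed, sim_factory):
    ped, _, truth = sim_factory(
        seed=100 + seed, theta=0.15, penetrance=1.0, censor_age_years=1e9,
        marker_mut_freq=0.5,
    )
    _, _, _, _, phases = full_pipeline(ped)
    crossed = {
        (m.parent_id, m.child_id) for m in truth.meioses if m.crossover
    }
    for e in detect_recombination(ped, phases):
        if e.grade != "certain":
            continue
        assert (e.parent_id, e.child_id) in crossed, e


def test_informative_meioses_definition(small_sim):
    ped, _, _ = small_sim
    _, _, _, _, phases = full_pipeline(ped)
    for pid, cid in informative_meioses(ped, phases):
        assert ped[pid].marker_genotype is MarkerGenotype.HET
        assert ped[cid].marker_genotype.is_homozygous
        assert phases[pid].is_resolved


# ---------------------------------------------------------------------------
# genotype tables
# ---------------------------------------------------------------------------

def test_table_fixture_rows():
    fx = make_table1_fixture()
    tr = identify_transmitters(fx.pedigree)
    lines = trace_to_sources(fx.pedigree, tr)
    risk = classify_risk(fx.pedigree, lines)
    tables = genotype_tables_by_group(
        fx.pedigree, lines, risk, extra_groups=fx.extra_groups
    )
    assert (tables["line1_cases"].hom, tables["line1_cases"].het,
            tables["line1_cases"].wt) == (10, 13, 0)
    assert (tables["line2_cases"].hom, tables["line2_cases"].het,
            tables["line2_cases"].wt) == (6, 8, 10)
    assert (tables["normal_by_pedigree"].hom, tables["normal_by_pedigree"].het,
            tables["normal_by_pedigree"].wt) == (5, 16, 10)


def test_empty_group_counts():
    ped = build_pedigree([{"id": "x", "affection": UNAFF, "marker_genotype": HOM}])
    tr = identify_transmitters(ped)
    lines = trace_to_sources(ped, tr)
    risk = classify_risk(ped, lines)
    tables = genotype_tables_by_group(
        ped, lines, risk, extra_groups={"empty": []}
    )
    c = tables["empty"]
    assert (c.hom, c.het, c.wt, c.total) == (0, 0, 0, 0)


def test_untyped_dogs_excluded(small_sim):
    ped, _, _ = small_sim
    for iid in list(ped.ids())[:10]:
        ped[iid].marker_genotype = MarkerGenotype.UNTYPED
    tr = identify_transmitters(ped)
    lines = trace_to_sources(ped, tr)
    risk = classify_risk(ped, lines)
    tables = genotype_tables_by_group(ped, lines, risk)
    n_typed = sum(1 for i in ped.ids() if ped[i].marker_genotype.is_typed)
    assert sum(t.total for t in tables.values()) <= n_typed
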