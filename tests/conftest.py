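"""Shared fixtures: small hand-built pedigrees and simulator shortcuts."""

from __future__ import annotations

import pytest

from pedilink.pedigree_core import (
    Affection,
    Individual,
    MarkerGenotype,
    Pedigree,
    Sex,
)
from pedilink.synthetic_data import SimConfig, simulate


def build_pedigree(rows):
    """rows: iterable of dicts passed to Individual."""
    return Pedigree(Individual(**r) for r in rows)


M, F = Sex.MALE, Sex.FEMALE
AFF, UNAFF = Affection.AFFECTED, Affection.UNAFFECTED
HOM, HET, WT = MarkerGenotype.HOM, MarkerGenotype.HET, MarkerGenotype.WT


@pytest.fixture
def minimal_family():
    """Founder pair plus one offspring."""
    return build_pedigree(
        [
            {"id": "sire1", "sex": M},
            {"id": "dam1", "sex": F},
            {"id": "kid1", "sire_id": "sire1", "dam_id": "dam1", "sex": M},
        ]
    )


@pytest.fixture
def fullsib_mating():
    """Founder pair -> two full sibs -> their offspring (F = 0.25)."""
    return build_pedigree(
        [
            {"id": "p", "sex": M},
            {"id": "q", "sex": F},
            {"id": "s1", "sire_id": "p", "dam_id": "q", "sex": M},
            {"id": "s2", "sire_id": "p", "dam_id": "q", "sex": F},
            {"id": "x", "sire_id": "s1", "dam_id": "s2"},
        ]
    )


@pytest.fixture
def halfsib_mating():
    """Shared sire, different dams -> half sibs -> offspring (F = 0.125)."""
    return build_pedigree(
        [
            {"id": "p", "sex": M},
            {"id": "q", "sex": F},
            {"id": "r", "sex": F},
            {"id": "s1", "sire_id": "p", "dam_id": "q", "sex": M},
            {"id": "s2", "sire_id": "p", "dam_id": "r", "sex": F},
            {"id": "x", "sire_id": "s1", "dam_id": "s2"},
        ]
    )


@pytest.fixture
def single_import_line():
    """Import A whose grandson B produced affected pups with two mates;
    the toy counterpart of a one-source line of descent."""
    rows = [
        {"id": "A", "sex": M, "affection": UNAFF, "is_import": True},
        {"id": "ax", "sex": F},
        {"id": "P", "sire_id": "A", "dam_id": "ax", "sex": M, "affection": UNAFF},
        {"id": "px", "sex": F},
        {"id": "B", "sire_id": "P", "dam_id": "px", "sex": M, "affection": UNAFF},
        {"id": "m1", "sex": F},
        {"id": "m2", "sex": F},
        {"id": "c1", "sire_id": "B", "dam_id": "m1", "affection": AFF},
        {"id": "c2", "sire_id": "B", "dam_id": "m1", "affection": UNAFF},
        {"id": "c3", "sire_id": "B", "dam_id": "m2", "affection": AFF},
    ]
    return build_pedigree(rows)


@pytest.fixture
def two_import_line():
    """Imports G and H heading chains that join: one line, sources {G, H}."""
    rows = [
        {"id": "G", "sex": M, "affection": UNAFF, "is_import": True},
        {"id": "H", "sex": M, "affection": UNAFF, "is_import": True},
        {"id": "g1", "sex": F},
        {"id": "g2", "sex": F},
        {"id": "h1", "sex": F},
        {"id": "h2", "sex": F},
        {"id": "ga", "sire_id": "G", "dam_id": "g1", "affection": AFF},
        {"id": "gb", "sire_id": "G", "dam_id": "g2", "affection": AFF},
        {"id": "J", "sire_id": "G", "dam_id": "g1", "sex": M, "affection": UNAFF},
        {"id": "ha", "sire_id": "H", "dam_id": "h1", "affection": AFF},
        {"id": "hb", "sire_id": "H", "dam_id": "h2", "affection": AFF},
        {"id": "K", "sire_id": "H", "dam_id": "h1", "sex": F, "affection": UNAFF},
        {"id": "jk1", "sire_id": "J", "dam_id": "K", "affection": AFF},
        {"id": "jk2", "sire_id": "J", "dam_id": "K", "affection": AFF},
    ]
    return build_pedigree(rows)


@pytest.fixture
def sim_factory():
    def _run(**kwargs):
        return simulate(SimConfig(**kwargs))

    return _run


@pytest.fixture
def small_sim(sim_factory):
    """Modest default gene drop with ground truth."""
    return sim_factory(seed=11, theta=0.1, penetrance=0.4, generations=3,
                       n_founders=24, marker_mut_freq=0.4)
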