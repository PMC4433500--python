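"""Segregation-ratio penetrance estimation for a dominant disease allele.

Offspring of a carrier x clear mating are expected to inherit the disease
allele with probability 1/2, so the observed affected fraction among such
offspring estimates penetrance/2.  Carrier x carrier matings are excluded
(the expected carrier fraction is no longer 1/2 and the fate of disease
homozygotes is unknown).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional

from pedilink.descent_tracing import RiskClass, TransmitterCall
from pedilink.linkage_inference import CarrierAssignment
from pedilink.pedigree_core import Pedigree


@dataclass(frozen=True)
class SegregationSummary:
    n_offspring_of_carrier_x_clear: int
    n_affected: int
    observed_fraction: Optional[float]
    expected_carrier_fraction: float
    penetrance_estimate: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]

    @property
    def empty(self) -> bool:
        return self.n_offspring_of_carrier_x_clear == 0

    def to_dict(self) -> dict:
        return {
            "n_offspring_of_carrier_x_clear": self.n_offspring_of_carrier_x_clear,
            "n_affected": self.n_affected,
            "observed_fraction": self.observed_fraction,
            "expected_carrier_fraction": self.expected_carrier_fraction,
            "penetrance_estimate": self.penetrance_estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
        }


def wilson_interval(k: int, n: int, z: float = 1.959963984540054) -> tuple[float, float]:
    """95% Wilson score interval for a binomial proportion."""
    if n == 0:
        raise ValueError("n must be positive")
    p = k / n
    denom = 1 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = (z / denom) * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n))
    return max(0.0, centre - half), min(1.0, centre + half)


def segregation_summary(
    ped: Pedigree,
    carriers: CarrierAssignment,
    risk: RiskClass,
) -> SegregationSummary:
    """Penetrance estimate from offspring of carrier x clear matings.

    penetrance = min(1, 2 * affected fraction); the Wilson 95% CI on the
    fraction is doubled and clipped the same way.  With no qualifying
    matings an explicit empty summary is returned.
    """
    n_off = n_aff = 0
    for iid in ped.ids():
        sire, dam = ped.parents_of(iid)
        if sire is None or dam is None:
            continue
        pair = (carriers.is_carrier(sire), carriers.is_carrier(dam))
        if pair == (True, True):
            continue  # carrier x carrier excluded
        if True not in pair:
            continue
        clear_side = dam if pair[0] else sire
        if not risk.is_clear(clear_side):
            continue  # unknown-status mate: not a qualifying mating
        n_off += 1
        if ped[iid].is_affected:
            n_aff += 1

    if n_off == 0:
        return SegregationSummary(0, 0, None, 0.5, None, None, None)
    frac = n_aff / n_off
    lo, hi = wilson_interval(n_aff, n_off)
    return SegregationSummary(
        n_offspring_of_carrier_x_clear=n_off,
        n_affected=n_aff,
        observed_fraction=frac,
        expected_carrier_fraction=0.5,
        penetrance_estimate=min(1.0, 2.0 * frac),
        ci_low=min(1.0, 2.0 * lo),
        ci_high=min(1.0, 2.0 * hi),
    )


def transmitter_expression_report(
    ped: Pedigree, transmitters: Iterable[TransmitterCall]
) -> dict:
    """How often transmitter dogs themselves express the disease.

    With low penetrance, parents proven to carry the allele through their
    affected offspring are themselves seldom diagnosed; the affected
    fraction among transmitters is a descriptive lower bound on penetrance
    over the follow-up achieved.
    """
    tids = sorted(t.id for t in transmitters if t.is_transmitter)
    producers = [
        i for i in tids
        if any(t.id == i and t.basis != "affected_self" for t in transmitters)
    ]
    affected = [i for i in tids if ped[i].is_affected]
    onsets = {
        i: ped[i].onset_age_years
        for i in affected
        if ped[i].onset_age_years is not None
    }
    return {
        "n_transmitters": len(tids),
        "n_unaffected_producers": len(producers),
        "n_affected": len(affected),
        "fraction_affected": len(affected) / len(tids) if tids else None,
        "onset_ages": onsets,
    }
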