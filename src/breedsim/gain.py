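"""Adjusted fitness, genetic gain per cycle/year, and closed-form oracles.

The fitness of a population is its mean grain-yield (GY) genotypic value
``F``. To compare populations on a common 0-100 scale it is rescaled between
the genotypic values of the two extreme target genotypes, ``TG_l`` (every
effect locus fixed for the decreasing allele) and ``TG_h`` (every effect
locus fixed for the increasing allele):

    F_ad = 100 * (F - TG_l) / (TG_h - TG_l)

Genetic gain per cycle is the difference in adjusted fitness before (the F2
prior to any selection) and after (the selected target lines) one breeding
cycle; gain per year divides by the cycle length — 2 years for F2-DH (one
year to the F2, one for DH production), 3 years for RIL and modified SSD.

The module also carries the independence-approximation oracles used to
validate the simulator: with k independently segregating loci, enrichment
retains a fraction (3/4)^k of the F2, a DH line from a retained plant is a
full target with probability (2/3)^k, and an F6 plant descending from the
retained F2 is a full target with probability (31/48)^k per locus chain
(1/3 + (2/3) * (15/32), the homozygous-target probability after four
further selfing generations conditional on enrichment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genetics import LinkageMap, Population, genotypic_values
from .strategies import ReplicateSet

#: breeding-cycle length in years (two glasshouse generations per year; one
#: year for DH production; one field generation per year otherwise)
YEARS_PER_CYCLE = {"F2DH": 2, "RIL": 3, "MSSD": 3}


def extreme_target_values(lmap: LinkageMap, trait: str = "GY",
                          environments: str | Sequence[str] | None = None,
                          baseline: float = 0.0) -> tuple[float, float]:
    """(TG_l, TG_h): genotypic values of the two extreme target genotypes.

    TG_h fixes the effect-increasing allele at every locus with an effect on
    ``trait``; TG_l fixes the decreasing allele. Effects are averaged across
    environments unless a single environment (or subset) is requested.
    """
    _, eff = lmap.effect_vector(trait, environments)
    if eff.size == 0:
        raise ValueError(f"no loci with effects on trait {trait!r}")
    span = float(np.abs(eff).sum())
    return baseline - span, baseline + span


def adjusted_fitness(values: np.ndarray | Population | float, tg_l: float, tg_h: float,
                     trait: str = "GY",
                     environments: str | Sequence[str] | None = None) -> float:
    """Population fitness rescaled to 0-100 between the extreme targets."""
    if tg_h <= tg_l:
        raise ValueError("TG_h must exceed TG_l")
    if isinstance(values, Population):
        values = genotypic_values(values, trait, environments)
    f = float(np.mean(values))
    return 100.0 * (f - tg_l) / (tg_h - tg_l)


@dataclass(frozen=True)
class GainReport:
    """Genetic gain of one strategy over replicates, on the adjusted scale."""

    strategy: str
    f_before: float
    f_after: float
    tg_l: float
    tg_h: float
    f_ad_before: float
    f_ad_after: float
    gain_per_cycle: float
    years_per_cycle: int
    gain_per_year: float


def genetic_gain(reps: ReplicateSet, tg_l: float, tg_h: float) -> GainReport:
    """Mean gain per cycle and per year over replicates.

    Per replicate, the "before" fitness is the F2 mean GY genotypic value
    and the "after" fitness the mean over the selected target lines.
    Replicates with zero target lines leave the population unchanged and
    contribute zero gain.
    """
    if tg_h <= tg_l:
        raise ValueError("TG_h must exceed TG_l")
    scale = 100.0 / (tg_h - tg_l)
    f_before = reps.f_before
    f_after = np.where(np.isnan(reps.f_after), f_before, reps.f_after)
    ad_before = (f_before - tg_l) * scale
    ad_after = (f_after - tg_l) * scale
    gain = ad_after - ad_before
    years = YEARS_PER_CYCLE[reps.strategy]
    return GainReport(
        strategy=reps.strategy,
        f_before=float(np.mean(f_before)),
        f_after=float(np.mean(f_after)),
        tg_l=tg_l,
        tg_h=tg_h,
        f_ad_before=float(np.mean(ad_before)),
        f_ad_after=float(np.mean(ad_after)),
        gain_per_cycle=float(np.mean(gain)),
        years_per_cycle=years,
        gain_per_year=float(np.mean(gain)) / years,
    )


@dataclass(frozen=True)
class AnalyticExpectation:
    """Closed-form expectations under the independence approximation."""

    strategy: str
    k: int
    census: int
    retained: float
    targets: float


#: per-locus probability an F6 plant is the target homozygote, given that its
#: F2 ancestor survived enrichment: 1/3 + (2/3) * (15/32)
F6_TARGET_PER_LOCUS = 31.0 / 48.0
#: per-locus probability a DH from a retained F2 plant is the target homozygote
DH_TARGET_PER_LOCUS = 2.0 / 3.0
#: per-locus F2 enrichment retention probability
RETENTION_PER_LOCUS = 3.0 / 4.0


def analytic_expectations(strategy: str, k: int, census: int) -> AnalyticExpectation:
    """Expected retained-F2 and final target counts for k independent loci.

    ``census`` is the F2 size for the retained expectation and the
    population size before final selection for the target expectation
    (identical in the study conditions for F2-DH and RIL).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    if census < 1:
        raise ValueError("census must be >= 1")
    retained = census * RETENTION_PER_LOCUS ** k
    if strategy == "F2DH":
        targets = census * DH_TARGET_PER_LOCUS ** k
    elif strategy in ("RIL", "MSSD"):
        targets = census * F6_TARGET_PER_LOCUS ** k
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return AnalyticExpectation(strategy, k, census, retained, targets)
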