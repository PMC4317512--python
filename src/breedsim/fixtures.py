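"""Packaged study fixtures and a synthetic cross generator.

The packaged fixture reproduces the published 23-locus selection panel: the
genotype grid of the five DH parents (plus the Avalon and Cadenza origin
patterns), the designed target genotype, a default linkage map, and an
additive-effect table in which every row is flagged ``paper`` (a published
magnitude) or ``synthetic`` (a package-chosen stand-in for a value that was
never published).

Map positions are package defaults: chromosome assignments follow the locus
names and the published gene locations (Yr6 on 7B, Yr7 on 2B, Sbm1 on 5D,
Vrn-A1 on 5A), while cM spacings — not printed anywhere — were fixed once so
the co-located 5A group exerts the mild repulsion drag the study observed,
and are documented in the methods note. They must not be read as measured
positions.

:func:`generate_synthetic_cross` builds fully synthetic fixtures of the same
shape (homozygous parents, a transgressive target, effects at realistic
magnitudes) for testing at arbitrary locus counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as bio
from .genetics import (
    ALLELE_CHAR,
    LineGenotype,
    LinkageMap,
    Locus,
    TargetGenotype,
    TraitEffect,
)

#: published study conditions per cross: (parent 1, parent 2, F2 size, final size)
CROSS_CONDITIONS = {
    "DH61xDH182": ("DH61", "DH182", 2000, 2000),
    "DH27xDH61": ("DH27", "DH61", 3000, 3000),
    "DH109xDH160": ("DH109", "DH160", 5000, 5000),
}
#: F2 size used by the modified SSD strategy
MSSD_F2_SIZE = 10_000

#: segregating-locus counts the packaged grid must reproduce
_EXPECTED_SEGREGATING = {"DH61xDH182": 13, "DH27xDH61": 15, "DH109xDH160": 16}


class FixtureIntegrityError(RuntimeError):
    """The packaged fixture failed its internal consistency checks."""


@dataclass
class FixtureSet:
    """A complete simulation input: map, homozygous parents, target, effects."""

    map: LinkageMap
    parents: dict[str, LineGenotype]
    target: TargetGenotype
    effects: pd.DataFrame  # locus_id/trait/environment/additive_effect/increasing_parent/provenance

    def segregating_loci(self, p1: str, p2: str) -> list[str]:
        a, b = self.parents[p1], self.parents[p2]
        diff = a.haplotypes[0] != b.haplotypes[0]
        return [l.id for l, d in zip(self.map.loci, diff) if d]


def _data_path(name: str) -> Path:
    return Path(str(resources.files("breedsim").joinpath("data", name)))


def load_study_fixture() -> FixtureSet:
    """The packaged 23-locus panel: five DH parents, origin patterns, target.

    Raises :class:`FixtureIntegrityError` if the packaged grid has been
    altered: parents must be fully homozygous and the three study crosses
    must segregate at exactly 13, 15 and 16 target loci.
    """
    effects = bio.read_effect_table(_data_path("study_effects.tsv"))
    lmap = bio.read_map_table(_data_path("study_map.tsv"), effects)
    parents = bio.read_genotype_table(_data_path("study_genotypes.tsv"), lmap)
    target = bio.read_target_table(_data_path("study_target.tsv"))
    fix = FixtureSet(lmap, parents, target, effects)

    for name, line in parents.items():
        if not line.is_homozygous():
            raise FixtureIntegrityError(f"parent {name} is not fully homozygous")
    for cross, (p1, p2, *_rest) in CROSS_CONDITIONS.items():
        n = len(fix.segregating_loci(p1, p2))
        if n != _EXPECTED_SEGREGATING[cross]:
            raise FixtureIntegrityError(
                f"cross {cross}: expected {_EXPECTED_SEGREGATING[cross]} segregating "
                f"target loci, packaged table gives {n}")
    try:
        target.validate(lmap)
    except KeyError as exc:  # pragma: no cover - packaged data
        raise FixtureIntegrityError(str(exc)) from exc
    return fix


def load_scenario_effects() -> pd.DataFrame:
    """Effect table of the 14 GY/PH/EM prediction loci (MET + per-year rows).

    Per-year rows are synthetic deviations around the multi-environment
    effects (flagged as such); the 2006 season is constructed as adverse for
    grain yield.
    """
    return bio.read_effect_table(_data_path("scenario_effects.tsv"))


def load_ideal_genotypes() -> pd.DataFrame:
    """Nine synthetic ideal-genotype reconstructions over the 14 scenario loci.

    The study's example lines were never published in full; these
    reconstructions satisfy the stated constraints (all
    favourable yield alleles, stature and flowering close to Avalon, and
    exactly three lines discordant at the 3A height/flowering pair).
    """
    return pd.read_csv(_data_path("ideal_genotypes_synthetic.tsv"), sep="\t",
                       dtype=str).set_index("line")


# ---------------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------------

LINKAGE_PROFILES = ("independent", "clustered")


def generate_synthetic_cross(k_loci: int,
                             n_chromosomes: int | None = None,
                             linkage_profile: str = "independent",
                             effect_scale: float = 1.0,
                             rng: np.random.Generator | None = None,
                             cluster_size: int = 5,
                             cluster_gap_cM: float = 10.0) -> FixtureSet:
    """A synthetic two-parent cross with k segregating biallelic loci.

    ``linkage_profile``:

    * ``"independent"`` — every locus on its own chromosome (free
      recombination), so closed-form expectations like the (3/4)^k
      enrichment retention hold exactly;
    * ``"clustered"`` — the first ``cluster_size`` loci sit on one
      chromosome at ``cluster_gap_cM`` intervals, mimicking a co-located
      QTL group; the rest stay independent.

    Parents are fully homozygous and opposite at every locus (parent P1
    carries the Avalon-origin allele throughout). The target mixes both
    parents' alleles (alternating), as designed targets generally must.
    Effects are drawn at realistic magnitudes — grain yield 0.1-0.4 t/ha
    scaled so the largest equals ``0.37 * effect_scale``, plant height 1-5
    cm, ear emergence 0.5-3 % — and all rows are flagged synthetic.
    """
    if k_loci < 1:
        raise ValueError("k_loci must be >= 1")
    if linkage_profile not in LINKAGE_PROFILES:
        raise ValueError(f"linkage_profile must be one of {LINKAGE_PROFILES}")
    if linkage_profile == "clustered" and cluster_size > k_loci:
        raise ValueError("cluster_size cannot exceed k_loci")
    rng = rng or np.random.default_rng()

    if linkage_profile == "independent":
        chroms = [f"C{i + 1:02d}" for i in range(k_loci)]
        pos = [0.0] * k_loci
    else:
        chroms = ["C01"] * cluster_size + [f"C{i + 2:02d}" for i in range(k_loci - cluster_size)]
        pos = [i * cluster_gap_cM for i in range(cluster_size)] + [0.0] * (k_loci - cluster_size)
    if n_chromosomes is not None and len(set(chroms)) != n_chromosomes:
        raise ValueError(
            f"{linkage_profile!r} profile with k={k_loci} implies {len(set(chroms))} "
            f"chromosomes, not {n_chromosomes}")

    # trait assignment round-robin with field-scale magnitudes
    traits = ("GY", "PH", "EM")
    lo_hi = {"GY": (0.1, 0.4), "PH": (1.0, 5.0), "EM": (0.5, 3.0)}
    raw: list[tuple[str, float, str]] = []
    for i in range(k_loci):
        t = traits[i % 3]
        a = float(rng.uniform(*lo_hi[t]))
        inc = "A" if rng.random() < 0.5 else "C"
        raw.append((t, a, inc))
    gy = [i for i, r in enumerate(raw) if r[0] == "GY"]
    if gy:  # anchor the largest GY effect at 0.37 * effect_scale
        top = max(gy, key=lambda i: raw[i][1])
        scale = 0.37 * effect_scale / raw[top][1]
        raw = [(t, a * scale, inc) if t == "GY" else (t, a * effect_scale, inc)
               for (t, a, inc) in raw]

    loci = [Locus(f"L{i + 1:02d}", chroms[i], pos[i],
                  (TraitEffect(raw[i][0], "MET", raw[i][1], raw[i][2]),))
            for i in range(k_loci)]
    lmap = LinkageMap(loci)

    hap1 = np.zeros((2, k_loci), dtype=np.int8)      # all Avalon-origin
    hap2 = np.ones((2, k_loci), dtype=np.int8)       # all Cadenza-origin
    # map order may differ from construction order; align via index
    parents = {"P1": LineGenotype(hap1, lmap), "P2": LineGenotype(hap2, lmap)}
    target = TargetGenotype({loc.id: ALLELE_CHAR[i % 2]
                             for i, loc in enumerate(lmap.loci)})
    rows = [(loc.id, e.trait, e.environment, e.effect, e.increasing, "synthetic")
            for loc in lmap.loci for e in loc.effects]
    effects = pd.DataFrame(rows, columns=bio.LOCUS_COLUMNS)
    return FixtureSet(lmap, parents, target, effects)
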