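"""Genome representation, meiosis and genotype-to-phenotype mapping.

Lines are modelled at a small set of biallelic loci whose alleles are
identified by parental origin: ``"A"`` (Avalon-derived) or ``"C"``
(Cadenza-derived). Genotypes are phased: every line carries two haplotypes
per chromosome, stored as one int8 array of shape ``(2, n_loci)`` aligned to
a :class:`LinkageMap`. Fully inbred material (parents, doubled haploids) has
identical haplotypes at every locus.

Meiosis follows the Haldane mapping model: no crossover interference, so the
recombination fraction between loci ``d`` centimorgans apart is
``r = (1 - exp(-2 d / 100)) / 2`` and a gamete is a first-order Markov
mosaic of the two parental haplotypes along each chromosome.

Phenotypes are purely additive. A locus effect is stated as the additive
effect ``a`` (half the difference between the two homozygotes) plus the
parental origin of the effect-increasing allele; heterozygotes contribute
zero (no dominance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

#: integer codes for allele (parental) origin
AVALON: int = 0
CADENZA: int = 1

ALLELE_CODE: dict[str, int] = {"A": AVALON, "C": CADENZA}
ALLELE_CHAR: dict[int, str] = {AVALON: "A", CADENZA: "C"}


def recombination_fraction(d: float) -> float:
    """Map distance in cM -> recombination fraction (Haldane, no interference).

    ``d = 0`` gives 0 (coincident loci never recombine); the fraction
    approaches the free-recombination limit of 0.5 as ``d`` grows. Loci on
    different chromosomes segregate with an effective fraction of 0.5, which
    is handled by the map, not by this function.
    """
    if d < 0:
        raise ValueError(f"map distance must be non-negative, got {d}")
    return 0.5 * (1.0 - math.exp(-2.0 * d / 100.0))


@dataclass(frozen=True)
class TraitEffect:
    """Additive effect of one locus on one trait in one environment.

    ``increasing`` names the parental origin ("A" or "C") whose homozygote
    shifts the trait by ``+effect``; the opposite homozygote shifts it by
    ``-effect`` and heterozygotes contribute nothing.
    """

    trait: str
    environment: str
    effect: float
    increasing: str

    def __post_init__(self) -> None:
        if self.increasing not in ALLELE_CODE:
            raise ValueError(f"increasing parent must be 'A' or 'C', got {self.increasing!r}")

    @property
    def effect_of_avalon(self) -> float:
        """Signed effect of the Avalon homozygote relative to the midpoint."""
        return self.effect if self.increasing == "A" else -self.effect


@dataclass(frozen=True)
class Locus:
    """A biallelic map position, optionally with per-trait/environment effects.

    Pleiotropy is expressed as multiple trait entries on one locus; loci used
    only for marker-assisted selection (disease resistance genes, root QTL
    without published magnitudes) simply carry no effects.
    """

    id: str
    chromosome: str
    pos_cM: float
    effects: tuple[TraitEffect, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.pos_cM < 0:
            raise ValueError(f"locus {self.id}: position must be >= 0, got {self.pos_cM}")
        keys = [(e.trait, e.environment) for e in self.effects]
        if len(keys) != len(set(keys)):
            raise ValueError(f"locus {self.id}: duplicate (trait, environment) effect entries")


class LinkageMap:
    """Ordered collection of loci grouped by chromosome, sorted by position.

    The map fixes the locus order used by every genotype array and
    precomputes the per-interval haplotype switch probabilities used by the
    meiosis sampler: the Haldane fraction within a chromosome, and 0.5 at
    each chromosome start (a fair, independent choice of haplotype).
    """

    def __init__(self, loci: Iterable[Locus]):
        loci = list(loci)
        if not loci:
            raise ValueError("a linkage map needs at least one locus")
        # stable sort: keep first-appearance chromosome order, sort by position within
        chrom_order = {}
        for loc in loci:
            chrom_order.setdefault(loc.chromosome, len(chrom_order))
        loci.sort(key=lambda l: (chrom_order[l.chromosome], l.pos_cM))
        ids = [l.id for l in loci]
        if len(ids) != len(set(ids)):
            raise ValueError("locus ids must be unique")
        self.loci: tuple[Locus, ...] = tuple(loci)
        self.index: dict[str, int] = {l.id: i for i, l in enumerate(loci)}
        self.chromosomes: tuple[str, ...] = tuple(chrom_order)
        pswitch = np.empty(len(loci))
        for i, loc in enumerate(loci):
            if i == 0 or loc.chromosome != loci[i - 1].chromosome:
                pswitch[i] = 0.5
            else:
                pswitch[i] = recombination_fraction(loc.pos_cM - loci[i - 1].pos_cM)
        self._pswitch = pswitch

    # -- basic introspection -------------------------------------------------
    def __len__(self) -> int:
        return len(self.loci)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_ids(self) -> list[str]:
        return [l.id for l in self.loci]

    @property
    def switch_probabilities(self) -> np.ndarray:
        """Per-locus haplotype switch probability used by the gamete sampler."""
        return self._pswitch.copy()

    def subset(self, ids: Sequence[str]) -> "LinkageMap":
        """New map over the given loci (positions/chromosomes retained)."""
        return LinkageMap(self.loci[self.index[i]] for i in ids)

    # -- effects -------------------------------------------------------------
    def effect_loci(self, trait: str, environment: str | None = None) -> list[Locus]:
        """Loci with at least one effect on ``trait`` (optionally in ``environment``)."""
        out = []
        for loc in self.loci:
            for e in loc.effects:
                if e.trait == trait and (environment is None or e.environment == environment):
                    out.append(loc)
                    break
        return out

    def effect_vector(self, trait: str, environments: str | Sequence[str] | None = None
                      ) -> tuple[np.ndarray, np.ndarray]:
        """(locus indices, Avalon-signed additive effects) for a trait.

        With a single environment label, per-environment effects are used;
        with a list, or ``None`` (= every environment present), effects are
        averaged across those environments locus by locus. Loci lacking any
        matching entry are excluded, so an unknown trait/environment yields
        empty arrays rather than zeros.
        """
        if isinstance(environments, str):
            environments = [environments]
        idx: list[int] = []
        eff: list[float] = []
        for i, loc in enumerate(self.loci):
            vals = [e.effect_of_avalon for e in loc.effects
                    if e.trait == trait
                    and (environments is None or e.environment in environments)]
            if vals:
                idx.append(i)
                eff.append(float(np.mean(vals)))
        return np.asarray(idx, dtype=np.intp), np.asarray(eff, dtype=float)


# ---------------------------------------------------------------------------
# genotype containers
# ---------------------------------------------------------------------------

class LineGenotype:
    """One line: two phased haplotypes aligned to a linkage map."""

    def __init__(self, haplotypes: np.ndarray, lmap: LinkageMap):
        haplotypes = np.asarray(haplotypes, dtype=np.int8)
        if haplotypes.shape != (2, lmap.n_loci):
            raise ValueError(
                f"haplotypes must have shape (2, {lmap.n_loci}), got {haplotypes.shape}")
        if not np.isin(haplotypes, (AVALON, CADENZA)).all():
            raise ValueError("alleles must be coded 0 (A) or 1 (C)")
        self.haplotypes = haplotypes
        self.map = lmap

    @classmethod
    def from_codes(cls, codes: Mapping[str, str], lmap: LinkageMap) -> "LineGenotype":
        """Build from {locus_id: 'AA' | 'CC' | 'AC'} genotype strings."""
        haps = np.zeros((2, lmap.n_loci), dtype=np.int8)
        for lid, code in codes.items():
            i = lmap.index[lid]
            haps[0, i] = ALLELE_CODE[code[0]]
            haps[1, i] = ALLELE_CODE[code[1]]
        return cls(haps, lmap)

    def is_homozygous(self) -> bool:
        return bool((self.haplotypes[0] == self.haplotypes[1]).all())

    def heterozygous_loci(self) -> list[str]:
        het = self.haplotypes[0] != self.haplotypes[1]
        return [l.id for l, h in zip(self.map.loci, het) if h]

    def genotype_codes(self) -> dict[str, str]:
        """{locus_id: 'AA'|'AC'|'CC'} with heterozygotes normalised to 'AC'."""
        out = {}
        for i, loc in enumerate(self.map.loci):
            a, b = sorted(self.haplotypes[:, i])
            out[loc.id] = ALLELE_CHAR[a] + ALLELE_CHAR[b]
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LineGenotype):
            return NotImplemented
        return self.map is other.map and np.array_equal(self.haplotypes, other.haplotypes)


class Population:
    """A generation of lines: int8 genotype array of shape (n, 2, n_loci)."""

    def __init__(self, genotypes: np.ndarray, lmap: LinkageMap):
        genotypes = np.asarray(genotypes, dtype=np.int8)
        if genotypes.ndim != 3 or genotypes.shape[1] != 2 or genotypes.shape[2] != lmap.n_loci:
            raise ValueError(f"genotypes must have shape (n, 2, {lmap.n_loci})")
        self.genotypes = genotypes
        self.map = lmap

    @classmethod
    def from_lines(cls, lines: Sequence[LineGenotype]) -> "Population":
        if not lines:
            raise ValueError("empty line list")
        lmap = lines[0].map
        return cls(np.stack([l.haplotypes for l in lines]), lmap)

    @classmethod
    def empty(cls, lmap: LinkageMap) -> "Population":
        return cls(np.zeros((0, 2, lmap.n_loci), dtype=np.int8), lmap)

    def __len__(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n(self) -> int:
        return len(self)

    def line(self, i: int) -> LineGenotype:
        return LineGenotype(self.genotypes[i], self.map)

    def subset(self, index: np.ndarray) -> "Population":
        return Population(self.genotypes[index], self.map)

    def is_homozygous(self) -> np.ndarray:
        """Per-line: homozygous at every locus."""
        return (self.genotypes[:, 0, :] == self.genotypes[:, 1, :]).all(axis=1)

    def allele_dosage(self) -> np.ndarray:
        """Per line and locus, count of Cadenza-origin alleles (0, 1 or 2)."""
        return self.genotypes.sum(axis=1)


# ---------------------------------------------------------------------------
# meiosis and generation advance
# ---------------------------------------------------------------------------

def _gametes_from(genotypes: np.ndarray, pswitch: np.ndarray,
                  rng: np.random.Generator) -> np.ndarray:
    """One gamete per row of ``genotypes`` ((n, 2, L) -> (n, L)).

    The source haplotype along each chromosome is a Markov chain: a fresh
    fair draw at each chromosome start (switch probability 0.5) and a switch
    with the Haldane recombination fraction between adjacent loci.
    """
    n, _, L = genotypes.shape
    switches = rng.random((n, L)) < pswitch
    source = np.logical_xor.accumulate(switches, axis=1)
    return np.where(source, genotypes[:, 1, :], genotypes[:, 0, :])


def sample_gamete(parent: LineGenotype, rng: np.random.Generator) -> np.ndarray:
    """A single gamete (1D allele-origin vector aligned to the parent's map)."""
    return _gametes_from(parent.haplotypes[None], parent.map.switch_probabilities, rng)[0]


def make_f1(p1: LineGenotype, p2: LineGenotype) -> LineGenotype:
    """F1 of two fully homozygous lines: one haplotype from each parent."""
    if p1.map is not p2.map and p1.map.locus_ids != p2.map.locus_ids:
        raise ValueError("parents must share a linkage map")
    if not (p1.is_homozygous() and p2.is_homozygous()):
        raise ValueError("F1 parents must be fully homozygous lines")
    return LineGenotype(np.stack([p1.haplotypes[0], p2.haplotypes[0]]), p1.map)


def make_dh(plant: LineGenotype, rng: np.random.Generator) -> LineGenotype:
    """One doubled haploid: a single sampled gamete duplicated."""
    g = sample_gamete(plant, rng)
    return LineGenotype(np.stack([g, g]), plant.map)


def make_dh_population(pop: Population, parent_index: np.ndarray,
                       rng: np.random.Generator) -> Population:
    """DH lines from ``pop``; line ``i`` is doubled from one gamete of plant
    ``parent_index[i]``."""
    parents = pop.genotypes[parent_index]
    g = _gametes_from(parents, pop.map.switch_probabilities, rng)
    return Population(np.stack([g, g], axis=1), pop.map)


def self_plant(plant: LineGenotype, rng: np.random.Generator, n_seeds: int) -> Population:
    """Self-pollinate one plant: each seed unites two independent gametes."""
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    pop = Population(np.broadcast_to(plant.haplotypes, (n_seeds, 2, plant.map.n_loci)),
                     plant.map)
    return self_population(pop, np.arange(n_seeds), rng)


def self_population(pop: Population, parent_index: np.ndarray,
                    rng: np.random.Generator) -> Population:
    """Next selfed generation; seed ``i`` comes from plant ``parent_index[i]``."""
    parents = pop.genotypes[parent_index]
    ps = pop.map.switch_probabilities
    g1 = _gametes_from(parents, ps, rng)
    g2 = _gametes_from(parents, ps, rng)
    return Population(np.stack([g1, g2], axis=1), pop.map)


# ---------------------------------------------------------------------------
# target genotypes and phenotype prediction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TargetGenotype:
    """Required homozygous allele origin at each selected locus."""

    required: Mapping[str, str]  # locus id -> "A" | "C"

    def __post_init__(self) -> None:
        bad = {a for a in self.required.values() if a not in ALLELE_CODE}
        if bad:
            raise ValueError(f"target alleles must be 'A' or 'C', got {bad}")

    def validate(self, lmap: LinkageMap) -> None:
        missing = [lid for lid in self.required if lid not in lmap.index]
        if missing:
            raise KeyError(f"target loci absent from map: {missing}")

    def arrays(self, lmap: LinkageMap) -> tuple[np.ndarray, np.ndarray]:
        """(locus indices, required allele codes) aligned to ``lmap``."""
        self.validate(lmap)
        idx = np.asarray([lmap.index[lid] for lid in self.required], dtype=np.intp)
        alleles = np.asarray([ALLELE_CODE[a] for a in self.required.values()], dtype=np.int8)
        return idx, alleles

    def restrict_to_segregating(self, p1: LineGenotype, p2: LineGenotype) -> "TargetGenotype":
        """Drop required loci at which the two (homozygous) parents agree."""
        seg = {lid for lid, h in zip(p1.map.locus_ids, p1.haplotypes[0] != p2.haplotypes[0])
               if h}
        return TargetGenotype({lid: a for lid, a in self.required.items() if lid in seg})


@dataclass(frozen=True)
class TraitPrediction:
    """Predicted genotypic value of one line for one trait/environment.

    ``value - baseline`` is the signed sum of the per-locus contributions;
    ``contributions`` lists them as (locus id, signed value). An unknown
    trait or environment yields an empty contribution tuple (value equal to
    the baseline) rather than failing silently — callers can inspect
    ``n_effect_loci``.
    """

    trait: str
    environment: str | None
    value: float
    baseline: float
    contributions: tuple[tuple[str, float], ...]

    @property
    def n_effect_loci(self) -> int:
        return len(self.contributions)


def genotypic_values(pop: Population, trait: str,
                     environments: str | Sequence[str] | None = None,
                     baseline: float = 0.0) -> np.ndarray:
    """Additive genotypic value of every line in ``pop`` for ``trait``.

    Per effect locus the contribution is ``s * a`` with ``s = +1`` for the
    homozygote of the effect-increasing origin, ``-1`` for the opposite
    homozygote and ``0`` for heterozygotes.
    """
    idx, eff = pop.map.effect_vector(trait, environments)
    if idx.size == 0:
        return np.full(pop.n, float(baseline))
    dosage = pop.genotypes[:, :, idx].sum(axis=1)  # Cadenza-allele count, (n, k)
    sign = 1 - dosage  # +1 hom Avalon, 0 het, -1 hom Cadenza
    return baseline + sign @ eff


def predict_phenotype(line: LineGenotype, trait: str,
                      environment: str | Sequence[str] | None = None,
                      baseline: float = 0.0) -> TraitPrediction:
    """Per-line phenotype prediction with per-locus contribution breakdown."""
    idx, eff = line.map.effect_vector(trait, environment)
    contribs = []
    value = float(baseline)
    for i, a in zip(idx, eff):
        dosage = int(line.haplotypes[0, i]) + int(line.haplotypes[1, i])
        s = 1 - dosage
        c = s * a
        contribs.append((line.map.loci[i].id, float(c)))
        value += c
    env_label = environment if isinstance(environment, (str, type(None))) else ",".join(environment)
    return TraitPrediction(trait=trait, environment=env_label, value=value,
                           baseline=float(baseline), contributions=tuple(contribs))
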