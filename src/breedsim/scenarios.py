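"""Large simulated-DH populations for phenotype prediction under pleiotropy.

Model: very large doubled-haploid populations are generated from the
Avalon x Cadenza F1 at the 14 grain-yield (GY), plant-height (PH) and
ear-emergence (EM) prediction loci. Two scenarios are compared:

* **scenario 1** — all 14 loci segregate independently, so every one of the
  2^14 homozygous allele-origin classes is attainable at expected frequency
  (1/2)^14;
* **scenario 2** — the co-located pairs on 2D (GY with PH) and 3A (PH with
  EM) are treated as single pleiotropic inheritance units (complete
  linkage), leaving 12 independent units and expected class frequency
  (1/2)^12; classes recombinant inside a merged pair never occur.

Phenotypes are predicted additively per environment; the packaged per-year
effect tables are synthetic deviations around the multi-environment
estimates (the published per-year analyses are not reproduced here).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genetics import (
    ALLELE_CHAR,
    ALLELE_CODE,
    LineGenotype,
    LinkageMap,
    Locus,
    Population,
    TraitEffect,
    genotypic_values,
    make_f1,
)
from .genetics import _gametes_from  # shared meiosis kernel

#: pleiotropic / completely linked pairs assumed by scenario 2
MERGED_PAIRS = (("qGY-psr-2D.1", "qPH-psr-2D"), ("qPH-psr-3A", "qEM-psr-3A"))

#: default population sizes: scenario 1 needs 200,000 individuals to contain
#: all 2^14 classes; 50,000 suffice for the 2^12 classes of scenario 2
DEFAULT_N = {1: 200_000, 2: 50_000}


@dataclass(frozen=True)
class ScenarioSpec:
    """Which loci segregate, how many individuals, and what is merged."""

    scenario: int
    n_individuals: int
    loci: tuple[str, ...]
    merges: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.scenario not in (1, 2):
            raise ValueError("scenario must be 1 or 2")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        for a, b in self.merges:
            if a not in self.loci or b not in self.loci:
                raise ValueError(f"merged pair ({a}, {b}) not in scenario loci")

    @property
    def n_units(self) -> int:
        """Independent inheritance units (merged pairs count once)."""
        return len(self.loci) - len(self.merges)


def default_spec(scenario: int, effects: pd.DataFrame,
                 n_individuals: int | None = None) -> ScenarioSpec:
    """Spec over every locus in the effect table; scenario 2 merges the
    2D GY/PH and 3A PH/EM pairs."""
    loci = tuple(dict.fromkeys(effects["locus_id"]))
    merges = MERGED_PAIRS if scenario == 2 else ()
    return ScenarioSpec(scenario, n_individuals or DEFAULT_N[scenario], loci, merges)


def build_scenario_map(spec: ScenarioSpec, effects: pd.DataFrame) -> LinkageMap:
    """Map with every locus on its own chromosome, except merged pairs which
    share a chromosome at identical positions (recombination fraction 0)."""
    chrom_of: dict[str, tuple[str, float]] = {}
    for i, (a, b) in enumerate(spec.merges):
        chrom_of[a] = (f"M{i + 1}", 0.0)
        chrom_of[b] = (f"M{i + 1}", 0.0)
    loci = []
    for j, lid in enumerate(spec.loci):
        chrom, pos = chrom_of.get(lid, (f"U{j + 1:02d}", 0.0))
        rows = effects[effects["locus_id"] == lid]
        effs = tuple(TraitEffect(r.trait, str(r.environment), float(r.additive_effect),
                                 r.increasing_parent)
                     for r in rows.itertuples())
        loci.append(Locus(lid, chrom, pos, effs))
    return LinkageMap(loci)


def founder_lines(lmap: LinkageMap) -> tuple[LineGenotype, LineGenotype]:
    """Avalon-pattern (all 'A') and Cadenza-pattern (all 'C') founders."""
    n = lmap.n_loci
    avalon = LineGenotype(np.zeros((2, n), dtype=np.int8), lmap)
    cadenza = LineGenotype(np.ones((2, n), dtype=np.int8), lmap)
    return avalon, cadenza


def simulate_sdh_population(spec: ScenarioSpec, effects: pd.DataFrame,
                            rng: np.random.Generator
                            ) -> tuple[Population, pd.DataFrame]:
    """n doubled haploids from the founder F1 plus the class-frequency table.

    Returns the population and a DataFrame with one row per observed
    homozygous allele-origin class: ``class`` (string of A/C over the
    scenario loci in spec order), ``count`` and ``frequency_pct``.
    """
    lmap = build_scenario_map(spec, effects)
    avalon, cadenza = founder_lines(lmap)
    f1 = make_f1(avalon, cadenza)
    geno = np.broadcast_to(f1.haplotypes, (spec.n_individuals, 2, lmap.n_loci))
    g = _gametes_from(geno, lmap.switch_probabilities, rng)
    pop = Population(np.stack([g, g], axis=1), lmap)
    freq = genotype_class_frequencies(pop, spec)
    return pop, freq


def genotype_class_frequencies(pop: Population, spec: ScenarioSpec) -> pd.DataFrame:
    """Frequency (percent) of each homozygous allele-origin class."""
    order = [pop.map.index[lid] for lid in spec.loci]
    hap = pop.genotypes[:, 0, :][:, order].astype(np.int64)
    k = len(order)
    codes = hap @ (1 << np.arange(k - 1, -1, -1, dtype=np.int64))
    uniq, counts = np.unique(codes, return_counts=True)
    labels = ["".join(ALLELE_CHAR[(int(c) >> s) & 1] for s in range(k - 1, -1, -1))
              for c in uniq]
    df = pd.DataFrame({"class": labels, "count": counts,
                       "frequency_pct": 100.0 * counts / pop.n})
    return df.sort_values("count", ascending=False, kind="stable").reset_index(drop=True)


def classify_by_yield(pop: Population, n_categories: int = 6,
                      environments: str | Sequence[str] | None = "MET"
                      ) -> tuple[pd.DataFrame, np.ndarray]:
    """Partition lines into equal-width GY categories; summarise PH and EM.

    Returns (summary, category index per line). A degenerate population
    (constant GY) collapses to a single category.
    """
    gy = genotypic_values(pop, "GY", environments)
    ph = genotypic_values(pop, "PH", environments)
    em = genotypic_values(pop, "EM", environments)
    lo, hi = float(gy.min()), float(gy.max())
    if hi == lo:
        cat = np.zeros(pop.n, dtype=np.intp)
        edges = np.array([lo, hi])
        n_categories = 1
    else:
        edges = np.linspace(lo, hi, n_categories + 1)
        cat = np.clip(np.searchsorted(edges, gy, side="right") - 1, 0, n_categories - 1)
    rows = []
    for c in range(n_categories):
        m = cat == c
        if not m.any():
            rows.append(dict(category=c, gy_low=edges[c], gy_high=edges[c + 1], n=0,
                             ph_min=np.nan, ph_max=np.nan, em_min=np.nan, em_max=np.nan))
            continue
        rows.append(dict(category=c, gy_low=edges[c], gy_high=edges[c + 1],
                         n=int(m.sum()),
                         ph_min=float(ph[m].min()), ph_max=float(ph[m].max()),
                         em_min=float(em[m].min()), em_max=float(em[m].max())))
    return pd.DataFrame(rows), cat


def attainable_ideal_genotypes(ideals: pd.DataFrame | Mapping[str, Mapping[str, str]],
                               spec: ScenarioSpec) -> list[str]:
    """Names of ideal genotypes attainable under the scenario's linkage.

    In scenario 2 a genotype is attainable iff, within every merged pair,
    both required alleles descend from the same parent; scenario 1 imposes
    no constraint.
    """
    if isinstance(ideals, pd.DataFrame):
        items: Iterable[tuple[str, Mapping[str, str]]] = ideals.to_dict("index").items()
    else:
        items = ideals.items()
    out = []
    for name, pattern in items:
        ok = all(pattern[a] == pattern[b] for a, b in spec.merges)
        if ok:
            out.append(name)
    return out


def predict_over_environments(pop: Population, trait: str,
                              environments: Sequence[str]
                              ) -> tuple[pd.DataFrame, list[str]]:
    """Per-environment predictions and across-environment dispersion per line.

    Environments with no effect entries for the trait are reported as absent
    (second return value) rather than imputed; the returned frame has one
    column per available environment plus ``sd`` across them.
    """
    cols: dict[str, np.ndarray] = {}
    absent: list[str] = []
    for env in environments:
        idx, _ = pop.map.effect_vector(trait, env)
        if idx.size == 0:
            absent.append(env)
            continue
        cols[env] = genotypic_values(pop, trait, env)
    df = pd.DataFrame(cols)
    if len(df.columns) > 0:
        df["sd"] = df.std(axis=1, ddof=0) if len(df.columns) > 1 else 0.0
    return df, absent
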