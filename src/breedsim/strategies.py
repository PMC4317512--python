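"""The three line-development strategies with F2-enrichment marker selection.

All three strategies start from a cross of two fully homozygous lines and
aim to recover lines homozygous for a designed target genotype at every
selected locus:

* **F2-DH** — F1 selfed to an F2, F2 enrichment by MAS, doubled haploids
  produced from the retained plants, final MAS on the DH lines.
* **RIL** — F2 enrichment, then bulk selfing from F3 to F6 (seeds of the
  retained plants are bulked; later generations are grown as bulks of
  constant census), final MAS in F6.
* **Modified SSD** — F2 enrichment under the pedigree method, three self
  seeds harvested and bulked per plant from F3 onwards while the census is
  held at the F3 size, final MAS in F6.

F2 enrichment keeps exactly those plants that carry at least one copy of the
required allele at every (segregating) target locus, i.e. it discards any
plant already homozygous for a non-target allele and therefore unable to
ever yield the target by selfing or DH production.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .genetics import (
    LineGenotype,
    LinkageMap,
    Population,
    TargetGenotype,
    genotypic_values,
    make_dh_population,
    make_f1,
    self_population,
)

STRATEGIES = ("F2DH", "RIL", "MSSD")

#: generations of selfing between the F2 and the final RIL/MSSD selection
_F2_TO_F6 = 4


@dataclass(frozen=True)
class StrategyConfig:
    """Population sizes and replication for one strategy run.

    ``f2_size`` is the F2 before enrichment; ``final_size`` the population
    grown before final selection (DH lines in F2-DH, the bulk census in
    RIL). Modified SSD ignores ``final_size``: its census is fixed by the
    enrichment outcome (three seeds per retained plant). Defaults mirror the
    study conditions for the DH61 x DH182 cross.
    """

    strategy: str
    f2_size: int = 2000
    final_size: int = 2000
    n_replicates: int = 1000
    seed: int = 0
    seeds_per_plant: int = 3  # modified SSD harvest per plant

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}, got {self.strategy!r}")
        for name in ("f2_size", "final_size", "n_replicates", "seeds_per_plant"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class StrategyRun:
    """Outcome of one replicate of a breeding strategy."""

    strategy: str
    retained_f2: int
    n_final: int
    n_targets: int
    f_before: float  # mean GY genotypic value of the F2 before any selection
    f_after: float   # mean GY genotypic value of the selected target lines (nan if none)
    final_population: Population | None = None


@dataclass
class ReplicateSet:
    """Per-replicate scalars collected over repeated strategy runs."""

    strategy: str
    retained_f2: np.ndarray
    n_final: np.ndarray
    n_targets: np.ndarray
    f_before: np.ndarray
    f_after: np.ndarray  # nan where a replicate produced no target line

    @property
    def n_replicates(self) -> int:
        return self.retained_f2.size

    def mean_se(self, values: np.ndarray) -> tuple[float, float]:
        """Mean and standard error (sample SD / sqrt(reps)); SE is nan for one rep."""
        m = float(np.mean(values))
        se = float(np.std(values, ddof=1) / np.sqrt(values.size)) if values.size > 1 else float("nan")
        return m, se


# ---------------------------------------------------------------------------
# selection operations
# ---------------------------------------------------------------------------

def enrichment_mask(pop: Population, target: TargetGenotype) -> np.ndarray:
    """Boolean mask of plants carrying >= 1 required allele at every target locus."""
    idx, alleles = target.arrays(pop.map)
    if idx.size == 0:
        return np.ones(pop.n, dtype=bool)
    g = pop.genotypes[:, :, idx]
    return ((g[:, 0, :] == alleles) | (g[:, 1, :] == alleles)).all(axis=1)


def f2_enrichment_select(pop: Population, target: TargetGenotype) -> Population:
    """Retained F2 subset after enrichment MAS (may be empty — not an error)."""
    return pop.subset(enrichment_mask(pop, target))


def count_targets(pop: Population, target: TargetGenotype) -> int:
    """Lines homozygous for the required allele at every target locus."""
    return int(target_mask(pop, target).sum())


def target_mask(pop: Population, target: TargetGenotype) -> np.ndarray:
    idx, alleles = target.arrays(pop.map)
    if idx.size == 0:
        return np.ones(pop.n, dtype=bool)
    g = pop.genotypes[:, :, idx]
    return ((g[:, 0, :] == alleles) & (g[:, 1, :] == alleles)).all(axis=1)


# ---------------------------------------------------------------------------
# strategy runners
# ---------------------------------------------------------------------------

def _start_f2(p1: LineGenotype, p2: LineGenotype, target: TargetGenotype,
              config: StrategyConfig, rng: np.random.Generator
              ) -> tuple[Population, Population, float]:
    f1 = make_f1(p1, p2)
    f1_pop = Population(np.broadcast_to(f1.haplotypes, (config.f2_size, 2, p1.map.n_loci)),
                        p1.map)
    f2 = self_population(f1_pop, np.arange(config.f2_size), rng)
    retained = f2_enrichment_select(f2, target)
    f_before = float(np.mean(genotypic_values(f2, "GY")))
    return f2, retained, f_before


def _finalise(strategy: str, retained_n: int, final_pop: Population | None,
              target: TargetGenotype, f_before: float,
              keep_population: bool) -> StrategyRun:
    if final_pop is None or final_pop.n == 0:
        return StrategyRun(strategy, retained_n, 0, 0, f_before, float("nan"),
                           final_pop if keep_population else None)
    mask = target_mask(final_pop, target)
    n_targets = int(mask.sum())
    if n_targets:
        f_after = float(np.mean(genotypic_values(final_pop.subset(mask), "GY")))
    else:
        f_after = float("nan")
    return StrategyRun(strategy, retained_n, final_pop.n, n_targets, f_before, f_after,
                       final_pop if keep_population else None)


def run_f2_dh(p1: LineGenotype, p2: LineGenotype, target: TargetGenotype,
              config: StrategyConfig, rng: np.random.Generator,
              keep_population: bool = False) -> StrategyRun:
    """F2-DH: enrichment in F2, DH production, final MAS on the DH lines.

    The ``final_size`` DH lines are allocated round-robin across the
    retained F2 plants, so every retained plant contributes a near-equal
    number of gametes.
    """
    _, retained, f_before = _start_f2(p1, p2, target, config, rng)
    if retained.n == 0:
        return _finalise("F2DH", 0, None, target, f_before, keep_population)
    parent_index = np.arange(config.final_size) % retained.n
    dh = make_dh_population(retained, parent_index, rng)
    return _finalise("F2DH", retained.n, dh, target, f_before, keep_population)


def run_ril(p1: LineGenotype, p2: LineGenotype, target: TargetGenotype,
            config: StrategyConfig, rng: np.random.Generator,
            keep_population: bool = False) -> StrategyRun:
    """RIL: enrichment in F2, bulk selfing F3..F6 at constant census, MAS in F6.

    Retained F2 plants contribute equally to the F3 bulk; from F4 onwards
    each plant descends from a uniformly drawn plant of the previous
    generation (seeds bulked without pedigree).
    """
    _, retained, f_before = _start_f2(p1, p2, target, config, rng)
    if retained.n == 0:
        return _finalise("RIL", 0, None, target, f_before, keep_population)
    gen = self_population(retained, np.arange(config.final_size) % retained.n, rng)
    for _ in range(_F2_TO_F6 - 1):
        gen = self_population(gen, rng.integers(0, gen.n, gen.n), rng)
    return _finalise("RIL", retained.n, gen, target, f_before, keep_population)


def run_modified_ssd(p1: LineGenotype, p2: LineGenotype, target: TargetGenotype,
                     config: StrategyConfig, rng: np.random.Generator,
                     keep_population: bool = False) -> StrategyRun:
    """Modified SSD: pedigree enrichment in F2, three seeds per plant onwards.

    The F3 is formed from exactly ``seeds_per_plant`` self seeds of every
    retained F2 plant; each later generation is a uniform draw (without
    replacement) of the same census from the pooled three-seeds-per-plant
    bulk, keeping the census at the F3 size through F6.
    """
    _, retained, f_before = _start_f2(p1, p2, target, config, rng)
    if retained.n == 0:
        return _finalise("MSSD", 0, None, target, f_before, keep_population)
    k = config.seeds_per_plant
    gen = self_population(retained, np.repeat(np.arange(retained.n), k), rng)
    census = gen.n
    for _ in range(_F2_TO_F6 - 1):
        pool = np.repeat(np.arange(gen.n), k)
        parents = rng.permutation(pool)[:census]
        gen = self_population(gen, parents, rng)
    return _finalise("MSSD", retained.n, gen, target, f_before, keep_population)


_RUNNERS: dict[str, Callable[..., StrategyRun]] = {
    "F2DH": run_f2_dh,
    "RIL": run_ril,
    "MSSD": run_modified_ssd,
}


def run_strategy(p1: LineGenotype, p2: LineGenotype, target: TargetGenotype,
                 config: StrategyConfig, rng: np.random.Generator,
                 keep_population: bool = False) -> StrategyRun:
    return _RUNNERS[config.strategy](p1, p2, target, config, rng, keep_population)


def replicate_strategy(p1: LineGenotype, p2: LineGenotype, target: TargetGenotype,
                       config: StrategyConfig) -> ReplicateSet:
    """Run a strategy ``config.n_replicates`` times.

    Each replicate draws its random stream deterministically from
    ``(config.seed, replicate_index)``, so any single replicate can be
    reproduced in isolation.
    """
    n = config.n_replicates
    retained = np.empty(n, dtype=np.int64)
    n_final = np.empty(n, dtype=np.int64)
    n_targets = np.empty(n, dtype=np.int64)
    f_before = np.empty(n)
    f_after = np.empty(n)
    for rep in range(n):
        rng = replicate_rng(config.seed, rep)
        run = run_strategy(p1, p2, target, config, rng)
        retained[rep] = run.retained_f2
        n_final[rep] = run.n_final
        n_targets[rep] = run.n_targets
        f_before[rep] = run.f_before
        f_after[rep] = run.f_after
    return ReplicateSet(config.strategy, retained, n_final, n_targets, f_before, f_after)


def replicate_rng(master_seed: int, replicate: int) -> np.random.Generator:
    """Deterministic per-replicate stream derived from (master seed, replicate)."""
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence((master_seed, replicate))))
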