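"""Tab-separated readers and writers for maps, genotypes, targets, summaries.

All tables are plain TSV so fixtures stay human-diffable; writers emit a
deterministic column order and re-parsing reproduces the in-memory objects
exactly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .genetics import LineGenotype, LinkageMap, Locus, TargetGenotype, TraitEffect

LOCUS_COLUMNS = ["locus_id", "trait", "environment", "additive_effect",
                 "increasing_parent", "provenance"]
MAP_COLUMNS = ["locus_id", "chromosome", "pos_cM"]
SUMMARY_COLUMNS = ["strategy", "cross", "n_replicates", "retained_f2_mean",
                   "n_targets_mean", "n_targets_se", "gain_per_cycle", "gain_per_year"]


def read_map_table(path: str | Path,
                   effects: pd.DataFrame | None = None) -> LinkageMap:
    """Build a :class:`LinkageMap` from a map TSV, optionally attaching effects.

    ``effects`` is an effect table (see :func:`read_effect_table`); rows are
    attached to loci by ``locus_id``. Effect rows referring to loci absent
    from the map raise, to catch mismatched inputs early.
    """
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "chromosome": str})
    missing = [c for c in MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"map table {path} lacks columns {missing}")
    by_locus: dict[str, list[TraitEffect]] = {}
    if effects is not None:
        unknown = set(effects["locus_id"]) - set(df["locus_id"])
        if unknown:
            raise KeyError(f"effect rows for loci absent from map: {sorted(unknown)}")
        for row in effects.itertuples():
            by_locus.setdefault(row.locus_id, []).append(
                TraitEffect(row.trait, str(row.environment),
                            float(row.additive_effect), row.increasing_parent))
    loci = [Locus(r.locus_id, r.chromosome, float(r.pos_cM),
                  tuple(by_locus.get(r.locus_id, ())))
            for r in df.itertuples()]
    return LinkageMap(loci)


def read_effect_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"locus_id": str, "environment": str})
    missing = [c for c in LOCUS_COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"effect table {path} lacks columns {missing}")
    if "provenance" not in df.columns:
        df["provenance"] = "synthetic"
    return df


def write_map_table(lmap: LinkageMap, path: str | Path) -> None:
    pd.DataFrame(
        [(l.id, l.chromosome, l.pos_cM) for l in lmap.loci], columns=MAP_COLUMNS
    ).to_csv(path, sep="\t", index=False)


def write_effect_table(lmap: LinkageMap, path: str | Path,
                       provenance: Mapping[tuple[str, str, str], str] | None = None) -> None:
    rows = []
    for loc in lmap.loci:
        for e in loc.effects:
            prov = (provenance or {}).get((loc.id, e.trait, e.environment), "synthetic")
            rows.append((loc.id, e.trait, e.environment, e.effect, e.increasing, prov))
    pd.DataFrame(rows, columns=LOCUS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_genotype_table(path: str | Path, lmap: LinkageMap) -> dict[str, LineGenotype]:
    """Columns: ``locus_id`` then one column per line; values AA, CC or AC."""
    df = pd.read_csv(path, sep="\t", dtype=str).set_index("locus_id")
    unknown = set(df.index) - set(lmap.index)
    if unknown:
        raise KeyError(f"genotype rows for loci absent from map: {sorted(unknown)}")
    return {name: LineGenotype.from_codes(df[name].to_dict(), lmap)
            for name in df.columns}


def write_genotype_table(lines: Mapping[str, LineGenotype], path: str | Path) -> None:
    names = list(lines)
    lmap = lines[names[0]].map
    rows = []
    for loc in lmap.loci:
        rows.append([loc.id] + [lines[n].genotype_codes()[loc.id] for n in names])
    pd.DataFrame(rows, columns=["locus_id"] + names).to_csv(path, sep="\t", index=False)


def read_target_table(path: str | Path) -> TargetGenotype:
    """Columns ``locus_id`` and ``genotype`` (AA or CC: required homozygote)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {}
    for row in df.itertuples():
        g = row.genotype
        if g not in ("AA", "CC"):
            raise ValueError(f"target genotype must be AA or CC, got {g!r} at {row.locus_id}")
        required[row.locus_id] = g[0]
    return TargetGenotype(required)


def write_target_table(target: TargetGenotype, path: str | Path) -> None:
    pd.DataFrame([(lid, a * 2) for lid, a in target.required.items()],
                 columns=["locus_id", "genotype"]).to_csv(path, sep="\t", index=False)


def write_summary_table(rows: list[dict], path: str | Path) -> None:
    """Strategy summary rows in the fixed reporting column order."""
    df = pd.DataFrame(rows)
    cols = [c for c in SUMMARY_COLUMNS if c in df.columns]
    cols += [c for c in df.columns if c not in cols]
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.6g")
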