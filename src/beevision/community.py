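"""Community-weighted means from inventories and species trait tables.

The inventory is a long table of (site, species, year, count) records.
Records are aggregated over years, empty sites are dropped, traits of
unmeasured species are imputed by whole-vector resampling from the measured
pool, and the community-weighted mean (CWM) of each trait is the
abundance-weighted average across the species present at a site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "aggregate_inventory",
    "filter_sites",
    "impute_missing_traits",
    "cwm",
    "cwm_across_draws",
    "species_richness",
]

logger = logging.getLogger(__name__)


def aggregate_inventory(records: pd.DataFrame) -> pd.DataFrame:
    """Sum abundances over years into a site x species matrix.

    ``records`` needs columns site, species, year, count; counts must be
    non-negative integers. The result is a dense DataFrame indexed by site
    with one column per species (absences are zeros).
    """
    required = {"site", "species", "year", "count"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"inventory is missing columns: {sorted(missing)}")
    counts = records["count"]
    bad = records.index[
        (counts < 0) | (counts != np.floor(counts)) | ~np.isfinite(counts)
    ]
    if len(bad):
        raise ValueError(
            f"counts must be non-negative integers; offending records: {list(bad[:5])}"
        )
    matrix = records.pivot_table(
        index="site", columns="species", values="count", aggfunc="sum", fill_value=0
    )
    return matrix.astype(int)


def filter_sites(matrix: pd.DataFrame) -> pd.DataFrame:
    """Keep sites with at least one recorded specimen."""
    keep = matrix.sum(axis=1) >= 1
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_sites: dropped %d empty site(s)", dropped)
    return matrix.loc[keep]


@dataclass
class TraitDraw:
    """One imputation draw: a complete species x trait table plus provenance."""

    draw: int
    traits: pd.DataFrame  # indexed by species
    provenance: pd.Series  # 'measured' | 'imputed', indexed by species


def impute_missing_traits(
    trait_table: pd.DataFrame,
    inventoried_species: list[str],
    n_draws: int = 30,
    seed: int = 0,
    species_column: str = "species",
) -> list[TraitDraw]:
    """Fill trait vectors of unmeasured species by resampling measured ones.

    For each draw, every inventoried species absent from ``trait_table``
    receives the *complete* trait vector of a measured species drawn
    uniformly with replacement — whole-vector resampling preserves the
    covariance between traits. Measured species pass through unchanged in
    every draw. With no missing species a single draw is returned.
    """
    measured = trait_table.set_index(species_column)
    if len(measured) == 0:
        raise ValueError("cannot impute from an empty measured pool")
    missing = [s for s in inventoried_species if s not in measured.index]
    if not missing:
        prov = pd.Series("measured", index=measured.index)
        return [TraitDraw(draw=0, traits=measured.copy(), provenance=prov)]

    rng = np.random.default_rng(seed)
    pool = measured.index.to_numpy()
    draws = []
    for d in range(n_draws):
        donors = rng.choice(pool, size=len(missing), replace=True)
        imputed = measured.loc[donors].copy()
        imputed.index = pd.Index(missing, name=species_column)
        full = pd.concat([measured, imputed])
        prov = pd.Series("measured", index=full.index)
        prov.loc[missing] = "imputed"
        draws.append(TraitDraw(draw=d, traits=full, provenance=prov))
    return draws


def cwm(
    matrix: pd.DataFrame,
    traits: pd.DataFrame,
    trait: str,
) -> pd.DataFrame:
    """Community-weighted mean of one trait per site.

    ``CWM_j = sum_s a_js t_s / sum_s a_js`` over species present at site j.
    Every species with positive abundance must have a trait value.

    Returns a DataFrame indexed by site with columns ``cwm``, ``n_species``,
    ``total_abundance``.
    """
    present = matrix.columns[(matrix > 0).any(axis=0)]
    missing = [s for s in present if s not in traits.index or not np.isfinite(traits.loc[s, trait])]
    if missing:
        raise ValueError(f"species without a '{trait}' value: {sorted(missing)[:10]}")
    t = traits.loc[matrix.columns.intersection(traits.index), trait]
    sub = matrix[t.index]
    total = sub.sum(axis=1)
    if (total == 0).any():
        raise ValueError("CWM undefined for empty sites; run filter_sites first")
    values = sub.to_numpy(dtype=float) @ t.to_numpy(dtype=float) / total.to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "cwm": values,
            "n_species": (sub > 0).sum(axis=1),
            "total_abundance": total,
        },
        index=matrix.index,
    )


def cwm_across_draws(
    matrix: pd.DataFrame,
    draws: list[TraitDraw],
    trait: str,
) -> pd.DataFrame:
    """CWM per site averaged over imputation draws.

    Returns columns ``cwm`` (mean across draws — the reported value),
    ``cwm_sd`` (spread across draws, a sensitivity diagnostic),
    ``n_species`` and ``total_abundance``.
    """
    per_draw = [cwm(matrix, d.traits, trait) for d in draws]
    stacked = np.column_stack([p["cwm"].to_numpy() for p in per_draw])
    out = per_draw[0].copy()
    out["cwm"] = stacked.mean(axis=1)
    out["cwm_sd"] = stacked.std(axis=1, ddof=0) if len(per_draw) > 1 else 0.0
    return out


def species_richness(matrix: pd.DataFrame) -> pd.Series:
    """Number of species with abundance >= 1 per site."""
    return (matrix >= 1).sum(axis=1).rename("richness")
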