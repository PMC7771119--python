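"""Individual-level caterpillar-plant interaction records and their summaries.

The raw unit of observation is a count of caterpillar individuals of one
herbivore species collected on one tree individual of one plant species at
one site, labeled with a feeding guild (``exposed`` = free-living on the
foliage, ``shelter`` = leaf roller / tier / webber). Analyses run at the
plant-species level; the tree individual is kept only for provenance.

Herbivore species sampled in fewer than ``min_n`` individuals (default 3)
are excluded before any analysis, to purge erroneous interaction records
and avoid overestimating specialization. The filter is applied per site by
default: each site is an independent dataset with its own species pool
(pooled filtering across sites is available via ``per_site=False``).
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GUILDS = ("exposed", "shelter")
GUILD_SCOPES = ("all",) + GUILDS

INTERACTION_COLUMNS = (
    "site",
    "tree_individual",
    "plant_species",
    "herbivore_species",
    "guild",
    "n_individuals",
)
COMMUNITY_COLUMNS = ("site", "plant_species", "leaf_area_m2", "n_tree_individuals")

#: Transforms applied to each response before model fitting. Abundance is
#: natural-log transformed (zero rows are dropped for that response);
#: density uses log(x + 1) so zero densities are retained; richness and
#: mean DSI* enter untransformed.
RESPONSE_TRANSFORMS = {
    "abundance": "log",
    "density": "log1p",
    "richness": "none",
    "mean_dsi_star": "none",
}


class TableValidationError(ValueError):
    """A delimited input table violates the schema."""


def _require_columns(df: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise TableValidationError(f"{what} table missing columns: {missing}")


def validate_interactions(df: pd.DataFrame) -> pd.DataFrame:
    """Validate schema, guild vocabulary and counts; returns a clean copy."""
    _require_columns(df, INTERACTION_COLUMNS, "interaction")
    df = df.loc[:, list(INTERACTION_COLUMNS)].copy()
    for col in ("site", "tree_individual", "plant_species", "herbivore_species", "guild"):
        df[col] = df[col].astype(str).str.strip()
    bad_guilds = sorted(set(df["guild"]) - set(GUILDS))
    if bad_guilds:
        raise TableValidationError(
            f"unknown guild labels {bad_guilds}; expected one of {list(GUILDS)}"
        )
    counts = pd.to_numeric(df["n_individuals"], errors="raise")
    if (counts < 1).any() or not np.allclose(counts, counts.astype(int)):
        raise TableValidationError("n_individuals must be positive integers")
    df["n_individuals"] = counts.astype(int)
    # one herbivore species must carry a single guild label
    guilds_per_species = df.groupby(["site", "herbivore_species"])["guild"].nunique()
    mixed = guilds_per_species[guilds_per_species > 1]
    if len(mixed):
        raise TableValidationError(
            f"herbivore species with conflicting guild labels: {list(mixed.index)}"
        )
    return df


def validate_community(df: pd.DataFrame) -> pd.DataFrame:
    _require_columns(df, COMMUNITY_COLUMNS, "community")
    df = df.loc[:, list(COMMUNITY_COLUMNS)].copy()
    for col in ("site", "plant_species"):
        df[col] = df[col].astype(str).str.strip()
    df["leaf_area_m2"] = pd.to_numeric(df["leaf_area_m2"], errors="raise")
    if (df["leaf_area_m2"] < 0).any() or not np.isfinite(df["leaf_area_m2"]).all():
        raise TableValidationError("leaf_area_m2 must be finite and >= 0")
    if df.duplicated(["site", "plant_species"]).any():
        raise TableValidationError("duplicate (site, plant_species) community rows")
    return df


def read_interactions(path) -> pd.DataFrame:
    """Read the interaction CSV (header: site,tree_individual,plant_species,
    herbivore_species,guild,n_individuals)."""
    return validate_interactions(pd.read_csv(path))


def read_community(path) -> pd.DataFrame:
    """Read the plant community CSV (header: site,plant_species,leaf_area_m2,
    n_tree_individuals)."""
    return validate_community(pd.read_csv(path))


def filter_rare_herbivores(
    records: pd.DataFrame, min_n: int = 3, per_site: bool = True
) -> pd.DataFrame:
    """Drop herbivore species with fewer than ``min_n`` total individuals.

    Removal is all-or-nothing per species (within each site when
    ``per_site``, the default, else across the pooled dataset). ``min_n=1``
    is the identity. Idempotent.
    """
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    keys = ["site", "herbivore_species"] if per_site else ["herbivore_species"]
    totals = records.groupby(keys)["n_individuals"].transform("sum")
    kept = records.loc[totals >= min_n].reset_index(drop=True)
    n_dropped = records["herbivore_species"].nunique() - kept["herbivore_species"].nunique()
    if kept.empty and not records.empty:
        logger.warning("rare-species filter (min_n=%d) removed every record", min_n)
    elif n_dropped:
        logger.info(
            "rare-species filter (min_n=%d, per_site=%s) dropped %d herbivore species",
            min_n, per_site, n_dropped,
        )
    return kept


def build_assemblage_matrix(
    records: pd.DataFrame, site: str, guild_scope: str = "all"
) -> pd.DataFrame:
    """Plant x herbivore matrix of summed individual counts for one site.

    ``guild_scope`` is ``all``, ``exposed`` or ``shelter``. Plant rows that
    are all-zero under the scope are dropped (and logged): an absent
    assemblage is "no data", not an observation of zero overlap.
    """
    if guild_scope not in GUILD_SCOPES:
        raise ValueError(
            f"unknown guild_scope {guild_scope!r}; expected one of {list(GUILD_SCOPES)}"
        )
    sub = records.loc[records["site"] == site]
    if guild_scope != "all":
        sub = sub.loc[sub["guild"] == guild_scope]
    if sub.empty:
        logger.warning(
            "no records for site=%r guild_scope=%r; empty assemblage matrix",
            site, guild_scope,
        )
        return pd.DataFrame(dtype=int)
    mat = (
        sub.pivot_table(
            index="plant_species",
            columns="herbivore_species",
            values="n_individuals",
            aggfunc="sum",
            fill_value=0,
        )
        .astype(int)
        .sort_index(axis=0)
        .sort_index(axis=1)
    )
    empty_rows = mat.index[mat.sum(axis=1) == 0]
    if len(empty_rows):
        logger.info("dropping all-zero plant rows: %s", list(empty_rows))
        mat = mat.drop(index=empty_rows)
    mat.index.name = "plant_species"
    mat.columns.name = "herbivore_species"
    return mat


def summarize_assemblages(
    matrix: pd.DataFrame, community: pd.DataFrame, site: str | None = None
) -> pd.DataFrame:
    """Per-plant abundance, density and richness from an assemblage matrix.

    abundance = summed individuals on the plant; density = abundance per m2
    of the plant's summed leaf area; richness = number of herbivore species.
    Values are returned untransformed; the transforms the model stage applies
    are recorded in :data:`RESPONSE_TRANSFORMS`.
    """
    comm = community if site is None else community.loc[community["site"] == site]
    areas = comm.set_index("plant_species")["leaf_area_m2"]
    missing = [p for p in matrix.index if p not in areas.index]
    if missing:
        raise TableValidationError(f"plants missing from community table: {missing}")
    bad_area = [p for p in matrix.index if not areas[p] > 0]
    if bad_area:
        raise TableValidationError(
            f"plants with zero or missing leaf area: {bad_area}"
        )
    abundance = matrix.sum(axis=1).astype(float)
    out = pd.DataFrame(
        {
            "abundance": abundance,
            "density": abundance / areas.loc[matrix.index],
            "richness": (matrix > 0).sum(axis=1).astype(int),
        }
    )
    out.index.name = "plant_species"
    return out


def site_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per site x guild totals: N individuals, N herbivore species, N plants."""
    rows = []
    for site, site_df in records.groupby("site"):
        for scope in GUILD_SCOPES:
            sub = site_df if scope == "all" else site_df[site_df["guild"] == scope]
            rows.append(
                {
                    "site": site,
                    "guild_scope": scope,
                    "n_individuals": int(sub["n_individuals"].sum()),
                    "n_herbivore_species": sub["herbivore_species"].nunique(),
                    "n_plant_species": sub["plant_species"].nunique(),
                }
            )
    return pd.DataFrame(rows)


def transform_response(values: pd.Series, response: str) -> pd.Series:
    """Apply the declared transform; log-of-zero rows are dropped (logged)."""
    how = RESPONSE_TRANSFORMS[response]
    if how == "log":
        zero = values.index[values <= 0]
        if len(zero):
            logger.info(
                "dropping %d zero-%s rows (log transform undefined)",
                len(zero), response,
            )
        return np.log(values[values > 0])
    if how == "log1p":
        return np.log1p(values)
    return values
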