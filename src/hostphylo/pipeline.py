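"""Config-driven end-to-end orchestration.

A run takes either real inputs (a master Newick host phylogeny, an
interaction CSV and a community CSV) or a synthetic-data configuration,
and produces a deterministic result bundle:

    filtered_interactions.csv      rare-species-filtered records
    site_summary.csv               per site x guild totals
    <site>_distances.csv           patristic distances on the site subphylogeny
    <site>_ed.csv                  fair-proportions distinctiveness (PI)
    <site>_<scope>_<index>_similarity.csv
    mantel_results.json            stratified Mantel r / p per scope x index
    specialization.csv             per-species MPD / DSI / DSI_lim / DSI*
    plant_mean_dsi.csv             per-plant mean DSI* per guild scope
    model_rank_<response>.csv      full AICc-ranked candidate tables
    model_results.json             best models, LRTs, contrasts, PI-area pre-check
    manifest.json                  config, seeds and conventions in effect

Every stochastic stage takes an explicit seed; the same config reproduces
the bundle byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from hostphylo import __version__
from hostphylo.interactions import (
    GUILDS,
    GUILD_SCOPES,
    RESPONSE_TRANSFORMS,
    build_assemblage_matrix,
    filter_rare_herbivores,
    read_community,
    read_interactions,
    site_summary,
    summarize_assemblages,
    transform_response,
)
from hostphylo.assemblage_similarity import SIMILARITY_INDICES, similarity_matrix
from hostphylo.dsi import assemblage_mean_dsi, compute_specialization
from hostphylo.herbivore_models import (
    RESPONSES,
    check_pi_leafarea_confounding,
    fit_candidates,
    guild_site_contrasts,
    lrt_vs_null,
    rank_and_select,
)
from hostphylo.phylo_metrics import (
    evolutionary_distinctiveness,
    patristic_distances,
    prune_to_taxa,
    read_tree_file,
    tip_labels,
)
from hostphylo.stratified_mantel import run_overlap_analysis
from hostphylo.synthetic_data import SyntheticConfig, generate_dataset

logger = logging.getLogger(__name__)


class InputValidationError(ValueError):
    """Inputs are mutually inconsistent; the run aborts before computing."""


@dataclass
class RunConfig:
    """Everything one pipeline run needs; exactly one data source."""

    synthetic: SyntheticConfig | None = None
    tree_path: str | None = None
    interactions_path: str | None = None
    community_path: str | None = None
    min_n: int = 3
    filter_per_site: bool = True
    mantel_n_permutations: int = 9999
    mantel_alternative: str = "less"
    mantel_indices: tuple[str, ...] = SIMILARITY_INDICES
    mantel_guild_scopes: tuple[str, ...] = GUILD_SCOPES
    mantel_seed: int = 1
    dsi_n_iterations: int = 999
    dsi_weighting: str = "interaction_counts"
    dsi_seed: int = 2
    fit_models: bool = True

    def __post_init__(self):
        real = all(
            p is not None
            for p in (self.tree_path, self.interactions_path, self.community_path)
        )
        if (self.synthetic is None) == (not real):
            raise ValueError(
                "config must provide exactly one of: synthetic config, "
                "or all three input paths"
            )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        if "synthetic" in raw:
            kwargs["synthetic"] = SyntheticConfig.from_dict(raw["synthetic"])
        inputs = raw.get("inputs", {})
        kwargs["tree_path"] = inputs.get("tree")
        kwargs["interactions_path"] = inputs.get("interactions")
        kwargs["community_path"] = inputs.get("community")
        flt = raw.get("filter", {})
        kwargs["min_n"] = int(flt.get("min_n", 3))
        kwargs["filter_per_site"] = bool(flt.get("per_site", True))
        mantel = raw.get("mantel", {})
        kwargs["mantel_n_permutations"] = int(mantel.get("n_permutations", 9999))
        kwargs["mantel_alternative"] = mantel.get("alternative", "less")
        kwargs["mantel_indices"] = tuple(mantel.get("indices", SIMILARITY_INDICES))
        kwargs["mantel_guild_scopes"] = tuple(
            mantel.get("guild_scopes", GUILD_SCOPES)
        )
        if "seed" not in mantel:
            raise ValueError("mantel.seed must be set explicitly")
        kwargs["mantel_seed"] = int(mantel["seed"])
        dsi_cfg = raw.get("dsi", {})
        kwargs["dsi_n_iterations"] = int(dsi_cfg.get("n_iterations", 999))
        kwargs["dsi_weighting"] = dsi_cfg.get("weighting", "interaction_counts")
        if "seed" not in dsi_cfg:
            raise ValueError("dsi.seed must be set explicitly")
        kwargs["dsi_seed"] = int(dsi_cfg["seed"])
        kwargs["fit_models"] = bool(raw.get("models", {}).get("enabled", True))
        return cls(**kwargs)


def validate_inputs(tree, interactions: pd.DataFrame, community: pd.DataFrame) -> dict:
    """Cross-check tree tips against community and interaction labels.

    Fatal: an interaction plant absent from the community or the tree, or a
    community plant absent from the tree. Non-fatal: tree tips or community
    plants hosting no interactions (plants may legitimately host nothing).
    """
    tips = set(tip_labels(tree))
    report: dict = {"fatal": [], "notes": []}
    for site, comm in community.groupby("site"):
        plants = set(comm["plant_species"])
        inter = interactions[interactions["site"] == site]
        used = set(inter["plant_species"])
        for p in sorted(used - plants):
            report["fatal"].append(
                f"site {site}: interaction plant {p!r} missing from community table"
            )
        for p in sorted(plants - tips):
            report["fatal"].append(
                f"site {site}: community plant {p!r} missing from tree"
            )
        for p in sorted(plants - used):
            report["notes"].append(f"site {site}: plant {p!r} hosts no interactions")
    orphan_sites = set(interactions["site"]) - set(community["site"])
    for s in sorted(orphan_sites):
        report["fatal"].append(f"site {s!r} has interactions but no community table")
    return report


def _json_dump(obj, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def build_response_table(
    records: pd.DataFrame,
    community: pd.DataFrame,
    pi_scores: pd.DataFrame,
    plant_mean_dsi: pd.DataFrame,
) -> pd.DataFrame:
    """One row per site x plant x guild with all responses and predictors.

    ``pi_scores`` has columns site, plant_species, pi; ``plant_mean_dsi``
    comes from :func:`hostphylo.dsi.assemblage_mean_dsi`.
    """
    rows = []
    for site in sorted(records["site"].unique()):
        comm = community[community["site"] == site]
        for guild in GUILDS:
            mat = build_assemblage_matrix(records, site, guild)
            if mat.empty:
                continue
            summary = summarize_assemblages(mat, comm)
            for plant, r in summary.iterrows():
                rows.append(
                    {
                        "site": site,
                        "plant_species": plant,
                        "guild": guild,
                        "abundance": r["abundance"],
                        "density": r["density"],
                        "richness": r["richness"],
                    }
                )
    table = pd.DataFrame(rows)
    table = table.merge(pi_scores, on=["site", "plant_species"], how="left")
    areas = community[["site", "plant_species", "leaf_area_m2"]]
    table = table.merge(areas, on=["site", "plant_species"], how="left")
    table["leaf_area_sqrt"] = np.sqrt(table["leaf_area_m2"])
    mds = plant_mean_dsi[plant_mean_dsi["guild_scope"].isin(GUILDS)].rename(
        columns={"guild_scope": "guild"}
    )
    table = table.merge(
        mds[["site", "plant_species", "guild", "mean_dsi_star"]],
        on=["site", "plant_species", "guild"],
        how="left",
    )
    table["tree_id"] = table["site"] + "/" + table["plant_species"]
    return table.sort_values(["site", "plant_species", "guild"]).reset_index(drop=True)


def run_models(table: pd.DataFrame) -> tuple[dict, dict[str, pd.DataFrame]]:
    """AICc-ranked candidate sets, best models, LRTs and contrasts per response."""
    results: dict = {}
    rank_tables: dict[str, pd.DataFrame] = {}
    for response in RESPONSES:
        if response not in table.columns or table[response].dropna().empty:
            logger.warning("response %r unavailable; skipped", response)
            continue
        data = table.copy()
        data["value"] = transform_response(data[response], response)
        data = data.dropna(subset=["value", "pi", "leaf_area_sqrt"])
        fits = fit_candidates(response, data)
        rank_table, best = rank_and_select(fits)
        null_fit = next(f for f in fits if f.spec.is_null and f.converged)
        lrt = lrt_vs_null(best, null_fit)
        contrasts = guild_site_contrasts(best, data)
        results[response] = {
            "transform": RESPONSE_TRANSFORMS[response],
            "n_obs": int(best.n_obs),
            "best_model": best.spec.label(),
            "best_k": int(best.k),
            "best_aicc": float(best.aicc),
            "best_weight": float(best.weight),
            "coefficients": {
                name: {"estimate": float(est), "se": float(se)}
                for (name, est), se in zip(
                    best.coefficients.items(), best.bse
                )
            },
            "lrt_vs_null": lrt,
            "guild_site_contrasts": contrasts.to_dict(orient="records"),
        }
        rank_tables[response] = rank_table
    return results, rank_tables


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the full analysis and write the result bundle to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.synthetic is not None:
        dataset = generate_dataset(config.synthetic)
        site_trees = dataset.trees
        interactions = dataset.interactions
        community = dataset.community
        for site, nwk in sorted(dataset.newicks.items()):
            (out / f"{site}_tree.nwk").write_text(nwk + "\n", encoding="utf-8")
        dataset.ground_truth.to_csv(out / "ground_truth.csv", index=False)
    else:
        master = read_tree_file(config.tree_path)
        interactions = read_interactions(config.interactions_path)
        community = read_community(config.community_path)
        report = validate_inputs(master, interactions, community)
        if report["fatal"]:
            raise InputValidationError("; ".join(report["fatal"]))
        site_trees = {
            site: prune_to_taxa(master, set(comm["plant_species"]))
            for site, comm in community.groupby("site")
        }

    filtered = filter_rare_herbivores(
        interactions, min_n=config.min_n, per_site=config.filter_per_site
    )
    filtered.to_csv(out / "filtered_interactions.csv", index=False)
    site_summary(filtered).to_csv(out / "site_summary.csv", index=False)

    site_distances, pi_frames = {}, []
    for site in sorted(site_trees):
        D = patristic_distances(site_trees[site])
        site_distances[site] = D
        D.to_csv(out / f"{site}_distances.csv")
        ed = evolutionary_distinctiveness(site_trees[site])
        ed.rename("pi").to_csv(out / f"{site}_ed.csv")
        pi_frames.append(
            pd.DataFrame(
                {"site": site, "plant_species": ed.index, "pi": ed.to_numpy()}
            )
        )
    pi_scores = pd.concat(pi_frames, ignore_index=True)

    for site in sorted(site_trees):
        for scope in config.mantel_guild_scopes:
            mat = build_assemblage_matrix(filtered, site, scope)
            if mat.empty or (mat.sum(axis=1) > 0).sum() < 2:
                continue
            for index in config.mantel_indices:
                similarity_matrix(mat, index).to_csv(
                    out / f"{site}_{scope}_{index}_similarity.csv"
                )

    mantel_results = run_overlap_analysis(
        filtered,
        site_distances,
        guild_scopes=config.mantel_guild_scopes,
        indices=config.mantel_indices,
        n_permutations=config.mantel_n_permutations,
        alternative=config.mantel_alternative,
        seed=config.mantel_seed,
    )
    _json_dump(
        {
            f"{scope}|{index}": res.to_dict()
            for (scope, index), res in mantel_results.items()
        },
        out / "mantel_results.json",
    )

    scores = compute_specialization(
        filtered,
        community.assign(),
        site_distances,
        n_iterations=config.dsi_n_iterations,
        seed=config.dsi_seed,
        weighting=config.dsi_weighting,
    )
    scores.to_csv(out / "specialization.csv", index=False)
    plant_mean = assemblage_mean_dsi(scores, filtered)
    plant_mean.to_csv(out / "plant_mean_dsi.csv", index=False)

    model_results: dict = {}
    if config.fit_models:
        comm_pi = community.merge(pi_scores, on=["site", "plant_species"], how="left")
        model_results["pi_leafarea_precheck"] = check_pi_leafarea_confounding(comm_pi)
        table = build_response_table(filtered, community, pi_scores, plant_mean)
        table.to_csv(out / "response_table.csv", index=False)
        per_response, rank_tables = run_models(table)
        model_results["responses"] = per_response
        for response, rt in rank_tables.items():
            rt.to_csv(out / f"model_rank_{response}.csv", index=False)
        _json_dump(model_results, out / "model_results.json")

    manifest = {
        "package": "hostphylo",
        "version": __version__,
        "config": {
            "synthetic": (
                config.synthetic.to_dict() if config.synthetic is not None else None
            ),
            "inputs": {
                "tree": config.tree_path,
                "interactions": config.interactions_path,
                "community": config.community_path,
            },
            "filter": {"min_n": config.min_n, "per_site": config.filter_per_site},
            "mantel": {
                "n_permutations": config.mantel_n_permutations,
                "alternative": config.mantel_alternative,
                "indices": list(config.mantel_indices),
                "guild_scopes": list(config.mantel_guild_scopes),
                "seed": config.mantel_seed,
            },
            "dsi": {
                "n_iterations": config.dsi_n_iterations,
                "weighting": config.dsi_weighting,
                "seed": config.dsi_seed,
            },
            "models": {"enabled": config.fit_models},
        },
        "conventions": {
            "dsi_sign": "DSI = -(MPD_obs - null mean) / null sd; +1 = max specialization",
            "rare_filter": "per-site totals by default",
            "estimator": "maximum likelihood (not REML)",
            "posthoc": "Holm-adjusted Wald guild contrasts per site",
        },
    }
    _json_dump(manifest, out / "manifest.json")
    return out
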