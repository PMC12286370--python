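"""Publication-style report tables and the full analysis pipeline.

Produces three tables from any directed two-mode network:

* a degree table (per mode and direction: mean, SD, median, skewness);
* a whole-network table (density, per-mode indegree centralization,
  reciprocity);
* a CUG table (observed mean, Pr(<=obs), Pr(>=obs), simulated mean and
  SD for the directional desirability gaps and the reciprocated-pair
  gap).

``run_full_analysis`` chains preprocessing -> descriptives -> gender
gap -> CUG suite and writes the tables as CSV plus a JSON manifest
(version, seed, parameters, filter reports) from which every number is
recomputable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .network import DirectedBipartiteNetwork
from . import descriptives as dsc
from .cug import cug_test
from .preprocess import filter_active, filter_bots, split_markets

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "degree_table", "structure_table", "cug_table", "run_full_analysis"]

DEFAULT_CUG_STATS = ("gap_men_to_women", "gap_women_to_men", "reciprocal_gap")


@dataclass
class AnalysisConfig:
    """Everything one full pipeline run needs, serializable to YAML."""

    edges: str
    nodes: str
    out_dir: str = "swipenet_report"
    seed: int | None = None
    n_sims: int = 1000
    weighted: bool = False
    cug_statistics: tuple = DEFAULT_CUG_STATS
    min_received: float = 30
    accept_rate: float = 1.0
    by_city: bool = False
    gender_gap_permutations: int = 10_000
    filters: tuple = ("bots", "active")  # applied in order, after any city split

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("cug_statistics", "filters"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def degree_table(net: DirectedBipartiteNetwork, standardized: bool = False) -> pd.DataFrame:
    """Degree summary rows: (all, men, women) x (in, out)."""
    rows = []
    for direction in ("in", "out"):
        for mode in ("all", "men", "women"):
            s = dsc.degree_summary(net, mode, direction, standardized=standardized)
            rows.append(
                {
                    "direction": f"{direction}degree",
                    "mode": mode,
                    "mean": s.mean,
                    "sd": s.sd,
                    "median": s.median,
                    "skewness": s.skewness,
                    "max": s.max,
                    "n": s.n,
                }
            )
    return pd.DataFrame(rows)


def structure_table(net: DirectedBipartiteNetwork) -> pd.DataFrame:
    """Whole-network measures: density, centralizations, reciprocity."""
    rows = [
        {"measure": "density", "value": dsc.density(net)},
        {"measure": "indegree_centralization_men", "value": dsc.indegree_centralization(net, "men")},
        {"measure": "indegree_centralization_women", "value": dsc.indegree_centralization(net, "women")},
        {"measure": "reciprocity", "value": dsc.reciprocity(net)},
    ]
    return pd.DataFrame(rows)


def cug_table(
    net: DirectedBipartiteNetwork,
    statistics=DEFAULT_CUG_STATS,
    n_sims: int = 1000,
    seed: int | None = None,
    weighted: bool = False,
) -> pd.DataFrame:
    """One CUG-test row per requested statistic."""
    if seed is None:
        raise ValueError("cug_table requires a seed")
    rows = []
    for i, stat in enumerate(statistics):
        res = cug_test(net, stat, n_sims=n_sims, seed=seed + i, weighted=weighted)
        rows.append(res.summary())
    return pd.DataFrame(rows)


def _analyse_one(net, config: AnalysisConfig, seed: int) -> dict:
    reports = []
    for rule in config.filters:
        if rule == "bots":
            net, rep = filter_bots(
                net, min_received=config.min_received, accept_rate=config.accept_rate
            )
        elif rule == "active":
            net, rep = filter_active(net)
        else:
            raise ValueError(f"unknown filter rule {rule!r}")
        reports.append(rep.to_dict())
    gg = dsc.gender_gap(net, n_permutations=config.gender_gap_permutations, seed=seed)
    return {
        "network": net,
        "filter_reports": reports,
        "n_women": net.n_women,
        "n_men": net.n_men,
        "total_ties": net.total_ties,
        "degree_table": degree_table(net),
        "degree_table_standardized": degree_table(net, standardized=True),
        "structure_table": structure_table(net),
        "cug_table": cug_table(
            net, config.cug_statistics, n_sims=config.n_sims, seed=seed, weighted=config.weighted
        ),
        "gender_gap": {
            "mean_std_indegree_women": gg.mean_women,
            "mean_std_indegree_men": gg.mean_men,
            "cohens_d": gg.cohens_d,
            "p_value": gg.p_value,
            "n_permutations": gg.n_permutations,
            "seed": gg.seed,
        },
    }


def run_full_analysis(config: AnalysisConfig, net: DirectedBipartiteNetwork | None = None) -> dict:
    """Run the whole pipeline and write the report bundle.

    Stages: (optional city split) -> bot filter -> active filter ->
    degree/structure tables -> gender gap -> CUG suite.  Writes per-
    market CSV tables and one ``manifest.json`` under
    ``config.out_dir``; returns the bundle as a dict of DataFrames.
    Deterministic: the same config and seed produce identical output.
    """
    if config.seed is None:
        raise ValueError("a seed is required: the CUG suite and the gender-gap test are stochastic")
    if net is None:
        from .io import load_network_csv

        net = load_network_csv(config.edges, config.nodes)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    markets = split_markets(net) if config.by_city else {"all": net}
    manifest = {
        "swipenet_version": __version__,
        "seed": config.seed,
        "n_sims": config.n_sims,
        "weighted": config.weighted,
        "filters": list(config.filters),
        "filter_params": {"min_received": config.min_received, "accept_rate": config.accept_rate},
        "input": {"edges": str(config.edges), "nodes": str(config.nodes)},
        "markets": {},
    }
    bundle = {}
    for i, (label, subnet) in enumerate(sorted(markets.items())):
        logger.info("analysing market %r: %d women, %d men, %d ties",
                    label, subnet.n_women, subnet.n_men, subnet.total_ties)
        res = _analyse_one(subnet, config, seed=config.seed + 1000 * i)
        bundle[label] = res
        tag = f"{label}_" if label != "all" else ""
        res["degree_table"].to_csv(out / f"{tag}table_degrees.csv", index=False)
        res["degree_table_standardized"].to_csv(out / f"{tag}table_degrees_standardized.csv", index=False)
        res["structure_table"].to_csv(out / f"{tag}table_structure.csv", index=False)
        res["cug_table"].to_csv(out / f"{tag}table_cug.csv", index=False)
        manifest["markets"][label] = {
            "n_women": res["n_women"],
            "n_men": res["n_men"],
            "total_ties": res["total_ties"],
            "filter_reports": res["filter_reports"],
            "gender_gap": res["gender_gap"],
            "seed": config.seed + 1000 * i,
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=float)
    return bundle
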