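"""End-to-end analysis pipeline.

Runs the full chain the package exists for: nitrogen partition and
HRT-smoothed performance index -> rarefied diversity -> Bray-Curtis /
NMDS -> Ward+elbow staging -> indicator taxa -> per-stage Mann-Kendall
and Sen's slope -> best-AIC performance models over ENV/DIV/COM
predictor pools and over dominant-genus abundances -> db-RDA of
community composition on the operational variables.  Identical config
and seed give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as nio
from .annotations import annotate_guilds
from .balance import chem_series_from_concentrations, partition_series
from .community import (
    CommunityTable,
    aggregate_taxa,
    bray_curtis,
    cluster_stages,
    dissimilarity_structure,
    indicator_taxa,
    nmds,
    rarefied_mean_table,
    rarefy_diversity,
)
from .models import (
    PREDICTOR_GROUPS,
    ModelResult,
    best_subset_aic,
    dbrda_variance,
    fit_standardized_ols,
    standardize,
)
from .scenarios import get_scenario, run_scenario
from .trends import mann_kendall

__all__ = ["PipelineConfig", "run_full_pipeline"]

logger = logging.getLogger("nitflow")


def _subseed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Provide either a packaged ``scenario`` name or the three input paths
    (chemistry CSV, counts TSV, taxonomy TSV).  ``flow`` (L/day) converts
    effluent concentrations to rates for file inputs.
    """

    scenario: str | None = "paper_default"
    chemistry: str | None = None
    counts: str | None = None
    taxonomy: str | None = None
    flow: float = 0.72
    rarefaction_depth: int = 30000
    rarefaction_reps: int = 100
    nmds_dims: int = 3
    nmds_restarts: int = 20
    k_max: int = 8
    permutations: int = 999
    smoothing_window: float = 6.25
    seed: int = 0
    outdir: str = "nitflow_out"

    def __post_init__(self) -> None:
        files = (self.chemistry, self.counts, self.taxonomy)
        if self.scenario is None and any(f is None for f in files):
            raise ValueError(
                "config needs either a scenario or all three input paths")

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "PipelineConfig":
        text = Path(path).read_text()
        data = (json.loads(text) if str(path).endswith(".json")
                else yaml.safe_load(text)) or {}
        data.update(overrides)
        return cls(**data)


def _load(config: PipelineConfig) -> tuple[pd.DataFrame, CommunityTable, float]:
    """Load or simulate inputs; returns (chemistry, community, flow)."""
    if config.chemistry is not None:
        chem = nio.read_chemistry(config.chemistry)
        table = nio.load_community(config.counts, config.taxonomy)
        chem, table = nio.align_days(chem, table, logger=logger)
        return chem, table, config.flow
    scenario = get_scenario(config.scenario)
    sim, counts = run_scenario(scenario, seed=config.seed)
    table = CommunityTable(counts=counts.counts,
                           sample_days=counts.sample_days,
                           taxonomy=counts.taxonomy)
    return sim.chem, table, scenario.config.influent_flow


def _model_row(name: str, result: ModelResult, columns: list[str]) -> dict:
    row = {"model": name,
           "adjusted_r2": result.adjusted_r2,
           "aic": result.aic,
           "overall_p": result.overall_p}
    for col in columns:
        row[f"beta_{col}"] = np.nan
        row[f"p_{col}"] = np.nan
    for nm, b, p in zip(result.predictor_names,
                        result.standardized_coefficients, result.p_values):
        row[f"beta_{nm}"] = b
        row[f"p_{nm}"] = p
    return row


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute the whole analysis and write all outputs to the config's
    output directory.  Returns the result bundle as a dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed

    chem, table, flow = _load(config)
    if config.scenario is not None and config.chemistry is None:
        nio.write_chemistry(chem, outdir / "chemistry.csv")
        nio.write_counts(table.counts, outdir / "counts.tsv")
        nio.write_taxonomy(table.taxonomy, outdir / "taxonomy.tsv")

    # --- nitrogen partition and performance index -------------------------
    records = chem_series_from_concentrations(chem, flow)
    partition = partition_series(records, config.smoothing_window)
    nio_write_csv(partition, outdir / "partition.csv")

    # --- alpha diversity --------------------------------------------------
    diversity = rarefy_diversity(table, depth=config.rarefaction_depth,
                                 reps=config.rarefaction_reps,
                                 seed=_subseed(seed, 10))
    nio_write_csv(diversity, outdir / "diversity.csv")

    # --- beta diversity, ordination, staging ------------------------------
    rare_table = rarefied_mean_table(table, depth=config.rarefaction_depth,
                                     reps=min(config.rarefaction_reps, 20),
                                     seed=_subseed(seed, 11))
    dist = bray_curtis(rare_table)
    dist_df = pd.DataFrame(dist.data,
                           index=[f"{d:g}" for d in table.sample_days],
                           columns=[f"{d:g}" for d in table.sample_days])
    dist_df.to_csv(outdir / "dissimilarity.csv", float_format=nio.FLOAT_FORMAT)

    ordination = nmds(dist, k=config.nmds_dims, restarts=config.nmds_restarts,
                      seed=_subseed(seed, 12))
    ord_df = pd.DataFrame(
        ordination.coordinates,
        columns=[f"NMDS{i + 1}" for i in range(config.nmds_dims)])
    ord_df.insert(0, "day", table.sample_days)
    nio_write_csv(ord_df, outdir / "ordination.csv")

    stages = cluster_stages(dist, k_max=config.k_max)
    stage_df = pd.DataFrame({"day": table.sample_days,
                             "stage": stages.labels})
    nio_write_csv(stage_df, outdir / "stages.csv")

    gap_curve, within = dissimilarity_structure(dist, table.sample_days, stages)
    nio_write_csv(gap_curve, outdir / "dissimilarity_by_gap.csv")

    # --- indicator taxa ---------------------------------------------------
    genus_table = aggregate_taxa(rare_table, "genus")
    indicators = indicator_taxa(genus_table, stages,
                                permutations=config.permutations,
                                seed=_subseed(seed, 13))
    guilds = annotate_guilds(list(indicators["taxon"].unique()))
    indicators["functions"] = [
        ";".join(sorted(guilds[t])) for t in indicators["taxon"]]
    nio_write_csv(indicators, outdir / "indicators.csv")

    # --- trends per stage -------------------------------------------------
    trend_rows = []
    series = list(zip(partition["day"], partition["ratio"]))
    scopes = [("all", np.ones(len(series), dtype=bool))]
    for lab in np.unique(stages.labels):
        scopes.append((f"stage_{lab}", stages.labels == lab))
    for name, mask_comm in scopes:
        if name == "all":
            sub = series
        else:
            stage_days = set(table.sample_days[mask_comm].tolist())
            sub = [s for s in series if s[0] in stage_days]
        finite = [s for s in sub if np.isfinite(s[1])]
        if len(finite) < 3:
            continue
        res = mann_kendall(sub)
        trend_rows.append({"stage": name, "n": res.n, "S": res.s,
                           "var_S": res.var_s, "Z": res.z,
                           "p_value": res.p_value,
                           "sen_slope": res.sen_slope})
    trends = pd.DataFrame(trend_rows)
    nio_write_csv(trends, outdir / "trends.csv")

    # --- performance models ----------------------------------------------
    env = pd.DataFrame({"temperature": chem["temp_C"],
                        "ph": chem["ph"],
                        "do": chem["do_mgO2_L"]})
    env.index = chem["day"].to_numpy(dtype=float)
    div = diversity.set_index("day")[["richness", "shannon", "pielou"]]
    com = ord_df.set_index("day")[[f"NMDS{i + 1}"
                                   for i in range(min(config.nmds_dims, 3))]]
    response = partition.set_index("day")["ratio"]
    frame = pd.concat([response, env, div, com], axis=1, join="inner").dropna()
    y = standardize(frame[["ratio"]]).to_numpy()[:, 0]
    predictors = standardize(frame.drop(columns="ratio"))

    table1_rows = []
    all_cols = list(predictors.columns)
    row_defs = [("Only ENV", ("ENV",)), ("Only DIV", ("DIV",)),
                ("Only COM", ("COM",)), ("ENV+DIV", ("ENV", "DIV")),
                ("ENV+COM", ("ENV", "COM")), ("DIV+COM", ("DIV", "COM")),
                ("ENV+DIV+COM", ("ENV", "DIV", "COM"))]
    best_by_row = {}
    for name, group_names in row_defs:
        pool_cols = [c for g in group_names for c in PREDICTOR_GROUPS[g]
                     if c in predictors.columns]
        result = best_subset_aic(y, predictors[pool_cols],
                                 groups=PREDICTOR_GROUPS)
        best_by_row[name] = result
        table1_rows.append(_model_row(name, result, all_cols))
    table1 = pd.DataFrame(table1_rows)
    nio_write_csv(table1, outdir / "models_table1.csv")

    # genus-abundance models (dominant genera)
    genus_rel = genus_table.relative()
    genus_rel.index = genus_table.sample_days
    ranked = genus_rel.mean(axis=0).drop(labels=["unclassified"],
                                         errors="ignore")
    top = ranked.sort_values(ascending=False).head(10).index
    genus_frame = pd.concat([response, genus_rel[top]], axis=1,
                            join="inner").dropna()
    y2 = standardize(genus_frame[["ratio"]]).to_numpy()[:, 0]
    x2 = standardize(genus_frame.drop(columns="ratio"))
    table2_rows = []
    for genus in top:
        res = fit_standardized_ols(y2, x2[[genus]])
        table2_rows.append(_model_row(f"Univariate {genus}", res, list(top)))
    multi = best_subset_aic(y2, x2)
    table2_rows.append(_model_row("Multivariate best AIC", multi, list(top)))
    table2 = pd.DataFrame(table2_rows)
    nio_write_csv(table2, outdir / "models_table2.csv")

    # --- db-RDA -----------------------------------------------------------
    env_aligned = env.loc[[d for d in table.sample_days if d in env.index]]
    rda = dbrda_variance(dist, standardize(env_aligned),
                         permutations=199, seed=_subseed(seed, 14))
    rda_df = pd.DataFrame({
        "constrained_fraction": [rda.constrained_fraction],
        "permutation_p": [rda.permutation_p],
    })
    nio_write_csv(rda_df, outdir / "dbrda.csv")

    log = {
        "config": {k: v for k, v in asdict(config).items()},
        "subseeds": {"diversity": _subseed(seed, 10),
                     "rarefied_table": _subseed(seed, 11),
                     "nmds": _subseed(seed, 12),
                     "indicators": _subseed(seed, 13),
                     "dbrda": _subseed(seed, 14)},
        "n_samples": int(table.n_samples),
        "stages_k": int(stages.k),
        "nmds_stress": ordination.stress,
    }
    (outdir / "run_log.json").write_text(json.dumps(log, indent=1,
                                                    sort_keys=True) + "\n")

    return {"partition": partition, "diversity": diversity, "dist": dist,
            "ordination": ordination, "stages": stages,
            "indicators": indicators, "trends": trends, "table1": table1,
            "table2": table2, "dbrda": rda, "gap_curve": gap_curve,
            "within_stage": within, "best_by_row": best_by_row}


def nio_write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format=nio.FLOAT_FORMAT)
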