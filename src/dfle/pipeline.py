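"""End-to-end orchestration: aggregation -> life tables -> Sullivan -> PLS.

The pipeline reads region-level demography, disability and covariate
tables, drops regions with incomplete data (exclusion, never imputation,
with the counts logged and recorded in a manifest), computes LE / DFLE /
DLE per region and sex at the index age, summarises them across regions,
and runs the two-stage VIP-pruned PLS of the four health-expectancy
responses on the regional covariates.  Identical config and seed give
byte-identical output files.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .life_table import AgeGroupSchema, default_schema
from .sullivan import health_expectancy_table, summary_table
from .pls import two_stage_fit, fig_pair_data, TwoStageResult

__all__ = [
    "VariableSpec",
    "PipelineConfig",
    "aggregate_to_regions",
    "run_analysis",
    "run_pipeline",
    "AnalysisResult",
]

log = logging.getLogger("dfle.pipeline")


@dataclass(frozen=True)
class VariableSpec:
    """One regional indicator: pooled numerator / pooled denominator * scale."""

    name: str
    numerator: str
    denominator: str | None = None
    scale: float = 1.0


def aggregate_to_regions(municipal: pd.DataFrame, crosswalk: pd.DataFrame,
                         specs: list[VariableSpec]) -> pd.DataFrame:
    """Aggregate municipality counts to regions, recomputing every ratio.

    Ratios are formed from pooled numerators and denominators — never by
    averaging municipal rates — so a small town cannot weigh as much as a
    city.  Every municipality must map to exactly one region.
    """
    if "municipality" not in municipal.columns:
        raise ValueError("municipal table needs a 'municipality' column")
    cw = crosswalk.set_index("municipality")["region"]
    if cw.index.duplicated().any():
        dupes = sorted(cw.index[cw.index.duplicated()].unique())
        raise ValueError(f"municipalities mapped to more than one region: {dupes}")
    unmapped = sorted(set(municipal["municipality"]) - set(cw.index))
    if unmapped:
        raise ValueError(f"municipalities missing from the crosswalk: {unmapped}")
    df = municipal.copy()
    df["region"] = df["municipality"].map(cw)
    pooled = df.groupby("region", sort=True).sum(numeric_only=True)
    out = pd.DataFrame(index=pooled.index)
    for spec in specs:
        if spec.numerator not in pooled.columns:
            raise ValueError(f"numerator column missing: {spec.numerator}")
        num = pooled[spec.numerator]
        if spec.denominator is None:
            out[spec.name] = num * spec.scale
        else:
            if spec.denominator not in pooled.columns:
                raise ValueError(f"denominator column missing: {spec.denominator}")
            den = pooled[spec.denominator]
            zero = den[den <= 0]
            if len(zero) > 0:
                raise ValueError(
                    f"zero pooled denominator for {spec.name} in regions "
                    f"{sorted(zero.index)}")
            out[spec.name] = num / den * spec.scale
    return out.reset_index()


@dataclass
class PipelineConfig:
    """Paths and analysis parameters of one run."""

    demography_path: str
    disability_path: str
    covariates_path: str
    out_dir: str
    index_age: float = 65.0
    age_schema: AgeGroupSchema = field(default_factory=default_schema)
    vip_threshold: float = 0.8
    alpha: float = 0.10
    k_max: int | None = None
    n_rand: int = 1999
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.vip_threshold < 0:
            raise ValueError("vip_threshold must be non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "age_schema" in d:
            from .life_table import AgeGroup
            groups = tuple(AgeGroup(float(s), float(w), bool(o))
                           for s, w, o in d.pop("age_schema"))
            d["age_schema"] = AgeGroupSchema(groups, a_fraction=d.pop("a_fraction", 0.5))
        return cls(**d)


@dataclass
class AnalysisResult:
    """Everything one run produces, before/besides writing files."""

    health_expectancy: pd.DataFrame
    summary: pd.DataFrame
    pls: TwoStageResult
    manifest: dict


def _complete_regions(demography: pd.DataFrame, disability: pd.DataFrame,
                      covariates: pd.DataFrame, schema: AgeGroupSchema
                      ) -> tuple[list, list]:
    """Split regions into complete and incomplete (any missing/NaN cell)."""
    starts = set(schema.starts)
    sexes = sorted(demography["sex"].unique())
    expected = len(starts) * len(sexes)
    regions = sorted(set(demography["region"]) | set(disability["region"])
                     | set(covariates["region"]))
    cov = covariates.set_index("region")
    complete, excluded = [], []
    demo_g = dict(tuple(demography.groupby("region")))
    dis_g = dict(tuple(disability.groupby("region")))
    for region in regions:
        ok = True
        d = demo_g.get(region)
        u = dis_g.get(region)
        for tbl, cols in ((d, ["population", "deaths"]), (u, ["unhealthy_count"])):
            if tbl is None or len(tbl) != expected:
                ok = False
                break
            if set(tbl["age_start"]) != starts or set(tbl["sex"]) != set(sexes):
                ok = False
                break
            if tbl[cols].isna().any().any():
                ok = False
                break
        if ok and (region not in cov.index or cov.loc[region].isna().any()):
            ok = False
        (complete if ok else excluded).append(region)
    return complete, excluded


def run_analysis(demography: pd.DataFrame, disability: pd.DataFrame,
                 covariates: pd.DataFrame, *, index_age: float = 65.0,
                 age_schema: AgeGroupSchema | None = None,
                 vip_threshold: float = 0.8, alpha: float = 0.10,
                 k_max: int | None = None, n_rand: int = 1999,
                 seed: int = 0) -> AnalysisResult:
    """Run the full analysis on in-memory tables (see :func:`run_pipeline`)."""
    t0 = time.perf_counter()
    schema = age_schema if age_schema is not None else default_schema(index_age)
    complete, excluded = _complete_regions(demography, disability, covariates, schema)
    n_in = len(complete) + len(excluded)
    log.info("regions: %d in, %d complete, %d excluded %s",
             n_in, len(complete), len(excluded), excluded)
    if len(complete) < 3:
        raise ValueError(f"only {len(complete)} complete regions; need at least 3")

    demo = demography[demography["region"].isin(complete)]
    dis = disability[disability["region"].isin(complete)]
    cov = (covariates[covariates["region"].isin(complete)]
           .sort_values("region").reset_index(drop=True))

    t1 = time.perf_counter()
    he = health_expectancy_table(demo, dis, schema, index_age=index_age)
    summary = summary_table(he)
    log.info("health expectancies for %d regions x %d sexes in %.2fs",
             len(complete), he["sex"].nunique(), time.perf_counter() - t1)

    # response block: DFLE and DLE per sex, region-aligned with the covariates
    wide = he.pivot(index="region", columns="sex", values=["dfle", "dle"])
    wide.columns = [f"{metric}_{sex}" for metric, sex in wide.columns]
    wide = wide.sort_index()
    Y = wide.reset_index(drop=True)
    X = cov.drop(columns=["region"])
    if not (cov["region"].to_numpy() == wide.index.to_numpy()).all():
        raise ValueError("covariate and response region alignment failed")

    t2 = time.perf_counter()
    try:
        pls_result = two_stage_fit(X, Y, vip_threshold=vip_threshold, alpha=alpha,
                                   k_max=k_max, n_rand=n_rand, seed=seed)
    except Exception as err:
        raise RuntimeError(f"PLS stage failed: {err}") from err
    log.info("two-stage PLS (%d -> %d variables, %d -> %d components) in %.2fs",
             X.shape[1], len(pls_result.retained),
             pls_result.stage1.selected, pls_result.stage2.selected,
             time.perf_counter() - t2)

    manifest = {
        "package_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": int(seed),
        "index_age": float(index_age),
        "vip_threshold": float(vip_threshold),
        "alpha": float(alpha),
        "n_rand": int(n_rand),
        "regions_in": n_in,
        "regions_analyzed": len(complete),
        "regions_excluded": len(excluded),
        "excluded_regions": [str(r) for r in excluded],
        "n_covariates": int(X.shape[1]),
        "n_retained": len(pls_result.retained),
        "stage1_selected_components": int(pls_result.stage1.selected),
        "stage2_selected_components": int(pls_result.stage2.selected),
    }
    assert manifest["regions_in"] == manifest["regions_analyzed"] + manifest["regions_excluded"]
    log.info("pipeline done in %.2fs", time.perf_counter() - t0)
    return AnalysisResult(health_expectancy=he, summary=summary,
                          pls=pls_result, manifest=manifest)


def write_outputs(result: AnalysisResult, out_dir) -> None:
    """Write the artifact bundle (CSV tables + JSON manifest)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.health_expectancy.to_csv(out / "health_expectancy.csv", index=False)
    result.summary.to_csv(out / "summary.csv", index=False)
    r = result.pls
    curve = r.curve2
    press = r.stage2.table.rename(columns={"p_value": "vdv_p"})
    full = pd.DataFrame({"k": np.arange(len(curve.press)), "press": curve.press})
    press_out = full.merge(press[["k", "vdv_p"]], on="k", how="left")
    press_out.to_csv(out / "press_curve.csv", index=False)
    r.vip2.rename_axis("variable").reset_index().to_csv(out / "vip.csv", index=False)
    r.vip1.rename_axis("variable").reset_index().to_csv(out / "vip_stage1.csv", index=False)
    r.loadings.to_csv(out / "loadings.csv", index=False)
    r.explained.to_csv(out / "explained.csv", index=False)
    fig_pair_data(r.loadings).to_csv(out / "fig1_data.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=2,
                                                  sort_keys=True) + "\n")


def run_pipeline(config: PipelineConfig) -> AnalysisResult:
    """Load the input CSVs, run the analysis and write the artifact bundle."""
    demography = pd.read_csv(config.demography_path)
    disability = pd.read_csv(config.disability_path)
    covariates = pd.read_csv(config.covariates_path)
    result = run_analysis(
        demography, disability, covariates,
        index_age=config.index_age, age_schema=config.age_schema,
        vip_threshold=config.vip_threshold, alpha=config.alpha,
        k_max=config.k_max, n_rand=config.n_rand, seed=config.seed)
    write_outputs(result, config.out_dir)
    return result
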