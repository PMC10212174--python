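"""Sullivan-method health expectancies and their regional summary.

Dementia-free life expectancy (De-FLE) at an index age ``x0`` combines a
period life table with cross-sectional prevalence of dementia-related
disability (here, Independence Level II or higher under Japan's Degree of
Independence in Daily Living for the Demented Elderly):

    DFLE(x0) = sum_{x >= x0} (1 - pi_x) * L_x / l_{x0}

Life expectancy with dementia is the complement, DLE = LE - DFLE, the
expected years lived above the disability threshold.  People absent from
the disability (claims) data count as healthy, so the prevalence
denominator is the whole age-group population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .life_table import AgeGroupSchema, central_death_rates, build_life_table

__all__ = [
    "HealthExpectancy",
    "RegionSummary",
    "prevalence",
    "sullivan_health_expectancy",
    "health_expectancy_table",
    "mean_ci",
    "summarize_regions",
    "summary_table",
]

#: columns expected in a tidy disability table
DISABILITY_COLUMNS = ("region", "sex", "age_start", "unhealthy_count")

#: normal quantile for a two-sided 95% confidence interval
Z_95 = 1.96


@dataclass(frozen=True)
class HealthExpectancy:
    """Life expectancy split at an index age: LE = DFLE + DLE."""

    index_age: float
    le: float
    dfle: float
    dle: float
    region: object = None
    sex: object = None


@dataclass(frozen=True)
class RegionSummary:
    """Across-region descriptive statistics of one metric."""

    n: int
    mean: float
    sd: float
    q25: float
    q50: float
    q75: float
    ci_low: float
    ci_high: float


def prevalence(unhealthy: np.ndarray, population: np.ndarray,
               labels: list | None = None) -> np.ndarray:
    """Proportion unhealthy per age group, ``pi_x = U_x / N_x``."""
    u = np.asarray(unhealthy, dtype=float)
    n = np.asarray(population, dtype=float)
    if u.shape != n.shape:
        raise ValueError("unhealthy and population vectors must have the same length")

    def _label(i: int) -> str:
        return str(labels[i]) if labels is not None else f"group {i}"

    for i in range(len(u)):
        if n[i] <= 0:
            raise ValueError(f"non-positive population in {_label(i)}")
        if u[i] < 0:
            raise ValueError(f"negative unhealthy count in {_label(i)}")
        if u[i] > n[i]:
            raise ValueError(f"unhealthy count exceeds population in {_label(i)}")
    return u / n


def sullivan_health_expectancy(life_table: pd.DataFrame, pi: np.ndarray,
                               index_age: float, region=None, sex=None) -> HealthExpectancy:
    """Sullivan weighting of life-table person-years by disability prevalence.

    ``pi`` must align with the life-table rows (same age schema).  The index
    age must be one of the table's group start ages.
    """
    pi = np.asarray(pi, dtype=float)
    if len(pi) != len(life_table):
        raise ValueError("prevalence vector does not match the life-table age schema")
    if np.any((pi < 0) | (pi > 1)):
        raise ValueError("prevalence values must lie in [0, 1]")
    ages = life_table["age_start"].to_numpy(dtype=float)
    at = np.flatnonzero(ages == float(index_age))
    if len(at) == 0:
        raise ValueError(f"index age {index_age} is not a group start age")
    i0 = int(at[0])
    keep = slice(i0, None)
    L = life_table["L"].to_numpy(dtype=float)[keep]
    l0 = float(life_table["l"].to_numpy(dtype=float)[i0])
    le = float(life_table["e"].to_numpy(dtype=float)[i0])
    dfle = float(np.sum((1.0 - pi[keep]) * L) / l0)
    return HealthExpectancy(index_age=float(index_age), le=le, dfle=dfle,
                            dle=le - dfle, region=region, sex=sex)


def health_expectancy_table(demography: pd.DataFrame, disability: pd.DataFrame,
                            schema: AgeGroupSchema, index_age: float = 65.0,
                            radix: float = 100_000.0) -> pd.DataFrame:
    """LE / DFLE / DLE for every (region, sex), lexicographic order.

    Demography and disability tables must cover identical
    (region, sex, age_start) cells; a missing cell is an error (regions with
    incomplete data should be excluded upstream, never imputed).
    """
    missing = set(DISABILITY_COLUMNS) - set(disability.columns)
    if missing:
        raise ValueError(f"disability table is missing columns: {sorted(missing)}")
    starts = schema.starts
    dis = disability.set_index(["region", "sex", "age_start"]).sort_index()
    rows = []
    for (region, sex), grp in demography.groupby(["region", "sex"], sort=True):
        grp = grp.sort_values("age_start")
        if not np.array_equal(grp["age_start"].to_numpy(dtype=float), starts):
            raise ValueError(
                f"region {region!r} sex {sex!r}: age groups do not match the schema")
        labels = [f"region {region!r} sex {sex!r} age {int(s)}" for s in starts]
        try:
            u = np.array([dis.loc[(region, sex, s), "unhealthy_count"] for s in starts],
                         dtype=float)
        except KeyError as err:
            raise ValueError(
                f"disability cell missing for region {region!r} sex {sex!r}: {err}") from None
        pop = grp["population"].to_numpy()
        m = central_death_rates(pop, grp["deaths"].to_numpy(), labels)
        pi = prevalence(u, pop, labels)
        lt = build_life_table(m, schema, radix=radix)
        he = sullivan_health_expectancy(lt, pi, index_age, region=region, sex=sex)
        rows.append({"region": region, "sex": sex, "index_age": he.index_age,
                     "le": he.le, "dfle": he.dfle, "dle": he.dle})
    return pd.DataFrame(rows)


def mean_ci(mean: float, sd: float, n: int, z: float = Z_95) -> tuple[float, float]:
    """Normal-approximation CI of a mean: mean +/- z * sd / sqrt(n)."""
    half = z * sd / np.sqrt(n)
    return mean - half, mean + half


def summarize_regions(values) -> RegionSummary:
    """Mean, SD (n-1), quartiles and 95% CI of the mean across regions.

    Quartiles use linear interpolation between order statistics.  Missing
    values are an error: incomplete regions are excluded, not imputed.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need at least two regional values to summarize")
    if np.any(~np.isfinite(v)):
        raise ValueError("missing or non-finite values in regional metric")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    q25, q50, q75 = np.percentile(v, [25, 50, 75])
    lo, hi = mean_ci(mean, sd, len(v))
    return RegionSummary(n=len(v), mean=mean, sd=sd,
                         q25=float(q25), q50=float(q50), q75=float(q75),
                         ci_low=float(lo), ci_high=float(hi))


def summary_table(he: pd.DataFrame) -> pd.DataFrame:
    """Descriptive-statistics table of LE, DFLE, DLE per sex across regions."""
    rows = []
    for sex, grp in he.groupby("sex", sort=True):
        for metric in ("le", "dfle", "dle"):
            s = summarize_regions(grp[metric].to_numpy())
            rows.append({"metric": metric, "sex": sex, "n": s.n, "mean": s.mean,
                         "sd": s.sd, "q25": s.q25, "q50": s.q50, "q75": s.q75,
                         "ci_low": s.ci_low, "ci_high": s.ci_high})
    return pd.DataFrame(rows)
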