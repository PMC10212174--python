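"""Abridged period life tables from region/sex/age-group counts.

The table follows the classic abridged construction: central death rates
``m_x = D_x / N_x`` (deaths over mid-year population, one-year observation
window) are converted to death probabilities with the Chiang formula

    q_x = n_x * m_x / (1 + (1 - a) * n_x * m_x)

where ``n_x`` is the group width and ``a`` the average fraction of the
interval lived by those who die in it (0.5 by default).  The open-ended
last group gets ``q = 1`` and person-years ``L = l / m`` (exponential
tail).  Remaining life expectancy is ``e_x = T_x / l_x``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AgeGroup",
    "AgeGroupSchema",
    "default_schema",
    "central_death_rates",
    "build_life_table",
    "life_tables_from_counts",
]

#: columns expected in a tidy demography table
DEMOGRAPHY_COLUMNS = ("region", "sex", "age_start", "population", "deaths")


@dataclass(frozen=True)
class AgeGroup:
    """One age interval: start age in years, width in years, open-ended flag."""

    start: float
    width: float
    is_open: bool = False


@dataclass(frozen=True)
class AgeGroupSchema:
    """Ordered age grouping plus the fraction ``a`` of the interval lived by decedents."""

    groups: tuple[AgeGroup, ...]
    a_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("schema needs at least one age group")
        starts = [g.start for g in self.groups]
        if any(s2 <= s1 for s1, s2 in zip(starts, starts[1:])):
            raise ValueError("age-group start ages must be strictly increasing")
        if any(g.width <= 0 for g in self.groups):
            raise ValueError("age-group widths must be positive")
        open_flags = [g.is_open for g in self.groups]
        if sum(open_flags) != 1 or not self.groups[-1].is_open:
            raise ValueError("exactly one open-ended group is required, and it must be last")
        if not 0.0 < self.a_fraction < 1.0:
            raise ValueError("a_fraction must lie strictly between 0 and 1")

    @property
    def starts(self) -> np.ndarray:
        return np.array([g.start for g in self.groups], dtype=float)

    @property
    def widths(self) -> np.ndarray:
        return np.array([g.width for g in self.groups], dtype=float)

    @property
    def midpoints(self) -> np.ndarray:
        """Representative age per group; the open group uses start + half a nominal width."""
        mid = self.starts + self.widths / 2.0
        return mid

    def __len__(self) -> int:
        return len(self.groups)


def default_schema(index_age: float = 65.0, width: float = 5.0,
                   open_start: float = 95.0, a_fraction: float = 0.5) -> AgeGroupSchema:
    """Five-year groups from the index age up to an open-ended last group.

    The default (65-69 ... 90-94, 95+) matches an age-65 index for
    health-expectancy work on the older population.
    """
    starts = np.arange(index_age, open_start, width)
    groups = [AgeGroup(float(s), float(width)) for s in starts]
    groups.append(AgeGroup(float(open_start), float(width), is_open=True))
    return AgeGroupSchema(tuple(groups), a_fraction=a_fraction)


def central_death_rates(population: np.ndarray, deaths: np.ndarray,
                        labels: list | None = None) -> np.ndarray:
    """``m_x = D_x / N_x`` per age group, in deaths per person-year.

    ``labels`` (one per group) is used to identify the offending cell in
    error messages.
    """
    pop = np.asarray(population, dtype=float)
    dth = np.asarray(deaths, dtype=float)
    if pop.shape != dth.shape:
        raise ValueError("population and deaths must have the same length")

    def _label(i: int) -> str:
        return str(labels[i]) if labels is not None else f"group {i}"

    for i in range(len(pop)):
        if pop[i] <= 0:
            raise ValueError(f"non-positive population in {_label(i)}")
        if dth[i] < 0:
            raise ValueError(f"negative deaths in {_label(i)}")
        if dth[i] > pop[i]:
            raise ValueError(f"deaths exceed population in {_label(i)}")
    return dth / pop


def build_life_table(m: np.ndarray, schema: AgeGroupSchema,
                     radix: float = 100_000.0) -> pd.DataFrame:
    """Abridged life table from central death rates.

    Returns a DataFrame with one row per age group and columns
    ``age_start, width, m, q, l, d, L, T, e``.  Death probabilities use the
    Chiang conversion for closed intervals and ``q = 1`` at the open
    interval, whose person-years are ``l / m`` (constant-hazard tail).
    """
    m = np.asarray(m, dtype=float)
    if len(m) != len(schema):
        raise ValueError("rate vector length does not match the age schema")
    if np.any(m < 0):
        raise ValueError("central death rates must be non-negative")
    if m[-1] <= 0:
        raise ValueError("open-interval rate must be positive")

    n = schema.widths
    a = schema.a_fraction
    q = n * m / (1.0 + (1.0 - a) * n * m)
    # Chiang's conversion can exceed 1 for extreme rates (n*m > 1/a); cap it.
    q = np.minimum(q, 1.0)
    q[-1] = 1.0

    G = len(m)
    l = np.empty(G)
    d = np.empty(G)
    l[0] = radix
    for i in range(G - 1):
        d[i] = l[i] * q[i]
        l[i + 1] = l[i] - d[i]
    d[-1] = l[-1]

    L = n * l - n * d * (1.0 - a)          # = n*(l-d) + a*n*d
    L[-1] = l[-1] / m[-1]
    T = np.cumsum(L[::-1])[::-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(l > 0, T / l, 0.0)

    return pd.DataFrame({
        "age_start": schema.starts,
        "width": n,
        "m": m,
        "q": q,
        "l": l,
        "d": d,
        "L": L,
        "T": T,
        "e": e,
    })


def life_tables_from_counts(demography: pd.DataFrame, schema: AgeGroupSchema,
                            radix: float = 100_000.0) -> pd.DataFrame:
    """Life tables for every (region, sex) in a tidy demography table.

    ``demography`` needs columns region, sex, age_start, population, deaths
    with a complete set of age groups per (region, sex).  Iteration order is
    lexicographic in (region, sex) for reproducible output.
    """
    missing = set(DEMOGRAPHY_COLUMNS) - set(demography.columns)
    if missing:
        raise ValueError(f"demography table is missing columns: {sorted(missing)}")
    starts = schema.starts
    out = []
    for (region, sex), grp in demography.groupby(["region", "sex"], sort=True):
        grp = grp.sort_values("age_start")
        if not np.array_equal(grp["age_start"].to_numpy(dtype=float), starts):
            raise ValueError(
                f"region {region!r} sex {sex!r}: age groups do not match the schema")
        labels = [f"region {region!r} sex {sex!r} age {int(s)}" for s in starts]
        m = central_death_rates(grp["population"].to_numpy(),
                                grp["deaths"].to_numpy(), labels)
        lt = build_life_table(m, schema, radix=radix)
        lt.insert(0, "sex", sex)
        lt.insert(0, "region", region)
        out.append(lt)
    return pd.concat(out, ignore_index=True)
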