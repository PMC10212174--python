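"""Region-level synthetic demography, disability and covariate data.

Real analyses of dementia-free life expectancy at the small-area level rest
on restricted long-term-care claims data that cannot be redistributed.
This generator emulates such data with known ground truth so that every
downstream stage (life table, Sullivan weighting, PLS) can be tested for
parameter recovery:

* each region gets latent scores Z ~ N(0, I) on a small number of factors
  (by default three: urbanicity, socioeconomic conditions, healthcare
  resources);
* regional covariates are X = Z @ loading_matrix + noise;
* age-group mortality follows a Gompertz hazard
  m(x) = a * exp(b * x) * exp(mortality_effect . Z), evaluated at the group
  midpoint;
* dementia-disability prevalence is logistic in age with a latent shift:
  pi(x) = expit(prev_intercept + prev_slope * x + prevalence_effect . Z);
* deaths and unhealthy counts are Binomial(N, .) draws per cell (one-year
  observation window, so the death probability is 1 - exp(-m)); counts can
  therefore never exceed the population;
* the true dementia-free life expectancy per region/sex is computed by
  piping the noiseless generating rates through the production life-table
  and Sullivan code.

Females get lower mortality (multiplier on the Gompertz level) and higher
disability prevalence (log-odds shift), mirroring the well-known pattern of
longer life but more years with dementia-related disability.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .life_table import AgeGroupSchema, default_schema, build_life_table
from .sullivan import sullivan_health_expectancy

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "default_loading_matrix",
    "simulate_dataset",
    "true_component_structure",
    "simulate_latent_pls",
]

_FACTOR_NAMES = ("urbanicity", "socioeconomic", "healthcare")


def default_loading_matrix(latent_dim: int = 3, per_factor: int = 4,
                           loading: float = 1.0) -> np.ndarray:
    """Block loading matrix: each factor drives ``per_factor`` covariates."""
    p = latent_dim * per_factor
    lam = np.zeros((latent_dim, p))
    for k in range(latent_dim):
        lam[k, k * per_factor:(k + 1) * per_factor] = loading
    return lam


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimulationConfig:
    """Parameters of the regional generator.

    Defaults target a plausible older-population setting: 333 regions (the
    number of secondary medical areas analysed in Japanese small-area
    work), five-year age groups 65-94 plus 95+, Gompertz mortality rising
    from ~1.5% per year at 65-69 to ~26% at 95+, and disability prevalence
    rising from ~1% to ~60% over the same range; that yields a life
    expectancy at 65 of roughly 19.5 years for males and 23.5 for females,
    of which about 1.8 and 4.0 years are lived with dementia-related
    disability.  The socioeconomic factor
    (index 1) lowers both prevalence and mortality by default, so regions
    with better socioeconomic conditions have longer dementia-free life
    expectancy — the structure the analysis is meant to recover.
    """

    n_regions: int = 333
    age_schema: AgeGroupSchema = field(default_factory=default_schema)
    gompertz_a: float = 2.5e-5
    gompertz_b: float = 0.095
    prev_intercept: float = -16.2
    prev_slope: float = 0.17
    latent_dim: int = 3
    loading_matrix: np.ndarray | None = None
    covariate_noise_sd: float = 0.5
    prevalence_effect: np.ndarray | None = None     # log-odds shift per unit latent score
    mortality_effect: np.ndarray | None = None      # log-hazard shift per unit latent score
    female_mortality_factor: float = 0.64
    female_prevalence_shift: float = 0.4            # log-odds
    population_per_group: int = 5000
    seed: int = 0
    deterministic: bool = False

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")
        if self.population_per_group < 1:
            raise ValueError("population_per_group must be positive")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be positive")
        if self.loading_matrix is None:
            self.loading_matrix = default_loading_matrix(self.latent_dim)
        self.loading_matrix = np.asarray(self.loading_matrix, dtype=float)
        if self.loading_matrix.shape[0] != self.latent_dim:
            raise ValueError("loading_matrix must have latent_dim rows")
        if self.prevalence_effect is None:
            self.prevalence_effect = np.zeros(self.latent_dim)
            if self.latent_dim >= 2:
                self.prevalence_effect[1] = -0.25
        self.prevalence_effect = np.asarray(self.prevalence_effect, dtype=float)
        if self.mortality_effect is None:
            self.mortality_effect = np.zeros(self.latent_dim)
            if self.latent_dim >= 2:
                self.mortality_effect[1] = -0.05
        self.mortality_effect = np.asarray(self.mortality_effect, dtype=float)
        for name in ("prevalence_effect", "mortality_effect"):
            if getattr(self, name).shape != (self.latent_dim,):
                raise ValueError(f"{name} must have length latent_dim")
        for name in ("gompertz_a", "gompertz_b", "prev_intercept", "prev_slope",
                     "covariate_noise_sd", "female_mortality_factor",
                     "female_prevalence_shift"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.gompertz_a <= 0:
            raise ValueError("gompertz_a must be positive")
        if self.covariate_noise_sd < 0:
            raise ValueError("covariate_noise_sd must be non-negative")

    @property
    def covariate_names(self) -> list[str]:
        p = self.loading_matrix.shape[1]
        if self.latent_dim == len(_FACTOR_NAMES) and p % self.latent_dim == 0:
            per = p // self.latent_dim
            return [f"{_FACTOR_NAMES[k]}_{j + 1}" for k in range(self.latent_dim)
                    for j in range(per)]
        return [f"cov_{j + 1}" for j in range(p)]

    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["age_schema"] = [[g.start, g.width, g.is_open] for g in self.age_schema.groups]
        d["a_fraction"] = self.age_schema.a_fraction
        for key in ("loading_matrix", "prevalence_effect", "mortality_effect"):
            d[key] = np.asarray(d[key]).tolist()
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "age_schema" in d:
            from .life_table import AgeGroup
            groups = tuple(AgeGroup(float(s), float(w), bool(o))
                           for s, w, o in d.pop("age_schema"))
            d["age_schema"] = AgeGroupSchema(groups, a_fraction=d.pop("a_fraction", 0.5))
        for key in ("loading_matrix", "prevalence_effect", "mortality_effect"):
            if d.get(key) is not None:
                d[key] = np.asarray(d[key], dtype=float)
        return cls(**d)


@dataclass
class SyntheticDataset:
    """Generated counts, covariates and ground truth."""

    demography: pd.DataFrame       # region, sex, age_start, population, deaths
    disability: pd.DataFrame       # region, sex, age_start, unhealthy_count
    covariates: pd.DataFrame       # region + one column per indicator
    latent_scores: pd.DataFrame    # region + one column per latent factor
    true_dfle: pd.DataFrame        # region, sex, true_dfle
    config: SimulationConfig

    def to_csv(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.demography.to_csv(out / "demography.csv", index=False)
        self.disability.to_csv(out / "disability.csv", index=False)
        self.covariates.to_csv(out / "covariates.csv", index=False)
        self.latent_scores.to_csv(out / "latent_scores.csv", index=False)
        self.true_dfle.to_csv(out / "true_dfle.csv", index=False)


def _cell_rates(cfg: SimulationConfig, z: np.ndarray, sex: str
                ) -> tuple[np.ndarray, np.ndarray]:
    """Noiseless (hazard, prevalence) vectors over age groups for one region/sex."""
    x = cfg.age_schema.midpoints
    level = cfg.gompertz_a * (cfg.female_mortality_factor if sex == "female" else 1.0)
    m = level * np.exp(cfg.gompertz_b * x) * np.exp(float(cfg.mortality_effect @ z))
    shift = cfg.female_prevalence_shift if sex == "female" else 0.0
    pi = _expit(cfg.prev_intercept + cfg.prev_slope * x
                + float(cfg.prevalence_effect @ z) + shift)
    if np.any(~np.isfinite(m)) or np.any(~np.isfinite(pi)):
        raise ValueError("mortality/prevalence parameters produce non-finite rates")
    return m, pi


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Draw one dataset; identical config and seed give identical output.

    Deterministic mode replaces Binomial draws by their exact expectations
    (non-integer counts), which makes downstream recovery of the ground
    truth exact rather than statistical.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    R = cfg.n_regions
    lam = cfg.loading_matrix
    p = lam.shape[1]
    regions = [f"R{str(i + 1).zfill(len(str(R)))}" for i in range(R)]

    Z = rng.standard_normal((R, cfg.latent_dim))
    noise = rng.standard_normal((R, p)) * cfg.covariate_noise_sd
    X = Z @ lam + noise

    starts = cfg.age_schema.starts
    N = cfg.population_per_group
    demo_rows, dis_rows, truth_rows = [], [], []
    for r, region in enumerate(regions):
        for sex in ("female", "male"):
            m, pi = _cell_rates(cfg, Z[r], sex)
            p_death = -np.expm1(-m)          # one-year death probability
            if cfg.deterministic:
                deaths = N * p_death
                unhealthy = N * pi
            else:
                deaths = rng.binomial(N, p_death).astype(float)
                unhealthy = rng.binomial(N, pi).astype(float)
            for g, s in enumerate(starts):
                demo_rows.append({"region": region, "sex": sex, "age_start": s,
                                  "population": N, "deaths": deaths[g]})
                dis_rows.append({"region": region, "sex": sex, "age_start": s,
                                 "unhealthy_count": unhealthy[g]})
            # ground truth: the rates the estimator targets (expected deaths / N)
            lt = build_life_table(p_death, cfg.age_schema)
            he = sullivan_health_expectancy(lt, pi, cfg.age_schema.starts[0])
            truth_rows.append({"region": region, "sex": sex, "true_dfle": he.dfle})

    covariates = pd.DataFrame(X, columns=cfg.covariate_names)
    covariates.insert(0, "region", regions)
    latent = pd.DataFrame(Z, columns=[f"factor_{k + 1}" for k in range(cfg.latent_dim)])
    latent.insert(0, "region", regions)
    return SyntheticDataset(
        demography=pd.DataFrame(demo_rows),
        disability=pd.DataFrame(dis_rows),
        covariates=covariates,
        latent_scores=latent,
        true_dfle=pd.DataFrame(truth_rows),
        config=cfg,
    )


def simulate_latent_pls(n: int = 200, p_informative: int = 20, p_noise: int = 0,
                        n_factors: int = 3, x_noise_sd: float = 0.05,
                        y_noise_sd: float = 0.5, response_strength: float = 2.0,
                        seed: int = 0
                        ) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Bare latent-factor regression data for exercising the PLS machinery.

    ``n_factors`` standard-normal factors drive ``p_informative`` predictor
    columns (random normal loadings, small measurement noise so the
    informative block has essentially the factors' rank) and one response
    per factor with coefficient ``response_strength`` plus substantial
    response noise.  ``p_noise`` extra predictor columns are pure standard
    normal noise, unrelated to anything — the ground-truth labels for
    variable-selection checks.  Returns (X, Y, factor scores).
    """
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n, n_factors))
    B = rng.standard_normal((n_factors, p_informative))
    X_inf = Z @ B + x_noise_sd * rng.standard_normal((n, p_informative))
    cols = [f"inf_{j + 1}" for j in range(p_informative)]
    if p_noise > 0:
        X_noise = rng.standard_normal((n, p_noise))
        X = np.hstack([X_inf, X_noise])
        cols += [f"noise_{j + 1}" for j in range(p_noise)]
    else:
        X = X_inf
    Y = Z * response_strength + y_noise_sd * rng.standard_normal((n, n_factors))
    return (pd.DataFrame(X, columns=cols),
            pd.DataFrame(Y, columns=[f"resp_{k + 1}" for k in range(n_factors)]),
            Z)


def true_component_structure(dataset: SyntheticDataset) -> pd.DataFrame:
    """Pearson correlation of each latent factor with true DFLE, per sex.

    The report is the oracle for recovery tests: it says which factor a
    correctly working analysis should find associated with dementia-free
    life expectancy.
    """
    factors = [c for c in dataset.latent_scores.columns if c != "region"]
    Z = dataset.latent_scores.set_index("region")
    rows = []
    for sex, grp in dataset.true_dfle.groupby("sex", sort=True):
        y = grp.set_index("region")["true_dfle"].reindex(Z.index).to_numpy()
        if np.std(y) == 0:
            raise ValueError(f"true_dfle is constant for sex {sex!r}; correlations undefined")
        for name in factors:
            z = Z[name].to_numpy()
            rows.append({"sex": sex, "factor": name,
                         "correlation": float(np.corrcoef(z, y)[0, 1])})
    return pd.DataFrame(rows)
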