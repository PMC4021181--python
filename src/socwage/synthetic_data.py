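"""Seeded generators for master (wage) and target (health) survey microdata.

The generators emulate the statistical structure the method assumes so
that every stage of the pipeline is exercisable without access-restricted
survey files: log-normal wages with independent group effects at the
minor and unit classification tiers, age and sex fixed effects, annual
price inflation (so preprocessing has real deflation work to do),
transitory multiplicative noise on reported income, and a latent-logit
link from the true wage to a binary poor-health indicator.

Default effect sizes and variance components are on the scale of a large
national labour-force survey: intercept ~5.1 log-GBP (~165 GBP/week at
age 0), +0.005 log-GBP per year of age, +0.27 log-GBP for men, minor and
unit intercept SDs of sqrt(0.14) and sqrt(0.10), a unit-tier age-slope
SD of sqrt(3e-5), no minor-tier slope variation, and residual SD
sqrt(0.28).  These are scenario parameters for the generator, not claims
about any particular survey.

All draws derive from one seed through named, stage-split substreams
(numpy SeedSequence spawn keys), so adding a stage never perturbs
earlier draws and master/health surveys built from the same config share
the same group effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit

from .preprocess import CPITable
from .soc import ClassificationTable, Tier

__all__ = ["GeneratorConfig", "generate_classification", "generate_master",
           "generate_health_survey", "cpi_table", "group_effects"]

# Fixed spawn keys per generator stage.
_STAGES = {"classification": 0, "group_effects": 1, "master_people": 2,
           "survey_people": 3, "income_noise": 4, "health": 5,
           "missingness": 6}


@dataclass(frozen=True)
class GeneratorConfig:
    """Scenario parameters of the synthetic population (log-GBP scale)."""

    n_minor: int = 80
    units_per_minor: int | tuple[int, int] = (3, 5)
    n_obs: int = 50_000
    n_survey: int = 10_000

    beta0: float = 5.1
    beta_age: float = 0.005
    beta_male: float = 0.27
    sd_minor_int: float = math.sqrt(0.14)
    sd_minor_slope: float = 0.0
    sd_unit_int: float = math.sqrt(0.10)
    sd_unit_slope: float = math.sqrt(3e-5)
    sd_resid: float = math.sqrt(0.28)

    age_range_female: tuple[int, int] = (16, 60)
    age_range_male: tuple[int, int] = (16, 65)
    male_fraction: float = 0.5

    years: tuple[int, ...] = tuple(range(2001, 2011))
    cpi_reference_year: int = 2006
    cpi_annual_growth: float = 0.025

    frac_unemployed: float = 0.03
    frac_missing_wage: float = 0.02

    # Reported income = true wage x exp(N(0, transitory_income_sd^2)):
    # single-time-point income mismeasures the medium-term average.
    transitory_income_sd: float = 0.25

    # Latent poor-health logit: alpha + gamma*(true wage/100) + age/sex terms.
    health_alpha: float = -0.7
    health_gamma: float = -0.4
    health_beta_age: float = 0.02
    health_beta_male: float = -0.1

    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sd_minor_int", "sd_minor_slope", "sd_unit_int",
                     "sd_unit_slope", "sd_resid", "transitory_income_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.male_fraction <= 1:
            raise ValueError("male_fraction must be in [0, 1]")
        lo, hi = self.units_range
        if self.n_obs < self.n_minor * lo:
            raise ValueError("n_obs must be >= n_minor * units_per_minor")

    @property
    def units_range(self) -> tuple[int, int]:
        u = self.units_per_minor
        return (u, u) if isinstance(u, int) else tuple(u)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["units_per_minor"] = list(self.units_range)
        d["years"] = list(self.years)
        return d


def _rng(config: GeneratorConfig, stage: str) -> np.random.Generator:
    ss = np.random.SeedSequence(config.seed, spawn_key=(_STAGES[stage],))
    return np.random.default_rng(ss)


def generate_classification(config: GeneratorConfig) -> ClassificationTable:
    """A synthetic tiered classification: 4-digit units nested in 3-digit minors."""
    if config.n_minor > 999:
        raise ValueError("at most 999 minor groups fit in 3-digit codes")
    lo, hi = config.units_range
    if hi > 9:
        raise ValueError("at most 9 unit groups fit per minor (digit capacity)")
    rng = _rng(config, "classification")
    minors = np.sort(rng.choice(np.arange(1, 1000), size=config.n_minor,
                                replace=False))
    n_units = rng.integers(lo, hi + 1, size=config.n_minor)
    codes = [f"{m:03d}{d}"
             for m, k in zip(minors, n_units) for d in range(1, int(k) + 1)]
    return ClassificationTable.from_codes(codes)


def cpi_table(config: GeneratorConfig) -> CPITable:
    """Annual CPI with constant relative growth, indexed 100 at the reference year."""
    years = sorted(set(config.years) | {config.cpi_reference_year})
    ref = config.cpi_reference_year
    index = {y: 100.0 * (1.0 + config.cpi_annual_growth) ** (y - ref)
             for y in years}
    return CPITable(index=index, reference_year=ref)


def group_effects(config: GeneratorConfig,
                  table: ClassificationTable) -> tuple[dict, dict]:
    """Random intercepts/slopes per minor and unit group, shared across surveys.

    Drawn from a dedicated seed stream in sorted code order, so the master
    and health-survey generators see identical group effects for the same
    (config, classification).
    """
    rng = _rng(config, "group_effects")
    minors = table.minor_codes
    units = table.unit_codes
    minor_fx = {
        m: {"intercept": rng.normal(0.0, config.sd_minor_int),
            "slope": rng.normal(0.0, config.sd_minor_slope)}
        for m in minors
    }
    unit_fx = {
        u: {"intercept": rng.normal(0.0, config.sd_unit_int),
            "slope": rng.normal(0.0, config.sd_unit_slope)}
        for u in units
    }
    return minor_fx, unit_fx


def _draw_people(config: GeneratorConfig, rng: np.random.Generator, n: int,
                 table: ClassificationTable):
    units = np.array(table.unit_codes)
    unit = rng.choice(units, size=n)
    male = rng.random(n) < config.male_fraction
    age = np.empty(n, dtype=int)
    flo, fhi = config.age_range_female
    mlo, mhi = config.age_range_male
    age[~male] = rng.integers(flo, fhi + 1, size=int((~male).sum()))
    age[male] = rng.integers(mlo, mhi + 1, size=int(male.sum()))
    return unit, male, age


def _true_log_wage(config: GeneratorConfig, unit, male, age,
                   minor_fx: dict, unit_fx: dict,
                   rng: np.random.Generator) -> np.ndarray:
    u = np.array([minor_fx[c[:3]]["intercept"] for c in unit])
    a = np.array([minor_fx[c[:3]]["slope"] for c in unit])
    v = np.array([unit_fx[c]["intercept"] for c in unit])
    b = np.array([unit_fx[c]["slope"] for c in unit])
    eps = rng.normal(0.0, config.sd_resid, size=len(unit))
    return (config.beta0 + config.beta_age * age
            + config.beta_male * male.astype(float)
            + u + v + (a + b) * age + eps)


def generate_master(config: GeneratorConfig,
                    table: ClassificationTable | None = None) -> pd.DataFrame:
    """Raw wage-survey records: one row per person, wages at survey-year prices.

    Wages are generated at reference-year price levels and then inflated
    by the survey year's CPI, so downstream preprocessing must deflate
    them back.  A small fraction of records is unemployed or missing a
    wage, exercising the cleaning filters.  Deterministic given config.
    """
    table = table or generate_classification(config)
    minor_fx, unit_fx = group_effects(config, table)
    rng = _rng(config, "master_people")
    unit, male, age = _draw_people(config, rng, config.n_obs, table)
    logw = _true_log_wage(config, unit, male, age, minor_fx, unit_fx, rng)
    year = rng.choice(np.array(config.years), size=config.n_obs)
    cpi = cpi_table(config)
    infl = np.array([cpi.index[int(y)] / cpi.index[cpi.reference_year]
                     for y in year])
    wage = np.exp(logw) * infl

    rng_miss = _rng(config, "missingness")
    employed = rng_miss.random(config.n_obs) >= config.frac_unemployed
    wage = np.where(rng_miss.random(config.n_obs) < config.frac_missing_wage,
                    np.nan, wage)
    return pd.DataFrame({
        "person_id": [f"L{i:07d}" for i in range(config.n_obs)],
        "age": age,
        "sex": np.where(male, "male", "female"),
        "soc": unit,
        "wage": wage,
        "year": year,
        "employed": employed,
    })


def generate_health_survey(config: GeneratorConfig,
                           table: ClassificationTable | None = None
                           ) -> pd.DataFrame:
    """Target-survey records with reported income and a binary health outcome.

    True wages come from the same wage process (and the same group
    effects) as the master generator, at reference-year prices.
    Reported income multiplies the true wage by log-normal transitory
    noise.  Poor health is Bernoulli with logit linear in true wage (per
    100 GBP), age and sex.  A 5-level categorical ``sep_class`` covariate
    is derived by binning each minor group's intercept effect; it is a
    synthetic stand-in for social-class / area-deprivation adjustment
    covariates.
    """
    table = table or generate_classification(config)
    minor_fx, unit_fx = group_effects(config, table)
    rng = _rng(config, "survey_people")
    unit, male, age = _draw_people(config, rng, config.n_survey, table)
    logw = _true_log_wage(config, unit, male, age, minor_fx, unit_fx, rng)
    true_wage = np.exp(logw)

    rng_inc = _rng(config, "income_noise")
    if config.transitory_income_sd > 0:
        noise = rng_inc.normal(0.0, config.transitory_income_sd,
                               size=config.n_survey)
    else:
        noise = np.zeros(config.n_survey)
    reported = true_wage * np.exp(noise)

    rng_h = _rng(config, "health")
    logit = (config.health_alpha + config.health_gamma * true_wage / 100.0
             + config.health_beta_age * age
             + config.health_beta_male * male.astype(float))
    poor = (rng_h.random(config.n_survey) < expit(logit)).astype(int)

    # SEP stand-in: quintile of the minor-group wage effect.
    minors = sorted(minor_fx)
    eff = np.array([minor_fx[m]["intercept"] for m in minors])
    quint = {m: int(q) for m, q in
             zip(minors, np.searchsorted(np.quantile(eff, [0.2, 0.4, 0.6, 0.8]),
                                         eff, side="right") + 1)}
    sep = np.array([f"class_{quint[c[:3]]}" for c in unit])

    return pd.DataFrame({
        "person_id": [f"S{i:07d}" for i in range(config.n_survey)],
        "age": age,
        "sex": np.where(male, "male", "female"),
        "soc": unit,
        "reported_income": reported,
        "true_wage": true_wage,
        "poor_health": poor,
        "sep_class": sep,
    })
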