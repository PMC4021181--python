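"""Apply a fitted wage model to a target survey: synthetic wage estimates.

A person's predicted log weekly wage combines the fixed effects for age
and sex with the Empirical Bayes shrunk residuals of their occupation
groups:

    log_wage_hat = b0 + b_age*age + b_male*[male]
                   + u_minor + v_unit + (a_minor + b_unit)*age

using only the terms present in the model configuration.  Occupation
codes never seen in the training data fall back tier-by-tier to the
zero random effect (the EB prior mean): unknown unit -> minor terms
only; unknown minor (or a code too coarse to resolve a minor group) ->
fixed effects only.  The fallback tier actually used is recorded per
record.  Predictions are on reference-year prices by construction of the
master data; the default pound-scale retransformation is the plain
exponential (consistent with geometric-mean baselines), with an optional
log-normal smearing factor exp(var_resid/2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .soc import MalformedCodeError, Tier, parse_code
from .wage_model import FittedWageModel

__all__ = [
    "SyntheticWageEstimate",
    "predict_log_wage",
    "transfer",
    "FALLBACK_UNIT",
    "FALLBACK_MINOR",
    "FALLBACK_FIXED",
]

FALLBACK_UNIT = "unit"
FALLBACK_MINOR = "minor"
FALLBACK_FIXED = "fixed-only"


@dataclass(frozen=True)
class SyntheticWageEstimate:
    log_wage_hat: float
    wage_hat: float
    fallback_tier: str


def _is_male(sex) -> bool:
    return str(sex).strip().lower() == "male"


def predict_log_wage(model: FittedWageModel, age: float, sex,
                     soc, smearing: bool = False) -> SyntheticWageEstimate:
    """Predict one person's log and pound-scale weekly wage."""
    code = parse_code(str(soc))
    a = float(age) - model.spec.age_centering
    lw = model.beta0 + model.beta_age * a + model.beta_male * _is_male(sex)
    tier = FALLBACK_FIXED
    if code.tier >= Tier.MINOR:
        minor = code.ancestor(Tier.MINOR).code
        m = model.eb.minor.get(minor)
        if m is not None:
            lw += m["intercept"] + m["slope"] * a
            tier = FALLBACK_MINOR
            if code.tier is Tier.UNIT:
                u = model.eb.unit.get(code.code)
                if u is not None:
                    lw += u["intercept"] + u["slope"] * a
                    tier = FALLBACK_UNIT
    offset = 0.5 * model.vc.var_resid if smearing else 0.0
    return SyntheticWageEstimate(
        log_wage_hat=float(lw), wage_hat=float(np.exp(lw + offset)),
        fallback_tier=tier,
    )


def transfer(model: FittedWageModel, survey: pd.DataFrame,
             age_col: str = "age", sex_col: str = "sex", soc_col: str = "soc",
             smearing: bool = False) -> tuple[pd.DataFrame, dict[str, int]]:
    """Augment a survey table with synthetic wage estimate columns.

    Adds ``synthetic_log_wage``, ``synthetic_wage`` and
    ``wage_fallback_tier``.  Rows with missing or unparseable age, sex or
    occupation receive missing estimates.  Returns the augmented copy and
    a summary of fallback-tier frequencies (including ``missing``).
    """
    for col in (age_col, sex_col, soc_col):
        if col not in survey.columns:
            raise KeyError(f"missing required column: {col!r}")
    out = survey.copy()
    n = len(out)
    log_hat = np.full(n, np.nan)
    tiers = np.full(n, None, dtype=object)
    ages = pd.to_numeric(out[age_col], errors="coerce")
    sexes = out[sex_col]
    socs = out[soc_col]
    for i, (age, sex, soc) in enumerate(zip(ages, sexes, socs)):
        if pd.isna(age) or pd.isna(sex) or pd.isna(soc):
            continue
        if str(sex).strip().lower() not in ("male", "female"):
            continue
        try:
            est = predict_log_wage(model, age, sex, soc, smearing=False)
        except MalformedCodeError:
            continue
        log_hat[i] = est.log_wage_hat
        tiers[i] = est.fallback_tier
    offset = 0.5 * model.vc.var_resid if smearing else 0.0
    out["synthetic_log_wage"] = log_hat
    out["synthetic_wage"] = np.exp(log_hat + offset)
    out["wage_fallback_tier"] = tiers
    summary = {FALLBACK_UNIT: 0, FALLBACK_MINOR: 0, FALLBACK_FIXED: 0,
               "missing": int(np.isnan(log_hat).sum())}
    for t in tiers:
        if t is not None:
            summary[t] += 1
    return out, summary
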