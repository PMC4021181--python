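"""Internal and external validation of synthetic wage estimates.

Internal validation compares each model's holdout-year wage predictions
against two geometric-mean baselines (the grand geometric mean, and the
geometric mean within each occupational unit group) using the standard
deviation of the pound-scale residuals.  The headline column is the
percentage reduction of deviation relative to the grand-mean baseline,
computed on the variance scale: 100*(1 - (dev/dev0)^2).

External validation regresses a binary poor-health indicator on an
income measure (continuous, scaled in units of 100 GBP, or deciled with
the lowest decile as reference) with age/sex adjustment and optional
categorical socio-economic covariates, reporting odds ratios with 95%
Wald intervals and the Zheng-Agresti fit measure: the Pearson
correlation between the observed outcomes and the fitted probabilities,
which allows comparison of non-nested logistic models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .preprocess import MasterDataset
from .synthesize import transfer
from .wage_model import FittedWageModel

__all__ = [
    "DeviationReport",
    "LogisticFit",
    "SeparationError",
    "geometric_mean",
    "baseline_predictions",
    "residual_deviation",
    "pct_reduction",
    "internal_validation",
    "decile_groups",
    "fit_logistic",
    "zheng_agresti_r",
    "external_validation",
]

MODEL_LABELS = {
    "M1": "Model 1: 2-level intercepts",
    "M2": "Model 2: 2-level intercepts and age slopes",
    "M3": "Model 3: 3-level intercepts",
    "M4": "Model 4: 3-level intercepts and age slopes",
}


class SeparationError(RuntimeError):
    """Logistic ML estimates diverge: a predictor perfectly separates the outcome."""


def geometric_mean(wages) -> float:
    """exp(mean of logs); errors on non-positive values."""
    w = np.asarray(wages, dtype=float)
    if w.size == 0:
        raise ValueError("empty wage vector")
    if np.any(w <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(w))))


def baseline_predictions(master: MasterDataset, holdout: pd.DataFrame,
                         kind: str = "grand") -> np.ndarray:
    """Geometric-mean baseline predictions for holdout rows.

    kind="grand": every row gets the master grand geometric mean.
    kind="per_unit_group": each row gets its unit group's geometric mean,
    falling back to the grand mean for groups unseen in the master data.
    """
    grand = geometric_mean(master.frame["wage"])
    n = len(holdout)
    if kind == "grand":
        return np.full(n, grand)
    if kind == "per_unit_group":
        means = master.frame.groupby("unit_code")["wage"].apply(geometric_mean)
        pred = holdout["unit_code"].astype(str).map(means)
        return pred.fillna(grand).to_numpy(float)
    raise ValueError(f"unknown baseline kind: {kind!r}")


def residual_deviation(predicted, actual, metric: str = "sd") -> float:
    """Deviation of predictions from actual wages on the pound scale.

    metric="sd": standard deviation (denominator n-1) of actual-predicted
    residuals; insensitive to constant bias.  metric="rms": root mean
    square about zero, which does penalise bias.
    """
    p = np.asarray(predicted, dtype=float)
    a = np.asarray(actual, dtype=float)
    if p.shape != a.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {a.shape}")
    if p.size < 2:
        raise ValueError("need at least 2 observations")
    r = a - p
    if metric == "sd":
        return float(np.std(r, ddof=1))
    if metric == "rms":
        return float(np.sqrt(np.mean(r ** 2)))
    raise ValueError(f"unknown metric: {metric!r}")


def pct_reduction(dev: float, dev_baseline: float) -> float:
    """% reduction of deviation relative to a baseline, on the variance scale."""
    if not dev_baseline > 0:
        raise ValueError("baseline deviation must be positive")
    if dev < 0:
        raise ValueError("deviation must be non-negative")
    return 100.0 * (1.0 - (dev / dev_baseline) ** 2)


@dataclass
class DeviationReport:
    """One row per predictor: pound-scale deviation and % reduction vs baseline."""

    frame: pd.DataFrame
    n: int
    baseline_name: str = "grand_geometric_mean"

    def to_text(self) -> str:
        lines = [f"{'Predictor':<48}{'Deviation':>12}{'% reduction':>14}"]
        for _, row in self.frame.iterrows():
            flag = "  <- best" if row["best"] else ""
            lines.append(f"{row['predictor']:<48}"
                         f"{row['deviation']:>11.2f} "
                         f"{row['pct_reduction']:>12.2f}%{flag}")
        lines.append(f"N = {self.n}")
        return "\n".join(lines)


def internal_validation(models: list[FittedWageModel], master: MasterDataset,
                        holdout: MasterDataset, metric: str = "sd"
                        ) -> DeviationReport:
    """Holdout deviation of baselines and fitted models, in one report.

    The holdout must be disjoint from the training data (a year-based
    split utility is provided in :mod:`socwage.preprocess`).  The
    lowest-deviation row is flagged as best.
    """
    hf = holdout.frame
    actual = hf["wage"].to_numpy(float)
    rows = []
    dev0 = residual_deviation(
        baseline_predictions(master, hf, "grand"), actual, metric)
    rows.append(("Grand geometric mean wage", dev0))
    rows.append((
        "Geometric mean wage in unit group",
        residual_deviation(
            baseline_predictions(master, hf, "per_unit_group"), actual, metric),
    ))
    for model in models:
        pred_df, _ = transfer(model, hf, soc_col="unit_code")
        rows.append((
            MODEL_LABELS.get(model.spec.config.value, model.spec.config.value),
            residual_deviation(pred_df["synthetic_wage"], actual, metric),
        ))
    frame = pd.DataFrame(rows, columns=["predictor", "deviation"])
    frame["pct_reduction"] = [pct_reduction(d, dev0) for d in frame["deviation"]]
    frame["best"] = frame["deviation"] == frame["deviation"].min()
    return DeviationReport(frame=frame, n=len(hf))


def decile_groups(x) -> np.ndarray:
    """Rank-based decile labels 1..10 (1 = lowest), balanced group sizes.

    Ties are broken by stable input order, so all-equal input still
    yields balanced groups (documented degenerate behaviour).  Group
    sizes differ by at most one, larger groups first.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError(f"need at least 10 observations for deciles, got {n}")
    order = np.argsort(x, kind="stable")
    labels = np.empty(n, dtype=int)
    for g, chunk in enumerate(np.array_split(order, 10), start=1):
        labels[chunk] = g
    return labels


@dataclass
class LogisticFit:
    """A fitted logistic model: log-odds coefficients, ORs, CIs, fit measure."""

    params: "pd.Series[float]"          # log-odds scale
    bse: "pd.Series[float]"
    odds_ratios: "pd.Series[float]"
    conf_int: pd.DataFrame              # columns lower/upper, OR scale
    fit_r: float
    n: int
    spec: str = ""
    measure: str = ""
    adjustment: str = ""
    form: str = ""                      # "continuous" or "decile"
    fitted_probs: np.ndarray | None = field(default=None, repr=False)

    @staticmethod
    def stars(p: float) -> str:
        return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""

    def summary_frame(self) -> pd.DataFrame:
        from scipy import stats as _st
        z = self.params / self.bse
        pvals = 2 * _st.norm.sf(np.abs(z))
        return pd.DataFrame({
            "coef": self.params, "se": self.bse,
            "odds_ratio": self.odds_ratios,
            "ci_lower": self.conf_int["lower"],
            "ci_upper": self.conf_int["upper"],
            "p": pvals,
            "sig": [self.stars(p) for p in pvals],
        })


def _expand_design(X: pd.DataFrame) -> pd.DataFrame:
    """Main-effects design: categoricals to treatment-coded indicators."""
    cat_cols = [c for c in X.columns
                if X[c].dtype == object or isinstance(X[c].dtype, pd.CategoricalDtype)
                or pd.api.types.is_string_dtype(X[c])]
    if cat_cols:
        X = pd.get_dummies(X, columns=cat_cols, drop_first=True, dtype=float)
    return X.astype(float)


def fit_logistic(y, X: pd.DataFrame, spec: str = "") -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald 95% intervals.

    ``X`` holds main effects (continuous columns as-is, categorical
    columns expanded to indicators with the first level as reference);
    an intercept is added.  Odds ratios are exp(coef) with CI
    exp(coef +/- 1.96*se).  Raises SeparationError when the ML estimates
    diverge and a rank-deficiency error for collinear designs.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("outcome contains a single class")
    design = _expand_design(X.reset_index(drop=True))
    design.insert(0, "intercept", 1.0)
    arr = design.to_numpy(float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        raise ValueError("rank-deficient design matrix")
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            res = sm.Logit(y, arr).fit(method="newton", disp=0, maxiter=100)
    except (PerfectSeparationError, np.linalg.LinAlgError, RuntimeWarning) as err:
        raise SeparationError(f"logistic fit diverged: {err}") from err
    if not res.mle_retvals.get("converged", False) or np.any(np.abs(res.params) > 50):
        raise SeparationError("logistic fit did not converge (possible separation)")
    names = list(design.columns)
    params = pd.Series(res.params, index=names)
    bse = pd.Series(res.bse, index=names)
    ci = pd.DataFrame({
        "lower": np.exp(params - 1.96 * bse),
        "upper": np.exp(params + 1.96 * bse),
    }, index=names)
    p_hat = res.predict(arr)
    return LogisticFit(
        params=params, bse=bse, odds_ratios=np.exp(params), conf_int=ci,
        fit_r=zheng_agresti_r(y, p_hat), n=len(y), spec=spec,
        fitted_probs=np.asarray(p_hat),
    )


def zheng_agresti_r(y, p_hat) -> float:
    """Pearson correlation between observed binary outcomes and fitted probabilities."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p_hat, dtype=float)
    if y.shape != p.shape:
        raise ValueError("length mismatch between outcomes and fitted values")
    if np.std(y) == 0 or np.std(p) == 0:
        raise ValueError("zero variance in outcomes or fitted probabilities")
    return float(np.corrcoef(y, p)[0, 1])


def external_validation(survey: pd.DataFrame,
                        income_measures: dict[str, str],
                        adjustments: dict[str, list[str]] | None = None,
                        outcome_col: str = "poor_health",
                        age_col: str = "age", sex_col: str = "sex",
                        ) -> list[LogisticFit]:
    """Health-gradient logistic models for each income measure x adjustment.

    For every measure (name -> survey column) and adjustment set (name ->
    extra categorical covariate columns; age and sex are always included)
    two models are fitted on that model's complete cases: a continuous
    fit with the measure scaled in units of 100 GBP, and a deciled fit
    with the lowest decile as reference.  Sample sizes may therefore
    differ across measures.
    """
    adjustments = adjustments or {"age_sex": []}
    male = (survey[sex_col].astype(str).str.strip().str.lower() == "male"
            ).astype(float)
    fits: list[LogisticFit] = []
    for m_name, m_col in income_measures.items():
        for a_name, extra in adjustments.items():
            cols = [outcome_col, m_col, age_col, sex_col] + list(extra)
            sub = survey[cols + []].copy()
            sub["_male"] = male
            sub = sub.dropna()
            base = pd.DataFrame({
                "age": pd.to_numeric(sub[age_col]).to_numpy(float),
                "male": sub["_male"].to_numpy(float),
            })
            for c in extra:
                base[c] = sub[c].astype(str).to_numpy()
            y = sub[outcome_col].astype(float).to_numpy()
            income = pd.to_numeric(sub[m_col]).to_numpy(float)

            Xc = base.copy()
            Xc.insert(0, "income_per_100", income / 100.0)
            f = fit_logistic(y, Xc, spec=f"{m_name} (per 100 GBP) | {a_name}")
            f.measure, f.adjustment, f.form = m_name, a_name, "continuous"
            fits.append(f)

            dec = decile_groups(income)
            Xd = base.copy()
            for d in range(2, 11):
                Xd[f"decile_{d}"] = (dec == d).astype(float)
            f = fit_logistic(y, Xd, spec=f"{m_name} (deciles) | {a_name}")
            f.measure, f.adjustment, f.form = m_name, a_name, "decile"
            fits.append(f)
    return fits
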