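"""Nested random-effects models of log weekly wage.

The model family regresses log standardised weekly wage on fixed effects
for age and sex (female reference) with random effects over the tiers of
the occupational classification:

    M1  random intercepts for minor groups
    M2  M1 + random age slopes for minor groups
    M3  M1 + random intercepts for unit groups (3-level nesting)
    M4  M3 + random age slopes at both tiers

Writing y_i for the log wages of minor group i, X_i = [1, age, male] and
Z_i the within-block random-effect design (minor intercept/slope columns
plus one intercept/slope column per unit group in the block),

    y_i ~ N(X_i beta, V_i),   V_i = sigma^2 I + Z_i G_i Z_i',

with G_i diagonal (intercepts and slopes at a tier are independent).
Observations in different minor groups are independent, so the marginal
likelihood, the profiled GLS fixed effects and the Empirical Bayes
(BLUP) group residuals are all computed exactly blockwise; each block
uses the Woodbury identity through the q_i x q_i matrix

    A_i = Z_i'Z_i + sigma^2 G_i^{-1},

so the per-evaluation cost is independent of block sample size once the
cross-products are accumulated.  Variance components are estimated by
maximum likelihood (REML optional), parameterised as log standard
deviations for positivity.  The EB residual for a group is the posterior
mean of its random effect, u_hat = A^{-1} Z'(y - X beta), shrunk toward
zero in proportion to the within-group information.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import linalg, optimize

from .preprocess import MasterDataset

__all__ = [
    "ModelConfig",
    "ModelSpec",
    "VarianceComponents",
    "WageModelParams",
    "EBResiduals",
    "FittedWageModel",
    "FitOptions",
    "NonFiniteLikelihoodError",
    "NonConvergenceError",
    "UnidentifiableModelError",
    "marginal_loglik",
    "eb_residuals",
    "fit",
]

#: Variance estimates below this are reported as exactly 0 with a boundary flag.
BOUNDARY_TOL = 1e-10

_LOG2PI = np.log(2.0 * np.pi)


class NonFiniteLikelihoodError(ArithmeticError):
    """A covariance block was numerically singular or the likelihood non-finite."""


class NonConvergenceError(RuntimeError):
    """Optimiser failed to converge; carries the iterate history."""

    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.history = history


class UnidentifiableModelError(ValueError):
    """The grouping structure cannot identify the requested variance components."""


class ModelConfig(str, enum.Enum):
    M1 = "M1"  # 2-level random intercepts (minor)
    M2 = "M2"  # 2-level random intercepts + age slopes (minor)
    M3 = "M3"  # 3-level random intercepts (minor + unit)
    M4 = "M4"  # 3-level random intercepts + age slopes (minor + unit)


@dataclass(frozen=True)
class ModelSpec:
    """Which random-effect terms are present, and the age centering constant."""

    config: ModelConfig = ModelConfig.M4
    age_centering: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "config", ModelConfig(self.config))

    @property
    def has_minor_slope(self) -> bool:
        return self.config in (ModelConfig.M2, ModelConfig.M4)

    @property
    def has_unit(self) -> bool:
        return self.config in (ModelConfig.M3, ModelConfig.M4)

    @property
    def has_unit_slope(self) -> bool:
        return self.config is ModelConfig.M4

    @property
    def varcomp_names(self) -> tuple[str, ...]:
        names = ["minor_int"]
        if self.has_minor_slope:
            names.append("minor_slope")
        if self.has_unit:
            names.append("unit_int")
        if self.has_unit_slope:
            names.append("unit_slope")
        return tuple(names)


@dataclass(frozen=True)
class VarianceComponents:
    """Variances (not SDs) of each random-effect term plus the residual."""

    var_minor_int: float = 0.0
    var_minor_slope: float = 0.0
    var_unit_int: float = 0.0
    var_unit_slope: float = 0.0
    var_resid: float = 1.0

    def __post_init__(self) -> None:
        for name, v in asdict(self).items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if not self.var_resid > 0:
            raise ValueError(f"var_resid must be > 0, got {self.var_resid}")

    def get(self, name: str) -> float:
        return getattr(self, f"var_{name}")


@dataclass(frozen=True)
class WageModelParams:
    """A full candidate parameter set: fixed effects + variance components."""

    beta0: float
    beta_age: float
    beta_male: float
    vc: VarianceComponents

    @property
    def beta(self) -> np.ndarray:
        return np.array([self.beta0, self.beta_age, self.beta_male])


@dataclass
class EBResiduals:
    """Per-group Empirical Bayes shrunk residuals, keyed by group code.

    Each entry is {"intercept": float, "slope": float}; slope is 0 for
    model configurations without a random slope at that tier.
    """

    minor: dict[str, dict[str, float]] = field(default_factory=dict)
    unit: dict[str, dict[str, float]] = field(default_factory=dict)


# Column kinds in the within-block random-effect design.
_K_MINOR_INT, _K_MINOR_SLOPE, _K_UNIT_INT, _K_UNIT_SLOPE = 0, 1, 2, 3


@dataclass
class _Block:
    """Sufficient statistics of one minor-group block."""

    minor_code: str
    n: int
    unit_codes: list[str]
    kinds: np.ndarray          # per-Z-column kind code
    col_unit: np.ndarray       # per-Z-column unit index (-1 for minor terms)
    ZtZ: np.ndarray
    ZtX: np.ndarray
    Zty: np.ndarray
    XtX: np.ndarray
    Xty: np.ndarray
    yty: float


def _build_blocks(data: MasterDataset, spec: ModelSpec) -> list[_Block]:
    df = data.frame.sort_values(["minor_code", "unit_code"], kind="stable")
    age_c = df["age"].to_numpy(float) - spec.age_centering
    male = df["male"].to_numpy(float)
    y = df["log_wage"].to_numpy(float)
    minor = df["minor_code"].to_numpy(str)
    unit = df["unit_code"].to_numpy(str)

    blocks: list[_Block] = []
    for code in np.unique(minor):
        sel = minor == code
        a, m, yy = age_c[sel], male[sel], y[sel]
        n = int(sel.sum())
        ucodes = sorted(np.unique(unit[sel]).tolist())
        cols, kinds, col_unit = [np.ones(n)], [_K_MINOR_INT], [-1]
        if spec.has_minor_slope:
            cols.append(a); kinds.append(_K_MINOR_SLOPE); col_unit.append(-1)
        if spec.has_unit:
            for j, uc in enumerate(ucodes):
                cols.append((unit[sel] == uc).astype(float))
                kinds.append(_K_UNIT_INT); col_unit.append(j)
        if spec.has_unit_slope:
            for j, uc in enumerate(ucodes):
                cols.append((unit[sel] == uc) * a)
                kinds.append(_K_UNIT_SLOPE); col_unit.append(j)
        Z = np.column_stack(cols)
        X = np.column_stack([np.ones(n), a, m])
        blocks.append(_Block(
            minor_code=str(code), n=n, unit_codes=ucodes,
            kinds=np.array(kinds), col_unit=np.array(col_unit),
            ZtZ=Z.T @ Z, ZtX=Z.T @ X, Zty=Z.T @ yy,
            XtX=X.T @ X, Xty=X.T @ yy, yty=float(yy @ yy),
        ))
    return blocks


_KIND_TO_NAME = {_K_MINOR_INT: "minor_int", _K_MINOR_SLOPE: "minor_slope",
                 _K_UNIT_INT: "unit_int", _K_UNIT_SLOPE: "unit_slope"}


def _g_vector(block: _Block, vc: VarianceComponents) -> np.ndarray:
    return np.array([vc.get(_KIND_TO_NAME[k]) for k in block.kinds])


def _block_quantities(block: _Block, vc: VarianceComponents):
    """Woodbury pieces of one block: V^{-1}-weighted cross-products + logdet V."""
    s2 = vc.var_resid
    g = _g_vector(block, vc)
    act = g > 0
    q = int(act.sum())
    if q == 0:
        xx, xy, yy = block.XtX, block.Xty, block.yty
        logdet = block.n * np.log(s2)
    else:
        idx = np.where(act)[0]
        A = block.ZtZ[np.ix_(idx, idx)] + np.diag(s2 / g[idx])
        try:
            c, low = linalg.cho_factor(A, lower=True)
        except linalg.LinAlgError as err:
            raise NonFiniteLikelihoodError(
                f"singular covariance block for minor group {block.minor_code}"
            ) from err
        sol_X = linalg.cho_solve((c, low), block.ZtX[idx])
        sol_y = linalg.cho_solve((c, low), block.Zty[idx])
        xx = block.XtX - block.ZtX[idx].T @ sol_X
        xy = block.Xty - block.ZtX[idx].T @ sol_y
        yy = block.yty - block.Zty[idx] @ sol_y
        logdet_A = 2.0 * np.sum(np.log(np.diag(c)))
        logdet = (block.n - q) * np.log(s2) + np.sum(np.log(g[idx])) + logdet_A
    return xx / s2, xy / s2, yy / s2, logdet


def _loglik_blocks(blocks: Sequence[_Block], vc: VarianceComponents,
                   beta: np.ndarray | None, reml: bool = False):
    """Marginal log-likelihood; profiles beta by GLS when ``beta`` is None.

    Returns (loglik, beta, XtVinvX).
    """
    p = 3
    XtVinvX = np.zeros((p, p))
    XtVinvy = np.zeros(p)
    yVinvy = 0.0
    logdet = 0.0
    n_total = 0
    for b in blocks:
        xx, xy, yy, ld = _block_quantities(b, vc)
        XtVinvX += xx
        XtVinvy += xy
        yVinvy += yy
        logdet += ld
        n_total += b.n
    if beta is None:
        beta = linalg.solve(XtVinvX, XtVinvy, assume_a="pos")
        quad = yVinvy - beta @ XtVinvy
    else:
        beta = np.asarray(beta, dtype=float)
        quad = yVinvy - 2.0 * beta @ XtVinvy + beta @ XtVinvX @ beta
    ll = -0.5 * (n_total * _LOG2PI + logdet + quad)
    if reml:
        sign, ld_x = np.linalg.slogdet(XtVinvX)
        if sign <= 0:
            raise NonFiniteLikelihoodError("X'V^{-1}X not positive definite")
        ll += -0.5 * ld_x + 0.5 * p * _LOG2PI
    if not np.isfinite(ll):
        raise NonFiniteLikelihoodError("non-finite log-likelihood")
    return float(ll), beta, XtVinvX


def marginal_loglik(params: WageModelParams, data: MasterDataset,
                    spec: ModelSpec) -> float:
    """Log marginal normal likelihood of the log wages under ``params``.

    Random effects are integrated out analytically; the computation is
    blockwise by minor group (blocks are independent).  Components absent
    from the ModelSpec are treated as fixed at 0.
    """
    vc = _restrict_vc(params.vc, spec)
    blocks = _build_blocks(data, spec)
    ll, _, _ = _loglik_blocks(blocks, vc, params.beta)
    return ll


def _restrict_vc(vc: VarianceComponents, spec: ModelSpec) -> VarianceComponents:
    names = spec.varcomp_names
    return VarianceComponents(
        var_minor_int=vc.var_minor_int if "minor_int" in names else 0.0,
        var_minor_slope=vc.var_minor_slope if "minor_slope" in names else 0.0,
        var_unit_int=vc.var_unit_int if "unit_int" in names else 0.0,
        var_unit_slope=vc.var_unit_slope if "unit_slope" in names else 0.0,
        var_resid=vc.var_resid,
    )


def _eb_blocks(blocks: Sequence[_Block], vc: VarianceComponents,
               beta: np.ndarray, spec: ModelSpec) -> EBResiduals:
    out = EBResiduals()
    beta = np.asarray(beta, dtype=float)
    for b in blocks:
        g = _g_vector(b, vc)
        act = g > 0
        u = np.zeros(len(g))
        if act.any():
            idx = np.where(act)[0]
            A = b.ZtZ[np.ix_(idx, idx)] + np.diag(vc.var_resid / g[idx])
            w = b.Zty[idx] - b.ZtX[idx] @ beta
            u[idx] = linalg.solve(A, w, assume_a="pos")
        m_entry = {"intercept": 0.0, "slope": 0.0}
        u_entries = {uc: {"intercept": 0.0, "slope": 0.0} for uc in b.unit_codes}
        for val, kind, ju in zip(u, b.kinds, b.col_unit):
            if kind == _K_MINOR_INT:
                m_entry["intercept"] = float(val)
            elif kind == _K_MINOR_SLOPE:
                m_entry["slope"] = float(val)
            elif kind == _K_UNIT_INT:
                u_entries[b.unit_codes[ju]]["intercept"] = float(val)
            else:
                u_entries[b.unit_codes[ju]]["slope"] = float(val)
        out.minor[b.minor_code] = m_entry
        if spec.has_unit:
            out.unit.update(u_entries)
    return out


def eb_residuals(vc: VarianceComponents, beta, data: MasterDataset,
                 spec: ModelSpec) -> EBResiduals:
    """Posterior-mean (BLUP) random effects per group given the parameters.

    Solved exactly per minor-group block via the mixed-model equations
    u = (Z'Z + sigma^2 G^{-1})^{-1} Z'(y - X beta); components with zero
    variance have residual exactly 0 (the prior mean).
    """
    vc = _restrict_vc(vc, spec)
    blocks = _build_blocks(data, spec)
    return _eb_blocks(blocks, vc, np.asarray(beta, dtype=float), spec)


@dataclass(frozen=True)
class FitOptions:
    tol: float = 1e-8          # convergence tolerance on the log-likelihood
    max_iter: int = 2000
    reml: bool = False
    n_restarts: int = 2        # simplex restarts from the incumbent optimum


@dataclass
class FittedWageModel:
    """A maximum-likelihood fit: fixed effects, variance components, EB residuals."""

    spec: ModelSpec
    beta0: float
    beta_age: float
    beta_male: float
    se_beta0: float
    se_beta_age: float
    se_beta_male: float
    vc: VarianceComponents
    eb: EBResiduals
    loglik: float
    n_obs: int
    n_minor: int
    n_unit: int
    boundary: list[str] = field(default_factory=list)
    converged: bool = True
    reml: bool = False
    # Log-likelihood at the optimiser's accepted iterate after each
    # iteration (non-decreasing for a correct ascent); not serialised.
    opt_history: list[float] = field(default_factory=list, repr=False)

    @property
    def params(self) -> WageModelParams:
        return WageModelParams(self.beta0, self.beta_age, self.beta_male, self.vc)

    @property
    def sd_components(self) -> dict[str, float]:
        """Random-effect standard deviations (square roots of the variances)."""
        d = asdict(self.vc)
        return {k.replace("var_", "sd_"): float(np.sqrt(v)) for k, v in d.items()}

    def to_dict(self) -> dict:
        return {
            "format": "socwage-fitted-wage-model",
            "version": 1,
            "spec": {"config": self.spec.config.value,
                     "age_centering": self.spec.age_centering},
            "fixed_effects": {"intercept": self.beta0, "age": self.beta_age,
                              "male": self.beta_male},
            "fixed_effect_se": {"intercept": self.se_beta0,
                                "age": self.se_beta_age,
                                "male": self.se_beta_male},
            "variance_components": asdict(self.vc),
            "sd_components": self.sd_components,
            "eb_residuals": {"minor": self.eb.minor, "unit": self.eb.unit},
            "loglik": self.loglik,
            "n_obs": self.n_obs, "n_minor": self.n_minor, "n_unit": self.n_unit,
            "boundary": self.boundary, "converged": self.converged,
            "reml": self.reml,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n", encoding="utf-8")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "FittedWageModel":
        spec = ModelSpec(config=d["spec"]["config"],
                         age_centering=d["spec"]["age_centering"])
        fe, se = d["fixed_effects"], d["fixed_effect_se"]
        eb = EBResiduals(minor=d["eb_residuals"]["minor"],
                         unit=d["eb_residuals"]["unit"])
        return cls(
            spec=spec, beta0=fe["intercept"], beta_age=fe["age"],
            beta_male=fe["male"], se_beta0=se["intercept"],
            se_beta_age=se["age"], se_beta_male=se["male"],
            vc=VarianceComponents(**d["variance_components"]), eb=eb,
            loglik=d["loglik"], n_obs=d["n_obs"], n_minor=d["n_minor"],
            n_unit=d["n_unit"], boundary=list(d.get("boundary", [])),
            converged=d.get("converged", True), reml=d.get("reml", False),
        )

    @classmethod
    def from_json(cls, source: str | Path) -> "FittedWageModel":
        p = Path(source)
        text = p.read_text(encoding="utf-8") if p.exists() else str(source)
        return cls.from_dict(json.loads(text))


def _check_identifiable(data: MasterDataset, spec: ModelSpec) -> None:
    df = data.frame
    n_minor = df["minor_code"].nunique()
    if n_minor < 2:
        raise UnidentifiableModelError(
            f"need >= 2 minor groups, found {n_minor}"
        )
    if spec.has_unit:
        units_per_minor = df.groupby("minor_code")["unit_code"].nunique()
        if (units_per_minor < 2).all():
            raise UnidentifiableModelError(
                "need >= 2 unit groups within at least one minor group"
            )


def _vc_from_theta(theta: np.ndarray, names: tuple[str, ...]) -> VarianceComponents:
    # theta holds log-SDs of the active components, residual SD last.
    theta = np.clip(theta, -20.0, 10.0)
    var = {f"var_{nm}": float(np.exp(2.0 * t)) for nm, t in zip(names, theta[:-1])}
    return VarianceComponents(var_resid=float(np.exp(2.0 * theta[-1])), **var)


def fit(data: MasterDataset, spec: ModelSpec = ModelSpec(),
        opts: FitOptions = FitOptions()) -> FittedWageModel:
    """Maximum-likelihood fit of one model configuration.

    Variance components are optimised on the log-SD scale by Nelder-Mead
    (restarted from the incumbent optimum); at each candidate the fixed
    effects are profiled out exactly by generalised least squares, so the
    search space has at most 5 dimensions.  Variance estimates below
    1e-10 are reported as exactly 0 and flagged as boundary estimates.
    """
    _check_identifiable(data, spec)
    blocks = _build_blocks(data, spec)
    names = spec.varcomp_names
    df = data.frame

    # Moment-based starting values from an OLS fit.
    X = np.column_stack([np.ones(len(df)),
                         df["age"].to_numpy(float) - spec.age_centering,
                         df["male"].to_numpy(float)])
    y = df["log_wage"].to_numpy(float)
    beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta_ols
    s2 = float(resid @ resid) / max(len(y) - 3, 1)
    age_scale = float(np.sqrt(np.mean(X[:, 1] ** 2))) or 1.0
    start_sd = {"minor_int": np.sqrt(s2) / 2, "unit_int": np.sqrt(s2) / 3,
                "minor_slope": np.sqrt(s2) / (2 * age_scale),
                "unit_slope": np.sqrt(s2) / (3 * age_scale)}
    x0 = np.array([np.log(start_sd[nm]) for nm in names]
                  + [0.5 * np.log(0.75 * s2)])

    cache: dict[bytes, float] = {}
    accepted: list[float] = []

    def objective(theta: np.ndarray) -> float:
        vc = _vc_from_theta(theta, names)
        try:
            ll, _, _ = _loglik_blocks(blocks, vc, None, reml=opts.reml)
        except NonFiniteLikelihoodError:
            return np.inf
        cache[np.asarray(theta).tobytes()] = ll
        return -ll

    def record(xk: np.ndarray) -> None:
        # xk is the current best simplex vertex; it has been evaluated.
        ll = cache.get(np.asarray(xk).tobytes())
        if ll is not None:
            accepted.append(ll)

    res = None
    x_best = x0
    for _ in range(max(opts.n_restarts, 1)):
        res = optimize.minimize(
            objective, x_best, method="Nelder-Mead", callback=record,
            options={"fatol": opts.tol, "xatol": 1e-7,
                     "maxiter": opts.max_iter, "maxfev": opts.max_iter},
        )
        x_best = res.x
    if res is None or not res.success:
        raise NonConvergenceError(
            f"optimiser did not converge: {res.message if res else 'no run'}",
            accepted,
        )

    vc_hat = _vc_from_theta(x_best, names)
    # Zero out boundary components before the final evaluation so the
    # reported likelihood and EB residuals match the reported variances.
    boundary = []
    vals = asdict(vc_hat)
    for nm in names:
        if vals[f"var_{nm}"] < BOUNDARY_TOL:
            vals[f"var_{nm}"] = 0.0
            boundary.append(nm)
    vc_hat = VarianceComponents(**vals)

    ll, beta, XtVinvX = _loglik_blocks(blocks, vc_hat, None, reml=opts.reml)
    cov_beta = linalg.inv(XtVinvX)
    se = np.sqrt(np.diag(cov_beta))
    eb = _eb_blocks(blocks, vc_hat, beta, spec)

    return FittedWageModel(
        spec=spec,
        beta0=float(beta[0]), beta_age=float(beta[1]), beta_male=float(beta[2]),
        se_beta0=float(se[0]), se_beta_age=float(se[1]), se_beta_male=float(se[2]),
        vc=vc_hat, eb=eb, loglik=float(ll),
        n_obs=len(df), n_minor=df["minor_code"].nunique(),
        n_unit=df["unit_code"].nunique(),
        boundary=boundary, converged=bool(res.success), reml=opts.reml,
        opt_history=accepted,
    )
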