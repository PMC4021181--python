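from __future__ import annotations

import json

import numpy as np
import pandas as pd
import pytest

from oracles import dense_blup, dense_loglik
from conftest import random_master
from socwage.preprocess import MasterDataset
from socwage.synthetic_data import GeneratorConfig, generate_master, cpi_table
from socwage.preprocess import build_master
from socwage.wage_model import (FitOptions, FittedWageModel, ModelSpec,
                                UnidentifiableModelError, VarianceComponents,
                                WageModelParams, eb_residuals, fit,
                                marginal_loglik)

ALL_SPECS = [ModelSpec("M1"), ModelSpec("M2"), ModelSpec("M3"), ModelSpec("M4")]

VC = VarianceComponents(var_minor_int=0.15, var_minor_slope=2e-5,
                        var_unit_int=0.08, var_unit_slope=1e-5,
                        var_resid=0.3)


def _params(vc=VC):
    return WageModelParams(beta0=5.1, beta_age=0.005, beta_male=0.27, vc=vc)


class TestMarginalLoglik:
    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.config.value)
    def test_matches_dense_multivariate_normal(self, rng, spec):
        """Blockwise Woodbury likelihood equals a dense n x n MVN density."""
        data = random_master(rng, n_minor=4, units_per_minor=3, n_per_unit=12)
        p = _params()
        ll = marginal_loglik(p, data, spec)
        # Oracle must restrict to the spec's active components the same way.
        vc = VarianceComponents(
            var_minor_int=VC.var_minor_int,
            var_minor_slope=VC.var_minor_slope if spec.has_minor_slope else 0.0,
            var_unit_int=VC.var_unit_int if spec.has_unit else 0.0,
            var_unit_slope=VC.var_unit_slope if spec.has_unit_slope else 0.0,
            var_resid=VC.var_resid)
        expected = dense_loglik(p.beta, vc, data.frame, spec)
        assert ll == pytest.approx(expected, abs=1e-6)

    def test_zero_variances_reduce_to_independent_normals(self, rng):
        data = random_master(rng, n_minor=3, units_per_minor=2, n_per_unit=8)
        vc = VarianceComponents(var_resid=0.3)
        p = _params(vc)
        ll = marginal_loglik(p, data, ModelSpec("M4"))
        f = data.frame
        mu = 5.1 + 0.005 * f["age"].to_numpy(float) + 0.27 * f["male"].to_numpy(float)
        resid = f["log_wage"].to_numpy(float) - mu
        expected = float(np.sum(-0.5 * np.log(2 * np.pi * 0.3)
                                - resid ** 2 / (2 * 0.3)))
        assert ll == pytest.approx(expected, abs=1e-8)

    def test_row_duplication_doubles_loglik_only_without_group_effects(self, rng):
        data = random_master(rng, n_minor=3, units_per_minor=2, n_per_unit=6)
        doubled = MasterDataset.from_modelling_frame(
            pd.concat([data.frame, data.frame], ignore_index=True))
        spec = ModelSpec("M3")

        iid = _params(VarianceComponents(var_resid=0.3))
        assert marginal_loglik(iid, doubled, spec) == pytest.approx(
            2 * marginal_loglik(iid, data, spec), rel=1e-10)

        corr = _params()
        ll2 = marginal_loglik(corr, doubled, spec)
        # Correlated observations are not independent: doubling the rows
        # must NOT simply double the log-likelihood.
        assert ll2 != pytest.approx(2 * marginal_loglik(corr, data, spec),
                                    rel=1e-6)
        assert ll2 == pytest.approx(dense_loglik(corr.beta, VarianceComponents(
            var_minor_int=VC.var_minor_int, var_unit_int=VC.var_unit_int,
            var_resid=VC.var_resid), doubled.frame, spec), abs=1e-6)


class TestEBResiduals:
    def test_one_group_closed_form_blup(self):
        """Single random intercept: EB = (n tau^2/(n tau^2 + sigma^2)) rbar."""
        for n, tau2, sigma2, rbar in [(1, 1.0, 1.0, 2.0), (5, 0.5, 2.0, 1.3),
                                      (50, 0.1, 0.4, -0.7)]:
            df = pd.DataFrame({
                "age": [0] * n, "sex": ["female"] * n,
                "unit_code": ["1111"] * n, "log_wage": [rbar] * n,
            })
            data = MasterDataset.from_modelling_frame(df)
            vc = VarianceComponents(var_minor_int=tau2, var_resid=sigma2)
            eb = eb_residuals(vc, [0.0, 0.0, 0.0], data, ModelSpec("M1"))
            expected = n * tau2 / (n * tau2 + sigma2) * rbar
            assert eb.minor["111"]["intercept"] == pytest.approx(expected,
                                                                 abs=1e-12)

    def test_degenerate_prior_gives_zero_residuals(self, rng):
        data = random_master(rng, n_minor=3, units_per_minor=2, n_per_unit=5)
        vc = VarianceComponents(var_minor_int=0.0, var_resid=0.5)
        eb = eb_residuals(vc, [5.0, 0.0, 0.0], data, ModelSpec("M1"))
        assert all(v["intercept"] == 0.0 for v in eb.minor.values())

    @pytest.mark.parametrize("spec", ALL_SPECS, ids=lambda s: s.config.value)
    def test_matches_dense_joint_solve(self, rng, spec):
        """Blockwise BLUP equals the dense GLS/mixed-model-equations solve."""
        data = random_master(rng, n_minor=4, units_per_minor=3, n_per_unit=10)
        beta = [5.2, 0.004, 0.3]
        eb = eb_residuals(VC, beta, data, spec)
        vc_active = VarianceComponents(
            var_minor_int=VC.var_minor_int,
            var_minor_slope=VC.var_minor_slope if spec.has_minor_slope else 0.0,
            var_unit_int=VC.var_unit_int if spec.has_unit else 0.0,
            var_unit_slope=VC.var_unit_slope if spec.has_unit_slope else 0.0,
            var_resid=VC.var_resid)
        minor, unit = dense_blup(beta, vc_active, data.frame, spec)
        for code, entry in eb.minor.items():
            assert entry["intercept"] == pytest.approx(minor[code]["intercept"],
                                                       abs=1e-8)
            assert entry["slope"] == pytest.approx(minor[code]["slope"],
                                                   abs=1e-8)
        for code, entry in eb.unit.items():
            assert entry["intercept"] == pytest.approx(unit[code]["intercept"],
                                                       abs=1e-8)
            assert entry["slope"] == pytest.approx(unit[code]["slope"],
                                                   abs=1e-8)

    def test_shrinkage_monotone_in_group_size(self):
        """|EB| grows with group size and approaches the raw group mean."""
        tau2, sigma2, rbar = 0.2, 0.8, 1.0
        previous = 0.0
        for n in [1, 2, 5, 20, 100, 1000]:
            df = pd.DataFrame({"age": [0] * n, "sex": ["female"] * n,
                               "unit_code": ["1111"] * n,
                               "log_wage": [rbar] * n})
            data = MasterDataset.from_modelling_frame(df)
            vc = VarianceComponents(var_minor_int=tau2, var_resid=sigma2)
            u = eb_residuals(vc, [0.0, 0.0, 0.0], data,
                             ModelSpec("M1")).minor["111"]["intercept"]
            assert u > previous
            assert 0 < u < rbar
            previous = u
        assert previous == pytest.approx(rbar, rel=1e-2)  # n -> inf limit


class TestFit:
    def test_zero_variance_data_matches_ols(self, rng):
        """With no group effects the ML fit collapses to OLS."""
        n = 2000
        df = pd.DataFrame({
            "age": rng.integers(16, 66, n),
            "sex": np.where(rng.random(n) < 0.5, "male", "female"),
            "unit_code": rng.choice([f"{m}{u}" for m in ["111", "243", "352"]
                                     for u in "123"], n),
        })
        mu = (5.1 + 0.005 * df["age"].to_numpy(float)
              + 0.27 * (df["sex"] == "male").to_numpy(float))
        df["log_wage"] = mu + rng.normal(0, 0.5, n)
        data = MasterDataset.from_modelling_frame(df)
        model = fit(data, ModelSpec("M1"))

        X = np.column_stack([np.ones(n), df["age"].to_numpy(float),
                             (df["sex"] == "male").to_numpy(float)])
        y = df["log_wage"].to_numpy(float)
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_ols
        cov = np.linalg.inv(X.T @ X) * (resid @ resid) / (n - 3)
        se = np.sqrt(np.diag(cov))
        for est, ols, s in zip([model.beta0, model.beta_age, model.beta_male],
                               beta_ols, se):
            assert abs(est - ols) < 2 * s
        assert model.vc.var_minor_int <= 1e-4

    def test_boundary_component_reported_as_zero(self, rng):
        df = random_master(rng, n_minor=6, units_per_minor=2, n_per_unit=30).frame
        # iid log wages: both variance components should hit the boundary
        df["log_wage"] = rng.normal(5.5, 0.5, len(df))
        data = MasterDataset.from_modelling_frame(df)
        model = fit(data, ModelSpec("M3"))
        assert set(model.boundary) <= {"minor_int", "unit_int"}
        for name in model.boundary:
            assert model.vc.get(name) == 0.0

    def test_single_minor_group_unidentifiable(self, rng):
        df = pd.DataFrame({"age": rng.integers(20, 60, 30),
                           "sex": ["female"] * 30,
                           "unit_code": ["1111"] * 15 + ["1112"] * 15,
                           "log_wage": rng.normal(5.5, 0.4, 30)})
        with pytest.raises(UnidentifiableModelError, match="minor"):
            fit(MasterDataset.from_modelling_frame(df), ModelSpec("M1"))

    def test_likelihood_ascent_and_nested_dominance(self, rng):
        cfg = GeneratorConfig(n_minor=12, units_per_minor=3, n_obs=4000,
                              frac_unemployed=0.0, frac_missing_wage=0.0,
                              seed=7)
        raw = generate_master(cfg)
        data = build_master(raw, cpi_table(cfg))
        lls = {}
        for spec in ALL_SPECS:
            model = fit(data, spec)
            lls[spec.config.value] = model.loglik
            hist = np.array(model.opt_history)
            assert np.all(np.diff(hist) >= -1e-9)  # accepted iterates ascend
        assert lls["M3"] >= lls["M1"] - 1e-6  # nesting
        assert lls["M4"] >= lls["M3"] - 1e-6
        assert lls["M2"] >= lls["M1"] - 1e-6

    def test_sex_reference_invariance(self, rng):
        data = random_master(rng, n_minor=5, units_per_minor=2, n_per_unit=25)
        m_f = fit(data, ModelSpec("M1"))
        flipped = data.frame.copy()
        flipped["sex"] = np.where(flipped["sex"] == "male", "female", "male")
        flipped = flipped.drop(columns=["male"])
        m_m = fit(MasterDataset.from_modelling_frame(flipped), ModelSpec("M1"))
        assert m_m.beta_male == pytest.approx(-m_f.beta_male, abs=1e-6)
        assert m_m.beta0 == pytest.approx(m_f.beta0 + m_f.beta_male, abs=1e-6)
        # fitted values unchanged for the same person
        f = data.frame.iloc[0]
        fv_f = m_f.beta0 + m_f.beta_age * f["age"] + m_f.beta_male * f["male"]
        fv_m = m_m.beta0 + m_m.beta_age * f["age"] + m_m.beta_male * (1 - f["male"])
        assert fv_f == pytest.approx(fv_m, abs=1e-6)

    def test_statsmodels_cross_check_m1(self, rng):
        """Independent reference fit: statsmodels MixedLM (ML) on M1 data."""
        import statsmodels.formula.api as smf
        cfg = GeneratorConfig(n_minor=15, units_per_minor=2, n_obs=3000,
                              sd_unit_int=0.0, sd_unit_slope=0.0,
                              frac_unemployed=0.0, frac_missing_wage=0.0,
                              seed=11)
        raw = generate_master(cfg)
        data = build_master(raw, cpi_table(cfg))
        ours = fit(data, ModelSpec("M1"))
        ref = smf.mixedlm("log_wage ~ age + male", data.frame,
                          groups=data.frame["minor_id"]).fit(reml=False)
        assert ours.beta0 == pytest.approx(ref.params["Intercept"], abs=1e-3)
        assert ours.beta_age == pytest.approx(ref.params["age"], abs=1e-5)
        assert ours.beta_male == pytest.approx(ref.params["male"], abs=1e-3)
        assert ours.vc.var_resid == pytest.approx(ref.scale, rel=1e-2)
        assert ours.vc.var_minor_int == pytest.approx(
            float(ref.cov_re.iloc[0, 0]), rel=2e-2)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-2)


class TestSerialisation:
    def test_json_round_trip_lossless(self, rng):
        data = random_master(rng, n_minor=4, units_per_minor=2, n_per_unit=10)
        model = fit(data, ModelSpec("M3"))
        back = FittedWageModel.from_dict(json.loads(model.to_json()))
        assert back.beta0 == model.beta0
        assert back.beta_age == model.beta_age
        assert back.vc == model.vc
        assert back.eb.minor == model.eb.minor
        assert back.eb.unit == model.eb.unit
        assert back.loglik == model.loglik
        assert back.spec == model.spec

    def test_json_file_round_trip(self, rng, tmp_path):
        data = random_master(rng, n_minor=4, units_per_minor=2, n_per_unit=10)
        model = fit(data, ModelSpec("M1"))
        path = tmp_path / "model.json"
        model.to_json(path)
        back = FittedWageModel.from_json(path)
        assert back.to_json() == model.to_json()
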