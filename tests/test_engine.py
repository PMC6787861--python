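"""Marginal-likelihood engine: closed-form oracles, parameter counting,
prediction identities and invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

import lfmcdyn as L
from lfmcdyn.exceptions import UnsupportedOperationError
from lfmcdyn.model import LfmcModel, ModelSpec

FULL_FIXED = tuple((p, "by_leaf_type") for p in ("A", "w", "m", "s"))


def _small_dataset(seed=4, sigma=5.0, re_sd=8.0):
    truth = L.GeneratingParams(random_sds={"A": re_sd} if re_sd else {},
                               sigma_base=sigma)
    return L.simulate_dataset(L.DesignSpec(days=(0, 15, 30, 45, 60, 75, 89),
                                           n_lost=0), truth, seed=seed)


def _natural_params(model, **overrides):
    """A plausible full natural parameter dict for a model."""
    base = {"A0": 54.3, "A[GE]": 30.9, "A[SM]": 223.4, "A[SS]": 240.3,
            "w0": 29.1, "w[GE]": -20.7, "w[SM]": 31.7, "w[SS]": 26.7,
            "m": 30.9, "s": -16.1, "sigma": 7.1,
            "m0": 30.9, "m[GE]": 0.0, "m[SM]": 0.0, "m[SS]": 0.0,
            "s0": -16.1, "s[GE]": 0.0, "s[SM]": 0.0, "s[SS]": 0.0,
            "delta(GE)": 0.9, "delta(SM)": 3.2, "delta(SS)": 3.0,
            "sd(A)": 9.4, "sd(w)": 4.0}
    out = {}
    for nm in model.layout.full_names:
        if nm in overrides:
            out[nm] = overrides[nm]
        elif nm in base:
            out[nm] = base[nm]
        else:
            raise KeyError(nm)
    return out


def _closed_form_nll(model, params):
    """Exact Gaussian marginal -loglik for random effects that enter the
    logistic mean *linearly* (A and/or w): per plot,
    y ~ N(mu0, Sigma + sd_A^2 g g' + sd_w^2 (1-g)(1-g)') with
    g = 1/(1 + exp((m - t)/s))."""
    des = model.design
    df = model.data.table
    P = model._resolve_params(df, pd.Series(params), None, "population")
    E = np.exp((P["m"] - des.t) / P["s"])
    g = 1.0 / (1.0 + E)
    mu0 = P["w"] + (P["A"] - P["w"]) * g
    if model.spec.varident:
        ratios = np.concatenate(([1.0], [params[f"delta({lt})"]
                                         for lt in des.leaf_offsets]))
        sd = params["sigma"] * ratios[des.row_leaf]
    else:
        sd = np.full(des.n, params["sigma"])
    nll = 0.0
    for j in range(des.J):
        idx = des.row_plot == j
        cov = np.diag(sd[idx] ** 2)
        if "A" in model.spec.random:
            cov = cov + params["sd(A)"] ** 2 * np.outer(g[idx], g[idx])
        if "w" in model.spec.random:
            cov = cov + params["sd(w)"] ** 2 * np.outer(1 - g[idx], 1 - g[idx])
        nll -= multivariate_normal.logpdf(df["lfmc"].to_numpy()[idx],
                                          mean=mu0[idx], cov=cov)
    return nll


class TestLikelihoodOracles:
    def test_iid_reduction_matches_rss_formula(self):
        """Without random effects or structures the marginal likelihood is
        the plain iid Gaussian nonlinear-regression likelihood."""
        ds = _small_dataset(re_sd=0.0)
        spec = ModelSpec(mean="logistic", fixed=FULL_FIXED, random=(),
                         varident=False)
        model = LfmcModel(ds, spec)
        params = _natural_params(model)
        got = model.nloglik_natural(params)
        mu = LfmcModel(ds, spec)._resolve_params(ds.table, pd.Series(params),
                                                 None, "population")
        E = np.exp((mu["m"] - ds.table["day"].to_numpy(float)) / mu["s"])
        fitted = mu["w"] + (mu["A"] - mu["w"]) / (1 + E)
        rss = np.sum((ds.table["lfmc"].to_numpy() - fitted) ** 2)
        n, s2 = ds.n, params["sigma"] ** 2
        expect = 0.5 * (n * np.log(2 * np.pi * s2) + rss / s2)
        assert got == pytest.approx(expect, rel=1e-10)

    @pytest.mark.parametrize("varident", [False, True])
    def test_quadrature_matches_linear_in_A_closed_form(self, varident):
        ds = _small_dataset()
        spec = ModelSpec(mean="logistic", fixed=FULL_FIXED, random=("A",),
                         varident=varident)
        model = LfmcModel(ds, spec)
        params = _natural_params(model)
        got = model.nloglik_natural(params)
        expect = _closed_form_nll(model, params)
        assert got == pytest.approx(expect, abs=1e-6, rel=1e-9)

    def test_two_dimensional_quadrature_matches_closed_form(self):
        ds = _small_dataset()
        spec = ModelSpec(mean="logistic", fixed=FULL_FIXED, random=("A", "w"),
                         varident=True)
        model = LfmcModel(ds, spec)
        params = _natural_params(model)
        got = model.nloglik_natural(params)
        expect = _closed_form_nll(model, params)
        assert got == pytest.approx(expect, abs=2e-6, rel=1e-9)

    def test_gaussian_scaling_relation(self):
        """Doubling every SD while mapping residuals y - mu0 -> 2(y - mu0)
        shifts the -loglik by exactly n log 2 (random effect enters linearly)."""
        ds1 = _small_dataset()
        spec = ModelSpec(mean="logistic", fixed=FULL_FIXED, random=("A",),
                         varident=True)
        m1 = LfmcModel(ds1, spec)
        params = _natural_params(m1)
        P = m1._resolve_params(ds1.table, pd.Series(params), None, "population")
        E = np.exp((P["m"] - ds1.table["day"].to_numpy(float)) / P["s"])
        mu0 = P["w"] + (P["A"] - P["w"]) / (1 + E)
        df2 = ds1.table.copy()
        df2["lfmc"] = mu0 + 2.0 * (df2["lfmc"].to_numpy() - mu0)
        ds2 = L.LfmcDataset.from_frame(
            df2[["site", "plot", "point", "leaf_type", "day", "lfmc"]],
            require_nonnegative=False)
        m2 = LfmcModel(ds2, spec)
        p2 = dict(params)
        for nm in ("sigma", "sd(A)"):
            p2[nm] = 2.0 * p2[nm]
        nll1 = m1.nloglik_natural(params)
        nll2 = m2.nloglik_natural(p2)
        assert nll2 - nll1 == pytest.approx(ds1.n * np.log(2.0), abs=1e-6)


class TestParameterCounting:
    def test_final_model_has_15_parameters(self, dataset):
        assert LfmcModel(dataset, ModelSpec.final_lfmc()).k_params == 15

    def test_hand_counts_for_model_suite(self, dataset):
        from lfmcdyn.selection import _m2_spec, _m3_spec, _m4_spec, _m5_spec
        # M2: 16 logistic coefficients + 5 plot offsets on A + 5 on w + sigma
        assert LfmcModel(dataset, _m2_spec()).k_params == 27
        # M3: 8 (day x leaf type) + sd(b0) + sigma + 3 deltas + rho + theta
        assert LfmcModel(dataset, _m3_spec((1, 1))).k_params == 15
        # M4: 8 + 5 + 5 plot offsets + sigma
        assert LfmcModel(dataset, _m4_spec()).k_params == 19
        # M5: grand mean + sigma
        assert LfmcModel(dataset, _m5_spec()).k_params == 2

    def test_aic_bic_identities(self, m1_fit):
        assert m1_fit.aic == pytest.approx(-2 * m1_fit.llf + 2 * m1_fit.k_params)
        assert m1_fit.bic == pytest.approx(
            -2 * m1_fit.llf + np.log(m1_fit.nobs) * m1_fit.k_params)

    def test_wald_interval_identity(self, m1_fit):
        ci = m1_fit.conf_int()
        lo = m1_fit.params - 1.959963984540054 * m1_fit.bse
        np.testing.assert_allclose(ci["lower"], lo, rtol=1e-12)


class TestDesignExpansion:
    def test_reference_and_offset_resolution(self, dataset):
        model = LfmcModel(dataset, ModelSpec.final_lfmc())
        exp = model.expand_design()
        names, D = exp["A"]
        assert names == ["A0", "A[GE]", "A[SM]", "A[SS]"]
        lt = dataset.table["leaf_type"].to_numpy()
        gw = lt == "GW"
        sm = lt == "SM"
        # GW rows resolve to A0 alone; SM rows to A0 + A[SM]
        np.testing.assert_array_equal(D[gw, 1:], 0.0)
        np.testing.assert_array_equal(D[sm, 2], 1.0)
        # common parameter: single pooled coefficient
        names_s, D_s = exp["s"]
        assert names_s == ["s"]
        np.testing.assert_array_equal(D_s, np.ones((dataset.n, 1)))


class TestFitRecovery:
    def test_noiseless_data_recover_fixed_effects(self):
        truth = L.GeneratingParams(random_sds={}, sigma_base=0.0)
        ds = L.simulate_dataset(L.DesignSpec(n_lost=0), truth, seed=0)
        spec = ModelSpec(mean="logistic", fixed=FULL_FIXED, random=(),
                         varident=False)
        res = LfmcModel(ds, spec).fit(seed=0)
        expect = truth.fixed_effect_values()
        expect.update({"m[GE]": 0.0, "m[SM]": 0.0, "m[SS]": 0.0,
                       "s[GE]": 0.0, "s[SM]": 0.0, "s[SS]": 0.0,
                       "m0": truth.curves["GW"].m, "s0": truth.curves["GW"].s})
        for nm in res.model.layout.beta_names:
            key = nm if nm in expect else {"m0": "m", "s0": "s"}.get(nm, nm)
            tv = expect[key]
            tol = 1e-6 * max(1.0, abs(tv))
            assert abs(res.params[nm] - tv) < tol, (nm, res.params[nm], tv)

    def test_row_permutation_invariance(self):
        ds = _small_dataset(seed=9)
        perm = ds.table.sample(frac=1.0, random_state=3).reset_index(drop=True)
        ds_perm = L.LfmcDataset.from_frame(
            perm[["site", "plot", "point", "leaf_type", "day", "lfmc"]],
            require_nonnegative=False)
        spec = ModelSpec.final_lfmc()
        m_a, m_b = LfmcModel(ds, spec), LfmcModel(ds_perm, spec)
        params = _natural_params(m_a)
        assert m_a.nloglik_natural(params) == pytest.approx(
            m_b.nloglik_natural(params), abs=1e-8)
        # fitted estimates agree up to optimizer termination jitter (the
        # likelihood itself is permutation-invariant to floating precision)
        r_a, r_b = m_a.fit(seed=0), m_b.fit(seed=0)
        np.testing.assert_allclose(r_a.params, r_b.params, rtol=1e-2, atol=2e-2)

    def test_plot_relabelling_invariance(self):
        ds = _small_dataset(seed=9)
        renamed = ds.table.copy()
        renamed["plot"] = renamed["plot"].map({"1": "7", "2": "8", "3": "9"})
        ds_r = L.LfmcDataset.from_frame(
            renamed[["site", "plot", "point", "leaf_type", "day", "lfmc"]],
            require_nonnegative=False)
        spec = ModelSpec.final_lfmc()
        r_a = LfmcModel(ds, spec).fit(seed=0)
        r_b = LfmcModel(ds_r, spec).fit(seed=0)
        np.testing.assert_allclose(r_a.params, r_b.params, rtol=1e-6, atol=1e-7)
        np.testing.assert_allclose(r_a.random_effects.to_numpy(),
                                   r_b.random_effects.to_numpy(), atol=1e-5)


class TestPredictions:
    def test_population_midpoint_identity(self, m1_fit):
        m_hat = float(m1_fit.params["m"])
        nd = pd.DataFrame({"leaf_type": ["GW"], "day": [m_hat]})
        got = m1_fit.predict(nd, level="population")[0]
        expect = (m1_fit.params["A0"] + m1_fit.params["w0"]) / 2
        assert got == pytest.approx(expect, rel=1e-12)

    def test_no_random_effects_levels_identical(self):
        ds = _small_dataset(re_sd=0.0)
        spec = ModelSpec(mean="logistic", fixed=FULL_FIXED, random=(),
                         varident=False)
        res = LfmcModel(ds, spec).fit(seed=0)
        nd = ds.table.head(20)
        np.testing.assert_allclose(res.predict(nd, "population"),
                                   res.predict(nd, "plot"))

    def test_plot_level_differs_only_through_random_parameters(self, m1_fit):
        for pk in m1_fit.model.design.plot_keys[:2]:
            lt = "GW" if pk.startswith("W") else "GE"
            pop = m1_fit.resolved_curve(lt)
            plc = m1_fit.resolved_curve(lt, plot=pk)
            assert plc.w == pop.w and plc.m == pop.m and plc.s == pop.s
            assert plc.A == pytest.approx(
                pop.A + m1_fit.random_effects.loc[pk, "A"], rel=1e-12)

    def test_unknown_plot_rejected(self, m1_fit):
        nd = pd.DataFrame({"leaf_type": ["GW"], "day": [10], "plot_key": ["W9"]})
        with pytest.raises(L.exceptions.LabelingError):
            m1_fit.predict(nd, level="plot")

    def test_unknown_leaf_type_rejected(self, m1_fit):
        nd = pd.DataFrame({"leaf_type": ["QQ"], "day": [10]})
        with pytest.raises(L.exceptions.LabelingError):
            m1_fit.predict(nd)


class TestDryingSpeed:
    def test_peak_rate_closed_form(self, m1_fit):
        m_hat = float(m1_fit.params["m"])
        nd = pd.DataFrame({"leaf_type": ["GW"], "day": [m_hat]})
        got = m1_fit.drying_speed(nd)[0]
        expect = (m1_fit.params["A0"] - m1_fit.params["w0"]) / (4 * m1_fit.params["s"])
        assert got == pytest.approx(expect, rel=1e-12)

    def test_everywhere_nonpositive_for_declining_fit(self, m1_fit):
        nd = pd.DataFrame({"leaf_type": ["SM"] * 50, "day": np.linspace(0, 89, 50)})
        assert np.all(m1_fit.drying_speed(nd) <= 0)

    def test_matches_finite_differences_of_predict(self, m1_fit):
        days = np.linspace(5, 85, 9)
        nd = pd.DataFrame({"leaf_type": ["GE"] * 9, "day": days})
        h = 1e-5
        up = m1_fit.predict(nd.assign(day=days + h))
        dn = m1_fit.predict(nd.assign(day=days - h))
        np.testing.assert_allclose(m1_fit.drying_speed(nd), (up - dn) / (2 * h),
                                   rtol=1e-6, atol=1e-9)

    def test_unsupported_for_linear_mean(self, dataset):
        from lfmcdyn.selection import _m5_spec
        res = LfmcModel(dataset, _m5_spec()).fit(seed=0)
        with pytest.raises(UnsupportedOperationError):
            res.drying_speed(dataset.table.head(3))


class TestSummaryExports:
    def test_summary_mentions_criteria_and_coefficients(self, m1_fit):
        text = m1_fit.summary()
        assert "AIC" in text and "A[SM]" in text and "sigma" in text

    def test_to_dict_roundtrips_numbers(self, m1_fit):
        d = m1_fit.to_dict()
        assert d["k"] == 15
        assert d["AIC"] == pytest.approx(m1_fit.aic)
        assert set(d["params"]) == set(m1_fit.params.index)
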