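"""Stepwise protocol mechanics, alternative-model suite and contrasts."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

import lfmcdyn as L
from lfmcdyn.exceptions import UnsupportedOperationError
from lfmcdyn.selection import (
    ComparisonTable,
    _m5_spec,
    _prefer_richer,
    fit_alternatives,
    leaf_type_contrasts,
    null_model_aic,
    select_model,
)


class TestDeltaAicGate:
    def test_equal_aic_keeps_simpler_model(self):
        rich = SimpleNamespace(aic=100.0)
        simple = SimpleNamespace(aic=100.0)
        assert not _prefer_richer(rich, simple, 2.0)

    def test_small_gap_keeps_simpler_model(self):
        assert not _prefer_richer(SimpleNamespace(aic=98.5), SimpleNamespace(aic=100.0), 2.0)

    def test_large_gap_keeps_richer_model(self):
        assert _prefer_richer(SimpleNamespace(aic=97.0), SimpleNamespace(aic=100.0), 2.0)

    def test_failed_candidate_never_preferred(self):
        assert not _prefer_richer(None, SimpleNamespace(aic=100.0), 2.0)


class TestNullModel:
    def test_closed_form_gaussian_mle_identity(self, dataset):
        res = L.LfmcModel(dataset, _m5_spec()).fit(seed=0)
        y = dataset.table["lfmc"].to_numpy()
        s2 = np.mean((y - y.mean()) ** 2)
        expect = dataset.n * (np.log(2 * np.pi * s2) + 1) + 4
        assert res.aic == pytest.approx(expect, abs=1e-6)
        assert null_model_aic(dataset) == pytest.approx(expect, abs=1e-10)
        assert res.k_params == 2
        assert res.params["b0"] == pytest.approx(y.mean(), abs=1e-6)


class TestComparisonTable:
    def test_sorted_with_zero_delta_for_best(self):
        rows = [SimpleNamespace(model=SimpleNamespace(spec=SimpleNamespace(label=lab)),
                                k_params=k, llf=ll, aic=-2 * ll + 2 * k)
                for lab, k, ll in (("a", 3, -50.0), ("b", 2, -49.0), ("c", 5, -60.0))]
        tab = ComparisonTable.from_results(rows)
        assert tab.frame["dAIC"].iloc[0] == 0.0
        assert tab.frame["AIC"].is_monotonic_increasing

    def test_five_model_suite_ranks_selected_model_first(self, dataset, m1_fit):
        table, results = fit_alternatives(dataset, L.ProtocolConfig(seed=0), m1=m1_fit)
        frame = table.frame
        assert set(frame["model"]) == {"M1", "M2", "M3", "M4", "M5"}
        assert frame["model"].iloc[0] == "M1"
        # shared stochastic structure but linear mean: M3 beats the purely
        # fixed-effects alternatives; the null model is last
        order = list(frame["model"])
        assert order.index("M3") < order.index("M2") or order.index("M3") < order.index("M4")
        assert frame["model"].iloc[-1] == "M5"
        m5 = frame[frame["model"] == "M5"].iloc[0]
        assert m5["k"] == 2
        assert m5["AIC"] == pytest.approx(null_model_aic(dataset), abs=1e-4)


class TestProtocol:
    def test_recovers_generating_structure(self, selection_run):
        spec = selection_run.spec
        assert spec.random == ("A",)
        assert spec.varident is True
        assert spec.arma is None
        assert spec.coding("A") == "by_leaf_type"
        assert spec.coding("w") == "by_leaf_type"
        assert spec.coding("m") == "common"
        assert spec.coding("s") == "common"
        assert selection_run.fit.k_params == 15

    def test_decision_log_complete_and_traceable(self, selection_run):
        log = selection_run.decision_log()
        fitted = log.dropna(subset=["AIC"])
        # every decision row's AIC matches a logged fit at that AIC
        decisions = log[log["note"].str.startswith(("kept", "dropped", "collapsed"))]
        for _, row in decisions.iterrows():
            assert np.isclose(fitted["AIC"], row["AIC"], atol=1e-6).any()
        # the final model's AIC is itself logged
        assert np.isclose(fitted["AIC"], selection_run.fit.aic, atol=1e-6).any()
        assert set(log["step"]) <= {1, 2, 3}

    def test_protocol_deterministic_given_seed(self):
        ds = L.simulate_dataset(L.DesignSpec(points=2, days=(0, 20, 45, 65, 89)),
                                seed=23, n_lost=0)
        cfg = L.ProtocolConfig(seed=5, random_candidates=("A",), arma_orders=((1, 0),))
        a = L.select_model(ds, cfg)
        b = L.select_model(ds, cfg)
        assert a.spec == b.spec
        assert a.fit.aic == b.fit.aic
        pd.testing.assert_frame_equal(a.decision_log(), b.decision_log())

    def test_leaf_differences_only_in_asymptote_detected(self):
        """Generated with leaf-type differences in A only (w, m, s shared):
        the protocol keeps leaf type on A and drops it from m and s."""
        curves = {
            "GW": L.LogisticParams(A=60.0, w=25.0, m=30.0, s=-14.0),
            "GE": L.LogisticParams(A=140.0, w=25.0, m=30.0, s=-14.0),
            "SM": L.LogisticParams(A=260.0, w=25.0, m=30.0, s=-14.0),
            "SS": L.LogisticParams(A=200.0, w=25.0, m=30.0, s=-14.0),
        }
        truth = L.GeneratingParams(curves=curves, random_sds={"A": 6.0},
                                   sigma_base=6.0, delta={"GE": 1.0, "SM": 1.5, "SS": 1.5})
        ds = L.simulate_dataset(L.DesignSpec(n_lost=0), truth, seed=17)
        sel = L.select_model(ds, L.ProtocolConfig(seed=0, arma_orders=((1, 0),)))
        assert sel.spec.coding("A") == "by_leaf_type"
        assert sel.spec.coding("m") == "common"
        assert sel.spec.coding("s") == "common"


class TestContrasts:
    def test_reference_contrast_equals_offset_coefficient(self, m1_fit):
        tab = leaf_type_contrasts(m1_fit, "A")
        row = tab[tab["contrast"] == "GE - GW"].iloc[0]
        assert row["estimate"] == pytest.approx(m1_fit.params["A[GE]"], rel=1e-12)
        assert row["se"] == pytest.approx(m1_fit.bse["A[GE]"], rel=1e-9)

    def test_all_six_pairs_present(self, m1_fit):
        tab = leaf_type_contrasts(m1_fit, "w")
        assert len(tab) == 6
        # difference between the two shrubs equals the offset difference
        row = tab[tab["contrast"] == "SS - SM"].iloc[0]
        assert row["estimate"] == pytest.approx(
            m1_fit.params["w[SS]"] - m1_fit.params["w[SM]"], rel=1e-12)

    def test_ci_is_wald_interval(self, m1_fit):
        tab = leaf_type_contrasts(m1_fit, "A")
        np.testing.assert_allclose(tab["ci_high"] - tab["estimate"],
                                   1.96 * tab["se"], rtol=1e-12)

    def test_tukey_adjustment_never_smaller_than_unadjusted(self, m1_fit):
        raw = leaf_type_contrasts(m1_fit, "A", adjust="none")
        adj = leaf_type_contrasts(m1_fit, "A", adjust="tukey")
        assert np.all(adj["p"].to_numpy() >= raw["p"].to_numpy() - 1e-12)

    def test_common_parameter_rejected(self, m1_fit):
        with pytest.raises(UnsupportedOperationError):
            leaf_type_contrasts(m1_fit, "m")
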