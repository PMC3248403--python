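import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from tnbcsig.expression_io import SampleRecord
from tnbcsig.survival_stats import (
    CoxSeparationError,
    EfsRecord,
    code_clinical_covariates,
    combine_endpoints,
    cox_fit,
    cox_score_test,
    km_logrank,
)

from oracles import logrank_chi2_binary


def rec(sid, endpoint, time, event, **kw):
    return SampleRecord(sid, "D0", endpoint_type=endpoint, time=time, event=event, **kw)


def efs_from_arrays(time, event, endpoint="RFS"):
    return [
        EfsRecord(f"s{i}", float(t), int(e), endpoint)
        for i, (t, e) in enumerate(zip(time, event))
    ]


class TestCombineEndpoints:
    def test_rfs_taken_when_available(self):
        out = combine_endpoints([rec("a", "RFS", 60.0, 1)])
        assert out[0].efs_time == 60.0
        assert out[0].efs_event == 1
        assert out[0].source_endpoint == "RFS"

    def test_censoring_truncated_at_horizon(self):
        out = combine_endpoints([rec("a", "DMFS", 150.0, 0)])
        assert (out[0].efs_time, out[0].efs_event) == (120.0, 0)

    def test_late_event_becomes_administrative_censoring(self):
        out = combine_endpoints([rec("a", "RFS", 130.0, 1)])
        assert (out[0].efs_time, out[0].efs_event) == (120.0, 0)

    def test_records_without_endpoint_excluded(self):
        out = combine_endpoints(
            [rec("a", "RFS", 10.0, 1), SampleRecord("b", "D0", endpoint_type="none")]
        )
        assert [r.sample_id for r in out] == ["a"]


class TestKmLogrank:
    def test_six_sample_toy_matches_hand_chi_square(self):
        time = [2.0, 5.0, 7.0, 11.0, 13.0, 17.0]
        event = [1, 0, 1, 1, 0, 1]
        group = [1, 0, 1, 0, 1, 0]
        efs = efs_from_arrays(time, event)
        res = km_logrank(efs, pd.Series(group, index=[f"s{i}" for i in range(6)]))
        expected = logrank_chi2_binary(time, event, group)
        assert res.chi2 == pytest.approx(expected, abs=1e-10)

    def test_km_curve_starts_at_one_and_is_nonincreasing(self):
        rng = np.random.default_rng(0)
        time = rng.exponential(40, 60)
        event = rng.integers(0, 2, 60)
        event[0] = 1
        efs = efs_from_arrays(time, event)
        groups = pd.Series(
            ["g1"] * 30 + ["g2"] * 30, index=[f"s{i}" for i in range(60)]
        )
        res = km_logrank(efs, groups)
        for curve in res.curves.values():
            surv = curve["survival"].to_numpy()
            assert surv[0] <= 1.0 + 1e-12
            assert (np.diff(surv) <= 1e-12).all()
        first_event = min(r.efs_time for r in efs if r.efs_event)
        for g in ("g1", "g2"):
            assert res.survival_at(g, first_event - 1e-9) == pytest.approx(1.0)

    def test_single_group_errors(self):
        efs = efs_from_arrays([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError, match="groups"):
            km_logrank(efs, pd.Series(["g"] * 2, index=["s0", "s1"]))


class TestCoxFit:
    def test_score_test_equals_logrank_on_untied_toy(self):
        time = [3.0, 5.0, 8.0, 9.0, 12.0, 15.0, 20.0, 24.0]
        event = [1, 1, 0, 1, 1, 0, 1, 0]
        group = [1, 0, 0, 1, 0, 1, 1, 0]
        efs = efs_from_arrays(time, event)
        cov = pd.DataFrame({"g": group}, index=[f"s{i}" for i in range(8)])
        chi2 = cox_score_test(efs, cov)
        expected = logrank_chi2_binary(time, event, group)
        assert chi2 == pytest.approx(expected, abs=1e-8)

    def test_matches_lifelines_on_untied_data(self):
        rng = np.random.default_rng(1)
        n = 120
        x = rng.normal(size=n)
        time = rng.exponential(1.0 / (0.02 * np.exp(0.7 * x)))
        cens = rng.uniform(5, 100, n)
        obs = np.minimum(time, cens)
        event = (time <= cens).astype(int)
        assert len(np.unique(obs)) == n  # tie-free: Efron == Breslow
        efs = efs_from_arrays(obs, event)
        cov = pd.DataFrame({"x": x}, index=[f"s{i}" for i in range(n)])
        fit = cox_fit(efs, cov)
        cph = CoxPHFitter().fit(
            pd.DataFrame({"T": obs, "E": event, "x": x}), "T", "E"
        )
        assert fit.table.loc["x", "coef"] == pytest.approx(
            float(cph.params_["x"]), abs=1e-4
        )
        assert fit.table.loc["x", "se"] == pytest.approx(
            float(cph.standard_errors_["x"]), abs=1e-4
        )

    def test_null_covariate_hr_near_one(self):
        rng = np.random.default_rng(2)
        inside = 0
        for _ in range(100):
            n = 400
            x = rng.normal(size=n)
            time = rng.exponential(50, n)
            cens = rng.uniform(10, 120, n)
            obs, event = np.minimum(time, cens), (time <= cens).astype(int)
            efs = efs_from_arrays(obs, event)
            cov = pd.DataFrame({"x": x}, index=[f"s{i}" for i in range(n)])
            hr = cox_fit(efs, cov).hazard_ratio("x")
            inside += 0.8 < hr < 1.25
        assert inside >= 90

    def test_known_beta_recovered_within_two_se(self):
        rng = np.random.default_rng(3)
        beta = 0.6
        covered = 0
        for _ in range(100):
            n = 300
            x = rng.normal(size=n)
            time = rng.exponential(1.0 / (0.008 * np.exp(beta * x)))
            cens = rng.uniform(10, 120, n)
            obs, event = np.minimum(time, cens), (time <= cens).astype(int)
            efs = efs_from_arrays(obs, event)
            cov = pd.DataFrame({"x": x}, index=[f"s{i}" for i in range(n)])
            fit = cox_fit(efs, cov)
            est, se = fit.table.loc["x", "coef"], fit.table.loc["x", "se"]
            covered += abs(est - beta) <= 2 * se
        assert covered >= 95

    def test_collinear_design_detected(self):
        efs = efs_from_arrays([3.0, 5.0, 8.0, 9.0], [1, 1, 1, 0])
        cov = pd.DataFrame(
            {"a": [1.0, 0, 1, 0], "b": [2.0, 0, 2, 0]},
            index=[f"s{i}" for i in range(4)],
        )
        with pytest.raises(ValueError, match="rank deficient"):
            cox_fit(efs, cov)

    def test_separation_raises_with_diagnostic(self):
        # perfect separation: all events in one group, which also fails first
        time = [1.0, 2.0, 3.0, 50.0, 60.0, 70.0]
        event = [1, 1, 1, 0, 0, 0]
        group = [1.0, 1, 1, 0, 0, 0]
        efs = efs_from_arrays(time, event)
        cov = pd.DataFrame({"g": group}, index=[f"s{i}" for i in range(6)])
        with pytest.raises(CoxSeparationError):
            with pytest.warns(UserWarning):
                cox_fit(efs, cov)

    def test_complete_case_exclusion_reported(self):
        rng = np.random.default_rng(4)
        n = 60
        x = rng.normal(size=n)
        time = rng.exponential(1.0 / (0.02 * np.exp(0.8 * x)))
        cens = rng.uniform(5, 100, n)
        obs, event = np.minimum(time, cens), (time <= cens).astype(int)
        efs = efs_from_arrays(obs, event)
        x[:10] = np.nan
        cov = pd.DataFrame({"x": x}, index=[f"s{i}" for i in range(n)])
        fit = cox_fit(efs, cov)
        assert fit.n_used == 50


class TestCovariateCoding:
    def test_table_contrasts(self):
        r = rec(
            "a", "RFS", 10.0, 1,
            age_class=">50", size_class="<=2cm", node_class="LNN", grade_class="G3",
        )
        coded = code_clinical_covariates([r])
        assert coded.loc["a"].tolist() == [1.0, 1.0, 1.0, 1.0]
        r2 = rec("b", "RFS", 10.0, 1, age_class="<=50", node_class="LNP")
        coded2 = code_clinical_covariates([r2])
        assert coded2.loc["b", "node_lnn"] == 0.0
        assert coded2.loc["b", "age_gt50"] == 0.0
        assert np.isnan(coded2.loc["b", "grade_g3"])
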