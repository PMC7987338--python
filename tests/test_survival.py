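"""Siler hazard machinery, Cox models, and the Bayesian trajectory fits."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import quad
from scipy.optimize import minimize

import silverback as sb
from silverback.survival import (
    SilerFit,
    siler_cumulative_hazard,
    siler_hazard,
    siler_loglik,
    siler_survival,
)


class TestSilerHazard:
    def test_constant_hazard_limit(self):
        p = sb.SilerParams(a0=0.0, a1=1.0, c=0.05, b0=0.0, b1=1.0)
        ages = np.linspace(0, 30, 7)
        np.testing.assert_allclose(siler_hazard(p, ages), 0.05)
        assert siler_survival(p, 2.0, 10.0) == pytest.approx(np.exp(-0.4))

    def test_fast_infant_decay_vanishes_after_infancy(self):
        p = sb.SilerParams(a0=0.5, a1=1e6, c=0.02, b0=0.001, b1=0.1)
        assert siler_hazard(p, 1.0) == pytest.approx(0.02 + 0.001 * np.exp(0.1))

    def test_cumulative_hazard_matches_quadrature_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            p = sb.SilerParams(a0=rng.uniform(0, 1), a1=rng.uniform(0.1, 3),
                               c=rng.uniform(0, 0.1), b0=rng.uniform(0, 0.05),
                               b1=rng.uniform(0.01, 0.3))
            x = rng.uniform(0.5, 40)
            numeric, _ = quad(lambda t: siler_hazard(p, t), 0, x, limit=200)
            assert siler_cumulative_hazard(p, x) == pytest.approx(numeric, abs=1e-8)

    def test_survival_monotone_and_one_at_entry(self):
        p = sb.SilerParams()
        ages = np.linspace(2, 50, 60)
        s = siler_survival(p, 2.0, ages)
        assert s[0] == pytest.approx(1.0)
        assert (np.diff(s) <= 1e-12).all()

    def test_bathtub_shape(self):
        p = sb.SilerParams(a0=0.5, a1=1.5, c=0.01, b0=0.002, b1=0.15)
        assert siler_hazard(p, 0.1) > siler_hazard(p, 3.0)
        assert siler_hazard(p, 45.0) > siler_hazard(p, 20.0)

    def test_negative_parameters_rejected(self):
        with pytest.raises(ValueError):
            sb.SilerParams(a0=-0.1)

    def test_sampled_ages_follow_the_siler_law(self):
        from scipy.stats import kstest

        p = sb.SilerParams()
        rng = np.random.default_rng(9)
        draws = sb.sample_siler(p, 1500, rng, entry_age=2.0)
        h2 = siler_cumulative_hazard(p, 2.0)
        resid = siler_cumulative_hazard(p, draws) - h2
        assert kstest(resid, "expon").pvalue > 0.01


class TestRecords:
    def _roster(self, rows):
        return pd.DataFrame(rows)

    def test_death_before_age_two_excluded(self):
        roster = self._roster([
            dict(id="a", sex="F", death_age=1.9, censor_age=np.nan, loss_age=np.nan),
            dict(id="b", sex="F", death_age=12.0, censor_age=np.nan, loss_age=np.nan),
        ])
        recs = sb.build_survival_records(roster)
        assert list(recs.id) == ["b"]

    def test_orphan_enters_at_loss_age_with_class(self):
        roster = self._roster([
            dict(id="a", sex="F", death_age=12.0, censor_age=np.nan, loss_age=5.1),
        ])
        rec = sb.build_survival_records(roster).iloc[0]
        assert (rec.entry_age, rec.exit_age, rec.event, rec.orphan_class) \
            == (5.1, 12.0, 1, "juvenile")

    def test_episode_split_switches_class_at_loss(self):
        roster = self._roster([
            dict(id="a", sex="F", death_age=12.0, censor_age=np.nan, loss_age=5.0),
            dict(id="b", sex="F", death_age=np.nan, censor_age=9.0, loss_age=np.nan),
        ])
        ep = sb.episode_split(sb.build_survival_records(roster))
        a = ep[ep.id == "a"].sort_values("start")
        assert list(a.start) == [2.0, 5.0] and list(a.stop) == [5.0, 12.0]
        assert list(a.event) == [0, 1]
        assert list(a.class_juvenile) == [0.0, 1.0]
        b = ep[ep.id == "b"].iloc[0]
        assert (b.start, b.stop, b.event) == (2.0, 9.0, 0)

    def test_missing_exit_information_rejected(self):
        roster = self._roster([
            dict(id="a", sex="F", death_age=np.nan, censor_age=np.nan,
                 loss_age=np.nan),
        ])
        with pytest.raises(ValueError, match="neither"):
            sb.build_survival_records(roster)


def _brute_force_cox(episodes, covariate="class_orphan"):
    """Direct maximization of the written Cox partial likelihood."""
    events = episodes[episodes.event == 1]

    def negpl(beta):
        ll = 0.0
        for _, row in events.iterrows():
            t = row.stop
            risk = episodes[(episodes.start < t) & (episodes.stop >= t)]
            ll += (row[covariate] * beta[0]
                   - np.log(np.sum(np.exp(risk[covariate] * beta[0]))))
        return -ll

    return minimize(negpl, [0.0], method="Nelder-Mead",
                    options=dict(xatol=1e-12, fatol=1e-14)).x[0]


class TestCox:
    def test_identical_hazards_give_null_coefficient(self):
        recs = sb.simulate_lifespans(300, sb.SilerParams(), orphan_frac=0.5,
                                     log_hr=0.0, seed=2)
        fit = sb.fit_cox_ph(recs, class_coding="merged")
        assert (fit.est.abs() < 0.5).all()
        assert (fit.p > 0.01).all()

    def test_matches_partial_likelihood_oracle_on_small_datasets(self):
        rng = np.random.default_rng(5)
        compared = 0
        for r in range(30):
            n = int(rng.integers(4, 9))
            recs = sb.simulate_lifespans(n, sb.SilerParams(), orphan_frac=0.5,
                                         log_hr=0.6, censor_age=40, seed=300 + r)
            recs["orphan_class"] = np.where(recs.orphan_class == "non_orphan",
                                            "non_orphan", "orphan")
            if recs.orphan_class.nunique() < 2 or recs.event.sum() == 0:
                continue
            if recs.groupby("orphan_class").event.sum().min() == 0:
                continue
            oracle = _brute_force_cox(sb.episode_split(recs))
            if abs(oracle) > 5:        # monotone likelihood: flagged, not compared
                continue
            fit = sb.fit_cox_ph(recs, class_coding="merged")
            assert fit.est.iloc[0] == pytest.approx(oracle, abs=1e-6)
            compared += 1
        assert compared >= 10

    def test_proportional_hazard_recovery(self):
        recs = sb.simulate_lifespans(400, sb.SilerParams(), orphan_frac=0.5,
                                     log_hr=np.log(2.0), seed=17)
        recs["orphan_class"] = np.where(recs.orphan_class == "non_orphan",
                                        "non_orphan", "juv_subadult")
        fit = sb.fit_cox_ph(recs, class_coding="merged")
        assert fit.est.iloc[0] == pytest.approx(np.log(2.0), abs=0.25)

    def test_no_events_rejected(self):
        recs = sb.simulate_lifespans(30, sb.SilerParams(), censor_age=2.5, seed=3)
        recs["event"] = 0
        with pytest.raises(ValueError, match="no events"):
            sb.fit_cox_ph(recs)


class TestSilerBayes:
    def test_prop_hazards_nests_null_at_zero_effects(self):
        recs = sb.simulate_lifespans(80, sb.SilerParams(), orphan_frac=0.5, seed=6)
        entry = recs.entry_age.to_numpy()
        exit = recs.exit_age.to_numpy()
        event = recs.event.to_numpy(float)
        Z = (recs.orphan_class != "non_orphan").to_numpy(float)[:, None]
        theta = sb.SilerParams().as_array()
        ll_null = siler_loglik(theta, "null", entry, exit, event,
                               np.zeros((len(recs), 0)))
        ll_prop = siler_loglik(np.r_[theta, 0.0], "prop_hazards", entry, exit,
                               event, Z)
        ll_all = siler_loglik(np.r_[theta, np.zeros(5)], "all_params", entry, exit,
                              event, Z)
        assert ll_prop == pytest.approx(ll_null, abs=1e-10)
        assert ll_all == pytest.approx(ll_null, abs=1e-10)

    def test_dic_identity_recomputable_from_samples(self):
        recs = sb.simulate_lifespans(120, sb.SilerParams(), seed=8)
        fit = sb.fit_siler_bayes(recs, "null", n_steps=400, seed=0)
        entry, exit = recs.entry_age.to_numpy(), recs.exit_age.to_numpy()
        event = recs.event.to_numpy(float)
        Z = np.zeros((len(recs), 0))
        mean_dev = np.mean([-2 * siler_loglik(t, "null", entry, exit, event, Z)
                            for t in fit.samples])
        dev_at_mean = -2 * siler_loglik(fit.posterior_mean(), "null", entry, exit,
                                        event, Z)
        assert fit.dic == pytest.approx(2 * mean_dev - dev_at_mean, rel=1e-10)
        assert fit.p_d == pytest.approx(mean_dev - dev_at_mean, rel=1e-10)

    def test_log_hazard_ratio_recovered(self):
        recs = sb.simulate_lifespans(500, sb.SilerParams(), orphan_frac=0.4,
                                     log_hr=0.7, seed=30)
        fit = sb.fit_siler_bayes(recs, "prop_hazards", n_steps=900, seed=1)
        ci = fit.credible_interval()
        row = [n for n in fit.param_names if n.startswith("log_hr")][0]
        assert ci.loc[row, "lower"] < 0.7 < ci.loc[row, "upper"]
        assert ci.loc[row, "mean"] == pytest.approx(0.7, abs=0.3)


def _stub_fit(variant, dic, n=100):
    return SilerFit(variant=variant, param_names=("a0",), samples=np.zeros((1, 1)),
                    log_likelihoods=np.zeros(1), dic=dic, p_d=1.0,
                    mean_deviance=dic - 1.0, rhat=np.ones(1), n_records=n,
                    converged=True)


class TestDicComparison:
    def test_deltas_use_unrounded_dics(self):
        fits = {"null": _stub_fit("null", 371.455), "prop": _stub_fit("prop", 374.16),
                "all": _stub_fit("all", 377.04)}
        table = sb.compare_dic(fits)
        assert table.delta_dic.loc["null"] == 0.0
        assert table.delta_dic.loc["prop"] == pytest.approx(374.16 - 371.455)
        assert table.delta_dic.loc["all"] == pytest.approx(377.04 - 371.455)
        assert list(table.index) == ["null", "prop", "all"]

    def test_single_fit_rejected(self):
        with pytest.raises(ValueError, match="two"):
            sb.compare_dic({"null": _stub_fit("null", 100.0)})

    def test_input_order_invariant(self):
        a = sb.compare_dic({"x": _stub_fit("x", 10.0), "y": _stub_fit("y", 12.0)})
        b = sb.compare_dic({"y": _stub_fit("y", 12.0), "x": _stub_fit("x", 10.0)})
        pd.testing.assert_frame_equal(a, b)

    def test_mismatched_record_sets_rejected(self):
        with pytest.raises(ValueError, match="different record"):
            sb.compare_dic({"x": _stub_fit("x", 10.0, n=100),
                            "y": _stub_fit("y", 12.0, n=90)})
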