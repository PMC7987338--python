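"""The synthetic generator: determinism, invariants, and statistical structure."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

import silverback as sb
from silverback.config import age_sex_class, orphan_class_at_loss
from silverback.survival import siler_cumulative_hazard


class TestClassification:
    @pytest.mark.parametrize(
        "age, expected",
        [(2.0, "infant"), (3.0, "infant"), (4.0, "juvenile"), (5.9, "juvenile"),
         (6.0, "subadult"), (7.99, "subadult")],
    )
    def test_orphan_class_bins(self, age, expected):
        assert orphan_class_at_loss(age) == expected

    def test_merged_coding_pools_juveniles_and_subadults(self):
        assert orphan_class_at_loss(5.0, merged=True) == "juv_subadult"
        assert orphan_class_at_loss(7.0, merged=True) == "juv_subadult"
        assert orphan_class_at_loss(3.0, merged=True) == "infant"

    @pytest.mark.parametrize("age", [1.9, 8.0, -1.0])
    def test_ages_outside_orphan_window_rejected(self, age):
        with pytest.raises(ValueError):
            orphan_class_at_loss(age)

    @pytest.mark.parametrize(
        "age, sex, dominant, expected",
        [(3.0, "M", False, "infant"), (5.0, "F", False, "juvenile"),
         (7.0, "M", False, "subadult_male"), (7.0, "F", False, "subadult_female"),
         (10.0, "F", False, "adult_female"), (10.0, "M", False, "blackback"),
         (15.0, "M", False, "subordinate_adult_male"),
         (15.0, "M", True, "dominant_male")],
    )
    def test_age_sex_classes(self, age, sex, dominant, expected):
        assert age_sex_class(age, sex, dominant) == expected


class TestPopulation:
    def test_same_seed_gives_identical_output(self):
        cfg = sb.PopulationConfig(n_groups=3, seed=42)
        r1, i1 = sb.simulate_population(cfg)
        r2, i2 = sb.simulate_population(cfg)
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(i1, i2)
        s1 = sb.simulate_incident_dataset(cfg).scans
        s2 = sb.simulate_incident_dataset(cfg).scans
        pd.testing.assert_frame_equal(s1, s2)

    def test_group_size_below_three_rejected(self):
        with pytest.raises(ValueError, match="roup size"):
            sb.PopulationConfig(group_size_range=(2, 5))

    def test_every_incident_has_orphans_and_a_non_orphan_peer(self, small_study):
        roster, incidents = small_study.roster, small_study.incidents
        for inc in incidents.itertuples():
            orphans = set(inc.orphan_ids)
            assert orphans
            grp = roster[roster.group == inc.group]
            ages = (inc.date - grp.birth_date).dt.days / 365.25
            peers = grp[(ages >= 2) & (ages < 8) & ~grp.id.isin(orphans)]
            assert len(peers) >= 1
            assert (grp.set_index("id").loc[list(orphans), "mother_id"]
                    == inc.mother_id).all()

    def test_orphan_class_matches_age_at_loss(self, small_study):
        roster = small_study.roster
        orphans = roster[roster.orphan_class != "non_orphan"]
        for rec in orphans.itertuples():
            assert rec.orphan_class == orphan_class_at_loss(rec.loss_age)

    def test_mother_in_roster_or_unknown(self, small_study):
        roster = small_study.roster
        known = set(roster.id) | {"unknown"}
        assert roster.mother_id.isin(known).all()


class TestLifespans:
    def test_null_hazard_effect_gives_identical_siler_law(self):
        """With zero orphan log-HR the exponential residuals
        H(exit) - H(entry) of orphans and non-orphans are the same Exp(1)."""
        params = sb.SilerParams()
        recs = sb.simulate_lifespans(2000, params, orphan_frac=0.5, log_hr=0.0,
                                     censor_age=500.0, seed=13)
        resid = (siler_cumulative_hazard(params, recs.exit_age.to_numpy())
                 - siler_cumulative_hazard(params, recs.entry_age.to_numpy()))
        orphan = recs.orphan_class != "non_orphan"
        stat = ks_2samp(resid[orphan], resid[~orphan])
        assert stat.pvalue > 0.01

    def test_positive_log_hr_shortens_orphan_survival(self):
        params = sb.SilerParams()
        recs = sb.simulate_lifespans(3000, params, orphan_frac=0.5, log_hr=1.0,
                                     censor_age=500.0, seed=13)
        orphan = recs.orphan_class != "non_orphan"
        resid_o = (siler_cumulative_hazard(params, recs.exit_age[orphan].to_numpy())
                   - siler_cumulative_hazard(params, recs.entry_age[orphan].to_numpy()))
        resid_n = (siler_cumulative_hazard(params, recs.exit_age[~orphan].to_numpy())
                   - siler_cumulative_hazard(params, recs.entry_age[~orphan].to_numpy()))
        # hazard ratio e -> H-increments scaled by 1/e
        assert resid_o.mean() < 0.6 * resid_n.mean()


class TestLatentAssociations:
    def test_contact_never_exceeds_proximity(self, small_study):
        roster, inc = small_study.roster, small_study.incidents.iloc[0]
        latent = sb.simulate_latent_associations(roster, inc.group, inc.date, seed=11)
        assert (latent.p_contact <= latent.p_proximity + 1e-12).all()
        assert np.allclose(latent.p_proximity, latent.p_proximity.T)

    def test_invalid_probability_ordering_rejected(self):
        with pytest.raises(ValueError):
            sb.LatentAssociation(("a", "b"), p_proximity=0.2, p_contact=0.5)

    def test_maternal_loss_null_effect_removes_only_the_mother(self, small_study,
                                                               null_effects):
        roster, inc = small_study.roster, small_study.incidents.iloc[0]
        latent = sb.simulate_latent_associations(roster, inc.group, inc.date, seed=11)
        post = sb.apply_maternal_loss(latent, inc.to_dict(), roster, null_effects)
        assert inc.mother_id not in post.ids
        keep = [k for k, i in enumerate(latent.ids) if i != inc.mother_id]
        np.testing.assert_allclose(post.p_proximity,
                                   latent.p_proximity[np.ix_(keep, keep)])

    def test_boost_is_additive_on_probability(self, small_study):
        roster, inc = small_study.roster, small_study.incidents.iloc[0]
        latent = sb.simulate_latent_associations(roster, inc.group, inc.date, seed=11)
        orphan = inc.orphan_ids[0]
        dom = roster[(roster.group == inc.group) & roster.dominant].id.iloc[0]
        before = latent.get(orphan, dom).p_proximity
        fx = sb.OrphanEffectConfig(boost_by_class={"dominant_male": 0.2})
        post = sb.apply_maternal_loss(latent, inc.to_dict(), roster, fx)
        assert post.get(orphan, dom).p_proximity == pytest.approx(before + 0.2)

    def test_boost_above_one_is_clipped(self, small_study):
        roster, inc = small_study.roster, small_study.incidents.iloc[0]
        latent = sb.simulate_latent_associations(roster, inc.group, inc.date, seed=11)
        fx = sb.OrphanEffectConfig(boost_by_class={c: 5.0 for c in sb.AGE_SEX_CLASSES})
        post = sb.apply_maternal_loss(latent, inc.to_dict(), roster, fx)
        assert post.p_proximity.max() <= 1.0
        assert (post.p_contact <= post.p_proximity + 1e-12).all()

    def test_unknown_orphan_id_rejected(self, small_study, null_effects):
        roster, inc = small_study.roster, small_study.incidents.iloc[0]
        latent = sb.simulate_latent_associations(roster, inc.group, inc.date, seed=11)
        bad = inc.to_dict()
        bad["orphan_ids"] = ("nobody",)
        with pytest.raises(KeyError):
            sb.apply_maternal_loss(latent, bad, roster, null_effects)


class TestFocalScans:
    def _pair_latent(self, p_prox, p_contact):
        m = np.array([[0.0, p_prox], [p_prox, 0.0]])
        c = np.array([[0.0, p_contact], [p_contact, 0.0]])
        return sb.LatentAssociations(["a", "b"], m, c)

    def test_certain_dyad_has_sri_one(self):
        latent = self._pair_latent(1.0, 0.0)
        scans = sb.simulate_focal_scans(latent, ("2010-01-01", "2010-01-11"), 6, seed=1)
        assert sb.compute_sri(scans, ("a", "b"), "proximity") == 1.0

    def test_zero_contact_probability_gives_empty_contact_sets(self):
        latent = self._pair_latent(0.8, 0.0)
        scans = sb.simulate_focal_scans(latent, ("2010-01-01", "2010-01-11"), 6, seed=1)
        assert all(len(c) == 0 for c in scans.contact_partners)

    def test_sri_converges_to_latent_probability(self):
        latent = self._pair_latent(0.4, 0.1)
        scans = sb.simulate_focal_scans(latent, ("2010-01-01", "2010-12-01"), 8, seed=2)
        assert len(scans) >= 2000
        assert sb.compute_sri(scans, ("a", "b"), "proximity") == pytest.approx(0.4, abs=0.03)
        assert sb.compute_sri(scans, ("a", "b"), "contact") == pytest.approx(0.1, abs=0.03)

    def test_contact_subset_of_proximity_every_scan(self, small_study):
        for prox, cont in zip(small_study.scans.proximity_partners,
                              small_study.scans.contact_partners):
            assert set(cont) <= set(prox)

    def test_focal_rotation_is_balanced(self, small_study):
        inc = small_study.incidents.iloc[0]
        scans = small_study.scans_for_group(inc.group)
        pre = scans[scans.date < inc.date]  # mother present for the whole window
        counts = pre.focal.value_counts()
        assert counts.max() - counts.min() <= 2

    def test_window_and_rate_validation(self):
        latent = self._pair_latent(0.5, 0.1)
        with pytest.raises(ValueError, match="empty"):
            sb.simulate_focal_scans(latent, ("2010-01-02", "2010-01-01"), 6, seed=1)
        with pytest.raises(ValueError, match="positive"):
            sb.simulate_focal_scans(latent, ("2010-01-01", "2010-01-05"), 0, seed=1)


class TestDispersal:
    def test_long_run_fraction_matches_logistic_intercept(self):
        roster = pd.DataFrame({"id": [f"x{i}" for i in range(20000)],
                               "orphan_class": "non_orphan"})
        out = sb.simulate_dispersal(roster, {"intercept": np.log(0.6)}, seed=4)
        # logistic(log 0.6) = 0.6 / 1.6 = 0.375
        assert out.dispersed.mean() == pytest.approx(0.375, abs=0.01)

    def test_extreme_log_odds_are_capped_not_overflowed(self):
        roster = pd.DataFrame({"id": [f"x{i}" for i in range(5000)],
                               "orphan_class": "non_orphan"})
        out = sb.simulate_dispersal(roster, {"intercept": 500.0}, seed=4)
        assert out.dispersed.all()

    def test_offsets_recovered_by_binomial_glm(self):
        n = 5000
        rng = np.random.default_rng(8)
        classes = rng.choice(["non_orphan", "infant", "juv_subadult"], size=n)
        roster = pd.DataFrame({"id": [f"x{i}" for i in range(n)],
                               "orphan_class": classes})
        truth = {"intercept": -0.511, "infant": 0.693, "juv_subadult": 1.609}
        out = sb.simulate_dispersal(roster, truth, seed=9)
        fit = sb.fit_binomial_glm(out,
                                  "dispersed ~ C(orphan_class, Treatment('non_orphan'))")
        est = fit.coefficients
        assert est.iloc[0] == pytest.approx(truth["intercept"], abs=0.15)
        infant = [k for k in est.index if "infant" in k][0]
        jsa = [k for k in est.index if "juv_subadult" in k][0]
        assert est[infant] == pytest.approx(truth["infant"], abs=0.15)
        assert est[jsa] == pytest.approx(truth["juv_subadult"], abs=0.15)
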