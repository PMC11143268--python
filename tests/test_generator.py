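"""Synthetic-data generator: determinism, calibration, planted effects."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from phenostate.generator import (CalibrationError, GeneratorParams,
                                  TrueVitalRates, generate_abundance_table,
                                  generate_environment, generate_relev_samples,
                                  generate_two_census_inventory, mat_from_pc1)
from phenostate.inventory import Fate, Phenology, compute_plot_summary


class TestEnvironment:
    def test_same_seed_identical(self):
        p = GeneratorParams(n_plots=50, seed=9)
        a = generate_environment(p)
        b = generate_environment(p)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.env_pcs, y.env_pcs)
            assert x.lon == y.lon and x.mat == y.mat

    def test_pc_means_near_zero(self):
        p = GeneratorParams(n_plots=10_000, seed=1)
        env = generate_environment(p)
        pcs = np.array([e.env_pcs for e in env])
        assert np.all(np.abs(pcs.mean(axis=0)) < 4 / np.sqrt(10_000))

    def test_mat_range(self):
        p = GeneratorParams(n_plots=5000, seed=2)
        mats = np.array([e.mat for e in generate_environment(p)])
        assert mats.min() >= -2.0 and mats.max() <= 23.0
        assert np.ptp(mats) > 20  # the gradient is actually used

    def test_empty(self):
        assert generate_environment(GeneratorParams(n_plots=0, seed=0)) == []

    def test_determinants_present(self):
        env = generate_environment(GeneratorParams(n_plots=3, seed=0))
        assert env[0].determinants["mat_c"] == pytest.approx(env[0].mat)
        assert set(env[0].determinants) >= {"soil_ph", "annual_precip_mm"}


class TestCalibration:
    """The closed-form truth realises the knobs exactly at the reference."""

    def setup_method(self):
        self.p = GeneratorParams()
        self.r = TrueVitalRates(self.p)
        self.ref = (self.p.dbh_ref, self.p.ba_ref, self.p.density_ref, np.zeros(10))

    def _surv(self, ph, relev):
        d, ba, dn, env = self.ref
        return float(self.r.survival_prob(ph, d, ba, dn, env, relev))

    def _growth(self, ph, relev):
        d, ba, dn, env = self.ref
        return float(self.r.growth_increment(ph, d, ba, dn, env, relev))

    def test_survival_advantages(self):
        adv_de = 100 * (self._surv(Phenology.DE, 0) / self._surv(Phenology.EV, 0) - 1)
        adv_ev = 100 * (self._surv(Phenology.EV, 1) / self._surv(Phenology.DE, 1) - 1)
        assert adv_de == pytest.approx(self.p.target_survival_advantage_de, abs=1e-9)
        assert adv_ev == pytest.approx(self.p.target_survival_advantage_ev, abs=1e-9)

    def test_growth_advantages(self):
        adv_ev = 100 * (self._growth(Phenology.EV, 1) / self._growth(Phenology.DE, 1) - 1)
        adv_de = 100 * (self._growth(Phenology.DE, 0) / self._growth(Phenology.EV, 0) - 1)
        assert adv_ev == pytest.approx(self.p.target_growth_advantage_ev, abs=1e-9)
        assert adv_de == pytest.approx(self.p.target_growth_advantage_de, abs=1e-9)

    def test_recruitment_ratio(self):
        d, ba, dn, env = self.ref
        num = self.r.recruitment_rate(Phenology.EV, ba, ba * 0.9, dn, env, 0.9)
        den = self.r.recruitment_rate(Phenology.DE, ba, ba * 0.1, dn, env, 0.9)
        assert float(num / den) == pytest.approx(self.p.target_recruitment_ratio)

    def test_infeasible_knob_names_itself(self):
        bad = dataclasses.replace(GeneratorParams(), target_survival_advantage_de=-150.0)
        with pytest.raises(CalibrationError, match="target_survival_advantage_de"):
            TrueVitalRates(bad)

    def test_null_variant_removes_frequency_dependence(self):
        rn = TrueVitalRates(self.p, variant="null")
        d, ba, dn, env = self.ref
        s0 = rn.survival_prob(Phenology.EV, d, ba, dn, env, 0.0)
        s1 = rn.survival_prob(Phenology.EV, d, ba, dn, env, 1.0)
        assert float(s0) == pytest.approx(float(s1))

    def test_mat_from_pc1_is_affine_inside_clip(self):
        x = np.array([-1.0, 0.0, 1.0])
        m = mat_from_pc1(x)
        assert np.diff(m)[0] == pytest.approx(np.diff(m)[1])


class TestInventory:
    def test_reproducible(self):
        p = GeneratorParams(n_plots=30, seed=5)
        env = generate_environment(p)
        a = generate_two_census_inventory(env, p)
        b = generate_two_census_inventory(env, p)
        assert sum(len(x.trees) for x in a) == sum(len(x.trees) for x in b)
        assert a[7].trees[3].dbh_prev == b[7].trees[3].dbh_prev

    def test_zero_feedback_makes_phenologies_exchangeable(self):
        p = GeneratorParams(
            n_plots=1500, seed=6, target_survival_advantage_de=0.0,
            target_survival_advantage_ev=0.0, target_growth_advantage_ev=0.0,
            target_growth_advantage_de=0.0, target_recruitment_ratio=1.0)
        plots = generate_two_census_inventory(generate_environment(p), p)
        surv = {Phenology.EV: [0, 0], Phenology.DE: [0, 0]}
        for pl in plots:
            for t in pl.trees:
                if t.fate is Fate.RECRUIT:
                    continue
                surv[t.phenology][0] += t.fate is Fate.SURVIVOR
                surv[t.phenology][1] += 1
        s_ev = surv[Phenology.EV][0] / surv[Phenology.EV][1]
        s_de = surv[Phenology.DE][0] / surv[Phenology.DE][1]
        assert abs(s_ev - s_de) < 0.01

    def test_planted_survival_advantage_in_extreme_stratum(self, recovery_inventory):
        """Direct empirical frequency oracle, before any model fitting."""
        params, plots = recovery_inventory
        surv = {Phenology.EV: [0, 0], Phenology.DE: [0, 0]}
        for pl in plots:
            init = [t for t in pl.trees if t.fate is not Fate.RECRUIT]
            s = compute_plot_summary(pl)
            if s.relev_area is None or s.relev_area > 0.10:
                continue
            for t in init:
                surv[t.phenology][0] += t.fate is Fate.SURVIVOR
                surv[t.phenology][1] += 1
        s_ev = surv[Phenology.EV][0] / surv[Phenology.EV][1]
        s_de = surv[Phenology.DE][0] / surv[Phenology.DE][1]
        adv = 100 * (s_de / s_ev - 1)
        # Monte-Carlo error on a few hundred evergreen trees is several points
        assert adv == pytest.approx(params.target_survival_advantage_de, abs=10.0)

    def test_planted_recruitment_ratio_in_strata(self, recovery_inventory):
        params, plots = recovery_inventory
        recs = {"hi": [0, 0, 0], "lo": [0, 0, 0]}   # ev, de, n_plots
        for pl in plots:
            s = compute_plot_summary(pl)
            if s.relev_area is None:
                continue
            key = "hi" if s.relev_area > 0.85 else ("lo" if s.relev_area < 0.15 else None)
            if key is None:
                continue
            recs[key][0] += sum(t.fate is Fate.RECRUIT and t.phenology is Phenology.EV
                                for t in pl.trees)
            recs[key][1] += sum(t.fate is Fate.RECRUIT and t.phenology is Phenology.DE
                                for t in pl.trees)
            recs[key][2] += 1
        ratio_hi = recs["hi"][0] / max(recs["hi"][1], 1)
        ratio_lo = recs["lo"][1] / max(recs["lo"][0], 1)
        # strata sit near, not at, the reference compositions 0.9 / 0.1, and
        # plot-level rate heterogeneity amplifies the count ratio (Jensen)
        assert ratio_hi == pytest.approx(params.target_recruitment_ratio, rel=0.6)
        assert ratio_lo == pytest.approx(params.target_recruitment_ratio, rel=0.6)
        assert ratio_hi > 2.0 and ratio_lo > 2.0

    def test_recruits_enter_at_the_minimum_diameter(self, recovery_inventory):
        _, plots = recovery_inventory
        recs = [t for pl in plots for t in pl.trees if t.fate is Fate.RECRUIT]
        assert recs and all(t.dbh_prev is None and t.dbh_curr == 12.7 for t in recs)


class TestAbundance:
    def test_zero_fraction_matches_constant_pi0(self):
        p = GeneratorParams(n_plots=6000, seed=8, abundance_zero_env=0.0)
        env = generate_environment(p)
        tab = generate_abundance_table(env, p)
        from scipy.special import expit
        pi0 = expit(p.abundance_zero_intercept)
        assert (tab.ev_count == 0).mean() == pytest.approx(pi0, abs=0.02)
        assert (tab.de_count == 0).mean() == pytest.approx(pi0, abs=0.02)

    def test_uncoupled_counts_have_no_partial_correlation(self):
        p = GeneratorParams(n_plots=4000, seed=9)
        env = generate_environment(p)
        tab = generate_abundance_table(env, p)
        pcs = np.array([e.env_pcs for e in env])
        # regress log1p counts on pc1 and correlate residuals
        X = np.column_stack([np.ones(len(pcs)), pcs[:, :2]])
        res_ev = np.log1p(tab.ev_count) - X @ np.linalg.lstsq(
            X, np.log1p(tab.ev_count), rcond=None)[0]
        res_de = np.log1p(tab.de_count) - X @ np.linalg.lstsq(
            X, np.log1p(tab.de_count), rcond=None)[0]
        rho = stats.spearmanr(res_ev, res_de).statistic
        assert abs(rho) < 0.05

    def test_negative_coupling_enriches_outer_bins(self):
        def outer_mass(coupling, seed):
            p = GeneratorParams(n_plots=4000, seed=seed,
                                abundance_coupling=coupling)
            env = generate_environment(p)
            tab = generate_abundance_table(env, p)
            tot = tab.ev_count + tab.de_count
            keep = tot >= 10
            relev = tab.ev_count[keep] / tot[keep]
            return ((relev < 0.05) | (relev > 0.95)).mean()

        # environmental filtering already puts sizeable mass in the outer
        # bins; the coupling must add clearly on top of it
        assert outer_mass(-0.9, 10) > outer_mass(0.0, 10) + 0.04


class TestRelevSamples:
    def test_reproducible(self):
        a = generate_relev_samples("bimodal", 100, seed=3)
        b = generate_relev_samples("bimodal", 100, seed=3)
        np.testing.assert_array_equal(a, b)

    def test_symmetric_preset_has_zero_skew(self):
        x = generate_relev_samples("bimodal", 50_000, seed=4)
        assert stats.skew(x) == pytest.approx(0.0, abs=0.05)

    def test_evergreen_heavy_preset_left_skewed(self):
        x = generate_relev_samples("unimodal_right", 20_000, seed=5)
        assert stats.skew(x) < -0.3

    def test_invalid_weights_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            generate_relev_samples([(0.4, 2.0, 2.0), (0.4, 5.0, 1.0)], 10, seed=0)


def test_label_swap_symmetry():
    """Swapping the EV/DE roles of every knob mirrors relEV about 0.5."""
    base = GeneratorParams(n_plots=1200, seed=77)
    swapped = dataclasses.replace(
        base, seed=78,
        target_survival_advantage_de=base.target_survival_advantage_ev,
        target_survival_advantage_ev=base.target_survival_advantage_de,
        target_growth_advantage_ev=base.target_growth_advantage_de,
        target_growth_advantage_de=base.target_growth_advantage_ev,
        frac_pure_de=base.frac_pure_ev, frac_pure_ev=base.frac_pure_de,
        surv_env=(0.0,), growth_env=(0.0,), recruit_env=(0.0,))
    sym = dataclasses.replace(base, seed=79, surv_env=(0.0,), growth_env=(0.0,),
                              recruit_env=(0.0,))

    def relev_dist(p):
        plots = generate_two_census_inventory(generate_environment(p), p)
        out = []
        for pl in plots:
            s = compute_plot_summary(pl)
            if s.relev_area is not None:
                out.append(s.relev_area)
        return np.array(out)

    a = relev_dist(sym)
    b = 1.0 - relev_dist(dataclasses.replace(swapped))
    ks = stats.ks_2samp(a, b)
    assert ks.pvalue > 0.01
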