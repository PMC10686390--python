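"""Nested mixed-model fitting, contrasts and model comparison."""

import subprocess
import sys
import textwrap

import numpy as np
import pandas as pd
import pytest

import mpsf
from mpsf.stats import DegenerateDesignError


def null_cohort_table(n_patients=8, n_eyes=12, n_visits=3, seed=31, **eff_kw):
    effects = mpsf.TrueEffects(
        beta_drusen=0.0, beta_hrf=0.0, beta_visit=0.0, beta_ecc=0.0,
        beta_drusen_visit=0.0, beta_drusen_ecc=0.0, **eff_kw)
    cfg = mpsf.CohortConfig(n_patients=n_patients, n_eyes=n_eyes,
                            n_visits=n_visits, effects=effects)
    return mpsf.extract_cohort_table(mpsf.simulate_cohort(cfg, seed))


class TestVolumeModel:
    def test_recovers_signs_on_medium_cohort(self, medium_table):
        fit = mpsf.fit_volume_model(medium_table)
        assert fit.converged
        assert fit.coef("drusen_vol_e3mm3") < 0
        assert fit.coef("visit") > 0
        assert fit.n_obs == len(medium_table)
        t = fit.terms
        assert ((t["ci_low"] <= t["estimate"])
                & (t["estimate"] <= t["ci_high"])).all()
        assert all(v >= 0 for v in fit.variance_components.values())

    def test_null_effects_statistically_zero(self):
        table = null_cohort_table(sd_patient=0.0, sd_eye=0.0, sd_spot=0.0,
                                  sd_resid=0.0)
        fit = mpsf.fit_volume_model(table)
        for term in ("drusen_vol_e3mm3", "hrf_vol_e3mm3", "visit", "ecc_deg"):
            row = fit.terms.loc[term]
            assert abs(row["estimate"]) < 3 * row["se"], term
        # with all generative variation off, the residual is staircase noise
        resid_var = fit.variance_components["residual"]
        sens_var = table["sensitivity_db"].var()
        assert resid_var == pytest.approx(sens_var, rel=0.5)

    def test_matches_ols_oracle_when_variance_components_are_zero(self):
        # generator and model spec both carry zero random SDs; the fit must
        # coincide with a hand-built normal-equations solution
        table = null_cohort_table(sd_patient=0.0, sd_eye=0.0, sd_spot=0.0,
                                  sd_resid=1.0)
        fit = mpsf.fit_volume_model(table, include_random=False)
        x = np.column_stack([
            np.ones(len(table)),
            table["drusen_vol_e3mm3"], table["hrf_vol_e3mm3"],
            table["visit"], table["ecc_deg"],
            table["drusen_vol_e3mm3"] * table["visit"],
            table["drusen_vol_e3mm3"] * table["ecc_deg"]])
        beta, *_ = np.linalg.lstsq(x, table["sensitivity_db"].to_numpy(),
                                   rcond=None)
        order = ["Intercept", "drusen_vol_e3mm3", "hrf_vol_e3mm3", "visit",
                 "ecc_deg", "drusen_vol_e3mm3:visit",
                 "drusen_vol_e3mm3:ecc_deg"]
        for term, expected in zip(order, beta):
            assert fit.coef(term) == pytest.approx(expected, rel=1e-6,
                                                   abs=1e-9), term
        # the full mixed fit remains close (boundary variance components)
        mixed = mpsf.fit_volume_model(table)
        assert mixed.coef("visit") == pytest.approx(fit.coef("visit"),
                                                    abs=0.02)

    def test_constant_covariate_rejected(self, medium_table):
        broken = medium_table.copy()
        broken["hrf_vol_e3mm3"] = 0.0
        with pytest.raises(DegenerateDesignError):
            mpsf.fit_volume_model(broken)

    def test_out_of_raster_rows_excluded(self, medium_table):
        flagged = medium_table.copy()
        drop = flagged.index[:45]
        flagged.loc[drop, "in_raster"] = False
        fit = mpsf.fit_volume_model(flagged)
        assert fit.n_obs == len(flagged) - len(drop)


class TestAgainstLme4:
    def test_fixed_effects_match_lme4(self, tiny_table, tmp_path):
        """Independent oracle: the same nested REML fit in R/lme4."""
        df = tiny_table.copy()
        df["spot_uid"] = df["eye_id"] * 10000 + df["spot_id"]
        csv = tmp_path / "table.csv"
        df.to_csv(csv, index=False)
        out = tmp_path / "coefs.csv"
        script = textwrap.dedent(f"""
            suppressMessages(library(lme4))
            d <- read.csv("{csv}")
            m <- lmer(sensitivity_db ~ drusen_vol_e3mm3 + hrf_vol_e3mm3
                      + visit + ecc_deg + drusen_vol_e3mm3:visit
                      + drusen_vol_e3mm3:ecc_deg
                      + (1|patient_id) + (1|eye_id) + (1|spot_uid),
                      data=d, REML=TRUE)
            write.csv(data.frame(term=names(fixef(m)), est=fixef(m)),
                      "{out}", row.names=FALSE)
        """)
        r = subprocess.run(["Rscript", "-e", script], capture_output=True,
                           text=True)
        assert r.returncode == 0, r.stderr
        ref = pd.read_csv(out).set_index("term")["est"]
        fit = mpsf.fit_volume_model(tiny_table)
        mapping = {"(Intercept)": "Intercept",
                   "drusen_vol_e3mm3:visit": "drusen_vol_e3mm3:visit",
                   "drusen_vol_e3mm3:ecc_deg": "drusen_vol_e3mm3:ecc_deg"}
        for rterm, est in ref.items():
            pterm = mapping.get(rterm, rterm)
            # agreement far inside statistical uncertainty; weakly
            # identified terms tolerate optimizer differences via their SE
            tol = max(5e-3, 0.02 * float(fit.terms.loc[pterm, "se"]))
            assert fit.coef(pterm) == pytest.approx(est, abs=tol), rterm


class TestPresenceModel:
    def test_signs_on_medium_cohort(self, medium_table):
        fit = mpsf.fit_presence_model(medium_table)
        assert fit.coef("drusen_present_i") < 0
        assert fit.coef("hrf_present_i") < 0

    def test_constant_presence_not_identifiable(self):
        cfg = mpsf.CohortConfig(
            n_patients=2, n_eyes=3, n_visits=2,
            drusen=mpsf.DrusenFieldParams(mean_bumps=0.0),
            hrf=mpsf.HRFFieldParams(blob_rate=0.0))
        table = mpsf.extract_cohort_table(mpsf.simulate_cohort(cfg, 8))
        with pytest.raises(DegenerateDesignError):
            mpsf.fit_presence_model(table)

    def test_null_drusen_effect_statistically_zero(self):
        table = null_cohort_table(seed=37)
        fit = mpsf.fit_presence_model(table)
        row = fit.terms.loc["drusen_present_i"]
        assert abs(row["estimate"]) < 3 * row["se"]


class TestSectorModel:
    def test_bonferroni_adjustment_and_foveal_deficit(self):
        # steep true eccentricity gradient makes the central subfield
        # clearly worst once drusen volume is adjusted for
        effects = mpsf.TrueEffects(beta_ecc=0.8)
        cfg = mpsf.CohortConfig(n_patients=12, n_eyes=18, n_visits=3,
                                effects=effects)
        table = mpsf.extract_cohort_table(mpsf.simulate_cohort(cfg, 19))
        with pytest.warns(UserWarning, match="sectors"):
            fit, contrasts = mpsf.fit_sector_model(table)
        m = len(contrasts)
        assert m == len({c.sector_a for c in contrasts}
                        | {c.sector_b for c in contrasts}) * (
            len({c.sector_a for c in contrasts}
                | {c.sector_b for c in contrasts}) - 1) // 2
        for c in contrasts:
            assert c.p_adjusted == pytest.approx(min(1.0, m * c.p_raw))
        sector1 = [c for c in contrasts if 1 in (c.sector_a, c.sector_b)]
        assert sector1
        for c in sector1:
            diff = c.estimate if c.sector_a == 1 else -c.estimate
            assert diff < 0  # sector 1 lower than every other sector

    def test_single_sector_rejected(self, medium_table):
        broken = medium_table.copy()
        broken["sector"] = 1
        with pytest.raises(DegenerateDesignError):
            mpsf.fit_sector_model(broken)


class TestLearningEffect:
    def test_visit_coefficient_stable_under_baseline_exclusion(self,
                                                               medium_table):
        fits = mpsf.learning_sensitivity(medium_table)
        assert [f.label for f in fits] == ["all visits", "excluding baseline",
                                           "excluding first two visits"]
        for f in fits:
            assert f.estimable
            # generative truth is linear in visit: 0.242 dB/visit
            assert abs(f.estimate - 0.242) < 0.15, f.label
            assert f.ci_low <= f.estimate <= f.ci_high

    def test_single_visit_table_flagged(self, medium_table):
        base_only = medium_table[medium_table["visit"] == 0]
        fits = mpsf.learning_sensitivity(base_only)
        assert all(not f.estimable for f in fits)


class TestModelComparison:
    def test_identical_models_delta_zero(self, tiny_table):
        a = mpsf.fit_volume_model(tiny_table, reml=False)
        b = mpsf.fit_volume_model(tiny_table, reml=False)
        out = mpsf.compare_models([a, b])
        assert (out["delta_aic"] == 0).all()

    def test_volume_model_beats_presence_model_when_truth_is_linear(
            self, medium_table):
        a = mpsf.fit_volume_model(medium_table, reml=False)
        b = mpsf.fit_presence_model(medium_table, reml=False)
        out = mpsf.compare_models([a, b])
        assert out.loc[0, "aic"] < out.loc[1, "aic"]

    def test_reml_fits_refused(self, tiny_table):
        a = mpsf.fit_volume_model(tiny_table, reml=True)
        with pytest.raises(ValueError):
            mpsf.compare_models([a, a])

    def test_differing_rows_refused(self, medium_table):
        a = mpsf.fit_volume_model(medium_table, reml=False)
        b = mpsf.fit_volume_model(medium_table[medium_table.visit > 0],
                                  reml=False)
        with pytest.raises(ValueError):
            mpsf.compare_models([a, b])
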