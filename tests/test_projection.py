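"""Future covariate trajectories and PARF/RR disease-risk projection."""

import numpy as np
import pandas as pd
import pytest

import perlife as pl
from perlife.projection import _annual_onset


def _record(**over):
    base = {
        "age": 40, "sex": "male", "bmi": 27.0, "pa_met_min": 300.0,
        "diet_score": 2.0, "packs_lifetime": 0.0, "years_since_quit": 0.0,
        "smoker_current": False, "diabetes": False, "irregular_pulse": False,
        "chd": False, "stroke": False, "cancer": False,
    }
    base.update(over)
    return base


class TestFitTrajectories:
    def test_recovers_known_quartic(self):
        rng = np.random.default_rng(2)
        ages = rng.integers(20, 85, 4000)
        coef = np.array([20.0, 0.5, -0.012, 1.2e-4, -4.0e-7])
        bmi = np.polynomial.polynomial.polyval(ages.astype(float), coef)
        df = pd.DataFrame({
            "sex": "male", "age": ages, "bmi": bmi + rng.normal(0, 0.05, len(ages)),
            "pa_met_min": 2000 * np.exp(-0.02 * ages) + 50,
            "weight": np.ones(len(ages)),
        })
        model = pl.fit_trajectories(df)
        grid = np.arange(20, 85, dtype=float)
        fitted = model.bmi_at("male", grid)
        truth = np.polynomial.polynomial.polyval(grid, coef)
        assert np.abs(fitted - truth).max() < 0.1

    def test_constant_bmi_yields_constant_polynomial(self):
        rng = np.random.default_rng(3)
        ages = rng.integers(20, 85, 2000)
        df = pd.DataFrame({
            "sex": "female", "age": ages, "bmi": np.full(len(ages), 26.0),
            "pa_met_min": np.full(len(ages), 100.0), "weight": np.ones(len(ages)),
        })
        model = pl.fit_trajectories(df)
        grid = np.arange(20, 85, dtype=float)
        assert np.allclose(model.bmi_at("female", grid), 26.0, atol=1e-6)

    def test_declining_activity_gives_negative_rate(self, trajectory_model):
        # the synthetic cohort generates less activity at older ages
        for sex in ("male", "female"):
            a, b, c = trajectory_model.pa_coef[sex]
            assert a * b < 0 or (a > 0 and b < 0)
            pa = trajectory_model.pa_at(sex, np.arange(25, 85, dtype=float))
            assert (np.diff(pa) <= 1e-9).all()

    def test_too_few_ages_rejected(self):
        df = pd.DataFrame({
            "sex": "male", "age": [30, 31, 32, 33], "bmi": 25.0,
            "pa_met_min": 100.0, "weight": 1.0,
        })
        with pytest.raises(ValueError, match="distinct ages"):
            pl.fit_trajectories(df)


class TestProjectCovariates:
    def test_anchored_at_current_age(self, trajectory_model, disease_params):
        rec = _record(bmi=31.0, pa_met_min=500.0, diabetes=True)
        traj = pl.project_covariates(rec, trajectory_model, disease_params,
                                     np.arange(40, 111))
        first = traj.loc[40]
        assert first["bmi"] == pytest.approx(31.0)
        assert first["pa_met_min"] == pytest.approx(500.0)
        assert first["x6"] == pytest.approx(2.0)
        assert first["x7"] == 1.0

    def test_on_population_curves_stays_on_them(self, trajectory_model):
        age0 = 40
        rec = _record(
            bmi=float(trajectory_model.bmi_at("male", age0)),
            pa_met_min=float(trajectory_model.pa_at("male", age0)),
        )
        traj = pl.project_covariates(rec, trajectory_model, None, np.arange(40, 90))
        ages = traj.index.to_numpy(dtype=float)
        assert np.allclose(traj["bmi"], trajectory_model.bmi_at("male", ages), atol=1e-9)
        assert np.allclose(traj["pa_met_min"], trajectory_model.pa_at("male", ages),
                           atol=1e-9)

    def test_quitter_exposure_gone_after_25_years(self, trajectory_model):
        rec = _record(packs_lifetime=1.0, years_since_quit=0.0, smoker_current=False)
        traj = pl.project_covariates(rec, trajectory_model, None, np.arange(40, 80))
        assert traj.loc[40, "x3"] == pytest.approx(1.0)
        assert traj.loc[65, "x3"] == 0.0
        assert (np.diff(traj["x3"]) <= 1e-12).all()

    def test_current_smoker_keeps_accruing(self, trajectory_model):
        rec = _record(packs_lifetime=2.0, smoker_current=True, packs_per_month=15)
        traj = pl.project_covariates(rec, trajectory_model, None, np.arange(40, 60))
        assert traj.loc[40, "x3"] == pytest.approx(2.0)
        # 15 packs/month = 0.18 thousand packs/year
        assert traj.loc[50, "x3"] == pytest.approx(2.0 + 0.18 * 10)

    def test_disease_probabilities_monotone(self, trajectory_model, disease_params):
        rec = _record(bmi=33.0, packs_lifetime=5.0, smoker_current=True)
        traj = pl.project_covariates(rec, trajectory_model, disease_params,
                                     np.arange(40, 111))
        for term in ("x7", "x8", "x9", "x10", "x11"):
            assert (np.diff(traj[term]) >= -1e-15).all()
            assert traj[term].between(0, 1).all()

    def test_deterministic(self, trajectory_model, disease_params):
        rec = _record()
        a = pl.project_covariates(rec, trajectory_model, disease_params, np.arange(40, 90))
        b = pl.project_covariates(rec, trajectory_model, disease_params, np.arange(40, 90))
        pd.testing.assert_frame_equal(a, b)

    def test_null_parf_and_rr_recover_population_curve(self, trajectory_model):
        # with PARF = 0 and all RR = 1 the projected expected indicator
        # equals the population prevalence, for a curve starting at 0
        ages = np.arange(40, 91)
        prev = np.clip(0.004 * (ages - 40), 0, 0.3)
        params = pl.DiseaseRiskParams(diseases={"diabetes": {
            "parf": 0.0,
            "prevalence": {"male": {
                "type": "knots", "ages": ages.tolist(), "values": prev.tolist(),
            }},
            "rr": [],
        }})
        traj = pl.project_covariates(_record(), trajectory_model, params, ages)
        assert np.abs(traj["x7"].to_numpy() - prev).max() < 1e-9


class TestRiskAlgebra:
    @pytest.mark.parametrize("p, parf, expected", [(0.1, 0.0, 0.1), (0.1, 0.4, 0.06)])
    def test_unexposed_risk(self, p, parf, expected):
        assert pl.unexposed_risk(p, parf) == pytest.approx(expected)

    def test_unexposed_risk_rejects_parf_one(self):
        with pytest.raises(ValueError):
            pl.unexposed_risk(0.1, 1.0)

    @pytest.mark.parametrize(
        "p, rrs, expected",
        [(0.05, [], 0.05), (0.02, [2, 3], 0.12), (0.5, [10], 1.0)],
    )
    def test_individual_risk(self, p, rrs, expected):
        assert pl.individual_risk(p, rrs) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "p, onset, expected",
        [(1.0, 0.7, 1.0), (0.0, 0.1, 0.1), (0.1, 0.1, 0.19)],
    )
    def test_update_disease_probability(self, p, onset, expected):
        # two steps of 0.1 from 0: 0.1 then 0.1 + 0.9*0.1 = 0.19
        assert pl.update_disease_probability(p, onset) == pytest.approx(expected)

    def test_parf_self_consistency(self):
        # population risk = mean over an exposure mix of RR-scaled
        # unexposed risk, with PARF chosen to match that mix exactly
        rng = np.random.default_rng(9)
        p_pop = 0.08
        rr = 2.5
        p_exposed_frac = 0.3
        parf = p_exposed_frac * (rr - 1) / (1 + p_exposed_frac * (rr - 1))
        p0 = pl.unexposed_risk(p_pop, parf)
        exposed = rng.random(200_000) < p_exposed_frac
        risks = np.where(exposed, pl.individual_risk(p0, [rr]), p0)
        assert risks.mean() == pytest.approx(p_pop, abs=3e-4)


class TestDiseaseRiskParams:
    def test_default_file_validates(self, disease_params):
        assert set(disease_params.diseases) == {
            "diabetes", "irregular_pulse", "chd", "stroke", "cancer"
        }
        p = disease_params.prevalence_at("diabetes", "male", np.array([30.0, 70.0]))
        assert p[1] > p[0]

    def test_rr_binning(self, disease_params):
        rr_low = disease_params.relative_risks(
            "diabetes", {"bmi": 22.0, "pa_met_min": 700.0,
                         "smoking_exposure": 0.0, "diet_score": 0.0})
        rr_high = disease_params.relative_risks(
            "diabetes", {"bmi": 36.0, "pa_met_min": 0.0,
                         "smoking_exposure": 0.0, "diet_score": 0.0})
        assert np.prod(rr_high) > np.prod(rr_low)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="PARF"):
            pl.DiseaseRiskParams(diseases={"stroke": {"parf": 1.2, "prevalence": {}}})
        with pytest.raises(ValueError, match="unknown disease"):
            pl.DiseaseRiskParams(diseases={"gout": {"parf": 0.1}})

    def test_annual_onset_from_prevalence(self, disease_params):
        onset = _annual_onset(disease_params, "diabetes", "male", 55.0)
        p0 = disease_params.prevalence_at("diabetes", "male", 55.0)
        p1 = disease_params.prevalence_at("diabetes", "male", 56.0)
        assert onset == pytest.approx((p1 - p0) / (1 - p0))
        assert onset >= 0
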