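"""Projection of an individual's covariates over future ages.

Continuous lifestyle factors follow population age-trajectory curves
(a quartic polynomial for BMI, an exponential for physical activity),
with the individual carried as a deviation from the curve.  Smoking
exposure decays after quitting (or keeps accruing for current smokers).
Chronic diseases are irreversible: the expected disease indicator at
each future age evolves by an absorbing update whose annual onset
probability combines the population prevalence curve with the
individual's lifestyle via the population attributable risk fraction
(PARF) and literature relative risks (RR).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import curve_fit
from scipy.special import expit

from . import risk_factors

__all__ = [
    "TrajectoryModel",
    "DiseaseRiskParams",
    "fit_trajectories",
    "project_covariates",
    "unexposed_risk",
    "individual_risk",
    "update_disease_probability",
]

DISEASES = ("diabetes", "irregular_pulse", "chd", "stroke", "cancer")
_DISEASE_TO_TERM = dict(zip(DISEASES, ("x7", "x8", "x9", "x10", "x11")))


# ---------------------------------------------------------------------------
# Trajectory curves

@dataclass
class TrajectoryModel:
    """Population age-trajectory curves for BMI and physical activity.

    ``bmi_coef[sex]`` are ascending coefficients of a degree-4
    polynomial for mean BMI versus age; ``pa_coef[sex] = (a, b, c)``
    parameterizes mean activity ``a * exp(b * age) + c`` (MET-min/week).
    """

    bmi_coef: dict[str, np.ndarray]
    pa_coef: dict[str, tuple[float, float, float]]

    def bmi_at(self, sex: str, age) -> np.ndarray:
        return np.polynomial.polynomial.polyval(np.asarray(age, float),
                                                self.bmi_coef[sex])

    def pa_at(self, sex: str, age) -> np.ndarray:
        a, b, c = self.pa_coef[sex]
        return np.maximum(a * np.exp(b * np.asarray(age, float)) + c, 0.0)


def fit_trajectories(cohort: pd.DataFrame) -> TrajectoryModel:
    """Fit the population BMI and activity age curves from a cohort.

    BMI: weighted least-squares quartic polynomial on individual
    records.  Activity: ``a exp(b age) + c`` fitted to the per-age
    weighted means (weighted by cell size), which is robust to the
    zero-inflated individual-level distribution.
    """
    if cohort["age"].nunique() < 5:
        raise ValueError("need at least 5 distinct ages to fit trajectories")
    bmi_coef: dict[str, np.ndarray] = {}
    pa_coef: dict[str, tuple[float, float, float]] = {}
    for sex, g in cohort.groupby("sex"):
        age = g["age"].to_numpy(dtype=float)
        w = g["weight"].to_numpy(dtype=float)
        bmi_coef[sex] = np.polynomial.polynomial.polyfit(
            age, g["bmi"].to_numpy(dtype=float), 4, w=np.sqrt(w)
        )
        means = g.groupby("age").apply(
            lambda s: pd.Series({
                "pa": np.average(s["pa_met_min"], weights=s["weight"]),
                "n": len(s),
            }),
            include_groups=False,
        )
        x = means.index.to_numpy(dtype=float)
        yv = means["pa"].to_numpy()

        def expo(t, a, b, c):
            return a * np.exp(b * t) + c

        p0 = (max(yv.max() - yv.min(), 1.0), -0.02, max(yv.min(), 0.0))
        try:
            popt, _ = curve_fit(
                expo, x, yv, p0=p0, sigma=1.0 / np.sqrt(means["n"].to_numpy()),
                maxfev=20000,
            )
        except RuntimeError as err:
            raise RuntimeError(f"activity trajectory fit failed for {sex}: {err}")
        pa_coef[sex] = tuple(float(v) for v in popt)
    return TrajectoryModel(bmi_coef=bmi_coef, pa_coef=pa_coef)


# ---------------------------------------------------------------------------
# Disease risk parameters

@dataclass
class DiseaseRiskParams:
    """Per-disease population prevalence curves, PARFs and RR tables.

    Loaded from YAML/JSON with the structure::

        diseases:
          diabetes:
            parf: 0.35
            prevalence:
              male:   {type: logistic, pmax: 0.25, age50: 62, scale: 12}
              female: {type: knots, ages: [20, 50, 80], values: [0.01, 0.08, 0.2]}
            rr:
              - {factor: bmi, breaks: [0, 25, 30, 35], rr: [1.0, 1.0, 1.8, 3.0]}
              - {factor: smoking_exposure, breaks: [0, 0.001, 5], rr: [1.0, 1.2, 1.5]}

    ``breaks`` are left bin edges (the last bin is open-ended); the RR
    factors refer to current projected values: ``bmi``, ``pa_met_min``,
    ``smoking_exposure`` (decayed, thousands of packs) or ``diet_score``.
    """

    diseases: dict[str, dict]

    def __post_init__(self) -> None:
        for name, d in self.diseases.items():
            if name not in DISEASES:
                raise ValueError(f"unknown disease {name!r}; expected one of {DISEASES}")
            parf = d.get("parf", 0.0)
            if not 0.0 <= parf < 1.0:
                raise ValueError(f"{name}: PARF must lie in [0, 1), got {parf}")
            for sex, curve in d.get("prevalence", {}).items():
                kind = curve.get("type", "logistic")
                if kind == "logistic":
                    if not 0.0 <= curve["pmax"] <= 1.0:
                        raise ValueError(f"{name}/{sex}: pmax outside [0, 1]")
                elif kind == "knots":
                    vals = np.asarray(curve["values"], float)
                    if np.any((vals < 0) | (vals > 1)):
                        raise ValueError(f"{name}/{sex}: knot values outside [0, 1]")
                    if len(curve["ages"]) != len(vals):
                        raise ValueError(f"{name}/{sex}: ages/values length mismatch")
                else:
                    raise ValueError(f"{name}/{sex}: unknown curve type {kind!r}")
            for entry in d.get("rr", []):
                rr = np.asarray(entry["rr"], float)
                if np.any(rr < 0):
                    raise ValueError(f"{name}: RRs must be >= 0")
                if len(entry["breaks"]) != len(rr):
                    raise ValueError(f"{name}: breaks/rr length mismatch")

    @classmethod
    def from_yaml(cls, path) -> "DiseaseRiskParams":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        return cls(diseases=payload["diseases"])

    @classmethod
    def default(cls) -> "DiseaseRiskParams":
        from importlib.resources import files

        return cls.from_yaml(files("perlife") / "data" / "disease_risk.yaml")

    def prevalence_at(self, disease: str, sex: str, age) -> np.ndarray:
        curve = self.diseases[disease]["prevalence"][sex]
        age = np.asarray(age, dtype=float)
        if curve.get("type", "logistic") == "logistic":
            out = curve["pmax"] * expit((age - curve["age50"]) / curve["scale"])
        else:
            out = np.interp(age, curve["ages"], curve["values"])
        return out

    def relative_risks(self, disease: str, exposures: Mapping[str, float]) -> list[float]:
        """RRs of one individual's current exposures for one disease."""
        rrs = []
        for entry in self.diseases[disease].get("rr", []):
            value = exposures[entry["factor"]]
            idx = int(np.searchsorted(entry["breaks"], value, side="right")) - 1
            rrs.append(float(entry["rr"][max(idx, 0)]))
        return rrs


def unexposed_risk(p_pop: float, parf: float) -> float:
    """Average risk of the unexposed: ``p_pop * (1 - PARF)``.

    The PARF is the expected proportional reduction in average
    population risk were the exposure eliminated, so dividing it out of
    the population risk recovers the unexposed stratum's risk.
    """
    if not 0.0 <= p_pop <= 1.0:
        raise ValueError("p_pop must lie in [0, 1]")
    if not 0.0 <= parf < 1.0:
        raise ValueError("PARF must lie in [0, 1)")
    return p_pop * (1.0 - parf)


def individual_risk(p_unexposed: float, rrs: Sequence[float]) -> float:
    """Individual risk: unexposed risk times the product of RRs, capped at 1.

    RRs of distinct exposures are treated as independent (multiplicative).
    """
    out = p_unexposed * float(np.prod(np.asarray(list(rrs), dtype=float))) if rrs else p_unexposed
    return min(1.0, out)


def update_disease_probability(p_now: float, onset: float) -> float:
    """Absorbing one-step update of the expected disease indicator.

    Diseases are irreversible, so ``p_next = p_now + (1 - p_now) * onset``.
    """
    if not (0.0 <= p_now <= 1.0 and 0.0 <= onset <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    return p_now + (1.0 - p_now) * onset


# ---------------------------------------------------------------------------
# Individual projection

def _annual_onset(params: DiseaseRiskParams, disease: str, sex: str, age: float) -> float:
    """Population annual onset hazard from the prevalence curve.

    Derived as max(0, d prevalence) / (1 - prevalence): the share of the
    not-yet-diseased who acquire the (irreversible) disease that year.
    """
    p0 = float(params.prevalence_at(disease, sex, age))
    p1 = float(params.prevalence_at(disease, sex, age + 1))
    if p0 >= 1.0:
        return 0.0
    return max(0.0, p1 - p0) / (1.0 - p0)


def project_covariates(
    record: Mapping,
    model: TrajectoryModel,
    disease_params: DiseaseRiskParams | None,
    ages: np.ndarray,
    bmi_mode: str = "additive",
    pa_mode: str = "multiplicative",
    smoker_accrual: bool = True,
    slope_high: float = risk_factors.DEFAULT_SLOPE_HIGH,
    slope_low: float = risk_factors.DEFAULT_SLOPE_LOW,
) -> pd.DataFrame:
    """Project one individual's engineered profile over future ages.

    ``record`` holds the current raw covariates (age, sex, bmi,
    pa_met_min, diet_score, packs_lifetime, years_since_quit,
    smoker_current, disease flags, optionally packs_per_month).  Returns
    a DataFrame indexed by age with columns x3..x11 plus raw bmi and
    pa_met_min, anchored so the projection at the current age equals the
    current values.

    BMI is carried as an additive deviation from the population curve
    (or multiplicative with ``bmi_mode='multiplicative'``); activity as a
    multiplicative deviation floored at 0 (or additive).  Quitters'
    smoking exposure decays to 0 over 25 years; current smokers keep
    accruing at their current rate when ``smoker_accrual`` is set.
    Disease indicators evolve as expected probabilities (absorbing
    onset updates driven by PARF/RR-adjusted population incidence);
    diagnosed diseases stay fixed at 1.
    """
    ages = np.asarray(ages, dtype=int)
    age0 = int(record["age"])
    sex = record["sex"]
    if ages[0] != age0:
        raise ValueError("projection must start at the record's current age")

    # BMI
    pop_bmi = np.asarray(model.bmi_at(sex, ages), dtype=float)
    pop_bmi0 = float(model.bmi_at(sex, age0))
    if bmi_mode == "additive":
        bmi = np.maximum(pop_bmi + (float(record["bmi"]) - pop_bmi0), 10.0)
    elif bmi_mode == "multiplicative":
        bmi = pop_bmi * (float(record["bmi"]) / pop_bmi0)
    else:
        raise ValueError("bmi_mode must be 'additive' or 'multiplicative'")

    # physical activity
    pop_pa = np.asarray(model.pa_at(sex, ages), dtype=float)
    pop_pa0 = float(model.pa_at(sex, age0))
    pa0 = float(record["pa_met_min"])
    if pa_mode == "multiplicative":
        ratio = pa0 / pop_pa0 if pop_pa0 > 0 else 0.0
        pa = np.maximum(pop_pa * ratio, 0.0)
    elif pa_mode == "additive":
        pa = np.maximum(pop_pa + (pa0 - pop_pa0), 0.0)
    else:
        raise ValueError("pa_mode must be 'additive' or 'multiplicative'")

    # smoking exposure
    packs = float(record["packs_lifetime"])
    dt = (ages - age0).astype(float)
    if record.get("smoker_current", False):
        rate = 0.0
        if smoker_accrual and packs > 0:
            rate = float(record.get(
                "packs_per_month", 1000.0 * packs / max(age0 - 18.0, 1.0) / 12.0
            )) * 12.0 / 1000.0  # thousands of packs per year
        x3 = risk_factors.smoking_exposure(packs + rate * dt, np.zeros_like(dt))
    else:
        ysq0 = float(record["years_since_quit"])
        x3 = risk_factors.smoking_exposure(
            np.full_like(dt, packs), ysq0 + dt
        )

    diet = float(record["diet_score"])
    out = pd.DataFrame(index=pd.Index(ages, name="age"))
    out["bmi"] = bmi
    out["pa_met_min"] = pa
    out["x3"] = np.asarray(x3, dtype=float)
    out["x4"] = risk_factors.bmi_transform(bmi, slope_high, slope_low)
    out["x5"] = risk_factors.pa_transform(pa)
    out["x6"] = diet

    # diseases: expected indicators, absorbing
    for disease, term in _DISEASE_TO_TERM.items():
        p = 1.0 if record.get(disease, False) else 0.0
        vals = np.empty(len(ages))
        for k, a in enumerate(ages):
            vals[k] = p
            if p < 1.0 and disease_params is not None and disease in disease_params.diseases:
                onset_pop = _annual_onset(disease_params, disease, sex, float(a))
                parf = disease_params.diseases[disease].get("parf", 0.0)
                exposures = {
                    "bmi": float(out["bmi"].iloc[k]),
                    "pa_met_min": float(out["pa_met_min"].iloc[k]),
                    "smoking_exposure": float(out["x3"].iloc[k]),
                    "diet_score": diet,
                }
                rrs = disease_params.relative_risks(disease, exposures)
                onset = individual_risk(unexposed_risk(onset_pop, parf), rrs)
                p = update_disease_probability(p, onset)
            elif p < 1.0 and disease_params is not None:
                pass  # disease absent from the parameter file: held constant
        out[term] = vals
    return out
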