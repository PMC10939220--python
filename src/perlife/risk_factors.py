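"""Deterministic predictor engineering for the two-year mortality model.

Raw survey covariates (BMI, leisure-time physical activity, smoking
history, diet score, disease flags) are turned into the engineered
predictors ``x1..x11`` plus the two product terms ``i12 = x1*x2`` and
``i13 = x1*x4``.  All transforms are pure functions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .reference import PREDICTORS

__all__ = [
    "smoking_exposure",
    "bmi_transform",
    "pa_transform",
    "winsorize",
    "impute",
    "build_features",
    "RAW_COVARIATES",
]

#: Raw covariate columns of the participant schema that feed the predictors.
RAW_COVARIATES = (
    "bmi", "pa_met_min", "diet_score", "packs_lifetime", "years_since_quit",
    "diabetes", "irregular_pulse", "chd", "stroke", "cancer",
)

_BINARY_COVARIATES = ("diabetes", "irregular_pulse", "chd", "stroke", "cancer")

# Default slopes of the piecewise-linear BMI penalty.  The penalty is 0 on
# the normal range, rises with slope_high per kg/m^2 above 25 and with
# slope_low per kg/m^2 below 18.5 (underweight carries the steeper risk).
DEFAULT_SLOPE_HIGH = 1.0
DEFAULT_SLOPE_LOW = 2.0

#: Years since quitting after which smoking exposure is fully discounted.
SMOKING_DECAY_YEARS = 25.0


def smoking_exposure(packs_lifetime, years_since_quit):
    """Decayed lifetime smoking exposure (x3).

    Cumulative packs smoked (in thousands) discounted linearly by time
    since cessation at a rate of 1/25 per year, so the exposure of a
    quitter vanishes exactly 25 years after quitting.  Current smokers
    pass ``years_since_quit = 0``.

    Parameters
    ----------
    packs_lifetime : array_like
        Lifetime cigarette consumption in thousands of packs, >= 0.
    years_since_quit : array_like
        Years since smoking cessation, >= 0 (0 for current smokers).

    Returns
    -------
    ndarray or scalar
        ``packs_lifetime * max(0, 1 - years_since_quit / 25)``.
    """
    packs = np.asarray(packs_lifetime, dtype=float)
    ysq = np.asarray(years_since_quit, dtype=float)
    if np.any(packs < 0) or np.any(ysq < 0):
        raise ValueError("packs_lifetime and years_since_quit must be >= 0")
    out = packs * np.clip(1.0 - ysq / SMOKING_DECAY_YEARS, 0.0, 1.0)
    return out.item() if out.ndim == 0 else out


def bmi_transform(bmi, slope_high=DEFAULT_SLOPE_HIGH, slope_low=DEFAULT_SLOPE_LOW):
    """Piecewise-linear BMI penalty f(BMI) (x4).

    Zero on the normal range [18.5, 25] kg/m^2, increasing above it with
    slope ``slope_high`` and below it with slope ``slope_low``, preserving
    the U-shaped BMI-mortality relationship as a continuous predictor.
    """
    if slope_high <= 0 or slope_low <= 0:
        raise ValueError("BMI penalty slopes must be positive")
    b = np.asarray(bmi, dtype=float)
    if np.any(b <= 0):
        raise ValueError("BMI must be positive")
    out = slope_high * np.clip(b - 25.0, 0.0, None) + slope_low * np.clip(18.5 - b, 0.0, None)
    return out.item() if out.ndim == 0 else out


def pa_transform(met_min):
    """Log physical activity f(PA) = ln(1 + MET-min/week) (x5).

    The unit offset keeps the 41% of adults reporting zero leisure-time
    moderate-to-vigorous activity at a finite value (0) while compressing
    the heavy right tail.
    """
    m = np.asarray(met_min, dtype=float)
    if np.any(m < 0):
        raise ValueError("physical activity must be >= 0")
    out = np.log1p(m)
    return out.item() if out.ndim == 0 else out


def winsorize(values, lower_pct: float = 1.0, upper_pct: float = 99.0):
    """Clip a vector to its empirical percentile bounds.

    Percentiles use numpy's default linear interpolation of order
    statistics; bounds are computed on the input itself (unweighted).
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot winsorize an empty vector")
    if not (0 <= lower_pct < upper_pct <= 100):
        raise ValueError("need 0 <= lower_pct < upper_pct <= 100")
    lo, hi = np.percentile(v, [lower_pct, upper_pct])
    return np.clip(v, lo, hi)


def _age_band(age: pd.Series) -> pd.Series:
    return (np.clip(age, 20, 89) // 10 * 10).astype(int)


def impute(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Single deterministic imputation of missing covariates.

    Continuous covariates are imputed by the median, binary ones by the
    mode, within sex x 10-year-age-band cells; a cell with no observed
    value falls back to the overall median/mode.  Outcome and design
    variables must be complete.

    Returns the completed table and a per-variable report with the number
    imputed and the number of band-level fallbacks.
    """
    for col in ("died_2y", "weight", "stratum", "psu", "age", "sex"):
        if col in table.columns and table[col].isna().any():
            raise ValueError(f"outcome/design variable {col!r} contains missing values")
    out = table.copy()
    band = _age_band(out["age"])
    rows = []
    for col in RAW_COVARIATES:
        if col not in out.columns:
            continue
        miss = out[col].isna()
        n_fallback = 0
        if miss.any():
            is_binary = col in _BINARY_COVARIATES
            obs = out.loc[~miss, col].astype(float)
            if is_binary:
                overall = float(obs.mode().iloc[0])
            else:
                overall = float(obs.median())
            grp = out.loc[~miss].groupby([out.loc[~miss, "sex"], band[~miss]])[col]
            fill = grp.agg(
                (lambda s: float(s.astype(float).mode().iloc[0])) if is_binary
                else (lambda s: float(s.astype(float).median()))
            )
            keys = list(zip(out.loc[miss, "sex"], band[miss]))
            vals = []
            for k in keys:
                if k in fill.index:
                    vals.append(fill.loc[k])
                else:
                    vals.append(overall)
                    n_fallback += 1
            out.loc[miss, col] = vals
            if is_binary:
                out[col] = out[col].astype(float).astype(bool)
        rows.append({"variable": col, "n_missing": int(miss.sum()), "n_fallback": n_fallback})
    report = pd.DataFrame(rows)
    return out, report


def build_features(
    table: pd.DataFrame,
    slope_high: float = DEFAULT_SLOPE_HIGH,
    slope_low: float = DEFAULT_SLOPE_LOW,
    winsorize_continuous: bool = False,
) -> pd.DataFrame:
    """Engineer the predictor matrix x1..x11, i12, i13 from raw records.

    Design variables (stratum, psu, weight) and the outcome ``died_2y``
    are carried through unchanged; product terms are recomputed from their
    components.  With ``winsorize_continuous`` the raw continuous inputs
    (BMI, PA, diet score, smoking exposure) are clipped at the 1st/99th
    percentile before transformation.
    """
    t = table
    if t[list(set(RAW_COVARIATES) & set(t.columns))].isna().any().any():
        raise ValueError("missing covariates present; run impute() first")

    bmi = t["bmi"].to_numpy(dtype=float)
    pa = t["pa_met_min"].to_numpy(dtype=float)
    diet = t["diet_score"].to_numpy(dtype=float)
    x3 = smoking_exposure(t["packs_lifetime"], t["years_since_quit"])
    if winsorize_continuous:
        bmi = winsorize(bmi)
        pa = winsorize(pa)
        diet = winsorize(diet)
        x3 = winsorize(x3)

    out = pd.DataFrame(index=t.index)
    for col in ("id", "stratum", "psu", "weight"):
        if col in t.columns:
            out[col] = t[col]
    out["x1"] = t["age"].to_numpy(dtype=float) - 20.0
    out["x2"] = (t["sex"] == "male").astype(float)
    out["x3"] = x3
    out["x4"] = bmi_transform(bmi, slope_high, slope_low)
    out["x5"] = pa_transform(pa)
    out["x6"] = diet
    for xj, col in zip(("x7", "x8", "x9", "x10", "x11"), _BINARY_COVARIATES):
        out[xj] = t[col].astype(float)
    out["i12"] = out["x1"] * out["x2"]
    out["i13"] = out["x1"] * out["x4"]
    if "died_2y" in t.columns:
        out["died_2y"] = t["died_2y"].astype(int)
    assert list(PREDICTORS) == [c for c in out.columns if c in PREDICTORS]
    return out
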