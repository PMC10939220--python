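"""Baseline population covariate profiles by age and sex.

The odds adjustment of the life table is relative to an age- and
sex-typical reference person: the survey-weighted mean of each
engineered predictor (prevalence, for indicators) by single year of
age, smoothed over age with cubic smoothing splines.  Including the
disease prevalences in the baseline is what makes the baseline
life-expectancy identity hold with disease terms in the model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline

from . import risk_factors

__all__ = ["BaselineProfile", "weighted_age_profiles", "smooth_profiles"]

#: Engineered predictors carried in the baseline, plus raw BMI/PA means.
PROFILE_COLUMNS = (
    "x3", "x4", "x5", "x6", "x7", "x8", "x9", "x10", "x11", "bmi", "pa_met_min",
)
_INDICATORS = ("x7", "x8", "x9", "x10", "x11")


@dataclass
class BaselineProfile:
    """Smoothed age -> baseline predictor values, per sex.

    ``data`` has columns sex, age and one column per entry of
    ``PROFILE_COLUMNS``, defined on every integer age of the target
    life-table support.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = self.data.sort_values(["sex", "age"]).reset_index(drop=True)
        self._by_sex = {
            s: g.set_index("age") for s, g in self.data.groupby("sex")
        }

    def profile_at(self, sex: str, age: int) -> pd.Series:
        g = self._by_sex[sex]
        a = int(np.clip(age, g.index.min(), g.index.max()))
        return g.loc[a]

    def to_csv(self, path, provenance: str = "") -> None:
        with open(path, "w") as fh:
            fh.write("# baseline covariate profile (survey-weighted, spline-smoothed)\n")
            if provenance:
                fh.write(f"# {provenance}\n")
            self.data.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "BaselineProfile":
        return cls(pd.read_csv(path, comment="#"))


def weighted_age_profiles(
    table: pd.DataFrame,
    features: pd.DataFrame | None = None,
    min_cell: int = 30,
    band_width: int = 5,
) -> pd.DataFrame:
    """Survey-weighted means/prevalences of the predictors by sex and age.

    Default resolution is single year of age; any cell with fewer than
    ``min_cell`` records falls back to the value of its ``band_width``-
    year band.  Returns a long table with sex, age, n and one column per
    profile entry.
    """
    if features is None:
        features = risk_factors.build_features(table)
    df = features[["weight"] + [c for c in PROFILE_COLUMNS if c in features]].copy()
    df["bmi"] = table["bmi"].to_numpy(dtype=float)
    df["pa_met_min"] = table["pa_met_min"].to_numpy(dtype=float)
    df["sex"] = table["sex"].to_numpy()
    df["age"] = table["age"].to_numpy(dtype=int)
    if (df["weight"] <= 0).any():
        raise ValueError("weights must be positive")

    def wmean(g: pd.DataFrame) -> pd.Series:
        w = g["weight"].to_numpy()
        out = {c: float(np.average(g[c].to_numpy(dtype=float), weights=w))
               for c in PROFILE_COLUMNS}
        out["n"] = len(g)
        return pd.Series(out)

    per_year = df.groupby(["sex", "age"]).apply(wmean, include_groups=False)
    band = (df["age"] // band_width) * band_width
    per_band = df.groupby(["sex", band]).apply(wmean, include_groups=False)

    rows = []
    for (sex, age), row in per_year.iterrows():
        if row["n"] < min_cell:
            key = (sex, (age // band_width) * band_width)
            brow = per_band.loc[key]
            if brow["n"] == 0:
                raise ValueError(f"empty cell for sex={sex}, age={age}")
            vals = brow
        else:
            vals = row
        rows.append({"sex": sex, "age": int(age), "n": int(row["n"]),
                     **{c: vals[c] for c in PROFILE_COLUMNS}})
    return pd.DataFrame(rows).sort_values(["sex", "age"]).reset_index(drop=True)


def smooth_profiles(
    raw: pd.DataFrame,
    ages: np.ndarray | None = None,
    lam: float | None = None,
) -> BaselineProfile:
    """Smooth raw age profiles with cubic smoothing splines.

    ``lam`` is the spline penalty; None selects it by generalized
    cross-validation.  ``ages`` are the integer target ages (default:
    the observed range); outside the observed age range the endpoint
    value is carried flat rather than extrapolating the spline.
    Smoothed prevalences are clamped to [0, 1].  Curves with fewer than
    4 age points pass through unsmoothed (with a warning).
    """
    out_frames = []
    for sex, g in raw.groupby("sex"):
        g = g.sort_values("age")
        x = g["age"].to_numpy(dtype=float)
        target = np.asarray(ages if ages is not None else
                            np.arange(int(x.min()), int(x.max()) + 1))
        block = {"sex": sex, "age": target}
        for col in PROFILE_COLUMNS:
            yv = g[col].to_numpy(dtype=float)
            if len(x) < 4:
                warnings.warn(f"too few age points for {col} ({sex}); not smoothed")
                sm_vals = np.interp(target, x, yv)
            else:
                w = g["n"].to_numpy(dtype=float) if "n" in g else None
                spl = make_smoothing_spline(x, yv, w=w, lam=lam)
                clipped = np.clip(target, x.min(), x.max())
                sm_vals = spl(clipped)  # flat extension beyond data support
            if col in _INDICATORS:
                sm_vals = np.clip(sm_vals, 0.0, 1.0)
            block[col] = sm_vals
        out_frames.append(pd.DataFrame(block))
    return BaselineProfile(pd.concat(out_frames, ignore_index=True))
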