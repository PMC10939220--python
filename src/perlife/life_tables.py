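"""Personalized period life tables.

The core method: one-year death probabilities ``q_x`` from a population
period life table are combined into two-year probabilities, converted to
odds, multiplied by the individual-versus-baseline odds ratio implied by
the mortality model, converted back to annual probabilities, and the
resulting personalized table yields life expectancy by the standard
life-table method.  By construction an individual whose covariate
trajectory equals the baseline population profile at every age gets back
the population table, and hence the population life expectancy.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .reference import REFERENCE_A_MAX

__all__ = [
    "PeriodLifeTable",
    "PersonalizedTable",
    "two_year_prob",
    "adjust_odds",
    "linear_predictor",
    "personalize",
    "life_expectancy",
    "le_percentile_profiles",
]

#: Profile columns entering the baseline-relative odds adjustment.
PROFILE_TERMS = ("x3", "x4", "x5", "x6", "x7", "x8", "x9", "x10", "x11")


# ---------------------------------------------------------------------------
# Life-table containers

@dataclass
class PeriodLifeTable:
    """Sex-specific period life table: age -> one-year death probability.

    ``data`` holds columns ``sex`` ('male'/'female'), ``age`` (integer
    years) and ``qx``; for each sex the ages are contiguous and the last
    (terminal) age omega carries ``q = 1``.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.data
        missing = {"sex", "age", "qx"} - set(d.columns)
        if missing:
            raise ValueError(f"life table missing columns: {sorted(missing)}")
        d = d.astype({"age": int, "qx": float}).sort_values(["sex", "age"])
        for sex, g in d.groupby("sex"):
            ages = g["age"].to_numpy()
            q = g["qx"].to_numpy()
            if np.any((q <= 0) | (q > 1)):
                raise ValueError(f"q_x out of (0, 1] for sex={sex}")
            if np.any(np.diff(ages) != 1):
                raise ValueError(f"ages not contiguous for sex={sex}")
            if q[-1] != 1.0:
                raise ValueError(f"terminal q must be 1 for sex={sex}")
        self.data = d.reset_index(drop=True)

    def qx(self, sex: str) -> pd.Series:
        g = self.data[self.data["sex"] == sex]
        if g.empty:
            raise KeyError(f"no life table for sex={sex!r}")
        return g.set_index("age")["qx"]

    def omega(self, sex: str) -> int:
        return int(self.qx(sex).index.max())

    def ages(self, sex: str) -> np.ndarray:
        return self.qx(sex).index.to_numpy()

    def life_expectancy(self, sex: str, from_age: int) -> float:
        return life_expectancy(self.qx(sex), from_age)

    # -- I/O -----------------------------------------------------------------
    #: accepted spellings for each canonical column (HMD extracts use
    #: capitalized 'Age'/'qx' and may carry extra columns such as mx, lx, ex)
    _ALIASES = {"age": {"age"}, "qx": {"qx", "q(x)"}, "sex": {"sex", "gender"}}

    @classmethod
    def from_csv(cls, path, sex: str | None = None) -> "PeriodLifeTable":
        """Read a life table CSV, tolerating HMD-style column names.

        ``sex`` supplies the sex label for single-sex files without a sex
        column.  Open-ended HMD terminal ages like '110+' are parsed as
        their integer part.
        """
        df = pd.read_csv(path, comment="#")
        rename = {}
        for col in df.columns:
            key = col.strip().lower()
            for canon, names in cls._ALIASES.items():
                if key in names:
                    rename[col] = canon
        df = df.rename(columns=rename)
        if "sex" not in df.columns:
            if sex is None:
                raise ValueError("no sex column; pass sex= for single-sex files")
            df["sex"] = sex
        df["sex"] = df["sex"].astype(str).str.lower()
        df["age"] = (
            df["age"].astype(str).str.replace("+", "", regex=False).astype(int)
        )
        return cls(df[["sex", "age", "qx"]])

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class PersonalizedTable:
    """A personalized annual life table for one individual.

    Shares the shape of a single-sex :class:`PeriodLifeTable` slice and
    carries the projected covariate trajectory it was built from.
    """

    sex: str
    qx: pd.Series  # index: age, values: adjusted one-year death probability
    trajectory: pd.DataFrame | None = field(default=None, repr=False)

    def life_expectancy(self, from_age: int | None = None) -> float:
        if from_age is None:
            from_age = int(self.qx.index.min())
        return life_expectancy(self.qx, from_age)


# ---------------------------------------------------------------------------
# Probability/odds algebra

def two_year_prob(q_x: float, q_x1: float):
    """Two-year death probability from two annual ones.

    ``1 - (1 - q_x)(1 - q_x1)``: dying within two years means failing to
    survive both years.
    """
    qa = np.asarray(q_x, dtype=float)
    qb = np.asarray(q_x1, dtype=float)
    if np.any((qa < 0) | (qa > 1) | (qb < 0) | (qb > 1)):
        raise ValueError("annual death probabilities must lie in [0, 1]")
    out = 1.0 - (1.0 - qa) * (1.0 - qb)
    return out.item() if out.ndim == 0 else out


def adjust_odds(q2_pop: float, eta_ind: float, eta_base: float) -> float:
    """Adjust a population two-year death probability by an odds ratio.

    The probability is converted to odds, multiplied by
    ``exp(eta_ind - eta_base)`` (the individual-versus-baseline odds
    ratio from the logistic model), and converted back.  Degenerate
    probabilities 0 and 1 have no odds and pass through with a warning.
    """
    if not 0.0 <= q2_pop <= 1.0:
        raise ValueError("q2_pop must lie in [0, 1]")
    if q2_pop in (0.0, 1.0):
        warnings.warn("q2 in {0, 1}: odds undefined, returned unchanged")
        return q2_pop
    odds = q2_pop / (1.0 - q2_pop) * math.exp(eta_ind - eta_base)
    return odds / (1.0 + odds)


def _beta_of(model) -> Mapping[str, float]:
    beta = getattr(model, "beta", model)
    if isinstance(beta, pd.Series):
        beta = beta.to_dict()
    return beta


def combined_bmi_coefficient(model, age: float, a_max: int = REFERENCE_A_MAX) -> float:
    """Age-specific coefficient of f(BMI): beta_x4 + beta_i13 * (age - 20).

    Within ages 20..a_max the fit already guarantees the sum is
    nonnegative; beyond a_max it is floored at 0 so that abnormal BMI
    never becomes protective at old age (the "obesity paradox" guard).
    """
    beta = _beta_of(model)
    c = beta["x4"] + beta.get("i13", 0.0) * (age - 20.0)
    return max(0.0, c) if age > a_max else c


def linear_predictor(
    model,
    sex: str,
    age: float,
    profile: Mapping[str, float],
    a_max: int = REFERENCE_A_MAX,
) -> float:
    """Log-odds of two-year death for a covariate profile at a given age.

    ``profile`` maps the engineered terms x3..x11 to values; the age and
    sex terms (x1, x2, i12) and the age-dependent BMI coefficient (i13)
    are evaluated at the supplied age.
    """
    beta = _beta_of(model)
    u = age - 20.0
    male = 1.0 if sex == "male" else 0.0
    eta = (
        beta["const"]
        + beta["x1"] * u
        + beta["x2"] * male
        + beta.get("i12", 0.0) * u * male
        + combined_bmi_coefficient(model, age, a_max) * profile["x4"]
    )
    for term in ("x3", "x5", "x6", "x7", "x8", "x9", "x10", "x11"):
        eta += beta[term] * profile[term]
    return eta


def _split_two_year(qa: float, qb: float, q2_target: float) -> tuple[float, float]:
    """Split an adjusted two-year probability back into two annual ones.

    Both annual odds are scaled by a common factor t chosen so the
    two-year survival product matches ``1 - q2_target``:

        (1 + o_a t)(1 + o_b t) = 1 / (1 - q2_target)

    a quadratic in t with a unique positive root.  When the adjustment is
    the identity, t = 1 and the original annual probabilities come back
    exactly, which is what makes the baseline-identity property hold
    age by age.
    """
    if q2_target >= 1.0:
        return 1.0, 1.0
    oa = qa / (1.0 - qa)
    ob = qb / (1.0 - qb)
    r = 1.0 / (1.0 - q2_target)
    if oa == 0.0 and ob == 0.0:
        return qa, qb
    if oa == 0.0 or ob == 0.0:
        o = oa + ob
        t = (r - 1.0) / o
    else:
        # positive root of  p t^2 + s t + (1 - r) = 0  in the cancellation-
        # safe form (r ~ 1 makes the textbook form lose precision)
        s, p = oa + ob, oa * ob
        t = 2.0 * (r - 1.0) / (s + math.sqrt(s * s + 4.0 * p * (r - 1.0)))
    qa2 = oa * t / (1.0 + oa * t)
    qb2 = ob * t / (1.0 + ob * t)
    return qa2, qb2


# ---------------------------------------------------------------------------
# Personalization and life expectancy

def personalize(
    table: PeriodLifeTable,
    model,
    baseline,
    trajectory: pd.DataFrame,
    sex: str,
    current_age: int | None = None,
    a_max: int = REFERENCE_A_MAX,
) -> PersonalizedTable:
    """Build the personalized life table for one individual.

    Parameters
    ----------
    table : PeriodLifeTable
        Population one-year death probabilities.
    model
        Fitted (or reference) mortality model with a ``beta`` mapping.
    baseline
        :class:`~perlife.baseline.BaselineProfile`: age- and sex-specific
        baseline values of the engineered predictors.
    trajectory : DataFrame
        The individual's projected engineered profile, indexed by integer
        age, with columns x3..x11; must cover every age from the current
        age to the terminal age of the table.
    sex, current_age
        Individual's sex and starting age (defaults to the trajectory's
        first age).

    Stepping is in two-year blocks from the current age; within a block
    the population two-year probability is odds-adjusted and split back
    to annual probabilities by a common odds factor.  A dangling single
    year before the terminal age is adjusted at one-year resolution, and
    the terminal age keeps q = 1.
    """
    q = table.qx(sex)
    omega = int(q.index.max())
    if current_age is None:
        current_age = int(trajectory.index.min())
    if current_age < q.index.min() or current_age > omega:
        raise ValueError(f"current_age {current_age} outside table support")
    needed = np.arange(current_age, omega + 1)
    missing = np.setdiff1d(needed[:-1], trajectory.index.to_numpy())
    if missing.size:
        raise ValueError(f"trajectory missing ages: {missing.tolist()}")

    def delta_eta(age: int) -> float:
        prof_i = trajectory.loc[age]
        prof_b = baseline.profile_at(sex, age)
        eta_i = linear_predictor(model, sex, age, prof_i, a_max)
        eta_b = linear_predictor(model, sex, age, prof_b, a_max)
        return eta_i - eta_b

    out: dict[int, float] = {}
    a = current_age
    while a <= omega:
        if a == omega:
            out[a] = 1.0
            break
        if a + 1 == omega:
            # dangling year: one-year odds adjustment, then terminal closure
            out[a] = adjust_odds(float(q.loc[a]), delta_eta(a), 0.0)
            out[omega] = 1.0
            break
        qa, qb = float(q.loc[a]), float(q.loc[a + 1])
        q2 = two_year_prob(qa, qb)
        q2_adj = adjust_odds(q2, delta_eta(a), 0.0)
        out[a], out[a + 1] = _split_two_year(qa, qb, q2_adj)
        a += 2
    qx = pd.Series(out, name="qx").sort_index()
    qx.index.name = "age"
    return PersonalizedTable(sex=sex, qx=qx, trajectory=trajectory)


def life_expectancy(qx: pd.Series, from_age: int) -> float:
    """Remaining life expectancy from a given age under a q_x schedule.

    Standard period life-table computation with the fraction of the year
    lived by those dying set to a_x = 0.5 in every interval:

        LE = sum_x l_x * (1 - q_x / 2),   l_{x+1} = l_x (1 - q_x)

    starting from l = 1 at ``from_age`` up to the terminal age (q = 1).
    """
    if from_age not in qx.index:
        raise ValueError(f"from_age {from_age} outside table support")
    qs = qx.loc[from_age:].to_numpy(dtype=float)
    surv = np.concatenate([[1.0], np.cumprod(1.0 - qs[:-1])])
    return float(np.sum(surv * (1.0 - qs / 2.0)))


# ---------------------------------------------------------------------------
# Ranked lifestyle profiles

def _weighted_quantile(values: np.ndarray, weights: np.ndarray, pct: float) -> float:
    order = np.argsort(values)
    v, w = values[order], weights[order]
    cdf = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(pct / 100.0, cdf, v))


def le_percentile_profiles(
    cohort: pd.DataFrame,
    model,
    baseline,
    table: PeriodLifeTable,
    trajectory_model,
    disease_params,
    percentiles: Sequence[float],
    age: int,
    sex: str,
    age_window: int = 5,
    a_max: int = REFERENCE_A_MAX,
) -> pd.DataFrame:
    """Life expectancy for lifestyle profiles ranked within an age-sex group.

    For each requested percentile p, a profile is built with every
    lifestyle factor at rank p of its weighted distribution among cohort
    members of the same sex within ``age_window`` years (favorable
    direction = higher rank): diet score and physical activity at the
    p-th percentile, smoking exposure and BMI penalty at the (100-p)-th.
    Disease history is set to none.  Each profile is projected over
    future ages and its personalized life expectancy computed.
    """
    from .projection import project_covariates
    from .risk_factors import bmi_transform, smoking_exposure

    for p in percentiles:
        if not 0.0 < p < 100.0:
            raise ValueError("percentiles must lie strictly between 0 and 100")
    grp = cohort[
        (cohort["sex"] == sex) & (cohort["age"] - age).abs().le(age_window)
    ]
    if grp.empty:
        raise ValueError("no cohort members in the requested age-sex group")
    w = grp["weight"].to_numpy(dtype=float)
    bmi_v = grp["bmi"].to_numpy(dtype=float)
    pa_v = grp["pa_met_min"].to_numpy(dtype=float)
    diet_v = grp["diet_score"].to_numpy(dtype=float)
    smoke_v = np.asarray(
        smoking_exposure(grp["packs_lifetime"], grp["years_since_quit"])
    )

    rows = []
    for p in percentiles:
        diet = _weighted_quantile(diet_v, w, p)
        pa = _weighted_quantile(pa_v, w, p)
        exposure = _weighted_quantile(smoke_v, w, 100.0 - p)
        # rank BMI by its mortality penalty f(BMI); map the selected
        # penalty back to a BMI on the overweight branch (the dominant
        # side of the distribution), or normal BMI when the penalty is 0
        pen = _weighted_quantile(np.asarray(bmi_transform(bmi_v)), w, 100.0 - p)
        bmi = 25.0 + pen if pen > 0 else 22.0
        record = {
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "pa_met_min": pa,
            "diet_score": diet,
            "packs_lifetime": exposure,
            "years_since_quit": 0.0,
            "smoker_current": exposure > 0,
            "diabetes": False,
            "irregular_pulse": False,
            "chd": False,
            "stroke": False,
            "cancer": False,
        }
        traj = project_covariates(
            record, trajectory_model, disease_params,
            ages=np.arange(age, table.omega(sex) + 1),
        )
        pt = personalize(table, model, baseline, traj, sex, age, a_max)
        rows.append({
            "percentile": p, "diet_score": diet, "pa_met_min": pa,
            "smoking_exposure": exposure, "bmi": bmi,
            "life_expectancy": pt.life_expectancy(age),
        })
    return pd.DataFrame(rows)
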