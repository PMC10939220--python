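"""Synthetic survey cohort and life-table generator.

Emulates the statistical structure of a pooled national health
examination survey (stratified multistage design with unequal weights,
right-skewed smoking/activity/BMI distributions, age-increasing chronic
disease prevalence, roughly 2% two-year mortality among adults aged
20-84) and of a national period life table, with a known ground-truth
mortality mechanism so every downstream stage can be tested without the
real restricted-use data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit

from . import risk_factors
from .life_tables import PeriodLifeTable
from .reference import REFERENCE_BETA

__all__ = [
    "DesignSpec",
    "TruthParams",
    "DEFAULT_MAKEHAM",
    "simulate_cohort",
    "simulate_life_table",
    "inject_missingness",
]


@dataclass
class DesignSpec:
    """Stratified multistage sampling design of the synthetic survey."""

    n_strata: int = 15
    psus_per_stratum: int = 2
    participants_per_psu: int = 100
    weight_dispersion: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_strata, self.psus_per_stratum, self.participants_per_psu) < 1:
            raise ValueError("all design counts must be >= 1")
        if self.weight_dispersion <= 0:
            raise ValueError("weight_dispersion must be positive")

    @property
    def n(self) -> int:
        return self.n_strata * self.psus_per_stratum * self.participants_per_psu


@dataclass
class TruthParams:
    """Ground-truth mortality mechanism and covariate distributions.

    ``beta`` is the 14-term logistic coefficient vector (intercept,
    x1..x11, i12, i13) that generates the two-year death indicator from
    the engineered predictors; it defaults to the published reference
    model.  Covariate distribution parameters emulate the survey:
    ages uniform on 20..84 (open-ended top ages excluded, topcoded 84);
    BMI lognormal with a mild mid-life hump; leisure-time activity
    zero-inflated lognormal (about 41% report none, more at older ages);
    smoking zero-inflated lognormal with roughly half of ever-smokers
    having quit; diet score normal; disease prevalences logistic in age.
    An optional Gaussian-copula correlation between the continuous
    lifestyle factors is available but defaults to independence.
    """

    beta: dict[str, float] = field(default_factory=lambda: dict(REFERENCE_BETA))
    age_range: tuple[int, int] = (20, 84)
    p_male: float = 0.484
    bmi_meanlog: float = 3.322      # median ~27.7 kg/m^2
    bmi_sdlog: float = 0.21
    bmi_age_lin: float = 0.0020     # per year from age 45, lognormal scale
    bmi_age_quad: float = -5.0e-5
    pa_zero_base: float = 0.41      # P(no leisure MVPA) at age 45
    pa_zero_age_slope: float = 0.035  # logit slope per year of age
    pa_meanlog: float = 7.09        # nonzero MET-min/week, median ~1200
    pa_sdlog: float = 1.5
    pa_age_slope: float = -0.010    # lognormal-scale decline per year
    diet_mean: float = 2.1
    diet_sd: float = 5.0
    p_ever_smoker: float = 0.45
    p_current_of_ever: float = 0.5
    packs_meanlog: float = 1.10     # thousands of packs, median ~3
    packs_sdlog: float = 1.10
    packs_age_slope: float = 0.02   # accumulation with age, lognormal scale
    quit_years_mean: float = 12.0   # exponential, truncated at age - 18
    # logistic-in-age prevalence: pmax * expit((age - age50) / scale)
    disease_prevalence: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "diabetes": (0.25, 62.0, 12.0),
            "irregular_pulse": (0.10, 70.0, 12.0),
            "chd": (0.20, 72.0, 10.0),
            "stroke": (0.12, 72.0, 10.0),
            "cancer": (0.12, 75.0, 9.0),
        }
    )
    lifestyle_copula_rho: float = 0.0  # latent correlation diet/PA/BMI/smoking

    def __post_init__(self) -> None:
        for name, (pmax, _, scale) in self.disease_prevalence.items():
            if not 0.0 <= pmax <= 1.0 or scale <= 0:
                raise ValueError(f"invalid prevalence parameters for {name}")
        for p in (self.p_male, self.pa_zero_base, self.p_ever_smoker,
                  self.p_current_of_ever):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if not -1.0 < self.lifestyle_copula_rho < 1.0:
            raise ValueError("copula correlation must lie in (-1, 1)")
        if set(self.beta) != set(REFERENCE_BETA):
            raise ValueError("beta must supply exactly the 14 model terms")


def _copula_uniforms(rng: np.random.Generator, n: int, k: int, rho: float) -> np.ndarray:
    """k columns of Uniform(0,1) with a shared Gaussian latent factor."""
    from scipy.stats import norm

    z = rng.standard_normal((n, k))
    if rho != 0.0:
        common = rng.standard_normal((n, 1))
        z = np.sqrt(abs(rho)) * np.sign(rho) * common + np.sqrt(1 - abs(rho)) * z
    return norm.cdf(z)


def simulate_cohort(design: DesignSpec, truth: TruthParams | None = None) -> pd.DataFrame:
    """Draw a synthetic survey cohort with a known mortality mechanism.

    Deterministic for a fixed ``design.seed``.  The two-year death
    indicator is Bernoulli with probability given by the ground-truth
    logistic model applied to the engineered predictors of each record.
    Weights are lognormal around a per-stratum base (unequal-probability
    design) and normalized to sum to the sample size.
    """
    truth = truth or TruthParams()
    rng = np.random.default_rng(design.seed)
    n = design.n
    lo, hi = truth.age_range

    stratum = np.repeat(np.arange(1, design.n_strata + 1),
                        design.psus_per_stratum * design.participants_per_psu)
    psu = np.tile(
        np.repeat(np.arange(1, design.psus_per_stratum + 1), design.participants_per_psu),
        design.n_strata,
    )
    base = rng.lognormal(0.0, design.weight_dispersion, design.n_strata)
    weight = base[stratum - 1] * rng.lognormal(0.0, design.weight_dispersion / 2, n)
    weight *= n / weight.sum()

    age = rng.integers(lo, hi + 1, n)
    sex = np.where(rng.random(n) < truth.p_male, "male", "female")

    u = _copula_uniforms(rng, n, 4, truth.lifestyle_copula_rho)
    from scipy.stats import lognorm, norm

    da = age - 45.0
    bmi_mu = truth.bmi_meanlog + truth.bmi_age_lin * da + truth.bmi_age_quad * da**2
    bmi = np.exp(bmi_mu + truth.bmi_sdlog * norm.ppf(u[:, 0]))

    p_zero = expit(np.log(truth.pa_zero_base / (1 - truth.pa_zero_base))
                   + truth.pa_zero_age_slope * da)
    pa = np.where(
        u[:, 1] < p_zero,
        0.0,
        lognorm.ppf(
            (u[:, 1] - p_zero) / (1 - p_zero),
            s=truth.pa_sdlog,
            scale=np.exp(truth.pa_meanlog + truth.pa_age_slope * da),
        ),
    )

    diet = truth.diet_mean + truth.diet_sd * norm.ppf(u[:, 2])

    ever = u[:, 3] > 1 - truth.p_ever_smoker  # high rank of latent factor = smoker
    packs = np.zeros(n)
    packs[ever] = lognorm.ppf(
        rng.random(ever.sum()),
        s=truth.packs_sdlog,
        scale=np.exp(truth.packs_meanlog + truth.packs_age_slope * da[ever]),
    )
    current = ever & (rng.random(n) < truth.p_current_of_ever)
    ysq = np.zeros(n)
    quit = ever & ~current
    ysq[quit] = np.minimum(
        rng.exponential(truth.quit_years_mean, quit.sum()),
        np.maximum(age[quit] - 18.0, 0.0),
    )

    disease = {}
    for name, (pmax, a50, scale) in truth.disease_prevalence.items():
        prev = pmax * expit((age - a50) / scale)
        disease[name] = rng.random(n) < prev

    df = pd.DataFrame({
        "id": np.arange(1, n + 1),
        "stratum": stratum,
        "psu": psu,
        "weight": weight,
        "age": age,
        "sex": sex,
        "bmi": bmi,
        "pa_met_min": pa,
        "diet_score": diet,
        "packs_lifetime": packs,
        "years_since_quit": ysq,
        "smoker_current": current,
        **disease,
    })

    feats = risk_factors.build_features(df)
    eta = np.full(n, truth.beta["const"])
    for term in set(truth.beta) - {"const"}:
        eta += truth.beta[term] * feats[term].to_numpy()
    df["died_2y"] = rng.random(n) < expit(eta)
    df.attrs["truth"] = asdict(truth)
    return df


#: Gompertz-Makeham hazard mu(x) = makeham + a * exp(b * x), per sex,
#: roughly matching recent US period mortality.
DEFAULT_MAKEHAM: dict[str, tuple[float, float, float]] = {
    "male": (5.0e-4, 3.0e-5, 0.095),
    "female": (3.0e-4, 1.5e-5, 0.099),
}


def simulate_life_table(
    params: Mapping[str, tuple[float, float, float]] | None = None,
    max_age: int = 110,
    min_age: int = 0,
    monotone_from: int = 30,
) -> PeriodLifeTable:
    """Synthetic period life table from a Gompertz-Makeham hazard.

    With hazard ``mu(x) = makeham + a exp(bx)`` the one-year death
    probability is the closed form ``q_x = 1 - exp(-makeham -
    (a/b)(e^{b(x+1)} - e^{bx}))`` (or ``1 - e^{-makeham}`` when the
    Gompertz term is absent).  The terminal age carries q = 1.
    """
    params = params or DEFAULT_MAKEHAM
    if max_age < 100:
        raise ValueError("max_age must be >= 100")
    rows = []
    ages = np.arange(min_age, max_age + 1)
    for sex, (lam, a, b) in params.items():
        if lam < 0 or a < 0 or (a > 0 and b <= 0):
            raise ValueError(f"hazard parameters must be positive for {sex}")
        if a > 0:
            integ = lam + (a / b) * (np.exp(b * (ages + 1)) - np.exp(b * ages))
        else:
            integ = np.full(ages.shape, lam, dtype=float)
        q = 1.0 - np.exp(-integ)
        q[-1] = 1.0
        if np.any((q <= 0) | (q > 1)):
            raise ValueError(f"generated q_x out of (0, 1] for {sex}")
        tail = q[ages >= monotone_from]
        if np.any(np.diff(tail) < -1e-15):
            raise ValueError(f"q_x not nondecreasing beyond age {monotone_from}")
        rows.append(pd.DataFrame({"sex": sex, "age": ages, "qx": q}))
    return PeriodLifeTable(pd.concat(rows, ignore_index=True))


def inject_missingness(
    table: pd.DataFrame, rates: Mapping[str, float], seed: int
) -> pd.DataFrame:
    """Mask covariate entries completely at random.

    ``rates`` maps covariate columns to masking probabilities in [0, 1).
    Outcome and design variables are never masked.
    """
    protected = {"id", "stratum", "psu", "weight", "died_2y"}
    rng = np.random.default_rng(seed)
    out = table.copy()
    for col, rate in rates.items():
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"masking rate for {col!r} must lie in [0, 1)")
        if col in protected:
            raise ValueError(f"refusing to mask outcome/design variable {col!r}")
        if col not in out.columns:
            raise KeyError(col)
        mask = rng.random(len(out)) < rate
        if out[col].dtype == bool:
            out[col] = out[col].astype(object)
        out.loc[mask, col] = np.nan
    return out
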