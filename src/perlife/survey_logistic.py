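"""Design-based logistic regression for two-year mortality.

Fits the weighted logistic model under a stratified multistage design:
coefficients maximize the survey-weighted log-likelihood (coefficients
fixed a priori — by default the physical-activity term — enter as an
offset), variances come from Taylor linearization over strata and PSUs,
and the sign constraint on the combined f(BMI) effect is enforced by an
active-boundary refit.  Odds ratios with normal-theory confidence
intervals, Wald tests and Holm-adjusted p-values are reported in the
layout of the published coefficient table.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .reference import (
    HUMAN_LABELS,
    PREDICTORS,
    REFERENCE_A_MAX,
    REFERENCE_BETA,
    REFERENCE_FIXED,
    REFERENCE_SE,
    TERMS,
)

__all__ = [
    "ModelSpec",
    "FittedMortalityModel",
    "fit",
    "or_with_ci",
    "holm_adjust",
    "wald_holm",
    "predictor_screens",
]

Z_95 = 1.959964  # normal quantile used for all 95% intervals


@dataclass
class ModelSpec:
    """Specification of the mortality model to fit.

    ``fixed`` maps predictors whose coefficients are specified a priori
    to their values (entered as an offset, excluded from testing).  The
    constraint keeps ``beta_x4 + beta_i13 * (age - 20) >= 0`` over ages
    20..``a_max`` so that abnormal BMI never appears protective within
    the modelling range.
    """

    predictors: tuple[str, ...] = PREDICTORS
    fixed: dict[str, float] = field(default_factory=lambda: dict(REFERENCE_FIXED))
    constrain_bmi: bool = True
    a_max: int = REFERENCE_A_MAX
    bmi_term: str = "x4"
    bmi_age_term: str = "i13"
    single_psu: str = "error"  # or "certainty": contributes no variance

    def free_predictors(self) -> list[str]:
        return [p for p in self.predictors if p not in self.fixed]


@dataclass
class FittedMortalityModel:
    """Fitted two-year mortality model.

    ``beta`` covers every term including the intercept and any fixed
    coefficients; ``se`` is NaN for fixed terms.  ``vcov`` is the
    design-based covariance of the estimated terms.
    """

    beta: pd.Series
    se: pd.Series
    vcov: pd.DataFrame | None
    fixed: dict[str, float]
    wald_p: pd.Series
    holm_p: pd.Series
    n: int
    loglik: float
    constrained: bool = False
    a_max: int = REFERENCE_A_MAX

    def or_table(self, level: float = 0.95) -> pd.DataFrame:
        """Odds ratios with confidence intervals, one row per term."""
        rows = []
        for term in self.beta.index:
            b = self.beta[term]
            s = self.se.get(term, np.nan)
            if term == "const" or not np.isfinite(s) or s <= 0:
                orr, lo, hi = np.exp(b), np.nan, np.nan
            else:
                orr, lo, hi = or_with_ci(b, s, level)
            rows.append({
                "term": term,
                "label": HUMAN_LABELS.get(term, term),
                "beta": b,
                "se": s,
                "wald_p": self.wald_p.get(term, np.nan),
                "holm_p": self.holm_p.get(term, np.nan),
                "odds_ratio": orr,
                "ci_lower": lo,
                "ci_upper": hi,
            })
        return pd.DataFrame(rows).set_index("term")

    @classmethod
    def reference(cls) -> "FittedMortalityModel":
        """The packaged published model (no covariance available)."""
        beta = pd.Series(REFERENCE_BETA).reindex(list(TERMS))
        se = pd.Series(REFERENCE_SE).reindex(list(TERMS))
        z = (beta / se).abs()
        wald = pd.Series(2 * norm.sf(z), index=beta.index).where(se.notna())
        tested = [t for t in beta.index if t != "const" and np.isfinite(se.get(t, np.nan))]
        holm = pd.Series(np.nan, index=beta.index)
        holm[tested] = holm_adjust(wald[tested].to_numpy())
        return cls(
            beta=beta, se=se, vcov=None, fixed=dict(REFERENCE_FIXED),
            wald_p=wald, holm_p=holm, n=38481, loglik=np.nan,
        )

    def to_json(self, path) -> None:
        payload = {
            "beta": self.beta.to_dict(),
            "se": {k: v for k, v in self.se.items() if np.isfinite(v)},
            "vcov": None if self.vcov is None else {
                "terms": list(self.vcov.index),
                "matrix": self.vcov.to_numpy().tolist(),
            },
            "fixed": self.fixed,
            "wald_p": {k: v for k, v in self.wald_p.items() if np.isfinite(v)},
            "holm_p": {k: v for k, v in self.holm_p.items() if np.isfinite(v)},
            "n": self.n,
            "loglik": None if not np.isfinite(self.loglik) else self.loglik,
            "constrained": self.constrained,
            "a_max": self.a_max,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "FittedMortalityModel":
        with open(path) as fh:
            d = json.load(fh)
        terms = list(d["beta"])
        vcov = None
        if d.get("vcov"):
            vcov = pd.DataFrame(
                d["vcov"]["matrix"], index=d["vcov"]["terms"], columns=d["vcov"]["terms"]
            )
        return cls(
            beta=pd.Series(d["beta"]).reindex(terms),
            se=pd.Series(d.get("se", {})).reindex(terms),
            vcov=vcov,
            fixed=d.get("fixed", {}),
            wald_p=pd.Series(d.get("wald_p", {})).reindex(terms),
            holm_p=pd.Series(d.get("holm_p", {})).reindex(terms),
            n=d.get("n", 0),
            loglik=d.get("loglik") if d.get("loglik") is not None else np.nan,
            constrained=d.get("constrained", False),
            a_max=d.get("a_max", REFERENCE_A_MAX),
        )


def or_with_ci(beta_j: float, se_j: float, level: float = 0.95):
    """Odds ratio and normal-theory confidence interval from (beta, se)."""
    if se_j <= 0:
        raise ValueError("standard error must be positive")
    z = norm.ppf(0.5 + level / 2.0)
    return (
        float(np.exp(beta_j)),
        float(np.exp(beta_j - z * se_j)),
        float(np.exp(beta_j + z * se_j)),
    )


def holm_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Holm step-down adjustment with monotonicity enforcement."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="holm")[1]


def wald_holm(model: FittedMortalityModel) -> pd.Series:
    """Holm-adjusted two-sided Wald p-values for the tested terms.

    Fixed coefficients and the intercept are outside the testing family.
    """
    tested = [
        t for t in model.beta.index
        if t != "const" and t not in model.fixed and np.isfinite(model.se.get(t, np.nan))
    ]
    raw = 2 * norm.sf(np.abs(model.beta[tested] / model.se[tested]))
    return pd.Series(holm_adjust(raw), index=tested)


# ---------------------------------------------------------------------------
# Design-based fitting

def _check_design(data: pd.DataFrame, single_psu: str) -> None:
    counts = data.groupby("stratum")["psu"].nunique()
    lone = counts[counts < 2]
    if len(lone) and single_psu == "error":
        raise ValueError(
            f"strata with a single PSU: {list(lone.index)}; collapse them with a "
            "neighboring stratum or fit with single_psu='certainty'"
        )


def _wls_info_and_scores(X, y, w, mu):
    resid = w * (y - mu)
    scores = X * resid[:, None]
    info = X.T @ (X * (w * mu * (1 - mu))[:, None])
    return info, scores


def _taylor_vcov(info, scores, strata, psus, single_psu: str) -> np.ndarray:
    """Stratified with-replacement PSU linearization covariance."""
    score_cols = list(range(scores.shape[1]))
    df = pd.DataFrame(scores, columns=score_cols)
    df["_s"], df["_p"] = np.asarray(strata), np.asarray(psus)
    b = np.zeros((scores.shape[1], scores.shape[1]))
    for _, g in df.groupby("_s"):
        z = g.groupby("_p")[score_cols].sum().to_numpy()
        n_h = z.shape[0]
        if n_h < 2:
            if single_psu == "certainty":
                continue
            raise ValueError("stratum with a single PSU in variance estimation")
        dev = z - z.mean(axis=0)
        b += n_h / (n_h - 1) * dev.T @ dev
    ainv = np.linalg.inv(info)
    return ainv @ b @ ainv


def _weighted_loglik(y, mu, w) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(np.sum(w * (y * np.log(mu) + (1 - y) * np.log(1 - mu))))


def _glm_fit(X: np.ndarray, y: np.ndarray, w: np.ndarray, offset: np.ndarray):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(
            y, X, family=sm.families.Binomial(), var_weights=w, offset=offset
        ).fit(maxiter=200, tol=1e-10)
    if not res.converged:
        raise RuntimeError("IRLS did not converge")
    if np.any(~np.isfinite(res.params)) or np.max(np.abs(res.params)) > 50:
        raise RuntimeError(
            "separation suspected: diverging coefficient "
            f"(largest |beta| at column {int(np.argmax(np.abs(res.params)))})"
        )
    return res


def fit(data: pd.DataFrame, spec: ModelSpec | None = None) -> FittedMortalityModel:
    """Fit the two-year mortality model under the complex design.

    ``data`` is the engineered-feature table (columns x1..x11, i12, i13,
    plus stratum, psu, weight, died_2y) with no missing values.  Fixed
    coefficients enter as an offset; if the unconstrained optimum
    violates the BMI sign constraint the model is refit on the active
    constraint boundary (the candidate boundary fits are compared by
    weighted log-likelihood).  The covariance is the stratified
    with-replacement PSU Taylor linearization.
    """
    spec = spec or ModelSpec()
    cols = list(spec.predictors) + ["stratum", "psu", "weight", "died_2y"]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ValueError(f"feature table missing columns: {missing}")
    if data[cols].isna().any().any():
        raise ValueError("feature table contains missing values")
    y = data["died_2y"].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary")
    _check_design(data, spec.single_psu)

    w = data["weight"].to_numpy(dtype=float)
    free = spec.free_predictors()
    offset = np.zeros(len(data))
    for term, val in spec.fixed.items():
        offset += val * data[term].to_numpy(dtype=float)

    def design_matrix(columns: list[str]) -> np.ndarray:
        return np.column_stack([np.ones(len(data))]
                               + [data[c].to_numpy(dtype=float) for c in columns])

    X = design_matrix(free)
    try:
        res = _glm_fit(X, y, w, offset)
    except RuntimeError as err:
        raise RuntimeError(f"mortality model fit failed: {err}") from err
    params = dict(zip(["const"] + free, res.params))
    constrained = False
    # transform matrix T mapping reduced parameters to ("const", *free)
    T = np.eye(len(free) + 1)
    X_used, res_used = X, res

    if spec.constrain_bmi and spec.bmi_term in free and spec.bmi_age_term in free:
        u_max = float(spec.a_max - 20)
        b4, b13 = params[spec.bmi_term], params[spec.bmi_age_term]
        if min(b4, b4 + u_max * b13) < -1e-12:
            cand = []
            i4 = free.index(spec.bmi_term) + 1
            i13 = free.index(spec.bmi_age_term) + 1
            # edge A: beta_i13 = -beta_x4 / u_max  (binding at the age ceiling)
            colsA = [c for c in free if c != spec.bmi_age_term]
            XA = design_matrix(colsA)
            jA = colsA.index(spec.bmi_term) + 1
            XA[:, jA] = (data[spec.bmi_term].to_numpy(dtype=float)
                         - data[spec.bmi_age_term].to_numpy(dtype=float) / u_max)
            TA = np.zeros((len(free) + 1, len(colsA) + 1))
            for r, term in enumerate(["const"] + free):
                if term == spec.bmi_age_term:
                    TA[r, jA] = -1.0 / u_max
                else:
                    TA[r, (["const"] + colsA).index(term)] = 1.0
            try:
                resA = _glm_fit(XA, y, w, offset)
                if resA.params[jA] >= 0:
                    cand.append((resA, XA, TA))
            except RuntimeError:
                pass
            # edge B: beta_x4 = 0 (binding at age 20)
            colsB = [c for c in free if c != spec.bmi_term]
            XB = design_matrix(colsB)
            jB = colsB.index(spec.bmi_age_term) + 1
            TB = np.zeros((len(free) + 1, len(colsB) + 1))
            for r, term in enumerate(["const"] + free):
                if term != spec.bmi_term:
                    TB[r, (["const"] + colsB).index(term)] = 1.0
            try:
                resB = _glm_fit(XB, y, w, offset)
                if resB.params[jB] >= 0:
                    cand.append((resB, XB, TB))
            except RuntimeError:
                pass
            if not cand:
                # vertex of the constraint cone: beta_x4 = beta_i13 = 0
                colsV = [c for c in free if c not in (spec.bmi_term, spec.bmi_age_term)]
                XV = design_matrix(colsV)
                TV = np.zeros((len(free) + 1, len(colsV) + 1))
                for r, term in enumerate(["const"] + free):
                    if term not in (spec.bmi_term, spec.bmi_age_term):
                        TV[r, (["const"] + colsV).index(term)] = 1.0
                resV = _glm_fit(XV, y, w, offset)
                cand.append((resV, XV, TV))
            lls = [_weighted_loglik(y, c[0].fittedvalues, w) for c in cand]
            res_used, X_used, T = cand[int(np.argmax(lls))]
            constrained = True
            full = T @ res_used.params
            params = dict(zip(["const"] + free, full))

    mu = np.asarray(res_used.fittedvalues)
    info, scores = _wls_info_and_scores(X_used, y, w, mu)
    v_red = _taylor_vcov(
        info, scores, data["stratum"], data["psu"], spec.single_psu
    )
    v_full = T @ v_red @ T.T
    terms_full = ["const"] + free
    vcov = pd.DataFrame(v_full, index=terms_full, columns=terms_full)
    se = pd.Series(np.sqrt(np.diag(v_full)), index=terms_full)

    all_terms = ["const"] + list(spec.predictors)
    beta = pd.Series({**params, **spec.fixed}).reindex(all_terms)
    se_all = se.reindex(all_terms)
    z = (beta / se_all).abs()
    wald = pd.Series(2 * norm.sf(z), index=all_terms).where(se_all.notna())
    tested = [t for t in free]
    holm = pd.Series(np.nan, index=all_terms)
    holm[tested] = holm_adjust(wald[tested].to_numpy())

    return FittedMortalityModel(
        beta=beta,
        se=se_all,
        vcov=vcov,
        fixed=dict(spec.fixed),
        wald_p=wald,
        holm_p=holm,
        n=len(data),
        loglik=_weighted_loglik(y, mu, w),
        constrained=constrained,
        a_max=spec.a_max,
    )


# ---------------------------------------------------------------------------
# Predictor screening statistics

def _weighted_auc(score: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(y, score, sample_weight=w))


def predictor_screens(
    data: pd.DataFrame,
    predictors: Sequence[str] = PREDICTORS,
    outcome: str = "died_2y",
    n_bins: int = 10,
) -> pd.DataFrame:
    """Univariate predictive-power screens: IV, Cramer's V, Gini.

    Information Value is computed over decile bins of continuous
    predictors (categorical levels for binaries), Cramer's V from the
    predictor-outcome contingency table, and Gini = 2*AUC - 1 from the
    rank statistic of the lone predictor.  Constant predictors score 0
    with a warning.
    """
    from scipy.stats import chi2_contingency

    y = data[outcome].to_numpy(dtype=float)
    w = data["weight"].to_numpy(dtype=float) if "weight" in data else np.ones(len(data))
    rows = []
    for pred in predictors:
        x = data[pred].to_numpy(dtype=float)
        if np.all(x == x[0]):
            warnings.warn(f"predictor {pred!r} is constant; screens set to 0")
            rows.append({"predictor": pred, "iv": 0.0, "cramers_v": 0.0, "gini": 0.0})
            continue
        if len(np.unique(x)) <= n_bins:
            bins = pd.Series(x).astype("category").cat.codes.to_numpy()
        else:
            bins = pd.qcut(x, n_bins, labels=False, duplicates="drop")
        tab = pd.crosstab(bins, y, values=w, aggfunc="sum").fillna(0.0)
        if tab.shape[1] < 2:
            rows.append({"predictor": pred, "iv": 0.0, "cramers_v": 0.0, "gini": 0.0})
            continue
        bad = tab[1.0].to_numpy()
        good = tab[0.0].to_numpy()
        keep = (bad > 0) & (good > 0)
        gshare = good[keep] / good.sum()
        bshare = bad[keep] / bad.sum()
        iv = float(np.sum((gshare - bshare) * np.log(gshare / bshare)))
        # no continuity correction: screening wants the raw association scale
        chi2 = chi2_contingency(tab.to_numpy(), correction=False)[0]
        ntot = tab.to_numpy().sum()
        k = min(tab.shape) - 1
        cramers = float(np.sqrt(chi2 / (ntot * k))) if k > 0 else 0.0
        gini = 2.0 * _weighted_auc(x, y, w) - 1.0
        rows.append({"predictor": pred, "iv": iv, "cramers_v": cramers, "gini": gini})
    return pd.DataFrame(rows).set_index("predictor")
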