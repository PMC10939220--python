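"""Bootstrap internal validation under the complex survey design.

Resamples whole PSUs within strata, refits the mortality model on each
replicate, and corrects apparent performance (AUC, Youden-threshold
sensitivity/specificity, Brier score) for optimism: the mean excess of
train-on-replicate over test-on-original performance.  The same
replicate coefficient sets yield percentile 95% uncertainty intervals
for personalized life expectancy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve

from .survey_logistic import FittedMortalityModel, ModelSpec, fit

__all__ = [
    "ValidationReport",
    "design_bootstrap",
    "classification_metrics",
    "optimism_correct",
    "le_uncertainty",
]

logger = logging.getLogger(__name__)

METRICS = ("auc", "sensitivity", "specificity", "brier")


@dataclass
class ValidationReport:
    """Optimism-corrected performance of the mortality model.

    One row per metric: apparent (full-data) value, mean train and test
    values across replicates, optimism = mean(train - test), corrected =
    apparent - optimism, and the percentile 95% uncertainty interval of
    the per-replicate corrected values.
    """

    table: pd.DataFrame
    b_requested: int
    b_used: int
    replicate_models: list[FittedMortalityModel] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        t = self.table
        if not np.allclose(t["corrected"], t["apparent"] - t["optimism"]):
            raise ValueError("corrected must equal apparent - optimism")
        if (t["ui_lower"] > t["ui_upper"]).any():
            raise ValueError("uncertainty interval bounds out of order")


def design_bootstrap(data: pd.DataFrame, B: int = 200, seed: int = 0):
    """Yield B design-respecting bootstrap replicates of a survey table.

    Within each stratum the PSUs are resampled with replacement (as many
    draws as the stratum has PSUs), carrying every member record of each
    drawn PSU; with n_h draws out of n_h PSUs the expected multiplicity
    of each PSU is one, so the original weights are kept.  Deterministic
    for a fixed seed.
    """
    counts = data.groupby("stratum")["psu"].nunique()
    if (counts < 2).any():
        raise ValueError(
            f"strata with a single PSU: {list(counts[counts < 2].index)}; "
            "collapse them before bootstrapping"
        )
    rng = np.random.default_rng(seed)
    groups = {
        s: {p: g2 for p, g2 in g.groupby("psu")}
        for s, g in data.groupby("stratum")
    }
    for _ in range(B):
        parts = []
        for s, psus in groups.items():
            ids = list(psus)
            draws = rng.choice(len(ids), size=len(ids), replace=True)
            for k, j in enumerate(draws):
                g2 = psus[ids[j]].copy()
                # each draw is its own resampled PSU: relabel so a PSU drawn
                # twice contributes two distinct units to the replicate design
                g2["psu"] = k + 1
                parts.append(g2)
        yield pd.concat(parts, ignore_index=True)


def classification_metrics(
    probabilities: np.ndarray,
    outcomes: np.ndarray,
    weights: np.ndarray | None = None,
    threshold: float | None = None,
) -> dict[str, float]:
    """Weighted AUC, Youden-threshold sensitivity/specificity, Brier.

    With ``threshold=None`` the threshold maximizing the Youden index
    (sensitivity + specificity - 1) on this data is used and reported.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    w = np.ones_like(y) if weights is None else np.asarray(weights, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    if len(np.unique(y)) < 2:
        raise ValueError("AUC undefined: outcome takes a single class")
    auc = float(roc_auc_score(y, p, sample_weight=w))
    if threshold is None:
        fpr, tpr, thr = roc_curve(y, p, sample_weight=w)
        threshold = float(thr[int(np.argmax(tpr - fpr))])
    pred = p >= threshold
    wpos, wneg = w[y == 1].sum(), w[y == 0].sum()
    sens = float(w[(y == 1) & pred].sum() / wpos)
    spec = float(w[(y == 0) & ~pred].sum() / wneg)
    brier = float(np.average((p - y) ** 2, weights=w))
    return {
        "auc": auc, "sensitivity": sens, "specificity": spec,
        "brier": brier, "threshold": threshold,
    }


def _predict(model: FittedMortalityModel, data: pd.DataFrame) -> np.ndarray:
    from scipy.special import expit

    eta = np.full(len(data), model.beta["const"])
    for term in model.beta.index:
        if term != "const":
            eta += model.beta[term] * data[term].to_numpy(dtype=float)
    return expit(eta)


def optimism_correct(
    data: pd.DataFrame,
    spec: ModelSpec | None = None,
    B: int = 200,
    seed: int = 0,
) -> ValidationReport:
    """Bootstrap optimism correction of the mortality model's performance.

    For each replicate: refit, evaluate on the replicate (train) and on
    the original data (test); the Youden threshold is recomputed on the
    replicate and carried to the original data, since the threshold is
    part of the model under validation.  Replicates whose fit fails are
    logged and skipped; the run errors out if none survive.
    """
    spec = spec or ModelSpec()
    full = fit(data, spec)
    w = data["weight"].to_numpy(dtype=float)
    y = data["died_2y"].to_numpy(dtype=float)
    apparent = classification_metrics(_predict(full, data), y, w)

    train_rows, test_rows, models = [], [], []
    for b, rep in enumerate(design_bootstrap(data, B, seed)):
        try:
            m = fit(rep, spec)
        except (RuntimeError, ValueError) as err:
            logger.warning("replicate %d failed: %s", b, err)
            continue
        tr = classification_metrics(
            _predict(m, rep),
            rep["died_2y"].to_numpy(dtype=float),
            rep["weight"].to_numpy(dtype=float),
        )
        te = classification_metrics(_predict(m, data), y, w, threshold=tr["threshold"])
        train_rows.append(tr)
        test_rows.append(te)
        models.append(m)
    if not models:
        raise RuntimeError("all bootstrap replicates failed to fit")
    if len(models) < 0.9 * B:
        logger.warning("only %d/%d replicates converged", len(models), B)

    train = pd.DataFrame(train_rows)
    test = pd.DataFrame(test_rows)
    rows = []
    for metric in METRICS:
        opt = float((train[metric] - test[metric]).mean())
        per_rep_corrected = apparent[metric] - (train[metric] - test[metric])
        lo, hi = np.percentile(per_rep_corrected, [2.5, 97.5])
        rows.append({
            "metric": metric,
            "apparent": apparent[metric],
            "train_mean": float(train[metric].mean()),
            "test_mean": float(test[metric].mean()),
            "optimism": opt,
            "corrected": apparent[metric] - opt,
            "ui_lower": float(lo),
            "ui_upper": float(hi),
        })
    return ValidationReport(
        table=pd.DataFrame(rows).set_index("metric"),
        b_requested=B,
        b_used=len(models),
        replicate_models=models,
    )


def le_uncertainty(
    record,
    replicate_models: list[FittedMortalityModel],
    point_model: FittedMortalityModel,
    baseline,
    table,
    trajectory_model,
    disease_params,
    a_max: int | None = None,
) -> dict[str, float]:
    """Personalized life expectancy with a percentile 95% UI.

    The point estimate uses the full-data model; the interval recomputes
    life expectancy under each bootstrap replicate's coefficients
    (baseline profiles and the population life table held fixed, so the
    interval reflects coefficient uncertainty only).
    """
    from .life_tables import personalize
    from .projection import project_covariates

    if a_max is None:
        a_max = point_model.a_max
    sex, age = record["sex"], int(record["age"])
    ages = np.arange(age, table.omega(sex) + 1)
    traj = project_covariates(record, trajectory_model, disease_params, ages)

    def le_of(model) -> float:
        pt = personalize(table, model, baseline, traj, sex, age, a_max)
        return pt.life_expectancy(age)

    point = le_of(point_model)
    les = []
    for m in replicate_models:
        try:
            les.append(le_of(m))
        except (ValueError, RuntimeError) as err:  # pragma: no cover
            logger.warning("replicate LE failed: %s", err)
    if len(les) < 0.5 * len(replicate_models):
        raise RuntimeError("fewer than half of the replicates yielded an LE")
    lo, hi = np.percentile(les, [2.5, 97.5])
    return {"le": point, "ui_lower": float(lo), "ui_upper": float(hi),
            "n_replicates": len(les)}
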