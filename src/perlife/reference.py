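"""Published reference coefficients of the two-year mortality model.

The model is a multivariable logistic regression of two-year all-cause
mortality estimated on pooled NHANES 1999-2014 adult data (n = 38,481,
complex sampling design) linked to mortality follow-up.  Its odds ratios
are the engine of the life-table personalization: shipping the published
coefficients lets life expectancy be computed without refitting.

Predictor layout (engineered scale, see :mod:`perlife.risk_factors`):

========  ==================================================  =========
term      meaning                                             units
========  ==================================================  =========
const     intercept                                           log-odds
x1        age - 20                                            years
x2        sex (male = 1, female = 0)                          indicator
x3        lifetime smoking exposure, decayed since quitting   1000 packs
x4        f(BMI), 0 on the normal range 18.5-25 kg/m^2        f-units
x5        log-transformed leisure-time physical activity      log units
x6        diet quality score                                  points
x7        history of diabetes                                 indicator
x8        irregular pulse on examination                      indicator
x9        history of coronary heart disease (incl. MI)        indicator
x10       history of stroke                                   indicator
x11       history of high-mortality cancers                   indicator
i12       x1 * x2  (age by sex)                               —
i13       x1 * x4  (age by f(BMI))                            —
========  ==================================================  =========

``x5`` was specified a priori from literature meta-analyses (reverse
causation makes its freely estimated effect implausibly large) and
therefore carries no standard error.
"""

from __future__ import annotations

PREDICTORS: tuple[str, ...] = (
    "x1", "x2", "x3", "x4", "x5", "x6",
    "x7", "x8", "x9", "x10", "x11", "i12", "i13",
)

TERMS: tuple[str, ...] = ("const",) + PREDICTORS

#: Published point estimates (log-odds scale).
REFERENCE_BETA: dict[str, float] = {
    "const": -10.6913,
    "x1": 0.1337,
    "x2": 1.4898,
    "x3": 0.0261,
    "x4": 0.0660,
    "x5": -0.1000,
    "x6": -0.0234,
    "x7": 0.4526,
    "x8": 0.4581,
    "x9": 0.6094,
    "x10": 0.7654,
    "x11": 1.1049,
    "i12": -0.0240,
    "i13": -0.0011,
}

#: Published design-based standard errors; ``x5`` is fixed a priori and has none.
REFERENCE_SE: dict[str, float] = {
    "const": 1.7029,
    "x1": 0.0285,
    "x2": 0.3575,
    "x3": 0.0047,
    "x4": 0.0299,
    "x6": 0.0079,
    "x7": 0.1036,
    "x8": 0.1826,
    "x9": 0.1279,
    "x10": 0.1247,
    "x11": 0.1897,
    "i12": 0.0070,
    "i13": 0.0005,
}

#: Coefficients fixed a priori (entered as an offset when refitting).
REFERENCE_FIXED: dict[str, float] = {"x5": -0.1000}

#: Age ceiling for the sign constraint on the combined f(BMI) effect
#: beta_x4 + beta_i13 * (age - 20): with the published values the sum
#: reaches zero exactly at age 80.
REFERENCE_A_MAX: int = 80

HUMAN_LABELS: dict[str, str] = {
    "const": "Intercept",
    "x1": "Age - 20",
    "x2": "Gender (male=1)",
    "x3": "Lifetime smoking exposure",
    "x4": "f(BMI)",
    "x5": "f(Physical activity)",
    "x6": "Diet quality score",
    "x7": "History of diabetes",
    "x8": "Irregular pulse",
    "x9": "History of coronary heart disease",
    "x10": "History of stroke",
    "x11": "History of cancer",
    "i12": "Gender x (Age - 20)",
    "i13": "f(BMI) x (Age - 20)",
}
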