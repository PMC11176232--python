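"""Published Japanese reference numbers used as defaults and test inputs.

Two kinds of constants live here:

* the published Japanese conditional-logit coefficients (unweighted and
  weighted Model 1), used as informative priors for design search and as
  the default "truth" of the choice simulator;
* the valuation-survey sample composition and the Japanese general-population
  margins for the demographic variables, used as defaults for the synthetic
  cohort and the raking targets.

All values are on the scale they were published at (coefficients are utility
per life-year; margins are proportions).
"""

from __future__ import annotations

from typing import Dict, Tuple

from .dimensions import DIMENSIONS

CoefKey = Tuple[str, int]  # (dimension, level in {2,3,4}); "duration" handled apart

# Japanese conditional logit, Model 1 (all 30 level decrements), unweighted.
# Values: (coefficient, clustered SE). Duration is utility per life-year;
# dimension-level terms are per-life-year decrements relative to level 1.
UNWEIGHTED_M1_DURATION: Tuple[float, float] = (0.4986, 0.0195)
UNWEIGHTED_M1: Dict[CoefKey, Tuple[float, float]] = {
    ("physical", 2): (-0.0528, 0.0069),
    ("physical", 3): (-0.0798, 0.0074),
    ("physical", 4): (-0.1330, 0.0071),
    ("role", 2): (-0.0205, 0.0055),
    ("role", 3): (-0.0638, 0.0060),
    ("role", 4): (-0.0803, 0.0055),
    ("social", 2): (-0.0120, 0.0054),
    ("social", 3): (-0.0441, 0.0058),
    ("social", 4): (-0.0574, 0.0054),
    ("emotional", 2): (-0.0121, 0.0053),
    ("emotional", 3): (-0.0176, 0.0058),
    ("emotional", 4): (-0.0361, 0.0051),
    ("pain", 2): (-0.0127, 0.0055),
    ("pain", 3): (-0.0588, 0.0058),
    ("pain", 4): (-0.0845, 0.0053),
    ("fatigue", 2): (-0.0157, 0.0052),
    ("fatigue", 3): (-0.0380, 0.0055),
    ("fatigue", 4): (-0.0421, 0.0050),
    ("sleep", 2): (-0.0276, 0.0050),
    ("sleep", 3): (-0.0278, 0.0056),
    ("sleep", 4): (-0.0380, 0.0050),
    ("appetite", 2): (-0.0089, 0.0050),
    ("appetite", 3): (-0.0359, 0.0055),
    ("appetite", 4): (-0.0387, 0.0050),
    ("nausea", 2): (-0.0269, 0.0052),
    ("nausea", 3): (-0.0511, 0.0056),
    ("nausea", 4): (-0.0644, 0.0051),
    ("bowel", 2): (-0.0126, 0.0051),
    ("bowel", 3): (-0.0224, 0.0056),
    ("bowel", 4): (-0.0395, 0.0050),
}

# Same model estimated with raking weights (income, education, EQ-5D band,
# Kessler-6). Note the sleep dimension's published non-monotonicity:
# level 3 (-0.0223) is less negative than level 2 (-0.0317).
WEIGHTED_M1_DURATION: Tuple[float, float] = (0.4769, 0.0345)
WEIGHTED_M1: Dict[CoefKey, Tuple[float, float]] = {
    ("physical", 2): (-0.0494, 0.0102),
    ("physical", 3): (-0.0646, 0.0102),
    ("physical", 4): (-0.1273, 0.0101),
    ("role", 2): (-0.0194, 0.0079),
    ("role", 3): (-0.0615, 0.0080),
    ("role", 4): (-0.0766, 0.0070),
    ("social", 2): (-0.0047, 0.0079),
    ("social", 3): (-0.0434, 0.0088),
    ("social", 4): (-0.0586, 0.0086),
    ("emotional", 2): (-0.0076, 0.0073),
    ("emotional", 3): (-0.0086, 0.0082),
    ("emotional", 4): (-0.0373, 0.0074),
    ("pain", 2): (-0.0069, 0.0081),
    ("pain", 3): (-0.0543, 0.0089),
    ("pain", 4): (-0.0752, 0.0084),
    ("fatigue", 2): (-0.0255, 0.0080),
    ("fatigue", 3): (-0.0340, 0.0085),
    ("fatigue", 4): (-0.0367, 0.0075),
    ("sleep", 2): (-0.0317, 0.0069),
    ("sleep", 3): (-0.0223, 0.0088),
    ("sleep", 4): (-0.0293, 0.0072),
    ("appetite", 2): (-0.0086, 0.0068),
    ("appetite", 3): (-0.0349, 0.0072),
    ("appetite", 4): (-0.0365, 0.0073),
    ("nausea", 2): (-0.0170, 0.0073),
    ("nausea", 3): (-0.0457, 0.0080),
    ("nausea", 4): (-0.0595, 0.0079),
    ("bowel", 2): (-0.0218, 0.0083),
    ("bowel", 3): (-0.0345, 0.0092),
    ("bowel", 4): (-0.0452, 0.0079),
}

# Published fit statistics of the unweighted Model 1 (n = 2435 completers,
# 16 sets each): pseudo-R2, log pseudo-likelihood, AIC, BIC.
UNWEIGHTED_M1_FIT_STATS = {
    "pseudo_r2": 0.1199,
    "loglik": -23765.0,
    "aic": 47592.0,
    "bic": 47879.0,
    "k": 31,
    "n_rows": 77920,
}

STUDY_N_COMPLETERS = 2435
STUDY_SETS_PER_RESPONDENT = 16
STUDY_N_SETS = 960
STUDY_OVERLAP = 4


def coefficient_vector(
    coefs: Dict[CoefKey, Tuple[float, float]] | None = None,
    duration: Tuple[float, float] | None = None,
) -> "pandas.Series":  # noqa: F821 - imported lazily
    """Published coefficients as a Series in canonical parameter order
    (duration first, then (dimension, level) in dimension order)."""
    import pandas as pd

    coefs = UNWEIGHTED_M1 if coefs is None else coefs
    duration = UNWEIGHTED_M1_DURATION if duration is None else duration
    index = ["duration"] + [f"{d}_{l}" for d in DIMENSIONS for l in (2, 3, 4)]
    values = [duration[0]] + [coefs[(d, l)][0] for d in DIMENSIONS for l in (2, 3, 4)]
    return pd.Series(values, index=index, name="coef")


def _norm(d: Dict[str, float]) -> Dict[str, float]:
    s = sum(d.values())
    return {k: v / s for k, v in d.items()}


# Valuation-sample composition (n = 2435 completers) and Japanese
# general-population margins. Printed percentage columns are renormalized
# to sum to exactly 1.
SAMPLE_MARGINS: Dict[str, Dict[str, float]] = {
    "sex": _norm({"male": 47.6, "female": 52.4}),
    "age": _norm(
        {
            "18-29": 13.2,
            "30-39": 12.9,
            "40-49": 16.6,
            "50-59": 14.8,
            "60-69": 15.3,
            "70+": 27.2,
        }
    ),
    "income": _norm(
        {
            "<1M": 7.1,
            "1-2M": 7.8,
            "2-3M": 13.4,
            "3-4M": 15.1,
            "4-5M": 14.8,
            "5-7M": 16.8,
            "7-10M": 13.3,
            "10-15M": 7.6,
            "15-20M": 2.7,
            ">20M": 1.4,
        }
    ),
    "education": _norm(
        {
            "junior_high": 2.1,
            "high_school": 28.8,
            "college": 19.6,
            "university": 49.4,
        }
    ),
    "kessler6": _norm({"0-4": 63.4, "5-9": 19.9, "10-14": 10.2, "15-24": 6.4}),
    # EQ-5D-5L health status entered raking as a categorical variable; the
    # published table reports only VAS means by age/sex, so these band
    # margins are synthetic placeholders preserving the pattern that the
    # online panel is slightly less healthy than the population.
    "eq5d_band": _norm({"low": 30.0, "mid": 45.0, "high": 25.0}),
}

POPULATION_MARGINS: Dict[str, Dict[str, float]] = {
    "sex": _norm({"male": 48.7, "female": 51.3}),
    "age": _norm(
        {
            "18-29": 14.0,
            "30-39": 13.3,
            "40-49": 17.2,
            "50-59": 15.1,
            "60-69": 15.1,
            "70+": 25.3,
        }
    ),
    "income": _norm(
        {
            "<1M": 6.4,
            "1-2M": 12.6,
            "2-3M": 13.6,
            "3-4M": 12.8,
            "4-5M": 10.5,
            "5-7M": 16.7,
            "7-10M": 15.2,
            "10-15M": 8.8,
            "15-20M": 2.1,
            ">20M": 1.2,
        }
    ),
    "education": _norm(
        {
            "junior_high": 14.8,
            "high_school": 39.7,
            "college": 20.5,
            "university": 24.3,
        }
    ),
    "kessler6": _norm({"0-4": 71.0, "5-9": 18.7, "10-14": 7.6, "15-24": 2.7}),
    "eq5d_band": _norm({"low": 22.0, "mid": 48.0, "high": 30.0}),  # synthetic, see above
}

#: The four variables entered into raking for the published weighted analyses.
RAKING_VARIABLES = ("income", "education", "eq5d_band", "kessler6")

# Survey completion-time summaries (minutes).
COMPLETION_TIME_MEDIAN = 12.5
COMPLETION_TIME_MIN = 3.75
COMPLETION_TIME_MAX = 69.33
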