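"""Published study-level estimates from the INDANA hypertension trials.

The INDANA individual participant data are not redistributable, but the
published study-level estimates (treatment effects on systolic blood
pressure, treatment log-hazard ratios for death / myocardial infarction /
stroke, and joint-model association parameters, each with a 95% CI) are
aggregate data and can be pooled directly with the stage-2 machinery.
They serve as the package's worked example of pooling published
aggregate rows without raw data.

Estimates are keyed by outcome ("death", "mi", "stroke"), parameter
("beta12" = longitudinal treatment effect, "beta21" = time-to-event
treatment effect, "alpha" = association), and analysis ("separate" or
"joint"; the association parameter exists only for "joint").
"""

from __future__ import annotations

from .pooling import EffectEstimate, ci_to_se

# (study, estimate, ci_lower, ci_upper) at the 95% level
_TABLES: dict[tuple[str, str, str], list[tuple[str, float, float, float]]] = {
    ("death", "beta12", "separate"): [
        ("COOP", -10.9, -13.11, -8.69),
        ("EWPHE", -11.38, -13.44, -9.32),
        ("MRC1", -8.18, -8.57, -7.78),
        ("MRC2", -10.66, -11.31, -10.01),
        ("SHEP", -6.99, -7.59, -6.38),
        ("STOP", -11.94, -13.27, -10.62),
    ],
    ("death", "beta12", "joint"): [
        ("COOP", -10.9, -13.3, -8.54),
        ("EWPHE", -11.38, -13.78, -9.09),
        ("MRC1", -8.18, -8.52, -7.81),
        ("MRC2", -10.66, -11.46, -10.07),
        ("SHEP", -6.99, -7.64, -6.4),
        ("STOP", -11.94, -13.48, -10.43),
    ],
    ("death", "beta21", "separate"): [
        ("COOP", -0.04, -0.38, 0.31),
        ("EWPHE", -0.1, -0.33, 0.13),
        ("MRC1", -0.03, -0.2, 0.15),
        ("MRC2", -0.04, -0.19, 0.12),
        ("SHEP", -0.13, -0.32, 0.05),
        ("STOP", -0.51, -0.92, -0.1),
    ],
    ("death", "beta21", "joint"): [
        ("COOP", -0.05, -0.46, 0.32),
        ("EWPHE", -0.06, -0.32, 0.18),
        ("MRC1", 0.02, -0.18, 0.18),
        ("MRC2", -0.04, -0.18, 0.11),
        ("SHEP", -0.11, -0.31, 0.07),
        ("STOP", -0.56, -1.12, -0.15),
    ],
    ("death", "alpha", "joint"): [
        ("COOP", -0.003, -0.021, 0.012),
        ("EWPHE", 0.007, -0.004, 0.018),
        ("MRC1", 0.034, 0.024, 0.042),
        ("MRC2", -0.001, -0.013, 0.011),
        ("SHEP", 0.008, -0.001, 0.016),
        ("STOP", -0.011, -0.04, 0.012),
    ],
    ("mi", "beta12", "separate"): [
        ("COOP", -11.1, -13.32, -8.89),
        ("MRC1", -8.18, -8.58, -7.79),
        ("MRC2", -10.7, -11.36, -10.05),
        ("SHEP", -7.01, -7.61, -6.4),
        ("STOP", -11.96, -13.28, -10.64),
    ],
    ("mi", "beta21", "separate"): [
        ("COOP", 0.03, -0.43, 0.49),
        ("MRC1", -0.06, -0.24, 0.12),
        ("MRC2", -0.21, -0.44, 0.02),
        ("SHEP", -0.32, -0.57, -0.06),
        ("STOP", -0.23, -0.72, 0.27),
    ],
    ("mi", "alpha", "joint"): [
        ("COOP", -0.001, -0.019, 0.013),
        ("MRC1", 0.032, 0.024, 0.041),
        ("MRC2", 0.018, 0.0, 0.035),
        ("SHEP", 0.003, -0.011, 0.015),
        ("STOP", -0.004, -0.035, 0.018),
    ],
    ("stroke", "beta12", "separate"): [
        ("COOP", -10.73, -12.94, -8.51),
        ("MRC1", -8.18, -8.58, -7.79),
        ("MRC2", -10.66, -11.31, -10.0),
        ("SHEP", -6.96, -7.56, -6.35),
        ("STOP", -11.7, -13.03, -10.37),
    ],
    ("stroke", "beta21", "separate"): [
        ("COOP", -0.58, -1.12, -0.04),
        ("MRC1", -0.6, -0.92, -0.29),
        ("MRC2", -0.28, -0.54, -0.02),
        ("SHEP", -0.45, -0.7, -0.2),
        ("STOP", -0.64, -1.1, -0.19),
    ],
    ("stroke", "beta21", "joint"): [
        ("COOP", -0.48, -1.23, -0.02),
        ("MRC1", -0.51, -0.87, -0.24),
        ("MRC2", -0.24, -0.49, 0.0),
        ("SHEP", -0.39, -0.62, -0.15),
        ("STOP", -0.7, -1.21, -0.24),
    ],
    ("stroke", "alpha", "joint"): [
        ("COOP", 0.034, 0.016, 0.053),
        ("MRC1", 0.061, 0.048, 0.072),
        ("MRC2", 0.02, -0.003, 0.039),
        ("SHEP", 0.021, 0.01, 0.03),
        ("STOP", -0.014, -0.038, 0.01),
    ],
}

# subject / event / measurement counts for the time-to-death analysis
STUDY_COUNTS_DEATH = {
    "COOP": (884, 130, 4621),
    "EWPHE": (840, 284, 3825),
    "MRC1": (17354, 501, 101078),
    "MRC2": (4396, 616, 26457),
    "SHEP": (4736, 455, 20816),
    "STOP": (1615, 96, 5777),
}


def indana_effects(
    outcome: str = "death",
    parameter: str = "beta12",
    analysis: str = "separate",
    level: float = 0.95,
) -> list[EffectEstimate]:
    """Published per-study estimates as stage-2 inputs, with variances
    recovered from the printed 95% CIs."""
    key = (outcome, parameter, analysis)
    if key not in _TABLES:
        raise KeyError(
            f"no published rows for outcome={outcome!r}, parameter={parameter!r}, "
            f"analysis={analysis!r}"
        )
    return [
        EffectEstimate(
            study_id=s,
            parameter=parameter,
            estimate=est,
            variance=ci_to_se(lo, hi, level) ** 2,
        )
        for s, est, lo, hi in _TABLES[key]
    ]
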