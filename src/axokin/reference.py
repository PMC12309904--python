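"""Published reference values for the axolotl suction-feeding scaling table.

These are the printed per-variable scaling estimates from the original
ontogenetic study (25 individuals: 16 larvae, 4 juveniles, 5 adults):
ordinary least-squares fits of log10 peak performance per individual on
log10 snout-vent length, with the geometric-similarity prediction and the
resulting allometry classification.  They serve two roles here: as the seed
for the record-tier simulator defaults, and as a self-contained input for
checking the allometry classifier against the published classifications.

``ci`` bounds are the printed 95% confidence intervals of the slope;
``significant`` marks a printed p below 0.05.
"""

from __future__ import annotations

__all__ = ["REFERENCE_SCALING", "VARIABLE_CATEGORIES", "HILL_EXPONENTS"]

#: Variable -> category used for peak aggregation and Hill predictions.
VARIABLE_CATEGORIES: dict[str, str] = {
    "MG": "metric", "Mhd1": "metric", "Mhd2": "metric",
    "MGA": "angle", "MHA": "angle",
    "MSGO": "speed", "MSGC": "speed", "MShd1down": "speed",
    "MShd2down": "speed", "MShd1up": "speed", "MShd2up": "speed",
    "MAGO": "acceleration", "MAGC": "acceleration",
    "MAhd1down": "acceleration", "MAhd2down": "acceleration",
    "TMG": "timing", "Thd1": "timing", "Thd2": "timing",
    "TMhd1": "timing", "TMhd2": "timing", "TMHA": "timing",
    "DG": "duration", "Dhd1": "duration", "Dhd2": "duration",
    "PCD": "duration",
}

#: Geometric-similarity (Hill) scaling exponents by variable category.
HILL_EXPONENTS: dict[str, float] = {
    "metric": 1.0,
    "angle": 0.0,
    "speed": 0.0,
    "acceleration": -1.0,
    "timing": 1.0,
    "duration": 1.0,
}


def _row(variable, slope, se, intercept, ise, r2, ci, significant, allometry):
    return {
        "variable": variable,
        "category": VARIABLE_CATEGORIES[variable],
        "slope": slope,
        "slope_se": se,
        "intercept": intercept,
        "intercept_se": ise,
        "r_squared": r2,
        "ci_low": ci[0],
        "ci_high": ci[1],
        "hill_prediction": HILL_EXPONENTS[VARIABLE_CATEGORIES[variable]],
        "significant": significant,
        "allometry": allometry,
    }


REFERENCE_SCALING = [
    _row("MG", 0.98, 0.09, -0.92, 0.07, 0.83, (0.79, 1.17), True, "isometry"),
    _row("Mhd1", 0.86, 0.12, -1.03, 0.09, 0.70, (0.61, 1.10), True, "isometry"),
    _row("Mhd2", 0.80, 0.12, -0.90, 0.09, 0.67, (0.56, 1.05), True, "isometry"),
    _row("MGA", 0.15, 0.11, 1.63, 0.08, 0.08, (-0.07, 0.37), False, "isometry"),
    _row("MHA", 0.00, 0.02, 2.21, 0.01, 0.00, (-0.04, 0.03), False, "isometry"),
    _row("MSGO", 0.72, 0.09, 1.32, 0.07, 0.73, (0.53, 0.90), True, "positive"),
    _row("MSGC", 0.72, 0.09, 1.21, 0.07, 0.73, (0.53, 0.91), True, "positive"),
    _row("MShd1down", 0.67, 0.12, 1.03, 0.08, 0.59, (0.43, 0.91), True, "positive"),
    _row("MShd2down", 0.67, 0.09, 1.13, 0.06, 0.72, (0.49, 0.85), True, "positive"),
    _row("MShd1up", 0.80, 0.14, 0.63, 0.10, 0.59, (0.51, 1.09), True, "positive"),
    _row("MShd2up", 0.71, 0.14, 0.72, 0.10, 0.54, (0.42, 0.99), True, "positive"),
    _row("MAGO", 0.69, 0.21, 3.86, 0.15, 0.33, (0.26, 1.11), True, "positive"),
    _row("MAGC", 0.63, 0.20, 3.67, 0.14, 0.31, (0.22, 1.04), True, "positive"),
    _row("MAhd1down", 0.54, 0.13, 3.57, 0.09, 0.43, (0.27, 0.80), True, "positive"),
    _row("MAhd2down", 0.65, 0.11, 3.56, 0.08, 0.59, (0.42, 0.89), True, "positive"),
    _row("TMG", 0.00, 0.00, 0.30, 0.00, 0.21, (0.00, 0.01), True, "negative"),
    _row("Thd1", 0.00, 0.00, 0.30, 0.00, 0.23, (0.00, 0.00), True, "negative"),
    _row("Thd2", 0.00, 0.00, 0.30, 0.00, 0.01, (0.00, 0.00), False, "negative"),
    _row("TMhd1", 0.03, 0.01, 0.29, 0.01, 0.31, (0.01, 0.06), True, "negative"),
    _row("TMhd2", 0.01, 0.00, 0.31, 0.00, 0.23, (0.00, 0.02), True, "negative"),
    _row("TMHA", -0.06, 0.03, 0.38, 0.02, 0.14, (-0.12, 0.00), False, "negative"),
    _row("DG", 0.27, 0.21, -1.27, 0.15, 0.07, (-0.17, 0.71), False, "negative"),
    _row("Dhd1", 0.15, 0.20, -0.56, 0.15, 0.02, (-0.26, 0.57), False, "negative"),
    _row("Dhd2", 0.09, 0.19, -0.53, 0.13, 0.01, (-0.29, 0.48), False, "negative"),
    _row("PCD", 0.07, 0.20, -0.48, 0.14, 0.01, (-0.33, 0.48), False, "negative"),
]
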