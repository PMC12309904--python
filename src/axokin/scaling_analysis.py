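"""Allometric scaling of peak feeding performance against body size.

For every kinematic variable the *peak performance per individual* (largest
gape, fastest jaw opening, ...; shortest time for timing and duration
variables) is regressed on snout-vent length on log10-log10 axes with
ordinary least squares.  The fitted slope, with its 95% confidence interval
(t-based, n - 2 df), is compared with the exponent predicted by the
geometric-similarity (Hill) model, under which shapes are size-invariant
and muscle shortening velocity is size-independent:

    lengths ~ L^1,  angles ~ L^0,  speeds ~ L^0,
    durations and timings ~ L^1,  accelerations ~ L^-1.

A variable shows *negative allometry* when the predicted slope lies above
the upper confidence bound, *positive allometry* when it lies below the
lower bound, and isometry otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .event_extraction import KINEMATIC_VARIABLES
from .reference import HILL_EXPONENTS, VARIABLE_CATEGORIES

__all__ = [
    "ScalingFit",
    "hill_prediction",
    "aggregate_peaks",
    "fit_loglog",
    "classify_allometry",
    "scaling_table",
    "scaling_table_frame",
]

#: Aggregation direction: peak performance is the maximum for magnitudes and
#: the minimum (fastest) for timing and duration variables.
_MIN_CATEGORIES = ("timing", "duration")


@dataclass
class ScalingFit:
    """One row of the scaling table: log-log OLS fit plus classification."""

    variable: str
    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    p_value: float
    r_squared: float
    ci_low: float
    ci_high: float
    n: int
    hill_prediction: float = float("nan")
    allometry: str = ""

    @property
    def significant(self) -> bool:
        return self.p_value < 0.05


def hill_prediction(category: str) -> float:
    """Geometric-similarity scaling exponent for a variable category."""
    try:
        return HILL_EXPONENTS[category]
    except KeyError:
        raise ValueError(f"unknown variable category {category!r}") from None


def aggregate_peaks(
    records: pd.DataFrame,
    timing_rule: str = "min",
) -> pd.DataFrame:
    """Collapse per-bout records to per-individual peak performance.

    Magnitude variables (metric, angle, speed, acceleration) take the
    maximum across an individual's bouts; timing and duration variables take
    the minimum — the fastest bout is the best performance — unless
    ``timing_rule='max'``.  Individuals with no usable bouts are dropped
    with a warning.
    """
    if timing_rule not in ("min", "max"):
        raise ValueError("timing_rule must be 'min' or 'max'")
    present = [v for v in KINEMATIC_VARIABLES if v in records.columns]
    agg = {
        v: (timing_rule if VARIABLE_CATEGORIES[v] in _MIN_CATEGORIES else "max")
        for v in present
    }
    usable = records.dropna(subset=present)
    dropped = set(records["individual_id"]) - set(usable["individual_id"])
    if dropped:
        warnings.warn(
            f"dropping individuals with no usable bouts: {sorted(dropped)}",
            stacklevel=2,
        )
    meta = usable.groupby("individual_id").agg(
        stage=("stage", "first"), svl=("svl", "first"),
        n_bouts=("individual_id", "size"),
    )
    peaks = usable.groupby("individual_id").agg(agg)
    return meta.join(peaks).reset_index()


def fit_loglog(x_svl: np.ndarray, y_peak: np.ndarray,
               variable: str = "") -> ScalingFit:
    """OLS of log10(y) on log10(SVL) with a t-based 95% CI on the slope."""
    x = np.asarray(x_svl, dtype=float)
    y = np.asarray(y_peak, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    bad = np.flatnonzero((x <= 0) | (y <= 0) | ~np.isfinite(x) | ~np.isfinite(y))
    if bad.size:
        raise ValueError(
            f"non-positive or non-finite values at indices {bad.tolist()}"
            + (f" for variable {variable}" if variable else "")
        )
    res = stats.linregress(np.log10(x), np.log10(y))
    n = x.size
    tcrit = stats.t.ppf(0.975, n - 2)
    return ScalingFit(
        variable=variable,
        slope=float(res.slope),
        slope_se=float(res.stderr),
        intercept=float(res.intercept),
        intercept_se=float(res.intercept_stderr),
        p_value=float(res.pvalue),
        r_squared=float(res.rvalue ** 2),
        ci_low=float(res.slope - tcrit * res.stderr),
        ci_high=float(res.slope + tcrit * res.stderr),
        n=n,
    )


def classify_allometry(ci_low: float, ci_high: float,
                       prediction: float) -> str:
    """Compare the predicted exponent with the slope's 95% CI.

    Prediction above the upper bound -> shallower growth than predicted:
    ``negative``; below the lower bound -> ``positive``; inside the interval
    (bounds inclusive) -> ``isometry``.
    """
    if ci_low > ci_high:
        raise ValueError("ci_low must not exceed ci_high")
    if prediction > ci_high:
        return "negative"
    if prediction < ci_low:
        return "positive"
    return "isometry"


def scaling_table(
    records: pd.DataFrame,
    timing_rule: str = "min",
) -> list[ScalingFit]:
    """Full scaling analysis: one classified fit per kinematic variable."""
    peaks = aggregate_peaks(records, timing_rule=timing_rule)
    fits = []
    for var in KINEMATIC_VARIABLES:
        if var not in peaks.columns:
            continue
        fit = fit_loglog(peaks["svl"].to_numpy(), peaks[var].to_numpy(), var)
        fit.hill_prediction = hill_prediction(VARIABLE_CATEGORIES[var])
        fit.allometry = classify_allometry(fit.ci_low, fit.ci_high,
                                           fit.hill_prediction)
        fits.append(fit)
    return fits


def scaling_table_frame(records: pd.DataFrame,
                        timing_rule: str = "min") -> pd.DataFrame:
    """The scaling table as a tidy DataFrame (one row per variable)."""
    rows = []
    for f in scaling_table(records, timing_rule=timing_rule):
        rows.append({
            "variable": f.variable,
            "category": VARIABLE_CATEGORIES[f.variable],
            "slope": f.slope, "slope_se": f.slope_se,
            "intercept": f.intercept, "intercept_se": f.intercept_se,
            "p_value": f.p_value, "r_squared": f.r_squared,
            "ci_low": f.ci_low, "ci_high": f.ci_high,
            "hill_prediction": f.hill_prediction,
            "allometry": f.allometry,
            "significant": f.significant,
            "n": f.n,
        })
    return pd.DataFrame(rows)
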