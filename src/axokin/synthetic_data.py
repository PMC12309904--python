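"""Forward simulator of suction-feeding bouts with known ground truth.

Two tiers of simulation are provided, matching what the downstream stages
consume:

* **Trajectory tier** (:func:`generate_bout`, :func:`simulate_cohort`) —
  full landmark trajectories.  Each bout is built from smooth unimodal
  excursion pulses (:class:`BetaPulse`, C^2 everywhere so that peak
  accelerations are recoverable from a twice-differenced signal) driving a
  2-D head template: a gape pulse of amplitude MG, two delayed
  hyoid-depression pulses, and a small head-elevation pulse.  Pulse
  parameters are drawn from log-log scaling laws of snout-vent length with
  individual random effects, a shared per-bout "effort" factor (vigorous
  strikes are larger *and* faster, as in real feeding data), and
  idiosyncratic noise.  Gaussian landmark noise and a tracking-confidence
  model emulate pose-tracker output.  Every bout carries a
  :class:`GroundTruth` with the exact derivative maxima of its generating
  pulses.

* **Record tier** (:func:`sample_records`, :func:`sample_null_records`) —
  per-bout tables of the 25 kinematic variables drawn directly from
  per-variable scaling laws (with stage-specific slopes for the speed and
  acceleration variables, where adult slopes are several times the immature
  ones).  The 25 variables of a real bout are functionally coupled through
  the pulse shapes, so independent per-variable effects can only be imposed
  at this tier; it is what the mixed-model screening and calibration suites
  consume.

Because event detection is threshold-based (a cycle starts where the
excursion crosses 5% of its peak), the *detectable* timings differ from the
generating pulse onsets by known closed-form offsets.  GroundTruth therefore
carries two records: ``true`` (the generating values) and ``expected`` (the
values an ideal noise-free detector reports at the configured thresholds);
recovery tests compare against ``expected`` for timings and against
``true`` for amplitudes and peak rates.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .event_extraction import DetectionConfig, KINEMATIC_VARIABLES
from .trajectory_io import CalibrationSpec, LandmarkTrajectory

__all__ = [
    "ScalingLaw",
    "SimConfig",
    "Individual",
    "GroundTruth",
    "HeadTemplate",
    "sample_cohort",
    "generate_bout",
    "simulate_cohort",
    "export_cohort",
    "conditional_expected_record",
    "generating_slopes",
    "sample_records",
    "sample_null_records",
    "INTERACTION_VARIABLES",
    "ADULT_SLOPE_RATIOS",
]

#: Speed/acceleration variables whose scaling steepens at adulthood in the
#: record-tier defaults (the simulator's positive control for interaction
#: screening), plus the posterior-hyoid onset time.  Values are the
#: adult:immature slope ratios (the published shifts run three- to
#: seven-fold; the onset time's shift is qualitative only).
INTERACTION_VARIABLES = ("MAGO", "MSGC", "MAGC", "MAhd1down", "MShd1up",
                         "Thd2", "MShd2up")
ADULT_SLOPE_RATIOS = {"MAGO": 5.0, "MSGC": 3.0, "MAGC": 4.0,
                      "MAhd1down": 7.0, "MShd1up": 4.0, "MShd2up": 4.0,
                      "Thd2": 6.0}


@dataclass(frozen=True)
class ScalingLaw:
    """Log-log law: value = 10 ** (a + b * x + db_stage * (x - c_stage) + u + e)
    with ``x = log10(SVL)``.

    ``db_stage = stage_offsets.get(stage, 0)`` is a stage-specific slope
    deviation that pivots about the stage's mean log size ``c_stage``, so it
    changes within-stage scaling without displacing the stage off the
    common allometry.  ``u`` is the individual effect (shared ``quality``
    times ``loading`` plus an idiosyncratic draw of sd ``sd_individual``)
    and ``e`` the bout effect (shared ``effort`` times ``loading`` plus sd
    ``sd_bout``).
    """

    intercept: float
    slope: float
    sd_individual: float = 0.0
    sd_bout: float = 0.0
    loading: float = 0.0
    stage_offsets: dict = field(default_factory=dict)

    def stage_slope(self, stage: str) -> float:
        return self.slope + self.stage_offsets.get(stage, 0.0)

    def log_value(self, stage: str, log_svl: float, center: float) -> float:
        """Noise-free log10 value at ``log_svl`` for a stage centred at
        ``center`` (the stage's mean log10 SVL)."""
        db = self.stage_offsets.get(stage, 0.0)
        return self.intercept + self.slope * log_svl + db * (log_svl - center)


def _primitive_laws() -> dict[str, ScalingLaw]:
    """Default pulse-parameter laws for the trajectory tier.

    Amplitudes and the gape cycle follow published-scale allometries for
    axolotl suction feeding (gape ~ 0.12 * SVL^0.98 cm, gape cycle
    ~ 60 ms * SVL^0.27); onset delays of the hyoid pulses are
    size-independent at 35-65 ms, and the hyoid's return is slower than its
    depression (rise:fall = 1:1.4, via the ``*_down`` / ``*_up`` split of
    each hyoid cycle).  The posterior hyoid starts later and cycles longer
    than the anterior one, so the buccal compression wave ends posteriorly
    and the bout end (PCD) is unambiguous.  Hyoid phase durations are set near the gape-cycle
    timescale so that depression speeds and accelerations stay dynamically
    consistent with the amplitude laws and well above the observation-noise
    floor; the printed cycle durations for the hyoid are several-fold
    longer but are incompatible with the printed depression speeds, so the
    dynamics win.
    """
    amp = dict(sd_individual=0.04, sd_bout=0.03, loading=1.0)
    dur = dict(sd_individual=0.08, sd_bout=0.03, loading=-0.35)
    onset = dict(sd_individual=0.08, sd_bout=0.035, loading=0.0)
    # duration intercepts refer to the nominal pulse support, which is
    # ~1.38x the detectable (threshold-to-threshold) cycle duration
    return {
        "MG": ScalingLaw(-0.92, 0.98, **amp),
        "DGO": ScalingLaw(-1.36, 0.27, **dur),      # gape opening time
        "DGC": ScalingLaw(-1.36, 0.27, **dur),      # gape closing time
        "Thd1": ScalingLaw(-1.46, 0.00, **onset),
        "Mhd1": ScalingLaw(-1.03, 0.86, **amp),
        "Dhd1down": ScalingLaw(-1.38, 0.15, **dur),
        "Dhd1up": ScalingLaw(-1.234, 0.15, **dur),
        "Thd2": ScalingLaw(-1.20, 0.00, **onset),
        "Mhd2": ScalingLaw(-0.90, 0.80, **amp),
        "Dhd2down": ScalingLaw(-1.13, 0.09, **dur),
        "Dhd2up": ScalingLaw(-0.984, 0.09, **dur),
        "HDA": ScalingLaw(0.78, 0.00, sd_individual=0.06, sd_bout=0.04, loading=0.5),
    }


def _record_laws() -> dict[str, ScalingLaw]:
    """Default per-variable laws for the record tier.

    Slopes and intercepts are seeded from the published scaling table for
    the axolotl ontogenetic series; the variables in
    :data:`INTERACTION_VARIABLES` get a stage-specific slope deviation in
    adults (adult slope 3-7x the immature slope, per variable, pivoting
    about the adult mean size so stage means stay on the common allometry)
    — the positive control for interaction screening.
    """
    from .reference import REFERENCE_SCALING, VARIABLE_CATEGORIES

    sds = {
        "metric": (0.06, 0.05),
        "angle": (0.02, 0.02),
        "speed": (0.08, 0.06),
        "acceleration": (0.15, 0.10),
        "timing": (0.06, 0.06),
        "duration": (0.15, 0.12),
    }
    laws = {}
    for row in REFERENCE_SCALING:
        var = row["variable"]
        sd_u, sd_e = sds[VARIABLE_CATEGORIES[var]]
        slope, intercept = row["slope"], row["intercept"]
        offsets: dict[str, float] = {}
        if var in INTERACTION_VARIABLES:
            ratio = ADULT_SLOPE_RATIOS[var]
            base = slope if slope != 0 else 0.03
            offsets = {"adult": (ratio - 1.0) * base}
        laws[var] = ScalingLaw(intercept, slope, sd_u, sd_e, 0.0, offsets)
    return laws


@dataclass
class SimConfig:
    """Study-shaped simulation settings.

    The cohort defaults mirror the study design: 16 larvae, 4 juveniles and
    5 adults filmed at 1000 frames/s, with 1-8 usable bouts each.  Adults
    average three times the larval snout-vent length while larvae and
    juveniles overlap in size.
    """

    n_larvae: int = 16
    n_juveniles: int = 4
    n_adults: int = 5
    bouts_min: int = 1
    bouts_max: int = 8
    fps: float = 1000.0
    #: stage -> (mean SVL in cm, coefficient of variation)
    svl_distributions: dict = field(default_factory=lambda: {
        "larva": (2.8, 0.35),
        "juvenile": (3.5, 0.20),
        "adult": (8.4, 0.30),
    })
    #: landmark observation noise in pixels (the refined-tracking regime,
    #: where the network has been retrained until predictions are
    #: accurate).  The camera frames each animal, so the cm-per-pixel
    #: calibration grows with body size (see ``reference_svl``) and pixel
    #: jitter is the natural noise unit.
    noise_px: float = 0.3
    outlier_prob: float = 0.01
    outlier_sd_px: float = 8.0
    #: SVL at which the default checkerboard calibration applies; the
    #: per-individual scale is ``calibration.scale * svl / reference_svl``
    reference_svl: float = 2.8
    #: shared log10-scale bout ("effort") and individual ("quality") factors
    effort_sd: float = 0.05
    quality_sd: float = 0.06
    #: recording margins around the bout (the retained video covers the
    #: approach and the settling after capture, not just the strike).  The
    #: margin scales with the bout's own duration — clips are trimmed
    #: relative to the behaviour they contain — which also keeps the
    #: fixed-df smoother's stiffness commensurate with the movement
    #: timescale across the 3x size range.
    margin_factor: float = 0.7
    margin_min_s: float = 0.12
    margin_max_s: float = 0.35
    calibration: CalibrationSpec = field(
        default_factory=lambda: CalibrationSpec(pixels_per_square=50.0)
    )
    laws: dict = field(default_factory=_primitive_laws)
    record_laws: dict = field(default_factory=_record_laws)

    def noiseless(self) -> "SimConfig":
        """Copy with observation noise switched off (bout variation kept)."""
        return dataclasses.replace(self, noise_px=0.0, outlier_prob=0.0)

    def stage_centers(self) -> dict[str, float]:
        """Mean log10 SVL per stage, the pivots for slope deviations."""
        return {s: math.log10(m) for s, (m, _) in self.svl_distributions.items()}

    def scale_for(self, svl: float) -> float:
        """Per-individual cm/px calibration (camera framed to the animal)."""
        return self.calibration.scale * svl / self.reference_svl

    def stages(self) -> list[str]:
        return (["larva"] * self.n_larvae + ["juvenile"] * self.n_juveniles
                + ["adult"] * self.n_adults)


@dataclass
class Individual:
    individual_id: str
    stage: str
    svl: float
    quality: float
    u: dict[str, float]


@dataclass
class GroundTruth:
    """Imposed parameters and analytic targets for one simulated bout."""

    bout_id: str
    individual_id: str
    stage: str
    svl: float
    quality: float
    effort: float
    params: dict[str, float]
    true: dict[str, float]
    expected: dict[str, float]


# ---------------------------------------------------------------------------
# Head template (lateral view, image convention: y points down)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HeadTemplate:
    """Landmark layout scaled to snout-vent length.

    The jaw joint (am) sits at the origin; both jaw tips lie at radius
    ``r_jaw`` so the gape angle follows from the gape distance by the chord
    relation ``gape = 2 r sin(theta / 2)``.  The hyoid points rest obliquely
    behind/below the jaw joint and depress radially away from it, so their
    distance to am is rest distance plus the pulse exactly.
    """

    svl: float
    r_jaw_frac: float = 0.22
    rest_gape_frac: float = 0.02
    uj_angle: float = -0.10  # radians from +x; negative = above horizontal

    @property
    def r_jaw(self) -> float:
        return self.r_jaw_frac * self.svl

    @property
    def rest_gape(self) -> float:
        return self.rest_gape_frac * self.svl

    @property
    def uj(self) -> np.ndarray:
        a = self.uj_angle
        return self.r_jaw * np.array([math.cos(a), math.sin(a)])

    @property
    def e(self) -> np.ndarray:
        return self.svl * np.array([0.05, -0.09])

    @property
    def sh(self) -> np.ndarray:
        return self.svl * np.array([-0.30, 0.05])

    @property
    def hd1_rest(self) -> np.ndarray:
        return self.svl * np.array([-0.10, 0.10])

    @property
    def hd2_rest(self) -> np.ndarray:
        return self.svl * np.array([-0.22, 0.12])

    def gape_angle_deg(self, gape: float) -> float:
        """Vertex angle at am between the jaw tips, for a given gape (cm)."""
        if gape >= 2.0 * self.r_jaw:
            raise ValueError("gape exceeds the jaw chord; template too small")
        return math.degrees(2.0 * math.asin(gape / (2.0 * self.r_jaw)))

    def head_geometry(self) -> tuple[float, float, float, float]:
        """(rho, psi0, base_angle_deg, sign) of the shoulder about the eye.

        ``sign`` is the rotation direction of ``sh`` around ``e`` that
        *increases* the head angle (vertex e, arms to uj and sh).
        """
        v = self.sh - self.e
        rho = float(np.hypot(*v))
        psi0 = float(math.atan2(v[1], v[0]))
        base = _angle_deg(self.e, self.uj, self.sh)
        eps = 1e-4
        v2 = rho * np.array([math.cos(psi0 + eps), math.sin(psi0 + eps)])
        bumped = _angle_deg(self.e, self.uj, self.e + v2)
        sign = 1.0 if bumped > base else -1.0
        return rho, psi0, base, sign


def _angle_deg(a, b, c) -> float:
    v1 = np.asarray(b, float) - np.asarray(a, float)
    v2 = np.asarray(c, float) - np.asarray(a, float)
    cosang = float(np.dot(v1, v2) / (np.hypot(*v1) * np.hypot(*v2)))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


# ---------------------------------------------------------------------------
# Pulses
# ---------------------------------------------------------------------------

class BetaPulse:
    """Smooth unimodal excursion pulse with asymmetric rise and fall.

    The profile is a rescaled beta-density bump over a support of length
    ``d_rise + d_fall``:

        f(onset + tau * T) = amp * tau^p (1-tau)^q / w(tau*),  tau in [0, 1]

    with the exponents chosen so the peak sits exactly at the end of the
    rise phase (``tau* = p/(p+q) = d_rise/T``) and ``p + q = k_shape``.  For
    ``p, q > 2`` the pulse is C^2 everywhere — including at the peak and at
    both ends — which matters because peak accelerations are read off the
    twice-differenced smoothed signal and a curvature jump can never be
    recovered by that pipeline.  Derivative maxima and threshold-crossing
    times follow from the exact formula (dense evaluation plus golden
    refinement of a smooth 1-D function), independent of any sampling grid.
    """

    def __init__(self, onset: float, amp: float, d_rise: float, d_fall: float,
                 k_shape: float = 8.0):
        if d_rise <= 0 or d_fall <= 0 or amp <= 0:
            raise ValueError("pulse amplitude and phase durations must be positive")
        self.onset = onset
        self.amp = amp
        self.d_rise = d_rise
        self.d_fall = d_fall
        self.duration = d_rise + d_fall
        self.p = k_shape * d_rise / self.duration
        self.q = k_shape * d_fall / self.duration
        if min(self.p, self.q) <= 2.0:
            raise ValueError(
                "rise/fall asymmetry too strong for a C^2 pulse; "
                "increase k_shape or balance the phase durations")
        tau_star = self.p / (self.p + self.q)
        self._wmax = tau_star ** self.p * (1.0 - tau_star) ** self.q
        self.peak_time = onset + d_rise

    # -- exact profile and derivatives (in tau units) -----------------------

    def _w(self, tau):
        return tau ** self.p * (1.0 - tau) ** self.q / self._wmax

    def _dw(self, tau):
        return self._w(tau) * (self.p / tau - self.q / (1.0 - tau))

    def _d2w(self, tau):
        r = self.p / tau - self.q / (1.0 - tau)
        return self._w(tau) * (r * r - self.p / tau ** 2
                               - self.q / (1.0 - tau) ** 2)

    def value(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        tau = (t - self.onset) / self.duration
        out = np.zeros_like(tau)
        inside = (tau > 0.0) & (tau < 1.0)
        out[inside] = self.amp * self._w(tau[inside])
        return out

    # -- analytic targets ---------------------------------------------------

    def crossing(self, frac: float, side: str) -> float:
        """Time at which the pulse crosses ``frac`` of its peak (rise/fall)."""
        from scipy.optimize import brentq

        tau_star = self.d_rise / self.duration
        if side == "rise":
            lo, hi = 1e-12, tau_star
        elif side == "fall":
            lo, hi = tau_star, 1.0 - 1e-12
        else:
            raise ValueError("side must be 'rise' or 'fall'")
        tau = brentq(lambda u: self._w(u) - frac, lo, hi, xtol=1e-14)
        return self.onset + tau * self.duration

    def _max_abs(self, fn, t_lo: float, t_hi: float) -> float:
        """Max |fn(tau)| over a time window by dense scan plus refinement."""
        lo = max((t_lo - self.onset) / self.duration, 1e-9)
        hi = min((t_hi - self.onset) / self.duration, 1.0 - 1e-9)
        if hi <= lo:
            raise ValueError("empty pulse window")
        taus = np.linspace(lo, hi, 4001)
        vals = np.abs(fn(taus))
        k = int(np.argmax(vals))
        a = taus[max(k - 1, 0)]
        b = taus[min(k + 1, taus.size - 1)]
        fine = np.linspace(a, b, 2001)
        return float(np.max(np.abs(fn(fine))))

    def max_rate(self, t_lo: float, t_hi: float) -> float:
        """Max |df/dt| over [t_lo, t_hi], in amp units per second."""
        return self.amp / self.duration * self._max_abs(self._dw, t_lo, t_hi)

    def max_accel(self, t_lo: float, t_hi: float) -> float:
        """Max |d2f/dt2| over [t_lo, t_hi], in amp units per second^2."""
        return self.amp / self.duration ** 2 * self._max_abs(self._d2w, t_lo, t_hi)


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

def _lognormal_mean_cv(rng: np.random.Generator, mean: float, cv: float,
                       size=None):
    if cv <= 0:
        return np.full(size, mean) if size else mean
    sigma2 = math.log(1.0 + cv ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=size)


def sample_cohort(config: SimConfig, rng: np.random.Generator) -> list[Individual]:
    """Draw individuals with stage-conditional SVL and random effects."""
    stages = config.stages()
    if not stages:
        raise ValueError("empty cohort: all stage counts are zero")
    counts: dict[str, int] = {}
    out = []
    for stage in stages:
        counts[stage] = counts.get(stage, 0) + 1
        mean, cv = config.svl_distributions[stage]
        svl = float(_lognormal_mean_cv(rng, mean, cv))
        quality = float(rng.normal(0.0, config.quality_sd))
        u = {k: float(rng.normal(0.0, law.sd_individual))
             for k, law in config.laws.items()}
        out.append(Individual(
            individual_id=f"{stage[0].upper()}{counts[stage]:02d}",
            stage=stage, svl=svl, quality=quality, u=u,
        ))
    return out


def _draw_params(ind: Individual, config: SimConfig,
                 rng: np.random.Generator) -> tuple[dict[str, float], float]:
    effort = float(rng.normal(0.0, config.effort_sd))
    centers = config.stage_centers()
    params = {}
    for key, law in config.laws.items():
        e = law.loading * effort + float(rng.normal(0.0, law.sd_bout))
        u = law.loading * ind.quality + ind.u[key]
        log10v = law.log_value(ind.stage, math.log10(ind.svl),
                               centers[ind.stage]) + u + e
        params[key] = 10.0 ** log10v
    return _apply_constraints(params), effort


def _expected_params(ind: Individual, config: SimConfig) -> dict[str, float]:
    """Noise-free bout parameters conditional on the individual's effects."""
    centers = config.stage_centers()
    params = {}
    for key, law in config.laws.items():
        u = law.loading * ind.quality + ind.u[key]
        log10v = law.log_value(ind.stage, math.log10(ind.svl),
                               centers[ind.stage]) + u
        params[key] = 10.0 ** log10v
    return _apply_constraints(params)


# ---------------------------------------------------------------------------
# Analytic records
# ---------------------------------------------------------------------------

#: p + q of every generated pulse.  The rise:fall ratio clamp keeps every
#: pulse C^2 (p, q > 2) *and* keeps the acceleration maximum on the broad
#: lobe at the pulse peak rather than in a sharp boundary tail lobe that a
#: smoothed, twice-differenced signal cannot resolve.
PULSE_SHAPE_K = 8.0
_RATIO_BOUNDS = (0.68, 1.45)


def _clamp_phases(d_rise: float, d_fall: float) -> tuple[float, float]:
    """Clamp the rise:fall ratio (preserving the total) to the C^2 range."""
    lo, hi = _RATIO_BOUNDS
    r = d_rise / d_fall
    if lo <= r <= hi:
        return d_rise, d_fall
    r = min(max(r, lo), hi)
    total = d_rise + d_fall
    return total * r / (1.0 + r), total / (1.0 + r)


_PHASE_PAIRS = (("DGO", "DGC"), ("Dhd1down", "Dhd1up"), ("Dhd2down", "Dhd2up"))

#: Excursion fraction used by the generator's onset-ordering constraint;
#: matches the default detection onset threshold.
_ONSET_FRAC = 0.05


def _apply_constraints(params: dict[str, float]) -> dict[str, float]:
    """Clamp phase asymmetries and enforce event ordering.

    The rise:fall clamp keeps every pulse C^2 with its acceleration maximum
    on the peak lobe; the onset floor guarantees that each hyoid excursion
    crosses the detection threshold at least 3 ms *after* the gape does, so
    detected hyoid onset times (referenced to detected mouth opening) stay
    positive for every bout.
    """
    for a, b in _PHASE_PAIRS:
        params[a], params[b] = _clamp_phases(params[a], params[b])
    gape = BetaPulse(0.0, 1.0, params["DGO"], params["DGC"], PULSE_SHAPE_K)
    t_on_g = gape.crossing(_ONSET_FRAC, "rise")
    for tag in ("1", "2"):
        h = BetaPulse(0.0, 1.0, params[f"Dhd{tag}down"], params[f"Dhd{tag}up"],
                      PULSE_SHAPE_K)
        floor = t_on_g - h.crossing(_ONSET_FRAC, "rise") + 0.003
        params[f"Thd{tag}"] = max(params[f"Thd{tag}"], floor)
    return params


def _bout_margin(params: dict[str, float], config: "SimConfig") -> float:
    """Pre/post recording margin for a bout, from its generating params."""
    pcd = max(params["DGO"] + params["DGC"],
              params["Thd1"] + params["Dhd1down"] + params["Dhd1up"],
              params["Thd2"] + params["Dhd2down"] + params["Dhd2up"])
    return min(max(config.margin_factor * pcd, config.margin_min_s),
               config.margin_max_s)


def _bout_pulses(params: dict[str, float], t_on: float) -> dict[str, BetaPulse]:
    """The four excursion pulses of a bout, at absolute onset ``t_on``."""
    p = params
    dg = p["DGO"] + p["DGC"]
    return {
        "gape": BetaPulse(t_on, p["MG"], p["DGO"], p["DGC"], PULSE_SHAPE_K),
        "hd1": BetaPulse(t_on + p["Thd1"], p["Mhd1"], p["Dhd1down"],
                         p["Dhd1up"], PULSE_SHAPE_K),
        "hd2": BetaPulse(t_on + p["Thd2"], p["Mhd2"], p["Dhd2down"],
                         p["Dhd2up"], PULSE_SHAPE_K),
        "head": BetaPulse(t_on, p["HDA"], dg / 2.0, dg / 2.0, PULSE_SHAPE_K),
    }


def _analytic_records(
    params: dict[str, float],
    template: HeadTemplate,
    detection: DetectionConfig,
    fps: float,
    t_on: float,
) -> tuple[dict[str, float], dict[str, float]]:
    """(true, expected) 25-variable records for one parameter set.

    ``true`` holds the generating values: pulse onsets, durations,
    amplitudes, and the exact derivative maxima of the generating pulses.
    ``expected`` holds what an ideal noise-free detector reports on the
    sampling grid: cycle boundaries sit on the last/first frame at or below
    ``onset_frac`` (or ``return_frac`` on the hyoid's return) of the peak
    excursion, peaks on the frame where the sampled pulse is largest, and
    all times are referenced to the detected mouth-opening frame.
    """
    p = params
    base_head = template.head_geometry()[2]
    pulses = _bout_pulses(params, t_on)
    gape, hd1p, hd2p, head = (pulses[k] for k in ("gape", "hd1", "hd2", "head"))
    dg = p["DGO"] + p["DGC"]

    def true_hyoid(pulse: BetaPulse, tag: str) -> dict[str, float]:
        return {
            f"Thd{tag}": p[f"Thd{tag}"],
            f"Mhd{tag}": pulse.amp,
            f"TMhd{tag}": p[f"Thd{tag}"] + pulse.d_rise,
            f"Dhd{tag}": pulse.duration,
            f"MShd{tag}down": pulse.max_rate(pulse.onset, pulse.peak_time),
            f"MShd{tag}up": pulse.max_rate(pulse.peak_time,
                                           pulse.onset + pulse.duration),
            f"MAhd{tag}down": pulse.max_accel(pulse.onset, pulse.peak_time),
        }

    true = {
        "MG": p["MG"],
        "TMG": p["DGO"],
        "MGA": template.gape_angle_deg(template.rest_gape + p["MG"]),
        "DG": dg,
        "MSGO": gape.max_rate(gape.onset, gape.peak_time),
        "MAGO": gape.max_accel(gape.onset, gape.peak_time),
        "MSGC": gape.max_rate(gape.peak_time, gape.onset + gape.duration),
        "MAGC": gape.max_accel(gape.peak_time, gape.onset + gape.duration),
        "MHA": base_head + p["HDA"],
        "TMHA": dg / 2.0,
        **true_hyoid(hd1p, "1"),
        **true_hyoid(hd2p, "2"),
    }
    true["PCD"] = max(dg, p["Thd1"] + true["Dhd1"], p["Thd2"] + true["Dhd2"])

    # grid-aware event frames
    eps = 1e-9

    def k_rise(pulse: BetaPulse, frac: float) -> int:
        return int(math.floor(pulse.crossing(frac, "rise") * fps + eps))

    def k_fall(pulse: BetaPulse, frac: float) -> int:
        return int(math.ceil(pulse.crossing(frac, "fall") * fps - eps))

    def k_peak(pulse: BetaPulse) -> int:
        k = int(round(pulse.peak_time * fps))
        cand = np.arange(k - 3, k + 4)
        return int(cand[np.argmax(pulse.value(cand / fps))])

    k0 = k_rise(gape, detection.onset_frac)
    k_gp = k_peak(gape)
    k_gc = k_fall(gape, detection.onset_frac)

    def exp_hyoid(pulse: BetaPulse, tag: str) -> tuple[dict[str, float], int]:
        ks = k_rise(pulse, detection.onset_frac)
        kp = k_peak(pulse)
        ke = k_fall(pulse, detection.return_frac)
        t_s = pulse.crossing(detection.onset_frac, "rise")
        t_e = pulse.crossing(detection.return_frac, "fall")
        return {
            f"Thd{tag}": (ks - k0) / fps,
            f"Mhd{tag}": pulse.amp,
            f"TMhd{tag}": (kp - k0) / fps,
            f"Dhd{tag}": (ke - ks) / fps,
            f"MShd{tag}down": pulse.max_rate(t_s, pulse.peak_time),
            f"MShd{tag}up": pulse.max_rate(pulse.peak_time, t_e),
            f"MAhd{tag}down": pulse.max_accel(t_s, pulse.peak_time),
        }, ke

    h1, ke1 = exp_hyoid(hd1p, "1")
    h2, ke2 = exp_hyoid(hd2p, "2")
    t_g0 = gape.crossing(detection.onset_frac, "rise")
    t_gc = gape.crossing(detection.onset_frac, "fall")
    expected = {
        "MG": p["MG"],
        "TMG": (k_gp - k0) / fps,
        "MGA": true["MGA"],
        "DG": (k_gc - k0) / fps,
        "MSGO": gape.max_rate(t_g0, gape.peak_time),
        "MAGO": gape.max_accel(t_g0, gape.peak_time),
        "MSGC": gape.max_rate(gape.peak_time, t_gc),
        "MAGC": gape.max_accel(gape.peak_time, t_gc),
        "MHA": true["MHA"],
        "TMHA": (k_peak(head) - k0) / fps,
        **h1,
        **h2,
    }
    expected["PCD"] = (max(k_gc, ke1, ke2) - k0) / fps
    return true, expected


# ---------------------------------------------------------------------------
# Bout generation
# ---------------------------------------------------------------------------

def generate_bout(
    ind: Individual,
    config: SimConfig,
    rng: np.random.Generator,
    bout_index: int = 1,
    detection: DetectionConfig | None = None,
) -> tuple[LandmarkTrajectory, GroundTruth]:
    """Simulate one feeding bout for an individual.

    Returns the (noisy, calibrated) landmark trajectory together with its
    ground truth.  Raises if the drawn gape cycle would span fewer than 4
    frames at the configured frame rate.
    """
    detection = detection or DetectionConfig()
    params, effort = _draw_params(ind, config, rng)
    if (params["DGO"] + params["DGC"]) * config.fps < 4:
        raise ValueError("gape cycle shorter than 4 frames; raise fps or sizes")
    template = HeadTemplate(svl=ind.svl)
    t_on = _bout_margin(params, config)
    true, expected = _analytic_records(params, template, detection,
                                       config.fps, t_on)
    pulses = _bout_pulses(params, t_on)

    t_end = 2.0 * t_on + true["PCD"]
    n = int(math.ceil(t_end * config.fps))
    n = int(math.ceil(n / 100.0)) * 100   # pad: few distinct lengths to smooth
    t = np.arange(n) / config.fps

    gape = template.rest_gape + pulses["gape"].value(t)
    theta = 2.0 * np.arcsin(gape / (2.0 * template.r_jaw))
    lj_angle = template.uj_angle + theta      # y down: +angle opens downward
    lj = template.r_jaw * np.column_stack([np.cos(lj_angle), np.sin(lj_angle)])

    def hyoid_path(rest: np.ndarray, tag: str) -> np.ndarray:
        h = pulses[f"hd{tag}"].value(t)
        direction = rest / np.hypot(*rest)    # radially away from am (origin)
        return rest + np.outer(h, direction)

    rho, psi0, _, sign = template.head_geometry()
    phi = np.radians(pulses["head"].value(t))
    psi = psi0 + sign * phi
    sh = template.e + rho * np.column_stack([np.cos(psi), np.sin(psi)])

    n_frames = n
    paths = {
        "e": np.tile(template.e, (n_frames, 1)),
        "uj": np.tile(template.uj, (n_frames, 1)),
        "lj": lj,
        "am": np.zeros((n_frames, 2)),
        "hd1": hyoid_path(template.hd1_rest, "1"),
        "hd2": hyoid_path(template.hd2_rest, "2"),
        "sh": sh,
    }

    scale = config.scale_for(ind.svl)
    noise_cm = config.noise_px * scale
    landmarks = {}
    for name, xy in paths.items():
        noisy = xy + rng.normal(0.0, noise_cm, size=xy.shape)
        conf = rng.uniform(0.95, 1.0, size=n_frames)
        if config.outlier_prob > 0:
            bad = rng.random(n_frames) < config.outlier_prob
            noisy[bad] += rng.normal(0.0, config.outlier_sd_px * scale,
                                     size=(bad.sum(), 2))
            conf[bad] = rng.uniform(0.0, 0.5, size=bad.sum())
        landmarks[name] = np.column_stack([noisy, conf])

    bout_id = f"{ind.individual_id}_b{bout_index:02d}"
    traj = LandmarkTrajectory(
        bout_id=bout_id,
        individual_id=ind.individual_id,
        stage=ind.stage,
        fps=config.fps,
        scale=scale,
        t=t,
        landmarks=landmarks,
    )
    gt = GroundTruth(
        bout_id=bout_id, individual_id=ind.individual_id, stage=ind.stage,
        svl=ind.svl, quality=ind.quality, effort=effort,
        params=params, true=true, expected=expected,
    )
    return traj, gt


def simulate_cohort(
    config: SimConfig,
    seed: int,
    detection: DetectionConfig | None = None,
) -> tuple[list[tuple[LandmarkTrajectory, GroundTruth]], list[Individual]]:
    """Simulate a full study: cohort, then 1-8 bouts per individual."""
    rng = np.random.default_rng(seed)
    individuals = sample_cohort(config, rng)
    bouts = []
    for ind in individuals:
        k = int(rng.integers(config.bouts_min, config.bouts_max + 1))
        for b in range(1, k + 1):
            bouts.append(generate_bout(ind, config, rng, b, detection))
    return bouts, individuals


def conditional_expected_record(
    ind: Individual,
    config: SimConfig,
    detection: DetectionConfig | None = None,
) -> dict[str, float]:
    """Noise-free expected measurements for an individual's typical bout.

    Conditional on the individual's realised random effects; bout-level
    noise and effort set to zero.  This is the individual-level truth that
    peak aggregation and the scaling regressions should recover.
    """
    detection = detection or DetectionConfig()
    params = _expected_params(ind, config)
    template = HeadTemplate(svl=ind.svl)
    _, expected = _analytic_records(params, template, detection,
                                    config.fps, _bout_margin(params, config))
    return expected


def generating_slopes(
    individuals: list[Individual],
    config: SimConfig,
    detection: DetectionConfig | None = None,
) -> dict[str, float]:
    """Imposed log-log slope of every variable over a realised cohort.

    Computed by regressing the log10 noise-free expected value (conditional
    on each individual's random effects) on log10 SVL.  For variables whose
    generating law is an exact power law this returns the configured slope;
    for composite variables (onset sums, the bout-duration maximum) it is
    the slope actually imposed on this cohort.
    """
    recs = [conditional_expected_record(ind, config, detection)
            for ind in individuals]
    x = np.log10([ind.svl for ind in individuals])
    out = {}
    for var in KINEMATIC_VARIABLES:
        y = np.log10([r[var] for r in recs])
        out[var] = float(np.polyfit(x, y, 1)[0])
    return out


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_cohort(
    bouts: list[tuple[LandmarkTrajectory, GroundTruth]],
    out_dir,
    config: SimConfig | None = None,
    seed: int | None = None,
) -> None:
    """Write pose CSVs (tracker dialect, pixel units), metadata and ground
    truth under ``out_dir``; a manifest records the seed and config."""
    os.makedirs(out_dir, exist_ok=True)
    pose_dir = os.path.join(out_dir, "pose")
    os.makedirs(pose_dir, exist_ok=True)
    meta_rows, gt_rows = [], []
    for traj, gt in bouts:
        n = traj.n_frames
        scale = traj.scale
        cols = {("sim", "frame", "coords"): np.arange(n)}
        for name in traj.landmarks:
            arr = traj.landmarks[name]
            cols[("sim", name, "x")] = arr[:, 0] / scale
            cols[("sim", name, "y")] = arr[:, 1] / scale
            cols[("sim", name, "likelihood")] = arr[:, 2]
        df = pd.DataFrame(cols)
        df.columns = pd.MultiIndex.from_tuples(
            df.columns, names=["scorer", "bodyparts", "coords"])
        df.to_csv(os.path.join(pose_dir, f"{traj.bout_id}.csv"),
                  index=False, float_format="%.10g")
        gt_rows.append({
            "bout_id": gt.bout_id, "individual_id": gt.individual_id,
            "stage": gt.stage, "svl": gt.svl,
            **{f"param_{k}": v for k, v in gt.params.items()},
            **{f"true_{k}": v for k, v in gt.true.items()},
            **{f"expected_{k}": v for k, v in gt.expected.items()},
        })
    seen = {}
    for traj, gt in bouts:
        seen.setdefault(gt.individual_id, (gt.stage, gt.svl, traj.scale))
    meta_rows = [{"individual_id": k, "stage": v[0], "svl": v[1],
                  "pixels_per_square": (config.calibration.square_size
                                        if config else 0.5) / v[2]}
                 for k, v in seen.items()]
    pd.DataFrame(meta_rows).to_csv(
        os.path.join(out_dir, "individuals.csv"), index=False, float_format="%.10g")
    pd.DataFrame(gt_rows).to_csv(
        os.path.join(out_dir, "ground_truth.csv"), index=False, float_format="%.10g")
    manifest = {
        "seed": seed,
        "n_bouts": len(bouts),
        "fps": bouts[0][0].fps,
        "square_size_cm": (config.calibration.square_size if config else 0.5),
        "note": "per-individual pixels_per_square in individuals.csv "
                "(camera framed to the animal)",
    }
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)


# ---------------------------------------------------------------------------
# Record tier
# ---------------------------------------------------------------------------

def sample_records(
    config: SimConfig,
    seed: int,
    individuals: list[Individual] | None = None,
) -> pd.DataFrame:
    """Per-bout table of the 25 variables drawn from per-variable laws.

    Unlike the trajectory tier, every variable gets its own independent
    random effects, so stage-specific slopes can be imposed per variable;
    this is the input for the mixed-model suites.
    """
    rng = np.random.default_rng(seed)
    if individuals is None:
        individuals = sample_cohort(config, rng)
    centers = config.stage_centers()
    rows = []
    for ind in individuals:
        u = {k: rng.normal(0.0, law.sd_individual)
             for k, law in config.record_laws.items()}
        k_bouts = int(rng.integers(config.bouts_min, config.bouts_max + 1))
        for b in range(1, k_bouts + 1):
            row = {"bout_id": f"{ind.individual_id}_b{b:02d}",
                   "individual_id": ind.individual_id,
                   "stage": ind.stage, "svl": ind.svl}
            for var, law in config.record_laws.items():
                e = rng.normal(0.0, law.sd_bout)
                row[var] = 10.0 ** (law.log_value(
                    ind.stage, math.log10(ind.svl), centers[ind.stage])
                    + u[var] + e)
            rows.append(row)
    return pd.DataFrame(rows)


def sample_null_records(
    rng: np.random.Generator,
    config: SimConfig | None = None,
    sd_individual: float = 0.10,
    sd_bout: float = 0.10,
) -> pd.DataFrame:
    """One null response (no size or stage effect) over the study shape.

    The returned frame has the usual metadata plus a single column ``y``
    made of an individual random intercept and bout noise only; used for
    type-I-error calibration of the ANCOVA machinery.
    """
    config = config or SimConfig()
    individuals = sample_cohort(config, rng)
    rows = []
    for ind in individuals:
        u = rng.normal(0.0, sd_individual)
        k_bouts = int(rng.integers(config.bouts_min, config.bouts_max + 1))
        for b in range(1, k_bouts + 1):
            rows.append({"individual_id": ind.individual_id, "stage": ind.stage,
                         "svl": ind.svl,
                         "y": u + rng.normal(0.0, sd_bout)})
    return pd.DataFrame(rows)
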