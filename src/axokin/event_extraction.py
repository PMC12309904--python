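"""Feeding-bout segmentation and extraction of the 25 kinematic variables.

A suction-feeding bout starts when the mouth begins to open and ends when
the hyobranchial apparatus has returned to its initial position (or, if it
plateaus, when it stops moving).  From the smoothed landmark trajectories
five signals are derived:

* **gape** — distance between the upper- and lower-jaw tips (uj-lj), cm;
* **gape angle** — angle at the jaw joint (am) between the jaw tips, deg;
* **head angle** — angle at the eye (e) between the upper-jaw tip and the
  shoulder (sh), deg;
* **hyoid-1 / hyoid-2 depression** — distance of each hyoid point (hd1,
  hd2) to the jaw joint, minus its pre-bout baseline, cm.  Depression (the
  hyoid moving away from the jaw joint) is positive.

Event marks are threshold crossings of each signal's excursion above its
pre-bout baseline; all reported times are relative to mouth-opening onset.
The 25 per-bout variables follow the standard naming for aquatic-feeding
kinematics (MG, TMG, MGA, DG, MSGO, MAGO, ... PCD); see
:data:`KINEMATIC_VARIABLES`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Mapping

import numpy as np

from .kinematics_core import DEFAULT_DF, SmoothedSignal, smooth_series, vertex_angle
from .trajectory_io import LandmarkTrajectory

__all__ = [
    "KINEMATIC_VARIABLES",
    "DetectionConfig",
    "KinematicProfile",
    "EventMarks",
    "KinematicRecord",
    "BoutDetectionError",
    "build_profile",
    "detect_events",
    "extract_variables",
    "process_trajectory",
]

#: The 25 kinematic variables, in canonical (output-table) order.
KINEMATIC_VARIABLES = (
    "MG",          # maximum gape distance (cm)
    "TMG",         # time to maximum gape (s)
    "MGA",         # maximum gape angle (deg)
    "DG",          # duration of the gape cycle (s)
    "MSGO",        # maximum speed of jaw opening (cm/s)
    "MAGO",        # maximum acceleration of jaw opening (cm/s^2)
    "MSGC",        # maximum speed of jaw closing (cm/s)
    "MAGC",        # maximum acceleration of jaw closing (cm/s^2)
    "MHA",         # maximum head angle (deg)
    "TMHA",        # time to maximum head angle (s)
    "Thd1",        # time anterior hyoid begins to depress (s)
    "Mhd1",        # maximum anterior hyoid depression (cm)
    "TMhd1",       # time to maximum anterior hyoid depression (s)
    "Dhd1",        # duration of the anterior hyoid cycle (s)
    "MShd1down",   # max speed of anterior hyoid depression (cm/s)
    "MShd1up",     # max speed of anterior hyoid elevation (cm/s)
    "MAhd1down",   # max acceleration of anterior hyoid depression (cm/s^2)
    "Thd2",        # time posterior hyoid begins to depress (s)
    "Mhd2",        # maximum posterior hyoid depression (cm)
    "TMhd2",       # time to maximum posterior hyoid depression (s)
    "Dhd2",        # duration of the posterior hyoid cycle (s)
    "MShd2down",   # max speed of posterior hyoid depression (cm/s)
    "MAhd2down",   # max acceleration of posterior hyoid depression (cm/s^2)
    "MShd2up",     # max speed of posterior hyoid elevation (cm/s)
    "PCD",         # prey-capture duration: mouth opening -> hyoid return (s)
)


class BoutDetectionError(RuntimeError):
    """Raised when no feeding bout can be located in a profile."""


@dataclass(frozen=True)
class DetectionConfig:
    """Operational thresholds for event detection.

    onset_frac
        A cycle starts/ends where the excursion crosses this fraction of its
        peak (above the pre-bout baseline).
    return_frac
        The hyoid counts as "returned" when its excursion falls back below
        this fraction of its peak.
    stillness_frac, dwell_frames
        Fallback for hyoid pulses that plateau instead of returning: the
        cycle ends at the start of the first run of ``dwell_frames`` frames
        whose |d1| stays below ``stillness_frac`` of the signal's peak |d1|.
    baseline_frames
        Length of the pre-bout window whose median defines each signal's
        baseline.
    """

    onset_frac: float = 0.05
    return_frac: float = 0.10
    stillness_frac: float = 0.05
    dwell_frames: int = 10
    baseline_frames: int = 30
    smoothing_df: float = DEFAULT_DF


@dataclass
class KinematicProfile:
    """Smoothed bout signals sharing a single time base."""

    bout_id: str
    individual_id: str
    stage: str
    fps: float
    t: np.ndarray
    gape: SmoothedSignal
    gape_angle: SmoothedSignal
    head_angle: SmoothedSignal
    hyoid1: SmoothedSignal
    hyoid2: SmoothedSignal
    baselines: dict[str, float]
    usable: bool = True
    flags: list[str] = field(default_factory=list)


@dataclass
class EventMarks:
    """Absolute event times (seconds on the recording clock) for one bout."""

    t0_mouth_open: float
    t_peak_gape: float
    t_mouth_closed: float
    t_hd1_start: float
    t_hd1_peak: float
    t_hd1_end: float
    t_hd2_start: float
    t_hd2_peak: float
    t_hd2_end: float
    t_bout_end: float
    plateau_ended: bool = False


@dataclass
class KinematicRecord:
    """The 25 kinematic variables for one bout, plus its metadata."""

    bout_id: str
    individual_id: str
    stage: str
    svl: float
    MG: float
    TMG: float
    MGA: float
    DG: float
    MSGO: float
    MAGO: float
    MSGC: float
    MAGC: float
    MHA: float
    TMHA: float
    Thd1: float
    Mhd1: float
    TMhd1: float
    Dhd1: float
    MShd1down: float
    MShd1up: float
    MAhd1down: float
    Thd2: float
    Mhd2: float
    TMhd2: float
    Dhd2: float
    MShd2down: float
    MAhd2down: float
    MShd2up: float
    PCD: float

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}

    def kinematics(self) -> dict[str, float]:
        """Only the 25 kinematic fields, in canonical order."""
        return {k: getattr(self, k) for k in KINEMATIC_VARIABLES}


# ---------------------------------------------------------------------------
# Profile construction
# ---------------------------------------------------------------------------

def build_profile(
    traj: LandmarkTrajectory,
    config: DetectionConfig | None = None,
) -> KinematicProfile:
    """Smooth the landmark coordinates and derive the five bout signals.

    The x and y series of every landmark are smoothed first (as the raw
    tracker output is what carries the observation noise) and all distances
    and angles are computed from the smoothed coordinates.
    """
    config = config or DetectionConfig()
    t = traj.t
    sm: dict[str, np.ndarray] = {}
    for name in traj.landmarks:
        xy = traj.xy(name)
        sx, _ = smooth_series(t, xy[:, 0], config.smoothing_df)
        sy, _ = smooth_series(t, xy[:, 1], config.smoothing_df)
        sm[name] = np.column_stack([sx, sy])

    gape = np.hypot(*(sm["uj"] - sm["lj"]).T)
    gape_angle = vertex_angle(sm["am"], sm["uj"], sm["lj"])
    head_angle = vertex_angle(sm["e"], sm["uj"], sm["sh"])
    hd1 = np.hypot(*(sm["hd1"] - sm["am"]).T)
    hd2 = np.hypot(*(sm["hd2"] - sm["am"]).T)

    nb = min(config.baseline_frames, t.size)
    baselines = {
        "gape": float(np.median(gape[:nb])),
        "gape_angle": float(np.median(gape_angle[:nb])),
        "head_angle": float(np.median(head_angle[:nb])),
        "hyoid1": float(np.median(hd1[:nb])),
        "hyoid2": float(np.median(hd2[:nb])),
    }
    # hyoid excursion is signed so that depression (away from the jaw joint)
    # is positive
    mk = lambda v: SmoothedSignal(t=t, value=v, effective_df=config.smoothing_df)
    return KinematicProfile(
        bout_id=traj.bout_id,
        individual_id=traj.individual_id,
        stage=traj.stage,
        fps=traj.fps,
        t=t,
        gape=mk(gape),
        gape_angle=mk(gape_angle),
        head_angle=mk(head_angle),
        hyoid1=mk(hd1 - baselines["hyoid1"]),
        hyoid2=mk(hd2 - baselines["hyoid2"]),
        baselines=baselines,
        usable=traj.usable,
        flags=list(traj.flags),
    )


# ---------------------------------------------------------------------------
# Event detection
# ---------------------------------------------------------------------------

def _cycle_marks(
    t: np.ndarray,
    excursion: np.ndarray,
    d1: np.ndarray,
    onset_frac: float,
    return_frac: float,
    stillness_frac: float,
    dwell: int,
    noise_floor: float,
) -> tuple[int, int, int, bool]:
    """Start / peak / end indices of one excursion pulse.

    The peak is the global maximum (earliest sample on ties).  The start is
    the last sample before the peak at which the excursion is still at or
    below ``onset_frac`` of the peak; the end is the first sample after the
    peak at or below ``return_frac`` of the peak, falling back to a
    stillness criterion when the signal plateaus.
    """
    peak = float(np.max(excursion))
    if peak <= noise_floor:
        raise BoutDetectionError("no excursion pulse exceeds the noise floor")
    k_peak = int(np.argmax(excursion))  # argmax takes the earliest tie

    below = np.flatnonzero(excursion[:k_peak] <= onset_frac * peak)
    k_start = int(below[-1]) if below.size else 0

    after = excursion[k_peak:]
    ret = np.flatnonzero(after <= return_frac * peak)
    if ret.size:
        return k_start, k_peak, k_peak + int(ret[0]), False
    # plateau: first dwell-long run of near-zero rate after the peak
    still = np.abs(d1[k_peak:]) < stillness_frac * float(np.max(np.abs(d1)))
    run = 0
    for i, s in enumerate(still):
        run = run + 1 if s else 0
        if run >= dwell:
            return k_start, k_peak, k_peak + i - dwell + 1, True
    return k_start, k_peak, t.size - 1, True


def detect_events(
    profile: KinematicProfile,
    config: DetectionConfig | None = None,
) -> EventMarks:
    """Locate the gape cycle and both hyoid cycles in a bout profile."""
    config = config or DetectionConfig()
    t = profile.t
    gape_exc = profile.gape.value - profile.baselines["gape"]
    g0, gp, gc, _ = _cycle_marks(
        t, gape_exc, profile.gape.d1_grid,
        config.onset_frac, config.onset_frac,
        config.stillness_frac, config.dwell_frames, 0.0,
    )
    plateau = False
    hyoid_marks = {}
    for name, sig in (("hd1", profile.hyoid1), ("hd2", profile.hyoid2)):
        s, p, e, plat = _cycle_marks(
            t, sig.value, sig.d1_grid,
            config.onset_frac, config.return_frac,
            config.stillness_frac, config.dwell_frames, 0.0,
        )
        plateau |= plat
        hyoid_marks[name] = (s, p, e)
    if plateau:
        profile.flags.append("plateau-ended")

    (h1s, h1p, h1e) = hyoid_marks["hd1"]
    (h2s, h2p, h2e) = hyoid_marks["hd2"]
    t_bout_end = float(t[max(gc, h1e, h2e)])
    return EventMarks(
        t0_mouth_open=float(t[g0]),
        t_peak_gape=float(t[gp]),
        t_mouth_closed=float(t[gc]),
        t_hd1_start=float(t[h1s]),
        t_hd1_peak=float(t[h1p]),
        t_hd1_end=float(t[h1e]),
        t_hd2_start=float(t[h2s]),
        t_hd2_peak=float(t[h2p]),
        t_hd2_end=float(t[h2e]),
        t_bout_end=t_bout_end,
        plateau_ended=plateau,
    )


# ---------------------------------------------------------------------------
# Variable extraction
# ---------------------------------------------------------------------------

def _win(t: np.ndarray, lo: float, hi: float, name: str) -> np.ndarray:
    m = (t >= lo - 1e-12) & (t <= hi + 1e-12)
    if not m.any():
        raise BoutDetectionError(f"empty time window for variable {name}")
    return m


def _max_abs(series: np.ndarray, mask: np.ndarray, name: str) -> float:
    if not mask.any():
        raise BoutDetectionError(f"empty time window for variable {name}")
    return float(np.max(np.abs(series[mask])))


def extract_variables(
    profile: KinematicProfile,
    events: EventMarks,
    svl: float = float("nan"),
) -> KinematicRecord:
    """Compute the 25 kinematic variables from a profile and its events.

    All times are reported relative to mouth-opening onset; speeds and
    accelerations are reported as magnitudes.
    """
    t = profile.t
    t0 = events.t0_mouth_open
    gape_exc = profile.gape.value - profile.baselines["gape"]
    d1g, d2g = profile.gape.d1_grid, profile.gape.d2_grid

    open_w = _win(t, t0, events.t_peak_gape, "MSGO")
    close_w = _win(t, events.t_peak_gape, events.t_mouth_closed, "MSGC")
    bout_w = _win(t, t0, events.t_bout_end, "MHA")

    mg = float(np.max(gape_exc))
    mga = float(np.max(profile.gape_angle.value[bout_w]))
    mha = float(np.max(profile.head_angle.value[bout_w]))
    # earliest tie within the bout window
    k_mha = int(np.flatnonzero(bout_w)[np.argmax(profile.head_angle.value[bout_w])])

    def hyoid_vars(sig: SmoothedSignal, s: float, p: float, e: float, tag: str):
        down_w = _win(t, s, p, f"MShd{tag}down")
        up_w = _win(t, p, e, f"MShd{tag}up")
        m = float(np.max(sig.value))
        return {
            f"Thd{tag}": s - t0,
            f"Mhd{tag}": m,
            f"TMhd{tag}": p - t0,
            f"Dhd{tag}": e - s,
            f"MShd{tag}down": _max_abs(sig.d1_grid, down_w, f"MShd{tag}down"),
            f"MShd{tag}up": _max_abs(sig.d1_grid, up_w, f"MShd{tag}up"),
            f"MAhd{tag}down": _max_abs(sig.d2_grid, down_w, f"MAhd{tag}down"),
        }

    h1 = hyoid_vars(profile.hyoid1, events.t_hd1_start, events.t_hd1_peak,
                    events.t_hd1_end, "1")
    h2 = hyoid_vars(profile.hyoid2, events.t_hd2_start, events.t_hd2_peak,
                    events.t_hd2_end, "2")

    return KinematicRecord(
        bout_id=profile.bout_id,
        individual_id=profile.individual_id,
        stage=profile.stage,
        svl=svl,
        MG=mg,
        TMG=events.t_peak_gape - t0,
        MGA=mga,
        DG=events.t_mouth_closed - t0,
        MSGO=_max_abs(d1g, open_w, "MSGO"),
        MAGO=_max_abs(d2g, open_w, "MAGO"),
        MSGC=_max_abs(d1g, close_w, "MSGC"),
        MAGC=_max_abs(d2g, close_w, "MAGC"),
        MHA=mha,
        TMHA=float(t[k_mha]) - t0,
        PCD=events.t_bout_end - t0,
        **h1,
        **h2,
    )


def process_trajectory(
    traj: LandmarkTrajectory,
    svl: float,
    config: DetectionConfig | None = None,
) -> KinematicRecord:
    """Convenience pipeline: profile -> events -> record for one bout."""
    config = config or DetectionConfig()
    profile = build_profile(traj, config)
    if not profile.usable:
        raise BoutDetectionError(
            f"bout {traj.bout_id} flagged unusable: {'; '.join(profile.flags)}"
        )
    events = detect_events(profile, config)
    return extract_variables(profile, events, svl=svl)
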