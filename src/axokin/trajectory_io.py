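"""Reading, calibrating and validating pose-tracking landmark tables.

The input dialect is the CSV layout exported by markerless pose trackers
such as DeepLabCut: three header rows (``scorer`` / ``bodyparts`` /
``coords``) followed by one row per video frame with ``x``, ``y`` and
``likelihood`` columns per tracked body part, in pixels.  Seven landmarks on
the head are expected:

====  =====================================================
e     eye
uj    tip of the upper jaw
lj    tip of the lower jaw
am    angle (corner) of the mouth, used as the jaw joint
hd1   anterior hyoid point (ceratohyal-basibranchial junction)
hd2   posterior hyoid point (ceratobranchial-basibranchial junction)
sh    shoulder
====  =====================================================

Pixel coordinates are converted to cm with a single global scale obtained
from a checkerboard of known square size placed in the tank.  The image
y-axis points down; all downstream geometry uses distances and angles only,
so no axis flip is performed (hyoid depression is defined through the
distance to the jaw joint, not through y).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LANDMARKS",
    "CalibrationSpec",
    "IndividualMeta",
    "LandmarkTrajectory",
    "PoseTableError",
    "read_pose_table",
    "fill_low_confidence",
    "write_kinematics_table",
    "read_kinematics_table",
]

#: Canonical landmark names, anterior to posterior.
LANDMARKS = ("e", "uj", "lj", "am", "hd1", "hd2", "sh")

#: Default gap-filling thresholds: samples below this tracking confidence are
#: replaced by linear interpolation, across gaps of at most this many frames
#: (20 ms at 1000 frames/s).
DEFAULT_MIN_CONFIDENCE = 0.9
DEFAULT_MAX_GAP = 20


class PoseTableError(ValueError):
    """Raised when a pose table does not conform to the expected dialect."""


@dataclass(frozen=True)
class CalibrationSpec:
    """Pixel-to-cm calibration from a checkerboard of known square size."""

    pixels_per_square: float
    square_size: float = 0.5  # cm

    def __post_init__(self) -> None:
        if self.pixels_per_square <= 0 or self.square_size <= 0:
            raise ValueError("calibration lengths must be positive")

    @property
    def scale(self) -> float:
        """cm per pixel."""
        return self.square_size / self.pixels_per_square


@dataclass
class IndividualMeta:
    """Per-individual metadata: stage and snout-vent length (SVL)."""

    individual_id: str
    stage: str
    svl_measurements: Sequence[float]

    def __post_init__(self) -> None:
        if self.stage not in ("larva", "juvenile", "adult"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if not len(self.svl_measurements):
            raise ValueError("need at least one SVL measurement")
        if any(v <= 0 for v in self.svl_measurements):
            raise ValueError("SVL measurements must be positive")

    @property
    def svl(self) -> float:
        """Mean of the per-video SVL measurements, in cm."""
        return float(np.mean(self.svl_measurements))


@dataclass
class LandmarkTrajectory:
    """Calibrated landmark time series for one recorded feeding bout.

    ``landmarks[name]`` is an (n, 3) array of x (cm), y (cm) and tracking
    confidence per frame.  ``usable`` is cleared (with a reason appended to
    ``flags``) when gap-filling cannot rescue the bout.
    """

    bout_id: str
    individual_id: str
    stage: str
    fps: float
    scale: float
    t: np.ndarray
    landmarks: dict[str, np.ndarray]
    usable: bool = True
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fps <= 0 or self.scale <= 0:
            raise ValueError("fps and scale must be positive")
        missing = [k for k in LANDMARKS if k not in self.landmarks]
        if missing:
            raise PoseTableError(f"missing landmarks: {', '.join(missing)}")
        n = self.t.size
        for name, arr in self.landmarks.items():
            if arr.shape != (n, 3):
                raise ValueError(f"landmark {name!r} has shape {arr.shape}, expected ({n}, 3)")
        dt = np.diff(self.t)
        if n > 1 and np.any(np.abs(dt - 1.0 / self.fps) > 1e-9):
            raise ValueError("t must be uniform with spacing 1/fps")

    @property
    def n_frames(self) -> int:
        return self.t.size

    def xy(self, name: str) -> np.ndarray:
        """(n, 2) x/y coordinates of one landmark, in cm."""
        return self.landmarks[name][:, :2]


def read_pose_table(
    path,
    fps: float,
    calibration: CalibrationSpec,
    *,
    bout_id: str = "",
    individual_id: str = "",
    stage: str = "larva",
    aliases: Mapping[str, str] | None = None,
) -> LandmarkTrajectory:
    """Read a 3-header-row pose CSV into a calibrated trajectory.

    Parameters
    ----------
    path
        CSV file (or file-like object) in the scorer/bodyparts/coords
        dialect, with or without a leading frame-index column.
    fps
        Recording frame rate; the time base is forced to ``t[k] = k / fps``.
    calibration
        Pixel-to-cm conversion.
    aliases
        Optional map from body-part labels found in the file to the seven
        canonical landmark names (tracker projects rename landmarks freely).
    """
    if fps <= 0:
        raise ValueError("fps must be positive")
    try:
        df = pd.read_csv(path, header=[0, 1, 2])
    except Exception as exc:  # noqa: BLE001 - reported as a dialect problem
        raise PoseTableError(f"could not parse pose table {path!r}: {exc}") from exc
    if df.columns.nlevels != 3:
        raise PoseTableError("expected 3 header rows (scorer / bodyparts / coords)")

    # optional leading frame-index column: coords level named like an index
    first = df.columns[0]
    if str(first[2]).lower() in ("coords", "index", "frame", ""):
        idx = pd.to_numeric(df[first], errors="coerce").to_numpy()
        if np.any(~np.isfinite(idx)) or np.any(np.diff(idx) != 1):
            raise PoseTableError("non-uniform frame index column")
        df = df.drop(columns=[first])

    aliases = dict(aliases or {})
    cols: dict[str, dict[str, np.ndarray]] = {}
    for scorer, bodypart, coord in df.columns:
        name = aliases.get(bodypart, bodypart)
        coord = str(coord).lower()
        if coord not in ("x", "y", "likelihood"):
            raise PoseTableError(f"unexpected coords label {coord!r}")
        cols.setdefault(name, {})[coord] = pd.to_numeric(
            df[(scorer, bodypart, coord)], errors="coerce"
        ).to_numpy(dtype=float)

    missing = [k for k in LANDMARKS if k not in cols]
    if missing:
        raise PoseTableError(f"missing landmarks: {', '.join(missing)}")

    n = len(df)
    landmarks = {}
    for name in LANDMARKS:
        parts = cols[name]
        if "x" not in parts or "y" not in parts:
            raise PoseTableError(f"landmark {name!r} lacks x/y columns")
        conf = parts.get("likelihood", np.ones(n))
        arr = np.column_stack(
            [parts["x"] * calibration.scale, parts["y"] * calibration.scale, conf]
        )
        landmarks[name] = arr

    if not bout_id:
        bout_id = os.path.splitext(os.path.basename(str(path)))[0] if not isinstance(
            path, io.IOBase
        ) else "bout"
    return LandmarkTrajectory(
        bout_id=bout_id,
        individual_id=individual_id or bout_id,
        stage=stage,
        fps=fps,
        scale=calibration.scale,
        t=np.arange(n) / fps,
        landmarks=landmarks,
    )


def _fill_one(
    xy: np.ndarray, good: np.ndarray, max_gap: int
) -> tuple[np.ndarray, bool, int]:
    """Linearly interpolate bad samples of one coordinate column.

    Returns (filled, rescued, longest_unfilled_gap).  Interior gaps longer
    than ``max_gap`` and boundary gaps are only filled when short enough;
    boundary gaps are padded with the nearest good value.
    """
    n = xy.size
    idx = np.flatnonzero(good)
    if idx.size == 0:
        return xy, False, n
    # longest run of bad frames (boundary runs included)
    bad = ~good
    runs = []
    k = 0
    while k < n:
        if bad[k]:
            j = k
            while j < n and bad[j]:
                j += 1
            runs.append(j - k)
            k = j
        else:
            k += 1
    longest = max(runs) if runs else 0
    if longest > max_gap:
        return xy, False, longest
    filled = np.interp(np.arange(n), idx, xy[idx])
    return filled, True, longest


def fill_low_confidence(
    traj: LandmarkTrajectory,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    max_gap: int = DEFAULT_MAX_GAP,
) -> LandmarkTrajectory:
    """Replace low-confidence samples by linear interpolation.

    Samples with tracking confidence below ``min_confidence`` are treated as
    missing and linearly interpolated across gaps of at most ``max_gap``
    frames.  A longer gap (including at the sequence boundary) marks the bout
    unusable rather than silently inventing data.
    """
    if not 0 <= min_confidence <= 1:
        raise ValueError("min_confidence must lie in [0, 1]")
    new_landmarks: dict[str, np.ndarray] = {}
    usable = traj.usable
    flags = list(traj.flags)
    for name in LANDMARKS:
        arr = traj.landmarks[name].copy()
        good = arr[:, 2] >= min_confidence
        good &= np.isfinite(arr[:, 0]) & np.isfinite(arr[:, 1])
        if good.all():
            new_landmarks[name] = arr
            continue
        for col in (0, 1):
            filled, ok, longest = _fill_one(arr[:, col], good, max_gap)
            arr[:, col] = filled
            if not ok:
                usable = False
                flag = f"gap of {longest} frames > max_gap={max_gap} on {name}"
                if flag not in flags:
                    flags.append(flag)
        new_landmarks[name] = arr
    return LandmarkTrajectory(
        bout_id=traj.bout_id,
        individual_id=traj.individual_id,
        stage=traj.stage,
        fps=traj.fps,
        scale=traj.scale,
        t=traj.t,
        landmarks=new_landmarks,
        usable=usable,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Kinematics tables
# ---------------------------------------------------------------------------

def write_kinematics_table(records: Iterable, path) -> pd.DataFrame:
    """Write extracted kinematic records as a tidy CSV, one row per bout.

    Columns are the bout metadata followed by the 25 kinematic variables in
    their canonical order.  Returns the DataFrame that was written.
    """
    from .event_extraction import KINEMATIC_VARIABLES  # local import: no cycle

    rows = [r.to_dict() if hasattr(r, "to_dict") else dict(r) for r in records]
    meta_cols = ["bout_id", "individual_id", "stage", "svl"]
    df = pd.DataFrame(rows, columns=meta_cols + list(KINEMATIC_VARIABLES))
    df.to_csv(path, index=False, float_format="%.12g")
    return df


def read_kinematics_table(path) -> pd.DataFrame:
    """Read a kinematics table written by :func:`write_kinematics_table`."""
    from .event_extraction import KINEMATIC_VARIABLES

    df = pd.read_csv(path)
    missing = [c for c in KINEMATIC_VARIABLES if c not in df.columns]
    if missing:
        raise ValueError(f"kinematics table lacks columns: {', '.join(missing)}")
    return df
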