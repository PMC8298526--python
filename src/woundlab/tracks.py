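"""Per-cell migration statistics from nucleus-centroid tracks.

A tracked cell is the time-stamped path of its nucleus centroid.  From it we
derive the eight whole-course statistics used to characterise directed
migration toward a scratch wound:

* trajectory length ``T`` — summed inter-frame path length (μm)
* displacement ``D`` — straight-line start→end distance (μm), with its angle
* straightness ``S = D/T`` in [0, 1]
* orientation ``O = cos(displacement angle − wound-closure angle)`` in [−1, 1]
* polarity index ``P = S·O`` in [−1, 1]
* speed T = T/Δt and speed D = D/Δt (μm/h)
* polarized speed = speed D · P — effective speed toward wound closure

The wound-closure direction is the optimal closure vector, perpendicular to
the scratch.  Orientation and polarity are undefined for a cell with zero net
displacement; such cells are reported as missing and counted separately in
group summaries rather than silently scored 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class TrackedCell:
    """Time-stamped nucleus path plus the wound-closure reference direction.

    ``t`` is in hours (strictly increasing, >= 2 points); ``x``/``y`` in μm
    using the image convention (x right, y down).  ``wound_direction_deg`` is
    the optimal closure direction in degrees, same angular convention as the
    coordinates.
    """

    cell_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    wound_direction_deg: float = 0.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.x = np.asarray(self.x, float)
        self.y = np.asarray(self.y, float)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must have equal length")
        if len(self.t) < 2:
            raise ValueError("a track needs at least 2 points")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        self.wound_direction_deg = float(np.mod(self.wound_direction_deg, 360.0))

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class MigrationMetrics:
    """The eight per-cell track statistics (NaN where undefined)."""

    cell_id: str
    trajectory_len: float
    displacement: float
    displacement_angle_deg: float
    straightness: float
    orientation: float
    polarity_index: float
    speed_T: float
    speed_D: float
    polarized_speed: float


def path_length(track: TrackedCell) -> float:
    """Total trajectory length T: sum of Euclidean inter-point distances."""
    steps = np.hypot(np.diff(track.x), np.diff(track.y))
    return float(steps.sum())


def displacement_vector(track: TrackedCell) -> tuple[float, float]:
    """Net displacement D as (magnitude μm, angle deg in [0, 360)).

    The angle uses the same (image-space) convention as the wound direction;
    it is NaN for a closed loop (zero net displacement).
    """
    dx = track.x[-1] - track.x[0]
    dy = track.y[-1] - track.y[0]
    mag = math.hypot(dx, dy)
    if mag == 0.0:
        return 0.0, float("nan")
    return mag, float(np.mod(math.degrees(math.atan2(dy, dx)), 360.0))


def straightness(track: TrackedCell) -> float:
    """S = displacement / trajectory, 1 for a linear path, → 0 for a long one.

    Undefined (NaN) for a stationary cell with zero path length.
    """
    T = path_length(track)
    if T == 0.0:
        return float("nan")
    D, _ = displacement_vector(track)
    return min(D / T, 1.0)


def orientation(track: TrackedCell) -> float:
    """O = cos(displacement angle − wound-closure angle).

    +1 when perfectly aligned with the closure vector, −1 when migrating in
    the opposite direction; NaN when the displacement is zero.
    """
    _, ang = displacement_vector(track)
    if math.isnan(ang):
        return float("nan")
    return math.cos(math.radians(ang - track.wound_direction_deg))


def polarity_index(S: float, O: float) -> float:
    """P = S·O: 1 for rectilinear migration in the best orientation."""
    return S * O


def speeds(track: TrackedCell) -> tuple[float, float, float]:
    """(speed T, speed D, polarized speed) in μm/h over the whole course.

    Polarized speed is speed D times the polarity index; for a cell with
    undefined orientation it is NaN (but 0 for an exactly stationary cell,
    which by any reading moves at zero effective speed).
    """
    dt = track.t[-1] - track.t[0]
    if dt <= 0:
        raise ValueError("elapsed time must be positive")
    T = path_length(track)
    D, _ = displacement_vector(track)
    speed_T = T / dt
    speed_D = D / dt
    if T == 0.0:
        return 0.0, 0.0, 0.0
    P = polarity_index(straightness(track), orientation(track))
    return speed_T, speed_D, speed_D * P


def compute_metrics(track: TrackedCell) -> MigrationMetrics:
    """All eight statistics for one cell."""
    T = path_length(track)
    D, ang = displacement_vector(track)
    S = straightness(track)
    O = orientation(track)
    P = polarity_index(S, O) if not (math.isnan(S) or math.isnan(O)) else float("nan")
    sT, sD, sP = speeds(track)
    return MigrationMetrics(
        cell_id=track.cell_id,
        trajectory_len=T,
        displacement=D,
        displacement_angle_deg=ang,
        straightness=S,
        orientation=O,
        polarity_index=P,
        speed_T=sT,
        speed_D=sD,
        polarized_speed=sP,
    )


_METRIC_COLS = [
    "trajectory_len",
    "displacement",
    "displacement_angle_deg",
    "straightness",
    "orientation",
    "polarity_index",
    "speed_T",
    "speed_D",
    "polarized_speed",
]


def metrics_table(tracks: list[TrackedCell]) -> pd.DataFrame:
    """Per-cell metrics as a tidy DataFrame (one row per cell)."""
    if not tracks:
        raise ValueError("no tracks given")
    return pd.DataFrame([compute_metrics(t).__dict__ for t in tracks])


def summarize_group(tracks: list[TrackedCell]) -> pd.DataFrame:
    """mean ± SEM and n per metric over a group of cells.

    Cells whose orientation is undefined (zero displacement) are excluded
    from orientation-dependent metrics and reported in ``n_excluded``.
    """
    tab = metrics_table(tracks)
    rows = []
    for col in _METRIC_COLS:
        vals = tab[col].to_numpy(float)
        ok = ~np.isnan(vals)
        n = int(ok.sum())
        if n == 0:
            mean = sem = float("nan")
        else:
            mean = float(vals[ok].mean())
            sem = float(vals[ok].std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        rows.append(
            {
                "metric": col,
                "mean": mean,
                "sem": sem,
                "n": n,
                "n_excluded": int(len(vals) - n),
            }
        )
    return pd.DataFrame(rows)
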