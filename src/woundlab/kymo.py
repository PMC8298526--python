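"""Kymograph construction and actin retrograde-wave extraction.

A kymograph samples intensity along a fixed line (drawn from the leading
edge inward along the local edge normal, row 0 = the edge end) in every
frame of a movie: rows are positions along the line (one pixel apart), and
columns are frames.  Rearward-travelling actin waves appear as sloped
ridges; |slope| converted by the spatial/temporal calibration is the wave
speed, and the number of retrograde ridges crossing a fixed reference row
per unit time is the wave frequency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .io import Calibration, RoiSpec


@dataclass
class Kymograph:
    matrix: np.ndarray     # rows = positions along line, cols = frames
    line: RoiSpec
    calibration: Calibration

    def __post_init__(self) -> None:
        if self.matrix.ndim != 2 or min(self.matrix.shape) < 2:
            raise ValueError("kymograph needs >= 2 rows and >= 2 columns")


@dataclass
class WaveTrace:
    rows: np.ndarray       # subpixel ridge row per linked column
    cols: np.ndarray       # strictly increasing frame indices
    speed: float           # μm/s, |Theil–Sen slope| x pixel_size / frame_interval
    direction: str         # retrograde | anterograde

    def crosses(self, ref_row: float) -> bool:
        return float(self.rows.min()) <= ref_row <= float(self.rows.max())


@dataclass
class WaveStats:
    retrograde_speed_mean: float   # μm/s
    wave_frequency: float          # waves/s crossing the reference row
    n_traces: int
    speed_frequency_rs: float = float("nan")


def build_kymograph(
    stack: np.ndarray,
    line: RoiSpec,
    calibration: Calibration,
    width_px: int = 1,
) -> Kymograph:
    """Sample each frame along a line ROI (bilinear, averaged across width).

    The line is sampled at one-pixel spacing from its first endpoint (the
    edge end, row 0) to its second; ``width_px`` parallel lines offset along
    the perpendicular are averaged.
    """
    stack = np.asarray(stack, float)
    if stack.ndim == 2:
        stack = stack[None]
    if line.kind != "line":
        raise ValueError("kymograph ROI must be a line")
    (r0, c0), (r1, c1) = line.vertices
    h, w = stack.shape[1:]
    for r, c in ((r0, c0), (r1, c1)):
        if not (0 <= r <= h - 1 and 0 <= c <= w - 1):
            raise ValueError("line endpoint outside the image")
    length = math.hypot(r1 - r0, c1 - c0)
    n = int(math.floor(length)) + 1
    s = np.linspace(0.0, length, n)
    ur, uc = (r1 - r0) / length, (c1 - c0) / length
    pr, pc = -uc, ur  # unit perpendicular
    offsets = np.arange(width_px, dtype=float) - (width_px - 1) / 2.0

    kymo = np.zeros((n, stack.shape[0]))
    for f in range(stack.shape[0]):
        acc = np.zeros(n)
        for o in offsets:
            rows = r0 + s * ur + o * pr
            cols = c0 + s * uc + o * pc
            acc += ndimage.map_coordinates(
                stack[f], [rows, cols], order=1, mode="nearest"
            )
        kymo[:, f] = acc / width_px
    return Kymograph(kymo, line, calibration)


# Ridge-detection parameters: prominence 3·(noise MAD_σ), link within
# 2 rows between adjacent columns, keep traces spanning >= 5 columns.
MAD_K = 3.0
MAX_JUMP_ROWS = 2.0
MIN_COLS = 5


def _column_peaks(col: np.ndarray, prominence: float, height: float) -> list[float]:
    """Prominent local maxima above a height floor, refined to subpixel."""
    from scipy.signal import find_peaks

    idx, _ = find_peaks(col, prominence=prominence, height=height)
    peaks = []
    for i in idx:
        if 0 < i < len(col) - 1:
            denom = col[i - 1] - 2.0 * col[i] + col[i + 1]
            off = 0.5 * (col[i - 1] - col[i + 1]) / denom if denom < 0 else 0.0
            peaks.append(i + float(np.clip(off, -0.5, 0.5)))
    return peaks


def detect_wave_traces(kymo: Kymograph, edge_row: float = 0.0) -> list[WaveTrace]:
    """Link ridge points across columns into wave traces.

    Per column, ridge candidates are local maxima lying above
    ``median + 3·σ̂`` with prominence at least ``3·σ̂``, where σ̂ is the
    1.4826-normalised MAD of the frame-to-frame intensity differences (a
    noise estimate that stays valid when wave trains cover the whole
    field).  Candidates are linked greedily to the
    nearest point within ``MAX_JUMP_ROWS`` in the next column; traces
    spanning fewer than ``MIN_COLS`` columns are discarded.  Speed is the
    |Theil–Sen slope| converted to μm/s; a trace moving away from
    ``edge_row`` is retrograde.
    """
    m = kymo.matrix
    if m.shape[1] < 5:
        raise ValueError("kymograph needs >= 5 columns for wave detection")
    # noise scale from frame-to-frame differences: ridges move a small
    # fraction of a pixel per frame, so temporal differences are almost
    # pure pixel noise even when the field is dense with waves
    detail = np.diff(m, axis=1)
    sigma = float(np.median(np.abs(detail))) * 1.4826 / math.sqrt(2.0)
    prominence = max(MAD_K * sigma, 1e-12)
    height = float(np.median(m)) + MAD_K * sigma

    active: list[dict] = []
    done: list[dict] = []
    for f in range(m.shape[1]):
        peaks = _column_peaks(m[:, f], prominence, height)
        used = set()
        still_active = []
        for tr in active:
            best, best_d = None, None
            for j, p in enumerate(peaks):
                if j in used:
                    continue
                d = abs(p - tr["rows"][-1])
                if d <= MAX_JUMP_ROWS and (best_d is None or d < best_d):
                    best, best_d = j, d
            if best is None:
                done.append(tr)
            else:
                used.add(best)
                tr["rows"].append(peaks[best])
                tr["cols"].append(f)
                still_active.append(tr)
        active = still_active
        for j, p in enumerate(peaks):
            if j not in used:
                active.append({"rows": [p], "cols": [f]})
    done.extend(active)

    px = kymo.calibration.pixel_size
    dt = kymo.calibration.frame_interval
    traces = []
    for tr in done:
        if len(tr["cols"]) < MIN_COLS:
            continue
        rows = np.asarray(tr["rows"])
        cols = np.asarray(tr["cols"])
        slope = stats.theilslopes(rows, cols)[0]  # rows per frame
        speed = abs(slope) * px / dt
        start, end = rows[0], rows[-1]
        direction = (
            "retrograde" if abs(end - edge_row) >= abs(start - edge_row)
            else "anterograde"
        )
        traces.append(WaveTrace(rows=rows, cols=cols, speed=speed,
                                direction=direction))
    return traces


def wave_stats(
    traces: list[WaveTrace], kymo: Kymograph, ref_row: float
) -> WaveStats:
    """Mean retrograde speed and crossing frequency at a reference row."""
    if not 0 <= ref_row < kymo.matrix.shape[0]:
        raise ValueError("reference row outside the kymograph")
    duration = kymo.matrix.shape[1] * kymo.calibration.frame_interval
    retro = [t for t in traces if t.direction == "retrograde"]
    crossing = [t for t in retro if t.crosses(ref_row)]
    mean_speed = float(np.mean([t.speed for t in retro])) if retro else 0.0
    return WaveStats(
        retrograde_speed_mean=mean_speed,
        wave_frequency=len(crossing) / duration,
        n_traces=len(traces),
    )
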