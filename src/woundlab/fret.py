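"""Ratiometric FRET activity maps and the front/rear activity ratio.

The biosensor activity map is the FRET channel (YFP emission under CFP
excitation, i.e. YFP−CFP acquisition) divided per pixel by the CFP channel,
after background subtraction and mild Gaussian smoothing; the map is
restricted to the cell footprint segmented from the dedicated YFP channel.
Per-cell activity is summarised as the front/rear ratio — mean activity in a
wound-facing band over mean activity in the opposite band — which cancels
probe-expression differences between cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import draw, filters

from .io import Calibration, RoiSpec

FRONT_DEPTH_FRACTION = 0.25   # front/rear bands each cover 25% of cell depth
CFP_FLOOR_MADS = 3.0          # exclude pixels with CFP below bg + 3·MAD
HIGH_BACKGROUND_FRACTION = 0.5


@dataclass
class FretAcquisition:
    fret_channel: np.ndarray
    cfp_channel: np.ndarray
    yfp_channel: np.ndarray
    calibration: Calibration | None = None
    wound_direction_deg: float = 0.0

    def __post_init__(self) -> None:
        shapes = {
            np.asarray(c).shape
            for c in (self.fret_channel, self.cfp_channel, self.yfp_channel)
        }
        if len(shapes) != 1:
            raise ValueError("all channels must share one shape")


@dataclass
class FretRatioResult:
    ratio_map: np.ma.MaskedArray
    front_mean: float
    rear_mean: float
    front_rear_ratio: float
    qc_excluded: bool = False
    qc_reason: str = ""


def _roi_mask(roi: RoiSpec, shape: tuple[int, int]) -> np.ndarray:
    mask = np.zeros(shape, bool)
    if roi.kind == "polygon":
        verts = np.asarray(roi.vertices, float)
        rr, cc = draw.polygon(verts[:, 0], verts[:, 1], shape=shape)
    elif roi.kind == "circle":
        rr, cc = draw.disk(roi.center, roi.radius, shape=shape)
    else:
        raise ValueError("background ROI must be polygon or circle")
    mask[rr, cc] = True
    return mask


def ratio_map(
    acq: FretAcquisition,
    background_roi: RoiSpec,
    smooth_sigma: float = 1.0,
) -> np.ma.MaskedArray:
    """Masked per-pixel FRET/CFP activity map.

    Both ratio channels are background-subtracted (median of the background
    ROI) and Gaussian-smoothed; the cell mask is an Otsu threshold of the
    YFP channel with holes filled; pixels whose CFP signal sits below
    background + 3·MAD are excluded to avoid ratio blow-up at dim pixels.
    """
    fret = np.asarray(acq.fret_channel, float)
    cfp = np.asarray(acq.cfp_channel, float)
    yfp = np.asarray(acq.yfp_channel, float)
    bg_mask = _roi_mask(background_roi, cfp.shape)
    bg_f = float(np.median(fret[bg_mask]))
    bg_c = float(np.median(cfp[bg_mask]))
    mad_c = float(np.median(np.abs(cfp[bg_mask] - bg_c)))

    fret_s = ndimage.gaussian_filter(fret - bg_f, smooth_sigma)
    cfp_s = ndimage.gaussian_filter(cfp - bg_c, smooth_sigma)

    cell = yfp > filters.threshold_otsu(yfp)
    cell = ndimage.binary_fill_holes(cell)
    if not cell.any():
        raise ValueError("empty cell mask from YFP segmentation")
    floor = CFP_FLOOR_MADS * mad_c
    valid = cell & (cfp_s > floor)
    if not valid.any():
        raise ValueError("no valid pixels above the CFP floor")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(valid, fret_s / np.where(valid, cfp_s, 1.0), np.nan)
    return np.ma.MaskedArray(ratio, mask=~valid)


def front_rear_ratio(
    rmap: np.ma.MaskedArray,
    wound_direction_deg: float,
    front_depth_fraction: float = FRONT_DEPTH_FRACTION,
) -> FretRatioResult:
    """Front/rear activity ratio of a masked map.

    Cell pixels are projected onto the wound-closure direction; the front
    band is the wound-side ``front_depth_fraction`` of the projected extent
    and the rear band the opposite, equally deep band.
    """
    valid = ~rmap.mask
    if not valid.any():
        raise ValueError("empty ratio map")
    rr, cc = np.nonzero(valid)
    theta = np.radians(wound_direction_deg)
    # image convention: x=col rightward, y=row downward
    proj = cc * np.cos(theta) + rr * np.sin(theta)
    hi = np.quantile(proj, 1.0 - front_depth_fraction)
    lo = np.quantile(proj, front_depth_fraction)
    vals = rmap.data[rr, cc]
    front = vals[proj >= hi]
    rear = vals[proj <= lo]
    if front.size == 0 or rear.size == 0:
        raise ValueError("front or rear band is empty")
    fm, rm = float(front.mean()), float(rear.mean())
    return FretRatioResult(
        ratio_map=rmap,
        front_mean=fm,
        rear_mean=rm,
        front_rear_ratio=fm / rm,
    )


def qc_exclude(
    acq: FretAcquisition,
    background_roi: RoiSpec,
    manual_flags: list[str] | None = None,
    high_background_fraction: float = HIGH_BACKGROUND_FRACTION,
) -> tuple[bool, str]:
    """Machine-checkable exclusion rules plus manual-flag pass-through.

    A cell is excluded for high background (background median above a
    fraction of the cell median), for detector saturation, or when a manual
    flag (out of focus, overlapping cell, isolated from the monolayer) is
    supplied by the annotator.
    """
    if manual_flags:
        return True, str(manual_flags[0])
    cfp = np.asarray(acq.cfp_channel, float)
    yfp = np.asarray(acq.yfp_channel, float)
    bg_mask = _roi_mask(background_roi, cfp.shape)
    cell = yfp > filters.threshold_otsu(yfp)
    if not cell.any():
        return True, "empty cell mask"
    bg_med = float(np.median(cfp[bg_mask]))
    cell_med = float(np.median(cfp[cell]))
    if bg_med > high_background_fraction * cell_med:
        return True, "high background"
    if np.issubdtype(acq.fret_channel.dtype, np.integer):
        sat = np.iinfo(acq.fret_channel.dtype).max
        if (np.asarray(acq.fret_channel)[cell] >= sat).mean() > 0.01:
            return True, "saturated"
    return False, ""


def analyze(
    acq: FretAcquisition,
    background_roi: RoiSpec,
    smooth_sigma: float = 1.0,
    front_depth_fraction: float = FRONT_DEPTH_FRACTION,
    manual_flags: list[str] | None = None,
) -> FretRatioResult:
    """Full per-cell pipeline: QC, ratio map, front/rear ratio."""
    excluded, reason = qc_exclude(acq, background_roi, manual_flags)
    if excluded:
        empty = np.ma.MaskedArray(
            np.zeros_like(np.asarray(acq.cfp_channel, float)), mask=True
        )
        return FretRatioResult(
            ratio_map=empty, front_mean=float("nan"), rear_mean=float("nan"),
            front_rear_ratio=float("nan"), qc_excluded=True, qc_reason=reason,
        )
    rmap = ratio_map(acq, background_roi, smooth_sigma)
    return front_rear_ratio(rmap, acq.wound_direction_deg, front_depth_fraction)
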