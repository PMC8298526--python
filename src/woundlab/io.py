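"""Readers/writers for the on-disk formats used across the pipeline.

Conventions
-----------
Image coordinates are 0-based ``(row, col)``; track coordinates are continuous
``(x, y)`` in micrometres with x rightward and y downward (the native image
convention, so a track overlays its source movie without flipping).  All
angles cross the I/O boundary in degrees; radians are internal only.  The
single point where the y-down image convention meets the conventional y-up
mathematical one is :func:`angle_image_to_math`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from . import __version__

logger = logging.getLogger("woundlab")

#: Canonical acquisition intervals: phase-contrast tracking movies are taken
#: every 15 min; confocal leading-edge movies every 3.7 s.
TRACK_FRAME_INTERVAL_S = 15 * 60.0
EDGE_FRAME_INTERVAL_S = 3.7


class FormatError(ValueError):
    """Input file or array does not match the expected format."""


def angle_image_to_math(angle_deg: float) -> float:
    """Convert an angle measured in image space (y down) to math space (y up).

    In image space a positive angle turns clockwise on screen; the conversion
    is simply a sign flip, wrapped to [0, 360).
    """
    return float(np.mod(-angle_deg, 360.0))


@dataclass(frozen=True)
class Calibration:
    """Spatial and temporal calibration of an acquisition.

    Parameters
    ----------
    pixel_size : float
        Micrometres per pixel, strictly positive.
    frame_interval : float
        Seconds per frame, strictly positive.
    """

    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        if not self.frame_interval > 0:
            raise ValueError(
                f"frame_interval must be > 0, got {self.frame_interval}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Calibration":
        return cls(**d)


@dataclass
class RoiSpec:
    """A region of interest: polygon, circle or (widthed) line.

    Coordinates are pixel ``(row, col)`` pairs.  Polygons need >= 3 vertices,
    circles a positive radius, lines exactly two endpoints and an integer
    width >= 1.
    """

    roi_id: str
    kind: str  # polygon | circle | line
    vertices: list[tuple[float, float]] | None = None
    center: tuple[float, float] | None = None
    radius: float | None = None
    width_px: int = 1

    def __post_init__(self) -> None:
        if self.kind == "polygon":
            if self.vertices is None or len(self.vertices) < 3:
                raise ValueError("polygon ROI requires >= 3 vertices")
        elif self.kind == "circle":
            if self.center is None or self.radius is None or self.radius <= 0:
                raise ValueError("circle ROI requires center and radius > 0")
        elif self.kind == "line":
            if self.vertices is None or len(self.vertices) != 2:
                raise ValueError("line ROI requires exactly 2 endpoints")
            if int(self.width_px) < 1:
                raise ValueError("line width_px must be >= 1")
        else:
            raise ValueError(f"unknown ROI kind {self.kind!r}")

    def to_dict(self) -> dict:
        d = {"roi_id": self.roi_id, "kind": self.kind, "width_px": self.width_px}
        if self.vertices is not None:
            d["vertices"] = [list(v) for v in self.vertices]
        if self.center is not None:
            d["center"] = list(self.center)
            d["radius"] = self.radius
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RoiSpec":
        return cls(
            roi_id=d["roi_id"],
            kind=d["kind"],
            vertices=[tuple(v) for v in d.get("vertices", [])] or None,
            center=tuple(d["center"]) if "center" in d else None,
            radius=d.get("radius"),
            width_px=int(d.get("width_px", 1)),
        )


@dataclass
class ImageStack:
    """A grayscale image stack (frames x rows x cols) with its calibration."""

    data: np.ndarray
    calibration: Calibration

    def __post_init__(self) -> None:
        if self.data.ndim == 2:
            self.data = self.data[None]
        if self.data.ndim != 3:
            raise FormatError(
                f"expected grayscale stack (frames, rows, cols), got shape {self.data.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


def read_stack(path: str | Path, calibration: Calibration) -> ImageStack:
    """Read a multi-frame grayscale TIFF as an :class:`ImageStack`.

    Intensities are preserved bit-exact.  RGB input is rejected: the pipeline
    quantifies raw grayscale acquisitions, not rendered overlays.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(path)
    if data.ndim == 3 and data.shape[-1] in (3, 4) and data.shape[-1] < min(data.shape[:2]):
        raise FormatError(f"{path} looks like an RGB image; grayscale required")
    if data.ndim not in (2, 3) or data.size == 0:
        raise FormatError(f"{path}: expected a 2D frame or 3D stack")
    return ImageStack(np.asarray(data), calibration)


def write_stack(path: str | Path, stack: ImageStack | np.ndarray) -> None:
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    # grayscale frames, never RGB planes, regardless of frame count
    tifffile.imwrite(Path(path), data, photometric="minisblack")


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single binary mask from TIFF or PNG; nonzero pixels are True."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim == 3:  # collapse RGB(A) exports of binary masks
            arr = arr[..., 0]
    if arr.ndim != 2:
        raise FormatError(f"{path}: expected a single 2D mask")
    return np.asarray(arr) > 0


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    tifffile.imwrite(Path(path), (np.asarray(mask) > 0).astype(np.uint8) * 255)


def read_tracks(path: str | Path, wound_direction_deg: float | None = None):
    """Read nucleus-centroid tracks from CSV into :class:`~woundlab.tracks.TrackedCell`.

    The CSV needs columns ``cell_id,t,x,y`` with optional
    ``wound_direction_deg`` (per-row constant within a cell).  Rows are
    sorted by time within each cell; duplicated ``(cell_id, t)`` pairs are
    rejected.
    """
    from .tracks import TrackedCell

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    required = {"cell_id", "t", "x", "y"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: need columns {sorted(required)}")
    if df.duplicated(subset=["cell_id", "t"]).any():
        dups = df[df.duplicated(subset=["cell_id", "t"], keep=False)]
        raise FormatError(
            f"{path}: duplicated (cell_id, t) pairs, e.g. {dups.iloc[0].to_dict()}"
        )
    cells = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("t")
        if "wound_direction_deg" in grp.columns:
            wd = float(grp["wound_direction_deg"].iloc[0])
        elif wound_direction_deg is not None:
            wd = float(wound_direction_deg)
        else:
            wd = 0.0
        cells.append(
            TrackedCell(
                cell_id=str(cell_id),
                t=grp["t"].to_numpy(float),
                x=grp["x"].to_numpy(float),
                y=grp["y"].to_numpy(float),
                wound_direction_deg=wd,
            )
        )
    return cells


def write_tracks(path: str | Path, cells: Sequence) -> None:
    rows = []
    for c in cells:
        for t, x, y in zip(c.t, c.x, c.y):
            rows.append(
                {
                    "cell_id": c.cell_id,
                    "t": t,
                    "x": x,
                    "y": y,
                    "wound_direction_deg": c.wound_direction_deg,
                }
            )
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def read_rois(path: str | Path) -> list[RoiSpec]:
    with open(path) as fh:
        payload = json.load(fh)
    if isinstance(payload, dict):
        payload = payload.get("rois", [payload])
    return [RoiSpec.from_dict(d) for d in payload]


def write_rois(path: str | Path, rois: Sequence[RoiSpec]) -> None:
    with open(path, "w") as fh:
        json.dump({"rois": [r.to_dict() for r in rois]}, fh, indent=1)


def load_config(path: str | Path | None, overrides: dict | None = None) -> dict:
    """Load a JSON config file; CLI flag overrides win over file values."""
    cfg: dict = {}
    if path is not None:
        with open(path) as fh:
            cfg.update(json.load(fh))
    for k, v in (overrides or {}).items():
        if v is not None:
            cfg[k] = v
    return cfg


def log_run(stage: str, params: dict) -> None:
    """Record package version, seed and the full parameter set for a run."""
    logger.info(
        "woundlab %s | stage=%s | seed=%s | params=%s",
        __version__,
        stage,
        params.get("seed"),
        json.dumps({k: _jsonable(v) for k, v in params.items()}, sort_keys=True),
    )


def _jsonable(v):
    if isinstance(v, (np.integer, np.floating)):
        return v.item()
    if isinstance(v, Path):
        return str(v)
    if dataclasses.is_dataclass(v) and not isinstance(v, type):
        return dataclasses.asdict(v)
    return v
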