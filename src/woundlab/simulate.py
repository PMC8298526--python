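"""Seeded synthetic-data generators with machine-readable ground truth.

Each generator emulates one class of input the pipeline consumes — biased
persistent random-walk nucleus tracks, a closing rectangular scratch in a
monolayer mask, a leading-edge movie carrying travelling actin waves and
scripted filopodia, single-exponential FRAP traces with acquisition
bleaching, two-channel ratiometric FRET images with a scripted front/rear
contrast, and nucleus/MTOC point populations with a known polarized
fraction — and emits the ground-truth parameters alongside, so every
analysis stage can be scored by parameter recovery.  Identical parameters
and seed give bit-identical output.

Defaults follow the acquisitions being emulated: tracking movies at 15 min
per frame, leading-edge confocal movies at 3.7 s per frame, FRAP scans at
0.4 s for 30 s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .io import Calibration, RoiSpec
from .tracks import TrackedCell

# ---------------------------------------------------------------- tracks


@dataclass
class TrackSimParams:
    """Biased persistent random walk in the image plane.

    At each step the heading is the convex combination
    ``b·bias_direction + (1−b)·(previous heading + wrapped-Gaussian noise)``
    (computed wrap-safely around the circle), and the cell advances
    ``mean_step`` μm.  ``bias_strength``=1 with zero noise gives a straight
    line along the bias direction; 0 gives an unbiased persistent walk.
    """

    n_cells: int = 12
    n_steps: int = 24           # 6 h at 15 min per frame
    dt: float = 0.25            # hours per step
    mean_step: float = 5.0      # μm
    angular_noise_sd: float = 30.0   # degrees
    bias_direction_deg: float = 0.0
    bias_strength: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_steps < 2:
            raise ValueError("n_steps must be >= 2")
        if self.mean_step <= 0:
            raise ValueError("mean_step must be > 0")
        if not 0.0 <= self.bias_strength <= 1.0:
            raise ValueError("bias_strength must be in [0, 1]")


def _wrap180(deg):
    return (np.asarray(deg) + 180.0) % 360.0 - 180.0


def gen_tracks(params: TrackSimParams) -> list[TrackedCell]:
    """Simulate nucleus tracks; wound direction = bias direction."""
    rng = np.random.default_rng(params.seed)
    cells = []
    bias = params.bias_direction_deg
    for i in range(params.n_cells):
        heading = rng.uniform(0.0, 360.0)  # initial persistence direction
        xs = [0.0]
        ys = [0.0]
        for _ in range(params.n_steps):
            noisy = heading + rng.normal(0.0, params.angular_noise_sd)
            # convex combination of headings, computed relative to the bias
            # direction so the 0/360 wrap cannot corrupt the average
            heading = bias + (1.0 - params.bias_strength) * _wrap180(noisy - bias)
            xs.append(xs[-1] + params.mean_step * math.cos(math.radians(heading)))
            ys.append(ys[-1] + params.mean_step * math.sin(math.radians(heading)))
        t = np.arange(params.n_steps + 1) * params.dt
        cells.append(
            TrackedCell(
                cell_id=f"sim{i:04d}",
                t=t,
                x=np.array(xs),
                y=np.array(ys),
                wound_direction_deg=bias,
            )
        )
    return cells


# ---------------------------------------------------------------- wound


def gen_wound_masks(
    width_um: float,
    closure_fraction: float,
    fov: tuple[int, int] = (512, 512),
    pixel_size: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Initial/final wound masks: a vertical cell-free band that narrows.

    Returns boolean masks where True = wound (cell-free).  The final band is
    narrowed symmetrically so its area is ``(1 − closure_fraction)`` of the
    initial area, emulating both fronts advancing at equal rates.
    """
    if width_um <= 0:
        raise ValueError("width_um must be > 0")
    if not 0.0 <= closure_fraction <= 1.0:
        raise ValueError("closure_fraction must be in [0, 1]")
    h, w = fov
    width_px = int(round(width_um / pixel_size))
    if width_px > w:
        raise ValueError(f"wound band {width_px}px wider than field {w}px")
    c = w // 2
    ti = np.zeros((h, w), bool)
    lo = c - width_px // 2
    ti[:, lo : lo + width_px] = True
    final_px = int(round(width_px * (1.0 - closure_fraction)))
    tf = np.zeros((h, w), bool)
    if final_px > 0:
        lo_f = c - final_px // 2
        tf[:, lo_f : lo_f + final_px] = True
    if closure_fraction == 0.0:
        tf = ti.copy()
    return ti, tf


def gen_wound_phase_image(
    wound_mask: np.ndarray,
    seed: int = 0,
    cell_texture_sd: float = 30.0,
    background: float = 100.0,
) -> np.ndarray:
    """Phase-contrast-like image for a wound mask: textured cells, smooth gap."""
    rng = np.random.default_rng(seed)
    img = np.full(wound_mask.shape, background, float)
    texture = rng.normal(0.0, cell_texture_sd, wound_mask.shape)
    img[~wound_mask] += texture[~wound_mask]
    img += rng.normal(0.0, 1.0, wound_mask.shape)  # mild camera noise
    return img


# ---------------------------------------------------------------- leading edge


@dataclass
class FilopodiumScript:
    """One scripted protrusion–dwell–retraction cycle.

    ``base_col`` is the pixel column of the filopodium base; length grows
    linearly to ``max_length_um`` over ``protrusion_frames``, dwells, then
    retracts linearly over ``retraction_frames``.  A ``lamellipodic`` event
    sits on a locally advancing lamellipodium rendered by the generator; an
    ``exploratory`` one on a static stretch of edge.
    """

    birth_frame: int
    base_col: int
    max_length_um: float
    protrusion_frames: int
    dwell_frames: int
    retraction_frames: int
    class_label: str = "exploratory"  # or "lamellipodic"

    def __post_init__(self) -> None:
        for name in ("protrusion_frames", "dwell_frames", "retraction_frames"):
            if getattr(self, name) < 1 and name != "dwell_frames":
                raise ValueError(f"{name} must be >= 1")
        if self.class_label not in ("lamellipodic", "exploratory"):
            raise ValueError("class_label must be lamellipodic or exploratory")

    @property
    def death_frame(self) -> int:
        return (
            self.birth_frame
            + self.protrusion_frames
            + self.dwell_frames
            + self.retraction_frames
        )

    def length_at(self, frame: int, pixel_size: float | None = None) -> float:
        """Scripted length (μm) above the local edge at a given frame."""
        f = frame - self.birth_frame
        if f < 0:
            return 0.0
        if f <= self.protrusion_frames:
            return self.max_length_um * f / self.protrusion_frames
        f -= self.protrusion_frames
        if f <= self.dwell_frames:
            return self.max_length_um
        f -= self.dwell_frames
        if f < self.retraction_frames:
            return self.max_length_um * (1.0 - f / self.retraction_frames)
        return 0.0


@dataclass
class EdgeSimParams:
    """A leading-edge movie: bright cell, travelling waves, scripted filopodia.

    The cell occupies the bottom of the field with a horizontal leading edge.
    Intensity ridges (Gaussian profile, ~3 px wide) are born at the edge at
    ``wave_frequency`` and travel rearward (into the cell) at ``wave_speed``.
    Lamellipodic filopodia sit on a broad bump of edge that advances by
    ``lamellipodium_advance_um`` over the event lifetime.
    """

    frames: int = 60
    fov: tuple[int, int] = (200, 300)
    pixel_size: float = 0.2        # μm/px, 60x confocal
    dt: float = 3.7                # s/frame
    wave_speed: float = 0.02       # μm/s rearward
    wave_frequency: float = 0.01   # waves/s
    filopodia_script: list[FilopodiumScript] = field(default_factory=list)
    noise_sd: float = 3.0
    edge_row: int = 100
    cell_level: float = 120.0
    wave_amplitude: float = 100.0
    filopodium_width_px: int = 3
    lamellipodium_advance_um: float = 1.5
    lamellipodium_halfwidth_px: int = 35
    seed: int = 0

    def __post_init__(self) -> None:
        if self.wave_speed < 0 or self.wave_frequency < 0:
            raise ValueError("wave_speed and wave_frequency must be >= 0")
        h, w = self.fov
        for s in self.filopodia_script:
            if not 0 <= s.base_col < w:
                raise ValueError(f"filopodium base_col {s.base_col} outside field")
            if s.max_length_um / self.pixel_size >= self.edge_row:
                raise ValueError("scripted filopodium extends outside field")


def _edge_rows(params: EdgeSimParams, frame: int) -> np.ndarray:
    """Local leading-edge row per column at a frame (lamellipodium bumps)."""
    h, w = params.fov
    rows = np.full(w, float(params.edge_row))
    for s in params.filopodia_script:
        if s.class_label != "lamellipodic":
            continue
        # smooth cosine bump advancing over the event lifetime
        life = max(s.death_frame - s.birth_frame, 1)
        prog = np.clip((frame - s.birth_frame) / life, 0.0, 1.0)
        adv_px = params.lamellipodium_advance_um / params.pixel_size * prog
        hw = params.lamellipodium_halfwidth_px
        cols = np.arange(max(s.base_col - hw, 0), min(s.base_col + hw + 1, w))
        profile = 0.5 * (1 + np.cos(np.pi * (cols - s.base_col) / hw))
        rows[cols] = np.minimum(rows[cols], params.edge_row - adv_px * profile)
    return rows


def gen_edge_stack(params: EdgeSimParams):
    """Render the movie.

    Returns ``(stack, masks, ground_truth)`` where ``stack`` is the float
    intensity movie (frames, rows, cols), ``masks`` the boolean cell masks
    per frame, and ``ground_truth`` a dict with the wave parameters, the
    scripted filopodium events (with their true speeds), and the leading-edge
    front length in μm.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.fov
    stack = np.zeros((params.frames, h, w), float)
    masks = np.zeros((params.frames, h, w), bool)
    rows_grid = np.arange(h)[:, None]

    # wave birth times: include waves born before t=0 so the field is
    # populated from the first frame
    births: list[float] = []
    if params.wave_frequency > 0 and params.wave_speed > 0:
        period = 1.0 / params.wave_frequency
        travel_time = (h - params.edge_row) * params.pixel_size / params.wave_speed
        t_end = params.frames * params.dt
        k = -int(math.ceil(travel_time / period)) - 1
        while k * period < t_end:
            births.append(k * period)
            k += 1

    speed_px = params.wave_speed / params.pixel_size  # px/s
    for f in range(params.frames):
        t = f * params.dt
        edge = _edge_rows(params, f)
        mask = rows_grid >= edge[None, :]
        img = np.where(mask, params.cell_level, 0.0)
        # travelling ridges, planar and parallel to the edge
        for tb in births:
            if t < tb:
                continue
            depth_px = speed_px * (t - tb)
            ridge_row = edge[None, :] + depth_px
            if depth_px > h:  # left the field
                continue
            prof = params.wave_amplitude * np.exp(
                -0.5 * ((rows_grid - ridge_row) / 1.5) ** 2
            )
            img += np.where(mask, prof, 0.0)
        # scripted filopodia: thin vertical protrusions above the local edge
        half_w = params.filopodium_width_px // 2
        for s in params.filopodia_script:
            L_px = s.length_at(f) / params.pixel_size
            if L_px <= 0:
                continue
            base_row = edge[s.base_col]
            top = int(round(base_row - L_px))
            bottom = int(math.ceil(base_row)) + 1  # overlap the cell body
            c0 = max(s.base_col - half_w, 0)
            c1 = min(s.base_col + half_w + 1, w)
            mask[max(top, 0) : bottom, c0:c1] = True
            img[max(top, 0) : bottom, c0:c1] = params.cell_level
        img += rng.normal(0.0, params.noise_sd, (h, w))
        stack[f] = img
        masks[f] = mask

    events = []
    for i, s in enumerate(params.filopodia_script):
        prot_t = s.protrusion_frames * params.dt
        total_t = (s.death_frame - s.birth_frame) * params.dt
        events.append(
            {
                "event_id": f"gt{i:03d}",
                "class_label": s.class_label,
                "base_col": s.base_col,
                "birth_t": s.birth_frame * params.dt,
                "t_max": (s.birth_frame + s.protrusion_frames) * params.dt,
                "death_t": s.death_frame * params.dt,
                "max_length": s.max_length_um,
                "protrusion_speed": s.max_length_um / prot_t,
                "overall_speed": s.max_length_um / total_t,
            }
        )
    ground_truth = {
        "wave_speed": params.wave_speed,
        "wave_frequency": params.wave_frequency,
        "wave_births": births,
        "filopodia": events,
        "front_length_um": w * params.pixel_size,
        "edge_row": params.edge_row,
    }
    return stack, masks, ground_truth


# ---------------------------------------------------------------- FRAP


@dataclass
class FrapSimParams:
    """Single-exponential FRAP recovery with acquisition bleaching.

    Post-bleach fluorescence follows ``F(t) = F0 + (Fp − F0)(1 − e^(−kt))``
    with plateau ``Fp = F0 + mobile_fraction·(F_pre − F0)``; the whole
    acquisition (and the parallel unbleached reference ROI) decays by
    ``e^(−acquisition_bleach_rate·t)`` from scan start.
    """

    pre_frames: int = 5
    post_frames: int = 75          # 30 s at 0.4 s
    dt: float = 0.4                # seconds
    F_pre: float = 1000.0
    F0: float = 200.0
    mobile_fraction: float = 0.6
    k: float = 0.2                 # 1/s
    acquisition_bleach_rate: float = 0.0
    noise_sd: float = 0.0
    background: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.F0 > self.F_pre:
            raise ValueError("F0 must be <= F_pre")
        if not 0.0 <= self.mobile_fraction <= 1.0:
            raise ValueError("mobile_fraction must be in [0, 1]")
        if self.k <= 0:
            raise ValueError("k must be > 0")


def gen_frap_trace(params: FrapSimParams):
    """Simulate one bleached-ROI trace plus reference and background traces.

    Returns ``(trace, ground_truth)`` with a :class:`~woundlab.frap.FrapTrace`.
    """
    from .frap import FrapTrace

    rng = np.random.default_rng(params.seed)
    n = params.pre_frames + params.post_frames
    t_abs = np.arange(n) * params.dt            # from scan start
    t_post = np.arange(params.post_frames) * params.dt  # from bleach
    Fp = params.F0 + params.mobile_fraction * (params.F_pre - params.F0)
    ideal = np.empty(n)
    ideal[: params.pre_frames] = params.F_pre
    ideal[params.pre_frames :] = params.F0 + (Fp - params.F0) * (
        1.0 - np.exp(-params.k * t_post)
    )
    decay = np.exp(-params.acquisition_bleach_rate * t_abs)
    raw = ideal * decay + params.background
    ref = params.F_pre * decay + params.background
    raw = raw + rng.normal(0.0, params.noise_sd, n)
    ref = ref + rng.normal(0.0, params.noise_sd, n)
    bg = np.full(n, params.background) + rng.normal(0.0, params.noise_sd, n)

    trace = FrapTrace(
        t=t_post,
        F_raw=raw[params.pre_frames :],
        F_background=bg[params.pre_frames :],
        F_reference=ref[params.pre_frames :],
        pre_bleach_mean=float(raw[: params.pre_frames].mean()),
        reference_pre_bleach=float(ref[: params.pre_frames].mean()),
        background_pre_bleach=float(bg[: params.pre_frames].mean()),
        dt=params.dt,
    )
    ground_truth = {
        "mobile_fraction": params.mobile_fraction,
        "k": params.k,
        "plateau_norm": Fp / params.F_pre,  # pre-bleach = 1 scale, bg-free
        "F0_norm": params.F0 / params.F_pre,
    }
    return trace, ground_truth


# ---------------------------------------------------------------- FRET


@dataclass
class FretSimParams:
    """Two-channel ratiometric FRET scene with a scripted front/rear contrast.

    The CFP channel is ``cfp_level`` inside the cell polygon; the FRET
    channel is the per-pixel scripted ratio times the CFP signal, with
    ``ratio_front`` in the wound-facing ``front_fraction`` of the cell and
    ``ratio_rear`` elsewhere.  The YFP channel is a bright cell footprint
    used only for segmentation.  Wound direction is +x (columns increasing).
    """

    shape: tuple[int, int] = (200, 260)
    ratio_front: float = 1.2
    ratio_rear: float = 1.0
    cfp_level: float = 500.0
    background: float = 50.0
    noise_sd: float = 0.0
    cell_polygon: RoiSpec | None = None
    front_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ratio_front <= 0 or self.ratio_rear <= 0:
            raise ValueError("ratios must be > 0")
        if not 0.0 < self.front_fraction < 1.0:
            raise ValueError("front_fraction must be in (0, 1)")
        if self.cell_polygon is None:
            h, w = self.shape
            self.cell_polygon = RoiSpec(
                roi_id="cell",
                kind="polygon",
                vertices=[
                    (h * 0.15, w * 0.15),
                    (h * 0.15, w * 0.85),
                    (h * 0.85, w * 0.85),
                    (h * 0.85, w * 0.15),
                ],
            )


def gen_fret_pair(params: FretSimParams):
    """Render (FRET, CFP, YFP) channels plus ground truth."""
    from skimage.draw import polygon as draw_polygon

    rng = np.random.default_rng(params.seed)
    h, w = params.shape
    verts = np.asarray(params.cell_polygon.vertices, float)
    if len(np.unique(verts, axis=0)) < 3:
        raise ValueError("degenerate cell polygon")
    rr, cc = draw_polygon(verts[:, 0], verts[:, 1], shape=(h, w))
    if rr.size == 0:
        raise ValueError("degenerate cell polygon")
    cell = np.zeros((h, w), bool)
    cell[rr, cc] = True

    # front = wound-facing (largest-column) fraction of the cell footprint
    cols_in = np.flatnonzero(cell.any(axis=0))
    split_col = np.quantile(
        np.repeat(np.arange(w), cell.sum(axis=0)), 1.0 - params.front_fraction
    )
    ratio = np.where(np.arange(w)[None, :] >= split_col, params.ratio_front,
                     params.ratio_rear)
    cfp_sig = np.where(cell, params.cfp_level, 0.0)
    fret_sig = ratio * cfp_sig
    yfp_sig = np.where(cell, 4.0 * params.cfp_level, 0.0)

    def ch(sig):
        return sig + params.background + rng.normal(0.0, params.noise_sd, (h, w))

    fret, cfp, yfp = ch(fret_sig), ch(cfp_sig), ch(yfp_sig)
    ground_truth = {
        "front_rear_ratio": params.ratio_front / params.ratio_rear,
        "ratio_front": params.ratio_front,
        "ratio_rear": params.ratio_rear,
        "split_col": float(split_col),
        "cell_mask": cell,
        "cols_in": cols_in,
    }
    return fret, cfp, yfp, ground_truth


# ---------------------------------------------------------------- MTOC


@dataclass
class MtocSimParams:
    """Population of nucleus/MTOC point pairs with known polarized fraction.

    A polarized cell has its nucleus→MTOC deviation from the wound direction
    drawn uniformly inside the ±``cone_deg`` cone; an unpolarized one
    uniformly outside (up to 180°).
    """

    n_cells: int = 100
    p_polarized: float = 0.5
    cone_deg: float = 60.0
    wound_direction_deg: float = 0.0
    separation_um: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_polarized <= 1.0:
            raise ValueError("p_polarized must be in [0, 1]")
        if not 0.0 < self.cone_deg < 180.0:
            raise ValueError("cone_deg must be in (0, 180)")


def gen_mtoc_population(params: MtocSimParams):
    """Returns a list of (nucleus_xy, mtoc_xy, wound_direction_deg, is_polarized)."""
    rng = np.random.default_rng(params.seed)
    out = []
    for i in range(params.n_cells):
        polarized = bool(rng.random() < params.p_polarized)
        if polarized:
            dev = rng.uniform(0.0, params.cone_deg)
        else:
            dev = rng.uniform(params.cone_deg, 180.0)
            dev = math.nextafter(dev, 181.0) if dev == params.cone_deg else dev
        sign = 1.0 if rng.random() < 0.5 else -1.0
        ang = math.radians(params.wound_direction_deg + sign * dev)
        nucleus = rng.uniform(20.0, 200.0, 2)
        mtoc = nucleus + params.separation_um * np.array(
            [math.cos(ang), math.sin(ang)]
        )
        out.append((tuple(nucleus), tuple(mtoc), params.wound_direction_deg, polarized))
    return out
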