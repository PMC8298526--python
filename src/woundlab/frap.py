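"""FRAP trace normalization and single-exponential recovery fitting.

A bleached-ROI trace is background-subtracted, relativized to its own
pre-bleach level and corrected for acquisition photobleaching with a
parallel unbleached reference ROI:

    F_norm(t) = [(F_raw − F_bg) / (F_pre − F_bg)]
              ÷ [(F_ref − F_bg) / (F_ref_pre − F_bg)]

so the pre-bleach level normalizes to 1.  Recovery is fitted with the
single-exponential approach to plateau

    F(t) = F0 + (plateau − F0)·(1 − e^(−k·t)),

and the mobile fraction is (plateau − F0)/(1 − F0): the share of the
bleached species that exchanges with the surrounding pool within the
observation.  Time to half recovery is ln 2 / k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class FrapTrace:
    """Raw bleached-ROI, background and unbleached-reference traces.

    ``t`` is seconds with 0 at the first post-bleach frame.
    """

    t: np.ndarray
    F_raw: np.ndarray
    F_background: np.ndarray
    F_reference: np.ndarray
    pre_bleach_mean: float
    reference_pre_bleach: float
    background_pre_bleach: float = 0.0
    dt: float = 0.4
    duration: float = 30.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, float)
        self.F_raw = np.asarray(self.F_raw, float)
        self.F_background = np.asarray(self.F_background, float)
        self.F_reference = np.asarray(self.F_reference, float)
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("time must be strictly increasing")
        if self.pre_bleach_mean <= self.F_raw[0]:
            raise ValueError("pre-bleach level must exceed first post-bleach value")


@dataclass
class FrapFit:
    F0: float
    plateau: float
    k: float
    mobile_fraction: float
    rmse: float
    converged: bool

    @property
    def half_time(self) -> float:
        """Time to half recovery, ln2/k."""
        return math.log(2.0) / self.k

    def summary(self) -> str:
        return (
            f"FRAP fit: F0={self.F0:.3f}  plateau={self.plateau:.3f}  "
            f"k={self.k:.4f}/s  t1/2={self.half_time:.2f}s  "
            f"mobile fraction={self.mobile_fraction:.3f}  "
            f"rmse={self.rmse:.4f}  converged={self.converged}"
        )


def normalize_trace(trace: FrapTrace) -> np.ndarray:
    """Normalized recovery: bg-subtracted, pre-bleach-relative, bleach-corrected."""
    bg = trace.F_background
    num = (trace.F_raw - bg) / (trace.pre_bleach_mean - trace.background_pre_bleach)
    ref = (trace.F_reference - bg) / (
        trace.reference_pre_bleach - trace.background_pre_bleach
    )
    if np.any(ref <= 0):
        raise ValueError("reference trace non-positive after background subtraction")
    return num / ref


def _model(t, F0, plateau, k):
    return F0 + (plateau - F0) * (1.0 - np.exp(-k * t))


def fit_recovery(t: np.ndarray, f_norm: np.ndarray) -> FrapFit:
    """Least-squares fit of the exponential approach to plateau.

    Initial guesses: F0 = first post-bleach point, plateau = mean of the
    last five points, k from the time to half recovery; bounds keep k
    positive and the plateau within [F0, 1.2] on the pre-bleach = 1 scale.
    """
    t = np.asarray(t, float)
    f = np.asarray(f_norm, float)
    if len(t) < 10:
        raise ValueError("need >= 10 post-bleach points")
    f0_guess = f[0]
    plateau_guess = float(np.mean(f[-5:]))
    half = f0_guess + 0.5 * (plateau_guess - f0_guess)
    above = np.nonzero(f >= half)[0]
    t_half = t[above[0]] if above.size and t[above[0]] > 0 else (t[-1] / 4.0)
    k_guess = math.log(2.0) / max(t_half, t[1] - t[0])
    try:
        popt, _ = curve_fit(
            _model,
            t,
            f,
            p0=[f0_guess, max(plateau_guess, f0_guess + 1e-6), k_guess],
            bounds=([-0.2, -0.2, 1e-6], [1.2, 1.2, np.inf]),
            maxfev=10000,
        )
        F0, plateau, k = map(float, popt)
        converged = True
    except RuntimeError:
        F0, plateau, k = f0_guess, plateau_guess, float("nan")
        converged = False
    if converged:
        rmse = float(np.sqrt(np.mean((f - _model(t, F0, plateau, k)) ** 2)))
    else:
        rmse = float("nan")
    mf = (plateau - F0) / (1.0 - F0) if F0 < 1.0 else float("nan")
    return FrapFit(
        F0=F0, plateau=plateau, k=k, mobile_fraction=float(mf),
        rmse=rmse, converged=converged,
    )


def fit_trace(trace: FrapTrace) -> FrapFit:
    """Normalize then fit in one call."""
    return fit_recovery(trace.t, normalize_trace(trace))


def mobile_fraction_summary(fits: list[FrapFit]) -> dict:
    """mean ± SEM of the mobile fraction over converged fits.

    Non-converged fits are excluded and counted in ``n_failed``.
    """
    ok = [f.mobile_fraction for f in fits if f.converged]
    if not ok:
        raise ValueError("no converged fits")
    arr = np.asarray(ok)
    sem = float(arr.std(ddof=1) / math.sqrt(len(arr))) if len(arr) > 1 else 0.0
    return {
        "mean": float(arr.mean()),
        "sem": sem,
        "n": len(arr),
        "n_failed": len(fits) - len(ok),
    }
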