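"""Microtissue wound-closure quantification.

A wounded 3D microtissue first recoils (the gap opens, driven by the
pre-stress the cells built into the tissue) and then closes as cells
migrate and pull the wound shut.  The normalized gap-area time course
is well described by a log-normal profile

    A(t) = amplitude · exp(−(ln(t/t_peak))² / (2·log_width²)),

whose fitted peak ("amplitude", a readout of tissue pre-stress) and
maximum descent slope ("closure rate") summarize the healing response.
This module segments the gap from brightfield-like frames, fits the
profile, derives the closure rate analytically, measures tissue width
contraction, and converts cantilever bead displacements into tissue
contractile force.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
from scipy.ndimage import binary_fill_holes, label
from skimage.filters import threshold_otsu

from .synthetic import WoundSeries, lognormal_profile

__all__ = [
    "LogNormalFit",
    "TissueForceSeries",
    "segment_wound_area",
    "fit_lognormal",
    "closure_rate_from_fit",
    "cantilever_force",
    "width_contraction",
    "CANTILEVER_SPRING_CONSTANT_UN_PER_UM",
]

#: Cantilever spring constant of the microtissue device (µN/µm),
#: a property of the published device geometry and PDMS formulation.
CANTILEVER_SPRING_CONSTANT_UN_PER_UM = 9.72


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

def segment_wound_area(frame: np.ndarray, threshold: float | str = "otsu",
                       um_per_px: float = 1.0) -> dict:
    """Gap area and tissue width from one grayscale frame.

    The tissue is bright on a dark background: thresholding (absolute
    value or Otsu) gives the tissue mask; the wound gap is the set of
    holes fully enclosed by the tissue (fill-holes minus mask).  The
    tissue width is the extent of the filled tissue along the
    horizontal centerline.

    Returns a dict with ``gap_area`` (µm²), ``width`` (µm),
    ``n_holes`` and ``threshold``.
    """
    img = np.asarray(frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single 2-D grayscale frame")
    thr = float(threshold_otsu(img)) if threshold == "otsu" else float(threshold)
    tissue = img > thr
    if not tissue.any():
        raise ValueError("no tissue component above threshold")
    filled = binary_fill_holes(tissue)
    holes = filled & ~tissue
    _, n_holes = label(holes)
    gap_area = float(holes.sum()) * um_per_px**2

    centerline = filled[filled.shape[0] // 2]
    cols = np.flatnonzero(centerline)
    width = float(cols[-1] - cols[0] + 1) * um_per_px if cols.size else 0.0
    return {"gap_area": gap_area, "width": width, "n_holes": int(n_holes),
            "threshold": thr}


def segment_wound_stack(frames: np.ndarray, time_h: np.ndarray,
                        threshold: float | str = "otsu",
                        um_per_px: float = 1.0) -> WoundSeries:
    """Apply :func:`segment_wound_area` to every frame of a stack and
    assemble a WoundSeries normalized to the first frame's gap area."""
    areas, widths = [], []
    for frame in frames:
        res = segment_wound_area(frame, threshold=threshold, um_per_px=um_per_px)
        areas.append(res["gap_area"])
        widths.append(res["width"])
    areas = np.asarray(areas)
    norm = areas / areas[0] if areas[0] > 0 else areas
    return WoundSeries(time_h=np.asarray(time_h, float), area_norm=norm,
                       width_um=np.asarray(widths))


# ---------------------------------------------------------------------------
# Log-normal closure fit
# ---------------------------------------------------------------------------

@dataclass
class LogNormalFit:
    """Fitted wound-closure profile.

    ``closure_rate`` is the maximum |dA/dt| on the descending limb of
    the fitted curve (normalized area per hour), evaluated in closed
    form; non-closing series carry ``converged = False`` and rate 0.
    """

    amplitude: float
    t_peak: float
    log_width: float
    closure_rate: float
    rss: float
    converged: bool

    def predict(self, t):
        return lognormal_profile(t, self.amplitude, self.t_peak, self.log_width)


def closure_rate_from_fit(amplitude: float, t_peak: float, log_width: float) -> float:
    """Maximum descent speed of the log-normal profile, analytically.

    With u = ln(t/t_peak), |dA/dt| on the descending limb is maximized
    at the positive root of u² + w²·u − w² = 0; the rate is linear in
    amplitude.
    """
    w2 = log_width**2
    u = (-w2 + np.sqrt(w2**2 + 4.0 * w2)) / 2.0
    t_star = t_peak * np.exp(u)
    a_star = amplitude * np.exp(-u**2 / (2.0 * w2))
    return float(a_star * u / (w2 * t_star))


def fit_lognormal(series: WoundSeries, min_points: int = 6,
                  non_closing_rate_fraction: float = 0.01) -> LogNormalFit:
    """Least-squares log-normal fit of a normalized wound-area series.

    Non-closing phenotypes (constant area, no descending limb within
    the observation window, or a descent slower than
    ``non_closing_rate_fraction``·amplitude/duration) are returned with
    ``converged = False`` and closure rate 0 rather than a spurious
    parameter set.
    """
    t = np.asarray(series.time_h, dtype=float)
    y = np.asarray(series.area_norm, dtype=float)
    keep = (t > 0) & np.isfinite(y)
    t, y = t[keep], y[keep]
    if t.size < min_points:
        raise ValueError(f"need at least {min_points} points with t > 0, got {t.size}")
    duration = float(t[-1])

    def failed(rss=np.nan):
        return LogNormalFit(amplitude=np.nan, t_peak=np.nan, log_width=np.nan,
                            closure_rate=0.0, rss=rss, converged=False)

    if np.ptp(y) == 0:
        return failed(rss=0.0)
    a0 = max(float(y.max()), 1e-9)
    tp0 = float(t[int(np.argmax(y))])
    try:
        popt, _ = scipy.optimize.curve_fit(
            lognormal_profile, t, y, p0=(a0, max(tp0, t[0]), 0.8),
            bounds=([1e-12, 1e-12, 1e-6], [np.inf, np.inf, np.inf]), maxfev=20000)
    except (RuntimeError, ValueError):
        return failed()
    amplitude, t_peak, log_width = (float(v) for v in popt)
    rss = float(np.sum((y - lognormal_profile(t, *popt)) ** 2))
    rate = closure_rate_from_fit(amplitude, t_peak, log_width)
    non_closing = (t_peak > duration) or (rate < non_closing_rate_fraction * amplitude / duration)
    if non_closing:
        return LogNormalFit(amplitude=amplitude, t_peak=t_peak, log_width=log_width,
                            closure_rate=0.0, rss=rss, converged=False)
    return LogNormalFit(amplitude=amplitude, t_peak=t_peak, log_width=log_width,
                        closure_rate=rate, rss=rss, converged=True)


# ---------------------------------------------------------------------------
# Cantilever force and width contraction
# ---------------------------------------------------------------------------

@dataclass
class TissueForceSeries:
    """Contractile force over time from cantilever bead displacements.

    ``force_uN`` = spring constant × sum of per-cantilever
    displacements at each time point (displacements must already be
    baseline-subtracted against the collagenase-released bead
    positions).
    """

    time_h: np.ndarray
    force_uN: np.ndarray
    spring_constant_uN_per_um: float
    net_force_difference_uN: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_h": self.time_h, "force_uN": self.force_uN})


def cantilever_force(displacements_um: np.ndarray, time_h: np.ndarray | None = None,
                     k_uN_per_um: float = CANTILEVER_SPRING_CONSTANT_UN_PER_UM,
                     pre_wound_index: int | None = None,
                     post_wound_index: int | None = None) -> TissueForceSeries:
    """Tissue contractile force: k × Σ cantilever displacements.

    ``displacements_um`` has shape (time, n_cantilevers), already
    baseline-subtracted.  When pre/post indices are given, the net
    force difference force[post] − force[pre] is reported (the
    24 h-post-wound vs pre-wound comparison).
    """
    disp = np.atleast_2d(np.asarray(displacements_um, dtype=float))
    if not np.all(np.isfinite(disp)):
        raise ValueError("displacements must be finite and baseline-subtracted")
    force = k_uN_per_um * disp.sum(axis=1)
    if time_h is None:
        time_h = np.arange(force.size, dtype=float)
    net = None
    if pre_wound_index is not None and post_wound_index is not None:
        net = float(force[post_wound_index] - force[pre_wound_index])
    return TissueForceSeries(time_h=np.asarray(time_h, float), force_uN=force,
                             spring_constant_uN_per_um=k_uN_per_um,
                             net_force_difference_uN=net)


def width_contraction(width_ref_um: float, width_t_um: float) -> float:
    """Percent width contraction 100·(w_ref − w_t)/w_ref at the
    analysis time point, relative to the pre-wound reference."""
    if width_ref_um <= 0:
        raise ValueError("reference width must be positive")
    return 100.0 * (width_ref_um - width_t_um) / width_ref_um
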