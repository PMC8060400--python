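"""Cell-migration trajectory metrics and persistent-random-walk fits.

Given 2-D nucleus tracks at uniform sampling, computes the
overlapping-interval mean squared displacement (time average per track,
count-weighted ensemble average across tracks), mean frame-to-frame
speed, and the straightness index (net displacement over path length).
The MSD over a 0-12 h lag window is fitted to the 2-D Fürth equation

    MSD(τ) = 4D·(τ − P·(1 − e^(−τ/P)))

to extract diffusivity D (µm²/h) and directional persistence P (h);
the implied RMS speed is S = sqrt(2D/P).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize

from .synthetic import furth_msd

__all__ = [
    "MSDCurve", "PRWFit",
    "compute_msd", "fit_prw", "cell_speed", "straightness",
    "iter_tracks",
]


def iter_tracks(trajectories):
    """Yield (track_id, t, xy) for a TrajectorySet or long DataFrame."""
    table = getattr(trajectories, "table", trajectories)
    for tid, grp in table.groupby("track_id", sort=True):
        grp = grp.sort_values("t_h")
        yield tid, grp["t_h"].to_numpy(float), grp[["x_um", "y_um"]].to_numpy(float)


def _check_uniform(t: np.ndarray, rtol: float = 1e-6) -> float:
    if t.size < 2:
        raise ValueError("track needs at least 2 samples")
    dts = np.diff(t)
    dt = dts[0]
    if dt <= 0 or np.any(np.abs(dts - dt) > rtol * dt):
        raise ValueError("track sampling must be uniform")
    return float(dt)


@dataclass
class MSDCurve:
    lag_h: np.ndarray
    msd: np.ndarray          # µm²
    counts: np.ndarray       # contributing intervals per lag

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"lag_h": self.lag_h, "msd_um2": self.msd,
                             "n_intervals": self.counts})


def compute_msd(trajectories, max_lag_h: float | None = None) -> MSDCurve:
    """Ensemble MSD with overlapping-interval time averaging.

    Per track, MSD(m·dt) averages (r(t+m·dt) − r(t))² over all start
    frames; tracks are combined weighted by their interval counts.  The
    default maximum lag is half the shortest track duration (longer
    lags carry few intervals and are noise-dominated); a requested lag
    beyond any track's duration is truncated with a warning.
    """
    per_track = []
    dts = []
    for _, t, xy in iter_tracks(trajectories):
        dts.append(_check_uniform(t))
        per_track.append((t, xy))
    dt = dts[0]
    if any(abs(d - dt) > 1e-9 * dt for d in dts):
        raise ValueError("all tracks must share the same sampling interval")

    min_steps = min(len(t) - 1 for t, _ in per_track)
    default_max = min_steps // 2
    if max_lag_h is None:
        max_m = max(default_max, 1)
    else:
        max_m = int(round(max_lag_h / dt))
        if max_m > min_steps:
            warnings.warn("max_lag exceeds track duration; truncating", stacklevel=2)
            max_m = min_steps

    sums = np.zeros(max_m + 1)
    counts = np.zeros(max_m + 1, dtype=int)
    for t, xy in per_track:
        n = len(t)
        for m in range(1, min(max_m, n - 1) + 1):
            d = xy[m:] - xy[:-m]
            sq = np.einsum("ij,ij->i", d, d)
            sums[m] += sq.sum()
            counts[m] += sq.size
    counts[0] = sum(len(t) for t, _ in per_track)
    msd = np.zeros(max_m + 1)
    nz = counts > 0
    msd[nz] = sums[nz] / counts[nz]
    return MSDCurve(lag_h=np.arange(max_m + 1) * dt, msd=msd, counts=counts)


@dataclass
class PRWFit:
    diffusivity: float | None   # D, µm²/h
    persistence: float | None   # P, h
    speed: float | None         # implied S = sqrt(2D/P), µm/h
    rss: float
    converged: bool


def fit_prw(msd: MSDCurve, window_h: tuple[float, float] = (0.0, 12.0)) -> PRWFit:
    """Ordinary nonlinear least-squares fit of the Fürth MSD over a lag
    window (default 0-12 h)."""
    lo, hi = window_h
    mask = (msd.lag_h > max(lo, 0)) & (msd.lag_h <= hi) & (msd.counts > 0)
    tau = msd.lag_h[mask]
    y = msd.msd[mask]
    if tau.size < 4:
        raise ValueError("need at least 4 lags inside the fit window")
    dt = float(tau[0])
    d0 = max(y[-1] / (4.0 * tau[-1]), 1e-9)
    try:
        popt, _ = scipy.optimize.curve_fit(
            furth_msd, tau, y, p0=(d0, dt),
            bounds=([0.0, 1e-9], [np.inf, np.inf]), maxfev=20000)
    except (RuntimeError, ValueError):
        return PRWFit(diffusivity=None, persistence=None, speed=None,
                      rss=np.nan, converged=False)
    D, P = float(popt[0]), float(popt[1])
    rss = float(np.sum((y - furth_msd(tau, D, P)) ** 2))
    return PRWFit(diffusivity=D, persistence=P, speed=float(np.sqrt(2.0 * D / P)),
                  rss=rss, converged=True)


def cell_speed(track) -> float:
    """Mean frame-to-frame displacement divided by dt (µm/h).

    ``track`` is (t, xy) or a per-track DataFrame.
    """
    t, xy = _coerce_track(track)
    dt = _check_uniform(t)
    steps = np.linalg.norm(np.diff(xy, axis=0), axis=1)
    return float(steps.mean() / dt)


def straightness(track) -> float:
    """Net displacement over total path length, in [0, 1].

    Undefined (NaN, with a warning) for a zero-length path.
    """
    t, xy = _coerce_track(track)
    _check_uniform(t)
    path = float(np.linalg.norm(np.diff(xy, axis=0), axis=1).sum())
    if path == 0.0:
        warnings.warn("zero path length; straightness undefined", stacklevel=2)
        return float("nan")
    net = float(np.linalg.norm(xy[-1] - xy[0]))
    return net / path


def _coerce_track(track):
    if isinstance(track, tuple):
        t, xy = track
        return np.asarray(t, float), np.asarray(xy, float)
    grp = track.sort_values("t_h")
    return grp["t_h"].to_numpy(float), grp[["x_um", "y_um"]].to_numpy(float)


def summarize_tracks(trajectories) -> pd.DataFrame:
    """Per-track speed and straightness table."""
    rows = []
    for tid, t, xy in iter_tracks(trajectories):
        rows.append({"track_id": tid,
                     "speed_um_per_h": cell_speed((t, xy)),
                     "straightness": straightness((t, xy))})
    return pd.DataFrame(rows)
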