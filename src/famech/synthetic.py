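"""Seeded synthetic-data generators for every input class the analysis
consumes: per-FA force/intensity tables, magnetic-bead Western-blot
ratio assays, microtissue wound-area time series and cantilever
displacement series, persistent-random-walk cell trajectories, and
small grayscale fixture images (post grids, wounded tissues).

Generators emulate the statistical structure the analyses assume — a
linear force-intensity mean with Gaussian noise scaled to a target R²,
an Ornstein-Uhlenbeck velocity process whose MSD is the Fürth curve, a
log-normal wound-area profile — not microscope physics.  Every
generator is reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
import tifffile

from .posts import LatticeSpec, PostGeometry, spring_constant

__all__ = [
    "FAGeneratorConfig", "BeadGeneratorConfig", "WoundGeneratorConfig",
    "PRWGeneratorConfig",
    "FADataset", "BeadAssay", "WoundSeries", "TrajectorySet",
    "generate_fa_dataset", "generate_bead_assay", "generate_wound_series",
    "generate_prw_trajectories", "generate_post_image", "generate_wound_frames",
    "generate_cantilever_displacements",
    "lognormal_profile", "furth_msd",
    "DEFAULT_GEOMETRY",
]

#: Default mPAD geometry attached to generated FA datasets (the stiff
#: "14 kPa" array on which linear coupling is observed).
DEFAULT_GEOMETRY = PostGeometry(height_um=6.1, diameter_um=1.83,
                                modulus_pa=2.4971e6, label="14 kPa")


def _check_finite(cfg, names) -> None:
    for name in names:
        v = getattr(cfg, name)
        vals = np.atleast_1d(np.asarray(v, dtype=float))
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"{type(cfg).__name__}.{name} must be finite, got {v!r}")


# ---------------------------------------------------------------------------
# Per-FA force/intensity datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FAGeneratorConfig:
    """Per-FA dataset generator settings.

    ``slope``/``intercept`` define the linear force-intensity mean for
    the tFAK channel (intensity AU per nN / AU); ``py397_slope`` and
    ``py397_intercept`` optionally give the second channel its own line
    (defaulting to the tFAK parameters).  In the coupled regime, noise
    sd is derived analytically from ``target_r2``:
    sd = slope·sd(force)·sqrt(1/R² − 1).  In the uncoupled regime
    intensities are force-independent log-normal draws matched to the
    coupled regime's mean and total variance.
    """

    n_fas: int = 66
    slope: float = 194.6
    intercept: float = 1178.0
    target_r2: float = 0.6
    force_range: tuple[float, float] = (0.0, 15.0)
    coupled: bool = True
    seed: int = 0
    py397_slope: float | None = None
    py397_intercept: float | None = None
    condition: str = "control"

    def __post_init__(self) -> None:
        _check_finite(self, ("slope", "intercept", "target_r2", "force_range"))
        if self.n_fas < 2:
            raise ValueError("n_fas must be >= 2")
        if not (0.0 < self.target_r2 < 1.0):
            raise ValueError("target_r2 must lie in (0, 1)")
        lo, hi = self.force_range
        if lo < 0 or lo >= hi:
            raise ValueError("force_range must satisfy 0 <= min < max")


@dataclass
class FADataset:
    """One row per focal adhesion, with the generating geometry attached."""

    table: pd.DataFrame = field(repr=False)
    geometry: PostGeometry = DEFAULT_GEOMETRY

    COLUMNS = ("fa_id", "cell_id", "condition", "deflection_x_um",
               "deflection_y_um", "force_nN", "tfak_au", "py397_au")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, geometry: PostGeometry = DEFAULT_GEOMETRY) -> "FADataset":
        return cls(table=pd.read_csv(path), geometry=geometry)


def _channel_values(rng, forces, slope, intercept, target_r2, coupled):
    sd_force = float(np.std(forces, ddof=1))
    noise_sd = abs(slope) * sd_force * np.sqrt(1.0 / target_r2 - 1.0)
    if coupled:
        return slope * forces + intercept + rng.normal(0.0, noise_sd, forces.size)
    # force-independent intensities matched to the coupled regime's
    # mean and total variance; log-normal because intensities are
    # positive and right-skewed in practice
    mean = slope * float(np.mean(forces)) + intercept
    var = slope**2 * sd_force**2 + noise_sd**2
    if mean <= 0:
        return rng.normal(mean, np.sqrt(var), forces.size)
    sigma2 = np.log1p(var / mean**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), forces.size)


def generate_fa_dataset(config: FAGeneratorConfig,
                        geometry: PostGeometry = DEFAULT_GEOMETRY,
                        cell_id: int = 0) -> FADataset:
    """Synthetic per-FA table of deflections, forces and intensities.

    Forces are uniform on ``force_range`` (nN); intensities follow the
    config's linear models (or the uncoupled alternative); deflection
    vectors are back-computed from force through the attached post
    geometry with a random pull direction per FA.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_fas
    forces = rng.uniform(*config.force_range, n)
    tfak = _channel_values(rng, forces, config.slope, config.intercept,
                           config.target_r2, config.coupled)
    p_slope = config.py397_slope if config.py397_slope is not None else config.slope
    p_int = config.py397_intercept if config.py397_intercept is not None else config.intercept
    py397 = _channel_values(rng, forces, p_slope, p_int,
                            config.target_r2, config.coupled)
    k = spring_constant(geometry)
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    mag = forces / k
    table = pd.DataFrame({
        "fa_id": np.arange(n),
        "cell_id": cell_id,
        "condition": config.condition,
        "deflection_x_um": mag * np.cos(theta),
        "deflection_y_um": mag * np.sin(theta),
        "force_nN": forces,
        "tfak_au": tfak,
        "py397_au": py397,
    })
    return FADataset(table=table, geometry=geometry)


# ---------------------------------------------------------------------------
# Magnetic-bead ratio assays
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeadGeneratorConfig:
    """pY397-FAK/tFAK ratio vs applied bead force (pN), with replicate
    noise; ratio = slope·force + intercept + N(0, noise_sd)."""

    slope: float = 0.0345
    intercept: float = 1.870
    force_levels: tuple[float, ...] = (0.0, 10.0, 30.0)
    n_reps: int = 3
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        _check_finite(self, ("slope", "intercept", "force_levels", "noise_sd"))
        if len(self.force_levels) == 0:
            raise ValueError("force_levels must be non-empty")
        if any(f < 0 for f in self.force_levels):
            raise ValueError("force levels must be non-negative")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class BeadAssay:
    table: pd.DataFrame = field(repr=False)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def generate_bead_assay(config: BeadGeneratorConfig) -> BeadAssay:
    rng = np.random.default_rng(config.seed)
    rows = []
    for f in config.force_levels:
        for rep in range(config.n_reps):
            ratio = config.slope * f + config.intercept + rng.normal(0.0, config.noise_sd)
            rows.append({"force_pN": f, "replicate": rep, "ratio": ratio})
    return BeadAssay(table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Wound-closure series and frames
# ---------------------------------------------------------------------------

def lognormal_profile(t, amplitude: float, t_peak: float, log_width: float):
    """Normalized wound-area profile A(t) = A·exp(−(ln(t/t_peak))²/(2w²)).

    Rises from 0 (elastic recoil after wounding), peaks at t_peak with
    value ``amplitude``, then decays toward closure.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    out[pos] = amplitude * np.exp(-np.log(t[pos] / t_peak) ** 2 / (2.0 * log_width**2))
    return out


@dataclass(frozen=True)
class WoundGeneratorConfig:
    """Log-normal wound-area profile plus Gaussian noise, clipped at 0.

    ``amplitude`` is the peak of the normalized-area profile (the
    pre-stress recoil); times in hours.
    """

    amplitude: float = 2.0
    t_peak: float = 3.0
    log_width: float = 0.8
    noise_sd: float = 0.05
    duration: float = 24.0
    dt: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        _check_finite(self, ("amplitude", "t_peak", "log_width", "noise_sd",
                             "duration", "dt"))
        if self.amplitude <= 0 or self.t_peak <= 0 or self.log_width <= 0:
            raise ValueError("amplitude, t_peak and log_width must be positive")
        if self.dt <= 0 or self.duration <= self.dt:
            raise ValueError("need dt > 0 and duration > dt")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class WoundSeries:
    """Wound gap area over time; ``area_norm`` is area normalized to
    the initial wound area."""

    time_h: np.ndarray
    area_norm: np.ndarray
    width_um: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"time_h": self.time_h, "area_norm": self.area_norm}
        if self.width_um is not None:
            data["width_um"] = self.width_um
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def generate_wound_series(config: WoundGeneratorConfig) -> WoundSeries:
    """Noisy log-normal wound-area series on a grid starting at t = dt
    (the first post-wound frame; the profile vanishes at t = 0)."""
    rng = np.random.default_rng(config.seed)
    t = np.arange(config.dt, config.duration + config.dt / 2.0, config.dt)
    area = lognormal_profile(t, config.amplitude, config.t_peak, config.log_width)
    area = area + rng.normal(0.0, config.noise_sd, t.size)
    return WoundSeries(time_h=t, area_norm=np.clip(area, 0.0, None))


def generate_cantilever_displacements(force_program_uN, k_uN_per_um: float,
                                      n_cantilevers: int = 2,
                                      noise_sd_um: float = 0.0,
                                      seed: int = 0) -> pd.DataFrame:
    """Per-cantilever bead displacements (µm) that a tissue-force
    program (µN over time) would produce: displacement sums to F/k,
    split equally across cantilevers, plus tracking noise."""
    force = np.asarray(force_program_uN, dtype=float)
    if k_uN_per_um <= 0 or n_cantilevers < 1:
        raise ValueError("need positive spring constant and >= 1 cantilever")
    rng = np.random.default_rng(seed)
    per = force / k_uN_per_um / n_cantilevers
    data = {"frame": np.arange(force.size)}
    for c in range(n_cantilevers):
        data[f"disp_um_{c}"] = per + rng.normal(0.0, noise_sd_um, force.size)
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# Persistent-random-walk trajectories
# ---------------------------------------------------------------------------

def furth_msd(tau, D: float, P: float):
    """2-D Fürth MSD: 4D·(τ − P·(1 − e^(−τ/P)))."""
    tau = np.asarray(tau, dtype=float)
    return 4.0 * D * (tau - P * (1.0 - np.exp(-tau / P)))


@dataclass(frozen=True)
class PRWGeneratorConfig:
    """OU-velocity persistent random walk.

    ``speed`` is the stationary root-mean-square speed (µm/h),
    ``persistence`` the velocity correlation time P (h).  The implied
    Fürth diffusivity is D = speed²·P/2.
    """

    speed: float = 30.0
    persistence: float = 1.0
    n_cells: int = 200
    duration: float = 48.0
    dt: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        _check_finite(self, ("speed", "persistence", "duration", "dt"))
        if self.speed < 0:
            raise ValueError("speed must be >= 0")
        if self.persistence <= 0 or self.dt <= 0:
            raise ValueError("persistence and dt must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.dt >= self.duration:
            raise ValueError("dt must be smaller than duration")

    @property
    def diffusivity(self) -> float:
        return self.speed**2 * self.persistence / 2.0


@dataclass
class TrajectorySet:
    table: pd.DataFrame = field(repr=False)

    COLUMNS = ("track_id", "t_h", "x_um", "y_um")

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TrajectorySet":
        return cls(table=pd.read_csv(path))


def generate_prw_trajectories(config: PRWGeneratorConfig) -> TrajectorySet:
    """Discrete OU velocity scheme:

        v(t+dt) = v(t)·e^(−dt/P) + η·σ_v·sqrt(1 − e^(−2dt/P)),

    η standard normal per component, σ_v = speed/√2 per component so
    the stationary RMS speed equals ``speed``; positions are cumulative
    sums of v·dt, starting at the origin.
    """
    rng = np.random.default_rng(config.seed)
    n_steps = int(round(config.duration / config.dt))
    rho = np.exp(-config.dt / config.persistence)
    sigma_v = config.speed / np.sqrt(2.0)
    kick = sigma_v * np.sqrt(1.0 - rho**2)

    v = rng.normal(0.0, sigma_v, (config.n_cells, 2))  # stationary start
    eta = rng.normal(0.0, 1.0, (n_steps, config.n_cells, 2))
    pos = np.zeros((n_steps + 1, config.n_cells, 2))
    for s in range(n_steps):
        pos[s + 1] = pos[s] + v * config.dt
        v = v * rho + kick * eta[s]

    t = np.arange(n_steps + 1) * config.dt
    frames = []
    for c in range(config.n_cells):
        frames.append(pd.DataFrame({
            "track_id": c, "t_h": t,
            "x_um": pos[:, c, 0], "y_um": pos[:, c, 1],
        }))
    return TrajectorySet(table=pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# Image fixtures
# ---------------------------------------------------------------------------

def generate_post_image(lattice: LatticeSpec, deflections_um: np.ndarray,
                        spot_sd_px: float = 2.0, amplitude: float = 10000.0,
                        noise_sd: float = 0.0, seed: int = 0,
                        shape: tuple[int, int] | None = None):
    """16-bit grayscale image of Gaussian post tops at lattice nodes
    displaced by ``deflections_um`` (n_posts, 2), plus the ground-truth
    centroid positions (px).

    Deflections larger than half the lattice pitch trigger a warning
    (the post could be assigned to the wrong node downstream).
    """
    deflections_um = np.asarray(deflections_um, dtype=float)
    if not np.all(np.isfinite(deflections_um)):
        raise ValueError("deflections must be finite")
    if spot_sd_px <= 0:
        raise ValueError("spot_sd_px must be positive")
    mags = np.hypot(deflections_um[:, 0], deflections_um[:, 1])
    if np.any(mags > lattice.pitch_um / 2.0):
        warnings.warn("deflection exceeds half the lattice pitch; "
                      "node assignment may be ambiguous", stacklevel=2)

    truth = lattice.node_positions_px() + deflections_um / lattice.um_per_px
    if shape is None:
        pad = lattice.pitch_px
        H = int(np.ceil(lattice.origin_px[1] + (lattice.n_rows - 1) * lattice.pitch_px + pad))
        W = int(np.ceil(lattice.origin_px[0] + (lattice.n_cols - 1) * lattice.pitch_px + pad))
        shape = (H, W)
    ys, xs = np.mgrid[0:shape[0], 0:shape[1]]
    img = np.zeros(shape, dtype=float)
    for cx, cy in truth:
        img += amplitude * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2.0 * spot_sd_px**2))
    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, shape)
    img = np.clip(img, 0, 65535).astype(np.uint16)
    return img, truth


def generate_wound_frames(config: WoundGeneratorConfig,
                          shape: tuple[int, int] = (120, 200),
                          tissue_value: int = 200, background_value: int = 30,
                          aspect: float = 2.0, max_gap_fraction: float = 0.25):
    """Image stack of a bright tissue rectangle with a dark elliptical
    gap whose area tracks the (noiseless) wound profile, plus the
    ground-truth gap areas in px².

    Returns (frames uint8 (T, H, W), truth_areas_px2, series).
    """
    import dataclasses
    series = generate_wound_series(dataclasses.replace(config, noise_sd=0.0))
    H, W = shape
    tissue = np.zeros(shape, dtype=bool)
    m_y, m_x = H // 8, W // 8
    tissue[m_y:H - m_y, m_x:W - m_x] = True
    tissue_area = tissue.sum()
    # the profile peak (= amplitude) maps to max_gap_fraction of the tissue
    area_px = series.area_norm / config.amplitude * max_gap_fraction * tissue_area
    if area_px.max() >= 0.9 * tissue_area:
        raise ValueError("gap would be larger than the tissue; shrink max_gap_fraction")

    ys, xs = np.mgrid[0:H, 0:W]
    cy, cx = H / 2.0, W / 2.0
    frames = np.full((len(series.time_h), H, W), background_value, dtype=np.uint8)
    truth = np.zeros(len(series.time_h))
    for i, a_px in enumerate(area_px):
        frame = np.where(tissue, tissue_value, background_value).astype(np.uint8)
        if a_px > 0:
            b = np.sqrt(a_px / (np.pi * aspect))  # semi-minor (y)
            a = aspect * b                        # semi-major (x)
            hole = ((xs - cx) / a) ** 2 + ((ys - cy) / b) ** 2 <= 1.0
            frame[hole & tissue] = background_value
            truth[i] = (hole & tissue).sum()
        frames[i] = frame
    return frames, truth, series


def write_tiff_stack(path, frames: np.ndarray) -> None:
    """Write an image or stack as TIFF (16-bit if the data needs it)."""
    tifffile.imwrite(path, frames)
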