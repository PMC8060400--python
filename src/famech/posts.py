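"""Micropost-array (mPAD) traction mechanics.

Elastomeric microposts behave as independent cantilever beams: a focal
adhesion pulling the post tip sideways by a deflection δ exerts a force

    F = δ · 3πED⁴ / (64 L³)

(Euler-Bernoulli beam theory), where E is the Young's modulus of the
post material, D the post diameter and L the post height.  This module
converts between geometry, spring constants and forces, detects post
centroids on grid images, infers per-post deflections against a fitted
reference lattice, and sums per-cell traction forces.

Units: geometry in µm, modulus in Pa, deflections in µm, forces in nN,
spring constants in nN/µm.  All SI conversion happens in one place
(:func:`spring_constant`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PostGeometry",
    "LatticeSpec",
    "DeflectionField",
    "ForceRecord",
    "spring_constant",
    "calibrate_modulus",
    "deflection_to_force",
    "detect_post_centroids",
    "compute_deflections",
    "total_cell_force",
    "load_geometry_registry",
]

_UM = 1e-6          # m per µm
_N_PER_M_TO_NN_PER_UM = 1e3   # 1 N/m = 1e9 nN per 1e6 µm


@dataclass(frozen=True)
class PostGeometry:
    """Micropost geometry and material.

    Parameters
    ----------
    height_um : post height L (µm)
    diameter_um : post diameter D (µm)
    modulus_pa : Young's modulus E of the post material (Pa)
    label : free-text array label, e.g. ``"14 kPa"`` (the effective
        substrate stiffness the array presents to cells).
    """

    height_um: float
    diameter_um: float
    modulus_pa: float
    label: str = ""

    def __post_init__(self) -> None:
        for name in ("height_um", "diameter_um", "modulus_pa"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"PostGeometry.{name} must be positive and finite, got {v!r}")

    @property
    def spring_constant_nn_per_um(self) -> float:
        return spring_constant(self)


def spring_constant(geom: PostGeometry) -> float:
    """Cantilever spring constant k = 3πED⁴/(64L³) in nN/µm.

    The formula is evaluated in SI (Pa, m → N/m) and converted once:
    1 N/m = 10⁹ nN per 10⁶ µm = 10³ nN/µm.
    """
    L = geom.height_um * _UM
    D = geom.diameter_um * _UM
    k_si = 3.0 * math.pi * geom.modulus_pa * D**4 / (64.0 * L**3)  # N/m
    return k_si * _N_PER_M_TO_NN_PER_UM


def calibrate_modulus(height_um: float, diameter_um: float, k_nn_per_um: float) -> float:
    """Invert the beam formula: modulus E (Pa) from geometry and a known k.

    Used to recover the post material modulus from one printed
    (geometry, spring constant) row so the same E predicts the other
    array geometries.
    """
    if not (k_nn_per_um > 0 and height_um > 0 and diameter_um > 0):
        raise ValueError("geometry and spring constant must be positive")
    k_si = k_nn_per_um / _N_PER_M_TO_NN_PER_UM  # nN/µm -> N/m
    L = height_um * _UM
    D = diameter_um * _UM
    return k_si * 64.0 * L**3 / (3.0 * math.pi * D**4)


def load_geometry_registry() -> dict[str, PostGeometry]:
    """mPAD geometry registry shipped with the package.

    The registry stores the three array rows (labelled by effective
    substrate stiffness) with their printed heights, diameters and
    spring constants; the PDMS modulus is calibrated by inverting the
    beam formula on the reference row and applied to every geometry.
    """
    text = resources.files("famech.data").joinpath("mpad_geometries.yaml").read_text()
    raw = yaml.safe_load(text)
    ref = next(p for p in raw["posts"] if p["label"] == raw["reference_label"])
    modulus = calibrate_modulus(ref["height_um"], ref["diameter_um"], ref["spring_constant_nn_per_um"])
    return {
        p["label"]: PostGeometry(
            height_um=p["height_um"],
            diameter_um=p["diameter_um"],
            modulus_pa=modulus,
            label=p["label"],
        )
        for p in raw["posts"]
    }


@dataclass(frozen=True)
class ForceRecord:
    """Traction force at one post: vector (nN), magnitude, optional FA id."""

    post_id: int
    force_nN: tuple[float, float]
    magnitude_nN: float
    fa_id: int | None = None


def deflection_to_force(delta_um, geom: PostGeometry, post_id: int = 0,
                        fa_id: int | None = None) -> ForceRecord:
    """Convert a tip deflection vector δ (µm) to a traction force (nN).

    The force is parallel to δ with magnitude k·|δ|.
    """
    delta = np.asarray(delta_um, dtype=float)
    if delta.shape == ():
        delta = np.array([float(delta), 0.0])
    if delta.shape != (2,) or not np.all(np.isfinite(delta)):
        raise ValueError("deflection must be a finite scalar or 2-vector in µm")
    k = spring_constant(geom)
    fvec = k * delta
    return ForceRecord(
        post_id=post_id,
        force_nN=(float(fvec[0]), float(fvec[1])),
        magnitude_nN=float(np.hypot(*fvec)),
        fa_id=fa_id,
    )


# ---------------------------------------------------------------------------
# Post-grid image analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LatticeSpec:
    """Regular square post lattice on an image.

    Image coordinates: origin at the top-left pixel centre, x to the
    right, y down, in pixels; ``um_per_px`` converts to µm.
    """

    n_rows: int
    n_cols: int
    pitch_um: float
    um_per_px: float
    origin_px: tuple[float, float] = (0.0, 0.0)  # (x, y) of node (0, 0)

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("lattice must have at least one row and column")
        if not (self.pitch_um > 0 and self.um_per_px > 0):
            raise ValueError("pitch and pixel scale must be positive")

    @property
    def pitch_px(self) -> float:
        return self.pitch_um / self.um_per_px

    def node_positions_px(self) -> np.ndarray:
        """(n_rows*n_cols, 2) array of ideal node (x, y) pixel positions."""
        jj, ii = np.meshgrid(np.arange(self.n_cols), np.arange(self.n_rows))
        x = self.origin_px[0] + jj.ravel() * self.pitch_px
        y = self.origin_px[1] + ii.ravel() * self.pitch_px
        return np.column_stack([x, y]).astype(float)


def detect_post_centroids(image: np.ndarray, lattice: LatticeSpec) -> np.ndarray:
    """Intensity-weighted centroid of each post, in pixels.

    Each lattice node gets a square search window of half-pitch radius;
    the background (image median) is subtracted and the centroid of the
    remaining positive signal returned.  Windows with no signal above
    background mark the post as missing (NaN row), never silently zero.

    Returns an (n_posts, 2) array of (x, y) pixel positions ordered
    row-major over the lattice.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    nodes = lattice.node_positions_px()
    half = lattice.pitch_px / 2.0
    background = float(np.median(img))
    out = np.full((len(nodes), 2), np.nan)
    H, W = img.shape
    for idx, (nx, ny) in enumerate(nodes):
        x0, x1 = int(max(0, math.floor(nx - half))), int(min(W, math.ceil(nx + half) + 1))
        y0, y1 = int(max(0, math.floor(ny - half))), int(min(H, math.ceil(ny + half) + 1))
        if x0 >= x1 or y0 >= y1:
            continue
        win = img[y0:y1, x0:x1] - background
        win = np.clip(win, 0.0, None)
        total = win.sum()
        if total <= 0:
            continue  # missing post
        ys, xs = np.mgrid[y0:y1, x0:x1]
        out[idx, 0] = (win * xs).sum() / total
        out[idx, 1] = (win * ys).sum() / total
    return out


@dataclass
class DeflectionField:
    """Per-post deflections relative to a registered reference lattice."""

    table: pd.DataFrame = field(repr=False)
    noise_floor_um: float = 0.1

    COLUMNS = (
        "post_id", "row", "col",
        "reference_x_um", "reference_y_um",
        "observed_x_um", "observed_y_um",
        "deflection_x_um", "deflection_y_um",
        "contacted",
    )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def _fit_rigid_lattice(nodes_um: np.ndarray, observed_um: np.ndarray,
                       mask: np.ndarray) -> np.ndarray:
    """Least-squares rigid (rotation + translation) fit of ideal nodes to
    observed positions over ``mask``; returns transformed node positions."""
    A = nodes_um[mask]
    B = observed_um[mask]
    ca, cb = A.mean(axis=0), B.mean(axis=0)
    H = (A - ca).T @ (B - cb)
    U, _, Vt = np.linalg.svd(H)
    R = Vt.T @ U.T
    if np.linalg.det(R) < 0:  # keep a proper rotation
        Vt[-1, :] *= -1
        R = Vt.T @ U.T
    return (nodes_um - ca) @ R.T + cb


def compute_deflections(detected_px: np.ndarray, lattice: LatticeSpec,
                        noise_floor_um: float = 0.1,
                        n_iterations: int = 3) -> DeflectionField:
    """Infer per-post deflections by registering an ideal lattice.

    An ideal lattice is fitted (translation + rotation, least squares)
    to posts classified as non-contacted; δ = detected − fitted
    reference.  Classification is iterative: fit → mark posts with
    |δ| < ``noise_floor_um`` as non-contacted → refit, for
    ``n_iterations`` rounds.  At least 4 non-contacted posts are
    required to register the lattice.
    """
    detected_px = np.asarray(detected_px, dtype=float)
    nodes_um = lattice.node_positions_px() * lattice.um_per_px
    observed_um = detected_px * lattice.um_per_px
    present = np.all(np.isfinite(observed_um), axis=1)
    if present.sum() < 4:
        raise ValueError("need at least 4 detected posts for lattice registration")

    mask = present.copy()  # start from "all detected posts are reference"
    reference = None
    for _ in range(n_iterations):
        if mask.sum() < 4:
            raise ValueError(
                f"fewer than 4 non-contacted posts (noise floor {noise_floor_um} µm); "
                "cannot register the reference lattice"
            )
        reference = _fit_rigid_lattice(nodes_um, observed_um, mask)
        delta = observed_um - reference
        mag = np.hypot(delta[:, 0], delta[:, 1])
        mask = present & (mag < noise_floor_um)
    delta = observed_um - reference
    mag = np.hypot(delta[:, 0], delta[:, 1])
    contacted = present & (mag >= noise_floor_um)

    rows, cols = np.divmod(np.arange(len(nodes_um)), lattice.n_cols)
    table = pd.DataFrame({
        "post_id": np.arange(len(nodes_um)),
        "row": rows,
        "col": cols,
        "reference_x_um": reference[:, 0],
        "reference_y_um": reference[:, 1],
        "observed_x_um": observed_um[:, 0],
        "observed_y_um": observed_um[:, 1],
        "deflection_x_um": delta[:, 0],
        "deflection_y_um": delta[:, 1],
        "contacted": contacted,
    })
    table.loc[~present, ["deflection_x_um", "deflection_y_um"]] = np.nan
    return DeflectionField(table=table, noise_floor_um=noise_floor_um)


def total_cell_force(records: list[ForceRecord] | np.ndarray,
                     cell_mask=None) -> float:
    """Total traction force of a cell: sum of force magnitudes (nN)
    over its contacted posts.

    ``records`` may be ForceRecords or an array of magnitudes;
    ``cell_mask`` optionally selects the subset under the cell.
    """
    if len(records) and isinstance(records[0], ForceRecord):
        mags = np.array([r.magnitude_nN for r in records], dtype=float)
    else:
        mags = np.asarray(records, dtype=float)
    if cell_mask is not None:
        mags = mags[np.asarray(cell_mask, dtype=bool)]
    if mags.size == 0:
        warnings.warn("no posts assigned to cell; total force is 0", stacklevel=2)
        return 0.0
    return float(mags.sum())
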