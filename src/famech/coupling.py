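"""Force-signaling coupling statistics at focal adhesions.

The central question is whether a signaling readout at an individual
focal adhesion (integrated tFAK or pY397-FAK immunofluorescence, or a
pY397-FAK/tFAK Western-blot ratio) scales linearly with the force borne
by that adhesion.  "Coupling" is operationalized as a significant OLS
slope of intensity on force (two-sided t-test, α = 0.05) on data pooled
across cells; the adequacy of the linear form is assessed against a
four-parameter logistic alternative by small-sample AICc and Akaike
weights.

Also here: the group-comparison dispatcher (ANOVA / Welch ANOVA /
Kruskal-Wallis with Dunn post-hoc, mirroring standard prism-style
screening), Gaussian-smoothed intensity heatmaps, magnetic-bead ratio
regression, and the magnetic-puller stiffness estimate.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.special
import scipy.stats
import statsmodels.api as sm
from scipy.ndimage import gaussian_filter

__all__ = [
    "RegressionResult",
    "ModelComparison",
    "GroupComparison",
    "HeatmapGrid",
    "linear_fit",
    "fit_force_intensity",
    "compare_linear_sigmoidal",
    "group_compare",
    "render_heatmap",
    "bead_ratio_regression",
    "puller_stiffness",
]

ALPHA = 0.05  # significance level used throughout to declare coupling


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of a readout on force."""

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    p_slope: float       # two-sided t-test on the slope
    r2: float
    n: int
    resid_sd: float

    @property
    def coupled(self) -> bool:
        """True when the slope is significant at α = 0.05."""
        return bool(self.p_slope < ALPHA)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope, "slope_se": self.slope_se,
            "intercept": self.intercept, "intercept_se": self.intercept_se,
            "p_slope": self.p_slope, "r2": self.r2, "n": self.n,
            "resid_sd": self.resid_sd, "coupled": self.coupled,
        }


def linear_fit(x, y) -> RegressionResult:
    """OLS of y on x with slope t-test; shared by every regression here."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 finite observations, got {n}")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant; the slope is not identifiable")
    if np.ptp(y) == 0:  # flat readout: exactly zero slope, no evidence
        return RegressionResult(slope=0.0, slope_se=0.0, intercept=float(y[0]),
                                intercept_se=0.0, p_slope=1.0, r2=0.0, n=int(n),
                                resid_sd=0.0)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    resid_sd = float(np.sqrt(model.ssr / model.df_resid)) if model.df_resid > 0 else 0.0
    # a perfect fit gives se == 0 and p == nan; report p = 0 for a nonzero slope
    p = float(model.pvalues[1])
    if not np.isfinite(p):
        p = 0.0 if model.params[1] != 0 else 1.0
    return RegressionResult(
        slope=float(model.params[1]), slope_se=float(model.bse[1]),
        intercept=float(model.params[0]), intercept_se=float(model.bse[0]),
        p_slope=p, r2=float(model.rsquared) if np.isfinite(model.rsquared) else 0.0,
        n=int(n), resid_sd=resid_sd,
    )


_CHANNELS = {"tfak": "tfak_au", "py397": "py397_au"}


def fit_force_intensity(dataset, channel: str = "tfak") -> RegressionResult:
    """Per-FA coupling regression: integrated intensity vs force (nN).

    ``dataset`` is an FADataset or a DataFrame with columns
    ``force_nN`` and ``tfak_au``/``py397_au``; ``channel`` selects the
    readout.  Data are pooled over all FAs (multiple cells included).
    """
    table = getattr(dataset, "table", dataset)
    key = channel.lower().replace("-", "").replace("_", "")
    col = _CHANNELS.get("tfak" if key == "tfak" else "py397" if key in ("py397", "py397fak") else key)
    if col is None or col not in table.columns:
        raise ValueError(f"unknown channel {channel!r}; expected 'tfak' or 'py397'")
    return linear_fit(table["force_nN"], table[col])


# ---------------------------------------------------------------------------
# Linear vs sigmoidal model comparison (AICc / Akaike weights)
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    """AICc comparison of candidate mean models fitted to the same data.

    ``k`` counts mean parameters plus one for the residual variance.
    Weights are Akaike weights: w_i ∝ exp(-ΔAICc_i / 2), normalized to 1.
    """

    n: int
    models: dict = field(default_factory=dict)   # name -> {k, rss, aicc, params, converged}
    weights: dict = field(default_factory=dict)  # name -> Akaike weight

    @property
    def best(self) -> str:
        return max(self.weights, key=self.weights.get)


def aicc(n: int, rss: float, k: int) -> float:
    """Small-sample corrected AIC for a Gaussian least-squares fit.

    AICc = n·ln(RSS/n) + 2k + 2k(k+1)/(n-k-1), with k counting mean
    parameters plus the residual-variance parameter.
    """
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    rss = max(rss, 1e-300)  # guard the log for interpolating fits
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values: dict) -> dict:
    delta = {m: a - min(aicc_values.values()) for m, a in aicc_values.items()}
    raw = {m: np.exp(-d / 2.0) for m, d in delta.items()}
    total = sum(raw.values())
    return {m: v / total for m, v in raw.items()}


def _logistic4(f, bottom, span, f50, scale):
    # top = bottom + span; span constrained non-negative at fit time
    return bottom + span * scipy.special.expit((np.asarray(f) - f50) / scale)


def fit_logistic4(x: np.ndarray, y: np.ndarray, n_starts: int = 5):
    """4PL least-squares fit with multi-start from data quantiles.

    Returns (params dict, rss) or raises RuntimeError when no start
    converges.  Ordering bottom ≤ top is enforced by parameterizing the
    span as non-negative.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    lo, hi = float(np.min(y)), float(np.max(y))
    span0 = max(hi - lo, 1e-9)
    starts = [
        (lo, span0, float(np.quantile(x, q)), max(np.ptp(x), 1e-9) / 5.0)
        for q in np.linspace(0.15, 0.85, n_starts)
    ]
    best = None
    for p0 in starts:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = scipy.optimize.curve_fit(
                    _logistic4, x, y, p0=p0,
                    bounds=([-np.inf, 0.0, -np.inf, 1e-9], [np.inf, np.inf, np.inf, np.inf]),
                    maxfev=20000,
                )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((y - _logistic4(x, *popt)) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        raise RuntimeError("4PL fit failed to converge from all starts")
    popt, rss = best
    params = {"bottom": popt[0], "top": popt[0] + popt[1], "f50": popt[2], "scale": popt[3]}
    return params, rss


def compare_linear_sigmoidal(dataset, channel: str = "tfak") -> ModelComparison:
    """Is the force-intensity relation better described as linear or
    sigmoidal?  AICc comparison of a 2-parameter line against a 4PL
    logistic; Akaike weights are the model probabilities.

    A non-converging logistic is reported as failed (the linear model
    then takes weight 1, flagged rather than silent).
    """
    table = getattr(dataset, "table", dataset)
    col = _CHANNELS["tfak" if channel.lower().startswith("t") else "py397"]
    x = np.asarray(table["force_nN"], float)
    y = np.asarray(table[col], float)
    n = x.size
    if n <= 6:
        raise ValueError("need n > 6 for the linear-vs-sigmoidal comparison")

    lin = linear_fit(x, y)
    rss_lin = lin.resid_sd**2 * (n - 2)
    comp = ModelComparison(n=n)
    comp.models["linear"] = {
        "k": 3, "rss": rss_lin, "aicc": aicc(n, rss_lin, 3),
        "params": {"slope": lin.slope, "intercept": lin.intercept}, "converged": True,
    }
    try:
        params, rss_sig = fit_logistic4(x, y)
        comp.models["sigmoidal"] = {
            "k": 5, "rss": rss_sig, "aicc": aicc(n, rss_sig, 5),
            "params": params, "converged": True,
        }
    except RuntimeError:
        comp.models["sigmoidal"] = {"k": 5, "rss": np.nan, "aicc": np.nan,
                                    "params": None, "converged": False}
        comp.weights = {"linear": 1.0, "sigmoidal": 0.0}
        return comp
    comp.weights = akaike_weights({m: d["aicc"] for m, d in comp.models.items()})
    return comp


# ---------------------------------------------------------------------------
# Group comparisons (ANOVA / Welch / Kruskal-Wallis + Dunn)
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    test: str                 # chosen omnibus test
    statistic: float
    p_value: float
    posthoc: pd.DataFrame | None
    screening: dict


def _welch_anova(groups: list[np.ndarray]) -> tuple[float, float]:
    """Welch's heteroscedastic one-way ANOVA (F*, p)."""
    k = len(groups)
    n = np.array([g.size for g in groups], float)
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    w = n / v
    mw = np.sum(w * m) / np.sum(w)
    a = np.sum(w * (m - mw) ** 2) / (k - 1)
    b = np.sum((1 - w / np.sum(w)) ** 2 / (n - 1))
    f = a / (1 + 2 * (k - 2) / (k**2 - 1) * b)
    df1 = k - 1
    df2 = (k**2 - 1) / (3 * b)
    return float(f), float(scipy.stats.f.sf(f, df1, df2))


def dunn_posthoc(groups: dict[str, np.ndarray], adjust: str = "holm") -> pd.DataFrame:
    """Dunn's rank-based pairwise z-tests after Kruskal-Wallis.

    Uses the pooled-rank statistic with tie correction; p-values are
    Holm-adjusted by default.
    """
    names = list(groups)
    values = np.concatenate([groups[g] for g in names])
    labels = np.concatenate([[g] * len(groups[g]) for g in names])
    ranks = scipy.stats.rankdata(values)
    N = len(values)
    _, counts = np.unique(values, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (N - 1))
    var_base = N * (N + 1) / 12.0 - tie_term
    mean_rank = {g: ranks[labels == g].mean() for g in names}
    n_g = {g: (labels == g).sum() for g in names}

    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(var_base * (1.0 / n_g[a] + 1.0 / n_g[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * scipy.stats.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_raw": p})
    out = pd.DataFrame(rows)
    if adjust == "holm":
        m = len(out)
        p_adj = np.minimum(1.0, out["p_raw"].values * (m - scipy.stats.rankdata(out["p_raw"], method="ordinal") + 1))
        # enforce monotonicity of the step-down procedure
        idx = np.argsort(out["p_raw"].values)
        running = 0.0
        adj_sorted = p_adj[idx]
        for i in range(len(adj_sorted)):
            running = max(running, adj_sorted[i])
            adj_sorted[i] = running
        p_final = np.empty_like(adj_sorted)
        p_final[idx] = adj_sorted
        out["p_adj"] = p_final
    else:
        out["p_adj"] = np.minimum(1.0, out["p_raw"] * len(out))
    return out


def group_compare(groups: dict[str, np.ndarray]) -> GroupComparison:
    """Compare ≥ 2 groups with the screening logic of standard
    biostatistics practice: Shapiro normality and Levene equal-variance
    checks choose between ANOVA (t-test for 2 groups), Welch's ANOVA
    (Welch t-test for 2 groups), and Kruskal-Wallis (Mann-Whitney for
    2 groups) with Dunn post-hoc pairwise tests.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(groups) < 2 or any(g.size < 2 for g in groups.values()):
        raise ValueError("need at least 2 groups with n >= 2 each")
    glist = list(groups.values())

    degenerate = any(g.size < 3 or np.ptp(g) == 0 for g in glist)
    if degenerate:
        warnings.warn("zero-variance or tiny group; using the nonparametric branch",
                      stacklevel=2)
        normal = False
        equal_var = False
        screening = {"forced_nonparametric": True}
    else:
        shapiro_p = [scipy.stats.shapiro(g).pvalue for g in glist]
        levene_p = scipy.stats.levene(*glist).pvalue
        normal = all(p > ALPHA for p in shapiro_p)
        equal_var = levene_p > ALPHA
        screening = {"shapiro_p": shapiro_p, "levene_p": float(levene_p),
                     "forced_nonparametric": False}

    posthoc = None
    if normal and equal_var:
        if len(glist) == 2:
            stat, p = scipy.stats.ttest_ind(*glist)
            test = "t-test"
        else:
            stat, p = scipy.stats.f_oneway(*glist)
            test = "anova"
            posthoc = dunn_posthoc(groups)
    elif normal:
        if len(glist) == 2:
            stat, p = scipy.stats.ttest_ind(*glist, equal_var=False)
            test = "welch-t"
        else:
            stat, p = _welch_anova(glist)
            test = "welch-anova"
            posthoc = dunn_posthoc(groups)
    else:
        if len(glist) == 2:
            stat, p = scipy.stats.mannwhitneyu(*glist, alternative="two-sided")
            test = "mann-whitney"
        else:
            stat, p = scipy.stats.kruskal(*glist)
            test = "kruskal-wallis"
            posthoc = dunn_posthoc(groups)
    return GroupComparison(test=test, statistic=float(stat), p_value=float(p),
                           posthoc=posthoc, screening=screening)


# ---------------------------------------------------------------------------
# Spatial intensity heatmaps
# ---------------------------------------------------------------------------

@dataclass
class HeatmapGrid:
    grid: np.ndarray          # smoothed intensity, shape (ny, nx)
    x_edges: np.ndarray
    y_edges: np.ndarray
    spacing_um: float
    sigma_grid_units: float
    contour_levels: np.ndarray


def render_heatmap(positions_um, intensities, extent_um, spacing_um: float = 1.0,
                   sigma: float = 3.0, n_levels: int = 8) -> HeatmapGrid:
    """Accumulate per-FA intensities on a grid and smooth with a 2-D
    Gaussian kernel of standard deviation ``sigma`` grid units.

    ``extent_um`` is (xmin, xmax, ymin, ymax).  Smoothing conserves
    total intensity away from the borders (``mode='constant'``).
    """
    positions = np.asarray(positions_um, dtype=float).reshape(-1, 2)
    intensities = np.asarray(intensities, dtype=float)
    xmin, xmax, ymin, ymax = extent_um
    x_edges = np.arange(xmin, xmax + spacing_um / 2, spacing_um)
    y_edges = np.arange(ymin, ymax + spacing_um / 2, spacing_um)
    if positions.size:
        acc, _, _ = np.histogram2d(positions[:, 1], positions[:, 0],
                                   bins=[y_edges, x_edges], weights=intensities)
    else:
        acc = np.zeros((len(y_edges) - 1, len(x_edges) - 1))
    smoothed = gaussian_filter(acc, sigma=sigma, mode="constant")
    top = smoothed.max() if smoothed.size else 0.0
    levels = np.linspace(0.0, top, n_levels + 1)[1:] if top > 0 else np.array([])
    return HeatmapGrid(grid=smoothed, x_edges=x_edges, y_edges=y_edges,
                       spacing_um=spacing_um, sigma_grid_units=sigma,
                       contour_levels=levels)


# ---------------------------------------------------------------------------
# Magnetic-bead assay
# ---------------------------------------------------------------------------

def bead_ratio_regression(assay) -> RegressionResult:
    """OLS of pY397-FAK/tFAK Western-blot ratio on applied bead force
    (pN), pooled over replicates."""
    table = getattr(assay, "table", assay)
    forces = np.asarray(table["force_pN"], float)
    if np.unique(forces).size < 2:
        raise ValueError("need at least 2 distinct force levels")
    return linear_fit(forces, table["ratio"])


def puller_stiffness(force_pN: float, displacement_um: float) -> float:
    """Effective stiffness of the magnetic puller, nN/µm.

    Applied bead force divided by the expected bead displacement; the
    pN → nN conversion (10⁻³) is explicit.
    """
    if not (force_pN > 0 and displacement_um > 0):
        raise ValueError("force and displacement must be positive")
    return force_pN * 1e-3 / displacement_um
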