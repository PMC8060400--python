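"""Mass-action kinetics of talin-FAK binding under force.

Talin at a focal adhesion interconverts between an unstretched (T) and
a stretched (T_st) conformation; stretched talin reversibly binds free
FAK (F) to form a complex (FT_st) which is reversibly phosphorylated
(pFT_st).  Force f (pN, per talin molecule) accelerates stretching via
the Bell model, k1 = k1o·e^(αf).  The governing equations are

    d(T_st)/dt  = k1·T − k2·T_st − k3·T_st·F + k4·FT_st
    d(FT_st)/dt = k3·T_st·F − k4·FT_st − k5·FT_st + k6·pFT_st
    d(pFT_st)/dt = k5·FT_st − k6·pFT_st

with conservation T_total = T + T_st + FT_st + pFT_st and
F_total = F + FT_st + pFT_st used to eliminate T and F.

Steady states (d/dt = 0) are found with a Newton-type root finder
started from 8 points spanning the conservation simplex; uniqueness is
asserted by agreement of all converged starts.  Force and parameter
sweeps report species both absolute and relative to the smallest force
in the sweep, plus per-species linearity diagnostics (OLS slope, R²).

Parameter units: first-order rates in 1/s, k3 in 1/(molecule·s), α in
1/pN, totals in molecules.  The base set is chosen to reproduce the
qualitative regimes of the model (linear force response at α = 0.05
over 7-11 pN; flattening under 100-fold k3 or k5 reduction); see
docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd
import scipy.optimize
import yaml
from scipy.integrate import solve_ivp

from .coupling import linear_fit

__all__ = [
    "KineticParameters",
    "SteadyState",
    "SweepResult",
    "BASE_PARAMETERS",
    "k1_of_force",
    "rhs",
    "solve_steady_state",
    "integrate_to_steady_state",
    "sweep_force",
    "sweep_parameter",
    "linearity_metric",
]

SPECIES = ("T", "T_st", "F", "FT_st", "pFT_st")
_BELL_EXPONENT_CAP = 50.0


@dataclass(frozen=True)
class KineticParameters:
    """Rate constants, Bell coupling factor and conserved totals."""

    k1o: float = 0.1      # base talin stretch rate, 1/s
    k2: float = 10.0      # talin relaxation rate, 1/s
    k3: float = 0.02      # FAK-talin forward binding, 1/(molecule·s)
    k4: float = 1.0       # complex dissociation, 1/s
    k5: float = 1.0       # FAK phosphorylation, 1/s
    k6: float = 1.0       # dephosphorylation, 1/s
    alpha: float = 0.05   # Bell force-coupling factor, 1/pN
    T_total: float = 100.0  # total talin, molecules
    F_total: float = 100.0  # total FAK, molecules

    def __post_init__(self) -> None:
        for name in ("k1o", "k2", "k3", "k4", "k5", "k6", "alpha"):
            if getattr(self, name) < 0 or not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite and >= 0")
        if not (self.T_total > 0 and self.F_total > 0):
            raise ValueError("totals must be positive")

    def replace(self, **kw) -> "KineticParameters":
        return replace(self, **kw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "KineticParameters":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


BASE_PARAMETERS = KineticParameters()


def k1_of_force(k1o: float, alpha: float, f: float) -> float:
    """Bell-model stretch rate k1 = k1o·e^(αf).

    The exponent is capped (with a warning) to avoid overflow in
    pathological sweeps; physical sweeps sit far below the cap.
    """
    if f < 0:
        raise ValueError("force must be non-negative")
    exponent = alpha * f
    if exponent > _BELL_EXPONENT_CAP:
        warnings.warn(f"Bell exponent α·f = {exponent:.1f} capped at {_BELL_EXPONENT_CAP}",
                      stacklevel=2)
        exponent = _BELL_EXPONENT_CAP
    return k1o * np.exp(exponent)


def _rhs_unchecked(state: np.ndarray, p: KineticParameters, f: float) -> np.ndarray:
    T_st, FT_st, pFT_st = state
    T = p.T_total - T_st - FT_st - pFT_st
    F = p.F_total - FT_st - pFT_st
    k1 = k1_of_force(p.k1o, p.alpha, f)
    dT_st = k1 * T - p.k2 * T_st - p.k3 * T_st * F + p.k4 * FT_st
    dFT_st = p.k3 * T_st * F - p.k4 * FT_st - p.k5 * FT_st + p.k6 * pFT_st
    dpFT_st = p.k5 * FT_st - p.k6 * pFT_st
    return np.array([dT_st, dFT_st, dpFT_st])


def rhs(state, params: KineticParameters, f: float) -> np.ndarray:
    """Time derivatives of (T_st, FT_st, pFT_st); T and F are
    eliminated through the conservation laws."""
    state = np.asarray(state, dtype=float)
    if state.shape != (3,):
        raise ValueError("state must be (T_st, FT_st, pFT_st)")
    if np.any(state < -1e-12 * params.T_total):
        raise ValueError("negative species count")
    T = params.T_total - state.sum()
    F = params.F_total - state[1] - state[2]
    if T < -1e-9 * params.T_total or F < -1e-9 * params.F_total:
        raise ValueError("state violates conservation bounds")
    return _rhs_unchecked(state, params, f)


@dataclass(frozen=True)
class SteadyState:
    """Molecule counts of all five species at one applied force."""

    T: float
    T_st: float
    F: float
    FT_st: float
    pFT_st: float
    f: float
    residual: float  # max |d/dt| at the solution

    def as_dict(self) -> dict:
        return {"f": self.f, "T": self.T, "T_st": self.T_st, "F": self.F,
                "FT_st": self.FT_st, "pFT_st": self.pFT_st}


def _quadratic_root(p: KineticParameters, f: float) -> np.ndarray | None:
    """Closed-form steady state used only to seed the root search.

    At steady state Eq. d(pFT_st)/dt = 0 gives pFT = (k5/k6)·FT, the
    complex equation then gives k3·T_st·F = k4·FT, and the talin
    equation reduces to T_st = (k1/k2)·T, collapsing the system to one
    quadratic in FT_st.
    """
    if p.k6 == 0 or p.k4 == 0 or p.k2 == 0:
        return None
    k1 = k1_of_force(p.k1o, p.alpha, f)
    c = 1.0 + p.k5 / p.k6
    a_t = k1 / (k1 + p.k2)  # T_st = a_t * (T_total - c*FT)
    # FT = (k3/k4) * T_st * (F_total - c*FT)
    g = p.k3 / p.k4 * a_t
    # FT = g (T_total - c FT)(F_total - c FT)  ->  g c² FT² - (g c (T+F) + 1) FT + g T F = 0
    A = g * c * c
    B = -(g * c * (p.T_total + p.F_total) + 1.0)
    C = g * p.T_total * p.F_total
    if A == 0:
        FT = -C / B
    else:
        disc = B * B - 4 * A * C
        if disc < 0:
            return None
        FT = (-B - np.sqrt(disc)) / (2 * A)  # smaller root keeps species positive
    pFT = p.k5 / p.k6 * FT
    T_st = a_t * (p.T_total - c * FT)
    return np.array([T_st, FT, pFT])


def solve_steady_state(params: KineticParameters, f: float,
                       tol: float = 1e-10, n_starts: int = 8) -> SteadyState:
    """Non-negative steady state of the reduced 3-variable system.

    A Newton-type root finder (MINPACK hybr) is run from ``n_starts``
    points spanning the conservation simplex; all converged,
    non-negative roots must agree, which doubles as a uniqueness check.
    A long-time stiff ODE integration is used as fallback when no start
    converges.
    """
    scale = max(params.T_total, params.F_total)

    rng = np.random.default_rng(0)  # fixed: starts are deterministic by design
    starts = [np.zeros(3), np.full(3, 0.05 * scale)]
    seed = _quadratic_root(params, f)
    if seed is not None and np.all(np.isfinite(seed)):
        starts.insert(0, np.clip(seed, 0, None))
    while len(starts) < n_starts:
        w = rng.dirichlet([1, 1, 1, 1])  # (T, T_st, FT, pFT) fractions
        t_part = w[1:] * params.T_total
        # keep FAK conservation feasible
        fak_used = t_part[1] + t_part[2]
        if fak_used > params.F_total:
            t_part[1:] *= 0.9 * params.F_total / fak_used
        starts.append(t_part)

    roots = []
    for x0 in starts:
        sol = scipy.optimize.root(lambda x: _rhs_unchecked(x, params, f), x0,
                                  method="hybr", tol=1e-13)
        x = sol.x
        res = np.max(np.abs(_rhs_unchecked(x, params, f)))
        if res < tol * max(1.0, scale) and np.all(x > -1e-9 * scale):
            roots.append(np.clip(x, 0.0, None))
    if not roots:
        x = integrate_to_steady_state(params, f)
        res = np.max(np.abs(_rhs_unchecked(x, params, f)))
        if res > 1e-6 * scale:
            raise RuntimeError(
                f"no converged non-negative steady state at f={f} (residual {res:.3e})")
        roots = [x]
    ref = roots[0]
    for r in roots[1:]:
        if np.max(np.abs(r - ref)) > 1e-6 * max(1.0, scale):
            raise RuntimeError(f"multiple distinct steady states found at f={f}")

    T_st, FT_st, pFT_st = ref
    return SteadyState(
        T=float(params.T_total - T_st - FT_st - pFT_st),
        T_st=float(T_st), F=float(params.F_total - FT_st - pFT_st),
        FT_st=float(FT_st), pFT_st=float(pFT_st), f=float(f),
        residual=float(np.max(np.abs(_rhs_unchecked(ref, params, f)))),
    )


def integrate_to_steady_state(params: KineticParameters, f: float,
                              rtol: float = 1e-10, atol: float = 1e-12) -> np.ndarray:
    """Long-time stiff integration of the ODEs from the fully
    unstretched state; serves as the independent relaxation oracle."""
    rates = [k1_of_force(params.k1o, params.alpha, f), params.k2,
             params.k3 * max(params.T_total, params.F_total),
             params.k4, params.k5, params.k6]
    min_rate = min(r for r in rates if r > 0)
    t_end = 1e4 / min_rate
    sol = solve_ivp(lambda t, y: _rhs_unchecked(y, params, f),
                    (0.0, t_end), np.zeros(3), method="Radau",
                    rtol=rtol, atol=atol * max(params.T_total, params.F_total))
    if not sol.success:
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.y[:, -1]


# ---------------------------------------------------------------------------
# Sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    """Steady states over a force grid, with normalized columns and
    per-species linearity diagnostics."""

    table: pd.DataFrame
    linearity: dict  # species -> {"slope": ..., "r2": ...}
    param_name: str | None = None
    param_value: float | None = None

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def sweep_force(params: KineticParameters, f_grid) -> SweepResult:
    """Steady state at every force in ``f_grid`` (pN).

    Species are reported absolute and relative to their value at the
    smallest force in the sweep (the "relative number" convention of
    force-response plots).
    """
    f_grid = np.asarray(f_grid, dtype=float)
    if f_grid.size == 0 or np.any(f_grid < 0):
        raise ValueError("force grid must be non-empty and non-negative")
    order = np.argsort(f_grid)
    states = []
    for f in f_grid[order]:
        try:
            states.append(solve_steady_state(params, f))
        except RuntimeError as err:
            raise RuntimeError(f"steady-state solve failed at f={f} pN") from err
    table = pd.DataFrame([s.as_dict() for s in states])
    for sp in SPECIES:
        base = table[sp].iloc[0]
        table[f"{sp}_rel"] = table[sp] / base if base > 0 else np.nan
    linearity = {}
    for sp in SPECIES:
        if table["f"].nunique() >= 3:
            fit = linear_fit(table["f"], table[sp])
            linearity[sp] = {"slope": fit.slope, "r2": fit.r2}
    return SweepResult(table=table, linearity=linearity)


_SWEEPABLE = {"k1o", "k2", "k3", "k4", "k5", "k6", "alpha", "T_total", "F_total"}


def sweep_parameter(params: KineticParameters, name: str, values, f_grid) -> list[SweepResult]:
    """One force sweep per value of parameter ``name`` (a family of
    curves, e.g. varying α, k3 or k5)."""
    if name not in _SWEEPABLE:
        raise ValueError(f"cannot sweep {name!r}; choose from {sorted(_SWEEPABLE)}")
    out = []
    for v in values:
        res = sweep_force(params.replace(**{name: float(v)}), f_grid)
        res.param_name = name
        res.param_value = float(v)
        res.table.insert(1, "param_value", float(v))
        out.append(res)
    return out


def linearity_metric(sweep: SweepResult, species: str) -> tuple[float, float]:
    """OLS slope and R² of one species' count against force over the
    sweep grid; quantifies "increases linearly with force"."""
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}")
    table = sweep.table
    if table["f"].nunique() < 3:
        raise ValueError("need at least 3 distinct forces")
    y = np.asarray(table[species], float)
    if np.ptp(y) == 0:  # flat curve: slope 0, R² undefined -> report 0
        return 0.0, 0.0
    fit = linear_fit(table["f"], y)
    return fit.slope, fit.r2
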