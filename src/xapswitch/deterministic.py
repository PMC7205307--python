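"""Deterministic analysis: fixed points, stability, reduction, bifurcations.

At steady state the mRNA and protein equations are linear and can be
eliminated:

    m_a = (rho_m / gamma_mp) * p_active(x_a),   p_a = rho_p * m_a,

leaving a single scalar balance for intracellular xanthosine

    g(x_a) = T(x_a) * rho * p_active(x_a) + k_eta * (c_a - xi * x_a) = 0,

with rho = rho_m rho_p / gamma_mp and T the per-protein net flux.  Roots
are bracketed on a log grid and polished by bisection; every root is
back-substituted and verified against the full 3D right-hand side.
Stability comes from the eigenvalues of the analytic Jacobian.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .model_core import NondimParams, SystemState, rhs_nondimensional
from .variants import CircuitVariant, RateLaws, apply_variant

__all__ = [
    "FixedPoint", "BifurcationDiagram", "find_fixed_points", "jacobian",
    "reduce_mrna_qss", "integrate", "bifurcation_diagram", "bistable_range",
]

#: Default log-spaced search window and resolution for the scalar root scan.
X_SCAN_BOUNDS = (1e-6, 1e8)
X_SCAN_POINTS = 2000

#: Eigenvalue dead zone around zero used for the marginal classification.
STABILITY_TOL = 1e-9

#: Acceptable residual of the full 3D RHS at a reported fixed point.
RESIDUAL_TOL = 1e-9


@dataclass(frozen=True)
class FixedPoint:
    """A steady state with its stability classification.

    ``index`` ranks coexisting fixed points by protein level (1 = lowest);
    ``stability`` is one of ``'stable'``, ``'unstable'`` or ``'marginal'``
    (an eigenvalue real part inside the dead zone, i.e. fold vicinity).
    """

    state: SystemState
    stability: str
    eigenvalues: tuple[complex, complex, complex]
    index: int = 0

    @property
    def is_stable(self) -> bool:
        return self.stability == "stable"

    @property
    def eig_re_max(self) -> float:
        return max(ev.real for ev in self.eigenvalues)


@dataclass
class BifurcationDiagram:
    """Fixed points along a control-parameter grid, with located folds."""

    control: str
    grid: np.ndarray
    points: list[list[FixedPoint]]
    folds: list[float] = field(default_factory=list)

    def branch_counts(self) -> np.ndarray:
        return np.array([len(fps) for fps in self.points])

    def bistable_window(self) -> tuple[float, float] | None:
        """Control-value range with three coexisting fixed points."""
        mask = self.branch_counts() == 3
        if not mask.any():
            return None
        vals = self.grid[mask]
        return float(vals.min()), float(vals.max())

    def to_frame(self):
        """Tidy table: one row per (control value, fixed point)."""
        import pandas as pd

        rows = []
        for cv, fps in zip(self.grid, self.points):
            for fp in fps:
                rows.append({
                    "control_value": float(cv), "branch_index": fp.index,
                    "m_a": fp.state.m_a, "p_a": fp.state.p_a, "x_a": fp.state.x_a,
                    "stability": fp.stability, "eig_re_max": fp.eig_re_max,
                })
        return pd.DataFrame(rows)


def _steady_scalar(laws: RateLaws):
    """The scalar steady-state balance g(x) and the back-substitution."""
    p = laws.params

    def g(x):
        pa = p.rho * laws.p_active(x)
        return laws.transport(x) * pa + p.k_eta * (p.c_a - p.xi * x)

    def back(x):
        pact = laws.p_active(x)
        m = p.rho_m / p.gamma_mp * pact
        return np.array([m, p.rho_p * m, x])

    return g, back


def jacobian(state, params: NondimParams,
             variant: CircuitVariant | None = None) -> np.ndarray:
    """Analytic 3x3 Jacobian of the nondimensional system at ``state``."""
    laws = apply_variant(variant or CircuitVariant(), params)
    y = state.as_array() if isinstance(state, SystemState) else np.asarray(state, float)
    _, p_a, x_a = y
    return np.array([
        [-params.gamma_mp, 0.0, params.rho_m * float(laws.dp_active_dx(x_a))],
        [params.rho_p, -1.0, 0.0],
        [0.0, float(laws.transport(x_a)),
         float(laws.dtransport_dx(x_a)) * p_a - params.k_eta * params.xi],
    ])


def _classify(eigs: np.ndarray) -> str:
    re = eigs.real
    if np.any(np.abs(re) <= STABILITY_TOL):
        return "marginal"
    return "stable" if np.all(re < 0) else "unstable"


def find_fixed_points(params: NondimParams,
                      variant: CircuitVariant | None = None,
                      x_bounds: tuple[float, float] = X_SCAN_BOUNDS,
                      n_grid: int = X_SCAN_POINTS) -> list[FixedPoint]:
    """All nonnegative steady states, ordered by protein level.

    Sign changes of the scalar balance g(x_a) are bracketed on a log grid
    over ``x_bounds`` and refined by bisection; x_a = 0 is checked
    explicitly (it is a root only at c_a = 0).  A warning is raised when a
    root sits on the scan boundary, which would indicate a missed branch.
    """
    v = variant or CircuitVariant()
    laws = apply_variant(v, params)
    g, back = _steady_scalar(laws)

    xs = np.geomspace(x_bounds[0], x_bounds[1], n_grid)
    vals = np.asarray(g(xs))
    roots: list[float] = []
    if params.c_a == 0.0 and g(0.0) == 0.0:
        roots.append(0.0)
    for i in np.flatnonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0):
        roots.append(brentq(g, xs[i], xs[i + 1], xtol=1e-30, rtol=1e-15))
    for i in np.flatnonzero(vals == 0.0):
        roots.append(float(xs[i]))
    # g(0) = k_eta c_a >= 0 and g -> -inf as x -> inf, so roots can escape
    # the window only if g has the "wrong" sign at a boundary.
    if vals[0] < 0 or vals[-1] > 0:
        warnings.warn("scalar balance has unexpected sign at the scan "
                      "boundary; a root may lie outside x_bounds", stacklevel=2)

    # dedupe (relative tolerance 1e-6)
    roots = sorted(roots)
    unique: list[float] = []
    for r in roots:
        if not unique or abs(r - unique[-1]) > 1e-6 * max(1.0, abs(unique[-1])):
            unique.append(r)

    fps = []
    for x in unique:
        y = back(x)
        resid = np.max(np.abs(rhs_nondimensional(np.clip(y, 0, None), params, v)))
        scale = max(1.0, float(np.max(np.abs(y))))
        if resid > RESIDUAL_TOL * scale:
            warnings.warn(f"discarding spurious root x_a={x:g} (residual {resid:g})",
                          stacklevel=2)
            continue
        eigs = np.linalg.eigvals(jacobian(y, params, v))
        eigs = tuple(sorted((complex(e) for e in eigs), key=lambda z: z.real))
        fps.append(FixedPoint(SystemState(*y), _classify(np.array(eigs)), eigs))

    fps.sort(key=lambda fp: fp.state.p_a)
    return [FixedPoint(fp.state, fp.stability, fp.eigenvalues, i + 1)
            for i, fp in enumerate(fps)]


# ---------------------------------------------------------------------------
# 2D reduction (mRNA quasi-steady state)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReducedSystem:
    """The (p_a, x_a) system with mRNA at quasi-steady state.

    d p_a/d tau = rho * p_active(x_a) - p_a
    d x_a/d tau = T(x_a) p_a + k_eta (c_a - xi x_a)

    ``protein_nullcline(x)`` returns p_a = rho * p_active(x); the
    xanthosine nullcline is p_a = -k_eta (c_a - xi x)/T(x) where defined.
    """

    laws: RateLaws

    def rhs(self, y) -> np.ndarray:
        p = self.laws.params
        pa, xa = np.asarray(y, dtype=float)
        dp = p.rho * self.laws.p_active(xa) - pa
        dx = self.laws.transport(xa) * pa + p.k_eta * (p.c_a - p.xi * xa)
        return np.array([dp, dx])

    def jacobian(self, y) -> np.ndarray:
        p = self.laws.params
        pa, xa = np.asarray(y, dtype=float)
        return np.array([
            [-1.0, p.rho * float(self.laws.dp_active_dx(xa))],
            [float(self.laws.transport(xa)),
             float(self.laws.dtransport_dx(xa)) * pa - p.k_eta * p.xi],
        ])

    def protein_nullcline(self, x):
        return self.laws.params.rho * self.laws.p_active(x)

    def xanthosine_nullcline(self, x):
        p = self.laws.params
        x = np.asarray(x, dtype=float)
        T = self.laws.transport(x)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(T != 0, -p.k_eta * (p.c_a - p.xi * x) / T, np.nan)

    def fixed_points(self) -> list[FixedPoint]:
        """2D fixed points: the (p_a, x_a) projections of the 3D ones,
        classified by the 2x2 Jacobian."""
        fps3 = find_fixed_points(self.laws.params, self.laws.variant)
        out = []
        for fp in fps3:
            y = (fp.state.p_a, fp.state.x_a)
            eigs = np.linalg.eigvals(self.jacobian(y))
            eigs = tuple(sorted((complex(e) for e in eigs), key=lambda z: z.real))
            out.append(FixedPoint(fp.state, _classify(np.array(eigs)), eigs, fp.index))
        return out


def reduce_mrna_qss(params: NondimParams,
                    variant: CircuitVariant | None = None) -> ReducedSystem:
    """Eliminate the fast mRNA variable by m_a = (rho_m/gamma_mp) p_active(x_a)."""
    return ReducedSystem(apply_variant(variant or CircuitVariant(), params))


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------

def integrate(params: NondimParams, initial, tau_end: float,
              variant: CircuitVariant | None = None,
              n_points: int = 500, rtol: float = 1e-8, atol: float = 1e-12):
    """Integrate the 3D system with a stiff solver (LSODA).

    Returns ``(tau, states)`` where ``states`` has shape (n_points, 3).
    States are clipped to the nonnegative octant, which the exact dynamics
    preserve anyway (all boundary fluxes point inward).
    """
    v = variant or CircuitVariant()
    y0 = initial.as_array() if isinstance(initial, SystemState) else np.asarray(initial, float)
    if np.any(y0 < 0):
        raise ValueError("initial state must be nonnegative")

    def f(t, y):
        return rhs_nondimensional(np.clip(y, 0.0, None), params, v)

    ts = np.linspace(0.0, tau_end, n_points)
    sol = solve_ivp(f, (0.0, tau_end), y0, method="LSODA", t_eval=ts,
                    rtol=rtol, atol=atol)
    if not sol.success:  # pragma: no cover - solver failure path
        raise RuntimeError(f"ODE integration failed: {sol.message}")
    return sol.t, np.clip(sol.y.T, 0.0, None)


# ---------------------------------------------------------------------------
# bifurcation analysis
# ---------------------------------------------------------------------------

def bifurcation_diagram(params: NondimParams, control: str = "c_a",
                        grid=None, variant: CircuitVariant | None = None,
                        refine_folds: bool = True,
                        fold_tol: float = 1e-4) -> BifurcationDiagram:
    """Fixed points along a grid of a control parameter.

    Fold (saddle-node) points, where the branch count changes along the
    grid, are refined by bisection on the count down to relative
    ``fold_tol``.  A single-point grid degenerates to one fixed-point
    computation.
    """
    if grid is None:
        grid = np.geomspace(1.0, 100.0, 61)
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be a nonempty sorted 1D array")

    def at(value):
        return find_fixed_points(params.with_(**{control: float(value)}), variant)

    points = [at(v) for v in grid]
    counts = [len(fps) for fps in points]

    folds: list[float] = []
    if refine_folds and len(grid) > 1:
        if max(counts) == 3 and (counts[0] == 3 or counts[-1] == 3):
            warnings.warn("grid may be too coarse to bracket both folds",
                          stacklevel=2)
        for i in range(len(grid) - 1):
            if counts[i] != counts[i + 1]:
                lo, hi = grid[i], grid[i + 1]
                nlo = counts[i]
                while (hi - lo) > fold_tol * max(1.0, abs(hi)):
                    mid = 0.5 * (lo + hi)
                    if len(at(mid)) == nlo:
                        lo = mid
                    else:
                        hi = mid
                folds.append(0.5 * (lo + hi))

    return BifurcationDiagram(control, grid, points, folds)


def bistable_range(params: NondimParams, scan: str,
                   bounds: tuple[float, float],
                   variant: CircuitVariant | None = None,
                   rel_tol: float = 1e-3) -> dict:
    """Critical value(s) of a scanned parameter where bistability appears/vanishes.

    Bisects on "number of fixed points == 3" over log-spaced probes of the
    scanned parameter (all others fixed).  Returns a dict with the probe
    grid verdicts and the refined critical values; if the system is
    monostable (or bistable) throughout, ``critical_values`` is empty and
    ``verdict`` says which.
    """
    lo, hi = bounds
    if not (0 < lo < hi):
        raise ValueError("bounds must be positive and increasing")
    probes = np.geomspace(lo, hi, 33)

    def bistable(value):
        return len(find_fixed_points(params.with_(**{scan: float(value)}), variant)) == 3

    flags = np.array([bistable(v) for v in probes])
    crit = []
    for i in range(len(probes) - 1):
        if flags[i] != flags[i + 1]:
            a, b = probes[i], probes[i + 1]
            fa = flags[i]
            while (b - a) > rel_tol * a:
                m = np.sqrt(a * b)
                if bistable(m) == fa:
                    a = m
                else:
                    b = m
            crit.append(float(np.sqrt(a * b)))

    if not crit:
        verdict = "bistable throughout" if flags[0] else "monostable throughout"
    else:
        verdict = "transition(s) found"
    return {"scan": scan, "bounds": bounds, "probes": probes,
            "bistable_flags": flags, "critical_values": crit, "verdict": verdict}
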