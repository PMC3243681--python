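"""Dimensionless miR-451/AMPK mutual-antagonism switch.

The module implements the two-variable core that decides whether a glioma
cell proliferates or migrates.  ``M`` is the miR-451 activity, ``A`` the
activity of the CAB39/LKB1/STRAD/AMPK complex, and ``G`` the glucose input.
Each species is produced autocatalytically with a Hill-type bound and is
repressed by the other, giving the slow-fast system

    eps * dM/dt = G + k1*k2^2 / (k2^2 + alpha*A^2) - M
          dA/dt = S + k3*k4^2 / (k4^2 + beta*M^2) - A

with time in units of the complex's lifetime (the reference hour) and
``eps`` the ratio of the degradation rates of the complex and of miR-451.
miR-451 turns over much faster, so eps is small and M is the fast variable,
relaxing almost instantly onto its nullcline for the current A.  For
intermediate glucose the system is bistable: a high-M (proliferative) and a
low-M (migratory) stable state coexist, separated by an unstable saddle
branch, and the two saddle-node folds of the equilibrium curve produce a
hysteresis loop in G.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "SwitchParams",
    "SwitchState",
    "Equilibrium",
    "EquilibriumBranch",
    "SwitchIntegrationError",
    "switch_rhs",
    "switch_jacobian",
    "ampk_nullcline",
    "steady_states",
    "integrate_switch",
    "continue_branch",
    "glucose_deprivation_response",
]


@dataclass(frozen=True)
class SwitchParams:
    """Dimensionless parameters of the miR-451/AMPK switch.

    Defaults are the reference parameterization of the model: autocatalytic
    rates ``k1 = k3 = 4.0``, inhibition half-max parameters ``k2 = k4 = 1.0``,
    inhibition strengths ``alpha = 1.6`` (of miR-451 by the complex) and
    ``beta = 1.0`` (of the complex by miR-451), complex source ``S = 0.2``,
    time-scale separation ``eps = 0.02``, and the go-or-grow threshold
    ``M_th = 2.0`` on miR-451.
    """

    k1: float = 4.0
    k2: float = 1.0
    alpha: float = 1.6
    k3: float = 4.0
    k4: float = 1.0
    beta: float = 1.0
    S: float = 0.2
    eps: float = 0.02
    M_th: float = 2.0

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "alpha", "k3", "k4", "beta", "S", "M_th"):
            if getattr(self, name) < 0:
                raise ValueError(f"SwitchParams.{name} must be nonnegative")
        if self.eps <= 0:
            raise ValueError("SwitchParams.eps must be positive")

    def with_(self, **kwargs) -> "SwitchParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SwitchState:
    """Phase point (M, A) of the switch."""

    M: float
    A: float

    def __post_init__(self) -> None:
        if self.M < 0 or self.A < 0:
            raise ValueError("SwitchState components must be nonnegative")


@dataclass(frozen=True)
class Equilibrium:
    M: float
    A: float
    stability: str  # "stable" | "unstable"


@dataclass(frozen=True)
class EquilibriumBranch:
    """The S-shaped equilibrium curve M*(G) with its fold points.

    ``points`` is ordered by G; ``fold_low``/``fold_high`` are the glucose
    levels of the two saddle-nodes, or ``None`` when the curve is monotone
    (no bistability).
    """

    G: np.ndarray
    M: np.ndarray
    A: np.ndarray
    stability: np.ndarray  # array of "stable"/"unstable" strings
    fold_low: float | None
    fold_high: float | None

    @property
    def bistable(self) -> bool:
        return self.fold_low is not None and self.fold_high is not None


class SwitchIntegrationError(RuntimeError):
    """Raised when the ODE integrator fails; carries the time reached."""

    def __init__(self, message: str, t_reached: float):
        super().__init__(f"{message} (time reached: {t_reached:g})")
        self.t_reached = t_reached


def _check_inputs(M, A, G) -> None:
    if np.any(np.asarray(G) < 0):
        raise ValueError("glucose level G must be nonnegative")
    if np.any(np.asarray(M) < 0) or np.any(np.asarray(A) < 0):
        raise ValueError("state (M, A) must be nonnegative")


def switch_rhs(M, A, G, params: SwitchParams = SwitchParams()):
    """Right-hand sides (dM/dt, dA/dt) of the switch ODE.

    Accepts scalars or arrays (broadcast elementwise); used both for the
    well-mixed switch and pointwise on spatial fields.  M is the fast
    variable (its balance is divided by eps).  Production terms are bounded
    by k1 and k3, so dM/dt < 0 whenever M > G + k1 and dA/dt < 0 whenever
    A > S + k3.
    """
    _check_inputs(M, A, G)
    p = params
    dM = (G + p.k1 * p.k2**2 / (p.k2**2 + p.alpha * np.square(A)) - M) / p.eps
    dA = p.S + p.k3 * p.k4**2 / (p.k4**2 + p.beta * np.square(M)) - A
    return dM, dA


def switch_jacobian(M: float, A: float, params: SwitchParams) -> np.ndarray:
    """Analytic 2x2 Jacobian of the switch ODE at (M, A)."""
    p = params
    dM_dA = -p.k1 * p.k2**2 * p.alpha * 2.0 * A / (p.k2**2 + p.alpha * A**2) ** 2 / p.eps
    dA_dM = -p.k3 * p.k4**2 * p.beta * 2.0 * M / (p.k4**2 + p.beta * M**2) ** 2
    return np.array([[-1.0 / p.eps, dM_dA], [dA_dM, -1.0]])


def ampk_nullcline(M, params: SwitchParams):
    """A on its nullcline as a function of M (the slow-manifold value)."""
    p = params
    return p.S + p.k3 * p.k4**2 / (p.k4**2 + p.beta * np.square(M))


def _equilibrium_residual(M, G, params: SwitchParams):
    """Scalar residual in M after eliminating A via its nullcline."""
    p = params
    A = ampk_nullcline(M, params)
    return G + p.k1 * p.k2**2 / (p.k2**2 + p.alpha * np.square(A)) - M


def steady_states(
    G: float,
    params: SwitchParams = SwitchParams(),
    *,
    scan_resolution: float = 1e-4,
) -> list[Equilibrium]:
    """All equilibria of the switch at glucose level ``G``, with stability.

    A is eliminated via its nullcline; the scalar residual in M is scanned
    on a dense grid over the production-bound box [0, G + k1], sign changes
    are bracketed with Brent's method and polished by Newton iteration to a
    residual below 1e-10.  Roots closer than 1e-8 are merged.  Stability is
    the sign of the largest real part of the analytic Jacobian eigenvalues.
    """
    if G < 0:
        raise ValueError("glucose level G must be nonnegative")
    p = params
    M_hi = G + p.k1 + 1e-9
    n_pts = max(int(np.ceil(1.0 / scan_resolution)), 64) + 1
    Ms = np.linspace(0.0, M_hi, n_pts)
    res = _equilibrium_residual(Ms, G, p)

    roots: list[float] = []
    # exact zeros on grid nodes
    for i in np.nonzero(res == 0.0)[0]:
        roots.append(float(Ms[i]))
    sign = np.sign(res)
    crossings = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    for i in crossings:
        r = brentq(_equilibrium_residual, Ms[i], Ms[i + 1], args=(G, p),
                   xtol=1e-14, rtol=8.9e-16)
        # Newton polish
        for _ in range(5):
            f = _equilibrium_residual(r, G, p)
            if abs(f) < 1e-12:
                break
            h = 1e-7
            df = (_equilibrium_residual(r + h, G, p) - _equilibrium_residual(r - h, G, p)) / (2 * h)
            if df == 0:
                break
            r -= f / df
        roots.append(float(r))

    roots.sort()
    merged: list[float] = []
    for r in roots:
        if not merged or abs(r - merged[-1]) > 1e-8:
            merged.append(r)

    out = []
    for M in merged:
        A = float(ampk_nullcline(M, p))
        eig = np.linalg.eigvals(switch_jacobian(M, A, p))
        stability = "stable" if np.max(eig.real) < 0 else "unstable"
        out.append(Equilibrium(M=M, A=A, stability=stability))
    return out


def integrate_switch(
    initial: SwitchState,
    glucose: Callable[[float], float] | float,
    params: SwitchParams = SwitchParams(),
    t_span: tuple[float, float] = (0.0, 100.0),
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    t_eval: Sequence[float] | None = None,
    method: str = "LSODA",
):
    """Integrate the switch ODE under a (possibly time-varying) glucose input.

    ``glucose`` is either a constant or a callable of time; it must be
    nonnegative on ``t_span``.  Uses a stiff-aware integrator (LSODA by
    default) since A evolves on the slow eps timescale.  Returns the
    ``scipy`` solution object (``sol.t``, ``sol.y`` with rows M, A).
    """
    g = (lambda t: float(glucose)) if not callable(glucose) else glucose
    if initial.M < 0 or initial.A < 0:
        raise ValueError("initial state must be nonnegative")

    def rhs(t, y):
        M, A = y
        Gt = g(t)
        if Gt < 0:
            raise ValueError(f"glucose waveform negative at t={t:g}")
        p = params
        dM = (Gt + p.k1 * p.k2**2 / (p.k2**2 + p.alpha * A * A) - M) / p.eps
        dA = p.S + p.k3 * p.k4**2 / (p.k4**2 + p.beta * M * M) - A
        return (dM, dA)

    def jac(t, y):
        return switch_jacobian(y[0], y[1], params)

    sol = solve_ivp(rhs, t_span, [initial.M, initial.A], method=method,
                    rtol=rtol, atol=atol, t_eval=t_eval, jac=jac)
    if not sol.success:
        raise SwitchIntegrationError(sol.message, float(sol.t[-1]) if sol.t.size else t_span[0])
    return sol


def _root_count(G: float, params: SwitchParams, scan_resolution: float) -> int:
    return len(steady_states(G, params, scan_resolution=scan_resolution))


def continue_branch(
    params: SwitchParams = SwitchParams(),
    G_range: tuple[float, float] = (0.0, 1.0),
    G_resolution: float = 0.002,
    *,
    fold_tol: float = 1e-4,
    scan_resolution: float = 1e-4,
) -> EquilibriumBranch:
    """Assemble the equilibrium curve M*(G) and locate its fold points.

    ``steady_states`` is called on a uniform G grid; fold points are found
    by bisection on the change of the equilibrium count between adjacent
    grid cells, refined to |dG| <= ``fold_tol``.  A monotone (fold-free)
    curve is reported with ``fold_low = fold_high = None``.
    """
    if G_range[0] < 0 or G_range[1] <= G_range[0] or G_resolution <= 0:
        raise ValueError("invalid G_range or G_resolution")
    Gs = np.arange(G_range[0], G_range[1] + 0.5 * G_resolution, G_resolution)
    rows: list[tuple[float, float, float, str]] = []
    counts = np.empty(Gs.size, dtype=int)
    for i, G in enumerate(Gs):
        eqs = steady_states(float(G), params, scan_resolution=scan_resolution)
        counts[i] = len(eqs)
        for eq in eqs:
            rows.append((float(G), eq.M, eq.A, eq.stability))

    def refine(lo: float, hi: float, lo_count: int) -> float:
        """Bisect the G interval across which the root count changes."""
        while hi - lo > fold_tol:
            mid = 0.5 * (lo + hi)
            if _root_count(mid, params, scan_resolution) == lo_count:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    fold_low = fold_high = None
    changes = np.nonzero(np.diff(counts) != 0)[0]
    fold_Gs = [refine(float(Gs[i]), float(Gs[i + 1]), int(counts[i])) for i in changes]
    if fold_Gs:
        fold_low = min(fold_Gs)
        fold_high = max(fold_Gs)
        if len(fold_Gs) == 1:  # only one fold inside the window: not an S-curve
            fold_low = fold_high = None

    arr = np.array(rows, dtype=object)
    return EquilibriumBranch(
        G=np.array([r[0] for r in rows]),
        M=np.array([r[1] for r in rows]),
        A=np.array([r[2] for r in rows]),
        stability=np.array([r[3] for r in rows]),
        fold_low=fold_low,
        fold_high=fold_high,
    )


def glucose_deprivation_response(
    params: SwitchParams = SwitchParams(),
    G_high: float = 0.7,
    G_low: float | None = None,
    *,
    relax_time: float = 400.0,
) -> float:
    """Percent reduction of equilibrium miR-451 on glucose deprivation.

    Emulates the glucose-withdrawal protocol (normal 4.5 g/l vs reduced
    0.3 g/l medium): the cell sits on the high-glucose equilibrium (upper
    branch at ``G_high``), glucose is stepped down to ``G_low`` (default
    ``G_high * 0.3/4.5``), and the state relaxes to the history-consistent
    equilibrium.  Returns ``100 * (1 - M_low / M_high)``.
    """
    if G_low is None:
        G_low = G_high * (0.3 / 4.5)
    if G_low == G_high:
        return 0.0
    if not (G_high > G_low >= 0):
        raise ValueError("require G_high >= G_low >= 0")

    eq_high = steady_states(G_high, params)
    stable_high = [e for e in eq_high if e.stability == "stable"]
    top = max(stable_high, key=lambda e: e.M)  # upper branch

    # history-consistent low state: relax from the high-glucose equilibrium
    sol = integrate_switch(SwitchState(top.M, top.A), G_low, params,
                           (0.0, relax_time), rtol=1e-10, atol=1e-12)
    M_end, A_end = sol.y[0, -1], sol.y[1, -1]
    eq_low = steady_states(G_low, params)
    stable_low = [e for e in eq_low if e.stability == "stable"]
    M_low = min(stable_low, key=lambda e: abs(e.M - M_end)).M
    if len(stable_low) == 1 and M_low > params.M_th:
        warnings.warn(
            "glucose_deprivation_response: G_low leaves the switch on a "
            "proliferative branch (no distinct low-glucose state)",
            stacklevel=2,
        )
    return 100.0 * (1.0 - M_low / top.M)
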