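"""1-D finite-volume spatial model of glioma growth and invasion.

Six fields live on a uniform grid over the dimensionless interval [0, 1]
(reference length 1 cm, x=0 the tumor core, x=1 the far field):

* ``n``   tumor cell density (carrying capacity 1),
* ``rho`` extracellular matrix (ECM) density (carrying capacity 1),
* ``P``   matrix-metalloproteinase (MMP) concentration,
* ``G``   glucose concentration,
* ``M``, ``A``  local miR-451 and AMPK-complex activities.

Cells are in growth mode where M > M_th (logistic proliferation) and in
invasion mode where M < M_th (random motility plus chemotaxis up the
glucose gradient and haptotaxis up the ECM gradient).  MMP is secreted by
invasive cells in the presence of ECM and degrades it; glucose is consumed
by cells and replenished by pulsed injections in a far-field band.

Discretization: finite volumes with central differences for diffusion and
first-order upwinding for the taxis advection; zero-flux boundaries for all
fields (glucose enters only through the injection source).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from glioswitch.switch_network import SwitchParams, steady_states, switch_rhs

__all__ = [
    "Grid1D",
    "FieldSet",
    "PDEParams",
    "InjectionSchedule",
    "phase_indicators",
    "taxis_velocity",
    "movement_flux",
    "reaction_terms",
    "injection_source",
    "initial_conditions",
]


@dataclass(frozen=True)
class Grid1D:
    """Uniform finite-volume grid on [0, 1]; default spacing dx = 0.01."""

    n_cells: int = 100

    def __post_init__(self) -> None:
        if self.n_cells < 2:
            raise ValueError("Grid1D needs at least 2 cells")

    @property
    def dx(self) -> float:
        return 1.0 / self.n_cells

    @property
    def centers(self) -> np.ndarray:
        return (np.arange(self.n_cells) + 0.5) * self.dx

    @property
    def faces(self) -> np.ndarray:
        return np.arange(self.n_cells + 1) * self.dx


@dataclass
class FieldSet:
    """Per-cell values of the six model fields on a Grid1D."""

    n: np.ndarray
    rho: np.ndarray
    P: np.ndarray
    G: np.ndarray
    M: np.ndarray
    A: np.ndarray

    def copy(self) -> "FieldSet":
        return FieldSet(*(getattr(self, f).copy() for f in ("n", "rho", "P", "G", "M", "A")))

    def as_dict(self) -> dict[str, np.ndarray]:
        return {f: getattr(self, f) for f in ("n", "rho", "P", "G", "M", "A")}

    def validate(self, tol: float = 1e-9) -> None:
        for name, arr in self.as_dict().items():
            if np.any(arr < -tol):
                raise ValueError(f"field {name} has negative values")
        if np.any(self.n > 1 + 1e-6) or np.any(self.rho > 1 + 1e-6):
            raise ValueError("n and rho must not exceed carrying capacity 1")


@dataclass(frozen=True)
class PDEParams:
    """Dimensionless coefficients of the tissue-scale model.

    Printed reference values: tumor growth rate ``r_growth = 0.1``, ECM
    degradation by MMP ``d_rho = 0.508``, ECM reconstruction ``r_rho =
    0.18``, MMP production ``a_P = 2.5``, MMP decay ``d_P = 0.18``, glucose
    consumption ``lambda_G = 1.0``.

    Transport coefficients (length unit 1 cm, time unit 1 h) are effective
    tissue-scale values chosen so that glucose pulses reach the tumor
    within a fraction of the injection period while cell motility stays
    small and MMP remains localized near the secreting front; see the
    methods note for the calibration rationale.  The taxis velocity uses
    the Lapidus-Schiller receptor law
    v = chi*grad(G)/(1+sigma_G*G)^2 + h*grad(rho)/(1+sigma_rho*rho)^2.
    """

    D_n: float = 1e-5
    D_P: float = 5e-4
    D_G: float = 0.45
    r_growth: float = 0.1
    d_rho: float = 0.508
    r_rho: float = 0.18
    a_P: float = 2.5
    d_P: float = 0.18
    lambda_G: float = 1.0
    chi: float = 0.01
    h_hapto: float = 0.001
    sigma_G: float = 1.0
    sigma_rho: float = 1.0
    smoothing_width: float = 0.05
    mmp_gated_by_invasion: bool = True
    switch: SwitchParams = field(default_factory=SwitchParams)

    def __post_init__(self) -> None:
        for name in ("D_n", "D_P", "D_G", "r_growth", "d_rho", "r_rho", "a_P",
                     "d_P", "lambda_G", "chi", "h_hapto", "sigma_G", "sigma_rho"):
            if getattr(self, name) < 0:
                raise ValueError(f"PDEParams.{name} must be nonnegative")
        if self.smoothing_width <= 0:
            raise ValueError("PDEParams.smoothing_width must be positive")

    def with_(self, **kwargs) -> "PDEParams":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class InjectionSchedule:
    """Pulsed glucose source in a far-field band adjacent to x = 1.

    Injections start at t = 0 and repeat with period ``tau`` (hours); each
    pulse lasts ``duration`` hours and delivers a dose ``g_in`` per unit
    length of the band, i.e. the source amplitude is ``g_in / duration`` on
    the band during the pulse and the total glucose added per pulse is
    ``g_in * band_width``.
    """

    tau: float = 10.0
    g_in: float = 5.0
    duration: float = 0.01
    band_width: float = 0.08
    n_injections: int | None = None

    def __post_init__(self) -> None:
        if self.tau <= 0 or self.duration <= 0 or self.g_in < 0:
            raise ValueError("tau and duration must be positive, g_in nonnegative")
        if self.duration >= self.tau:
            raise ValueError("InjectionSchedule: duration must be < tau")
        if not (0 < self.band_width <= 1):
            raise ValueError("InjectionSchedule: band_width must lie in (0, 1]")

    @property
    def band(self) -> tuple[float, float]:
        """The injection subdomain Omega_b = [1 - band_width, 1]."""
        return (1.0 - self.band_width, 1.0)

    @property
    def amplitude(self) -> float:
        """Source strength during a pulse (dose spread over the duration)."""
        return self.g_in / self.duration

    def pulse_times(self, t_end: float) -> np.ndarray:
        """Pulse start times t_i = i * tau in [0, t_end)."""
        n_max = int(np.floor(t_end / self.tau)) + 1
        if self.n_injections is not None:
            n_max = min(n_max, self.n_injections)
        t = np.arange(n_max) * self.tau
        return t[t < t_end]

    def dose_per_pulse(self) -> float:
        """Total glucose delivered per pulse (domain integral of the source)."""
        return self.g_in * self.band_width


def phase_indicators(M: np.ndarray, M_th: float, smoothing_width: float):
    """Smoothed growth/invasion indicator weights.

    Logistic sigmoids replacing the sharp indicators 1{M > M_th} and
    1{M < M_th}: the two weights sum to one everywhere and are both 1/2
    exactly at M = M_th.  ``smoothing_width`` sets the transition scale in
    M units; the sharp indicators are recovered as it tends to zero.
    """
    if smoothing_width <= 0:
        raise ValueError("smoothing_width must be positive")
    z = (np.asarray(M, dtype=float) - M_th) / smoothing_width
    growth = 0.5 * (1.0 + np.tanh(0.5 * z))  # logistic(z)
    return growth, 1.0 - growth


def taxis_velocity(G_face, dG_face, rho_face, drho_face, params: PDEParams):
    """Advective velocity on faces: saturating chemotaxis plus haptotaxis."""
    chemo = params.chi * dG_face / (1.0 + params.sigma_G * G_face) ** 2
    hapto = params.h_hapto * drho_face / (1.0 + params.sigma_rho * rho_face) ** 2
    return chemo + hapto


def movement_flux(
    n: np.ndarray,
    G: np.ndarray,
    rho: np.ndarray,
    params: PDEParams,
    grid: Grid1D,
    invasion_weight: np.ndarray | None = None,
) -> np.ndarray:
    """Tumor-cell flux on the n_cells+1 faces (zero at both boundaries).

    flux = -D_n dn/dx + n (1 - n) v with v the chemo/haptotactic velocity;
    diffusion by central differences, advection by first-order upwinding
    with the volume-filling factor evaluated in the receiving (downwind)
    cell, so cells cannot crowd past the carrying capacity even where the
    velocity field is compressive.  When ``invasion_weight`` is given the
    whole flux is gated by the face-averaged weight (movement happens in
    invasion mode only), keeping the scheme conservative.
    """
    if np.any(n < 0) or np.any(G < 0) or np.any(rho < 0):
        raise ValueError("movement_flux requires nonnegative fields")
    dx = grid.dx
    flux = np.zeros(grid.n_cells + 1)

    dn = np.diff(n) / dx
    dG = np.diff(G) / dx
    drho = np.diff(rho) / dx
    G_face = 0.5 * (G[:-1] + G[1:])
    rho_face = 0.5 * (rho[:-1] + rho[1:])

    v = taxis_velocity(G_face, dG, rho_face, drho, params)
    upwind_n = np.where(v > 0, n[:-1], n[1:])
    room = np.clip(1.0 - np.where(v > 0, n[1:], n[:-1]), 0.0, 1.0)
    interior = -params.D_n * dn + upwind_n * room * v
    if invasion_weight is not None:
        interior = interior * 0.5 * (invasion_weight[:-1] + invasion_weight[1:])
    flux[1:-1] = interior
    return flux


def injection_source(t: float, schedule: InjectionSchedule, grid: Grid1D) -> np.ndarray:
    """Per-cell indicator of the glucose injection (0, partial, or 1).

    1 inside the far-field band during a pulse window [t_i, t_i + duration];
    cells straddling the band boundary are weighted by their overlap
    fraction; 0 between pulses.
    """
    if t < 0:
        raise ValueError("time must be nonnegative")
    ind = np.zeros(grid.n_cells)
    i = int(np.floor(t / schedule.tau + 1e-12))
    if schedule.n_injections is not None and i >= schedule.n_injections:
        return ind
    t_i = i * schedule.tau
    if not (t_i <= t < t_i + schedule.duration):
        return ind
    lo, hi = schedule.band
    left = grid.faces[:-1]
    right = grid.faces[1:]
    overlap = np.clip(np.minimum(right, hi) - np.maximum(left, lo), 0.0, None)
    return overlap / grid.dx


def reaction_terms(
    fields: FieldSet,
    params: PDEParams,
    injection_indicator: np.ndarray,
    g_in_rate: float,
) -> dict[str, np.ndarray]:
    """Per-cell time derivatives of the local (non-transport) dynamics.

    n:    growth_weight * r_growth * n (1 - n)         (logistic, growth mode)
    rho:  -d_rho * P * rho + r_rho * rho (1 - rho)     (MMP degradation, remodeling)
    P:    a_P * [invasion_weight] * n * rho - d_P * P  (secretion by invasive cells)
    G:    -lambda_G * n * G + g_in_rate * indicator    (consumption + injection)
    M, A: pointwise switch dynamics driven by local G.
    """
    f = fields
    sw = params.switch
    growth_w, invasion_w = phase_indicators(f.M, sw.M_th, params.smoothing_width)
    dn = growth_w * params.r_growth * f.n * (1.0 - f.n)
    drho = -params.d_rho * f.P * f.rho + params.r_rho * f.rho * (1.0 - f.rho)
    gate = invasion_w if params.mmp_gated_by_invasion else 1.0
    dP = params.a_P * gate * f.n * f.rho - params.d_P * f.P
    dG = -params.lambda_G * f.n * f.G + g_in_rate * injection_indicator
    dM, dA = switch_rhs(f.M, f.A, np.maximum(f.G, 0.0), sw)
    return {"n": dn, "rho": drho, "P": dP, "G": dG, "M": dM, "A": dA}


def _smooth_plateau(x: np.ndarray, edge: float, width: float) -> np.ndarray:
    """1 left of ``edge``, smooth cosine ramp to exactly 0 over ``width``.

    Compact support matters: growth mode is purely logistic, so cells can
    only colonize new territory by moving there in invasion mode, never by
    amplifying a spurious density tail.
    """
    ramp = 0.5 * (1.0 + np.cos(np.pi * np.clip((x - edge) / width, 0.0, 1.0)))
    return np.where(x <= edge, 1.0, ramp)


def equilibrium_after_deprivation(G0: float, switch: SwitchParams,
                                  G_culture: float = 1.0) -> tuple[float, float]:
    """History-consistent switch state at glucose ``G0``.

    Cells arrive from normal-glucose culture (``G_culture``, mono-stable
    proliferative branch); the switch then relaxes under the ambient
    ``G0``.  With the reference parameters and low G0 this lands on the
    migratory branch (the upper branch has lost stability below the lower
    fold); with weakened inhibition of miR-451 the upper branch may persist
    down to G0 and the cells stay proliferative — the branch choice is the
    glucose history, not an arbitrary root.
    """
    from glioswitch.switch_network import SwitchState, integrate_switch

    stable_hi = [e for e in steady_states(G_culture, switch) if e.stability == "stable"]
    top = max(stable_hi, key=lambda e: e.M)
    sol = integrate_switch(SwitchState(top.M, top.A), G0, switch, (0.0, 300.0),
                           rtol=1e-10, atol=1e-12)
    M_end, A_end = sol.y[0, -1], sol.y[1, -1]
    stable_lo = [e for e in steady_states(G0, switch) if e.stability == "stable"]
    eq = min(stable_lo, key=lambda e: abs(e.M - M_end) + abs(e.A - A_end))
    return eq.M, eq.A


def initial_conditions(
    scenario: str,
    grid: Grid1D,
    params: PDEParams,
    *,
    tumor_width: float = 0.0575,
    front_width: float = 0.02,
    rho_inside: float = 0.5,
    G0: float = 0.1,
    G_culture: float = 1.0,
) -> FieldSet:
    """Canonical initial fields.

    ``"default"``: a tumor plateau of height 1 on [0, tumor_width] with a
    smooth compactly-supported front; ECM intact (rho = 1) outside the
    tumor and reduced to ``rho_inside`` within it; no MMP; uniform low
    glucose ``G0``; (M, A) at the history-consistent switch equilibrium for
    G0 (relaxed from the proliferative culture state; with the reference
    parameters this is the migratory branch, so cells begin invasive).
    """
    if scenario != "default":
        raise ValueError(f"unknown scenario {scenario!r}; available: 'default'")
    x = grid.centers
    shape = _smooth_plateau(x, tumor_width, front_width)
    n = shape.copy()
    rho = 1.0 - (1.0 - rho_inside) * shape
    P = np.zeros_like(x)
    G = np.full_like(x, G0)

    M0, A0 = equilibrium_after_deprivation(G0, params.switch, G_culture)
    M = np.full_like(x, M0)
    A = np.full_like(x, A0)
    return FieldSet(n=n, rho=rho, P=P, G=G, M=M, A=A)
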