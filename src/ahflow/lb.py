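"""Coupled lattice-Boltzmann solver for buoyant aqueous-humor flow.

The velocity field uses a 9-direction incompressible LBGK model whose
equilibria are written in pressure (the D2G9 model): with lattice speed
``c = 1`` and coefficients ``(σ, λ, γ)``,

    f_i^eq = −4σ p + s_0(u)          (rest direction)
    f_i^eq =  λ p + s_i(u)           (axis directions)
    f_i^eq =  γ p + s_i(u)           (diagonal directions)

where ``s_i(u) = w_i [3 e_i·u + 4.5 (e_i·u)² − 1.5 u²]``.  The macroscopic
fields are moments: ``u = Σ_{i≥1} e_i f_i`` and
``p = (1/4σ)(Σ_{i≥1} f_i + s_0(u))``; the canonical coefficient set
``λ = 1/3, γ = 1/12, σ = 5/12`` makes the pressure solve well posed.  The
kinematic viscosity is ``ν = (2τ − 1)/6`` in lattice units.

Temperature is a passive scalar carried by a 4-direction lattice with
equilibria ``T_i^eq = (T/4)(1 + 2 e_i·u)`` and diffusivity
``α = (2τ_T − 1)/4``; buoyancy enters the velocity lattice through a
Boussinesq force ``F = −g β (T − T₀)`` discretised onto the two lattice
directions aligned with gravity.  Aqueous outflow through the trabecular
meshwork follows Darcy's law ``u = −(K/μ)∇p`` applied as a velocity boundary,
with the pressure level anchored by global mass balance between ciliary
secretion and trabecular drainage.

Physical units map onto the lattice by direct scaling: the spacing ``dx``
fixes lengths, and the time step ``dt = ν_lat dx²/ν`` follows from matching
the physical kinematic viscosity at the chosen relaxation time.  Because
viscosity, thermal diffusivity (through the Prandtl number) and gravity are
all mapped consistently, the Rayleigh number of the physical problem is
preserved automatically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np

from . import _kernels
from .errors import ConfigurationError, DivergenceError, GeometryError
from .geometry import NodeGrid, NodeType

__all__ = [
    "D2G9Params",
    "FluidProperties",
    "RelaxationTimes",
    "LatticeScaling",
    "LatticeState",
    "SimResult",
    "equilibrium_f",
    "macroscopic_fields",
    "collide_stream_velocity",
    "thermal_step",
    "boussinesq_force",
    "darcy_outflow",
    "apply_boundaries",
    "initialize_state",
    "run_to_steady",
    "normal_eye_setup",
]

# D2Q9 direction set (x, y) and opposites
_EX = np.array([0, 1, 0, -1, 0, 1, -1, -1, 1], dtype=float)
_EY = np.array([0, 0, 1, 0, -1, 1, 1, -1, -1], dtype=float)
_OPP = np.array([0, 3, 4, 1, 2, 7, 8, 5, 6])
_W = np.array([4 / 9] + [1 / 9] * 4 + [1 / 36] * 4)

# 4-direction thermal lattice
_TEX = np.array([1, 0, -1, 0], dtype=float)
_TEY = np.array([0, 1, 0, -1], dtype=float)
_TOPP = np.array([2, 3, 0, 1])


@dataclass(frozen=True)
class D2G9Params:
    """Equilibrium coefficients of the incompressible 9-direction model."""

    sigma: float = 5.0 / 12.0
    lam: float = 1.0 / 3.0
    gamma: float = 1.0 / 12.0
    lattice_speed: float = 1.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive (pressure solve well-posedness)")
        if abs(self.lam + self.gamma - self.sigma) > 1e-12:
            raise ValueError("coefficients must satisfy lambda + gamma = sigma")

    @property
    def pressure_coeffs(self) -> np.ndarray:
        return np.array(
            [-4 * self.sigma] + [self.lam] * 4 + [self.gamma] * 4
        )


DEFAULT_D2G9 = D2G9Params()


@dataclass
class FluidProperties:
    """Physical properties of the aqueous humor and ocular boundaries.

    Units: SI throughout except temperatures (°C) and secretion_rate
    (µL/min).  ``outlet_reference_pressure`` is the pressure on the far side
    of the trabecular outlet; its default is a calibration constant chosen so
    that the normal eye (K = 7.0e-15 m², Q = 2.5 µL/min) settles at an
    intraocular pressure of 1950 Pa at the reference desk resolution.
    """

    density: float = 9.93e2
    dynamic_viscosity: float = 6.97e-4
    thermal_conductivity: float = 0.58
    specific_heat: float = 4178.0
    expansion_coeff: float = 3.0e-4
    gravity: float = 9.8
    reference_temp: float = 37.0
    cornea_temp: float = 34.0
    body_temp: float = 37.0
    tm_permeability: float = 7.0e-15
    secretion_rate: float = 2.5
    outlet_reference_pressure: float = 1943.6

    def __post_init__(self):
        for name in (
            "density",
            "dynamic_viscosity",
            "thermal_conductivity",
            "specific_heat",
            "gravity",
            "tm_permeability",
            "secretion_rate",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.expansion_coeff < 0:
            # zero switches buoyancy off (used by validation runs)
            raise ValueError("expansion_coeff must be nonnegative")
        if self.outlet_reference_pressure < 0:
            raise ValueError("outlet_reference_pressure must be >= 0")
        if not self.cornea_temp < self.body_temp:
            raise ValueError("cornea_temp must be below body_temp")

    @property
    def kinematic_viscosity(self) -> float:
        return self.dynamic_viscosity / self.density

    @property
    def thermal_diffusivity(self) -> float:
        return self.thermal_conductivity / (self.density * self.specific_heat)

    @property
    def prandtl(self) -> float:
        return self.kinematic_viscosity / self.thermal_diffusivity

    @property
    def inlet_speed(self) -> float:
        """Inlet velocity (m/s): Q = 2.5 µL/min maps to 2.0e-6 m/s, linear in Q."""
        return 2.0e-6 * (self.secretion_rate / 2.5)


@dataclass
class RelaxationTimes:
    """BGK relaxation times of the velocity and temperature lattices."""

    tau: float = 1.0
    tau_T: float = 0.5663146580046917

    def __post_init__(self):
        if self.tau <= 0.5 or self.tau_T <= 0.5:
            raise ValueError("relaxation times must exceed 1/2")

    @property
    def nu_lattice(self) -> float:
        return (2 * self.tau - 1) / 6.0

    @property
    def alpha_lattice(self) -> float:
        return (2 * self.tau_T - 1) / 4.0

    @property
    def prandtl(self) -> float:
        return self.nu_lattice / self.alpha_lattice

    @classmethod
    def from_properties(cls, props: FluidProperties, tau: float = 1.0) -> "RelaxationTimes":
        """Derive τ_T from τ so the lattice reproduces the physical Prandtl number."""
        nu_lat = (2 * tau - 1) / 6.0
        alpha_lat = nu_lat / props.prandtl
        return cls(tau=tau, tau_T=0.5 + 2 * alpha_lat)


@dataclass
class LatticeScaling:
    """Physical ↔ lattice unit mapping; dx in metres, dt in seconds."""

    dx: float
    dt: float
    density: float = 9.93e2

    @property
    def velocity_scale(self) -> float:
        """m/s per lattice velocity unit."""
        return self.dx / self.dt

    @property
    def pressure_scale(self) -> float:
        """Pa per lattice (kinematic) pressure unit."""
        return self.density * self.velocity_scale**2

    @property
    def time_scale(self) -> float:
        return self.dt

    def gravity_lattice(self, g_phys: float) -> float:
        return g_phys * self.dt**2 / self.dx

    @classmethod
    def from_physical(
        cls, dx_m: float, props: FluidProperties, times: RelaxationTimes
    ) -> "LatticeScaling":
        """Pick dt so the lattice viscosity at τ matches ν = μ/ρ."""
        dt = times.nu_lattice * dx_m**2 / props.kinematic_viscosity
        return cls(dx=dx_m, dt=dt, density=props.density)


@dataclass
class LatticeState:
    """Populations and derived macroscopic fields, all in lattice units.

    ``u``/``p`` are refreshed from the populations at the start of every
    tick; ``pressure_offset`` (Pa) anchors the lattice pressure to absolute
    units through the trabecular mass balance.
    """

    f: np.ndarray
    Tpop: np.ndarray
    u: np.ndarray
    p: np.ndarray
    T: np.ndarray
    tick: int = 0
    pressure_offset: float = 0.0


@dataclass
class SimResult:
    """Converged fields in physical units plus convergence metadata."""

    grid: NodeGrid
    scaling: LatticeScaling
    props: FluidProperties
    orientation: str
    u: np.ndarray  # (2, ny, nx) m/s
    p: np.ndarray  # (ny, nx) Pa, absolute
    T: np.ndarray  # (ny, nx) °C
    converged: bool
    ticks: int
    residuals: Tuple[Tuple[int, float], ...] = ()

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.u[0], self.u[1])


# ---------------------------------------------------------------------------
# cached per-grid connectivity
# ---------------------------------------------------------------------------


class _Domain:
    """Precomputed masks and boundary connectivity for a NodeGrid."""

    def __init__(self, grid: NodeGrid):
        labels = grid.labels
        self.fluid = labels == NodeType.FLUID
        self.inlet = labels == NodeType.INLET
        self.tm = labels == NodeType.TM_OUTLET
        self.boundary = self.inlet | self.tm
        self.solid = ~self.fluid & ~self.boundary
        self.fluid_f = self.fluid.astype(float)
        ny, nx = labels.shape
        # link masks: fluid node whose neighbour at x + e_i is solid
        self.bounce = []
        self.bounce_idx = []
        for i in range(9):
            ex, ey = int(_EX[i]), int(_EY[i])
            nbr_solid = np.roll(self.solid, (-ey, -ex), axis=(0, 1))
            mask = self.fluid & nbr_solid
            self.bounce.append(mask)
            self.bounce_idx.append(np.flatnonzero(mask))
        self._wall_temp_cache = {}

        # boundary-node connectivity: a 4-adjacent fluid neighbour + outward normal
        by, bx = np.nonzero(self.boundary)
        self.by, self.bx = by, bx
        nb = len(by)
        nbr_y = np.zeros(nb, dtype=int)
        nbr_x = np.zeros(nb, dtype=int)
        normal = np.zeros((nb, 2))
        for k in range(nb):
            offs = []
            for dy, dx_ in ((0, 1), (0, -1), (1, 0), (-1, 0)):
                yy, xx = by[k] + dy, bx[k] + dx_
                if 0 <= yy < ny and 0 <= xx < nx and self.fluid[yy, xx]:
                    offs.append((dy, dx_))
            if not offs:
                raise GeometryError("boundary node without adjacent fluid")
            nbr_y[k], nbr_x[k] = by[k] + offs[0][0], bx[k] + offs[0][1]
            mean = np.mean(offs, axis=0)  # (dy, dx) toward fluid
            vec = -np.array([mean[1], mean[0]])  # outward, (x, y)
            normal[k] = vec / np.linalg.norm(vec)
        self.nbr_y, self.nbr_x = nbr_y, nbr_x
        self.normal = normal
        self.is_tm = self.tm[by, bx]
        self.is_inlet = self.inlet[by, bx]
        self.n_inlet = int(self.is_inlet.sum())
        self.n_tm = int(self.is_tm.sum())


def _domain(grid: NodeGrid) -> _Domain:
    cache = getattr(grid, "_lb_domain", None)
    if cache is None:
        cache = _Domain(grid)
        grid._lb_domain = cache
    return cache


# ---------------------------------------------------------------------------
# core operators
# ---------------------------------------------------------------------------


def _s_terms(u: np.ndarray) -> np.ndarray:
    """Velocity polynomial s_i(u) for u of shape (2, ...) -> (9, ...)."""
    ux, uy = u[0], u[1]
    usq = ux * ux + uy * uy
    eu = np.multiply.outer(_EX, ux) + np.multiply.outer(_EY, uy)
    w = _W.reshape((9,) + (1,) * np.ndim(ux))
    return w * (3.0 * eu + 4.5 * eu * eu - 1.5 * usq)


def equilibrium_f(p, u, params: D2G9Params = DEFAULT_D2G9) -> np.ndarray:
    """Equilibrium populations for pressure ``p`` and velocity ``u``.

    Accepts scalars or fields (``u`` of shape ``(2, ...)``); returns an array
    of shape ``(9, ...)``.  The first velocity moment of the result equals
    ``u`` and the pressure moment returns ``p`` exactly.
    """
    u = np.asarray(u, dtype=float)
    p = np.asarray(p, dtype=float)
    s = _s_terms(u)
    coeffs = params.pressure_coeffs
    return coeffs.reshape((9,) + (1,) * p.ndim) * p + s


def macroscopic_fields(
    state: LatticeState, params: D2G9Params = DEFAULT_D2G9
) -> Tuple[np.ndarray, np.ndarray]:
    """Velocity and pressure moments of the populations (lattice units)."""
    f = state.f
    ux = np.tensordot(_EX, f, axes=(0, 0))
    uy = np.tensordot(_EY, f, axes=(0, 0))
    u = np.stack([ux, uy])
    s0 = _W[0] * (-1.5) * (ux * ux + uy * uy)
    p = (np.sum(f[1:], axis=0) + s0) / (4.0 * params.sigma)
    return u, p


def collide_stream_velocity(
    state: LatticeState,
    force_terms: Optional[np.ndarray],
    grid: NodeGrid,
    tau: float,
    params: D2G9Params = DEFAULT_D2G9,
) -> LatticeState:
    """One BGK collide-and-stream step with halfway bounce-back walls.

    ``state.u``/``state.p`` must hold the current moments (see
    :func:`macroscopic_fields`).  ``force_terms`` is a per-direction field
    ``(9, ny, nx)`` added after collision.  Populations that would stream
    into wall or exterior nodes are bounced back at the halfway links; inlet
    and trabecular nodes stream as-is (their populations are refreshed by
    :func:`apply_boundaries`).
    """
    dom = _domain(grid)
    feq = equilibrium_f(state.p, state.u, params)
    mask = dom.fluid_f
    fpost = state.f + (mask / tau) * (feq - state.f)
    if force_terms is not None:
        fpost += mask * force_terms
    fnew = np.empty_like(fpost)
    fnew[0] = fpost[0]
    for i in range(1, 9):
        fnew[i] = np.roll(fpost[i], (int(_EY[i]), int(_EX[i])), axis=(0, 1))
    for i in range(1, 9):
        idx = dom.bounce_idx[i]
        if idx.size:
            fnew[_OPP[i]].ravel()[idx] = fpost[i].ravel()[idx]
    if not np.all(np.isfinite(fnew[:, dom.fluid])):
        umax = float(np.nanmax(np.abs(state.u[:, dom.fluid]))) if dom.fluid.any() else 0.0
        raise DivergenceError(state.tick, umax)
    state.f = fnew
    state.tick += 1
    return state


def thermal_step(
    state: LatticeState,
    grid: NodeGrid,
    tau_T: float,
    props: FluidProperties,
) -> LatticeState:
    """One step of the 4-direction thermal lattice with Dirichlet walls.

    Relaxes toward ``T_i^eq = (T/4)(1 + 2 e_i·u)`` on fluid nodes and streams.
    Dirichlet boundary temperatures (cornea at ``cornea_temp``, every other
    wall, the inlet and the trabecular outlet at ``body_temp``) are imposed
    by holding all non-fluid nodes at their equilibrium populations
    ``T_wall/4``, so each boundary acts as a reservoir at its prescribed
    temperature.  This places the effective wall at the wall-node centre and
    is unconditionally damped, which matters in the nearly-enclosed wedge at
    the chamber angle where link-reflection Dirichlet schemes support
    undamped oscillatory modes.
    """
    dom = _domain(grid)
    key = (props.cornea_temp, props.body_temp)
    cached = dom._wall_temp_cache.get(key)
    if cached is None:
        W = np.where(
            grid.labels == NodeType.WALL_CORNEA, props.cornea_temp, props.body_temp
        ).astype(float)
        wall_q = (1.0 - dom.fluid_f) * 0.25 * W  # equilibrium reservoir populations
        cached = (W, wall_q)
        dom._wall_temp_cache[key] = cached
    W, wall_q = cached
    T = state.T
    ux, uy = state.u[0], state.u[1]
    mask = dom.fluid_f / tau_T
    Tpost = np.empty_like(state.Tpop)
    for i in range(4):
        eu = _TEX[i] * ux + _TEY[i] * uy
        teq = 0.25 * T * (1.0 + 2.0 * eu)
        Tpost[i] = dom.fluid_f * (state.Tpop[i] + mask * (teq - state.Tpop[i])) + wall_q
    Tnew = np.empty_like(Tpost)
    for i in range(4):
        Tnew[i] = np.roll(Tpost[i], (int(_TEY[i]), int(_TEX[i])), axis=(0, 1))
    state.Tpop = Tnew
    Tfield = Tnew[0] + Tnew[1] + Tnew[2] + Tnew[3]
    state.T = np.where(dom.fluid, Tfield, W)
    return state


def boussinesq_force(
    T: np.ndarray,
    props: FluidProperties,
    scaling: LatticeScaling,
    gravity_unit: Tuple[float, float],
) -> np.ndarray:
    """Boussinesq force discretised on the two gravity-aligned directions.

    Implements ``F = −g β (T − T₀)`` along ``gravity_unit``: the directional
    terms ``F_i = −(1/2) e_i·g β (T − T₀)`` are nonzero only for the lattice
    directions parallel and antiparallel to gravity, and their first moment
    reassembles the continuum force exactly.
    """
    unit = np.asarray(gravity_unit, dtype=float)
    norm = np.linalg.norm(unit)
    if norm == 0:
        raise ValueError("gravity_unit must be a nonzero vector")
    unit = unit / norm
    dots = _EX * unit[0] + _EY * unit[1]
    enorm = np.hypot(_EX, _EY)
    aligned = np.zeros(9, dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(enorm > 0, dots / enorm, 0.0)
    aligned[np.abs(np.abs(cos) - 1.0) < 1e-12] = True
    aligned[0] = False
    g_lat = scaling.gravity_lattice(props.gravity)
    dT = props.expansion_coeff * (T - props.reference_temp)
    F = np.zeros((9,) + T.shape)
    for i in np.nonzero(aligned)[0]:
        F[i] = -0.5 * (dots[i] * g_lat) * dT
    return F


def darcy_outflow(
    p_abs: np.ndarray,
    grid: NodeGrid,
    props: FluidProperties,
    scaling: LatticeScaling,
):
    """Darcy seepage velocity at every trabecular outlet node.

    The pressure gradient at each outlet node is the one-sided difference
    between the adjacent fluid node (absolute pressure ``p_abs``, Pa) and the
    fixed reference pressure beyond the outlet, over one lattice spacing.
    Returns ``(rows, cols, velocities)`` with velocities (m/s, 2-vectors
    along the outward normal), clamped at zero if the gradient would drive
    inflow.
    """
    dom = _domain(grid)
    sel = dom.is_tm
    if not sel.any():
        raise GeometryError("grid has no trabecular outlet nodes")
    p_nbr = p_abs[dom.nbr_y[sel], dom.nbr_x[sel]]
    k_over_mu = props.tm_permeability / props.dynamic_viscosity
    speed = k_over_mu * (p_nbr - props.outlet_reference_pressure) / scaling.dx
    speed = np.maximum(speed, 0.0)
    vel = speed[:, None] * dom.normal[sel]
    return dom.by[sel], dom.bx[sel], vel


def apply_boundaries(
    state: LatticeState,
    grid: NodeGrid,
    props: FluidProperties,
    inlet_speed: float,
    scaling: LatticeScaling,
    params: D2G9Params = DEFAULT_D2G9,
) -> LatticeState:
    """Impose inlet and trabecular velocity boundaries on the populations.

    The ciliary inlet carries the prescribed normal velocity; the trabecular
    outlet carries the Darcy seepage velocity.  Both are realised by setting
    the boundary-node populations to equilibrium at the imposed velocity and
    the pressure of the adjacent fluid node,
    ``f_i(b) = f_i^eq(p_n, u_b)`` — the pressure coupling makes the imposed
    flux consistent with the local field, and the fully-relaxed form stays
    damped even where a boundary node faces a nearly-enclosed fluid pocket
    (the chamber-angle wedge), where extrapolation schemes that recycle the
    neighbour's non-equilibrium part can self-excite.  Before the
    Darcy velocities are evaluated, the free additive constant of the
    incompressible pressure field is anchored so that the instantaneous
    trabecular outflux balances the secretion influx; the resulting offset is
    stored on the state and defines the absolute pressure level (and hence
    the intraocular pressure).
    """
    dom = _domain(grid)
    if dom.n_inlet == 0 and dom.n_tm == 0:
        return state
    u_in_lat = inlet_speed / scaling.velocity_scale
    if u_in_lat > 0.1:
        raise ConfigurationError(
            f"inlet speed {inlet_speed} m/s is {u_in_lat:.3f} of the lattice speed "
            "(limit 0.1); refine dx or reduce the secretion rate"
        )
    # fresh moments at the adjacent fluid nodes
    fn = state.f[:, dom.nbr_y, dom.nbr_x]
    ux = _EX @ fn
    uy = _EY @ fn
    un = np.stack([ux, uy])
    s0 = _W[0] * (-1.5) * (ux * ux + uy * uy)
    pn = (np.sum(fn[1:], axis=0) + s0) / (4.0 * params.sigma)

    # anchor the pressure level by global mass balance (secretion = drainage)
    ub = np.zeros_like(un)
    if dom.n_inlet:
        ub[:, dom.is_inlet] = -(dom.normal[dom.is_inlet] * u_in_lat).T
    if dom.n_tm:
        p_nbr_phys = pn[dom.is_tm] * scaling.pressure_scale
        influx = inlet_speed * dom.n_inlet * scaling.dx  # m²/s per unit depth
        balance_drop = (
            influx
            * props.dynamic_viscosity
            / (props.tm_permeability * max(dom.n_tm, 1))
        )
        offset = (
            props.outlet_reference_pressure + balance_drop - float(np.mean(p_nbr_phys))
        )
        state.pressure_offset = offset
        k_over_mu = props.tm_permeability / props.dynamic_viscosity
        speed = k_over_mu * (p_nbr_phys + offset - props.outlet_reference_pressure) / scaling.dx
        speed = np.maximum(speed, 0.0) / scaling.velocity_scale
        ub[:, dom.is_tm] = (speed[:, None] * dom.normal[dom.is_tm]).T

    feq_b = equilibrium_f(pn, ub, params)
    state.f[:, dom.by, dom.bx] = feq_b
    state.u[:, dom.by, dom.bx] = ub
    return state


# ---------------------------------------------------------------------------
# initialisation and steady-state driver
# ---------------------------------------------------------------------------


def _conduction_temperature(grid: NodeGrid, props: FluidProperties) -> np.ndarray:
    """Steady pure-conduction temperature field (sparse Laplace solve)."""
    from scipy.sparse import lil_matrix
    from scipy.sparse.linalg import spsolve

    dom = _domain(grid)
    labels = grid.labels
    W = np.where(labels == NodeType.WALL_CORNEA, props.cornea_temp, props.body_temp)
    fluid = dom.fluid
    idx = -np.ones(labels.shape, dtype=int)
    ys, xs = np.nonzero(fluid)
    idx[ys, xs] = np.arange(len(ys))
    n = len(ys)
    A = lil_matrix((n, n))
    b = np.zeros(n)
    ny, nx = labels.shape
    for k in range(n):
        y, x = ys[k], xs[k]
        A[k, k] = -4.0
        for dy, dx_ in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            yy, xx = y + dy, x + dx_
            if 0 <= yy < ny and 0 <= xx < nx and fluid[yy, xx]:
                A[k, idx[yy, xx]] = 1.0
            else:
                ww = W[yy, xx] if (0 <= yy < ny and 0 <= xx < nx) else props.body_temp
                b[k] -= ww
    sol = spsolve(A.tocsr(), b)
    T = W.astype(float).copy()
    T[ys, xs] = sol
    return T


def interpolate_fields(result: SimResult, grid: NodeGrid):
    """Linearly interpolate a result's (u, p, T) onto another lattice.

    Used for mesh-continuation warm starts: a coarse converged solution is
    a far better initial condition for a refined lattice than rest, and the
    refined run then only has to relax the discretisation difference.
    """
    from scipy.interpolate import RegularGridInterpolator

    src = result.grid
    ys = src.origin[1] + np.arange(src.shape[0]) * src.dx
    xs = src.origin[0] + np.arange(src.shape[1]) * src.dx
    yq = grid.origin[1] + np.arange(grid.shape[0]) * grid.dx
    xq = grid.origin[0] + np.arange(grid.shape[1]) * grid.dx
    YQ, XQ = np.meshgrid(yq, xq, indexing="ij")
    pts = np.column_stack([YQ.ravel(), XQ.ravel()])
    out = []
    fluid = src.fluid_mask
    p_level = float(np.mean(result.p[fluid]))
    for field in (result.u[0], result.u[1], result.p - p_level, result.T):
        interp = RegularGridInterpolator(
            (ys, xs), field, bounds_error=False, fill_value=None, method="linear"
        )
        out.append(interp(pts).reshape(grid.shape))
    u = np.stack(out[:2])
    mask = grid.fluid_mask
    u[:, ~mask] = 0.0
    return u, out[2], out[3]


def initialize_state(
    grid: NodeGrid,
    props: FluidProperties,
    scaling: LatticeScaling,
    init_temperature: str = "conduction",
    warm_start: Optional[SimResult] = None,
) -> LatticeState:
    """Quiescent initial state; temperature either uniform or pre-conducted.

    With ``warm_start`` the populations are initialised at equilibrium on
    the interpolated fields of a previous (typically coarser) result.
    """
    if warm_start is not None:
        u_phys, p_rel, T = interpolate_fields(warm_start, grid)
        u = u_phys / scaling.velocity_scale
        p = p_rel / scaling.pressure_scale
        W = np.where(
            grid.labels == NodeType.WALL_CORNEA, props.cornea_temp, props.body_temp
        ).astype(float)
        T = np.where(grid.fluid_mask, T, W)
        f = equilibrium_f(p, u)
        ux, uy = u[0], u[1]
        Tpop = np.empty((4,) + grid.shape)
        for i in range(4):
            eu = _TEX[i] * ux + _TEY[i] * uy
            Tpop[i] = 0.25 * T * (1.0 + 2.0 * eu)
        return LatticeState(f=f, Tpop=Tpop, u=u, p=p, T=T)
    ny, nx = grid.shape
    u = np.zeros((2, ny, nx))
    p = np.zeros((ny, nx))
    if isinstance(init_temperature, np.ndarray):
        T = init_temperature.astype(float)
    elif init_temperature == "conduction":
        T = _conduction_temperature(grid, props)
    else:
        T = np.full((ny, nx), props.body_temp, dtype=float)
    f = equilibrium_f(p, u)
    Tpop = np.repeat(T[None, :, :] / 4.0, 4, axis=0)
    return LatticeState(f=f, Tpop=Tpop, u=u, p=p, T=T)


def _kernel_inputs(grid, props, scaling, gravity_unit, buoyant):
    """Pack the static arrays the jitted tick loop needs."""
    dom = _domain(grid)
    celltype = np.zeros(grid.shape, dtype=np.uint8)
    celltype[dom.fluid] = 1
    celltype[dom.boundary] = 2
    W = np.where(
        grid.labels == NodeType.WALL_CORNEA, props.cornea_temp, props.body_temp
    ).astype(float)
    wall_q = np.where(dom.fluid, 0.0, 0.25 * W)
    gcoef = np.zeros(9)
    if buoyant:
        unit = np.asarray(gravity_unit, float)
        unit = unit / np.linalg.norm(unit)
        g_lat = scaling.gravity_lattice(props.gravity)
        dots = _EX * unit[0] + _EY * unit[1]
        enorm = np.hypot(_EX, _EY)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = np.where(enorm > 0, dots / enorm, 0.0)
        for i in range(1, 9):
            if abs(abs(cos[i]) - 1.0) < 1e-12:
                gcoef[i] = -0.5 * dots[i] * g_lat * props.expansion_coeff
    tm_coef = (
        props.tm_permeability
        / props.dynamic_viscosity
        * scaling.pressure_scale
        / (scaling.dx * scaling.velocity_scale)
    )
    pref_lat = props.outlet_reference_pressure / scaling.pressure_scale
    return dom, celltype, wall_q, gcoef, tm_coef, pref_lat


def run_to_steady(
    grid: NodeGrid,
    props: FluidProperties,
    times: RelaxationTimes,
    scaling: LatticeScaling,
    orientation: str = "standing",
    max_ticks: int = 200_000,
    tol: float = 1.0e-6,
    check_interval: int = 1000,
    init_temperature: str = "conduction",
    params: D2G9Params = DEFAULT_D2G9,
    inlet_speed: Optional[float] = None,
    accelerate: Optional[bool] = None,
    warm_start: Optional[SimResult] = None,
) -> SimResult:
    """Iterate the coupled velocity/thermal lattice to steady state.

    Orientation selects the gravity direction in grid coordinates:
    ``standing`` puts gravity in-plane perpendicular to the pupil axis
    (along columns), ``lying`` along the pupil axis (rows, from cornea
    toward lens, the supine posture).  Convergence is declared when the
    relative L2 change of the velocity field over ``check_interval`` ticks
    drops below ``tol``; non-convergence flags the result rather than
    raising.
    """
    if orientation == "standing":
        gravity_unit = (1.0, 0.0)
    elif orientation == "lying":
        # along the pupil axis toward the cornea; this sign reproduces the
        # two counter-rotating supine convection cells (the opposite sign
        # selects a weaker four-cell pattern)
        gravity_unit = (0.0, -1.0)
    else:
        raise ValueError(f"unknown orientation {orientation!r}")
    grid.gravity_unit = gravity_unit

    pr_lat = times.prandtl
    if abs(pr_lat - props.prandtl) / props.prandtl > 0.03:
        raise ConfigurationError(
            f"relaxation times imply Pr = {pr_lat:.3f} but the fluid properties "
            f"give Pr = {props.prandtl:.3f} (must agree within 3%)"
        )
    if inlet_speed is None:
        inlet_speed = props.inlet_speed

    dom = _domain(grid)
    state = initialize_state(grid, props, scaling, init_temperature, warm_start)
    buoyant = props.expansion_coeff > 0 and props.gravity > 0
    if inlet_speed / scaling.velocity_scale > 0.1:
        raise ConfigurationError(
            f"inlet speed {inlet_speed} m/s exceeds 0.1 of the lattice speed"
        )
    use_kernel = _kernels.HAS_NUMBA if accelerate is None else accelerate
    if use_kernel and not _kernels.HAS_NUMBA:
        raise ConfigurationError("accelerate=True requested but numba is unavailable")
    if use_kernel:
        _, celltype, wall_q, gcoef, tm_coef, pref_lat = _kernel_inputs(
            grid, props, scaling, gravity_unit, buoyant
        )
    residuals = []
    u_prev = state.u.copy()
    converged = False

    def _check(tick):
        nonlocal u_prev
        du = state.u - u_prev
        unorm = float(np.sqrt(np.sum(state.u[:, dom.fluid] ** 2)))
        res = float(np.sqrt(np.sum(du[:, dom.fluid] ** 2))) / max(unorm, 1e-300)
        residuals.append((tick, res))
        u_prev = state.u.copy()
        umax = float(np.max(np.abs(state.u[:, dom.fluid]))) if dom.fluid.any() else 0.0
        if not np.isfinite(res) or umax > 0.3:
            raise DivergenceError(tick, umax)
        return res < tol

    if use_kernel:
        u_in_lat = inlet_speed / scaling.velocity_scale
        ticks_done = 0
        while ticks_done < max_ticks:
            batch = min(check_interval, max_ticks - ticks_done)
            off_lat = _kernels.run_ticks(
                state.f, state.Tpop, state.u, state.p, state.T,
                celltype, wall_q, gcoef, props.reference_temp,
                times.tau, times.tau_T,
                dom.by, dom.bx, dom.nbr_y, dom.nbr_x, dom.normal,
                dom.is_tm, u_in_lat, tm_coef, pref_lat, dom.n_inlet,
                batch,
            )
            ticks_done += batch
            state.tick = ticks_done
            if dom.n_tm:
                state.pressure_offset = off_lat * scaling.pressure_scale
            if _check(ticks_done):
                converged = True
                break
    else:
        for _ in range(max_ticks):
            # boundary nodes need no special care here: their populations
            # carry the imposed velocity as their first moment
            u, p = macroscopic_fields(state, params)
            state.u, state.p = u, p
            F = (
                boussinesq_force(state.T, props, scaling, gravity_unit)
                if buoyant
                else None
            )
            collide_stream_velocity(state, F, grid, times.tau, params)
            if dom.n_inlet or dom.n_tm:
                apply_boundaries(state, grid, props, inlet_speed, scaling, params)
            thermal_step(state, grid, times.tau_T, props)
            if state.tick % check_interval == 0 and _check(state.tick):
                converged = True
                break

    u_final, p_final = macroscopic_fields(state, params)
    u_phys = u_final * scaling.velocity_scale
    u_phys[:, dom.solid] = 0.0
    p_phys = p_final * scaling.pressure_scale + state.pressure_offset
    return SimResult(
        grid=grid,
        scaling=scaling,
        props=props,
        orientation=orientation,
        u=u_phys,
        p=p_phys,
        T=state.T.copy(),
        converged=converged,
        ticks=state.tick,
        residuals=tuple(residuals),
    )


def normal_eye_setup(
    spec=None,
    dx_mm: float = 0.1,
    props: Optional[FluidProperties] = None,
    tau: float = 1.0,
):
    """Convenience bundle (grid, props, times, scaling) for the normal eye."""
    from .geometry import AnteriorSegmentSpec, build_parametric_domain

    if spec is None:
        spec = AnteriorSegmentSpec()
    if props is None:
        props = FluidProperties()
    grid = build_parametric_domain(spec, dx_mm)
    times = RelaxationTimes.from_properties(props, tau=tau)
    scaling = LatticeScaling.from_physical(dx_mm * 1e-3, props, times)
    return grid, props, times, scaling
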