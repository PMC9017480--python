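"""Observables and study drivers for the anterior-segment simulations.

Provides the measurements reported for each converged flow field (maximum
speed, intraocular pressure, vortex census) and the parameter studies:
posture comparison (standing vs supine), corneal-indentation sweep, pupil
size presets, and the trabecular-permeability / secretion-rate / viscosity
sweeps that trace how the intraocular pressure responds to outflow
resistance and inflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .geometry import AnteriorSegmentSpec, NodeGrid, NodeType, build_parametric_domain
from .lb import (
    FluidProperties,
    LatticeScaling,
    RelaxationTimes,
    SimResult,
    run_to_steady,
)

__all__ = [
    "Observables",
    "SweepResult",
    "Vortex",
    "max_speed",
    "streamfunction",
    "detect_vortices",
    "compute_iop",
    "observables",
    "orientation_study",
    "indentation_study",
    "pupil_study",
    "parameter_sweep",
]


@dataclass
class Vortex:
    """A closed recirculation cell: centre (mm), rotation sign, |ψ| strength."""

    center: Tuple[float, float]
    sign: int
    strength: float


@dataclass
class Observables:
    max_speed: float
    max_speed_location: Tuple[float, float]
    iop: float
    vortices: Tuple[Vortex, ...]
    temperature_minmax: Tuple[float, float]


@dataclass
class SweepResult:
    parameter: str
    values: Tuple[float, ...]
    observables: Tuple[Observables, ...]

    def __post_init__(self):
        if len(self.values) != len(self.observables):
            raise ValueError("values and observables must have equal length")
        diffs = np.diff(self.values)
        if len(diffs) and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("sweep values must be strictly monotone")

    def series(self, attr: str) -> np.ndarray:
        return np.array([getattr(o, attr) for o in self.observables])


def max_speed(result: SimResult) -> Tuple[float, Tuple[float, float]]:
    """Maximum |u| over fluid nodes and its physical location (mm)."""
    fluid = result.grid.fluid_mask
    speed = result.speed.copy()
    speed[~fluid] = 0.0
    iy, ix = np.unravel_index(int(np.argmax(speed)), speed.shape)
    x, y = result.grid.node_xy(iy, ix)
    return float(speed[iy, ix]), (float(x), float(y))


def streamfunction(result: SimResult) -> np.ndarray:
    """Streamfunction ψ (m²/s) with u = (∂ψ/∂y, −∂ψ/∂x), y pointing down.

    Integrated on the full grid with u = 0 on solids, so ψ is constant on
    each connected solid boundary and vanishes on the outer walls of a
    closed domain.
    """
    dx_m = result.grid.dx * 1e-3
    ux = np.where(result.grid.fluid_mask, result.u[0], 0.0)
    uy = np.where(result.grid.fluid_mask, result.u[1], 0.0)
    ny, nx = ux.shape
    psi = np.zeros((ny, nx))
    # down the first column: dψ = u_x dy
    psi[1:, 0] = np.cumsum(0.5 * (ux[1:, 0] + ux[:-1, 0])) * dx_m
    # across rows: dψ = −u_y dx
    psi[:, 1:] = psi[:, [0]] - np.cumsum(0.5 * (uy[:, 1:] + uy[:, :-1]), axis=1) * dx_m
    return psi


def detect_vortices(
    result: SimResult,
    threshold_frac: float = 0.05,
    region: Optional[np.ndarray] = None,
) -> List[Vortex]:
    """Locate recirculation cells as interior extrema of the streamfunction.

    A vortex is an 8-neighbourhood local extremum of ψ over the fluid (walls
    are excluded from the comparison window, so weak recirculations whose
    extremum hugs a wall — crypt micro-eddies — still register) with |ψ|
    above ``threshold_frac`` of the global |ψ| range; the sign of ψ gives
    the rotation sense and |ψ| the strength.  ``region`` restricts the
    search to a boolean submask of the grid.
    """
    psi = streamfunction(result)
    fluid = result.grid.fluid_mask
    if region is None:
        # default: interior extrema only, robust against boundary ripples
        search = ndimage.binary_erosion(fluid, structure=np.ones((3, 3), bool))
    else:
        # explicit region (e.g. a crypt recess): wall-adjacent extrema count
        search = fluid & region
    scale = float(np.max(np.abs(psi[fluid]))) if fluid.any() else 0.0
    if scale == 0.0:
        return []
    maxf = ndimage.maximum_filter(np.where(fluid, psi, -np.inf), size=3)
    minf = ndimage.minimum_filter(np.where(fluid, psi, np.inf), size=3)
    cand = search & (((psi >= maxf) & (psi > 0)) | ((psi <= minf) & (psi < 0)))
    cand &= np.abs(psi) >= threshold_frac * scale
    found: List[Vortex] = []
    rows, cols = np.nonzero(cand)
    order = np.argsort(-np.abs(psi[rows, cols]))
    taken: List[Tuple[int, int]] = []
    for k in order:
        r, c = int(rows[k]), int(cols[k])
        if any(abs(r - tr) <= 2 and abs(c - tc) <= 2 for tr, tc in taken):
            continue  # plateau / duplicate of a stronger extremum
        taken.append((r, c))
        x, y = result.grid.node_xy(r, c)
        found.append(
            Vortex(center=(float(x), float(y)), sign=int(np.sign(psi[r, c])), strength=float(abs(psi[r, c])))
        )
    return found


def compute_iop(result: SimResult, props: Optional[FluidProperties] = None) -> float:
    """Intraocular pressure: the fluid-area-averaged absolute pressure (Pa).

    The absolute level of the simulated pressure field is anchored by the
    trabecular mass balance against the outlet reference pressure, so in a
    quiescent closed chamber this reduces to the reference pressure itself.
    """
    fluid = result.grid.fluid_mask
    return float(np.mean(result.p[fluid]))


def observables(result: SimResult, props: Optional[FluidProperties] = None) -> Observables:
    props = props or result.props
    speed, loc = max_speed(result)
    fluid = result.grid.fluid_mask
    return Observables(
        max_speed=speed,
        max_speed_location=loc,
        iop=compute_iop(result, props),
        vortices=tuple(detect_vortices(result)),
        temperature_minmax=(
            float(result.T[fluid].min()),
            float(result.T[fluid].max()),
        ),
    )


# ---------------------------------------------------------------------------
# study drivers
# ---------------------------------------------------------------------------


COARSE_DX_MM = 0.1


def _steady_run(
    spec: AnteriorSegmentSpec,
    props: FluidProperties,
    orientation: str,
    dx_mm: float,
    tau: float = 1.0,
    **solver_kwargs,
) -> SimResult:
    """One steady run; resolutions finer than 0.1 mm use mesh continuation
    (converge at 0.1 mm first, interpolate, then refine)."""
    times = RelaxationTimes.from_properties(props, tau=tau)
    warm = None
    if dx_mm < COARSE_DX_MM:
        coarse = build_parametric_domain(spec, COARSE_DX_MM)
        coarse_scaling = LatticeScaling.from_physical(
            COARSE_DX_MM * 1e-3, props, times
        )
        warm = run_to_steady(
            coarse, props, times, coarse_scaling, orientation, **solver_kwargs
        )
    grid = build_parametric_domain(spec, dx_mm)
    scaling = LatticeScaling.from_physical(dx_mm * 1e-3, props, times)
    return run_to_steady(
        grid, props, times, scaling, orientation, warm_start=warm, **solver_kwargs
    )


def orientation_study(
    spec: AnteriorSegmentSpec,
    props: FluidProperties,
    orientation: str,
    dx_mm: float = 0.1,
    **solver_kwargs,
) -> Tuple[SimResult, Observables]:
    """Steady flow and temperature field for a body posture."""
    result = _steady_run(spec, props, orientation, dx_mm, **solver_kwargs)
    return result, observables(result, props)


def indentation_study(
    spec: AnteriorSegmentSpec,
    props: FluidProperties,
    depths: Sequence[float],
    dx_mm: float = 0.1,
    orientation: str = "standing",
    **solver_kwargs,
) -> SweepResult:
    """Steady standing-posture runs across flat corneal indentation depths."""
    obs = []
    for d in depths:
        s = replace(spec, indentation_depth=float(d))
        result = _steady_run(s, props, orientation, dx_mm, **solver_kwargs)
        obs.append(observables(result, props))
    return SweepResult(
        parameter="indentation_depth", values=tuple(float(d) for d in depths), observables=tuple(obs)
    )


def pupil_study(
    spec: AnteriorSegmentSpec,
    props: FluidProperties,
    diameters: Sequence[float] = (2.76, 3.69, 4.91),
    dx_mm: float = 0.1,
    orientation: str = "standing",
    **solver_kwargs,
) -> SweepResult:
    """Steady runs across pupil-diameter presets."""
    obs = []
    for d in diameters:
        s = replace(spec, pupil_diameter=float(d))
        result = _steady_run(s, props, orientation, dx_mm, **solver_kwargs)
        obs.append(observables(result, props))
    return SweepResult(
        parameter="pupil_diameter", values=tuple(float(d) for d in diameters), observables=tuple(obs)
    )


_SWEEPABLE = {
    "tm_permeability": "tm_permeability",
    "secretion_rate": "secretion_rate",
    "viscosity": "dynamic_viscosity",
}


def parameter_sweep(
    spec: AnteriorSegmentSpec,
    props: FluidProperties,
    parameter: str,
    values: Sequence[float],
    dx_mm: float = 0.125,
    orientation: str = "standing",
    **solver_kwargs,
) -> SweepResult:
    """Sweep a physical property and record IOP and maximum speed per value.

    ``parameter`` is one of ``tm_permeability`` (m²), ``secretion_rate``
    (µL/min) or ``viscosity`` (Pa·s).  Each value gets its own steady run;
    for viscosity the lattice time step and thermal relaxation are rederived
    so the physical viscosity and Prandtl number stay matched.
    """
    if parameter not in _SWEEPABLE:
        raise ValueError(
            f"unknown sweep parameter {parameter!r}; choose from {sorted(_SWEEPABLE)}"
        )
    vals = [float(v) for v in values]
    if any(v <= 0 for v in vals):
        raise ValueError("sweep values must be positive")
    attr = _SWEEPABLE[parameter]
    obs = []
    for v in vals:
        p = replace(props, **{attr: v})
        result = _steady_run(spec, p, orientation, dx_mm, **solver_kwargs)
        obs.append(observables(result, p))
    return SweepResult(parameter=parameter, values=tuple(vals), observables=tuple(obs))
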