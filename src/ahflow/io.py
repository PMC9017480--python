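"""Run configuration, serialization, and result export.

A run is described by a single YAML document with sections for the geometry
source, image-filter parameters, fluid properties, solver controls and study
selection.  Unknown keys are rejected, defaults are resolved at load time,
and every results directory receives an echo of the fully-resolved
configuration so a run can be reproduced from its outputs alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import yaml

from .errors import ConfigurationError
from .geometry import AnteriorSegmentSpec, NodeGrid, NodeType
from .image import DenoiseParams, EdgeParams
from .lb import FluidProperties, LatticeScaling, RelaxationTimes, SimResult

__all__ = ["RunConfig", "load_config", "save_config", "export_result"]

log = logging.getLogger("ahflow")

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Fully-resolved configuration of a simulation or study run."""

    spec: AnteriorSegmentSpec = field(default_factory=AnteriorSegmentSpec)
    props: FluidProperties = field(default_factory=FluidProperties)
    denoise: DenoiseParams = field(default_factory=DenoiseParams)
    edges: EdgeParams = field(default_factory=EdgeParams)
    image_path: Optional[str] = None
    feature_points: Optional[Tuple[Tuple[float, float], ...]] = None
    dx_mm: float = 0.1
    tau: float = 1.0
    orientation: str = "standing"
    study: str = "simulate"
    max_ticks: int = 200_000
    tol: float = 1.0e-6
    output_dir: str = "results"
    seed: int = 0
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self):
        if self.tau <= 0.5:
            raise ConfigurationError(
                f"tau = {self.tau} violates the stability bound tau > 1/2"
            )
        if self.orientation not in ("standing", "lying"):
            raise ConfigurationError(f"unknown orientation {self.orientation!r}")
        if self.dx_mm <= 0:
            raise ConfigurationError("dx_mm must be positive")
        # consistency: tau_T derived from tau must reproduce the fluid Prandtl
        times = RelaxationTimes.from_properties(self.props, tau=self.tau)
        if abs(times.prandtl - self.props.prandtl) / self.props.prandtl > 0.03:
            raise ConfigurationError(
                "relaxation times inconsistent with the fluid Prandtl number"
            )

    def relaxation_times(self) -> RelaxationTimes:
        return RelaxationTimes.from_properties(self.props, tau=self.tau)

    def scaling(self) -> LatticeScaling:
        return LatticeScaling.from_physical(
            self.dx_mm * 1e-3, self.props, self.relaxation_times()
        )


_SECTIONS = {
    "geometry": (AnteriorSegmentSpec, "spec"),
    "fluid": (FluidProperties, "props"),
    "denoise": (DenoiseParams, "denoise"),
    "edges": (EdgeParams, "edges"),
}
_TOP_KEYS = {
    "image_path",
    "feature_points",
    "dx_mm",
    "tau",
    "orientation",
    "study",
    "max_ticks",
    "tol",
    "output_dir",
    "seed",
    "schema_version",
}


def _build_section(cls, data: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in config section '{section}'"
        )
    try:
        return cls(**data)
    except (ValueError, TypeError) as exc:
        raise ConfigurationError(f"invalid '{section}' configuration: {exc}") from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration, resolving all defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("config must be a YAML mapping")
    unknown = set(raw) - set(_SECTIONS) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown top-level key(s) {sorted(unknown)}")
    kwargs = {}
    for section, (cls, attr) in _SECTIONS.items():
        data = raw.get(section, {}) or {}
        if section == "geometry" and "crypt_list" in data:
            data["crypt_list"] = tuple(tuple(c) for c in data["crypt_list"])
        kwargs[attr] = _build_section(cls, data, section)
    for key in _TOP_KEYS:
        if key in raw:
            kwargs[key] = raw[key]
    if kwargs.get("feature_points") is not None:
        kwargs["feature_points"] = tuple(tuple(p) for p in kwargs["feature_points"])
    try:
        return RunConfig(**kwargs)
    except (ValueError, TypeError) as exc:
        raise ConfigurationError(str(exc)) from exc


def save_config(config: RunConfig, path) -> None:
    """Write the fully-resolved configuration back to YAML."""
    doc = {
        "schema_version": config.schema_version,
        "geometry": dataclasses.asdict(config.spec),
        "fluid": dataclasses.asdict(config.props),
        "denoise": dataclasses.asdict(config.denoise),
        "edges": dataclasses.asdict(config.edges),
    }
    doc["geometry"]["crypt_list"] = [list(c) for c in config.spec.crypt_list]
    for key in sorted(_TOP_KEYS - {"schema_version"}):
        val = getattr(config, key)
        if key == "feature_points" and val is not None:
            val = [list(p) for p in val]
        doc[key] = val
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# result export
# ---------------------------------------------------------------------------


def _write_vtk(result: SimResult, path: Path) -> None:
    """Legacy-ASCII VTK structured-points export of u, p, T."""
    ny, nx = result.grid.shape
    dx = result.grid.dx * 1e-3
    ox, oy = (result.grid.origin[0] * 1e-3, result.grid.origin[1] * 1e-3)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("ahflow anterior-segment fields\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} 1\n")
        fh.write(f"ORIGIN {ox:.9e} {oy:.9e} 0.0\n")
        fh.write(f"SPACING {dx:.9e} {dx:.9e} {dx:.9e}\n")
        fh.write(f"POINT_DATA {nx * ny}\n")
        fh.write("SCALARS pressure double 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, result.p.ravel()[None].T, fmt="%.9e")
        fh.write("SCALARS temperature double 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, result.T.ravel()[None].T, fmt="%.9e")
        fh.write("SCALARS label int 1\nLOOKUP_TABLE default\n")
        np.savetxt(fh, result.grid.labels.ravel()[None].T, fmt="%d")
        fh.write("VECTORS velocity double\n")
        vec = np.column_stack(
            [result.u[0].ravel(), result.u[1].ravel(), np.zeros(nx * ny)]
        )
        np.savetxt(fh, vec, fmt="%.9e")


def _plot_fields(result: SimResult, outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fluid = result.grid.fluid_mask
    ny, nx = result.grid.shape
    x = result.grid.origin[0] + np.arange(nx) * result.grid.dx
    y = result.grid.origin[1] + np.arange(ny) * result.grid.dx
    speed = np.where(fluid, result.speed, np.nan)
    T = np.where(fluid, result.T, np.nan)

    fig, ax = plt.subplots(figsize=(8, 4))
    pc = ax.pcolormesh(x, y, speed, shading="nearest", cmap="viridis")
    fig.colorbar(pc, ax=ax, label="|u| (m/s)")
    ax.streamplot(x, y, np.where(fluid, result.u[0], 0), np.where(fluid, result.u[1], 0), color="w", density=1.2, linewidth=0.5)
    ax.invert_yaxis()
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_title(f"Aqueous flow, {result.orientation}")
    fig.savefig(outdir / "velocity.png", dpi=150, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(8, 4))
    pc = ax.pcolormesh(x, y, T, shading="nearest", cmap="inferno")
    fig.colorbar(pc, ax=ax, label="T (°C)")
    ax.invert_yaxis()
    ax.set_aspect("equal")
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    fig.savefig(outdir / "temperature.png", dpi=150, bbox_inches="tight")
    plt.close(fig)


def export_result(
    result: SimResult,
    outdir,
    config: Optional[RunConfig] = None,
    plots: bool = True,
) -> dict:
    """Write VTK fields, CSV observables, plots, and the config echo.

    Returns a dict of the written file paths.  CSV output is deterministic:
    exporting the same result twice produces byte-identical files.
    """
    import pandas as pd

    from .experiments import observables

    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise IOError(f"output directory {outdir} is not writable: {exc}") from exc

    files = {}
    vtk_path = outdir / "fields.vtk"
    _write_vtk(result, vtk_path)
    files["vtk"] = str(vtk_path)

    obs = observables(result)
    rows = {
        "orientation": result.orientation,
        "max_speed_m_per_s": obs.max_speed,
        "max_speed_x_mm": obs.max_speed_location[0],
        "max_speed_y_mm": obs.max_speed_location[1],
        "iop_pa": obs.iop,
        "n_vortices": len(obs.vortices),
        "temperature_min_c": obs.temperature_minmax[0],
        "temperature_max_c": obs.temperature_minmax[1],
        "converged": result.converged,
        "ticks": result.ticks,
    }
    obs_path = outdir / "observables.csv"
    pd.DataFrame([rows]).to_csv(obs_path, index=False)
    files["observables"] = str(obs_path)

    conv_path = outdir / "convergence.csv"
    pd.DataFrame(result.residuals, columns=["tick", "residual"]).to_csv(
        conv_path, index=False
    )
    files["convergence"] = str(conv_path)

    if config is not None:
        echo_path = outdir / "config_echo.yaml"
        save_config(config, echo_path)
        files["config"] = str(echo_path)
    if plots:
        _plot_fields(result, outdir)
        files["velocity_png"] = str(outdir / "velocity.png")
        files["temperature_png"] = str(outdir / "temperature.png")
    log.info("exported results to %s", outdir)
    return files
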