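"""Synthetic test inputs: OCT-like renderings and analytic solver benchmarks.

No patient imaging ships with the package; instead this module renders
anterior-segment cross-sections with known geometry and multiplicative gamma
speckle (the noise statistics of coherent imaging), and builds small lattice
configurations with closed-form solutions (plane Poiseuille flow, steady
conduction, free diffusion of a Gaussian spot, a decaying shear wave) used
to validate the solver's transport coefficients.  All randomness in the
package lives here and is seed-controlled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Tuple

import numpy as np
from scipy import ndimage

from .geometry import (
    AnteriorSegmentSpec,
    Contour,
    NodeGrid,
    NodeType,
    build_parametric_domain,
    _surface_profiles,
)
from .image import GrayImage

__all__ = [
    "SpeckleParams",
    "RenderedFixture",
    "render_oct_image",
    "AnalyticCase",
    "analytic_case",
]


@dataclass(frozen=True)
class SpeckleParams:
    """Multiplicative gamma speckle: unit mean, variance 1/looks.

    ``looks`` (the L parameter) counts incoherently averaged acquisitions;
    ``looks = inf`` disables the noise.
    """

    looks: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if not self.looks >= 1:
            raise ValueError("looks must be >= 1")


@dataclass
class RenderedFixture:
    image: GrayImage
    cornea_contour: Contour
    grid: NodeGrid
    feature_points: Tuple[Tuple[float, float], ...]  # A, B, C as (row, col)
    spec: AnteriorSegmentSpec
    pixel_size: float


def render_oct_image(
    spec: AnteriorSegmentSpec,
    pixel_size: float = 0.05,
    speckle: SpeckleParams = SpeckleParams(),
    background: float = 0.08,
    tissue: float = 0.85,
    band_mm: float = 0.5,
) -> RenderedFixture:
    """Render an OCT-like cross-section of a known anterior segment.

    Tissue walls within ``band_mm`` of the fluid (default 0.5 mm, the
    thickness of the human cornea) appear as bright bands over a dark
    background; multiplicative gamma speckle with the given seed is then
    applied.  The clean geometry is returned as ground truth: the labeled
    lattice, the posterior corneal contour, and the feature points A, B
    (at the chamber angles) and C (below the apex) used by the
    contour-extraction procedure.
    """
    band_px = max(2, int(round(band_mm / pixel_size)))
    grid = build_parametric_domain(spec, pixel_size)
    labels = grid.labels
    fluid = labels == NodeType.FLUID
    active = fluid | (labels == NodeType.INLET)
    near = ndimage.binary_dilation(active, iterations=band_px)
    wall_band = near & ~active
    img = np.full(labels.shape, background, dtype=float)
    img[wall_band] = tissue
    if np.isfinite(speckle.looks):
        rng = np.random.default_rng(speckle.seed)
        img = img * rng.gamma(speckle.looks, 1.0 / speckle.looks, size=img.shape)
    image = GrayImage(img, pixel_size=pixel_size)

    # ground-truth posterior corneal contour, one point per column
    ny, nx = labels.shape
    cols = np.arange(nx)
    x = grid.origin[0] + cols * pixel_size
    prof = _surface_profiles(spec, x)
    cor = prof["cornea"]
    ok = np.isfinite(cor)
    rows = (cor[ok] - grid.origin[1]) / pixel_size
    contour = Contour(points=np.column_stack([rows, cols[ok]]), pixel_size=pixel_size)

    # feature points: A and B at the visible chamber-angle apexes (the
    # points a user would click), C below the corneal apex
    pts = contour.points
    ia = prof["iris_ant"]
    open_ac = ok & np.isfinite(ia) & (cor < ia)
    open_ac |= ok & (np.abs(x - prof["xs"]) < prof["rp"])
    open_cols = np.nonzero(open_ac)[0]
    col_by_pt = {int(c): (r, c) for r, c in pts}
    A = tuple(map(float, col_by_pt[int(open_cols[0])]))
    B = tuple(map(float, col_by_pt[int(open_cols[-1])]))
    apex_k = int(np.argmin(pts[:, 0]))
    C = (float(pts[apex_k, 0] + 0.35 * spec.ac_depth / pixel_size), float(pts[apex_k, 1]))
    return RenderedFixture(
        image=image,
        cornea_contour=contour,
        grid=grid,
        feature_points=(A, B, C),
        spec=spec,
        pixel_size=pixel_size,
    )


# ---------------------------------------------------------------------------
# analytic validation cases
# ---------------------------------------------------------------------------


@dataclass
class AnalyticCase:
    """A ready-to-run lattice configuration with a closed-form solution.

    ``grid`` is the labeled lattice (periodic wherever no wall labels
    block streaming); ``config`` carries case-specific inputs (body-force
    magnitude, boundary temperatures, initial fields); ``exact`` evaluates
    the closed-form solution in lattice units.
    """

    name: str
    grid: NodeGrid
    config: dict
    exact: Callable


def _channel_grid(width: int, length: int) -> NodeGrid:
    """Periodic-in-x channel: `width` fluid rows between two wall rows."""
    labels = np.full((width + 2, length), int(NodeType.FLUID), dtype=np.int8)
    labels[0, :] = NodeType.WALL_IRIS
    labels[-1, :] = NodeType.WALL_IRIS
    return NodeGrid(labels=labels, dx=1.0)


def analytic_case(name: str, size: int = 64) -> AnalyticCase:
    """Construct one of the named validation cases.

    * ``poiseuille`` — body-forced periodic channel; steady parabolic
      profile ``u(y) = G (y+1/2)(H−1/2−y) / (2ν)`` with halfway walls.
    * ``conduction_slab`` — quiescent slab between two reservoirs; steady
      linear temperature profile between the wall-node planes.
    * ``diffusion_spot`` — periodic Gaussian temperature spot; its spatial
      variance grows as ``2α`` per tick, pinning α(τ_T).
    * ``stokes_decay`` — periodic shear wave ``u_x = A sin(k y)`` decaying
      as ``exp(−ν k² t)``, pinning ν(τ).
    """
    if name == "poiseuille":
        grid = _channel_grid(size, 4)
        G = 1.0e-6  # body acceleration along x, lattice units

        def exact(y, nu):
            # fluid rows are y = 1..size; halfway walls at 0.5 and size+0.5
            return G * (y - 0.5) * (size + 0.5 - y) / (2.0 * nu)

        return AnalyticCase(name, grid, {"force": G}, exact)

    if name == "conduction_slab":
        grid = _channel_grid(size, 4)
        T_top, T_bot = 34.0, 37.0

        def exact(y):
            # Dirichlet reservoirs at the wall-node centres y = 0 and size+1
            return T_top + (T_bot - T_top) * y / (size + 1)

        return AnalyticCase(name, grid, {"T_top": T_top, "T_bot": T_bot}, exact)

    if name == "diffusion_spot":
        labels = np.full((size, size), int(NodeType.FLUID), dtype=np.int8)
        grid = NodeGrid(labels=labels, dx=1.0)
        sigma0 = size / 12.0

        def exact(var0, alpha, ticks):
            return var0 + 2.0 * alpha * ticks

        return AnalyticCase(name, grid, {"sigma0": sigma0}, exact)

    if name == "stokes_decay":
        labels = np.full((size, 4), int(NodeType.FLUID), dtype=np.int8)
        grid = NodeGrid(labels=labels, dx=1.0)
        amp = 1.0e-3
        k = 2.0 * np.pi / size

        def exact(amp0, nu, ticks):
            return amp0 * np.exp(-nu * k**2 * ticks)

        return AnalyticCase(name, grid, {"amplitude": amp, "k": k}, exact)

    raise ValueError(f"unknown analytic case {name!r}")
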