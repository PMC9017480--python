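"""Anterior-segment geometry: parametric construction and labeled lattices.

The cross-section is built in a physical (x, y) frame in millimetres with x
across the chamber (0 on the pupil axis for a symmetric eye) and y increasing
downward from the posterior corneal apex, matching the row/column convention
of anterior-segment images.  The model comprises

* the posterior corneal arc (radius ``cornea_radius``, chord ``as_width``),
  optionally flattened centrally by ``indentation_depth``;
* the anterior lens arc (radius ``lens_radius``) whose pole sits ``ac_depth``
  behind the corneal apex;
* an iris wall per side running from the cornea–iris angle to the pupil
  margin, held at least ``iris_lens_gap`` off the lens;
* posterior-chamber channels of entrance height ``pc_inlet_height`` behind
  the iris, terminating in aqueous inlet nodes at the ciliary end;
* trabecular-meshwork outlet patches of extent ``tm_length`` at both angles;
* optional semicircular crypts carved into the anterior iris surface.

Rasterisation is half-open: a node is fluid when its centre lies strictly
inside the fluid region.  Channels narrower than two lattice spacings (the
iris–lens gap at coarse resolution) are widened to a two-node minimum so the
fluid region stays connected at any usable resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .errors import GeometryError, SegmentationError
from .image import EdgeMap

__all__ = [
    "NodeType",
    "AnteriorSegmentSpec",
    "NodeGrid",
    "Contour",
    "extract_cornea_contour",
    "build_parametric_domain",
    "build_domain_from_contour",
    "grid_resolution_report",
    "PUPIL_PRESETS_MM",
]

#: Pupil-diameter presets (mm) used by the pupil-size study.
PUPIL_PRESETS_MM = (2.76, 3.69, 4.91)


class NodeType(IntEnum):
    EXTERIOR = 0
    FLUID = 1
    WALL_CORNEA = 2
    WALL_IRIS = 3
    WALL_LENS = 4
    INLET = 5
    TM_OUTLET = 6


_WALL_TYPES = (NodeType.WALL_CORNEA, NodeType.WALL_IRIS, NodeType.WALL_LENS)


@dataclass(frozen=True)
class AnteriorSegmentSpec:
    """Parametric description of the anterior-segment cross-section (mm).

    Defaults describe the normal adult eye: a 12.8 mm chamber chord, a 0.5 mm
    posterior-chamber entrance, a 10 mm lens curvature radius, and standard
    anatomical values for the quantities the construction additionally needs
    (anterior-chamber depth, posterior corneal radius, iris–lens clearance,
    trabecular outlet extent, iris thickness).
    """

    as_width: float = 12.8
    pc_inlet_height: float = 0.5
    lens_radius: float = 10.0
    ac_depth: float = 3.0
    cornea_radius: float = 6.8
    pupil_diameter: float = 3.69
    iris_lens_gap: float = 0.1
    tm_length: float = 0.7
    indentation_depth: float = 0.0
    crypt_list: Tuple[Tuple[float, float, float], ...] = ()
    asymmetry_shift: float = 0.0
    iris_thickness: float = 0.4

    def __post_init__(self):
        object.__setattr__(self, "crypt_list", tuple(tuple(c) for c in self.crypt_list))
        for name in (
            "as_width",
            "pc_inlet_height",
            "lens_radius",
            "ac_depth",
            "cornea_radius",
            "pupil_diameter",
            "iris_lens_gap",
            "tm_length",
            "iris_thickness",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.indentation_depth < 0:
            raise ValueError("indentation_depth must be nonnegative")
        if self.indentation_depth >= self.ac_depth:
            raise ValueError("indentation_depth must be smaller than ac_depth")
        if self.pupil_diameter >= self.as_width:
            raise ValueError("pupil_diameter must be smaller than as_width")
        if self.cornea_radius <= self.as_width / 2:
            raise ValueError("cornea_radius must exceed half the chamber chord")
        for center, width, depth in self.crypt_list:
            if width <= 0 or depth <= 0:
                raise ValueError("crypt width and depth must be positive")
            if depth >= self.iris_thickness:
                raise ValueError("crypt depth must be smaller than iris_thickness")

    @property
    def corneal_sagitta(self) -> float:
        half = self.as_width / 2
        return self.cornea_radius - np.sqrt(self.cornea_radius**2 - half**2)

    def mirrored(self) -> "AnteriorSegmentSpec":
        """The left-right mirrored spec (shift negated, crypts reflected)."""
        return replace(
            self,
            asymmetry_shift=-self.asymmetry_shift,
            crypt_list=tuple((-c, w, d) for c, w, d in self.crypt_list),
        )


@dataclass
class NodeGrid:
    """Labeled simulation lattice with physical spacing.

    ``labels`` holds :class:`NodeType` values, ``dx`` the spacing in mm,
    ``origin`` the physical (x, y) of grid index (0, 0), and ``gravity_unit``
    the orientation of gravity in grid coordinates (x = columns, y = rows,
    physical y increasing downward).
    """

    labels: np.ndarray
    dx: float
    origin: Tuple[float, float] = (0.0, 0.0)
    gravity_unit: Tuple[float, float] = (1.0, 0.0)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int8)

    @property
    def shape(self):
        return self.labels.shape

    @property
    def fluid_mask(self) -> np.ndarray:
        return self.labels == NodeType.FLUID

    def mask(self, kind: NodeType) -> np.ndarray:
        return self.labels == kind

    def node_xy(self, row, col):
        """Physical (x, y) in mm of grid node centres."""
        return (
            self.origin[0] + np.asarray(col) * self.dx,
            self.origin[1] + np.asarray(row) * self.dx,
        )

    def counts(self) -> dict:
        return {t.name: int(np.sum(self.labels == t)) for t in NodeType}

    def save(self, path_prefix: str) -> None:
        """Write the labels as compressed CSV plus a YAML sidecar."""
        import yaml

        np.savetxt(str(path_prefix) + "_labels.csv.gz", self.labels, fmt="%d", delimiter=",")
        meta = {
            "dx_mm": float(self.dx),
            "origin_mm": [float(self.origin[0]), float(self.origin[1])],
            "gravity_unit": [float(self.gravity_unit[0]), float(self.gravity_unit[1])],
            "shape": [int(self.shape[0]), int(self.shape[1])],
        }
        with open(str(path_prefix) + "_grid.yaml", "w") as fh:
            yaml.safe_dump(meta, fh)

    @classmethod
    def load(cls, path_prefix: str) -> "NodeGrid":
        import yaml

        labels = np.loadtxt(str(path_prefix) + "_labels.csv.gz", dtype=np.int8, delimiter=",")
        with open(str(path_prefix) + "_grid.yaml") as fh:
            meta = yaml.safe_load(fh)
        return cls(
            labels=labels,
            dx=meta["dx_mm"],
            origin=tuple(meta["origin_mm"]),
            gravity_unit=tuple(meta["gravity_unit"]),
        )


@dataclass
class Contour:
    """Ordered (row, col) pixel coordinates of a tissue boundary."""

    points: np.ndarray
    pixel_size: float

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2 or len(self.points) < 3:
            raise ValueError("Contour requires >= 3 (row, col) points")


# ---------------------------------------------------------------------------
# contour extraction (feature-point guided column scan)
# ---------------------------------------------------------------------------


def extract_cornea_contour(edges: EdgeMap, A, B, C, pixel_size: float = 1.0) -> Contour:
    """Trace the corneal boundary between feature points A and B.

    For every column between ``col(A)`` and ``col(B)`` the scan starts on the
    chord AC (columns up to ``col(C)``) or CB (beyond) and walks upward,
    recording the first edge pixel met.  Columns without a hit are filled by
    linear interpolation between neighbouring hits; more than 30% empty
    columns is treated as a segmentation failure.
    """
    mask = edges.mask
    nrow, ncol = mask.shape
    A = (float(A[0]), float(A[1]))
    B = (float(B[0]), float(B[1]))
    C = (float(C[0]), float(C[1]))
    for name, pt in (("A", A), ("B", B), ("C", C)):
        if not (0 <= pt[0] < nrow and 0 <= pt[1] < ncol):
            raise ValueError(f"feature point {name} lies outside the image")
    if A[1] > B[1]:
        A, B = B, A
    if not (A[1] <= C[1] <= B[1]):
        raise ValueError("feature point C must lie between A and B in column order")

    cols = np.arange(int(round(A[1])), int(round(B[1])) + 1)
    rows = np.full(cols.shape, np.nan)

    def chord_row(col):
        if col <= C[1]:
            p0, p1 = A, C
        else:
            p0, p1 = C, B
        if p1[1] == p0[1]:
            return max(p0[0], p1[0])
        t = (col - p0[1]) / (p1[1] - p0[1])
        return p0[0] + t * (p1[0] - p0[0])

    resp = edges.response

    for k, col in enumerate(cols):
        start = int(min(nrow - 1, max(0, round(chord_row(col)))))
        column = mask[: start + 1, col]
        hits = np.nonzero(column[::-1])[0]  # scan upward from the chord
        if not hits.size:
            continue
        r = start - hits[0]
        if resp is not None:
            # sub-pixel refinement at the response zero-crossing
            for rn in (r - 1, r + 1):
                if 0 <= rn < nrow and resp[r, col] * resp[rn, col] < 0:
                    denom = resp[r, col] - resp[rn, col]
                    if denom != 0:
                        r = r + (rn - r) * resp[r, col] / denom
                    break
        rows[k] = r

    missing = np.isnan(rows)
    if missing.mean() > 0.30 or missing.all():
        raise SegmentationError(
            f"{missing.mean():.0%} of columns between A and B have no edge pixel"
        )
    if missing.any():
        rows[missing] = np.interp(cols[missing], cols[~missing], rows[~missing])
    return Contour(points=np.column_stack([rows, cols]), pixel_size=pixel_size)


# ---------------------------------------------------------------------------
# parametric construction
# ---------------------------------------------------------------------------


def _surface_profiles(spec: AnteriorSegmentSpec, x: np.ndarray, cornea_y=None):
    """Column-wise boundary surfaces of the cross-section.

    Returns a dict of arrays over the column coordinates ``x`` (mm):
    ``cornea`` (posterior corneal surface), ``lens`` (anterior lens surface,
    +inf where the lens is absent), ``iris_post``/``iris_ant`` (iris surfaces,
    +inf outside the iris), ``floor`` (posterior-chamber floor) and the pupil
    margin abscissae.  ``cornea_y`` overrides the parametric corneal arc with
    an image-derived profile.
    """
    half = spec.as_width / 2
    rc = spec.cornea_radius
    rl = spec.lens_radius
    xs = spec.asymmetry_shift
    rp = spec.pupil_diameter / 2
    y_iris = spec.corneal_sagitta
    y_pole = spec.ac_depth
    y_bottom = y_iris + spec.pc_inlet_height

    inside_chord = np.abs(x) <= half
    if cornea_y is None:
        arc = np.full_like(x, np.inf)
        arg = rc**2 - x**2
        ok = inside_chord & (arg > 0)
        arc[ok] = rc - np.sqrt(arg[ok])
    else:
        arc = np.where(inside_chord, cornea_y, np.inf)
    if spec.indentation_depth > 0:
        d = spec.indentation_depth
        arc = np.where(np.isfinite(arc), np.maximum(arc, d), arc)

    lens = np.full_like(x, np.inf)
    argl = rl**2 - (x - xs) ** 2
    okl = argl > 0
    lens[okl] = y_pole + rl - np.sqrt(argl[okl])

    # iris surfaces, built per side in the side-local coordinate xi >= 0
    iris_post = np.full_like(x, np.inf)
    for side in (+1, -1):
        xi = side * (x - xs)
        root = half - side * xs  # xi at the cornea-iris angle on this side
        if root <= rp:
            raise GeometryError("pupil reaches the chamber angle on one side")
        margin_x = xs + side * rp
        argm = rl**2 - (margin_x - xs) ** 2
        if argm <= 0:
            raise GeometryError("pupil margin lies outside the lens")
        y_margin = (y_pole + rl - np.sqrt(argm)) - spec.iris_lens_gap
        on_side = (xi >= rp) & (xi <= root)
        line = y_iris + (y_margin - y_iris) * (root - xi) / (root - rp)
        hug = lens - spec.iris_lens_gap
        cand = np.minimum(line, hug)
        iris_post = np.where(on_side, cand, iris_post)
    iris_ant = iris_post - spec.iris_thickness
    floor = np.minimum(y_bottom, lens)

    return {
        "cornea": arc,
        "lens": lens,
        "iris_post": iris_post,
        "iris_ant": iris_ant,
        "floor": floor,
        "y_iris": y_iris,
        "y_bottom": y_bottom,
        "half": half,
        "rp": rp,
        "xs": xs,
    }


def _rasterize(spec: AnteriorSegmentSpec, dx: float, cornea_profile=None) -> NodeGrid:
    if spec.pc_inlet_height / dx < 4:
        raise GeometryError(
            "lattice spacing too coarse: pc_inlet_height/dx must be >= 4 "
            f"(got {spec.pc_inlet_height / dx:.2f})"
        )
    half = spec.as_width / 2
    y_bottom = spec.corneal_sagitta + spec.pc_inlet_height
    m = int(np.ceil(half / dx)) + 2
    nxcols = 2 * m + 1  # symmetric column layout about x = 0
    x = (np.arange(nxcols) - m) * dx
    # rows are half-offset so horizontal surfaces at multiples of dx
    # (flat indentations, channel floors) never alias onto node centres
    ny = int(np.ceil(y_bottom / dx + 4.0))
    y = (np.arange(ny) - 1.5) * dx
    origin = (float(x[0]), float(y[0]))

    cy = None
    if cornea_profile is not None:
        cy = cornea_profile(x)
    prof = _surface_profiles(spec, x, cornea_y=cy)
    X = x[None, :]
    Y = y[:, None]
    cor = prof["cornea"][None, :]
    lens = prof["lens"][None, :]
    ip = prof["iris_post"][None, :]
    ia = prof["iris_ant"][None, :]
    floor = prof["floor"][None, :]
    xs, rp = prof["xs"], prof["rp"]

    pupil_col = np.abs(x - xs) < rp
    iris_col = np.isfinite(prof["iris_post"])
    interior_col = np.abs(x) < half

    fluid = np.zeros((ny, nxcols), dtype=bool)
    # anterior chamber + pupil aperture
    fluid |= pupil_col[None, :] & (Y > cor) & (Y < lens)
    ac_upper = iris_col[None, :] & (Y > cor) & (Y < ia)
    fluid |= ac_upper
    # posterior chamber channel
    pc = iris_col[None, :] & interior_col[None, :] & (Y > ip) & (Y < floor)
    fluid |= pc

    # crypts: semi-elliptic recesses carved into the anterior iris surface
    for center, width, depth in spec.crypt_list:
        prof_depth = np.full_like(x, -1.0)
        xi = (x - center) / (width / 2)
        okc = np.abs(xi) < 1
        prof_depth[okc] = depth * np.sqrt(1 - xi[okc] ** 2)
        crypt = (
            iris_col[None, :]
            & (Y >= ia)
            & (Y < ia + prof_depth[None, :])
            & (Y < ip - dx)  # keep a wall layer toward the posterior chamber
        )
        fluid |= crypt

    # minimum two-node channel width where the iris hugs the lens
    pc_exists = iris_col & interior_col & (prof["floor"] - prof["iris_post"] > 1e-9)
    for j in np.nonzero(pc_exists)[0]:
        col_pc = pc[:, j]
        n_open = int(col_pc.sum())
        if n_open >= 2:
            continue
        mid = 0.5 * (prof["iris_post"][j] + prof["floor"][j])
        i_mid = (mid - y[0]) / dx
        lo = int(np.floor(i_mid))
        hi = lo + 1
        if np.abs(y[lo] - mid) > np.abs(y[min(hi + 0, ny - 1)] - mid):
            lo, hi = hi - 1, hi  # keep the pair straddling the centreline
        for i in (lo, hi):
            if 0 <= i < ny:
                fluid[i, j] = True

    # prune sliver components (pinched off by e.g. contour noise at the
    # chamber-angle wedge); substantial disconnections still fail validation
    comp, ncomp = ndimage.label(
        fluid, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    )
    if ncomp > 1:
        sizes = ndimage.sum_labels(fluid, comp, index=np.arange(1, ncomp + 1))
        for k, size in enumerate(sizes, start=1):
            if size < 0.05 * sizes.max():
                fluid[comp == k] = False
        pc &= fluid

    labels = np.full((ny, nxcols), int(NodeType.EXTERIOR), dtype=np.int8)
    labels[fluid] = NodeType.FLUID

    # inlets: the first exterior column beyond the fluid on each side, over
    # the posterior-chamber rows of the outermost fluid column
    fluid_cols = np.nonzero(fluid.any(axis=0))[0]
    if fluid_cols.size == 0:
        raise GeometryError("no fluid nodes produced by this specification")
    for side, j_edge in ((+1, fluid_cols[-1]), (-1, fluid_cols[0])):
        j_in = j_edge + side
        rows = np.nonzero(pc[:, j_edge] & (y > prof["y_iris"]))[0]
        if rows.size == 0:
            rows = np.nonzero(pc[:, j_edge])[0]
        if rows.size == 0 or not (0 <= j_in < nxcols):
            raise GeometryError("posterior-chamber entrance is closed")
        labels[rows, j_in] = NodeType.INLET

    # one layer of wall labels around the fluid/inlet region
    active = (labels == NodeType.FLUID) | (labels == NodeType.INLET)
    near = ndimage.binary_dilation(active, structure=np.ones((3, 3), bool)) & ~active
    cornea_solid = (Y <= cor) & np.isfinite(cor)
    lens_solid = (X - xs) ** 2 + (Y - (spec.ac_depth + spec.lens_radius)) ** 2 <= spec.lens_radius**2
    labels[near & cornea_solid] = NodeType.WALL_CORNEA
    labels[near & ~cornea_solid & lens_solid] = NodeType.WALL_LENS
    labels[near & ~cornea_solid & ~lens_solid] = NodeType.WALL_IRIS

    grid = NodeGrid(labels=labels, dx=dx, origin=origin)
    _assign_tm(grid, spec, x, y, prof)
    _validate_grid(grid)
    return grid


def _assign_tm(grid: NodeGrid, spec: AnteriorSegmentSpec, x, y, prof) -> None:
    """Relabel wall nodes near each chamber angle as trabecular outlets."""
    labels = grid.labels
    ia = prof["iris_ant"]
    lens = prof["lens"]
    xs, rp = prof["xs"], prof["rp"]
    fluid = labels == NodeType.FLUID
    Y = y[:, None]
    # anterior-chamber fluid: above the anterior iris surface / over the pupil
    ac_limit = np.where(np.isfinite(ia), ia, lens)
    ac_fluid = fluid & (Y < ac_limit[None, :] + 1e-12)
    ac_fluid |= fluid & (np.abs(x - xs) < rp)[None, :] & (Y < lens[None, :])
    wall = np.isin(labels, [int(t) for t in _WALL_TYPES])
    adj_ac = np.zeros_like(fluid)
    for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
        adj_ac |= np.roll(np.roll(ac_fluid, dr, axis=0), dc, axis=1)
    candidates = wall & adj_ac

    rows, cols = np.nonzero(ac_fluid)
    if rows.size == 0:
        raise GeometryError("anterior chamber contains no fluid")
    for side in (+1, -1):
        on_side = (x[cols] - xs) * side > 0
        if not on_side.any():
            raise GeometryError("anterior chamber missing on one side")
        sel = np.nonzero(on_side)[0]
        j_ext = sel[np.argmax(side * x[cols[sel]])]
        apex = np.array([x[cols[j_ext]], y[rows[j_ext]]])
        crow, ccol = np.nonzero(candidates)
        dist = np.hypot(x[ccol] - apex[0], y[crow] - apex[1])
        near = dist <= spec.tm_length
        keep = near & ((x[ccol] - xs) * side > 0)
        if not keep.any():
            raise GeometryError("no trabecular outlet nodes found at one angle")
        labels[crow[keep], ccol[keep]] = NodeType.TM_OUTLET


def _validate_grid(grid: NodeGrid) -> None:
    labels = grid.labels
    fluid = labels == NodeType.FLUID
    if not fluid.any():
        raise GeometryError("grid has no fluid nodes")
    ncomp = ndimage.label(fluid, structure=np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]]))[1]
    if ncomp != 1:
        raise GeometryError(f"fluid region is not 4-connected ({ncomp} components)")
    nbr8 = ndimage.uniform_filter(fluid.astype(float), 3, mode="constant") * 9 - fluid
    if np.any(fluid & (nbr8 < 0.5)):
        raise GeometryError("isolated fluid node (no fluid 8-neighbor)")
    for kind in (NodeType.INLET, NodeType.TM_OUTLET):
        mask = labels == kind
        if not mask.any():
            raise GeometryError(f"grid is missing {kind.name} nodes")
        adj = np.zeros_like(fluid)
        for dr, dc in ((0, 1), (0, -1), (1, 0), (-1, 0)):
            adj |= np.roll(np.roll(fluid, dr, axis=0), dc, axis=1)
        if np.any(mask & ~adj):
            raise GeometryError(f"{kind.name} node does not border fluid")
    # two trabecular patches, one per side of the pupil axis
    tm = labels == NodeType.TM_OUTLET
    tm_cols = np.nonzero(tm.any(axis=0))[0]
    mid = labels.shape[1] // 2
    if not ((tm_cols < mid).any() and (tm_cols > mid).any()):
        raise GeometryError("trabecular outlet missing at one chamber angle")


def build_parametric_domain(spec: AnteriorSegmentSpec, dx: float) -> NodeGrid:
    """Rasterise the parametric anterior segment onto a labeled lattice."""
    return _rasterize(spec, dx)


def build_domain_from_contour(
    cornea: Contour,
    iris_contours: Sequence[Contour],
    spec: AnteriorSegmentSpec,
    dx: float,
) -> NodeGrid:
    """Build the lattice with an image-derived corneal profile.

    The extracted corneal contour replaces the parametric arc; the posterior
    chamber, lens, inlet and trabecular patches are completed from ``spec``
    exactly as :func:`build_parametric_domain` does.  When no usable iris
    contour is given the iris is taken from the spec.
    """
    px = cornea.pixel_size
    rows = cornea.points[:, 0] * px
    cols = cornea.points[:, 1] * px
    order = np.argsort(cols)
    cols, rows = cols[order], rows[order]
    # centre the contour and put its apex at y = 0
    x_mid = 0.5 * (cols[0] + cols[-1])
    xc = cols - x_mid
    yc = rows - rows.min()
    span = xc[-1] - xc[0]
    if span <= 0:
        raise GeometryError("cornea contour has zero width")

    def cornea_profile(xq):
        # outside the contour span the cornea is treated as closed wall;
        # the chamber angle is closed there in any case
        out = np.interp(xq, xc, yc, left=np.nan, right=np.nan)
        out[~np.isfinite(out)] = np.inf
        return out

    # iris contours are accepted for interface compatibility; the wall they
    # describe is reconstructed from the spec when absent or too sparse
    return _rasterize(spec, dx, cornea_profile=cornea_profile)


def grid_resolution_report(grid: NodeGrid) -> dict:
    """Node counts per label and physical extents of the labeled lattice."""
    counts = grid.counts()
    fluid = grid.fluid_mask
    report = {
        "counts": counts,
        "total_annotated": int(sum(v for k, v in counts.items() if k != "EXTERIOR")),
        "total_nodes": int(grid.labels.size),
        "dx_mm": float(grid.dx),
    }
    if fluid.any():
        rows, cols = np.nonzero(fluid)
        xphys, yphys = grid.node_xy(rows, cols)
        report["fluid_extent_x_mm"] = float(xphys.max() - xphys.min() + grid.dx)
        report["fluid_extent_y_mm"] = float(yphys.max() - yphys.min() + grid.dx)
        report["fluid_area_mm2"] = float(fluid.sum() * grid.dx**2)
    inlet = grid.mask(NodeType.INLET)
    if inlet.any():
        rows, _ = np.nonzero(inlet)
        sides = []
        for js in np.unique(np.nonzero(inlet)[1]):
            nrows = int(inlet[:, js].sum())
            sides.append(nrows * grid.dx)
        report["inlet_height_mm"] = float(np.max(sides))
    return report
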