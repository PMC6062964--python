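"""Parametric surface modelling of tubular structures.

Each contour stack is converted to an L x C grid of 3D surface points:
C points around every cross-section, L levels along the anterior-posterior
axis (default 150 levels x 100 circumferential points, i.e. 15,000
vertices).  The grid gives vertex correspondence across subjects, so maps
derived from it can be compared vertex by vertex.

Correspondence conventions
--------------------------
* Within a slice, points are equally spaced in arc length, counter-clockwise.
* Column 0 of each resampled slice starts where the boundary crosses the ray
  from the slice centroid in the +x direction; a minimal-twist pass then
  re-anchors each slice to the cyclic shift that minimizes the summed
  point-to-point distance to the previous slice, suppressing twist artifacts
  on non-circular sections.
* Levels between traced slices are piecewise-linear interpolations of the
  resampled slice contours at uniform normalized slice position.

The medial curve is the per-level centroid of the C grid points (equal arc
spacing makes this a perimeter-weighted center), and the radial map is the
per-vertex Euclidean distance from the medial point of its level — the
dependent variable of all vertex-wise statistics downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import trimesh

from .contours import Contour, ContourStack, polygon_area
from .errors import ValidationError

__all__ = [
    "ParametricSurface",
    "MedialCurve",
    "RadialMap",
    "resample_contour",
    "parameterize",
    "medial_curve",
    "radial_map",
    "average_surface",
    "surface_to_mesh",
    "export_mesh",
    "write_radial_map_csv",
    "read_radial_map_csv",
]

DEFAULT_LEVELS = 150
DEFAULT_CIRCUM = 100

#: End slices smaller than this cross-section (mm^2) are dropped with a warning.
MIN_SLICE_AREA = 0.5


@dataclass
class ParametricSurface:
    """L x C grid of 3D surface points with fixed vertex correspondence.

    ``grid[l, c]`` is the 3D position (mm) of circumferential point ``c`` on
    longitudinal level ``l``; rows run anterior to posterior and each row is
    a closed curve (column C-1 is adjacent to column 0).
    """

    grid: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3 or self.grid.shape[2] != 3:
            raise ValidationError(f"surface grid must be (L, C, 3), got {self.grid.shape}")
        if not np.all(np.isfinite(self.grid)):
            raise ValidationError("surface grid contains non-finite coordinates")

    @property
    def L(self) -> int:
        return self.grid.shape[0]

    @property
    def C(self) -> int:
        return self.grid.shape[1]


@dataclass
class MedialCurve:
    """Ordered central-axis points, one per surface level."""

    points: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValidationError(f"medial curve must be (L, 3), got {self.points.shape}")


@dataclass
class RadialMap:
    """L x C map of distances (mm) from the medial curve to the surface."""

    distances: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=float)
        if self.distances.ndim != 2:
            raise ValidationError("radial map must be 2-D")
        if np.any(self.distances < 0):
            raise ValidationError("radial distances must be non-negative")


# ---------------------------------------------------------------------------
# resampling and parameterization
# ---------------------------------------------------------------------------

def _polygon_centroid(points: np.ndarray) -> np.ndarray:
    """Area centroid of a simple polygon (open vertex ring)."""
    x, y = points[:, 0], points[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * cross.sum()
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


def _ray_origin_arc(points: np.ndarray, cum: np.ndarray) -> float:
    """Arc-length position where the +x ray from the centroid hits the boundary.

    Takes the crossing nearest the centroid; for star-shaped sections it is
    unique.  Falls back to the vertex with the largest x when no crossing is
    found (numerically grazing rays).
    """
    c = _polygon_centroid(points)
    p = points - c
    q = np.roll(p, -1, axis=0)
    d = q - p
    best_s = np.inf
    best_arc = None
    # solve p + t*d = (s, 0), s > 0, 0 <= t < 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = -p[:, 1] / d[:, 1]
    s = p[:, 0] + t * d[:, 0]
    ok = np.isfinite(t) & (t >= 0.0) & (t < 1.0) & (s > 0.0)
    for i in np.flatnonzero(ok):
        if s[i] < best_s:
            best_s = s[i]
            best_arc = cum[i] + t[i] * (cum[i + 1] - cum[i])
    if best_arc is None:
        best_arc = float(cum[int(np.argmax(p[:, 0]))])
    return float(best_arc)


def resample_contour(contour: Contour | np.ndarray, C: int) -> np.ndarray:
    """Resample a closed contour to C points equally spaced in arc length.

    Point 0 sits where the boundary crosses the +x ray from the section
    centroid; order is counter-clockwise.  Returns an ``(C, 2)`` array.
    """
    if C < 3:
        raise ValueError(f"C must be >= 3, got {C}")
    pts = contour.points if isinstance(contour, Contour) else np.asarray(contour, float)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    perim = cum[-1]
    if perim <= 0:
        raise ValidationError("zero-perimeter contour")
    s0 = _ray_origin_arc(pts, cum)
    samples = (s0 + perim * np.arange(C) / C) % perim
    x = np.interp(samples, cum, closed[:, 0])
    y = np.interp(samples, cum, closed[:, 1])
    return np.column_stack([x, y])


def _min_twist_shift(curr: np.ndarray, prev: np.ndarray) -> int:
    """Cyclic shift of ``curr`` minimizing summed squared distance to ``prev``."""
    C = len(curr)
    # ||curr[(i+s)%C] - prev[i]||^2 summed over i, for each s: expand the dot
    # product and evaluate the cross terms for all shifts via FFT correlation.
    const = (curr**2).sum() + (prev**2).sum()
    f_curr = np.fft.rfft(curr, axis=0, n=C)
    f_prev = np.fft.rfft(prev, axis=0, n=C)
    corr = np.fft.irfft((f_curr * np.conj(f_prev)).sum(axis=1), n=C)
    cost = const - 2.0 * corr
    return int(np.argmin(cost))


def parameterize(
    stack: ContourStack,
    L: int = DEFAULT_LEVELS,
    C: int = DEFAULT_CIRCUM,
    min_slice_area: float = MIN_SLICE_AREA,
) -> ParametricSurface:
    """Interpolate a contour stack onto an L x C parametric surface grid.

    Each slice is resampled to C arc-length-uniform points and anchored with
    the minimal-twist rule; L levels are generated by linear interpolation
    between adjacent slices at uniform normalized positions t in [0, 1].
    Tiny terminal slices (area below ``min_slice_area`` mm^2, a byproduct of
    freehand tracing of the tapering tail) are dropped with a warning.
    """
    kept = []
    for c in stack.contours:
        if polygon_area(c) >= min_slice_area:
            kept.append(c)
        else:
            warnings.warn(
                f"{stack.subject_id}: dropping slice {c.slice_index} "
                f"(area < {min_slice_area} mm^2)",
                stacklevel=2,
            )
    if len(kept) < 3:
        raise ValidationError(f"{stack.subject_id}: fewer than 3 usable slices")

    rings = np.empty((len(kept), C, 2))
    z = np.empty(len(kept))
    for i, c in enumerate(kept):
        ring = resample_contour(c, C)
        if i > 0:
            shift = _min_twist_shift(ring, rings[i - 1])
            ring = np.roll(ring, -shift, axis=0)
        rings[i] = ring
        z[i] = c.z

    K = len(kept)
    u = np.arange(K) / (K - 1)  # normalized slice positions
    t = np.linspace(0.0, 1.0, L)
    # piecewise-linear interpolation of rings and z at the L level positions
    j = np.clip(np.searchsorted(u, t, side="right") - 1, 0, K - 2)
    w = ((t - u[j]) / (u[j + 1] - u[j]))[:, None, None]
    grid_xy = (1.0 - w) * rings[j] + w * rings[j + 1]
    grid_z = (1.0 - w[:, :, 0]) * z[j, None] + w[:, :, 0] * z[j + 1, None]
    grid = np.concatenate([grid_xy, np.broadcast_to(grid_z[:, :, None], (L, C, 1))], axis=2)
    return ParametricSurface(grid, subject_id=stack.subject_id)


# ---------------------------------------------------------------------------
# medial curve, radial map, template
# ---------------------------------------------------------------------------

def medial_curve(surface: ParametricSurface) -> MedialCurve:
    """Per-level arithmetic centroid of the C grid points.

    With equal arc spacing this is a perimeter-weighted center of the
    cross-section; it is exact for symmetric sections and deterministic for
    all others.
    """
    return MedialCurve(surface.grid.mean(axis=1))


def radial_map(surface: ParametricSurface, medial: MedialCurve) -> RadialMap:
    """Distance from each level's medial point to each surface vertex (mm)."""
    if len(medial.points) != surface.L:
        raise ValueError(
            f"medial curve length {len(medial.points)} != surface levels {surface.L}"
        )
    d = np.linalg.norm(surface.grid - medial.points[:, None, :], axis=2)
    return RadialMap(d, subject_id=surface.subject_id)


def average_surface(surfaces: Sequence[ParametricSurface]) -> ParametricSurface:
    """Vertex-wise mean surface (the cohort template results are mapped onto).

    All surfaces must share the grid shape and already live in a common
    rigidly aligned space.
    """
    surfaces = list(surfaces)
    if not surfaces:
        raise ValueError("cannot average an empty collection of surfaces")
    shapes = {s.grid.shape for s in surfaces}
    if len(shapes) != 1:
        raise ValueError(f"mixed surface grid shapes: {sorted(shapes)}")
    mean = np.mean([s.grid for s in surfaces], axis=0)
    return ParametricSurface(mean, subject_id="template")


# ---------------------------------------------------------------------------
# meshing and export
# ---------------------------------------------------------------------------

def surface_to_mesh(surface: ParametricSurface, cap_ends: bool = False) -> trimesh.Trimesh:
    """Triangulate the parametric grid into a mesh.

    Quads between adjacent levels are split into two triangles and the
    circumferential wrap is closed.  Without end caps the vertex count is
    exactly L*C; ``cap_ends=True`` adds one fan center per end.
    """
    L, C = surface.L, surface.C
    verts = surface.grid.reshape(-1, 3)
    l_idx = np.repeat(np.arange(L - 1), C)
    c_idx = np.tile(np.arange(C), L - 1)
    c_next = (c_idx + 1) % C
    v00 = l_idx * C + c_idx
    v01 = l_idx * C + c_next
    v10 = (l_idx + 1) * C + c_idx
    v11 = (l_idx + 1) * C + c_next
    faces = np.concatenate(
        [np.column_stack([v00, v01, v11]), np.column_stack([v00, v11, v10])]
    )
    if cap_ends:
        centers = np.array([surface.grid[0].mean(axis=0), surface.grid[-1].mean(axis=0)])
        verts = np.vstack([verts, centers])
        i0, i1 = L * C, L * C + 1
        first = np.arange(C)
        last = (L - 1) * C + np.arange(C)
        cap0 = np.column_stack([np.full(C, i0), (first + 1) % C, first])
        cap1 = np.column_stack([np.full(C, i1), last, (L - 1) * C + (np.arange(C) + 1) % C])
        faces = np.vstack([faces, cap0, cap1])
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def export_mesh(
    surface: ParametricSurface,
    path: str | Path,
    vertex_scalars: np.ndarray | None = None,
    cap_ends: bool = False,
) -> Path:
    """Export the triangulated surface as OBJ or PLY (by extension).

    ``vertex_scalars`` (an L x C map) is attached as a vertex color ramp for
    overlay in external viewers; the raw values belong in the CSV maps.
    """
    path = Path(path)
    mesh = surface_to_mesh(surface, cap_ends=cap_ends)
    if vertex_scalars is not None:
        vals = np.asarray(vertex_scalars, float).reshape(-1)
        if len(vals) != surface.L * surface.C:
            raise ValueError("vertex_scalars shape does not match the surface grid")
        lo, hi = float(vals.min()), float(vals.max())
        unit = (vals - lo) / (hi - lo) if hi > lo else np.zeros_like(vals)
        if len(mesh.vertices) > len(vals):  # cap centers
            unit = np.concatenate([unit, [0.5, 0.5]])
        colors = np.zeros((len(unit), 4), dtype=np.uint8)
        colors[:, 0] = np.round(255 * unit)
        colors[:, 2] = np.round(255 * (1.0 - unit))
        colors[:, 3] = 255
        mesh.visual.vertex_colors = colors
    kind = path.suffix.lstrip(".").lower()
    if kind == "ply":
        path.write_bytes(trimesh.exchange.ply.export_ply(mesh, encoding="ascii"))
    elif kind == "obj":
        path.write_text(trimesh.exchange.obj.export_obj(mesh))
    else:
        raise ValueError(f"unsupported mesh format: {path.suffix!r}")
    return path


# ---------------------------------------------------------------------------
# radial map serialization
# ---------------------------------------------------------------------------

def write_radial_map_csv(rmap: RadialMap, path: str | Path) -> Path:
    """Write an L x C radial map as CSV with identifying header comments."""
    path = Path(path)
    L, C = rmap.distances.shape
    header = f"# subject_id={rmap.subject_id}\n# L={L} C={C}\n"
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, rmap.distances, delimiter=",", fmt="%.10g")
    return path


def read_radial_map_csv(path: str | Path) -> RadialMap:
    path = Path(path)
    subject_id = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# subject_id="):
            subject_id = first.split("=", 1)[1].strip()
    data = np.loadtxt(path, delimiter=",", comments="#")
    return RadialMap(np.atleast_2d(data), subject_id=subject_id)
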