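"""Wall reference space, distance fields and virtual sublayers.

The wall of an implanted tubular graft is delimited in a 2D histological
section by two manually delineated border polylines: the *adluminal* (inner,
facing the lumen) and *abluminal* (outer) border.  Every point of the wall is
assigned a relative radial position

    f = d1 / (d1 + d2)

where ``d1`` is the Euclidean distance to the outer border curve and ``d2``
the distance to the inner border curve, so that ``f = 0`` on the outer border
and ``f = 1`` on the inner border.  Thresholding ``f`` at 1/3 and 2/3 splits
the wall into three *virtual sublayers* (outer / middle / inner), each
comprising one third of the local wall thickness while following every
irregularity of the borders.  All geometry is handled in micrometres, image
convention (y grows downward).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from enum import IntEnum
from typing import Literal

import numpy as np
import shapely
from scipy.spatial import cKDTree
from shapely.geometry import LinearRing, LineString, Polygon

__all__ = [
    "BorderPolyline",
    "WallRegion",
    "RelativePositionField",
    "SublayerAreas",
    "Sublayer",
    "resample_polyline",
    "build_wall_region",
    "compute_relative_position_field",
    "estimate_thickness",
    "sublayer_areas",
]

BorderRole = Literal["inner", "outer"]

#: f thresholds delimiting the outer / middle / inner virtual sublayers.
F_THRESHOLDS = (1.0 / 3.0, 2.0 / 3.0)


class Sublayer(IntEnum):
    """Integer labels of the virtual sublayer raster."""

    BACKGROUND = 0
    OUTER = 1
    MIDDLE = 2
    INNER = 3


class GeometryError(ValueError):
    """Invalid border or wall geometry."""


@dataclass(frozen=True)
class BorderPolyline:
    """Ordered vertex chain delimiting one wall border.

    Parameters
    ----------
    vertices:
        ``(n, 2)`` array of (x, y) coordinates in µm.  For a closed border the
        first vertex must *not* be repeated at the end; closure is implied.
    role:
        ``"inner"`` (adluminal) or ``"outer"`` (abluminal).
    closed:
        Closed contour (full cross-section) or open chain (longitudinal
        section).
    """

    vertices: np.ndarray
    role: BorderRole
    closed: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise GeometryError("vertices must be an (n, 2) array")
        if not np.isfinite(v).all():
            raise GeometryError("border coordinates must be finite")
        min_n = 3 if self.closed else 2
        if v.shape[0] < min_n:
            raise GeometryError(
                f"{'closed' if self.closed else 'open'} border needs "
                f">= {min_n} vertices, got {v.shape[0]}"
            )
        if self.role not in ("inner", "outer"):
            raise GeometryError(f"unknown border role {self.role!r}")
        if not self.as_shapely().is_simple:
            raise GeometryError("border polyline must not self-intersect")
        object.__setattr__(self, "vertices", v)

    def as_shapely(self) -> LineString:
        """The border as a shapely curve (LinearRing when closed)."""
        if self.closed:
            return LinearRing(self.vertices)
        return LineString(self.vertices)

    @property
    def length(self) -> float:
        """Total arc length in µm."""
        return float(self.as_shapely().length)


def resample_polyline(border: BorderPolyline, spacing: float) -> BorderPolyline:
    """Resample a border at (at most) ``spacing`` µm between vertices.

    Vertices are placed at uniform arc length along the original curve, so the
    output lies exactly on the input geometry, endpoints (or closure) are
    preserved, and consecutive gaps never exceed ``spacing``.
    """
    if spacing <= 0:
        raise GeometryError("spacing must be positive")
    total = border.length
    if total <= 0:
        raise GeometryError("degenerate zero-length border")
    n_seg = max(1, int(np.ceil(total / spacing)))
    if border.closed:
        s = np.arange(n_seg, dtype=float) * total / n_seg
        if n_seg < 3:
            s = np.arange(3, dtype=float) * total / 3
    else:
        s = np.linspace(0.0, total, n_seg + 1)
    pts = _points_at_arclength(border.vertices, border.closed, s)
    return BorderPolyline(pts, role=border.role, closed=border.closed)


def _points_at_arclength(
    vertices: np.ndarray, closed: bool, s: np.ndarray
) -> np.ndarray:
    v = vertices
    if closed:
        v = np.vstack([v, v[:1]])
    seg = np.diff(v, axis=0)
    cum = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
    x = np.interp(s, cum, v[:, 0])
    y = np.interp(s, cum, v[:, 1])
    return np.column_stack([x, y])


@dataclass(frozen=True)
class WallRegion:
    """The wall reference space between the two border polylines.

    ``polygon`` is the shapely polygon bounded by the two borders; for open
    borders, straight end-caps join corresponding endpoints (pairing chosen to
    minimize total cap length).  End-caps are part of the region boundary but
    never act as distance targets for d1 / d2.
    """

    inner: BorderPolyline
    outer: BorderPolyline
    pixel_size: float
    polygon: Polygon = dc_field(repr=False, compare=False, default=None)

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise GeometryError("pixel_size must be positive")
        if self.polygon is None:
            raise GeometryError("use build_wall_region() to construct a WallRegion")

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of the wall in µm."""
        return self.polygon.bounds

    @property
    def area_um2(self) -> float:
        """Exact polygonal wall area in µm²."""
        return float(self.polygon.area)


def build_wall_region(
    inner: BorderPolyline, outer: BorderPolyline, pixel_size: float
) -> WallRegion:
    """Assemble the wall region from its two delineated borders."""
    if inner.role != "inner" or outer.role != "outer":
        raise GeometryError("borders must have roles inner and outer")
    if inner.closed != outer.closed:
        raise GeometryError("borders must share open/closed topology")
    gi, go = inner.as_shapely(), outer.as_shapely()
    if gi.intersects(go):
        raise GeometryError("inner and outer borders intersect")

    if inner.closed:
        ring_out = Polygon(outer.vertices)
        ring_in = Polygon(inner.vertices)
        if not ring_out.contains(ring_in):
            raise GeometryError("closed inner border must lie inside the outer")
        poly = Polygon(outer.vertices, holes=[inner.vertices])
    else:
        vo, vi = outer.vertices, inner.vertices
        # end-cap pairing minimizing total cap length
        same = np.linalg.norm(vo[0] - vi[0]) + np.linalg.norm(vo[-1] - vi[-1])
        swap = np.linalg.norm(vo[0] - vi[-1]) + np.linalg.norm(vo[-1] - vi[0])
        chain = vi[::-1] if same <= swap else vi
        poly = Polygon(np.vstack([vo, chain]))
    if not poly.is_valid or poly.area <= 0:
        raise GeometryError("borders do not enclose a valid positive-area wall")
    return WallRegion(inner=inner, outer=outer, pixel_size=pixel_size, polygon=poly)


@dataclass(frozen=True)
class RelativePositionField:
    """Raster of d1, d2, f and sublayer labels over the wall mask.

    The grid covers the wall bounding box; cell ``(r, c)`` has its center at
    ``origin + (c + 0.5, r + 0.5) * spacing``.  A cell belongs to the wall iff
    its center lies inside the wall polygon.  Distances are measured to the
    true border curves, densely resampled at a quarter of the grid spacing.
    """

    origin: tuple[float, float]
    spacing: float
    mask: np.ndarray
    d1: np.ndarray
    d2: np.ndarray
    f: np.ndarray
    sublayer: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    def cell_index(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Map µm points to (row, col) grid indices plus an in-bounds flag."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        col = np.floor((p[:, 0] - self.origin[0]) / self.spacing).astype(int)
        row = np.floor((p[:, 1] - self.origin[1]) / self.spacing).astype(int)
        nr, nc = self.mask.shape
        ok = (row >= 0) & (row < nr) & (col >= 0) & (col < nc)
        return row, col, ok

    def sublayer_at(self, points: np.ndarray) -> np.ndarray:
        """Sublayer label of the grid cell holding each point (0 = outside)."""
        row, col, ok = self.cell_index(points)
        out = np.zeros(row.shape, dtype=np.uint8)
        out[ok] = self.sublayer[row[ok], col[ok]]
        return out

    def f_at(self, points: np.ndarray) -> np.ndarray:
        """Relative position f of the grid cell holding each point (NaN outside)."""
        row, col, ok = self.cell_index(points)
        out = np.full(row.shape, np.nan)
        sel = ok.copy()
        sel[ok] &= self.mask[row[ok], col[ok]]
        out[sel] = self.f[row[sel], col[sel]]
        return out


def _dense_border_points(border: BorderPolyline, spacing: float) -> np.ndarray:
    return resample_polyline(border, spacing).vertices


def sublayer_of_f(f: np.ndarray) -> np.ndarray:
    """Label f values: outer [0, 1/3), middle [1/3, 2/3), inner [2/3, 1]."""
    f = np.asarray(f)
    lab = np.full(f.shape, Sublayer.OUTER, dtype=np.uint8)
    lab[f >= F_THRESHOLDS[0]] = Sublayer.MIDDLE
    lab[f >= F_THRESHOLDS[1]] = Sublayer.INNER
    return lab


def compute_relative_position_field(
    region: WallRegion, spacing: float | None = None
) -> RelativePositionField:
    """Compute d1, d2, f and sublayer labels on a regular grid over the wall.

    ``spacing`` defaults to the region's pixel size.  End-caps of open walls
    are excluded from the distance targets: distances always refer to the
    delineated border curves themselves.
    """
    if spacing is None:
        spacing = region.pixel_size
    if spacing <= 0:
        raise GeometryError("spacing must be positive")
    minx, miny, maxx, maxy = region.bounds
    nc = int(np.ceil((maxx - minx) / spacing))
    nr = int(np.ceil((maxy - miny) / spacing))
    if nc < 1 or nr < 1:
        raise GeometryError("grid spacing too coarse: empty wall mask")
    xs = minx + (np.arange(nc) + 0.5) * spacing
    ys = miny + (np.arange(nr) + 0.5) * spacing
    gx, gy = np.meshgrid(xs, ys)
    mask = shapely.contains_xy(region.polygon, gx.ravel(), gy.ravel()).reshape(nr, nc)
    if not mask.any():
        raise GeometryError("grid spacing too coarse: empty wall mask")

    centers = np.column_stack([gx.ravel()[mask.ravel()], gy.ravel()[mask.ravel()]])
    dense = 0.25 * spacing
    tree_out = cKDTree(_dense_border_points(region.outer, dense))
    tree_in = cKDTree(_dense_border_points(region.inner, dense))
    d1_v, _ = tree_out.query(centers, workers=-1)
    d2_v, _ = tree_in.query(centers, workers=-1)

    d1 = np.zeros((nr, nc))
    d2 = np.zeros((nr, nc))
    fval = np.full((nr, nc), np.nan)
    d1[mask] = d1_v
    d2[mask] = d2_v
    with np.errstate(invalid="ignore"):
        fval[mask] = d1_v / (d1_v + d2_v)
    sub = np.zeros((nr, nc), dtype=np.uint8)
    sub[mask] = sublayer_of_f(fval[mask])
    return RelativePositionField(
        origin=(minx, miny), spacing=float(spacing),
        mask=mask, d1=d1, d2=d2, f=fval, sublayer=sub,
    )


def estimate_thickness(region: WallRegion, spacing: float = 2.0) -> float:
    """Wall thickness as the mean distance between the two border curves.

    Both borders are resampled at ``spacing``; each resampled point of one
    border contributes its nearest Euclidean distance to the *other* border
    curve, and the pooled distances of both directions are averaged
    (symmetric pooling avoids the bias of a one-sided nearest distance when
    the borders curve unequally).  For open (longitudinal) walls, resampled
    points within one nominal thickness of either cut end are discarded
    before pooling, since nearest distances there escape through the open
    ends; the nominal thickness is taken as the median of the untrimmed pool.
    """
    if spacing <= 0:
        raise GeometryError("spacing must be positive")
    inner_r = resample_polyline(region.inner, spacing)
    outer_r = resample_polyline(region.outer, spacing)
    gi, go = region.inner.as_shapely(), region.outer.as_shapely()
    d_i = shapely.distance(shapely.points(inner_r.vertices), go)
    d_o = shapely.distance(shapely.points(outer_r.vertices), gi)
    if region.inner.closed:
        return float(np.mean(np.concatenate([d_i, d_o])))

    t0 = float(np.median(np.concatenate([d_i, d_o])))
    kept = []
    for res, dist in ((inner_r, d_i), (outer_r, d_o)):
        seg = np.diff(res.vertices, axis=0)
        arc = np.concatenate([[0.0], np.cumsum(np.hypot(seg[:, 0], seg[:, 1]))])
        total = arc[-1]
        sel = (arc >= t0) & (arc <= total - t0)
        kept.append(dist[sel])
    pooled = np.concatenate(kept)
    if pooled.size == 0:  # wall shorter than ~2 thicknesses: fall back untrimmed
        pooled = np.concatenate([d_i, d_o])
    return float(np.mean(pooled))


@dataclass(frozen=True)
class SublayerAreas:
    """Areas of the three virtual sublayers, mm²."""

    area_inner: float
    area_middle: float
    area_outer: float

    @property
    def area_total(self) -> float:
        return self.area_inner + self.area_middle + self.area_outer

    def of(self, layer: Sublayer) -> float:
        return {
            Sublayer.INNER: self.area_inner,
            Sublayer.MIDDLE: self.area_middle,
            Sublayer.OUTER: self.area_outer,
        }[layer]


def sublayer_areas(field: RelativePositionField) -> SublayerAreas:
    """Per-sublayer areas from the label raster (cell count × spacing²)."""
    if not field.mask.any():
        raise GeometryError("empty wall mask")
    cell_mm2 = (field.spacing ** 2) / 1e6
    counts = np.bincount(field.sublayer.ravel(), minlength=4)
    return SublayerAreas(
        area_inner=float(counts[Sublayer.INNER] * cell_mm2),
        area_middle=float(counts[Sublayer.MIDDLE] * cell_mm2),
        area_outer=float(counts[Sublayer.OUTER] * cell_mm2),
    )
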