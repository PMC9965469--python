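"""Synthetic walls, nuclei point patterns and rendered micrographs.

Ground-truth generator for end-to-end testing of the quantification pipeline:
parametric wall geometries (annular cross-sections and longitudinal strips,
optionally with sinusoidally irregular borders), inhomogeneous Poisson nuclei
patterns whose intensity λ(f) may vary with relative wall depth, and
brightfield renderings of hematoxylin-stained nuclei on an eosin-tinted wall.

The two presets emulate the colonization states of an electrospun
polycaprolactone aortic graft reported at the study's timepoints: 10 days
after implantation the wall (744 µm thick) is colonized homogeneously at
about 2500 nuclei profiles per mm²; at 6 months the wall has thinned to
686 µm and carries an adluminally increasing gradient (inner third
2976 mm⁻², middle 2367 mm⁻², outer 1997 mm⁻²).  Preset geometry defaults to
a longitudinal strip matching a single analysed field of view; the annular
variant uses the graft's 825 µm luminal radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Literal

import numpy as np
import pandas as pd
import shapely

from .nuclei_detection import DEFAULT_STAIN_MATRIX, Micrograph
from .wall_geometry import (
    BorderPolyline,
    RelativePositionField,
    Sublayer,
    WallRegion,
    build_wall_region,
    resample_polyline,
    sublayer_of_f,
)

__all__ = [
    "WallSpec",
    "DensityProfile",
    "NucleusRenderSpec",
    "make_wall",
    "exact_relative_position",
    "scatter_nuclei",
    "preset",
    "PRESETS",
    "render_micrograph",
    "overlap_benchmark",
    "match_points",
]

LAYER_NAMES = {
    int(Sublayer.OUTER): "outer",
    int(Sublayer.MIDDLE): "middle",
    int(Sublayer.INNER): "inner",
}

#: default field-of-view canvas, pixels (rows, cols)
DEFAULT_CANVAS = (1616, 1912)


@dataclass(frozen=True)
class WallSpec:
    """Parametric wall geometry.

    ``radius`` is the luminal (inner-border) radius of an annulus; ``length``
    the extent of a longitudinal strip.  Border irregularity is a sinusoid of
    the given amplitude/wavelength applied to the outer border.
    """

    shape: Literal["annulus", "longitudinal"]
    nominal_thickness: float
    length: float = 1800.0
    radius: float = 825.0
    irregularity_amplitude: float = 0.0
    irregularity_wavelength: float = 1000.0
    pixel_size: float = 1.0
    margin: float = 50.0

    def __post_init__(self) -> None:
        if self.shape not in ("annulus", "longitudinal"):
            raise ValueError(f"unknown wall shape {self.shape!r}")
        if not self.nominal_thickness > 2 * self.irregularity_amplitude >= 0:
            raise ValueError("require nominal_thickness > 2*irregularity_amplitude >= 0")
        if min(self.length, self.radius, self.pixel_size, self.irregularity_wavelength) <= 0:
            raise ValueError("all lengths must be positive")


@dataclass(frozen=True)
class DensityProfile:
    """Piecewise-linear nuclei intensity λ(f), mm⁻², over relative depth f."""

    f_knots: tuple[float, ...] = (0.0, 1.0)
    lambda_knots: tuple[float, ...] = (2500.0, 2500.0)

    def __post_init__(self) -> None:
        fk = np.asarray(self.f_knots, float)
        lk = np.asarray(self.lambda_knots, float)
        if fk.shape != lk.shape or fk.ndim != 1 or fk.size < 2:
            raise ValueError("f_knots and lambda_knots must be matching 1-D sequences")
        if (np.diff(fk) < 0).any() or (lk < 0).any():
            raise ValueError("f_knots must be non-decreasing and lambda >= 0")

    def intensity(self, f: np.ndarray) -> np.ndarray:
        """λ(f) in mm⁻²."""
        return np.interp(np.asarray(f, float), self.f_knots, self.lambda_knots)

    @property
    def lambda_max(self) -> float:
        return float(max(self.lambda_knots))

    @staticmethod
    def constant(lam: float) -> "DensityProfile":
        return DensityProfile((0.0, 1.0), (lam, lam))

    @staticmethod
    def step_by_layer(outer: float, middle: float, inner: float) -> "DensityProfile":
        """Piecewise-constant intensity per virtual sublayer."""
        eps = 1e-9
        return DensityProfile(
            (0.0, 1 / 3 - eps, 1 / 3, 2 / 3 - eps, 2 / 3, 1.0),
            (outer, outer, middle, middle, inner, inner),
        )


@dataclass(frozen=True)
class NucleusRenderSpec:
    """Appearance of rendered nuclei and tissue."""

    radius_range_um: tuple[float, float] = (3.0, 5.0)
    od_range: tuple[float, float] = (0.7, 1.0)
    background_eosin_od: float = 0.15
    noise_sigma: float = 2.0
    overlap_allowed: bool = True

    def __post_init__(self) -> None:
        if self.radius_range_um[0] <= 0 or self.radius_range_um[1] < self.radius_range_um[0]:
            raise ValueError("invalid radius range")
        if self.od_range[0] <= 0 or self.od_range[1] < self.od_range[0]:
            raise ValueError("invalid OD range")


def _sample_curve(fun: Callable[[np.ndarray], np.ndarray], t: np.ndarray) -> np.ndarray:
    return np.column_stack(fun(t))


def make_wall(spec: WallSpec) -> tuple[WallRegion, Callable[[np.ndarray], np.ndarray] | None]:
    """Build border polylines for a wall spec.

    Returns the wall region and, for regular (zero-irregularity) geometries,
    a closed-form oracle mapping µm points to their exact relative position f.
    Irregular borders are checked for non-intersection at construction.
    """
    t, m = spec.nominal_thickness, spec.margin
    amp, wav = spec.irregularity_amplitude, spec.irregularity_wavelength
    step = 2.0  # µm between generated vertices

    if spec.shape == "annulus":
        r_in = spec.radius
        r_out = r_in + t
        c = m + r_out + amp
        center = np.array([c, c])
        # integer lobe count closes the sinusoid on the ring
        k = max(1, int(round(2 * np.pi * r_out / wav)))

        def ring(r_of_theta: Callable[[np.ndarray], np.ndarray], r_ref: float) -> np.ndarray:
            n = max(16, int(np.ceil(2 * np.pi * r_ref / step)))
            th = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
            r = r_of_theta(th)
            return center + np.column_stack([r * np.cos(th), r * np.sin(th)])

        outer_v = ring(lambda th: r_out + amp * np.sin(k * th), r_out)
        inner_v = ring(lambda th: np.full_like(th, r_in), r_in)
        inner = BorderPolyline(inner_v, role="inner", closed=True)
        outer = BorderPolyline(outer_v, role="outer", closed=True)
        region = build_wall_region(inner, outer, spec.pixel_size)
        if amp == 0.0:
            def oracle(points: np.ndarray) -> np.ndarray:
                p = np.atleast_2d(points) - center
                r = np.hypot(p[:, 0], p[:, 1])
                return np.clip((r_out - r) / t, 0.0, 1.0)
            return region, oracle
        return region, None

    # longitudinal strip: outer border on top (small y), lumen below
    y0 = m + amp
    n = max(2, int(np.ceil(spec.length / step)) + 1)
    x = np.linspace(m, m + spec.length, n)
    outer_y = y0 + amp * np.sin(2 * np.pi * (x - m) / wav)
    outer = BorderPolyline(np.column_stack([x, outer_y]), role="outer", closed=False)
    inner = BorderPolyline(
        np.column_stack([x, np.full_like(x, y0 + t)]), role="inner", closed=False
    )
    region = build_wall_region(inner, outer, spec.pixel_size)
    if amp == 0.0:
        def oracle(points: np.ndarray) -> np.ndarray:
            p = np.atleast_2d(points)
            return np.clip((p[:, 1] - y0) / t, 0.0, 1.0)
        return region, oracle
    return region, None


def exact_relative_position(
    region: WallRegion, points: np.ndarray, resolution: float = 0.5
) -> np.ndarray:
    """Near-exact f at arbitrary points from densely resampled border curves.

    Grid-free: distances go to border polylines resampled at ``resolution``
    µm, so this serves as ground truth independent of any raster field.
    """
    from scipy.spatial import cKDTree

    pts = np.atleast_2d(np.asarray(points, float))
    d1, _ = cKDTree(resample_polyline(region.outer, resolution).vertices).query(pts)
    d2, _ = cKDTree(resample_polyline(region.inner, resolution).vertices).query(pts)
    return d1 / (d1 + d2)


def scatter_nuclei(
    region: WallRegion,
    field: RelativePositionField | None,
    profile: DensityProfile,
    rng: np.random.Generator | int,
) -> pd.DataFrame:
    """Sample an inhomogeneous Poisson nuclei pattern on the wall by thinning.

    Candidates arrive at rate λ_max over the wall's bounding box; a candidate
    inside the wall polygon is kept with probability λ(f)/λ_max, where f is
    its ground-truth relative position (grid-free).  Deterministic for a
    fixed seed.  Returns columns x_um, y_um, f_true, layer_true.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lam_max = profile.lambda_max
    cols = ["x_um", "y_um", "f_true", "layer_true"]
    if lam_max == 0.0:
        return pd.DataFrame(columns=cols)
    minx, miny, maxx, maxy = region.bounds
    bbox_mm2 = (maxx - minx) * (maxy - miny) / 1e6
    n = rng.poisson(lam_max * bbox_mm2)
    pts = np.column_stack(
        [rng.uniform(minx, maxx, n), rng.uniform(miny, maxy, n)]
    )
    inside = shapely.contains_xy(region.polygon, pts[:, 0], pts[:, 1])
    pts = pts[inside]
    f_true = exact_relative_position(region, pts) if len(pts) else np.empty(0)
    keep = rng.uniform(size=len(pts)) < profile.intensity(f_true) / lam_max
    pts, f_true = pts[keep], f_true[keep]
    layer = [LAYER_NAMES[int(v)] for v in sublayer_of_f(f_true)]
    return pd.DataFrame(
        {"x_um": pts[:, 0], "y_um": pts[:, 1], "f_true": f_true, "layer_true": layer}
    )


#: preset name -> (wall thickness µm, λ(f) profile builder)
PRESETS: dict[str, tuple[float, Callable[[], DensityProfile]]] = {
    # early homogeneous colonization: ~2500 nuclei profiles / mm² throughout
    "day10": (744.0, lambda: DensityProfile.constant(2500.0)),
    # remodeled state: density decreasing with distance from the lumen
    "month6": (686.0, lambda: DensityProfile.step_by_layer(1997.0, 2367.0, 2976.0)),
}


def preset(
    name: str, shape: Literal["annulus", "longitudinal"] = "longitudinal"
) -> tuple[WallSpec, DensityProfile]:
    """Named study-condition presets (see module docstring).

    These are generator parameters emulating the reported group means, not a
    reproduction of the in-vivo data.
    """
    if name not in PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(sorted(PRESETS))}"
        )
    thickness, profile = PRESETS[name]
    return WallSpec(shape=shape, nominal_thickness=thickness), profile()


def overlap_benchmark(
    rng: np.random.Generator | int,
    n_total: int = 500,
    overlap_fraction: float = 0.10,
    wall_length: float = 700.0,
    thickness: float = 700.0,
    pair_distance_um: tuple[float, float] = (4.0, 6.5),
) -> tuple[WallRegion, pd.DataFrame]:
    """Seeded ground-truth pattern for benchmarking the detector.

    Places ``n_total`` nuclei on a rectangular wall: a fixed fraction of them
    form overlapping pairs (center distance drawn from ``pair_distance_um``,
    below the sum of typical profile radii), the rest are isolated singles
    with a hard-core separation wide enough that they never touch.  Returns
    the wall region and a point table with an ``overlapping`` flag.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    spec = WallSpec("longitudinal", thickness, length=wall_length)
    region, _ = make_wall(spec)
    minx, miny, maxx, maxy = region.bounds
    pad = 8.0  # keep whole profiles inside the wall
    lo = np.array([minx + pad, miny + pad])
    hi = np.array([maxx - pad, maxy - pad])

    n_pairs = int(round(n_total * overlap_fraction / 2))
    n_anchors = n_total - n_pairs  # singles + one anchor per pair
    hard_core = 13.0  # µm; anchors never interact with each other
    anchors: list[np.ndarray] = []
    while len(anchors) < n_anchors:
        cand = rng.uniform(lo, hi)
        if all(np.hypot(*(cand - a)) >= hard_core for a in anchors):
            anchors.append(cand)
    anchors_arr = np.array(anchors)

    partners = []
    for a in anchors_arr[:n_pairs]:
        d = rng.uniform(*pair_distance_um)
        th = rng.uniform(0, 2 * np.pi)
        partners.append(a + d * np.array([np.cos(th), np.sin(th)]))
    pts = np.vstack([anchors_arr, np.array(partners).reshape(-1, 2)])
    overlapping = np.zeros(len(pts), dtype=bool)
    overlapping[:n_pairs] = True
    overlapping[n_anchors:] = True
    f_true = exact_relative_position(region, pts)
    return region, pd.DataFrame(
        {
            "x_um": pts[:, 0],
            "y_um": pts[:, 1],
            "f_true": f_true,
            "layer_true": [LAYER_NAMES[int(v)] for v in sublayer_of_f(f_true)],
            "overlapping": overlapping,
        }
    )


def match_points(
    detected: np.ndarray, truth: np.ndarray, radius: float = 3.0
) -> tuple[int, float, float]:
    """Greedy one-to-one matching of detections to ground truth.

    Pairs are accepted closest-first within ``radius`` µm, each truth point
    used at most once.  Returns (matches, recall, precision).
    """
    from scipy.spatial import cKDTree

    detected = np.atleast_2d(np.asarray(detected, float))
    truth = np.atleast_2d(np.asarray(truth, float))
    if len(detected) == 0 or len(truth) == 0:
        return 0, 0.0, 0.0
    d, idx = cKDTree(truth).query(detected)
    used: set[int] = set()
    hits = 0
    for di, ii in sorted(zip(d, idx)):
        if di <= radius and ii not in used:
            used.add(int(ii))
            hits += 1
    return hits, hits / len(truth), hits / len(detected)


def render_micrograph(
    region: WallRegion,
    points: pd.DataFrame,
    render_spec: NucleusRenderSpec | None = None,
    rng: np.random.Generator | int = 0,
    canvas_shape: tuple[int, int] | None = None,
    micrograph_id: str = "synthetic",
) -> tuple[Micrograph, pd.DataFrame]:
    """Render nuclei as shaded hematoxylin disks on an eosin-tinted wall.

    Each nucleus is drawn with a spherical-projection optical-density profile
    (peak OD at the center, falling to zero at the profile edge, as for the
    light path through a stained sphere); overlapping profiles combine by
    maximum.  The RGB image follows the Beer–Lambert transmission model under
    the default stain vectors, with additive Gaussian sensor noise.  Returns
    the micrograph and a ground-truth table (input columns plus radius and
    peak OD per nucleus).

    The canvas defaults to 1616 × 1912 pixels when the wall fits, otherwise
    to the wall bounds plus margin; points outside the canvas are an error.
    """
    spec = render_spec or NucleusRenderSpec()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    ps = region.pixel_size
    minx, miny, maxx, maxy = region.bounds
    pad = spec.radius_range_um[1] + 10.0
    need = (int(np.ceil((maxy + pad) / ps)), int(np.ceil((maxx + pad) / ps)))
    if canvas_shape is None:
        canvas_shape = (
            DEFAULT_CANVAS
            if need[0] <= DEFAULT_CANVAS[0] and need[1] <= DEFAULT_CANVAS[1]
            else need
        )
    h, w = canvas_shape
    xs = points["x_um"].to_numpy() if len(points) else np.empty(0)
    ys = points["y_um"].to_numpy() if len(points) else np.empty(0)
    if len(xs) and (
        (xs < 0).any() or (ys < 0).any() or (xs > w * ps).any() or (ys > h * ps).any()
    ):
        raise ValueError("nuclei points fall outside the canvas")

    n = len(xs)
    radii = rng.uniform(*spec.radius_range_um, size=n)
    ods = rng.uniform(*spec.od_range, size=n)

    # spherical-projection shading: absorbance follows the chord length of the
    # light path through a spherical nucleus, peaking at the center.  Profiles
    # combine by maximum: in a thin section overlapping profiles come from
    # laterally adjacent nuclei, not axially stacked ones, so their stain
    # densities do not add up.
    od_h = np.zeros((h, w))
    for x, y, r, od in zip(xs, ys, radii, ods):
        rp = r / ps
        cy, cx = y / ps - 0.5, x / ps - 0.5
        r0 = max(0, int(np.floor(cy - rp)))
        r1 = min(h, int(np.ceil(cy + rp)) + 1)
        c0 = max(0, int(np.floor(cx - rp)))
        c1 = min(w, int(np.ceil(cx + rp)) + 1)
        yy, xx = np.mgrid[r0:r1, c0:c1]
        d2 = ((yy - cy) ** 2 + (xx - cx) ** 2) / (rp * rp)
        shade = od * np.sqrt(np.clip(1.0 - d2, 0.0, None))
        od_h[r0:r1, c0:c1] = np.maximum(od_h[r0:r1, c0:c1], shade)

    gx = (np.arange(w) + 0.5) * ps
    gy = (np.arange(h) + 0.5) * ps
    mx, my = np.meshgrid(gx, gy)
    poly = region.polygon
    shapely.prepare(poly)
    wall_mask = shapely.contains_xy(poly, mx.ravel(), my.ravel()).reshape(h, w)
    od_e = np.where(wall_mask, spec.background_eosin_od, 0.0)

    v_h, v_e = DEFAULT_STAIN_MATRIX[0], DEFAULT_STAIN_MATRIX[1]
    od_rgb = od_h[..., None] * v_h + od_e[..., None] * v_e
    img = 255.0 * np.power(10.0, -od_rgb)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    rgb = np.clip(np.round(img), 0, 255).astype(np.uint8)

    truth = points.copy()
    truth["radius_um"] = radii
    truth["peak_od"] = ods
    return Micrograph(rgb=rgb, pixel_size=ps, id=micrograph_id), truth
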