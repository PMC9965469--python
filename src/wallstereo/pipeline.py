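"""End-to-end quantification of one micrograph: wall field → counts → report row."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .nuclei_detection import DetectionError, NucleusProfile, decisive_point
from .stereology import (
    MicrographResult,
    assign_and_count,
    mean_relative_distance,
)
from .wall_geometry import (
    RelativePositionField,
    WallRegion,
    compute_relative_position_field,
    estimate_thickness,
    sublayer_areas,
)

__all__ = ["profiles_from_points", "quantify_micrograph"]


def profiles_from_points(points: pd.DataFrame | np.ndarray) -> list[NucleusProfile]:
    """Wrap bare (x, y) points as single-point profiles (zero area).

    Accepts an (n, 2) array or a DataFrame with x_um / y_um columns; useful
    for pre-detected nuclei lists and for ground-truth point patterns.
    """
    if isinstance(points, pd.DataFrame):
        pts = points[["x_um", "y_um"]].to_numpy(float)
    else:
        pts = np.atleast_2d(np.asarray(points, float))
    out = []
    for i, (x, y) in enumerate(pts, start=1):
        p = (float(x), float(y))
        out.append(
            NucleusProfile(
                label=i, pixels=np.array([p]), area=0.0,
                centroid=p, decisive_point=p, provenance="manual_add",
            )
        )
    return out


def quantify_micrograph(
    profiles: Sequence[NucleusProfile],
    region: WallRegion,
    grid_spacing: float | None = None,
    micrograph_id: str = "",
    sample_id: str = "",
    field: RelativePositionField | None = None,
    thickness_spacing: float = 2.0,
) -> MicrographResult:
    """Run the stereological quantification for one field of view.

    Recomputes each multi-pixel profile's decisive point against the wall
    field (so the adluminal tie-break applies), assigns and counts per
    sublayer, and measures areas, densities, mean relative position and wall
    thickness.  A precomputed ``field`` for the same region may be passed to
    avoid recomputation across micrographs sharing one wall.
    """
    if field is None:
        field = compute_relative_position_field(region, grid_spacing)
    resolved: list[NucleusProfile] = []
    for p in profiles:
        if len(p.pixels) > 1:
            try:
                dp = decisive_point(p, field)
            except DetectionError:
                dp = p.decisive_point  # fully off-grid: will count as excluded
            if dp != p.decisive_point:
                from dataclasses import replace

                p = replace(p, decisive_point=dp)
        resolved.append(p)
    counts = assign_and_count(resolved, field) if resolved else assign_and_count([], field)
    areas = sublayer_areas(field)
    f_mean = mean_relative_distance(resolved, field)
    thickness = estimate_thickness(region, spacing=thickness_spacing)
    return MicrographResult.from_measurements(
        micrograph_id=micrograph_id, sample_id=sample_id,
        counts=counts, areas=areas, f_mean=f_mean, thickness_um=thickness,
    )
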