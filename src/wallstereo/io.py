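"""File formats: border/point/detection CSVs, report JSON/CSV, images, fields.

All files use a single µm coordinate frame; pixel↔µm conversion happens only
at image I/O.  JSON is the authoritative report format, CSV a flattened view.
Writers are deterministic so that a re-run from the same config and inputs
reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .nuclei_detection import Micrograph, NucleusProfile
from .stereology import LayerCounts, MicrographResult, StereologyReport
from .wall_geometry import (
    BorderPolyline,
    RelativePositionField,
    SublayerAreas,
    WallRegion,
    build_wall_region,
)

__all__ = [
    "RunConfig",
    "read_borders",
    "write_borders",
    "read_detections",
    "write_detections",
    "read_edits",
    "read_image",
    "write_image",
    "export_field",
    "micrograph_result_to_dict",
    "micrograph_result_from_dict",
    "write_report_json",
    "read_report_json",
    "write_report_csv",
]

log = logging.getLogger("wallstereo")

DETECTION_COLUMNS = [
    "label", "x_um", "y_um", "area_um2",
    "decisive_x_um", "decisive_y_um", "provenance",
]


@dataclass(frozen=True)
class RunConfig:
    """Serializable record of everything that determines a pipeline run."""

    pixel_size_um: float = 1.0
    grid_spacing_um: float | None = None
    od_threshold: float = 0.25
    min_area_um2: float = 10.0
    max_area_um2: float = 200.0
    split_min_distance_um: float = 4.0
    smoothing_sigma_um: float = 1.0
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        ).hexdigest()[:12]


def file_digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:12]


def stage_log(stage: str, **info) -> None:
    """One structured log line per pipeline stage."""
    kv = " ".join(f"{k}={v}" for k, v in sorted(info.items()))
    log.info("stage=%s %s", stage, kv)


# ---------------------------------------------------------------- borders ---

def write_borders(path: str | Path, region: WallRegion) -> None:
    """Write both borders to one CSV with columns role,closed,x_um,y_um."""
    rows = []
    for b in (region.inner, region.outer):
        for x, y in b.vertices:
            rows.append(
                {"role": b.role, "closed": int(b.closed), "x_um": x, "y_um": y}
            )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def read_borders(path: str | Path, pixel_size: float) -> WallRegion:
    """Read a borders CSV (roles exactly ``inner`` and ``outer``)."""
    df = pd.read_csv(path)
    needed = {"role", "closed", "x_um", "y_um"}
    if not needed.issubset(df.columns):
        raise ValueError(f"borders CSV must have columns {sorted(needed)}")
    borders = {}
    for role, grp in df.groupby("role", sort=False):
        if role not in ("inner", "outer"):
            raise ValueError(f"unknown border role {role!r} (expected inner|outer)")
        borders[role] = BorderPolyline(
            grp[["x_um", "y_um"]].to_numpy(),
            role=role,
            closed=bool(grp["closed"].iloc[0]),
        )
    if set(borders) != {"inner", "outer"}:
        raise ValueError("borders CSV must contain both an inner and an outer border")
    return build_wall_region(borders["inner"], borders["outer"], pixel_size)


# ------------------------------------------------------------- detections ---

def write_detections(path: str | Path, profiles: Sequence[NucleusProfile]) -> None:
    rows = [
        {
            "label": p.label,
            "x_um": p.centroid[0],
            "y_um": p.centroid[1],
            "area_um2": p.area,
            "decisive_x_um": p.decisive_point[0],
            "decisive_y_um": p.decisive_point[1],
            "provenance": p.provenance,
        }
        for p in profiles
    ]
    pd.DataFrame(rows, columns=DETECTION_COLUMNS).to_csv(
        path, index=False, float_format="%.4f"
    )


def read_detections(path: str | Path) -> list[NucleusProfile]:
    """Read a detections CSV back into (point-backed) profiles.

    Pixel memberships are not stored in the CSV, so each profile is restored
    with its decisive point as the sole member pixel — sufficient for all
    counting and position statistics.
    """
    df = pd.read_csv(path)
    missing = set(DETECTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"detections CSV missing columns {sorted(missing)}")
    out = []
    for r in df.itertuples(index=False):
        dp = (float(r.decisive_x_um), float(r.decisive_y_um))
        out.append(
            NucleusProfile(
                label=int(r.label),
                pixels=np.array([dp]),
                area=float(r.area_um2),
                centroid=(float(r.x_um), float(r.y_um)),
                decisive_point=dp,
                provenance=str(r.provenance),
            )
        )
    return out


def read_edits(path: str | Path) -> tuple[list[tuple[float, float]], list[int]]:
    """Read a manual-edits CSV (action,x_um,y_um,label) into (adds, removals)."""
    df = pd.read_csv(path)
    adds, removals = [], []
    for r in df.itertuples(index=False):
        if r.action == "add":
            adds.append((float(r.x_um), float(r.y_um)))
        elif r.action == "remove":
            removals.append(int(r.label))
        else:
            raise ValueError(f"unknown edit action {r.action!r} (expected add|remove)")
    return adds, removals


# ----------------------------------------------------------------- images ---

def write_image(path: str | Path, image: Micrograph) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.rgb, photometric="rgb")
    else:
        iio.imwrite(path, image.rgb)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps({"pixel_size_um": image.pixel_size, "id": image.id},
                   indent=2, sort_keys=True) + "\n"
    )


def read_image(
    path: str | Path, pixel_size: float | None = None, id: str | None = None
) -> Micrograph:
    """Read a TIFF/PNG micrograph; calibration from argument or JSON sidecar."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        rgb = tifffile.imread(path)
    else:
        rgb = iio.imread(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    if pixel_size is None:
        pixel_size = meta.get("pixel_size_um")
    if pixel_size is None:
        raise ValueError(
            f"no pixel size for {path.name}: pass --pixel-size-um or provide "
            f"a JSON sidecar with pixel_size_um"
        )
    return Micrograph(rgb=rgb, pixel_size=float(pixel_size),
                      id=id or meta.get("id") or path.stem)


# ----------------------------------------------------------------- fields ---

def export_field(path: str | Path, field: RelativePositionField) -> None:
    """Write d1/d2/f as 32-bit TIFF planes plus an 8-bit sublayer plane.

    A JSON sidecar records grid spacing, origin and label semantics.
    """
    path = Path(path)
    planes = np.stack([
        field.d1.astype(np.float32),
        field.d2.astype(np.float32),
        np.nan_to_num(field.f, nan=-1.0).astype(np.float32),
    ])
    tifffile.imwrite(path, planes, photometric="minisblack")
    tifffile.imwrite(path, field.sublayer, photometric="minisblack", append=True)
    minx, miny = field.origin
    nr, nc = field.shape
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "spacing_um": field.spacing,
        "origin_um": [minx, miny],
        "bounds_um": [minx, miny, minx + nc * field.spacing, miny + nr * field.spacing],
        "planes": ["d1_um", "d2_um", "f", "sublayer"],
        "sublayer_labels": {"0": "background", "1": "outer", "2": "middle", "3": "inner"},
    }, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------- reports ---

def _none_if_nan(x: float) -> float | None:
    return None if (x is None or (isinstance(x, float) and math.isnan(x))) else float(x)


def micrograph_result_to_dict(r: MicrographResult) -> dict:
    return {
        "micrograph_id": r.micrograph_id,
        "sample_id": r.sample_id,
        "counts": {
            "q_inner": r.counts.q_inner,
            "q_middle": r.counts.q_middle,
            "q_outer": r.counts.q_outer,
            "q_excluded": r.counts.q_excluded,
        },
        "areas_mm2": {
            "inner": r.areas.area_inner,
            "middle": r.areas.area_middle,
            "outer": r.areas.area_outer,
            "total": r.areas.area_total,
        },
        "qa_inner": r.qa_inner,
        "qa_middle": r.qa_middle,
        "qa_outer": r.qa_outer,
        "qa_mean": r.qa_mean,
        "f_mean": _none_if_nan(r.f_mean),
        "thickness_um": r.thickness_um,
    }


def micrograph_result_from_dict(d: dict) -> MicrographResult:
    counts = LayerCounts(
        q_inner=d["counts"]["q_inner"],
        q_middle=d["counts"]["q_middle"],
        q_outer=d["counts"]["q_outer"],
        q_excluded=d["counts"]["q_excluded"],
    )
    areas = SublayerAreas(
        area_inner=d["areas_mm2"]["inner"],
        area_middle=d["areas_mm2"]["middle"],
        area_outer=d["areas_mm2"]["outer"],
    )
    f_mean = d.get("f_mean")
    return MicrographResult(
        micrograph_id=d["micrograph_id"], sample_id=d["sample_id"],
        counts=counts, areas=areas,
        qa_inner=d["qa_inner"], qa_middle=d["qa_middle"], qa_outer=d["qa_outer"],
        qa_mean=d["qa_mean"],
        f_mean=math.nan if f_mean is None else float(f_mean),
        thickness_um=d["thickness_um"],
    )


def write_report_json(path: str | Path, report: StereologyReport) -> None:
    """Nested {group -> sample -> micrograph} report with group summaries."""
    nested: dict = {}
    for _, row in report.micrographs.iterrows():
        g = nested.setdefault(row["group"], {"samples": {}})
        s = g["samples"].setdefault(row["sample_id"], {"micrographs": {}})
        s["micrographs"][row["micrograph_id"]] = {
            k: _none_if_nan(row[k]) if isinstance(row[k], float) else row[k]
            for k in row.index
            if k not in ("micrograph_id", "sample_id", "group")
        }
    for _, row in report.samples.iterrows():
        s = nested[row["group"]]["samples"][row["sample_id"]]
        s["summary"] = {
            k: _none_if_nan(row[k])
            for k in row.index
            if k not in ("group", "sample_id", "n_micrographs")
        }
        s["summary"]["n_micrographs"] = int(row["n_micrographs"])
    for _, row in report.groups.iterrows():
        nested[row["group"]]["summary"] = {
            k: (_none_if_nan(row[k]) if k != "n_samples" else int(row[k]))
            for k in row.index
            if k != "group"
        }
    Path(path).write_text(json.dumps(nested, indent=2, sort_keys=True) + "\n")


def read_report_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_report_csv(path: str | Path, report: StereologyReport) -> None:
    """Flat CSV: one row per micrograph plus summary rows per sample/group."""
    cols = ["level", "group", "sample_id", "micrograph_id",
            "qa_inner", "qa_middle", "qa_outer", "qa_mean",
            "f_mean", "thickness_um", "n"]
    rows = []
    for _, r in report.micrographs.iterrows():
        rows.append({"level": "micrograph", "group": r["group"],
                     "sample_id": r["sample_id"], "micrograph_id": r["micrograph_id"],
                     **{k: r[k] for k in cols[4:-1]}, "n": 1})
    for _, r in report.samples.iterrows():
        rows.append({"level": "sample", "group": r["group"],
                     "sample_id": r["sample_id"], "micrograph_id": "",
                     **{k: r[k] for k in cols[4:-1]}, "n": int(r["n_micrographs"])})
    for _, r in report.groups.iterrows():
        rows.append({"level": "group", "group": r["group"], "sample_id": "",
                     "micrograph_id": "",
                     **{k: r[f"{k}_mean"] for k in cols[4:-1]},
                     "n": int(r["n_samples"])})
        rows.append({"level": "group_sem", "group": r["group"], "sample_id": "",
                     "micrograph_id": "",
                     **{k: r[f"{k}_sem"] for k in cols[4:-1]},
                     "n": int(r["n_samples"])})
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.6f")
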