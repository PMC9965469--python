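"""Per-layer 2D nuclei-profile densities and their hierarchical aggregation.

Counts of nucleus profiles, assigned by their decisive points to the three
virtual sublayers, are converted to areal densities Q_A = Q / A (mm⁻²).  The
overall wall density pools counts over the total wall area (ΣQ / ΣA), which
differs from the mean of the three layer densities whenever layer areas are
unequal.  The mean relative radial position f of the included profiles
summarizes how deep into the wall the cells sit (0 = outer border, 1 = lumen).

Micrographs aggregate to samples (animals) by averaging, samples to
experimental groups by mean ± SEM across samples, which avoids
pseudo-replication from multiple fields per animal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .nuclei_detection import NucleusProfile
from .wall_geometry import RelativePositionField, Sublayer, SublayerAreas

__all__ = [
    "LayerCounts",
    "MicrographResult",
    "StereologyReport",
    "assign_and_count",
    "compute_qa",
    "mean_relative_distance",
    "aggregate",
]

#: metric columns carried through aggregation
METRICS = ["qa_inner", "qa_middle", "qa_outer", "qa_mean", "f_mean", "thickness_um"]


class FrameMismatchError(ValueError):
    """Profiles and field live in different coordinate frames."""


@dataclass(frozen=True)
class LayerCounts:
    """Nucleus-profile counts per virtual sublayer.

    ``q_excluded`` counts profiles whose decisive point fell outside the
    wall; the four fields always sum to the number of submitted profiles.
    """

    q_inner: int
    q_middle: int
    q_outer: int
    q_excluded: int

    @property
    def q_included(self) -> int:
        return self.q_inner + self.q_middle + self.q_outer

    @property
    def total(self) -> int:
        return self.q_included + self.q_excluded


def assign_and_count(
    profiles: Sequence[NucleusProfile], field: RelativePositionField
) -> LayerCounts:
    """Assign each profile by its decisive point's sublayer cell and count.

    Profiles whose decisive point lands outside the wall mask (or off the
    grid) are excluded, never dropped silently from the bookkeeping.
    """
    if not profiles:
        return LayerCounts(0, 0, 0, 0)
    pts = np.array([p.decisive_point for p in profiles], dtype=float)
    _, _, ok = field.cell_index(pts)
    if not ok.any():
        raise FrameMismatchError(
            "no decisive point lies within the field bounds; "
            "profiles and field appear to be in different frames"
        )
    labels = field.sublayer_at(pts)
    counts = np.bincount(labels, minlength=4)
    return LayerCounts(
        q_inner=int(counts[Sublayer.INNER]),
        q_middle=int(counts[Sublayer.MIDDLE]),
        q_outer=int(counts[Sublayer.OUTER]),
        q_excluded=int(counts[Sublayer.BACKGROUND]),
    )


def compute_qa(
    counts: LayerCounts, areas: SublayerAreas
) -> tuple[float, float, float, float]:
    """Layer densities Q_A = Q / A (mm⁻²) and the pooled wall density.

    The pooled density relates the summed included counts to the total wall
    area; it is *not* the arithmetic mean of the three layer densities.
    """
    for a in (areas.area_inner, areas.area_middle, areas.area_outer):
        if a <= 0:
            raise ValueError("all sublayer areas must be positive")
    return (
        counts.q_inner / areas.area_inner,
        counts.q_middle / areas.area_middle,
        counts.q_outer / areas.area_outer,
        counts.q_included / areas.area_total,
    )


def mean_relative_distance(
    profiles: Sequence[NucleusProfile], field: RelativePositionField
) -> float:
    """Mean relative position f of included decisive points.

    Returns NaN (a missing value, never 0) when no profile is included.
    """
    if not profiles:
        return math.nan
    pts = np.array([p.decisive_point for p in profiles], dtype=float)
    fv = field.f_at(pts)
    fv = fv[~np.isnan(fv)]
    return float(fv.mean()) if fv.size else math.nan


@dataclass(frozen=True)
class MicrographResult:
    """All per-micrograph quantities entering the report."""

    micrograph_id: str
    sample_id: str
    counts: LayerCounts
    areas: SublayerAreas
    qa_inner: float
    qa_middle: float
    qa_outer: float
    qa_mean: float
    f_mean: float
    thickness_um: float

    @classmethod
    def from_measurements(
        cls,
        micrograph_id: str,
        sample_id: str,
        counts: LayerCounts,
        areas: SublayerAreas,
        f_mean: float,
        thickness_um: float,
    ) -> "MicrographResult":
        qa_i, qa_m, qa_o, qa_all = compute_qa(counts, areas)
        return cls(
            micrograph_id=micrograph_id, sample_id=sample_id,
            counts=counts, areas=areas,
            qa_inner=qa_i, qa_middle=qa_m, qa_outer=qa_o, qa_mean=qa_all,
            f_mean=f_mean, thickness_um=thickness_um,
        )


@dataclass(frozen=True)
class StereologyReport:
    """Micrograph-, sample- and group-level tables of the wall parameters.

    ``micrographs`` has one row per field of view; ``samples`` averages the
    fields of each sample; ``groups`` reports mean and SEM across samples
    (SEM = sd / √n with n−1 denominator, missing when a group has a single
    sample) plus the sample count n.
    """

    micrographs: pd.DataFrame
    samples: pd.DataFrame
    groups: pd.DataFrame


def aggregate(
    results: Sequence[MicrographResult], grouping: Mapping[str, str]
) -> StereologyReport:
    """Aggregate micrograph results: micrograph → sample → group.

    ``grouping`` maps sample id → group label and must cover every sample.
    Missing per-micrograph values (e.g. f_mean with zero included profiles)
    propagate as missing and are omitted from means, never imputed as 0.
    """
    if not results:
        raise ValueError("no micrograph results to aggregate")
    missing = sorted({r.sample_id for r in results} - set(grouping))
    if missing:
        raise ValueError(f"samples missing from grouping: {', '.join(missing)}")

    rows = []
    for r in results:
        rows.append(
            {
                "micrograph_id": r.micrograph_id,
                "sample_id": r.sample_id,
                "group": grouping[r.sample_id],
                "q_inner": r.counts.q_inner,
                "q_middle": r.counts.q_middle,
                "q_outer": r.counts.q_outer,
                "q_excluded": r.counts.q_excluded,
                "area_inner_mm2": r.areas.area_inner,
                "area_middle_mm2": r.areas.area_middle,
                "area_outer_mm2": r.areas.area_outer,
                "qa_inner": r.qa_inner,
                "qa_middle": r.qa_middle,
                "qa_outer": r.qa_outer,
                "qa_mean": r.qa_mean,
                "f_mean": r.f_mean,
                "thickness_um": r.thickness_um,
            }
        )
    mic = pd.DataFrame(rows).sort_values(
        ["group", "sample_id", "micrograph_id"], kind="stable"
    ).reset_index(drop=True)

    samples = (
        mic.groupby(["group", "sample_id"], sort=True)[METRICS]
        .mean()
        .reset_index()
    )
    samples["n_micrographs"] = (
        mic.groupby(["group", "sample_id"], sort=True)
        .size()
        .reset_index(drop=True)
    )

    def _group_stats(g: pd.DataFrame) -> pd.Series:
        out: dict[str, float] = {}
        for m in METRICS:
            vals = g[m].dropna()
            n = len(vals)
            out[f"{m}_mean"] = vals.mean() if n else math.nan
            out[f"{m}_sem"] = (
                vals.std(ddof=1) / math.sqrt(n) if n > 1 else math.nan
            )
        out["n_samples"] = float(len(g))
        return pd.Series(out)

    groups = (
        samples.groupby("group", sort=True)
        .apply(_group_stats, include_groups=False)
        .reset_index()
    )
    groups["n_samples"] = groups["n_samples"].astype(int)
    return StereologyReport(micrographs=mic, samples=samples, groups=groups)
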