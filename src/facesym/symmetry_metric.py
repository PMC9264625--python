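"""Thresholded degree-of-symmetry scoring.

A vertex is *symmetric* when its distance to the registered mirrored shell
is strictly below the threshold (default exactly 1.0 mm).  The degree of
symmetry is the percentage of surface that is symmetric — area-weighted by
default (barycentric vertex areas, tessellation-robust), with a plain
vertex-count variant available.  The whole-face degree is by construction
the area-weighted combination of the regional degrees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .face_regions import REGION_NAMES, RegionLabeling
from .mirror_align import DistanceMap

__all__ = [
    "SymmetryReport",
    "classify_vertices",
    "degree_of_symmetry",
    "cohort_report",
    "reports_to_frame",
]

DEFAULT_THRESHOLD = 1.0  # mm; strictly-below counts as symmetric


@dataclass
class SymmetryReport:
    """Whole-face and per-region degree of symmetry for one subject.

    Degrees are percentages in [0, 100]; a region absent from the mesh is
    reported as NaN.  ``region_areas`` (mm^2) and ``region_vertex_counts``
    carry the denominators.
    """

    subject_id: str
    whole_face: float
    regional: dict
    threshold: float
    weighted: bool
    region_areas: dict = field(default_factory=dict)
    region_vertex_counts: dict = field(default_factory=dict)
    mean_distance: float = float("nan")  # diagnostic only
    rms_distance: float = float("nan")   # diagnostic only

    def as_row(self) -> dict:
        row = {"subject": self.subject_id, "whole_face": self.whole_face}
        row.update(self.regional)
        return row


def classify_vertices(distmap: DistanceMap,
                      threshold: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """Binary symmetric flag per vertex: distance strictly below threshold.

    A distance exactly equal to the threshold counts as *asymmetric*
    ("below 1 mm" is strict).
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if not np.isfinite(distmap.distances).all():
        raise ValueError("distances must be finite")
    return distmap.distances < threshold


def degree_of_symmetry(distmap: DistanceMap,
                       labeling: RegionLabeling | None = None,
                       threshold: float = DEFAULT_THRESHOLD,
                       weighted: bool = True,
                       subject_id: str = "") -> SymmetryReport:
    """Percentage of symmetric surface, overall and per region.

    ``weighted=True`` (default) weights each vertex by its barycentric area
    share; ``weighted=False`` counts vertices.  If ``labeling`` is given its
    length must match the distance map; regions with zero total weight are
    reported as NaN with a warning.
    """
    flags = classify_vertices(distmap, threshold)
    w = distmap.weights if weighted else np.ones_like(distmap.distances)
    total = w.sum()
    if total <= 0:
        raise ValueError("total weight is zero")
    whole = 100.0 * float(w[flags].sum() / total)

    regional: dict = {}
    areas: dict = {}
    counts: dict = {}
    if labeling is not None:
        if len(labeling.labels) != len(distmap.distances):
            raise ValueError("labeling length does not match distance map")
        for rid, name in REGION_NAMES.items():
            mask = labeling.labels == rid
            counts[name] = int(mask.sum())
            areas[name] = float(distmap.weights[mask].sum())
            denom = w[mask].sum()
            if denom <= 0:
                warnings.warn(f"region {name} has zero total weight; degree is NaN",
                              stacklevel=2)
                regional[name] = float("nan")
            else:
                regional[name] = 100.0 * float(w[mask & flags].sum() / denom)

    return SymmetryReport(
        subject_id=subject_id,
        whole_face=whole,
        regional=regional,
        threshold=threshold,
        weighted=weighted,
        region_areas=areas,
        region_vertex_counts=counts,
        mean_distance=float(np.average(distmap.distances, weights=w)),
        rms_distance=float(np.sqrt(np.average(distmap.distances ** 2, weights=w))),
    )


def reports_to_frame(reports) -> pd.DataFrame:
    """One row per subject: whole_face plus the seven regional degrees."""
    return pd.DataFrame([r.as_row() for r in reports]).set_index("subject")


def cohort_report(reports, group_labels) -> pd.DataFrame:
    """Group-wise mean +- SD of each degree, one row per facial region.

    ``group_labels`` maps each report (in order) to a group name.  SD uses
    ddof=1; a single-subject group reports SD = 0 and is flagged by its
    ``n`` column.  Returns a frame with MultiIndex columns
    (group, {mean, sd, n, formatted}).
    """
    frame = reports_to_frame(reports)
    groups = pd.Series(list(group_labels), index=frame.index, name="group")
    out = {}
    for gname, sub in frame.groupby(groups, sort=True):
        mean = sub.mean()
        sd = sub.std(ddof=1).fillna(0.0) if len(sub) > 1 else mean * 0.0
        out[(gname, "mean")] = mean
        out[(gname, "sd")] = sd
        out[(gname, "n")] = pd.Series(len(sub), index=mean.index)
        out[(gname, "formatted")] = pd.Series(
            [f"{m:.2f} ± {s:.2f}" for m, s in zip(mean, sd)], index=mean.index
        )
    result = pd.DataFrame(out)
    result.index.name = "region"
    return result
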