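"""Lengths, areas, projected joint angles, and repeat/longitudinal stats.

The measurement layer is deliberately simple geometry:

* **Lengths** are Euclidean (straight-line) distances between marker
  centroids, in mm.
* **Areas** of a marker quadrilateral (vertices in perimeter order)
  are the sum of the two triangle areas — each one half the magnitude
  of the cross product of its edge vectors — computed for both
  diagonals and averaged.  For a planar quad the two triangulations
  agree; for a warped one the swap-average is a symmetric compromise.
* **Humeral orientation** is reported as three projected angles of
  humeral axes against scapular axes: abduction/adduction in the
  coronal plane (normal = scapular anterior) between the
  superior-inferior axes, internal/external rotation in the axial
  plane (normal = scapular superior) between the medial-lateral axes,
  and flexion/extension in the sagittal plane (normal = scapular
  lateral) between the superior-inferior axes.  Unsigned magnitudes
  are the tabulated quantity; a signed variant orients the angle by
  the plane normal.

Statistics mirror the study protocols: *precision* of a repeat-scan
series is the mean of the per-measurement sample standard deviations
(n-1 denominator) within each measurement class, and *longitudinal
change* is last-minus-baseline per measurement, summarized as the
class mean +/- sample SD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import IllConditionedProjectionError, MarkerMorphError, StudyValidationError
from .frames import AnatomicalFrame
from .volume_io import MeasurementDefinitions

__all__ = [
    "MeasurementRecord",
    "PrecisionSummary",
    "LongitudinalSummary",
    "length",
    "quad_area",
    "projected_angle",
    "humeral_orientation",
    "measure_scan",
    "precision_summary",
    "longitudinal_summary",
]

ANGLE_NAMES = ("extension", "external_rotation", "abduction")

#: relative norm floor below which a projection onto a plane is
#: considered degenerate (vector ~ parallel to the plane normal)
PROJECTION_NORM_FLOOR = 1e-6


def length(p: Sequence[float], q: Sequence[float]) -> float:
    """Euclidean distance (mm) between two marker positions."""
    return float(np.linalg.norm(np.asarray(p, float) - np.asarray(q, float)))


def _tri_area(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    return 0.5 * float(np.linalg.norm(np.cross(b - a, c - a)))


def quad_area(
    p1: Sequence[float],
    p2: Sequence[float],
    p3: Sequence[float],
    p4: Sequence[float],
) -> float:
    """Swap-averaged triangulated area (mm^2) of a marker quadrilateral.

    Vertices must be in perimeter order p1->p2->p3->p4.  The quad is
    split along each diagonal in turn and the two triangulated areas
    are averaged:

    ``area = (tri(p1,p2,p3) + tri(p1,p3,p4) + tri(p2,p3,p4) + tri(p2,p4,p1)) / 2``

    Degenerate (collinear/coincident) inputs return 0.
    """
    a, b, c, d = (np.asarray(p, float).reshape(3) for p in (p1, p2, p3, p4))
    area_first = _tri_area(a, b, c) + _tri_area(a, c, d)
    area_second = _tri_area(b, c, d) + _tri_area(b, d, a)
    return 0.5 * (area_first + area_second)


def projected_angle(
    u: Sequence[float],
    v: Sequence[float],
    plane_normal: Sequence[float],
    signed: bool = False,
) -> float:
    """Angle (degrees) between two vectors after projection onto a plane.

    Both vectors are projected onto the plane with unit normal
    ``plane_normal``; the unsigned angle lies in [0, 180].  With
    ``signed=True`` the angle is oriented by the normal (right-hand
    rule from ``u`` to ``v``) and lies in (-180, 180].

    Raises :class:`IllConditionedProjectionError` when a projection
    retains less than ``PROJECTION_NORM_FLOOR`` of its vector's norm
    (the vector is essentially parallel to the normal, a gimbal-like
    condition in which the projected angle is meaningless).
    """
    u = np.asarray(u, float).reshape(3)
    v = np.asarray(v, float).reshape(3)
    n = np.asarray(plane_normal, float).reshape(3)
    n = n / np.linalg.norm(n)
    proj = []
    for vec, name in ((u, "first"), (v, "second")):
        norm = np.linalg.norm(vec)
        if norm == 0:
            raise IllConditionedProjectionError(f"{name} vector is zero")
        p = vec - (vec @ n) * n
        if np.linalg.norm(p) < PROJECTION_NORM_FLOOR * norm:
            raise IllConditionedProjectionError(
                f"{name} vector is (numerically) normal to the projection "
                f"plane; projected angle is undefined"
            )
        proj.append(p)
    pu, pv = proj
    cos = float(pu @ pv)
    cross = np.cross(pu, pv)
    sin = float(np.linalg.norm(cross))
    ang = math.degrees(math.atan2(sin, cos))
    if signed:
        if float(cross @ n) < 0:
            ang = -ang
    return ang


def humeral_orientation(
    scapula: AnatomicalFrame,
    humerus: AnatomicalFrame,
    signed: bool = False,
) -> dict[str, float]:
    """The three projected humeral orientation angles (degrees).

    Returns ``{"extension": ..., "external_rotation": ..., "abduction": ...}``
    as unsigned magnitudes by default (the tabulated convention, where
    the direction word is part of the row label).  With ``signed=True``
    each angle is oriented by its projection-plane normal (scapular
    lateral, superior, anterior respectively).
    """
    return {
        "extension": projected_angle(
            humerus.axis_superior, scapula.axis_superior,
            scapula.axis_lateral, signed=signed,
        ),
        "external_rotation": projected_angle(
            humerus.axis_lateral, scapula.axis_lateral,
            scapula.axis_superior, signed=signed,
        ),
        "abduction": projected_angle(
            humerus.axis_superior, scapula.axis_superior,
            scapula.axis_anterior, signed=signed,
        ),
    }


# ---------------------------------------------------------------------------
# Per-scan measurement record
# ---------------------------------------------------------------------------

@dataclass
class MeasurementRecord:
    """All defined measurements for one scan.

    ``lengths`` (mm), ``areas`` (mm^2) and ``angles`` (degrees) are
    name->value maps; ``missing`` maps measurement names that could not
    be computed to the marker labels that were absent.
    """

    scan_id: str
    timepoint_weeks: float
    lengths: dict[str, float] = field(default_factory=dict)
    areas: dict[str, float] = field(default_factory=dict)
    angles: dict[str, float] = field(default_factory=dict)
    missing: dict[str, list[str]] = field(default_factory=dict)

    def values_by_class(self, cls: str) -> dict[str, float]:
        if cls not in ("lengths", "areas", "angles"):
            raise MarkerMorphError(f"unknown measurement class {cls!r}")
        return getattr(self, cls)

    def to_display(self) -> dict[str, dict[str, float]]:
        """Round for per-scan tables: lengths/areas 1 d.p., angles to
        the nearest degree.  Internal values stay unrounded."""
        return {
            "lengths": {k: round(v, 1) for k, v in self.lengths.items()},
            "areas": {k: round(v, 1) for k, v in self.areas.items()},
            "angles": {k: float(round(v)) for k, v in self.angles.items()},
        }


def measure_scan(
    positions: Mapping[str, np.ndarray],
    definitions: MeasurementDefinitions,
    scapula: AnatomicalFrame | None = None,
    humerus: AnatomicalFrame | None = None,
    scan_id: str = "",
    timepoint_weeks: float = 0.0,
) -> MeasurementRecord:
    """Evaluate every defined length/area (and the orientation angles,
    when both frames are given) from a label->position map.

    A measurement touching a missing marker label is recorded in
    ``missing`` rather than aborting the rest.
    """
    record = MeasurementRecord(scan_id=scan_id, timepoint_weeks=timepoint_weeks)
    for pair in definitions.lengths:
        name = "".join(pair)
        absent = [lbl for lbl in pair if lbl not in positions]
        if absent:
            record.missing[name] = absent
        else:
            record.lengths[name] = length(positions[pair[0]], positions[pair[1]])
    for quad in definitions.areas:
        name = "".join(quad)
        absent = [lbl for lbl in quad if lbl not in positions]
        if absent:
            record.missing[name] = absent
        else:
            record.areas[name] = quad_area(*(positions[lbl] for lbl in quad))
    if scapula is not None and humerus is not None:
        record.angles = humeral_orientation(scapula, humerus)
    return record


# ---------------------------------------------------------------------------
# Repeat-scan precision
# ---------------------------------------------------------------------------

@dataclass
class PrecisionSummary:
    """Repeat-scan repeatability of each measurement and class.

    ``table`` has one row per measurement (index) with columns
    ``class``, ``mean`` and ``sd`` (sample SD, n-1 denominator);
    ``pooled`` maps each class to its precision, the unweighted mean
    of the per-measurement SDs.
    """

    table: pd.DataFrame
    pooled: dict[str, float]
    n_scans: int

    def to_json_dict(self) -> dict:
        return {
            "n_scans": self.n_scans,
            "per_measurement": {
                name: {
                    "class": row["class"],
                    "mean": float(row["mean"]),
                    "sd": float(row["sd"]),
                }
                for name, row in self.table.iterrows()
            },
            "pooled_precision": {k: float(v) for k, v in self.pooled.items()},
        }


def _check_consistent(records: Sequence[MeasurementRecord]) -> None:
    first = records[0]
    for rec in records[1:]:
        for cls in ("lengths", "areas", "angles"):
            if set(rec.values_by_class(cls)) != set(first.values_by_class(cls)):
                raise StudyValidationError(
                    f"scan {rec.scan_id!r} has a different set of {cls} than "
                    f"scan {first.scan_id!r}"
                )


def precision_summary(records: Sequence[MeasurementRecord]) -> PrecisionSummary:
    """Mean and sample SD of each measurement over repeat scans, and
    the class-pooled precision (mean of SDs).

    Requires >=2 records with identical measurement sets.
    """
    if len(records) < 2:
        raise MarkerMorphError(
            f"precision needs >=2 repeat records, got {len(records)}"
        )
    _check_consistent(records)
    rows = []
    for cls in ("lengths", "areas", "angles"):
        for name in records[0].values_by_class(cls):
            vals = np.array([r.values_by_class(cls)[name] for r in records])
            rows.append(
                {
                    "measurement": name,
                    "class": cls,
                    "mean": float(vals.mean()),
                    "sd": float(vals.std(ddof=1)),
                }
            )
    table = pd.DataFrame(rows).set_index("measurement")
    pooled = {
        cls: float(grp["sd"].mean())
        for cls, grp in table.groupby("class", sort=False)
    }
    return PrecisionSummary(table=table, pooled=pooled, n_scans=len(records))


def pooled_precision(sds: Iterable[float]) -> float:
    """Precision of a measurement class: the unweighted mean of the
    per-measurement repeat-scan SDs."""
    sds = list(sds)
    if not sds:
        raise MarkerMorphError("no SDs supplied")
    return float(np.mean(sds))


# ---------------------------------------------------------------------------
# Longitudinal change
# ---------------------------------------------------------------------------

@dataclass
class LongitudinalSummary:
    """Per-measurement change (final - baseline) and class statistics.

    ``changes`` maps measurement name -> change; ``mean`` and ``sd``
    are the unweighted mean and sample SD of those changes;
    ``baseline_weeks``/``final_weeks`` record the compared timepoints.
    """

    measurement_class: str
    changes: dict[str, float]
    mean: float
    sd: float
    baseline_weeks: float
    final_weeks: float

    def display(self) -> tuple[float, float]:
        """(mean, sd) rounded to the nearest unit, the summary
        reporting convention."""
        return float(round(self.mean)), float(round(self.sd))

    def to_json_dict(self) -> dict:
        return {
            "class": self.measurement_class,
            "baseline_weeks": self.baseline_weeks,
            "final_weeks": self.final_weeks,
            "changes": {k: float(v) for k, v in self.changes.items()},
            "mean_change": float(self.mean),
            "sd_change": float(self.sd),
        }


def longitudinal_summary(
    records: Sequence[MeasurementRecord],
    measurement_class: Literal["lengths", "areas", "angles"] = "lengths",
    names: Sequence[str] | None = None,
) -> LongitudinalSummary:
    """Last-minus-baseline change of each measurement in a class.

    ``records`` must cover >=2 timepoints and are compared after
    sorting by ``timepoint_weeks`` (baseline = earliest).  ``names``
    restricts the summary to a subset of measurements (e.g. only the
    medio-lateral tendon lengths).
    """
    if len(records) < 2:
        raise MarkerMorphError(
            f"longitudinal change needs >=2 timepoints, got {len(records)}"
        )
    _check_consistent(records)
    ordered = sorted(records, key=lambda r: r.timepoint_weeks)
    baseline, final = ordered[0], ordered[-1]
    available = baseline.values_by_class(measurement_class)
    if names is None:
        names = list(available)
    else:
        unknown = [n for n in names if n not in available]
        if unknown:
            raise StudyValidationError(
                f"unknown {measurement_class} measurement(s): {', '.join(unknown)}"
            )
    if not names:
        raise MarkerMorphError(f"no {measurement_class} measurements to summarize")
    changes = {
        n: final.values_by_class(measurement_class)[n]
        - baseline.values_by_class(measurement_class)[n]
        for n in names
    }
    vals = np.array(list(changes.values()), float)
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return LongitudinalSummary(
        measurement_class=measurement_class,
        changes=changes,
        mean=float(vals.mean()),
        sd=sd,
        baseline_weeks=baseline.timepoint_weeks,
        final_weeks=final.timepoint_weeks,
    )
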