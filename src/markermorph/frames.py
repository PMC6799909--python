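"""Anatomical coordinate frames for the scapula and humerus.

Frames are right-handed orthonormal triads (lateral, anterior,
superior) built from CT-identifiable bony landmarks:

* **Scapula** — angulus acromialis (``AA``), trigonum spinae (``TS``),
  angulus inferior (``AI``).  Lateral is the unit vector TS->AA;
  superior is the component of AI->AA orthogonal to lateral (in the
  scapular plane, pointing toward the acromion); anterior completes
  the right-handed triad (superior x lateral).  Origin at AA.
* **Humerus** — humeral head center (``HH``, given directly or as the
  least-squares sphere center of >=5 head-surface points ``HS1``...),
  medial and lateral epicondyles (``ME``, ``LE``).  Superior is the
  unit vector from the elbow midpoint (ME+LE)/2 toward HH; lateral is
  the component of ME->LE orthogonal to superior; anterior completes
  the triad.  Origin at HH.

Because AA, AI and LE are lateral/superior on both shoulders, the
lateral and superior axes are anatomically true for either side; the
anterior axis is the frame's third right-handed axis and points
ventrally on right shoulders and dorsally on left ones.  Both frames
flip together, so relative (humerus-vs-scapula) angle magnitudes are
side-agnostic; the study ``side`` flag is used only to put direction
words (flexion vs extension...) on signed angles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import DegenerateGeometryError, StudyValidationError
from .volume_io import LandmarkSet

__all__ = [
    "AnatomicalFrame",
    "scapular_frame",
    "humeral_frame",
    "fit_sphere_center",
]

#: triangles whose area falls below this are treated as collinear
MIN_TRIANGLE_AREA_MM2 = 1.0

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class AnatomicalFrame:
    """Origin plus right-handed orthonormal anatomical axes.

    Invariants (checked on construction): unit axes, pairwise
    orthogonal, and ``lateral x anterior == superior``, all to 1e-9.
    """

    origin: np.ndarray
    axis_lateral: np.ndarray
    axis_anterior: np.ndarray
    axis_superior: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "axis_lateral", "axis_anterior", "axis_superior"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float).reshape(3))
        axes = (self.axis_lateral, self.axis_anterior, self.axis_superior)
        for ax in axes:
            if abs(np.linalg.norm(ax) - 1.0) > _ORTHO_TOL:
                raise DegenerateGeometryError("frame axis is not unit length")
        for i in range(3):
            for j in range(i + 1, 3):
                if abs(float(axes[i] @ axes[j])) > _ORTHO_TOL:
                    raise DegenerateGeometryError("frame axes are not orthogonal")
        if np.max(np.abs(np.cross(self.axis_lateral, self.axis_anterior)
                         - self.axis_superior)) > _ORTHO_TOL:
            raise DegenerateGeometryError(
                "frame is not right-handed (lateral x anterior != superior)"
            )

    @property
    def rotation(self) -> np.ndarray:
        """3x3 matrix with columns (lateral, anterior, superior): maps
        frame coordinates to world coordinates."""
        return np.column_stack(
            (self.axis_lateral, self.axis_anterior, self.axis_superior)
        )


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError(f"{what}: zero-length direction")
    return v / n


def _require(group: Mapping[str, np.ndarray], names: Sequence[str], which: str) -> list[np.ndarray]:
    missing = [n for n in names if n not in group]
    if missing:
        raise StudyValidationError(
            f"missing {which} landmark(s): {', '.join(missing)}"
        )
    return [np.asarray(group[n], float) for n in names]


def _check_triangle(p: np.ndarray, q: np.ndarray, r: np.ndarray, which: str) -> None:
    area = 0.5 * np.linalg.norm(np.cross(q - p, r - p))
    if area < MIN_TRIANGLE_AREA_MM2:
        raise DegenerateGeometryError(
            f"{which} landmarks are (near-)collinear: triangle area "
            f"{area:.3g} mm^2 < {MIN_TRIANGLE_AREA_MM2} mm^2"
        )


def scapular_frame(landmarks: LandmarkSet) -> AnatomicalFrame:
    """Scapular frame from the AA/TS/AI triad (origin at AA)."""
    aa, ts, ai = _require(landmarks.scapula, ("AA", "TS", "AI"), "scapular")
    _check_triangle(aa, ts, ai, "scapular")
    lateral = _unit(aa - ts, "scapular lateral (TS->AA)")
    sup_raw = aa - ai
    sup_raw = sup_raw - (sup_raw @ lateral) * lateral
    superior = _unit(sup_raw, "scapular superior (AI->AA in-plane)")
    anterior = np.cross(superior, lateral)
    return AnatomicalFrame(aa, lateral, anterior, superior)


def humeral_frame(landmarks: LandmarkSet) -> AnatomicalFrame:
    """Humeral frame from HH (or a sphere fit of HS* points), ME, LE."""
    group = landmarks.humerus
    if "HH" in group:
        hh = np.asarray(group["HH"], float)
    else:
        surface = sorted(k for k in group if k.startswith("HS"))
        if len(surface) < 5:
            raise StudyValidationError(
                "missing humeral landmark(s): HH (or >=5 head-surface points HS*)"
            )
        hh = fit_sphere_center(np.array([group[k] for k in surface]))
    me, le = _require(group, ("ME", "LE"), "humeral")
    _check_triangle(hh, me, le, "humeral")
    mid = 0.5 * (me + le)
    superior = _unit(hh - mid, "humeral superior (elbow->head)")
    lat_raw = le - me
    lat_raw = lat_raw - (lat_raw @ superior) * superior
    lateral = _unit(lat_raw, "humeral lateral (ME->LE orthogonalized)")
    anterior = np.cross(superior, lateral)
    return AnatomicalFrame(hh, lateral, anterior, superior)


def fit_sphere_center(points: np.ndarray) -> np.ndarray:
    """Least-squares (algebraic) sphere center through >=5 points.

    Solves the linear system obtained by expanding
    ``|p - c|^2 = r^2`` for each point; exact for noiseless spherical
    data, least-squares otherwise.
    """
    pts = np.asarray(points, float).reshape(-1, 3)
    if len(pts) < 5:
        raise StudyValidationError(
            f"sphere fit needs >=5 surface points, got {len(pts)}"
        )
    a = np.hstack([2 * pts, np.ones((len(pts), 1))])
    b = (pts ** 2).sum(axis=1)
    sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < 4:
        raise DegenerateGeometryError(
            "head-surface points are degenerate (coplanar/collinear); "
            "sphere center is not identifiable"
        )
    return sol[:3]
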