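"""Rigid-transform algebra, point-set registration and virtual markers.

The longitudinal protocol hinges on two rigid-body facts: follow-up
scans can be mapped into the reference (day-of-surgery) world frame by
the least-squares rigid transform between scapular landmarks, and
software-only "virtual" markers can be carried from the reference scan
into any follow-up by the rigid transform between the humeral bone
markers observed in both.  Both reduce to the Kabsch problem: the
proper rotation (and translation) minimizing summed squared residuals
between matched point sets.  The closed-form SVD solution is used,
with the standard smallest-singular-vector sign flip so a reflection
is never returned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .errors import (
    DegenerateGeometryError,
    InsufficientMarkersError,
    StudyValidationError,
)
from .volume_io import LandmarkSet

__all__ = [
    "RigidTransform",
    "RigidFit",
    "VirtualMarkerModel",
    "fit_rigid",
    "register_scan",
    "impute_virtual_markers",
]

_ORTHO_TOL = 1e-9

#: bone-marker triads with smallest triangle altitude below this (mm)
#: are rejected as collinear
MIN_TRIAD_ALTITUDE_MM = 0.5


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion ``p -> R p + t`` of world space (mm).

    Construction validates that ``rotation`` is orthonormal with
    determinant +1 (to 1e-9); improper matrices (reflections) are
    rejected.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, float).reshape(3, 3)
        t = np.asarray(self.translation, float).reshape(3)
        if np.max(np.abs(r.T @ r - np.eye(3))) > 1e-9:
            raise DegenerateGeometryError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(r) - 1.0) > 1e-9:
            raise DegenerateGeometryError(
                "rotation matrix is improper (det != +1); reflections are "
                "not rigid motions of an oriented body"
            )
        object.__setattr__(self, "rotation", r)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        m = np.asarray(matrix, float).reshape(4, 4)
        return cls(m[:3, :3], m[:3, 3])

    @property
    def matrix(self) -> np.ndarray:
        """Homogeneous 4x4 form (row-major)."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points: Sequence[float] | np.ndarray) -> np.ndarray:
        """Apply to one point or an ``(n, 3)`` stack of points."""
        pts = np.atleast_2d(np.asarray(points, float))
        out = pts @ self.rotation.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """``self.compose(other)`` applies ``other`` first: (A o B)(p) = A(B(p))."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)


class RigidFit(NamedTuple):
    """Result of a least-squares rigid fit: the transform and the
    root-mean-square residual (mm) over the fitted points."""

    transform: RigidTransform
    rms_mm: float


def _min_altitude(points: np.ndarray) -> float:
    """Smallest point-to-opposite-side distance of a triangle, or a
    rank-based surrogate for >3 points (second singular value of the
    centered set, which is 0 iff collinear)."""
    pts = np.asarray(points, float)
    if len(pts) == 3:
        alts = []
        for i in range(3):
            a, b, c = pts[i], pts[(i + 1) % 3], pts[(i + 2) % 3]
            base = np.linalg.norm(c - b)
            if base < 1e-12:
                return 0.0
            alts.append(np.linalg.norm(np.cross(a - b, c - b)) / base)
        return float(min(alts))
    centered = pts - pts.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    return float(s[1]) if len(s) > 1 else 0.0


def fit_rigid(
    source: np.ndarray,
    target: np.ndarray,
    min_altitude_mm: float = 1e-6,
) -> RigidFit:
    """Least-squares proper rigid transform mapping ``source`` onto
    ``target`` (Kabsch).

    Parameters
    ----------
    source, target
        Matched ``(n, 3)`` point sets, ``n >= 3``, in mm.
    min_altitude_mm
        Collinearity gate on the source points (smallest triangle
        altitude for triads, second singular value otherwise).

    Returns
    -------
    RigidFit
        The minimizing transform and the residual RMS.  The best
        *proper* rotation is returned even when a reflection would fit
        better.
    """
    src = np.asarray(source, float).reshape(-1, 3)
    tgt = np.asarray(target, float).reshape(-1, 3)
    if len(src) != len(tgt):
        raise StudyValidationError(
            f"matched point sets differ in size: {len(src)} vs {len(tgt)}"
        )
    if len(src) < 3:
        raise InsufficientMarkersError(
            f"rigid fit needs >=3 point pairs, got {len(src)}"
        )
    if _min_altitude(src) < min_altitude_mm:
        raise DegenerateGeometryError(
            "source points are collinear; rotation about their axis is "
            "unconstrained"
        )
    src_c = src - src.mean(axis=0)
    tgt_c = tgt - tgt.mean(axis=0)
    h = src_c.T @ tgt_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    if d == 0:
        d = 1.0
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    # Clean up round-off so the RigidTransform validator's 1e-9 gate holds.
    uu, _, vv = np.linalg.svd(rot)
    rot = uu @ vv
    trans = tgt.mean(axis=0) - rot @ src.mean(axis=0)
    transform = RigidTransform(rot, trans)
    residuals = transform.apply(src) - tgt
    rms = float(np.sqrt(np.mean(np.sum(residuals ** 2, axis=1))))
    return RigidFit(transform, rms)


def register_scan(
    reference: LandmarkSet, followup: LandmarkSet
) -> RigidFit:
    """Rigid transform taking follow-up world coordinates into the
    reference world frame, fitted on the shared scapular landmarks.

    Landmark names must match between the two sets; the fit RMS is the
    registration quality (mm) over the scapular landmarks.
    """
    ref_names = sorted(reference.scapula)
    fup_names = sorted(followup.scapula)
    if ref_names != fup_names:
        raise StudyValidationError(
            f"scapular landmark names differ between scans: "
            f"{ref_names} vs {fup_names}"
        )
    if len(ref_names) < 3:
        raise StudyValidationError(
            f"scapular registration needs >=3 landmarks, got {len(ref_names)}"
        )
    src = np.array([followup.scapula[n] for n in ref_names])
    tgt = np.array([reference.scapula[n] for n in ref_names])
    return fit_rigid(src, tgt, min_altitude_mm=MIN_TRIAD_ALTITUDE_MM)


@dataclass(frozen=True)
class VirtualMarkerModel:
    """Rigid-body relationship of virtual markers to the humeral bone
    markers, established in the reference scan.

    ``reference_virtual`` maps virtual labels (V1...) to reference-scan
    world positions; ``reference_bone`` maps bone labels (H1...) to
    reference-scan world positions.  At least three non-collinear bone
    markers are required.
    """

    reference_virtual: dict[str, np.ndarray]
    reference_bone: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for attr in ("reference_virtual", "reference_bone"):
            coerced = {
                k: np.asarray(v, float).reshape(3)
                for k, v in getattr(self, attr).items()
            }
            object.__setattr__(self, attr, coerced)
        if len(self.reference_bone) < 3:
            raise InsufficientMarkersError(
                f"virtual-marker model needs >=3 bone markers, got "
                f"{len(self.reference_bone)}"
            )
        pts = np.array(list(self.reference_bone.values()))
        if _min_altitude(pts) < MIN_TRIAD_ALTITUDE_MM:
            raise DegenerateGeometryError(
                "reference bone markers are (near-)collinear"
            )


def impute_virtual_markers(
    model: VirtualMarkerModel,
    followup_bone: dict[str, np.ndarray],
) -> tuple[dict[str, np.ndarray], float]:
    """Carry virtual markers into a follow-up scan via the bone markers.

    Fits the rigid transform from reference to follow-up bone-marker
    positions (matched by label) and applies it to the reference
    virtual-marker positions.  Returns the imputed positions (in the
    same frame the follow-up bone positions were given in) and the
    bone-marker fit RMS (mm), the imputation quality metric.
    """
    labels = sorted(model.reference_bone)
    missing = [lbl for lbl in labels if lbl not in followup_bone]
    if missing:
        raise InsufficientMarkersError(
            f"follow-up scan lacks bone marker(s): {', '.join(missing)}"
        )
    src = np.array([model.reference_bone[lbl] for lbl in labels])
    tgt = np.array([np.asarray(followup_bone[lbl], float) for lbl in labels])
    if _min_altitude(tgt) < MIN_TRIAD_ALTITUDE_MM:
        raise DegenerateGeometryError(
            "follow-up bone markers are (near-)collinear"
        )
    fit = fit_rigid(src, tgt, min_altitude_mm=MIN_TRIAD_ALTITUDE_MM)
    imputed = {
        lbl: fit.transform.apply(pos)
        for lbl, pos in model.reference_virtual.items()
    }
    return imputed, fit.rms_mm
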