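"""Synthetic CT phantoms with known ground truth.

Every pipeline stage can be exercised without any scan data: the
phantom renders barium-knot markers as small bright spheres (~1.5 mm
diameter, 2000 HU) over a soft-tissue background, with an optional
bone sphere (1200 HU, large enough to be rejected by the localizer's
component-size gate), partial-volume boundaries from 3x3x3
supersampled coverage fractions, a Gaussian reconstruction blur, and
seeded i.i.d. Gaussian noise.  All ground truth (marker centers,
landmark coordinates, analytic measurement values) is emitted in world
millimetres alongside the volume.

Two layouts mirror the study protocols: the *cadaver* layout carries
eight tendon markers in two rows 10 mm apart plus three humeral bone
markers and four virtual footprint markers (14 lengths, 6 areas, 3
angles); the *patient* layout carries the four lateral tendon markers
only (4 medio-lateral lengths, 3 antero-posterior lengths, 3 areas, 3
angles).  A :class:`MotionScript` turns a layout into a longitudinal
or repeat-scan series: per-timepoint tendon retraction (displacement
along the medial direction), optional humeral rotation about a
scapular axis, and whole-scan rigid repositioning on the fixed scanner
grid.

All randomness (noise, seed jitter, repositioning) flows from explicit
integer seeds; identical specs render bit-identical volumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import ndimage

from .errors import PhantomSpecError
from .frames import humeral_frame, scapular_frame
from .morphometry import MeasurementRecord, measure_scan
from .rigid import RigidTransform
from .volume_io import (
    LandmarkSet,
    MarkerDefinition,
    MeasurementDefinitions,
    VoxelVolume,
    write_landmarks,
    write_marker_definitions,
    write_volume,
)

__all__ = [
    "PhantomMarker",
    "SphereShape",
    "CylinderShape",
    "PhantomSpec",
    "GroundTruth",
    "MotionScript",
    "TimepointMotion",
    "PhantomScan",
    "PhantomStudy",
    "render_phantom",
    "render_cadaver_layout",
    "render_patient_layout",
    "render_longitudinal",
    "repeat_scan_script",
    "default_patient_script",
    "study_bundle",
    "write_study_bundle",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))  # 1/2.3548...

# sub-voxel sample offsets: 3 per axis at the centers of thirds
_SUPERSAMPLE = (np.arange(3) - 1.0) / 3.0


@dataclass(frozen=True)
class SphereShape:
    center: tuple[float, float, float]
    radius: float
    hu: float

    def contains(self, pts: np.ndarray) -> np.ndarray:
        d2 = ((pts - np.asarray(self.center)) ** 2).sum(axis=-1)
        return d2 <= self.radius ** 2

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        c = np.asarray(self.center, float)
        return c - self.radius, c + self.radius

    def moved(self, transform: RigidTransform) -> "SphereShape":
        return replace(self, center=tuple(transform.apply(np.asarray(self.center))))


@dataclass(frozen=True)
class CylinderShape:
    """Finite capped cylinder from ``p0`` to ``p1``."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float
    hu: float

    def contains(self, pts: np.ndarray) -> np.ndarray:
        a = np.asarray(self.p0, float)
        axis = np.asarray(self.p1, float) - a
        lsq = float(axis @ axis)
        rel = pts - a
        t = (rel @ axis) / lsq
        radial2 = (rel ** 2).sum(axis=-1) - (t ** 2) * lsq
        return (t >= 0) & (t <= 1) & (radial2 <= self.radius ** 2)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        a = np.asarray(self.p0, float)
        b = np.asarray(self.p1, float)
        lo = np.minimum(a, b) - self.radius
        hi = np.maximum(a, b) + self.radius
        return lo, hi

    def moved(self, transform: RigidTransform) -> "CylinderShape":
        return replace(
            self,
            p0=tuple(transform.apply(np.asarray(self.p0))),
            p1=tuple(transform.apply(np.asarray(self.p1))),
        )


@dataclass(frozen=True)
class PhantomMarker:
    """Ground-truth marker: virtual markers are *not* rendered."""

    label: str
    marker_class: Literal["tendon", "bone", "virtual"]
    center: tuple[float, float, float]
    radius: float = 0.75
    hu: float = 2000.0

    @property
    def rendered(self) -> bool:
        return self.marker_class != "virtual"

    @property
    def center_mm(self) -> np.ndarray:
        return np.asarray(self.center, float)


@dataclass
class PhantomSpec:
    """Full description of one synthetic scan.

    Defaults follow the imaging protocol the package targets: 0.5 x
    0.5 x 0.6 mm voxels, soft-tissue background (40 HU), ~0.8 mm FWHM
    reconstruction blur.  Noise is off by default; set
    ``noise_sigma_hu`` for stochastic studies.
    """

    dims: tuple[int, int, int] = (128, 128, 80)
    spacing: tuple[float, float, float] = (0.5, 0.5, 0.6)
    origin: tuple[float, float, float] = (-40.0, -12.0, -34.0)
    background_hu: float = 40.0
    bones: tuple = ()
    markers: tuple[PhantomMarker, ...] = ()
    landmarks: LandmarkSet | None = None
    measurements: MeasurementDefinitions = field(default_factory=MeasurementDefinitions)
    noise_sigma_hu: float = 0.0
    blur_fwhm_mm: float = 0.8
    seed: int = 0

    @property
    def affine(self) -> np.ndarray:
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.spacing)
        aff[:3, 3] = np.asarray(self.origin, float)
        return aff

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.asarray(self.origin, float)
        hi = lo + (np.asarray(self.dims) - 1) * np.asarray(self.spacing)
        return lo, hi

    def validate(self) -> None:
        if min(self.dims) < 1:
            raise PhantomSpecError(f"non-positive volume dims {self.dims}")
        if min(self.spacing) <= 0:
            raise PhantomSpecError(f"non-positive spacing {self.spacing}")
        lo, hi = self.world_bounds()
        rendered = [m for m in self.markers if m.rendered]
        labels = [m.label for m in self.markers]
        if len(set(labels)) != len(labels):
            raise PhantomSpecError("duplicate marker labels in phantom spec")
        for m in rendered:
            c = m.center_mm
            if np.any(c - m.radius < lo) or np.any(c + m.radius > hi):
                raise PhantomSpecError(
                    f"marker {m.label} at {m.center} (r={m.radius}) lies "
                    f"outside the volume bounds {lo}..{hi}"
                )
        for i, a in enumerate(rendered):
            for b in rendered[i + 1:]:
                gap = float(np.linalg.norm(a.center_mm - b.center_mm))
                if gap < a.radius + b.radius:
                    raise PhantomSpecError(
                        f"markers {a.label} and {b.label} overlap "
                        f"(centers {gap:.2f} mm apart)"
                    )


@dataclass
class GroundTruth:
    """What the phantom knows: true marker positions (world mm), true
    landmarks, and the analytic measurement record (the latter two are
    ``None`` for landmark-free specs)."""

    positions: dict[str, np.ndarray]
    landmarks: LandmarkSet | None
    record: MeasurementRecord | None
    seed: int


def _coverage(shape, spec: PhantomSpec, arr: np.ndarray) -> None:
    """Accumulate a shape into ``arr`` with supersampled partial volume."""
    lo_w, hi_w = shape.bounds()
    inv_sp = 1.0 / np.asarray(spec.spacing)
    origin = np.asarray(spec.origin)
    lo_i = np.floor((lo_w - origin) * inv_sp - 0.5).astype(int)
    hi_i = np.ceil((hi_w - origin) * inv_sp + 0.5).astype(int)
    lo_i = np.maximum(lo_i, 0)
    hi_i = np.minimum(hi_i, np.asarray(spec.dims) - 1)
    if np.any(lo_i > hi_i):
        return  # shape entirely outside the grid
    grids = np.meshgrid(
        *[np.arange(lo_i[d], hi_i[d] + 1) for d in range(3)], indexing="ij"
    )
    idx = np.stack([g.ravel() for g in grids], axis=1).astype(float)
    frac = np.zeros(len(idx))
    for oi in _SUPERSAMPLE:
        for oj in _SUPERSAMPLE:
            for ok in _SUPERSAMPLE:
                pts = (idx + (oi, oj, ok)) * spec.spacing + origin
                frac += shape.contains(pts)
    frac /= len(_SUPERSAMPLE) ** 3
    values = spec.background_hu + frac * (shape.hu - spec.background_hu)
    sub = arr[lo_i[0]:hi_i[0] + 1, lo_i[1]:hi_i[1] + 1, lo_i[2]:hi_i[2] + 1]
    np.maximum(sub, values.reshape(sub.shape), out=sub)


def render_phantom(spec: PhantomSpec) -> tuple[VoxelVolume, GroundTruth]:
    """Render a phantom spec to a volume plus its ground-truth bundle.

    Rendering order: shape coverage (supersampled partial volume, max
    composited), Gaussian blur of ``blur_fwhm_mm``, then i.i.d.
    Gaussian noise of ``noise_sigma_hu``, both driven by ``spec.seed``.
    """
    spec.validate()
    arr = np.full(spec.dims, float(spec.background_hu))
    shapes = list(spec.bones) + [
        SphereShape(m.center, m.radius, m.hu) for m in spec.markers if m.rendered
    ]
    for shape in shapes:
        _coverage(shape, spec, arr)
    if spec.blur_fwhm_mm > 0:
        sigma_vox = spec.blur_fwhm_mm * _FWHM_TO_SIGMA / np.asarray(spec.spacing)
        arr = ndimage.gaussian_filter(arr, sigma=sigma_vox)
    if spec.noise_sigma_hu > 0:
        rng = np.random.default_rng(spec.seed)
        arr = arr + rng.normal(0.0, spec.noise_sigma_hu, size=arr.shape)
    volume = VoxelVolume(arr.astype(np.float32), spec.affine)
    truth = _ground_truth(spec)
    return volume, truth


def _ground_truth(spec: PhantomSpec, scan_id: str = "phantom",
                  weeks: float = 0.0) -> GroundTruth:
    positions = {m.label: m.center_mm for m in spec.markers}
    if spec.landmarks is None:
        return GroundTruth(positions=positions, landmarks=None, record=None,
                           seed=spec.seed)
    record = measure_scan(
        positions,
        spec.measurements,
        scapula=scapular_frame(spec.landmarks),
        humerus=humeral_frame(spec.landmarks),
        scan_id=scan_id,
        timepoint_weeks=weeks,
    )
    return GroundTruth(
        positions=positions,
        landmarks=spec.landmarks,
        record=record,
        seed=spec.seed,
    )


# ---------------------------------------------------------------------------
# Study layouts
# ---------------------------------------------------------------------------

# Lateral tendon row (odd labels) sits ~13 mm medial of the footprint
# edge; the medial row (even labels) is exactly 10 mm further medial.
_LATERAL_ROW = {
    "T1": (-12.5, 6.5, 2.0),
    "T3": (-13.5, 13.8, 1.0),
    "T5": (-14.0, 20.5, 0.0),
    "T7": (-12.0, 27.5, -1.0),
}
_MEDIAL_ROW = {
    "T2": (-22.5, 6.5, 2.0),
    "T4": (-23.5, 13.8, 1.0),
    "T6": (-24.0, 20.5, 0.0),
    "T8": (-22.0, 27.5, -1.0),
}
_VIRTUAL = {
    "V1": (0.0, 6.0, 1.0),
    "V2": (0.0, 13.0, 0.3),
    "V3": (0.0, 20.0, -0.4),
    "V4": (0.0, 27.0, -1.1),
}
_BONE_MARKERS = {
    "H1": (6.0, 6.0, -4.0),
    "H2": (7.0, 16.0, -3.0),
    "H3": (5.0, 26.0, -6.0),
}
_HUMERAL_HEAD = SphereShape(center=(12.0, 16.0, -16.0), radius=10.0, hu=1200.0)
_LANDMARKS = {
    "scapula": {"AA": (-2.0, 0.0, 6.0), "TS": (-45.0, 8.0, 2.0),
                "AI": (-40.0, -10.0, -60.0)},
    "humerus": {"HH": (12.0, 16.0, -16.0), "ME": (4.0, 20.0, -310.0),
                "LE": (20.0, 24.0, -312.0)},
}

_CADAVER_LENGTHS = (
    # medio-lateral
    ("V1", "T1"), ("T1", "T2"), ("V2", "T3"), ("T3", "T4"),
    ("V3", "T5"), ("T5", "T6"), ("V4", "T7"), ("T7", "T8"),
    # antero-posterior
    ("T1", "T3"), ("T3", "T5"), ("T5", "T7"),
    ("T2", "T4"), ("T4", "T6"), ("T6", "T8"),
)
_CADAVER_AREAS = (
    ("V1", "V2", "T3", "T1"), ("T1", "T2", "T3", "T4"),
    ("V2", "V3", "T5", "T3"), ("T3", "T5", "T6", "T4"),
    ("V3", "V4", "T7", "T5"), ("T5", "T7", "T8", "T6"),
)
_PATIENT_LENGTHS = (
    ("V1", "T1"), ("V2", "T3"), ("V3", "T5"), ("V4", "T7"),
    ("T1", "T3"), ("T3", "T5"), ("T5", "T7"),
)
_PATIENT_AREAS = (
    ("V1", "V2", "T3", "T1"), ("V2", "V3", "T5", "T3"), ("V3", "V4", "T7", "T5"),
)


def _make_layout(tendon: Mapping[str, tuple], lengths, areas, **overrides) -> PhantomSpec:
    markers = (
        [PhantomMarker(lbl, "tendon", pos) for lbl, pos in tendon.items()]
        + [PhantomMarker(lbl, "bone", pos) for lbl, pos in _BONE_MARKERS.items()]
        + [PhantomMarker(lbl, "virtual", pos) for lbl, pos in _VIRTUAL.items()]
    )
    markers.sort(key=lambda m: m.label)
    spec = PhantomSpec(
        bones=(_HUMERAL_HEAD,),
        markers=tuple(markers),
        landmarks=LandmarkSet(
            scapula=dict(_LANDMARKS["scapula"]),
            humerus=dict(_LANDMARKS["humerus"]),
            side="right",
        ),
        measurements=MeasurementDefinitions(lengths=lengths, areas=areas),
    )
    return replace(spec, **overrides)


def render_cadaver_layout(**overrides) -> PhantomSpec:
    """Cadaver-protocol layout: 8 tendon + 3 bone + 4 virtual markers,
    14 lengths / 6 areas / 3 angles.  Keyword overrides replace any
    :class:`PhantomSpec` field (``noise_sigma_hu=20``, ``seed=7``...).
    """
    tendon = dict(_LATERAL_ROW) | dict(_MEDIAL_ROW)
    return _make_layout(tendon, _CADAVER_LENGTHS, _CADAVER_AREAS, **overrides)


def render_patient_layout(**overrides) -> PhantomSpec:
    """Patient-protocol layout: lateral tendon row only (T1, T3, T5,
    T7) + 3 bone + 4 virtual markers, 7 lengths / 3 areas / 3 angles."""
    return _make_layout(dict(_LATERAL_ROW), _PATIENT_LENGTHS, _PATIENT_AREAS, **overrides)


# ---------------------------------------------------------------------------
# Motion scripts and longitudinal rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TimepointMotion:
    """Pose of one timepoint relative to the baseline layout.

    ``retraction_mm`` displaces tendon markers along the medial
    direction (the negated scapular lateral axis): a scalar applies to
    every tendon marker, a mapping sets per-label displacements.
    ``humeral_rotation_deg`` rotates the humerus (bone markers,
    virtual markers, humeral landmarks, bone shapes) about the named
    scapular axis through the humeral head.  ``reposition`` is a
    whole-scan rigid motion on the fixed scanner grid.
    """

    weeks: float
    retraction_mm: float | Mapping[str, float] = 0.0
    humeral_rotation_deg: float = 0.0
    humeral_axis: Literal["lateral", "anterior", "superior"] = "superior"
    reposition: RigidTransform | None = None

    def retraction_for(self, label: str) -> float:
        if isinstance(self.retraction_mm, Mapping):
            return float(self.retraction_mm.get(label, 0.0))
        return float(self.retraction_mm)


@dataclass(frozen=True)
class MotionScript:
    timepoints: tuple[TimepointMotion, ...]

    def __post_init__(self) -> None:
        weeks = [t.weeks for t in self.timepoints]
        if len(weeks) < 1:
            raise PhantomSpecError("motion script needs >=1 timepoint")
        if any(b < a for a, b in zip(weeks, weeks[1:])):
            raise PhantomSpecError(f"timepoints must be ordered, got weeks {weeks}")


def _random_reposition(rng: np.random.Generator, max_deg: float,
                       max_mm: float, pivot: np.ndarray) -> RigidTransform:
    """Small rigid jitter: rotation of ``max_deg`` about a random axis
    through ``pivot`` plus a translation of norm ``max_mm`` in a random
    direction."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.deg2rad(max_deg)
    k = np.array([[0, -axis[2], axis[1]],
                  [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    rot = np.eye(3) + np.sin(ang) * k + (1 - np.cos(ang)) * (k @ k)
    shift = rng.normal(size=3)
    shift = shift / np.linalg.norm(shift) * max_mm
    trans = pivot - rot @ pivot + shift
    return RigidTransform(rot, trans)


def repeat_scan_script(
    n_scans: int = 3,
    jitter_mm: float = 0.3,
    jitter_deg: float = 0.3,
    seed: int = 0,
    pivot: Sequence[float] = (0.0, 16.0, -8.0),
) -> MotionScript:
    """Repeat-scan (precision) protocol: no anatomy motion, the whole
    specimen rigidly repositioned before each scan.  The first scan is
    unperturbed."""
    rng = np.random.default_rng(seed)
    pivot = np.asarray(pivot, float)
    tps = [TimepointMotion(weeks=0.0)]
    for _ in range(1, n_scans):
        tps.append(
            TimepointMotion(
                weeks=0.0,
                reposition=_random_reposition(rng, jitter_deg, jitter_mm, pivot),
            )
        )
    return MotionScript(tuple(tps))


#: per-marker retraction trajectories (mm medial of baseline) used by
#: the default patient script; final-visit mean is 19.075 mm
_DEFAULT_RETRACTION = {
    "T1": (0.0, 5.3, 12.3, 18.4),
    "T3": (0.0, 3.4, 15.2, 23.3),
    "T5": (0.0, 2.8, 12.4, 17.6),
    "T7": (0.0, 1.5, 12.1, 17.0),
}


def default_patient_script(
    weeks: Sequence[float] = (0.0, 3.0, 12.0, 26.0),
    retraction: Mapping[str, Sequence[float]] | None = None,
    reposition_mm: float = 1.0,
    reposition_deg: float = 1.0,
    seed: int = 0,
) -> MotionScript:
    """Four-visit longitudinal protocol with progressive medial tendon
    retraction (default trajectories average 19 mm at the final visit)
    and small random repositioning between visits.  Humeral pose is
    held fixed so the scripted retraction maps one-to-one onto the
    medio-lateral length changes."""
    retraction = dict(_DEFAULT_RETRACTION) if retraction is None else dict(retraction)
    rng = np.random.default_rng(seed)
    tps = []
    for i, wk in enumerate(weeks):
        per_label = {lbl: traj[i] for lbl, traj in retraction.items()}
        repos = None
        if i > 0 and (reposition_mm > 0 or reposition_deg > 0):
            repos = _random_reposition(
                rng, reposition_deg, reposition_mm, np.array([0.0, 16.0, -8.0])
            )
        tps.append(TimepointMotion(weeks=wk, retraction_mm=per_label, reposition=repos))
    return MotionScript(tuple(tps))


@dataclass
class PhantomScan:
    """One rendered timepoint: the volume, its sidecar inputs, and the
    true marker positions on the scanner grid."""

    scan_id: str
    weeks: float
    volume: VoxelVolume
    landmarks: LandmarkSet
    seeds: list[MarkerDefinition]
    true_positions: dict[str, np.ndarray]


@dataclass
class PhantomStudy:
    scans: list[PhantomScan]
    measurements: MeasurementDefinitions
    ground_truth: list[MeasurementRecord]
    side: str = "right"


def _posed_spec(spec: PhantomSpec, motion: TimepointMotion,
                scan_seed: int) -> tuple[PhantomSpec, dict[str, np.ndarray]]:
    """Apply a timepoint's motion to the baseline spec; returns the
    posed spec and the posed true positions (post-repositioning)."""
    assert spec.landmarks is not None
    scap = scapular_frame(spec.landmarks)
    medial = -scap.axis_lateral
    hum_transform = RigidTransform.identity()
    if motion.humeral_rotation_deg != 0.0:
        axis = getattr(scap, f"axis_{motion.humeral_axis}")
        ang = np.deg2rad(motion.humeral_rotation_deg)
        k = np.array([[0, -axis[2], axis[1]],
                      [axis[2], 0, -axis[0]],
                      [-axis[1], axis[0], 0]])
        rot = np.eye(3) + np.sin(ang) * k + (1 - np.cos(ang)) * (k @ k)
        pivot = np.asarray(spec.landmarks.humerus["HH"], float)
        hum_transform = RigidTransform(rot, pivot - rot @ pivot)
    repos = motion.reposition or RigidTransform.identity()

    markers = []
    for m in spec.markers:
        pos = m.center_mm
        if m.marker_class == "tendon":
            pos = pos + motion.retraction_for(m.label) * medial
        else:  # bone and virtual markers ride with the humerus
            pos = hum_transform.apply(pos)
        markers.append(replace(m, center=tuple(repos.apply(pos))))
    landmarks = LandmarkSet(
        scapula={k: repos.apply(v) for k, v in spec.landmarks.scapula.items()},
        humerus={k: repos.apply(hum_transform.apply(v))
                 for k, v in spec.landmarks.humerus.items()},
        side=spec.landmarks.side,
    )
    bones = tuple(b.moved(hum_transform).moved(repos) for b in spec.bones)
    posed = replace(
        spec, markers=tuple(markers), landmarks=landmarks, bones=bones,
        seed=scan_seed,
    )
    return posed, {m.label: m.center_mm for m in posed.markers}


def render_longitudinal(
    spec: PhantomSpec,
    script: MotionScript,
    seed_jitter_mm: float = 0.5,
) -> PhantomStudy:
    """Render one volume per script timepoint plus ground truth.

    Per-scan analyst marker seeds are the true tendon/bone positions
    plus isotropic Gaussian jitter of ``seed_jitter_mm`` (virtual
    seeds stay exact — they are placements, not clicks).  Noise and
    jitter derive from ``spec.seed`` so a study renders reproducibly.
    """
    rng = np.random.default_rng(spec.seed)
    scans: list[PhantomScan] = []
    truth_records: list[MeasurementRecord] = []
    for i, motion in enumerate(script.timepoints):
        scan_id = f"scan{i}"
        scan_seed = int(rng.integers(0, 2 ** 31 - 1))
        posed, positions = _posed_spec(spec, motion, scan_seed)
        volume, _ = render_phantom(posed)
        seeds = []
        for m in posed.markers:
            seed_pos = m.center_mm
            if m.rendered and seed_jitter_mm > 0:
                seed_pos = seed_pos + rng.normal(0.0, seed_jitter_mm, size=3)
            seeds.append(
                MarkerDefinition(m.label, m.marker_class, tuple(seed_pos))
            )
        assert posed.landmarks is not None
        truth_records.append(
            measure_scan(
                positions,
                spec.measurements,
                scapula=scapular_frame(posed.landmarks),
                humerus=humeral_frame(posed.landmarks),
                scan_id=scan_id,
                timepoint_weeks=motion.weeks,
            )
        )
        scans.append(
            PhantomScan(
                scan_id=scan_id,
                weeks=motion.weeks,
                volume=volume,
                landmarks=posed.landmarks,
                seeds=seeds,
                true_positions=positions,
            )
        )
    return PhantomStudy(
        scans=scans,
        measurements=spec.measurements,
        ground_truth=truth_records,
        side=spec.landmarks.side if spec.landmarks else "right",
    )


def study_bundle(study: PhantomStudy, localization=None):
    """Wrap a rendered :class:`PhantomStudy` as an in-memory
    :class:`~markermorph.volume_io.StudyBundle`, ready for
    :func:`~markermorph.pipeline.analyze_study` without a disk round
    trip."""
    from .volume_io import LocalizationParams, ScanRecord, StudyBundle

    return StudyBundle(
        scans=[
            ScanRecord(
                scan_id=s.scan_id,
                volume=s.volume,
                landmarks=s.landmarks,
                markers=s.seeds,
                timepoint_weeks=s.weeks,
            )
            for s in study.scans
        ],
        measurements=study.measurements,
        localization=localization or LocalizationParams(),
        side=study.side,  # type: ignore[arg-type]
    )


def write_study_bundle(study: PhantomStudy, out_dir: str | Path) -> Path:
    """Write a rendered study to disk in the study-config layout the
    pipeline consumes; returns the config path.

    Emits per scan ``<id>.nii.gz``, ``<id>_landmarks.json`` and
    ``<id>_markers.json``, plus ``config.json`` and
    ``ground_truth.json`` (true positions and analytic measurements).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scan_entries = []
    for scan in study.scans:
        write_volume(scan.volume, out / f"{scan.scan_id}.nii.gz")
        write_landmarks(scan.landmarks, out / f"{scan.scan_id}_landmarks.json")
        write_marker_definitions(scan.seeds, out / f"{scan.scan_id}_markers.json")
        scan_entries.append(
            {
                "id": scan.scan_id,
                "path": f"{scan.scan_id}.nii.gz",
                "landmarks": f"{scan.scan_id}_landmarks.json",
                "markers": f"{scan.scan_id}_markers.json",
                "timepoint_weeks": scan.weeks,
            }
        )
    config = {
        "side": study.side,
        "scans": scan_entries,
        "markers": f"{study.scans[0].scan_id}_markers.json",
        "measurements": {
            "lengths": [list(p) for p in study.measurements.lengths],
            "areas": [list(q) for q in study.measurements.areas],
        },
    }
    (out / "config.json").write_text(json.dumps(config, indent=1))
    truth = {
        "scans": [
            {
                "id": scan.scan_id,
                "timepoint_weeks": scan.weeks,
                "positions_mm": {
                    k: [float(x) for x in v] for k, v in scan.true_positions.items()
                },
            }
            for scan in study.scans
        ],
        "measurements": [
            {
                "id": rec.scan_id,
                "timepoint_weeks": rec.timepoint_weeks,
                "lengths": {k: float(v) for k, v in rec.lengths.items()},
                "areas": {k: float(v) for k, v in rec.areas.items()},
                "angles": {k: float(v) for k, v in rec.angles.items()},
            }
            for rec in study.ground_truth
        ],
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
    return out / "config.json"
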