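"""CT volume I/O and the voxel-to-world coordinate contract.

A :class:`VoxelVolume` couples a 3-D grid of Hounsfield-unit intensities
with a 4x4 affine that maps *voxel index* (i, j, k) to *world position*
(x, y, z) in millimetres.  Index (0, 0, 0) maps to the **center** of the
corner voxel; indices are 0-based everywhere, fractional and
out-of-bounds indices are meaningful (sub-voxel centroids live there).

The internal world convention is LPS (+x left, +y posterior, +z
superior), the native frame of DICOM-derived CT.  NIfTI files, which
store RAS affines, are converted on load; this is handled by SimpleITK,
whose world frame is LPS.  Anatomical directions are never assumed from
world axes — they are derived per subject from bony landmarks in
:mod:`markermorph.frames`.

Sidecar files (landmarks, marker definitions, measurement definitions,
study configs) are JSON; all world coordinates in them are millimetres
in the world frame of their own scan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Literal, Mapping, Sequence

import numpy as np
import SimpleITK as sitk
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import MetadataError, StudyValidationError, VolumeFormatError

__all__ = [
    "VoxelVolume",
    "LandmarkSet",
    "MarkerDefinition",
    "MeasurementDefinitions",
    "ScanRecord",
    "StudyBundle",
    "read_volume",
    "write_volume",
    "voxel_to_world",
    "world_to_voxel",
    "read_landmarks",
    "read_marker_definitions",
    "read_study",
]

_VOLUME_SUFFIXES = (".nii", ".nii.gz", ".nrrd", ".nhdr")

MarkerClass = Literal["tendon", "bone", "virtual"]


# ---------------------------------------------------------------------------
# VoxelVolume
# ---------------------------------------------------------------------------

@dataclass
class VoxelVolume:
    """A 3-D CT intensity grid with voxel-to-world affine.

    Parameters
    ----------
    intensities
        Array of shape ``(nx, ny, nz)``, Hounsfield units.
    affine
        4x4 matrix mapping homogeneous voxel index to world mm, with an
        invertible upper-left 3x3 block.
    """

    intensities: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.intensities.ndim != 3:
            raise MetadataError(
                f"volume must be 3-D, got shape {self.intensities.shape}"
            )
        if min(self.intensities.shape) < 1:
            raise MetadataError(
                f"volume dimensions must be positive, got {self.intensities.shape}"
            )
        if self.affine.shape != (4, 4):
            raise MetadataError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise MetadataError("affine upper-left 3x3 block is singular")
        if np.any(self.spacing <= 0):
            raise MetadataError(f"non-positive voxel spacing {self.spacing}")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Voxel spacing (mm): Euclidean norms of the affine's columns."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, index: Sequence[float]) -> np.ndarray:
        """Map (fractional) voxel indices to world mm.

        Accepts a single index triple or an ``(n, 3)`` array.
        """
        idx = np.atleast_2d(np.asarray(index, dtype=float))
        pts = idx @ self.affine[:3, :3].T + self.affine[:3, 3]
        return pts[0] if np.asarray(index).ndim == 1 else pts

    def world_to_voxel(self, point: Sequence[float]) -> np.ndarray:
        """Inverse of :meth:`voxel_to_world` (fractional indices)."""
        pts = np.atleast_2d(np.asarray(point, dtype=float))
        inv = np.linalg.inv(self.affine[:3, :3])
        idx = (pts - self.affine[:3, 3]) @ inv.T
        return idx[0] if np.asarray(point).ndim == 1 else idx

    @property
    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned world bounding box over all voxel centers."""
        corners = np.array(
            [[i, j, k]
             for i in (0, self.dims[0] - 1)
             for j in (0, self.dims[1] - 1)
             for k in (0, self.dims[2] - 1)],
            dtype=float,
        )
        w = self.voxel_to_world(corners)
        return w.min(axis=0), w.max(axis=0)


def voxel_to_world(volume: VoxelVolume, index: Sequence[float]) -> np.ndarray:
    """Functional form of :meth:`VoxelVolume.voxel_to_world`."""
    return volume.voxel_to_world(index)


def world_to_voxel(volume: VoxelVolume, point: Sequence[float]) -> np.ndarray:
    """Functional form of :meth:`VoxelVolume.world_to_voxel`."""
    return volume.world_to_voxel(point)


# ---------------------------------------------------------------------------
# Volume file I/O (NIfTI and NRRD via SimpleITK)
# ---------------------------------------------------------------------------

def _check_suffix(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _VOLUME_SUFFIXES):
        raise VolumeFormatError(
            f"unsupported volume format for {path} "
            f"(expected one of {_VOLUME_SUFFIXES})"
        )


def read_volume(path: str | Path) -> VoxelVolume:
    """Read a NIfTI (.nii/.nii.gz) or NRRD (.nrrd/.nhdr) volume.

    The returned affine is in the package's LPS world convention
    regardless of on-disk convention (SimpleITK normalizes NIfTI's RAS
    header on read).
    """
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"volume file does not exist: {path}")
    _check_suffix(path)
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # ITK throws RuntimeError on bad files
        raise VolumeFormatError(f"could not read volume {path}: {exc}") from exc
    if img.GetDimension() != 3:
        raise MetadataError(
            f"{path}: expected a 3-D volume, got {img.GetDimension()}-D"
        )
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    origin = np.asarray(img.GetOrigin(), dtype=float)
    affine = np.eye(4)
    affine[:3, :3] = direction * spacing  # column i scaled by spacing[i]
    affine[:3, 3] = origin
    # SimpleITK arrays are (z, y, x); transpose to (x, y, z) index order.
    arr = sitk.GetArrayFromImage(img).T
    return VoxelVolume(np.ascontiguousarray(arr), affine)


def write_volume(volume: VoxelVolume, path: str | Path) -> None:
    """Write a volume to NIfTI or NRRD, chosen by file extension.

    Intensities round-trip losslessly; the affine round-trips to within
    1e-6 elementwise (NIfTI headers store spacing in float32).
    """
    path = Path(path)
    _check_suffix(path)
    if not path.parent.exists():
        raise VolumeFormatError(f"parent directory does not exist: {path.parent}")
    spacing = volume.spacing
    direction = volume.affine[:3, :3] / spacing
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.intensities.T))
    img.SetSpacing(tuple(spacing))
    img.SetDirection(tuple(direction.ravel()))
    img.SetOrigin(tuple(volume.affine[:3, 3]))
    try:
        sitk.WriteImage(img, str(path))
    except RuntimeError as exc:
        raise VolumeFormatError(f"could not write volume {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

@dataclass
class LandmarkSet:
    """Named bony-landmark world coordinates for one scan.

    ``scapula`` and ``humerus`` map landmark names (e.g. ``AA``, ``TS``,
    ``AI``; ``HH``, ``ME``, ``LE``) to world-mm points of this scan.
    ``side`` flags the imaged shoulder; it controls only how signed
    angle directions are labelled downstream, never the frame algebra.
    """

    scapula: dict[str, np.ndarray]
    humerus: dict[str, np.ndarray]
    side: Literal["left", "right"] = "right"

    def __post_init__(self) -> None:
        for group_name in ("scapula", "humerus"):
            group = getattr(self, group_name)
            coerced = {}
            for name, pt in group.items():
                arr = np.asarray(pt, dtype=float).reshape(3)
                if not np.all(np.isfinite(arr)):
                    raise StudyValidationError(
                        f"landmark {group_name}/{name} has non-finite coordinates"
                    )
                coerced[name] = arr
            setattr(self, group_name, coerced)
        if self.side not in ("left", "right"):
            raise StudyValidationError(f"side must be left|right, got {self.side!r}")

    def group(self, which: str) -> dict[str, np.ndarray]:
        if which not in ("scapula", "humerus"):
            raise StudyValidationError(f"unknown landmark group {which!r}")
        return getattr(self, which)

    def transformed(self, func) -> "LandmarkSet":
        """Return a copy with every point mapped through ``func``."""
        return LandmarkSet(
            scapula={k: np.asarray(func(v), float) for k, v in self.scapula.items()},
            humerus={k: np.asarray(func(v), float) for k, v in self.humerus.items()},
            side=self.side,
        )

    def to_dict(self) -> dict:
        return {
            "scapula": {k: list(map(float, v)) for k, v in self.scapula.items()},
            "humerus": {k: list(map(float, v)) for k, v in self.humerus.items()},
            "side": self.side,
        }


def read_landmarks(path: str | Path) -> LandmarkSet:
    """Load a landmark JSON file (see :class:`LandmarkSet` for schema)."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise StudyValidationError(f"could not read landmarks {path}: {exc}") from exc
    for key in ("scapula", "humerus"):
        if key not in payload:
            raise StudyValidationError(f"{path}: missing landmark group '{key}'")
    return LandmarkSet(
        scapula=payload["scapula"],
        humerus=payload["humerus"],
        side=payload.get("side", "right"),
    )


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    Path(path).write_text(json.dumps(landmarks.to_dict(), indent=1))


# ---------------------------------------------------------------------------
# Marker definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MarkerDefinition:
    """An analyst-declared marker: label, class, and a world-mm seed.

    For tendon/bone markers the seed is an approximate click near the
    radiopaque knot (the localizer snaps it to the segmented centroid).
    For virtual markers the seed *is* the exact placement in the
    reference scan; virtual markers carry no image-derived data.
    """

    label: str
    marker_class: MarkerClass
    seed: tuple[float, float, float]

    @property
    def seed_mm(self) -> np.ndarray:
        return np.asarray(self.seed, dtype=float)


def read_marker_definitions(path: str | Path) -> list[MarkerDefinition]:
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise StudyValidationError(f"could not read markers {path}: {exc}") from exc
    return parse_marker_definitions(payload, source=str(path))


def parse_marker_definitions(
    payload: Sequence[Mapping], source: str = "<markers>"
) -> list[MarkerDefinition]:
    defs: list[MarkerDefinition] = []
    seen: set[str] = set()
    for entry in payload:
        try:
            label = str(entry["label"])
            cls = str(entry["class"])
            seed = tuple(float(x) for x in entry["seed"])
        except (KeyError, TypeError, ValueError) as exc:
            raise StudyValidationError(f"{source}: malformed marker entry {entry!r}") from exc
        if cls not in ("tendon", "bone", "virtual"):
            raise StudyValidationError(f"{source}: unknown marker class {cls!r}")
        if len(seed) != 3:
            raise StudyValidationError(f"{source}: seed for {label} must have 3 components")
        if label in seen:
            raise StudyValidationError(f"{source}: duplicate marker label {label}")
        seen.add(label)
        defs.append(MarkerDefinition(label, cls, seed))  # type: ignore[arg-type]
    return defs


def write_marker_definitions(defs: Sequence[MarkerDefinition], path: str | Path) -> None:
    payload = [
        {"label": d.label, "class": d.marker_class, "seed": list(map(float, d.seed))}
        for d in defs
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


# ---------------------------------------------------------------------------
# Measurement definitions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MeasurementDefinitions:
    """Which marker pairs form lengths and which quadruples form areas.

    ``lengths`` are ordered label pairs; ``areas`` are label quadruples
    in perimeter (traversal) order.  Measurement names are the
    concatenated labels, matching the row labels of study report tables
    (``V1T1``, ``V1V2T3T1``...).
    """

    lengths: tuple[tuple[str, str], ...] = ()
    areas: tuple[tuple[str, str, str, str], ...] = ()

    @property
    def length_names(self) -> list[str]:
        return ["".join(pair) for pair in self.lengths]

    @property
    def area_names(self) -> list[str]:
        return ["".join(quad) for quad in self.areas]

    def referenced_labels(self) -> set[str]:
        labels: set[str] = set()
        for pair in self.lengths:
            labels.update(pair)
        for quad in self.areas:
            labels.update(quad)
        return labels


# ---------------------------------------------------------------------------
# Study config (pydantic schema) and bundle
# ---------------------------------------------------------------------------

class LocalizationParams(BaseModel):
    """Segmentation/assignment knobs for the marker localizer."""

    model_config = ConfigDict(extra="forbid")

    threshold_hu: float = 800.0
    min_voxels: int = Field(3, ge=1)
    max_voxels: int = Field(500, ge=1)
    seed_cap_mm: float = Field(10.0, gt=0)
    weighting: Literal["uniform", "intensity"] = "uniform"


class _ScanModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    id: str
    path: str
    landmarks: str
    timepoint_weeks: float = 0.0
    markers: str | None = None  # per-scan seed override


class _MeasurementsModel(BaseModel):
    model_config = ConfigDict(extra="forbid")

    lengths: list[tuple[str, str]] = []
    areas: list[tuple[str, str, str, str]] = []


class StudyConfigModel(BaseModel):
    """On-disk study config schema (all paths relative to the config file)."""

    model_config = ConfigDict(extra="forbid")

    side: Literal["left", "right"] = "right"
    scans: list[_ScanModel] = Field(min_length=1)
    markers: str
    measurements: _MeasurementsModel = _MeasurementsModel()
    localization: LocalizationParams = LocalizationParams()


@dataclass
class ScanRecord:
    """One scan of a study: volume + landmarks + marker seeds."""

    scan_id: str
    volume: VoxelVolume
    landmarks: LandmarkSet
    markers: list[MarkerDefinition]
    timepoint_weeks: float
    volume_path: Path | None = None


@dataclass
class StudyBundle:
    """A fully validated study: scans, measurement definitions, params."""

    scans: list[ScanRecord]
    measurements: MeasurementDefinitions
    localization: LocalizationParams
    side: Literal["left", "right"] = "right"
    config_path: Path | None = None

    def __iter__(self) -> Iterator[ScanRecord]:
        return iter(self.scans)


def read_study(config_path: str | Path) -> StudyBundle:
    """Load and cross-validate a study bundle from a JSON config.

    Raises :class:`StudyValidationError` when a measurement references
    an undefined marker label, a scan file is missing, or a landmark
    group is absent.
    """
    config_path = Path(config_path)
    try:
        payload = json.loads(config_path.read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise StudyValidationError(f"could not read config {config_path}: {exc}") from exc
    try:
        cfg = StudyConfigModel.model_validate(payload)
    except ValidationError as exc:
        raise StudyValidationError(f"invalid study config {config_path}: {exc}") from exc

    base = config_path.parent
    shared_markers = read_marker_definitions(base / cfg.markers)
    measurements = MeasurementDefinitions(
        lengths=tuple(tuple(p) for p in cfg.measurements.lengths),
        areas=tuple(tuple(q) for q in cfg.measurements.areas),
    )

    known_labels = {d.label for d in shared_markers}
    dangling = sorted(measurements.referenced_labels() - known_labels)
    if dangling:
        raise StudyValidationError(
            f"{config_path}: measurements reference undefined marker labels "
            f"{', '.join(dangling)}"
        )

    scans: list[ScanRecord] = []
    seen_ids: set[str] = set()
    for scan in cfg.scans:
        if scan.id in seen_ids:
            raise StudyValidationError(f"{config_path}: duplicate scan id {scan.id}")
        seen_ids.add(scan.id)
        volume_path = base / scan.path
        if not volume_path.exists():
            raise StudyValidationError(
                f"{config_path}: scan {scan.id} volume missing: {volume_path}"
            )
        landmarks = read_landmarks(base / scan.landmarks)
        if landmarks.side != cfg.side:
            landmarks = LandmarkSet(landmarks.scapula, landmarks.humerus, cfg.side)
        markers = (
            read_marker_definitions(base / scan.markers)
            if scan.markers is not None
            else shared_markers
        )
        scan_labels = {d.label for d in markers}
        if not known_labels <= scan_labels:
            raise StudyValidationError(
                f"{config_path}: scan {scan.id} marker file lacks labels "
                f"{sorted(known_labels - scan_labels)}"
            )
        scans.append(
            ScanRecord(
                scan_id=scan.id,
                volume=read_volume(volume_path),
                landmarks=landmarks,
                markers=markers,
                timepoint_weeks=scan.timepoint_weeks,
                volume_path=volume_path,
            )
        )
    scans.sort(key=lambda s: s.timepoint_weeks)
    return StudyBundle(
        scans=scans,
        measurements=measurements,
        localization=cfg.localization,
        side=cfg.side,
        config_path=config_path,
    )
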