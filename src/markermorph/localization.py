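"""Segment radiopaque marker knots in CT and fit volumetric centroids.

The barium-loaded suture knots image as compact bright blobs (well
above soft tissue, below dense metal).  Identification is a fixed
Hounsfield threshold, 26-connected component labelling, and a component
size gate that rejects single-voxel noise and large bony structures.
Each retained component is reduced to the volumetric centroid of its
member voxel centers, in world millimetres; sub-voxel accuracy comes
from partial-volume averaging at the knot boundary.

Component-to-label assignment is greedy nearest-seed matching against
analyst-provided seed points, with a distance cap so a stray component
can never capture a distant label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage

from .errors import AmbiguityError, MarkerMorphError
from .volume_io import MarkerDefinition, VoxelVolume

__all__ = [
    "MarkerObservation",
    "segment_markers",
    "fit_centroid",
    "assign_labels",
    "localize_markers",
]

_STRUCTURE_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class MarkerObservation:
    """A localized marker.

    Attributes
    ----------
    label : str
        Marker identifier (``T1``..., ``H1``..., ``V1``...).
    centroid : ndarray
        World-mm centroid of the member voxels (or the imputed position
        for virtual markers).
    voxel_count : int
        Number of member voxels (0 for virtual/imputed markers).
    mean_intensity : float
        Mean HU over member voxels (NaN for virtual markers).
    bounding_radius : float
        Max distance (mm) from the centroid to a member voxel center.
    """

    label: str
    centroid: np.ndarray
    voxel_count: int
    mean_intensity: float
    bounding_radius: float

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "centroid_mm": [float(x) for x in self.centroid],
            "voxel_count": int(self.voxel_count),
            "mean_hu": float(self.mean_intensity),
            "bounding_radius_mm": float(self.bounding_radius),
        }


def segment_markers(
    volume: VoxelVolume,
    threshold: float = 800.0,
    min_voxels: int = 3,
    max_voxels: int = 500,
) -> list[np.ndarray]:
    """26-connected components of supra-threshold voxels, size-gated.

    Returns a list of ``(k, 3)`` integer index arrays, one per retained
    component, in scan order (deterministic).  Components smaller than
    ``min_voxels`` (noise specks) or larger than ``max_voxels``
    (cortical bone, metal hardware) are discarded.
    """
    if not np.isfinite(threshold):
        raise MarkerMorphError("threshold must be finite")
    if not (0 < min_voxels <= max_voxels):
        raise MarkerMorphError(
            f"need 0 < min_voxels <= max_voxels, got {min_voxels}, {max_voxels}"
        )
    mask = volume.intensities >= threshold
    labelled, n = ndimage.label(mask, structure=_STRUCTURE_26)
    if n == 0:
        return []
    sizes = np.bincount(labelled.ravel())[1:]  # component ids 1..n
    keep = np.flatnonzero((sizes >= min_voxels) & (sizes <= max_voxels)) + 1
    components: list[np.ndarray] = []
    if keep.size:
        all_idx = np.argwhere(np.isin(labelled, keep))
        comp_ids = labelled[tuple(all_idx.T)]
        order = np.argsort(comp_ids, kind="stable")
        all_idx, comp_ids = all_idx[order], comp_ids[order]
        boundaries = np.searchsorted(comp_ids, keep)
        for b, cid in zip(boundaries, keep):
            components.append(all_idx[b:b + sizes[cid - 1]])
    return components


def fit_centroid(
    volume: VoxelVolume,
    component: np.ndarray,
    weighting: Literal["uniform", "intensity"] = "uniform",
) -> np.ndarray:
    """Volumetric centroid of a component's voxel centers, in world mm.

    ``uniform`` (default) averages member voxel-center positions —
    the unweighted volume centroid.  ``intensity`` weights each voxel
    by its HU value (weights must sum to a positive number).
    """
    component = np.asarray(component)
    if component.size == 0:
        raise MarkerMorphError("cannot fit a centroid to an empty component")
    component = component.reshape(-1, 3)
    if weighting == "uniform":
        centroid_idx = component.mean(axis=0)
    elif weighting == "intensity":
        w = np.asarray(volume.intensities[tuple(component.T)], dtype=float)
        total = w.sum()
        if total <= 0:
            raise MarkerMorphError("intensity weights sum to a non-positive value")
        centroid_idx = (component * w[:, None]).sum(axis=0) / total
    else:
        raise MarkerMorphError(f"unknown weighting {weighting!r}")
    return volume.voxel_to_world(centroid_idx)


def _observe(volume: VoxelVolume, component: np.ndarray, label: str,
             weighting: Literal["uniform", "intensity"]) -> MarkerObservation:
    centroid = fit_centroid(volume, component, weighting)
    centers = volume.voxel_to_world(np.asarray(component, dtype=float))
    radius = float(np.linalg.norm(centers - centroid, axis=1).max())
    mean_hu = float(np.mean(volume.intensities[tuple(np.asarray(component).T)]))
    return MarkerObservation(
        label=label,
        centroid=centroid,
        voxel_count=int(len(component)),
        mean_intensity=mean_hu,
        bounding_radius=radius,
    )


def assign_labels(
    volume: VoxelVolume,
    components: Sequence[np.ndarray],
    seeds: Sequence[MarkerDefinition],
    cap_mm: float = 10.0,
    weighting: Literal["uniform", "intensity"] = "uniform",
) -> tuple[list[MarkerObservation], list[str]]:
    """Match segmented components to marker seeds, one-to-one.

    Greedy matching by ascending seed-to-centroid distance; pairs
    farther than ``cap_mm`` are never matched.  Equidistant ties break
    lexicographically by marker label, so the result is deterministic.
    Virtual-marker seeds are ignored (they carry no image data).

    Returns ``(observations, unmatched_labels)``.  A seed whose only
    in-cap candidate component was won by a nearer seed raises
    :class:`AmbiguityError`; a seed with no in-cap candidate is
    reported unmatched with a warning.
    """
    physical = [s for s in seeds if s.marker_class != "virtual"]
    if not physical:
        return [], []
    centroids = np.array(
        [fit_centroid(volume, c, weighting) for c in components]
    ).reshape(-1, 3)

    pairs: list[tuple[float, str, int]] = []
    for seed in physical:
        if centroids.size:
            dists = np.linalg.norm(centroids - seed.seed_mm, axis=1)
            for ci in np.flatnonzero(dists <= cap_mm):
                pairs.append((float(dists[ci]), seed.label, int(ci)))
    pairs.sort()

    assigned_seed: dict[str, int] = {}
    assigned_comp: dict[int, str] = {}
    for dist, label, ci in pairs:
        if label in assigned_seed or ci in assigned_comp:
            continue
        assigned_seed[label] = ci
        assigned_comp[ci] = label

    unmatched: list[str] = []
    for seed in physical:
        if seed.label in assigned_seed:
            continue
        candidates = [
            (d, ci) for d, lbl, ci in pairs if lbl == seed.label
        ]
        if candidates:
            # every in-cap candidate was claimed by a nearer seed
            _, nearest_ci = min(candidates)
            raise AmbiguityError(
                f"seeds {assigned_comp[nearest_ci]} and {seed.label} both claim "
                f"the component at {np.round(centroids[nearest_ci], 2)} mm"
            )
        warnings.warn(
            f"marker seed {seed.label} has no segmented component within "
            f"{cap_mm} mm", stacklevel=2,
        )
        unmatched.append(seed.label)

    observations = [
        _observe(volume, components[ci], label, weighting)
        for label, ci in sorted(assigned_seed.items())
    ]
    return observations, unmatched


def localize_markers(
    volume: VoxelVolume,
    seeds: Sequence[MarkerDefinition],
    threshold: float = 800.0,
    min_voxels: int = 3,
    max_voxels: int = 500,
    cap_mm: float = 10.0,
    weighting: Literal["uniform", "intensity"] = "uniform",
) -> tuple[list[MarkerObservation], list[str]]:
    """Segment + assign in one call; see :func:`segment_markers` and
    :func:`assign_labels`."""
    components = segment_markers(volume, threshold, min_voxels, max_voxels)
    return assign_labels(volume, components, seeds, cap_mm, weighting)
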