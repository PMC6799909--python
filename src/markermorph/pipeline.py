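"""End-to-end study runs: localize -> frames -> register -> impute ->
measure -> summarize.

Two execution modes mirror the two study protocols:

* ``precision`` — every scan is a repeat of the same specimen
  (repositioned between scans).  Each scan is analyzed in its own
  world frame; virtual markers are carried into each repeat from the
  first scan via the humeral bone markers; the summary is the
  repeat-scan precision (mean of per-measurement SDs per class).
* ``longitudinal`` — scans are timepoints.  Follow-ups are rigidly
  registered to the first (reference) scan through the scapular
  landmarks, virtual markers are imputed from the bone markers, and
  the summary is the last-minus-baseline change per measurement with
  class mean +/- SD, medio-lateral tendon lengths (the retraction
  measure) singled out.

``run_study`` writes ``measurements.csv`` (one measurement per row,
one column per scan), ``summary.json`` and a ``manifest.json`` with
config hash, stage parameters, per-stage warnings and output
checksums.  ``tables_from_literature`` applies the same statistics
directly to a CSV of published measurement values, bypassing the
imaging stages.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from importlib import metadata, resources
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .errors import PipelineError, StudyValidationError
from .frames import AnatomicalFrame, humeral_frame, scapular_frame
from .localization import MarkerObservation, localize_markers
from .morphometry import (
    LongitudinalSummary,
    MeasurementRecord,
    PrecisionSummary,
    longitudinal_summary,
    measure_scan,
    pooled_precision,
    precision_summary,
)
from .rigid import VirtualMarkerModel, impute_virtual_markers, register_scan
from .volume_io import ScanRecord, StudyBundle, read_study

__all__ = [
    "ScanAnalysis",
    "StudyResult",
    "analyze_study",
    "run_study",
    "tables_from_literature",
    "load_packaged_table",
]

Mode = Literal["precision", "longitudinal"]


@dataclass
class ScanAnalysis:
    """Everything derived from one scan: observations (with imputed
    virtual markers), frames, registration and the measurement record.
    Positions are in the scan's own world frame for precision mode and
    in the reference world frame for longitudinal mode."""

    scan_id: str
    timepoint_weeks: float
    positions: dict[str, np.ndarray]
    observations: list[MarkerObservation]
    scapula: AnatomicalFrame
    humerus: AnatomicalFrame
    record: MeasurementRecord
    registration_rms_mm: float = 0.0
    imputation_rms_mm: float = 0.0
    unmatched: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)


@dataclass
class StudyResult:
    mode: Mode
    scans: list[ScanAnalysis]
    precision: PrecisionSummary | None = None
    retraction: LongitudinalSummary | None = None
    area_change: LongitudinalSummary | None = None
    length_change: LongitudinalSummary | None = None

    @property
    def records(self) -> list[MeasurementRecord]:
        return [s.record for s in self.scans]


def _localize_scan(scan: ScanRecord, params) -> tuple[list[MarkerObservation], list[str]]:
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        obs, unmatched = localize_markers(
            scan.volume,
            scan.markers,
            threshold=params.threshold_hu,
            min_voxels=params.min_voxels,
            max_voxels=params.max_voxels,
            cap_mm=params.seed_cap_mm,
            weighting=params.weighting,
        )
    messages = [str(w.message) for w in caught]
    return obs, messages if messages else []


def _mediolateral_names(bundle: StudyBundle) -> list[str]:
    """Medio-lateral (retraction) lengths: pairs anchored on a virtual
    footprint marker."""
    virtual = {d.label for d in bundle.scans[0].markers if d.marker_class == "virtual"}
    return [
        "".join(pair) for pair in bundle.measurements.lengths
        if any(lbl in virtual for lbl in pair)
    ]


def analyze_study(bundle: StudyBundle, mode: Mode = "precision") -> StudyResult:
    """Run the full analysis sequence on a loaded study bundle."""
    if mode not in ("precision", "longitudinal"):
        raise PipelineError(f"unknown mode {mode!r}")
    if not bundle.scans:
        raise PipelineError("study has no scans")

    reference = bundle.scans[0]
    virtual_defs = [d for d in reference.markers if d.marker_class == "virtual"]

    analyses: list[ScanAnalysis] = []
    model: VirtualMarkerModel | None = None
    for i, scan in enumerate(bundle.scans):
        try:
            obs, warn_msgs = _localize_scan(scan, bundle.localization)
        except Exception as exc:
            raise PipelineError(
                f"stage 'localize' failed on scan {scan.scan_id}: {exc}"
            ) from exc
        positions = {o.label: o.centroid for o in obs}
        unmatched = [
            d.label for d in scan.markers
            if d.marker_class != "virtual" and d.label not in positions
        ]
        landmarks = scan.landmarks
        reg_rms = 0.0
        if mode == "longitudinal" and i > 0:
            try:
                reg = register_scan(reference.landmarks, scan.landmarks)
            except Exception as exc:
                raise PipelineError(
                    f"stage 'register' failed on scan {scan.scan_id}: {exc}"
                ) from exc
            reg_rms = reg.rms_mm
            positions = {k: reg.transform.apply(v) for k, v in positions.items()}
            landmarks = scan.landmarks.transformed(reg.transform.apply)

        if i == 0 and virtual_defs:
            # reference scan: virtual markers sit exactly at their seeds
            for d in virtual_defs:
                positions[d.label] = d.seed_mm
            bone = {
                o.label: o.centroid for o in obs
                if any(d.label == o.label and d.marker_class == "bone"
                       for d in scan.markers)
            }
            if len(bone) >= 3:
                model = VirtualMarkerModel(
                    reference_virtual={d.label: d.seed_mm for d in virtual_defs},
                    reference_bone=bone,
                )
        imput_rms = 0.0
        if i > 0 and model is not None:
            followup_bone = {
                lbl: positions[lbl] for lbl in model.reference_bone
                if lbl in positions
            }
            try:
                imputed, imput_rms = impute_virtual_markers(model, followup_bone)
            except Exception as exc:
                raise PipelineError(
                    f"stage 'impute' failed on scan {scan.scan_id}: {exc}"
                ) from exc
            positions.update(imputed)

        try:
            scap = scapular_frame(landmarks)
            hum = humeral_frame(landmarks)
        except Exception as exc:
            raise PipelineError(
                f"stage 'frames' failed on scan {scan.scan_id}: {exc}"
            ) from exc
        record = measure_scan(
            positions,
            bundle.measurements,
            scapula=scap,
            humerus=hum,
            scan_id=scan.scan_id,
            timepoint_weeks=scan.timepoint_weeks,
        )
        analyses.append(
            ScanAnalysis(
                scan_id=scan.scan_id,
                timepoint_weeks=scan.timepoint_weeks,
                positions=positions,
                observations=obs,
                scapula=scap,
                humerus=hum,
                record=record,
                registration_rms_mm=reg_rms,
                imputation_rms_mm=imput_rms,
                unmatched=unmatched,
                warnings=warn_msgs,
            )
        )

    result = StudyResult(mode=mode, scans=analyses)
    records = result.records
    if mode == "precision" and len(records) >= 2:
        result.precision = precision_summary(records)
    elif mode == "longitudinal" and len(records) >= 2:
        ml = _mediolateral_names(bundle)
        if ml:
            result.retraction = longitudinal_summary(records, "lengths", names=ml)
        if records[0].lengths:
            result.length_change = longitudinal_summary(records, "lengths")
        if records[0].areas:
            result.area_change = longitudinal_summary(records, "areas")
    return result


# ---------------------------------------------------------------------------
# Report writing
# ---------------------------------------------------------------------------

def _measurement_frame(records: list[MeasurementRecord]) -> pd.DataFrame:
    rows = []
    for cls in ("lengths", "areas", "angles"):
        for name in records[0].values_by_class(cls):
            row = {"measurement": name, "class": cls}
            for rec in records:
                row[rec.scan_id] = rec.values_by_class(cls).get(name, np.nan)
            rows.append(row)
    return pd.DataFrame(rows).set_index("measurement")


def _summary_payload(result: StudyResult) -> dict:
    payload: dict = {"mode": result.mode, "n_scans": len(result.scans)}
    payload["scans"] = [
        {
            "id": s.scan_id,
            "timepoint_weeks": s.timepoint_weeks,
            "registration_rms_mm": s.registration_rms_mm,
            "imputation_rms_mm": s.imputation_rms_mm,
            "unmatched_markers": s.unmatched,
            "warnings": s.warnings,
        }
        for s in result.scans
    ]
    if result.precision is not None:
        payload["precision"] = result.precision.to_json_dict()
    for key, summ in (
        ("retraction_mediolateral", result.retraction),
        ("length_change", result.length_change),
        ("area_change", result.area_change),
    ):
        if summ is not None:
            payload[key] = summ.to_json_dict()
    return payload


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_study(
    config_path: str | Path,
    mode: Mode = "precision",
    out_dir: str | Path | None = None,
) -> StudyResult:
    """Load a study config, run the analysis, and (optionally) write
    the report bundle: ``measurements.csv``, ``summary.json`` and
    ``manifest.json``."""
    config_path = Path(config_path)
    bundle = read_study(config_path)
    result = analyze_study(bundle, mode=mode)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame = _measurement_frame(result.records)
        csv_path = out / "measurements.csv"
        frame.to_csv(csv_path, float_format="%.6f")
        summary_path = out / "summary.json"
        summary_path.write_text(json.dumps(_summary_payload(result), indent=1))
        try:
            version = metadata.version("markermorph")
        except metadata.PackageNotFoundError:  # pragma: no cover
            version = "unknown"
        manifest = {
            "tool": "markermorph",
            "version": version,
            "timestamp_utc": datetime.now(timezone.utc).isoformat(),
            "mode": mode,
            "config": str(config_path),
            "config_sha256": _sha256(config_path),
            "localization": bundle.localization.model_dump(),
            "warnings": {s.scan_id: s.warnings for s in result.scans},
            "outputs": {
                p.name: _sha256(p) for p in (csv_path, summary_path)
            },
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return result


# ---------------------------------------------------------------------------
# Statistics on published tables
# ---------------------------------------------------------------------------

def load_packaged_table(name: Literal["cadaver_repeat", "patient_longitudinal"]) -> pd.DataFrame:
    """Bundled example tables: per-measurement repeat-scan mean/SD
    from a cadaveric shoulder validation experiment
    (``cadaver_repeat``) and four-visit longitudinal measurements from
    a patient after arthroscopic rotator cuff repair
    (``patient_longitudinal``)."""
    fname = {
        "cadaver_repeat": "cadaver_repeat_table.csv",
        "patient_longitudinal": "patient_longitudinal_table.csv",
    }[name]
    with resources.files("markermorph.data").joinpath(fname).open() as fh:
        return pd.read_csv(fh)


def _parse_table(path_or_frame) -> pd.DataFrame:
    if isinstance(path_or_frame, pd.DataFrame):
        df = path_or_frame.copy()
    else:
        try:
            df = pd.read_csv(path_or_frame)
        except Exception as exc:
            raise StudyValidationError(
                f"could not parse measurement table {path_or_frame}: {exc}"
            ) from exc
    if df.empty:
        raise StudyValidationError("measurement table is empty")
    required = {"measurement", "class"}
    if not required <= set(df.columns):
        raise StudyValidationError(
            f"measurement table needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    return df


def tables_from_literature(
    values: "str | Path | pd.DataFrame",
    mode: Mode = "precision",
    measurement_class: str = "lengths",
    group: str | None = None,
) -> PrecisionSummary | LongitudinalSummary:
    """Run the statistics layer directly on a table of published
    measurement values, bypassing the imaging stages.

    ``precision`` expects columns ``measurement, class, sd`` (and
    optionally ``mean``) and pools the SDs per class.  ``longitudinal``
    expects ``measurement, class`` plus one ``week_<w>`` column per
    timepoint, and summarizes last-minus-first changes for the rows of
    ``measurement_class`` (optionally restricted to ``group``, e.g.
    ``mediolateral``).
    """
    df = _parse_table(values)
    if mode == "precision":
        if "sd" not in df.columns:
            raise StudyValidationError("precision table needs an 'sd' column")
        table = df.set_index("measurement")[
            [c for c in ("class", "mean", "sd") if c in df.columns]
        ]
        if "mean" not in table.columns:
            table["mean"] = np.nan
        pooled = {
            cls: pooled_precision(grp["sd"])
            for cls, grp in table.groupby("class", sort=False)
        }
        return PrecisionSummary(table=table, pooled=pooled, n_scans=0)

    if mode == "longitudinal":
        week_cols = sorted(
            (c for c in df.columns if c.startswith("week_")),
            key=lambda c: float(c.split("_", 1)[1]),
        )
        if len(week_cols) < 2:
            raise StudyValidationError(
                "longitudinal table needs >=2 'week_<w>' columns"
            )
        sub = df[df["class"] == measurement_class]
        if group is not None:
            if "group" not in df.columns:
                raise StudyValidationError("table has no 'group' column")
            sub = sub[sub["group"] == group]
        if sub.empty:
            raise StudyValidationError(
                f"no rows of class {measurement_class!r}"
                + (f" and group {group!r}" if group else "")
            )
        baseline, final = week_cols[0], week_cols[-1]
        changes = {
            str(row["measurement"]): float(row[final]) - float(row[baseline])
            for _, row in sub.iterrows()
        }
        vals = np.array(list(changes.values()))
        return LongitudinalSummary(
            measurement_class=measurement_class,
            changes=changes,
            mean=float(vals.mean()),
            sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0,
            baseline_weeks=float(baseline.split("_", 1)[1]),
            final_weeks=float(final.split("_", 1)[1]),
        )
    raise PipelineError(f"unknown mode {mode!r}")
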