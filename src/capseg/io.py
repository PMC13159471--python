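"""On-disk layout, result writers, and the end-to-end run.

A pullback directory holds one multi-page TIFF per channel (page = frame) and
a JSON sidecar with the scan geometry:

    reflectance.tif  birefringence.tif  depolarization.tif  labels.tif
    metadata.json    [ground_truth.json]

Measurements are exchanged as CSV (one row per frame, fixed 6-significant-
digit float formatting so identical runs produce identical bytes) and lesion
summaries as JSON.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import tifffile

from .model import CapSegParams, PolarimetricFrame, ScanGeometry, SegmentationMask
from .phantom import GroundTruth, PullbackPhantom
from .pipeline import CapMeasurement, measure_frame
from .volumetric import (
    LesionSummary,
    find_mla,
    lumen_area,
    plaque_arc_fraction,
    select_lesion_segment,
    summarize_lesion,
)

__all__ = [
    "PullbackReadError",
    "RunConfig",
    "write_pullback",
    "read_pullback",
    "write_measurements_csv",
    "read_measurements_csv",
    "write_lesion_json",
    "read_readings_csv",
    "run_end_to_end",
]

logger = logging.getLogger(__name__)

MEASUREMENTS_SCHEMA = "capseg-measurements v1"
_CHANNELS = ("reflectance", "birefringence", "depolarization")

_CSV_COLUMNS = (
    "frame_index", "mct_um", "inner_x_um", "inner_y_um", "outer_x_um", "outer_y_um",
    "mean_cap_birefringence", "mean_cap_depolarization", "cap_pixel_count",
    "measurable_angle_count", "status",
)


class PullbackReadError(RuntimeError):
    """Raised when a pullback directory is missing files or inconsistent."""


@dataclasses.dataclass
class RunConfig:
    """Configuration of an end-to-end run."""

    input_dir: Path
    output_dir: Path
    params: CapSegParams = dataclasses.field(default_factory=CapSegParams)
    lesion_range: Optional[Tuple[int, int]] = None   # explicit lesion segment
    auto_lesion: bool = False                        # automatic segment selection
    seed: int = 0


def _geometry_to_json(g: ScanGeometry) -> Dict:
    return {
        "n_alines": g.n_alines,
        "axial_pitch_um": g.axial_pitch,
        "catheter_offset_um": g.catheter_offset,
        "frame_pitch_mm": g.frame_pitch,
        "angle_origin_rad": g.angle_origin,
    }


def _geometry_from_json(d: Dict) -> ScanGeometry:
    try:
        return ScanGeometry(
            n_alines=int(d["n_alines"]),
            axial_pitch=float(d["axial_pitch_um"]),
            catheter_offset=float(d.get("catheter_offset_um", 0.0)),
            frame_pitch=float(d.get("frame_pitch_mm", 0.2)),
            angle_origin=float(d.get("angle_origin_rad", 0.0)),
        )
    except KeyError as exc:
        raise PullbackReadError(f"metadata.json missing required key {exc}") from exc


def write_pullback(
    directory,
    frames: Sequence[PolarimetricFrame],
    masks: Sequence[SegmentationMask],
    geometry: ScanGeometry,
    ground_truths: Optional[Sequence[GroundTruth]] = None,
    mla_index: Optional[int] = None,
) -> Path:
    """Write a pullback to the TIFF+JSON directory layout."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in _CHANNELS:
        stack = np.stack([getattr(f, name) for f in frames]).astype(np.float32)
        tifffile.imwrite(directory / f"{name}.tif", stack, photometric="minisblack")
    tifffile.imwrite(directory / "labels.tif", np.stack([m.labels for m in masks]),
                     photometric="minisblack")
    (directory / "metadata.json").write_text(
        json.dumps(_geometry_to_json(geometry), indent=2, sort_keys=True) + "\n"
    )
    if ground_truths is not None:
        payload = {
            "mla_index": mla_index,
            "frames": [
                {
                    "true_mct_um": _jsonf(g.true_mct),
                    "lumen_area_mm2": _jsonf(g.lumen_area_mm2),
                    "plaque_arc_rad": list(g.plaque_arc) if g.plaque_arc else None,
                    "resolution_warning": g.resolution_warning,
                    "theta_dense_rad": [_jsonf(v) for v in g.theta_dense],
                    "inner_radius_dense_um": [_jsonf(v) for v in g.inner_radius_dense],
                    "outer_radius_dense_um": [_jsonf(v) for v in g.outer_radius_dense],
                }
                for g in ground_truths
            ],
        }
        (directory / "ground_truth.json").write_text(
            json.dumps(payload, sort_keys=True) + "\n"
        )
    return directory


def write_phantom_pullback(directory, pullback: PullbackPhantom) -> Path:
    return write_pullback(
        directory, pullback.frames, pullback.masks, pullback.geometry,
        ground_truths=pullback.ground_truths, mla_index=pullback.mla_index,
    )


def _read_stacks(directory) -> Tuple[Dict[str, np.ndarray], ScanGeometry]:
    directory = Path(directory)
    meta_path = directory / "metadata.json"
    if not meta_path.exists():
        raise PullbackReadError(f"missing metadata file: {meta_path}")
    try:
        geometry = _geometry_from_json(json.loads(meta_path.read_text()))
    except json.JSONDecodeError as exc:
        raise PullbackReadError(f"malformed metadata file {meta_path}: {exc}") from exc

    stacks = {}
    for name in _CHANNELS + ("labels",):
        path = directory / f"{name}.tif"
        if not path.exists():
            kind = "mask" if name == "labels" else "channel"
            raise PullbackReadError(f"missing {kind} file: {path}")
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        stacks[name] = arr

    n_pages = {name: s.shape[0] for name, s in stacks.items()}
    if len(set(n_pages.values())) != 1:
        raise PullbackReadError(f"page-count mismatch across channels: {n_pages}")
    for name, s in stacks.items():
        if s.shape[1] != geometry.n_alines:
            raise PullbackReadError(
                f"{name}.tif has {s.shape[1]} A-lines but metadata declares {geometry.n_alines}"
            )
    return stacks, geometry


def _frame_pair(stacks: Dict[str, np.ndarray], i: int, geometry: ScanGeometry):
    frame = PolarimetricFrame(
        stacks["reflectance"][i], stacks["birefringence"][i],
        stacks["depolarization"][i], geometry,
    )
    mask = SegmentationMask(stacks["labels"][i].astype(np.uint8), geometry)
    return frame, mask


def read_pullback(directory) -> Tuple[List[PolarimetricFrame], List[SegmentationMask], ScanGeometry]:
    """Read and validate a pullback directory.

    Strict: any invalid frame raises.  ``run_end_to_end`` uses a per-frame
    tolerant path instead so one corrupted frame cannot abort a whole run.
    """
    stacks, geometry = _read_stacks(directory)
    frames, masks = [], []
    for i in range(stacks["reflectance"].shape[0]):
        frame, mask = _frame_pair(stacks, i, geometry)
        frames.append(frame)
        masks.append(mask)
    return frames, masks, geometry


def _fmt(value) -> str:
    """Fixed 6-significant-digit float formatting for deterministic output."""
    if value is None:
        return ""
    v = float(value)
    if np.isnan(v):
        return ""
    return f"{v:.6g}"


def _jsonf(value):
    if value is None:
        return None
    v = float(value)
    return None if np.isnan(v) else float(f"{v:.6g}")


def write_measurements_csv(measurements: Sequence[CapMeasurement], path) -> Path:
    """Write per-frame measurements as deterministic CSV with a schema header."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(f"# {MEASUREMENTS_SCHEMA}\n")
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_CSV_COLUMNS)
        for m in measurements:
            if m.mct_pair is not None:
                (ix, iy), (ox, oy) = m.mct_pair
            else:
                ix = iy = ox = oy = None
            writer.writerow(
                [
                    m.frame_index, _fmt(m.mct), _fmt(ix), _fmt(iy), _fmt(ox), _fmt(oy),
                    _fmt(m.mean_cap_birefringence), _fmt(m.mean_cap_depolarization),
                    m.cap_pixel_count, m.measurable_angle_count, m.status,
                ]
            )
    return path


def read_measurements_csv(path) -> "pandas.DataFrame":
    import pandas as pd

    return pd.read_csv(path, comment="#")


def write_lesion_json(summary: Optional[LesionSummary], path, extra: Optional[Dict] = None) -> Path:
    path = Path(path)
    if summary is None:
        payload: Dict = {"status": "no measurable cap"}
    else:
        payload = {
            "status": "ok",
            "frame_range": list(summary.frame_range),
            "mla_frame": summary.mla_frame,
            "mla_area_mm2": _jsonf(summary.mla_area),
            "lesion_length_mm": _jsonf(summary.lesion_length),
            "mean_mct_um": _jsonf(summary.mean_mct),
            "overall_mct_um": _jsonf(summary.overall_mct),
            "mean_birefringence": _jsonf(summary.mean_birefringence),
            "mean_depolarization": _jsonf(summary.mean_depolarization),
            "n_frames_with_cap": summary.n_frames_with_cap,
        }
    if extra:
        payload.update(extra)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_readings_csv(path) -> Dict[str, Dict[object, List[float]]]:
    """Read a repeated-readings CSV (columns: case_id, observer, repetition,
    mct_um) into ``{observer: {case_id: [readings in repetition order]}}``."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    required = {"case_id", "observer", "repetition", "mct_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"readings CSV missing columns: {sorted(missing)}")
    out: Dict[str, Dict[object, List[float]]] = {}
    for (obs, case), grp in df.groupby(["observer", "case_id"], sort=True):
        grp = grp.sort_values("repetition")
        out.setdefault(str(obs), {})[case] = [float(v) for v in grp["mct_um"]]
    return out


def run_end_to_end(config: RunConfig) -> int:
    """Measure every frame of a pullback and optionally summarize a lesion.

    Frame-level failures are logged and reported as error rows; only an
    unreadable input aborts the run.  Returns the number of failed frames.
    """
    stacks, geometry = _read_stacks(config.input_dir)
    n_frames = stacks["reflectance"].shape[0]
    config.output_dir.mkdir(parents=True, exist_ok=True)

    measurements: List[CapMeasurement] = []
    masks: List[Optional[SegmentationMask]] = []
    n_failed = 0
    for i in range(n_frames):
        try:
            frame, mask = _frame_pair(stacks, i, geometry)
            m = measure_frame(frame, mask, config.params, frame_index=i)
        except Exception as exc:  # frame isolation: one bad frame never kills the run
            logger.error("frame %d failed: %s", i, exc)
            m = CapMeasurement(i, None, None, 0, float("nan"), float("nan"), 0,
                               status=f"error: {exc}")
            mask = None
            n_failed += 1
        logger.info("frame %d: %s", i, m.status if not m.has_cap else f"mct={m.mct:.1f} um")
        measurements.append(m)
        masks.append(mask)
    write_measurements_csv(measurements, config.output_dir / "measurements.csv")

    if config.lesion_range is not None or config.auto_lesion:
        areas, reliable = zip(
            *(lumen_area(m, geometry) if m is not None else (float("nan"), False) for m in masks)
        )
        mla = find_mla(areas, reliable)
        fractions = [plaque_arc_fraction(m) if m is not None else 0.0 for m in masks]
        (start, end), no_ref = select_lesion_segment(
            fractions, mla, explicit_range=config.lesion_range
        )
        summary = summarize_lesion(
            measurements, (start, end), geometry, mla_frame=mla, mla_area=areas[mla]
        )
        write_lesion_json(
            summary, config.output_dir / "lesion.json",
            extra={"no_healthy_reference": no_ref} if no_ref else None,
        )
    return n_failed
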