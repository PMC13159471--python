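"""Lesion-level (volumetric) cap analysis.

A lesion is a contiguous pullback segment anchored on the frame with the
minimum lumen area (MLA) and extending proximally and distally toward
minimally diseased cross-sections.  Within the segment, per-frame cap
measurements are aggregated into the four volumetric quantities compared
between patient groups: mean minimum cap thickness, overall minimum cap
thickness, mean cap birefringence (restricted to cap pixels with
depolarization < 0.2) and mean cap depolarization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .model import ScanGeometry, SegmentationMask
from .pipeline import CapMeasurement, delineate_plaque_angles, lumen_contour

__all__ = [
    "LesionSummary",
    "lumen_area",
    "find_mla",
    "plaque_arc_fraction",
    "select_lesion_segment",
    "summarize_lesion",
]


@dataclass
class LesionSummary:
    """Volumetric cap aggregates over one lesion segment."""

    frame_range: Tuple[int, int]           # inclusive
    mla_frame: int
    mla_area: float                        # mm²
    lesion_length: float                   # mm
    mean_mct: float                        # µm, mean over frames with a cap
    overall_mct: float                     # µm, min over frames with a cap
    mean_birefringence: float
    mean_depolarization: float
    n_frames_with_cap: int


def lumen_area(mask: SegmentationMask, geometry: ScanGeometry) -> Tuple[float, bool]:
    """Lumen cross-sectional area in mm² from the polygonal lumen contour.

    Absent contour angles (e.g. guidewire shadow) are interpolated circularly.
    Returns ``(area_mm2, reliable)``; the area is flagged unreliable when more
    than 25% of angles lack a contour.
    """
    contour = lumen_contour(mask)
    finite = np.isfinite(contour)
    if not finite.any():
        return float("nan"), False
    reliable = finite.mean() >= 0.75
    n = geometry.n_alines
    idx = np.arange(n)
    if not finite.all():
        # circular linear interpolation across the gaps
        good = np.flatnonzero(finite)
        contour = np.interp(idx, good, contour[good], period=n)
    r = geometry.radius_of(contour)
    theta = geometry.angle_of(idx)
    x, y = r * np.cos(theta), r * np.sin(theta)
    area_um2 = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    return float(area_um2) / 1e6, bool(reliable)


def find_mla(areas: Sequence[float], reliable: Optional[Sequence[bool]] = None) -> int:
    """Index of the minimum-lumen-area frame; ties go to the lowest index and
    unreliable frames are skipped."""
    areas = np.asarray(areas, dtype=float)
    valid = np.isfinite(areas)
    if reliable is not None:
        valid &= np.asarray(reliable, dtype=bool)
    if not valid.any():
        raise ValueError("no valid lumen areas")
    masked = np.where(valid, areas, np.inf)
    return int(np.argmin(masked))


def plaque_arc_fraction(mask: SegmentationMask) -> float:
    """Fraction of the circumference carrying plaque shadow."""
    return len(delineate_plaque_angles(mask)) / mask.geometry.n_alines


def select_lesion_segment(
    plaque_fractions: Sequence[float],
    mla: int,
    explicit_range: Optional[Tuple[int, int]] = None,
    k_healthy: int = 3,
    max_plaque_fraction: float = 30.0 / 360.0,
) -> Tuple[Tuple[int, int], bool]:
    """Choose the lesion frame range around the MLA.

    Two policies: an ``explicit_range`` supplied by the analyst (must contain
    the MLA), or automatic extension from the MLA in both directions until
    ``k_healthy`` consecutive frames have plaque angular extent below
    ``max_plaque_fraction`` of the circumference; the first frame of that
    minimally diseased run is included.  Returns ``((start, end),
    no_healthy_reference)`` where the flag marks a side clamped at the
    pullback end without finding a healthy run.
    """
    n = len(plaque_fractions)
    if not (0 <= mla < n):
        raise ValueError(f"mla index {mla} outside pullback of {n} frames")
    if explicit_range is not None:
        s, e = explicit_range
        if not (s <= mla <= e):
            raise ValueError(f"explicit range {explicit_range} does not contain MLA frame {mla}")
        return (max(s, 0), min(e, n - 1)), False

    healthy = np.asarray(plaque_fractions, dtype=float) < max_plaque_fraction
    no_ref = False

    def extend(direction: int) -> int:
        run = 0
        last = mla
        i = mla + direction
        while 0 <= i < n:
            run = run + 1 if healthy[i] else 0
            if run == k_healthy:
                return i - direction * (k_healthy - 1)  # first frame of the run
            i += direction
        nonlocal no_ref
        no_ref = True
        return 0 if direction < 0 else n - 1

    start = extend(-1)
    end = extend(+1)
    return (start, end), no_ref


def summarize_lesion(
    measurements: List[CapMeasurement],
    frame_range: Tuple[int, int],
    geometry: ScanGeometry,
    mla_frame: int = 0,
    mla_area: float = float("nan"),
    polarimetry_pooling: str = "pixel",
) -> Optional[LesionSummary]:
    """Aggregate per-frame cap measurements over a lesion segment.

    ``mean_mct`` averages only frames with a measurable cap; ``overall_mct``
    is the minimum of those.  Polarimetric means are pixel-weighted over the
    whole cap volume by default (``polarimetry_pooling="pixel"``);
    ``"frame"`` averages the per-frame means instead.  Returns None when no
    frame in the range has a measurable cap.
    """
    if polarimetry_pooling not in ("pixel", "frame"):
        raise ValueError("polarimetry_pooling must be 'pixel' or 'frame'")
    s, e = frame_range
    in_range = [m for m in measurements if s <= m.frame_index <= e]
    with_cap = [m for m in in_range if m.has_cap]
    if not with_cap:
        return None
    mcts = np.array([m.mct for m in with_cap])
    if polarimetry_pooling == "pixel":
        bn = sum(m.biref_n for m in with_cap)
        dn = sum(m.depol_n for m in with_cap)
        mean_b = sum(m.biref_sum for m in with_cap) / bn if bn else float("nan")
        mean_d = sum(m.depol_sum for m in with_cap) / dn if dn else float("nan")
    else:
        bs = [m.mean_cap_birefringence for m in with_cap if np.isfinite(m.mean_cap_birefringence)]
        ds = [m.mean_cap_depolarization for m in with_cap if np.isfinite(m.mean_cap_depolarization)]
        mean_b = float(np.mean(bs)) if bs else float("nan")
        mean_d = float(np.mean(ds)) if ds else float("nan")
    return LesionSummary(
        frame_range=(s, e),
        mla_frame=mla_frame,
        mla_area=mla_area,
        lesion_length=(e - s) * geometry.frame_pitch,
        mean_mct=float(mcts.mean()),
        overall_mct=float(mcts.min()),
        mean_birefringence=mean_b,
        mean_depolarization=mean_d,
        n_frames_with_cap=len(with_cap),
    )
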