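"""Per-frame fibrous-cap segmentation and minimum cap thickness.

The pipeline mirrors how a cross-section is processed in practice:

1. delineate the plaque from the plaque-shadow label of the segmentation mask;
2. trace the lumen contour and estimate the beam-to-surface incidence angle;
3. drop A-lines at grazing incidence (tangent within ±5° of the beam) and
   under the guidewire shadow;
4. classify cap pixels with the combined polarimetric criterion
   ``depolarization < 0.2 OR reflectance > 35 dB`` (both strict);
5. extract per-A-line inner (lumen–cap intersection) and outer (deepest pixel
   of the surface-anchored cap run) boundary points;
6. report the minimum Euclidean distance between the inner and outer
   boundaries in Cartesian µm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.signal import savgol_filter
from scipy.spatial.distance import cdist

from .model import (
    LABEL_GUIDEWIRE,
    LABEL_INTIMA,
    LABEL_MEDIA,
    LABEL_PLAQUE_SHADOW,
    CapSegParams,
    PolarimetricFrame,
    ScanGeometry,
    SegmentationMask,
    polar_points_to_cartesian,
    validate_pair,
)

__all__ = [
    "MeasurableRegion",
    "CapBoundary",
    "CapMeasurement",
    "delineate_plaque_angles",
    "lumen_contour",
    "smooth_contour",
    "surface_incidence_angles",
    "measurable_region",
    "cap_pixel_mask",
    "cap_boundaries",
    "minimum_cap_thickness",
    "measure_frame",
]

_TISSUE_LABELS = (LABEL_INTIMA, LABEL_MEDIA, LABEL_PLAQUE_SHADOW)


@dataclass
class MeasurableRegion:
    """Plaque A-lines split into measurable and excluded subsets."""

    plaque_angles: np.ndarray
    excluded_incidence: np.ndarray
    excluded_guidewire: np.ndarray
    measurable_angles: np.ndarray
    incidence_deg: np.ndarray  # per A-line, NaN where undefined


@dataclass
class CapBoundary:
    """Per-A-line cap boundary points in Cartesian µm.

    ``angles`` are the A-line indices that produced a boundary sample;
    ``inner_points[i]`` / ``outer_points[i]`` correspond to ``angles[i]``.
    Depth indices (pixels) are retained for diagnostics.
    """

    angles: np.ndarray
    inner_points: np.ndarray     # (n, 2) µm
    outer_points: np.ndarray     # (n, 2) µm
    inner_depths: np.ndarray     # (n,) pixels
    outer_depths: np.ndarray

    def __len__(self) -> int:
        return len(self.angles)


@dataclass
class CapMeasurement:
    """Cap metrics of a single cross-section.

    ``mct`` is the minimum cap thickness in µm, or None when the frame has no
    measurable cap.  ``mean_cap_birefringence`` is restricted to cap pixels
    with depolarization below the threshold (birefringence is unreliable where
    the light is depolarized); ``mean_cap_depolarization`` covers all cap
    pixels.  The ``*_sum``/``*_n`` accumulators allow exact pixel-weighted
    pooling across frames.
    """

    frame_index: int
    mct: Optional[float]
    mct_pair: Optional[Tuple[Tuple[float, float], Tuple[float, float]]]
    cap_pixel_count: int
    mean_cap_birefringence: float
    mean_cap_depolarization: float
    measurable_angle_count: int
    status: str = "ok"
    biref_sum: float = 0.0
    biref_n: int = 0
    depol_sum: float = 0.0
    depol_n: int = 0

    @property
    def has_cap(self) -> bool:
        return self.mct is not None


def delineate_plaque_angles(mask: SegmentationMask) -> np.ndarray:
    """A-line indices containing at least one plaque-shadow pixel."""
    return np.flatnonzero((mask.labels == LABEL_PLAQUE_SHADOW).any(axis=1))


def lumen_contour(mask: SegmentationMask) -> np.ndarray:
    """Per-A-line tissue-surface depth (pixels): the first depth index carrying
    a tissue label (intima, media or plaque shadow) beyond the lumen.

    Returns a float array of length ``n_alines`` with NaN where no surface is
    defined (A-line entirely lumen/background, or fully shadowed).
    """
    labels = mask.labels
    tissue = np.isin(labels, _TISSUE_LABELS)
    has_tissue = tissue.any(axis=1)
    first = np.argmax(tissue, axis=1).astype(float)
    first[~has_tissue] = np.nan
    return first


def smooth_contour(contour: np.ndarray, window: int) -> np.ndarray:
    """Circular contour smoothing prior to tangent estimation.

    Uses a quadratic Savitzky–Golay filter with circular wrap: it suppresses
    per-A-line jitter like a moving average but is exact for locally quadratic
    depth profiles, so it does not bias the surface tangent where the contour
    curves (a plain moving average flattens curved contours and distorts
    incidence angles near grazing).  NaN entries (absent contour) are bridged
    by circular interpolation for the fit and restored to NaN afterwards.
    """
    if window <= 1:
        return contour.copy()
    finite = np.isfinite(contour)
    if not finite.any():
        return contour.copy()
    vals = contour
    if not finite.all():
        n = contour.size
        good = np.flatnonzero(finite)
        vals = np.interp(np.arange(n), good, contour[good], period=n)
    w = min(window, vals.size if vals.size % 2 else vals.size - 1)
    out = savgol_filter(vals, w, 2, mode="wrap")
    out[~finite] = np.nan
    return out


def surface_incidence_angles(contour: np.ndarray, geometry: ScanGeometry) -> np.ndarray:
    """Unsigned acute angle (degrees, [0, 90]) between the tissue-surface
    tangent and the beam direction at each A-line.

    The tangent is the central difference of the neighbouring (smoothed)
    contour points in Cartesian coordinates; the beam is the radial unit
    vector.  90° means the beam hits the surface perpendicularly (a circular
    lumen centred on the catheter); 0° is grazing incidence.  NaN where the
    contour or either circular neighbour is undefined.
    """
    n = geometry.n_alines
    idx = np.arange(n)
    pts = polar_points_to_cartesian(idx, contour, geometry)
    prev_pts = np.roll(pts, 1, axis=0)
    next_pts = np.roll(pts, -1, axis=0)
    tangent = next_pts - prev_pts
    theta = geometry.angle_of(idx)
    beam = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    tnorm = np.linalg.norm(tangent, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.abs(np.sum(tangent * beam, axis=1)) / tnorm
    ang = np.degrees(np.arccos(np.clip(cosang, 0.0, 1.0)))
    # incidence = angle between tangent and beam measured from the tangent;
    # arccos(|cos|) already yields the acute angle between the two lines
    undefined = (
        ~np.isfinite(contour)
        | ~np.isfinite(np.roll(contour, 1))
        | ~np.isfinite(np.roll(contour, -1))
        | (tnorm == 0)
    )
    ang[undefined] = np.nan
    return ang


def measurable_region(
    mask: SegmentationMask, incidence: np.ndarray, params: CapSegParams
) -> MeasurableRegion:
    """Split the plaque angles into measurable and excluded subsets.

    A plaque A-line is excluded when the surface incidence is undefined or at
    or below the grazing threshold, or when it carries any guidewire-shadow
    pixel.
    """
    plaque = delineate_plaque_angles(mask)
    guidewire_all = np.flatnonzero((mask.labels == LABEL_GUIDEWIRE).any(axis=1))
    inc = incidence[plaque] if len(plaque) else np.empty(0)
    grazing = np.zeros(mask.geometry.n_alines, dtype=bool)
    grazing[plaque] = ~np.isfinite(inc) | (inc <= params.incidence_exclusion_deg)
    gw = np.zeros(mask.geometry.n_alines, dtype=bool)
    gw[guidewire_all] = True
    excluded_incidence = plaque[grazing[plaque] & ~gw[plaque]]
    excluded_guidewire = plaque[gw[plaque]]
    keep = ~grazing[plaque] & ~gw[plaque]
    return MeasurableRegion(
        plaque_angles=plaque,
        excluded_incidence=excluded_incidence,
        excluded_guidewire=excluded_guidewire,
        measurable_angles=plaque[keep],
        incidence_deg=incidence,
    )


def cap_pixel_mask(
    frame: PolarimetricFrame,
    region: MeasurableRegion,
    contour: np.ndarray,
    params: CapSegParams,
) -> np.ndarray:
    """Boolean polar mask of fibrous-cap pixels.

    A pixel (theta, z) is cap iff theta is measurable, z is at or below the
    tissue surface, and ``depolarization < depol_threshold OR reflectance >
    refl_threshold`` (strict, per the printed criterion).  NaN-valued pixels
    never qualify.
    """
    n_alines, n_depth = frame.shape
    measurable = np.zeros(n_alines, dtype=bool)
    measurable[region.measurable_angles] = True
    depth = np.arange(n_depth)
    below_surface = np.isfinite(contour)[:, None] & (
        depth[None, :] >= np.nan_to_num(contour, nan=np.inf)[:, None]
    )
    d, r = frame.depolarization, frame.reflectance
    crit = (np.isfinite(d) & (d < params.depol_threshold)) | (
        np.isfinite(r) & (r > params.refl_threshold)
    )
    return measurable[:, None] & below_surface & crit


def _run_end(cap_row: np.ndarray, start: int, max_gap: int) -> int:
    """Deepest cap pixel of the run starting at ``start``, tolerating gaps of
    at most ``max_gap`` consecutive non-cap pixels."""
    if max_gap == 0:
        tail = cap_row[start:]
        stop = np.argmax(~tail) if not tail.all() else tail.size
        return start + int(stop) - 1
    end = start
    gap = 0
    for z in range(start, cap_row.size):
        if cap_row[z]:
            end = z
            gap = 0
        else:
            gap += 1
            if gap > max_gap:
                break
    return end


def cap_boundaries(
    cap_mask: np.ndarray,
    contour: np.ndarray,
    region: MeasurableRegion,
    geometry: ScanGeometry,
    params: CapSegParams,
) -> CapBoundary:
    """Per-A-line inner/outer cap boundary points.

    For each measurable angle whose surface pixel is cap, the inner point is
    the lumen–cap intersection (raw contour) and the outer point the deepest
    pixel of the surface-anchored cap run.  Angles with no cap at the surface
    are omitted; deep isolated cap-positive pixels beyond the allowed gap are
    ignored.
    """
    angles, inner_d, outer_d = [], [], []
    for a in region.measurable_angles:
        c = contour[a]
        if not np.isfinite(c):
            continue
        s = int(c)
        if not cap_mask[a, s]:
            continue
        angles.append(a)
        inner_d.append(s)
        outer_d.append(_run_end(cap_mask[a], s, params.min_run_gap))
    angles = np.asarray(angles, dtype=int)
    inner_d = np.asarray(inner_d, dtype=float)
    outer_d = np.asarray(outer_d, dtype=float)
    inner_pts = polar_points_to_cartesian(angles, inner_d, geometry) if len(angles) else np.empty((0, 2))
    outer_pts = polar_points_to_cartesian(angles, outer_d, geometry) if len(angles) else np.empty((0, 2))
    return CapBoundary(angles, inner_pts, outer_pts, inner_d, outer_d)


def minimum_cap_thickness(
    boundary: CapBoundary,
) -> Tuple[float, Tuple[Tuple[float, float], Tuple[float, float]], Tuple[int, int]]:
    """Smallest Euclidean distance (µm) between any inner and any outer
    boundary point, with the realizing pair.

    Exhaustive over all inner x outer pairs; ties broken lexicographically on
    (inner index, outer index) within ``boundary.angles`` order.
    """
    if len(boundary) == 0:
        raise ValueError("empty cap boundary: no measurable cap")
    dmat = cdist(boundary.inner_points, boundary.outer_points)
    flat = int(np.argmin(dmat))  # first occurrence = lexicographic tie-break
    i, j = divmod(flat, dmat.shape[1])
    pair = (tuple(boundary.inner_points[i]), tuple(boundary.outer_points[j]))
    return float(dmat[i, j]), pair, (i, j)


def measure_frame(
    frame: PolarimetricFrame,
    mask: SegmentationMask,
    params: Optional[CapSegParams] = None,
    frame_index: int = 0,
) -> CapMeasurement:
    """Run the full per-frame pipeline and summarize the cap.

    Never raises for an unmeasurable frame: the returned measurement carries
    ``mct=None`` and a status of ``"no plaque"`` or ``"no measurable cap"``.
    """
    if params is None:
        params = CapSegParams()
    validate_pair(frame, mask)
    contour = lumen_contour(mask)
    smoothed = smooth_contour(contour, params.contour_smoothing_window)
    incidence = surface_incidence_angles(smoothed, frame.geometry)
    region = measurable_region(mask, incidence, params)

    if len(region.plaque_angles) == 0:
        return CapMeasurement(frame_index, None, None, 0, float("nan"), float("nan"), 0,
                              status="no plaque")

    cap = cap_pixel_mask(frame, region, contour, params)
    boundary = cap_boundaries(cap, contour, region, frame.geometry, params)
    n_meas = len(region.measurable_angles)
    if len(boundary) == 0:
        return CapMeasurement(frame_index, None, None, int(cap.sum()), float("nan"),
                              float("nan"), n_meas, status="no measurable cap")

    mct, pair, _ = minimum_cap_thickness(boundary)

    d = frame.depolarization[cap]
    b = frame.birefringence[cap]
    d_ok = np.isfinite(d)
    b_ok = np.isfinite(b) & d_ok & (d < params.depol_threshold)
    depol_sum, depol_n = float(d[d_ok].sum()), int(d_ok.sum())
    biref_sum, biref_n = float(b[b_ok].sum()), int(b_ok.sum())
    return CapMeasurement(
        frame_index=frame_index,
        mct=mct,
        mct_pair=pair,
        cap_pixel_count=int(cap.sum()),
        mean_cap_birefringence=biref_sum / biref_n if biref_n else float("nan"),
        mean_cap_depolarization=depol_sum / depol_n if depol_n else float("nan"),
        measurable_angle_count=n_meas,
        biref_sum=biref_sum,
        biref_n=biref_n,
        depol_sum=depol_sum,
        depol_n=depol_n,
    )
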