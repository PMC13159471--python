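"""Shared data model and geometry conventions for intravascular PS-OCT frames.

A frame is a set of A-lines (radial depth scans) acquired over one catheter
rotation.  All images are stored in polar coordinates with shape
``(n_alines, n_depth)``: axis 0 is the rotation angle, axis 1 the depth along
the beam.  Thickness measurements are carried out in Cartesian coordinates
(micrometres), with the origin at the catheter rotation axis; A-line index 0
points along ``angle_origin`` and indices increase counter-clockwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

__all__ = [
    "LABEL_BACKGROUND",
    "LABEL_LUMEN",
    "LABEL_INTIMA",
    "LABEL_MEDIA",
    "LABEL_GUIDEWIRE",
    "LABEL_PLAQUE_SHADOW",
    "VALID_LABELS",
    "ScanGeometry",
    "PolarimetricFrame",
    "SegmentationMask",
    "CapSegParams",
    "ValidationError",
    "polar_to_cartesian",
    "polar_points_to_cartesian",
    "validate_pair",
]

# Six-class segmentation label convention of the upstream mask network.
LABEL_BACKGROUND = 0
LABEL_LUMEN = 1
LABEL_INTIMA = 2
LABEL_MEDIA = 3
LABEL_GUIDEWIRE = 4
LABEL_PLAQUE_SHADOW = 5
VALID_LABELS = frozenset(range(6))


class ValidationError(ValueError):
    """Raised when a frame/mask pair violates the data-model contract."""


@dataclass(frozen=True)
class ScanGeometry:
    """Acquisition geometry of one pullback.

    Parameters
    ----------
    n_alines:
        Number of A-lines (depth scans) per frame; the clinical system
        acquires 1024 per rotation.
    axial_pitch:
        Depth sampling pitch in tissue, micrometres per pixel.  Required —
        thickness in µm is the headline output, so no silent default exists.
    catheter_offset:
        Radial distance (µm) from the rotation axis to the first depth pixel.
    frame_pitch:
        Longitudinal spacing between consecutive frames, millimetres.  The
        clinical system pulls back at 20 mm/s while rotating at 100 fps,
        giving 0.2 mm.
    angle_origin:
        Angle (radians) of A-line index 0.
    """

    n_alines: int
    axial_pitch: float
    catheter_offset: float = 0.0
    frame_pitch: float = 0.2
    angle_origin: float = 0.0

    def __post_init__(self) -> None:
        if self.n_alines < 8:
            raise ValueError(f"n_alines must be >= 8, got {self.n_alines}")
        if self.axial_pitch <= 0:
            raise ValueError(f"axial_pitch must be > 0, got {self.axial_pitch}")
        if self.catheter_offset < 0:
            raise ValueError(f"catheter_offset must be >= 0, got {self.catheter_offset}")
        if self.frame_pitch <= 0:
            raise ValueError(f"frame_pitch must be > 0, got {self.frame_pitch}")

    @property
    def angular_step(self) -> float:
        """Angle between consecutive A-lines, radians."""
        return 2.0 * np.pi / self.n_alines

    def angle_of(self, angle_index) -> np.ndarray:
        """Beam angle (radians) of an A-line index (scalar or array)."""
        return self.angle_origin + 2.0 * np.pi * np.asarray(angle_index, dtype=float) / self.n_alines

    def radius_of(self, depth_index) -> np.ndarray:
        """Radial distance (µm) from the rotation axis of a depth index."""
        return self.catheter_offset + np.asarray(depth_index, dtype=float) * self.axial_pitch

    def arc_step_at(self, radius_um: float) -> float:
        """Lateral arc length (µm) between adjacent A-lines at a given radius."""
        return float(radius_um) * self.angular_step


def polar_to_cartesian(angle_index: int, depth_index: float, geometry: ScanGeometry) -> Tuple[float, float]:
    """Map one polar sample to Cartesian µm coordinates.

    ``r = catheter_offset + depth_index * axial_pitch`` and
    ``theta = angle_origin + 2*pi*angle_index / n_alines``; the returned point
    is ``(r cos(theta), r sin(theta))`` with the origin on the rotation axis.
    """
    if not (0 <= angle_index < geometry.n_alines):
        raise IndexError(
            f"angle_index {angle_index} out of range [0, {geometry.n_alines})"
        )
    if depth_index < 0:
        raise IndexError(f"depth_index must be >= 0, got {depth_index}")
    r = geometry.catheter_offset + depth_index * geometry.axial_pitch
    theta = geometry.angle_origin + 2.0 * np.pi * angle_index / geometry.n_alines
    return (r * np.cos(theta), r * np.sin(theta))


def polar_points_to_cartesian(angle_indices, depth_indices, geometry: ScanGeometry) -> np.ndarray:
    """Vectorised :func:`polar_to_cartesian`; returns an ``(n, 2)`` array in µm."""
    a = np.asarray(angle_indices, dtype=float)
    z = np.asarray(depth_indices, dtype=float)
    r = geometry.catheter_offset + z * geometry.axial_pitch
    theta = geometry.angle_origin + 2.0 * np.pi * a / geometry.n_alines
    return np.stack([r * np.cos(theta), r * np.sin(theta)], axis=-1)


@dataclass
class PolarimetricFrame:
    """Co-registered polar images of one cross-section.

    ``reflectance`` is in dB above the noise floor, ``birefringence`` is the
    unitless refractive-index difference Δn (order 1e-4 in collagenous
    tissue) and ``depolarization`` is in [0, 1].  NaN is the missing-value
    sentinel in every channel and is excluded from all statistics.
    """

    reflectance: np.ndarray
    birefringence: np.ndarray
    depolarization: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        for name in ("reflectance", "birefringence", "depolarization"):
            arr = np.asarray(getattr(self, name), dtype=np.float32)
            if arr.ndim != 2:
                raise ValidationError(f"{name} must be 2-D (angle x depth)")
            setattr(self, name, arr)
        shape = self.reflectance.shape
        for name in ("birefringence", "depolarization"):
            if getattr(self, name).shape != shape:
                raise ValidationError(
                    f"channel {name!r} shape {getattr(self, name).shape} "
                    f"does not match reflectance shape {shape}"
                )
        if shape[0] != self.geometry.n_alines:
            raise ValidationError(
                f"frame has {shape[0]} A-lines but geometry declares {self.geometry.n_alines}"
            )
        d = self.depolarization
        finite = d[np.isfinite(d)]
        if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
            raise ValidationError(
                "depolarization outside [0, 1]: "
                f"range [{finite.min():.4g}, {finite.max():.4g}]"
            )
        b = self.birefringence
        finite_b = b[np.isfinite(b)]
        if finite_b.size and finite_b.min() < 0.0:
            raise ValidationError(f"birefringence must be >= 0, min {finite_b.min():.4g}")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.reflectance.shape


@dataclass
class SegmentationMask:
    """Polar label image with the six-class convention (see module constants)."""

    labels: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValidationError("labels must be 2-D (angle x depth)")
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError(f"labels must be an integer image, got dtype {arr.dtype}")
        present = set(np.unique(arr).tolist())
        if not present <= VALID_LABELS:
            raise ValidationError(f"unknown label codes: {sorted(present - VALID_LABELS)}")
        if arr.shape[0] != self.geometry.n_alines:
            raise ValidationError(
                f"mask has {arr.shape[0]} A-lines but geometry declares {self.geometry.n_alines}"
            )
        self.labels = arr.astype(np.uint8)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.labels.shape


@dataclass(frozen=True)
class CapSegParams:
    """Tunable parameters of the cap segmentation pipeline.

    ``depol_threshold`` (0.2) and ``refl_threshold`` (35 dB) define the cap
    criterion ``depolarization < 0.2 OR reflectance > 35 dB``, both strict.
    ``incidence_exclusion_deg`` removes A-lines where the beam grazes the
    tissue surface (tangent within ±5° of the beam), which produces
    artifactually high depolarization.  ``min_run_gap`` controls how many
    consecutive non-cap pixels a surface-anchored cap run may bridge
    (0 = strictly contiguous).  ``contour_smoothing_window`` is the circular
    moving-average window (A-lines) applied to the lumen contour before
    tangent estimation only.
    """

    depol_threshold: float = 0.2
    refl_threshold: float = 35.0
    incidence_exclusion_deg: float = 5.0
    min_run_gap: int = 0
    contour_smoothing_window: int = 11

    def __post_init__(self) -> None:
        if not (0.0 < self.depol_threshold < 1.0):
            raise ValueError("depol_threshold must be in (0, 1)")
        if self.refl_threshold <= 0:
            raise ValueError("refl_threshold must be > 0")
        if not (0.0 <= self.incidence_exclusion_deg < 90.0):
            raise ValueError("incidence_exclusion_deg must be in [0, 90)")
        if self.min_run_gap < 0:
            raise ValueError("min_run_gap must be >= 0")
        if self.contour_smoothing_window < 1 or self.contour_smoothing_window % 2 == 0:
            raise ValueError("contour_smoothing_window must be a positive odd integer")


def validate_pair(frame: PolarimetricFrame, mask: SegmentationMask):
    """Check that a frame and its segmentation mask are mutually consistent.

    Returns the pair unchanged; raises :class:`ValidationError` naming the
    offending channel on dimension mismatch.
    """
    if mask.shape != frame.shape:
        raise ValidationError(
            f"mask shape {mask.shape} does not match frame shape {frame.shape}"
        )
    if mask.geometry != frame.geometry:
        raise ValidationError("mask geometry differs from frame geometry")
    return frame, mask
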