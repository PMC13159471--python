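"""Synthetic coronary vessel phantoms with analytic cap ground truth.

The generator emulates what the clinical PS-OCT system and its segmentation
network would deliver for a vessel cross-section: three co-registered polar
images (reflectance in dB above the noise floor, birefringence, and
depolarization) plus a six-class label mask, together with the analytic cap
geometry so that every downstream measurement can be checked against a known
truth.

Tissue is laid out radially per A-line: lumen out to ``r_L(theta)``; within the
plaque arc a fibrous cap of thickness ``t(theta)`` over a lipid core; outside
the plaque arc a normal intima/media wall.  Optics follow a simple layered
model — reflectance decays linearly in dB with depth at a per-class attenuation
slope, while birefringence and depolarization are per-class Gaussian draws
clipped to their valid ranges.  Lipid cores depolarize strongly and carry no
meaningful birefringence (NaN sentinel), while fibrous caps are collagen-rich:
high birefringence, low depolarization.  There is no speckle model and no
catheter-sheath or motion artefact — the phantom exercises the measurement
pipeline, not OCT physics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.spatial import cKDTree

from .model import (
    LABEL_BACKGROUND,
    LABEL_GUIDEWIRE,
    LABEL_INTIMA,
    LABEL_LUMEN,
    LABEL_MEDIA,
    LABEL_PLAQUE_SHADOW,
    PolarimetricFrame,
    ScanGeometry,
    SegmentationMask,
)

__all__ = [
    "TissueOptics",
    "default_optics",
    "VesselPhantomSpec",
    "GroundTruth",
    "PullbackPhantom",
    "generate_cross_section",
    "generate_pullback",
    "true_min_cap_thickness",
    "circle_lumen_profile",
    "ellipse_lumen_profile",
    "offset_circle_cap_profile",
    "lesion_spec_sequence",
]

RadialProfile = Union[float, Callable[[np.ndarray], np.ndarray]]

# Generating tissue classes (distinct from mask labels).
CLASS_LUMEN = 0
CLASS_CAP = 1
CLASS_CORE = 2
CLASS_INTIMA = 3
CLASS_MEDIA = 4
CLASS_ADVENTITIA = 5
CLASS_GUIDEWIRE = 6


@dataclass(frozen=True)
class TissueOptics:
    """Optical signature of one tissue class.

    ``refl_db`` is the reflectance extrapolated to the tissue surface (dB
    above noise floor); ``atten_db_per_um`` the linear dB attenuation slope
    with depth into tissue; ``biref`` the mean birefringence (NaN for tissue
    with no meaningful birefringence, e.g. lipid core); ``depol`` the mean
    depolarization.  ``*_sd`` are per-pixel Gaussian noise SDs.
    """

    refl_db: float
    atten_db_per_um: float
    biref: float
    depol: float
    refl_sd: float = 2.0
    biref_sd: float = 0.5e-4
    depol_sd: float = 0.03


def default_optics() -> Dict[str, TissueOptics]:
    """Default per-class optics table.

    Values straddle the pipeline's thresholds the way real tissue does: caps
    are bright and polarization-preserving (40 dB, depolarization 0.05) while
    lipid cores are dim and strongly depolarizing (25 dB, 0.4) with no defined
    birefringence.
    """
    return {
        "cap": TissueOptics(40.0, 0.008, 4.5e-4, 0.05),
        "lipid_core": TissueOptics(25.0, 0.015, float("nan"), 0.40),
        "intima": TissueOptics(38.0, 0.006, 3.0e-4, 0.05),
        "media": TissueOptics(36.0, 0.006, 5.0e-4, 0.10),
        "adventitia": TissueOptics(28.0, 0.010, 3.0e-4, 0.35),
        "lumen": TissueOptics(2.0, 0.0, float("nan"), 0.50),
    }


_CLASS_TO_OPTICS = {
    CLASS_LUMEN: "lumen",
    CLASS_CAP: "cap",
    CLASS_CORE: "lipid_core",
    CLASS_INTIMA: "intima",
    CLASS_MEDIA: "media",
    CLASS_ADVENTITIA: "adventitia",
}


@dataclass
class VesselPhantomSpec:
    """Declarative description of one synthetic cross-section.

    ``lumen_radius_profile`` and ``cap_thickness_profile`` are either constant
    values (µm) or callables of the beam angle theta (radians, vectorised).
    ``plaque_arc`` and ``guidewire_arc`` are half-open angular intervals
    ``[theta1, theta2)`` within [0, 2*pi); an empty guidewire arc is allowed.
    ``noise_scale`` multiplies every per-class noise SD (0 = noiseless).
    """

    lumen_radius_profile: RadialProfile = 1500.0
    plaque_arc: Optional[Tuple[float, float]] = (0.5, 2.5)
    cap_thickness_profile: RadialProfile = 100.0
    core_thickness: float = 600.0
    wall_thickness: float = 600.0
    guidewire_arc: Optional[Tuple[float, float]] = (4.2, 4.5)
    tissue_optics: Dict[str, TissueOptics] = field(default_factory=default_optics)
    seed: int = 0
    noise_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.plaque_arc is not None:
            t1, t2 = self.plaque_arc
            if not (0.0 <= t1 < t2 <= 2.0 * math.pi):
                raise ValueError("plaque_arc must satisfy 0 <= theta1 < theta2 <= 2*pi")
        if self.guidewire_arc is not None:
            g1, g2 = self.guidewire_arc
            if not (0.0 <= g1 < g2 <= 2.0 * math.pi):
                raise ValueError("guidewire_arc must satisfy 0 <= theta1 < theta2 <= 2*pi")
        if self.core_thickness <= 0 or self.wall_thickness <= 0:
            raise ValueError("core_thickness and wall_thickness must be > 0")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")

    def lumen_radius(self, theta: np.ndarray) -> np.ndarray:
        return _eval_profile(self.lumen_radius_profile, theta)

    def cap_thickness(self, theta: np.ndarray) -> np.ndarray:
        return _eval_profile(self.cap_thickness_profile, theta)


def _eval_profile(profile: RadialProfile, theta: np.ndarray) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if callable(profile):
        out = np.asarray(profile(theta), dtype=float)
        return np.broadcast_to(out, theta.shape).copy()
    return np.full(theta.shape, float(profile))


def _in_arc(theta: np.ndarray, arc: Optional[Tuple[float, float]]) -> np.ndarray:
    if arc is None:
        return np.zeros(np.shape(theta), dtype=bool)
    theta = np.mod(np.asarray(theta, dtype=float), 2.0 * math.pi)
    return (theta >= arc[0]) & (theta < arc[1])


@dataclass
class GroundTruth:
    """Analytic cap geometry of one phantom cross-section.

    Boundary profiles are densely sampled (``oversample`` points per A-line)
    over the plaque arc so the exact minimum cap thickness can be recovered by
    exhaustive pairwise search.  ``true_mct`` is that exhaustive minimum.
    ``resolution_warning`` flags caps thinner than one axial pixel anywhere.
    """

    theta_dense: np.ndarray
    inner_radius_dense: np.ndarray
    outer_radius_dense: np.ndarray
    cap_inner_radius: np.ndarray   # per A-line, NaN outside plaque arc
    cap_outer_radius: np.ndarray
    true_mct: float
    lumen_area_mm2: float
    class_map: np.ndarray
    plaque_arc: Optional[Tuple[float, float]]
    resolution_warning: bool = False


def _dense_boundaries(
    spec: VesselPhantomSpec, geometry: ScanGeometry, oversample: int
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    t1, t2 = spec.plaque_arc
    n_arc = max(int(math.ceil((t2 - t1) / geometry.angular_step)), 2)
    theta = np.linspace(t1, t2, n_arc * oversample + 1)
    inner = spec.lumen_radius(theta)
    outer = inner + spec.cap_thickness(theta)
    return theta, inner, outer


def _min_pair_distance(inner_xy: np.ndarray, outer_xy: np.ndarray) -> float:
    d, _ = cKDTree(outer_xy).query(inner_xy, k=1)
    return float(d.min())


def true_min_cap_thickness(gt: GroundTruth, geometry: ScanGeometry) -> float:
    """Exact minimum inner-to-outer boundary distance (µm) by exhaustive search
    over the densely sampled analytic boundaries."""
    inner_xy = np.stack(
        [gt.inner_radius_dense * np.cos(gt.theta_dense),
         gt.inner_radius_dense * np.sin(gt.theta_dense)], axis=1
    )
    outer_xy = np.stack(
        [gt.outer_radius_dense * np.cos(gt.theta_dense),
         gt.outer_radius_dense * np.sin(gt.theta_dense)], axis=1
    )
    return _min_pair_distance(inner_xy, outer_xy)


def _analytic_lumen_area_mm2(spec: VesselPhantomSpec, n_samples: int = 8192) -> float:
    theta = np.linspace(0.0, 2.0 * math.pi, n_samples, endpoint=False)
    r = spec.lumen_radius(theta)
    # polygon (shoelace) area of the sampled contour, µm² -> mm²
    x, y = r * np.cos(theta), r * np.sin(theta)
    area = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
    return float(area) / 1e6


def generate_cross_section(
    spec: VesselPhantomSpec,
    geometry: ScanGeometry,
    n_depth: int = 384,
    rng: Optional[np.random.Generator] = None,
    gt_oversample: int = 10,
) -> Tuple[PolarimetricFrame, SegmentationMask, GroundTruth]:
    """Render one phantom cross-section.

    Returns the polarimetric frame, its six-class mask, and the analytic
    ground truth.  Deterministic for a fixed ``spec.seed`` (an explicit
    ``rng`` overrides the seed, e.g. within a pullback).
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    theta = geometry.angle_of(np.arange(geometry.n_alines))
    r = geometry.radius_of(np.arange(n_depth))          # (n_depth,)
    r_grid = np.broadcast_to(r, (geometry.n_alines, n_depth))

    r_lumen = spec.lumen_radius(theta)                  # (n_alines,)
    if np.any(r_lumen <= 0):
        raise ValueError("lumen radius profile must be positive everywhere")
    in_plaque = _in_arc(theta, spec.plaque_arc)
    in_guidewire = _in_arc(theta, spec.guidewire_arc)

    has_plaque = bool(in_plaque.any())
    t_cap = np.full(theta.shape, np.nan)
    if has_plaque:
        t_cap[in_plaque] = spec.cap_thickness(theta[in_plaque])
        if np.any(t_cap[in_plaque] <= 0):
            raise ValueError("cap thickness profile must be positive on the plaque arc")

    rl = r_lumen[:, None]
    depth_into_tissue = r_grid - rl                     # µm beyond the surface

    class_map = np.full((geometry.n_alines, n_depth), CLASS_ADVENTITIA, dtype=np.int8)
    class_map[r_grid < rl] = CLASS_LUMEN
    # plaque arc: cap then lipid core
    tc = t_cap[:, None]
    plaque_rows = in_plaque[:, None]
    cap_px = plaque_rows & (depth_into_tissue >= 0) & (depth_into_tissue < tc)
    core_px = plaque_rows & (depth_into_tissue >= tc) & (depth_into_tissue < tc + spec.core_thickness)
    class_map[cap_px] = CLASS_CAP
    class_map[core_px] = CLASS_CORE
    # normal wall elsewhere: intima (30%) then media (70%)
    intima_t = 0.3 * spec.wall_thickness
    wall_rows = ~plaque_rows
    intima_px = wall_rows & (depth_into_tissue >= 0) & (depth_into_tissue < intima_t)
    media_px = wall_rows & (depth_into_tissue >= intima_t) & (depth_into_tissue < spec.wall_thickness)
    class_map[intima_px] = CLASS_INTIMA
    class_map[media_px] = CLASS_MEDIA
    class_map[in_guidewire, :] = CLASS_GUIDEWIRE

    frame = _render_channels(spec, class_map, depth_into_tissue, rng, geometry)
    mask = _render_mask(class_map, r_grid, rl, plaque_rows, in_guidewire, geometry)

    if has_plaque:
        theta_d, inner_d, outer_d = _dense_boundaries(spec, geometry, gt_oversample)
    else:
        theta_d = inner_d = outer_d = np.empty(0)
    cap_inner = np.where(in_plaque, r_lumen, np.nan)
    cap_outer = np.where(in_plaque, r_lumen + t_cap, np.nan)
    gt = GroundTruth(
        theta_dense=theta_d,
        inner_radius_dense=inner_d,
        outer_radius_dense=outer_d,
        cap_inner_radius=cap_inner,
        cap_outer_radius=cap_outer,
        true_mct=float("nan"),
        lumen_area_mm2=_analytic_lumen_area_mm2(spec),
        class_map=class_map,
        plaque_arc=spec.plaque_arc,
        resolution_warning=bool(np.nanmin(t_cap[in_plaque]) < geometry.axial_pitch) if has_plaque else False,
    )
    if has_plaque:
        gt.true_mct = true_min_cap_thickness(gt, geometry)
    return frame, mask, gt


def _render_channels(
    spec: VesselPhantomSpec,
    class_map: np.ndarray,
    depth_into_tissue: np.ndarray,
    rng: np.random.Generator,
    geometry: ScanGeometry,
) -> PolarimetricFrame:
    shape = class_map.shape
    refl = np.zeros(shape, dtype=np.float64)
    biref = np.full(shape, np.nan)
    depol = np.zeros(shape, dtype=np.float64)

    # Draw the full noise fields up-front so the pixel stream is independent
    # of the class layout (keeps pullbacks reproducible when geometry varies).
    ns = spec.noise_scale
    noise_refl = rng.standard_normal(shape)
    noise_biref = rng.standard_normal(shape)
    noise_depol = rng.standard_normal(shape)

    depth_pos = np.maximum(depth_into_tissue, 0.0)
    for cls, key in _CLASS_TO_OPTICS.items():
        sel = class_map == cls
        if not sel.any():
            continue
        opt = spec.tissue_optics[key]
        refl[sel] = opt.refl_db - opt.atten_db_per_um * depth_pos[sel] + ns * opt.refl_sd * noise_refl[sel]
        if math.isnan(opt.biref):
            biref[sel] = np.nan
        else:
            biref[sel] = np.clip(opt.biref + ns * opt.biref_sd * noise_biref[sel], 0.0, None)
        depol[sel] = np.clip(opt.depol + ns * opt.depol_sd * noise_depol[sel], 0.0, 1.0)

    gw = class_map == CLASS_GUIDEWIRE
    refl[gw] = np.nan
    biref[gw] = np.nan
    depol[gw] = np.nan
    return PolarimetricFrame(refl, biref, depol, geometry)


def _render_mask(
    class_map: np.ndarray,
    r_grid: np.ndarray,
    rl: np.ndarray,
    plaque_rows: np.ndarray,
    in_guidewire: np.ndarray,
    geometry: ScanGeometry,
) -> SegmentationMask:
    labels = np.full(class_map.shape, LABEL_BACKGROUND, dtype=np.uint8)
    labels[class_map == CLASS_LUMEN] = LABEL_LUMEN
    labels[class_map == CLASS_INTIMA] = LABEL_INTIMA
    labels[class_map == CLASS_MEDIA] = LABEL_MEDIA
    # plaque shadow: the layered structure is lost, so everything from the
    # surface down on plaque-arc A-lines is flagged (lumen stays lumen)
    labels[plaque_rows & (r_grid >= rl)] = LABEL_PLAQUE_SHADOW
    labels[in_guidewire, :] = LABEL_GUIDEWIRE
    return SegmentationMask(labels, geometry)


@dataclass
class PullbackPhantom:
    """A rendered pullback: per-frame data plus the analytic MLA frame index."""

    frames: List[PolarimetricFrame]
    masks: List[SegmentationMask]
    ground_truths: List[GroundTruth]
    geometry: ScanGeometry
    mla_index: int


def generate_pullback(
    spec_sequence: Sequence[VesselPhantomSpec],
    geometry: ScanGeometry,
    n_depth: int = 384,
) -> PullbackPhantom:
    """Render an ordered sequence of cross-sections at ``frame_pitch`` spacing.

    The designated true MLA frame is the one with the smallest analytic lumen
    area (ties broken to the lowest index).  Each frame uses its own spec seed.
    """
    if len(spec_sequence) == 0:
        raise ValueError("spec_sequence must contain at least one frame")
    frames, masks, gts = [], [], []
    for spec in spec_sequence:
        f, m, g = generate_cross_section(spec, geometry, n_depth=n_depth)
        frames.append(f)
        masks.append(m)
        gts.append(g)
    areas = np.array([g.lumen_area_mm2 for g in gts])
    mla = int(np.argmin(areas))
    return PullbackPhantom(frames, masks, gts, geometry, mla)


# ---------------------------------------------------------------------------
# Analytic lumen/cap profile helpers


def circle_lumen_profile(radius: float, cx: float = 0.0, cy: float = 0.0) -> Callable:
    """Polar radius of a circle of ``radius`` centred at (cx, cy), seen from
    the origin (the catheter axis must lie inside the circle)."""
    if math.hypot(cx, cy) >= radius:
        raise ValueError("catheter axis must lie inside the lumen circle")

    def profile(theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        b = -2.0 * (cx * np.cos(theta) + cy * np.sin(theta))
        c = cx * cx + cy * cy - radius * radius
        return (-b + np.sqrt(b * b - 4.0 * c)) / 2.0

    return profile


def ellipse_lumen_profile(a: float, b: float, cx: float = 0.0, cy: float = 0.0) -> Callable:
    """Polar radius of an axis-aligned ellipse (semi-axes ``a``, ``b``) centred
    at (cx, cy); the catheter axis must lie inside."""
    if (cx / a) ** 2 + (cy / b) ** 2 >= 1.0:
        raise ValueError("catheter axis must lie inside the lumen ellipse")

    def profile(theta: np.ndarray) -> np.ndarray:
        theta = np.asarray(theta, dtype=float)
        u, v = np.cos(theta), np.sin(theta)
        A = (u / a) ** 2 + (v / b) ** 2
        B = -2.0 * (cx * u / a**2 + cy * v / b**2)
        C = (cx / a) ** 2 + (cy / b) ** 2 - 1.0
        return (-B + np.sqrt(B * B - 4.0 * A * C)) / (2.0 * A)

    return profile


def offset_circle_cap_profile(
    lumen_profile: Callable, outer_radius: float, cx: float = 0.0, cy: float = 0.0
) -> Callable:
    """Cap thickness t(theta) whose outer boundary is a circle of
    ``outer_radius`` centred at (cx, cy): t = r_outer(theta) - r_lumen(theta)."""
    outer = circle_lumen_profile(outer_radius, cx, cy)

    def profile(theta: np.ndarray) -> np.ndarray:
        return outer(theta) - lumen_profile(theta)

    return profile


def lesion_spec_sequence(
    n_frames: int = 9,
    base_radius: float = 1500.0,
    mla_radius: float = 1000.0,
    cap_thickness: RadialProfile = 120.0,
    plaque_arc: Tuple[float, float] = (0.6, 2.8),
    optics: Optional[Dict[str, TissueOptics]] = None,
    seed: int = 0,
    noise_scale: float = 1.0,
    plaque_frames: Optional[Tuple[int, int]] = None,
) -> List[VesselPhantomSpec]:
    """Build a lesion-like pullback: lumen radius dips smoothly (cosine bump)
    to ``mla_radius`` at the central frame; plaque is present on
    ``plaque_frames`` (inclusive, default all frames).

    Per-frame seeds are spawned deterministically from ``seed``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    centre = (n_frames - 1) / 2.0
    child_seeds = np.random.SeedSequence(seed).generate_state(n_frames) % (2**31)
    specs = []
    for i in range(n_frames):
        # cosine bump, 1 at the centre frame, 0 at the ends
        w = 0.5 * (1.0 + math.cos(math.pi * min(abs(i - centre) / max(centre, 1e-9), 1.0)))
        radius = base_radius - (base_radius - mla_radius) * w
        has_plaque = plaque_frames is None or (plaque_frames[0] <= i <= plaque_frames[1])
        specs.append(
            VesselPhantomSpec(
                lumen_radius_profile=radius,
                plaque_arc=plaque_arc if has_plaque else None,
                cap_thickness_profile=cap_thickness,
                tissue_optics=optics if optics is not None else default_optics(),
                seed=int(child_seeds[i]),
                noise_scale=noise_scale,
            )
        )
    return specs
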