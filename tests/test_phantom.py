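"""Phantom generator: determinism, analytic ground truth, mask consistency."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from capseg.model import (
    LABEL_GUIDEWIRE,
    LABEL_PLAQUE_SHADOW,
    CapSegParams,
    ScanGeometry,
)
from capseg.phantom import (
    CLASS_CAP,
    VesselPhantomSpec,
    circle_lumen_profile,
    default_optics,
    generate_cross_section,
    generate_pullback,
    lesion_spec_sequence,
    offset_circle_cap_profile,
    true_min_cap_thickness,
)
from capseg.pipeline import measure_frame


@pytest.fixture
def geom512():
    return ScanGeometry(n_alines=512, axial_pitch=5.0)


def harmonic_spec(seed, noise_scale=1.0):
    rng = np.random.default_rng(seed)
    phase = rng.uniform(0, 2 * np.pi, 3)
    amp_r = rng.uniform(50, 150)
    amp_t = rng.uniform(10, 40)
    base_t = rng.uniform(80, 160)
    return VesselPhantomSpec(
        lumen_radius_profile=lambda th: 1300 + amp_r * np.sin(th + phase[0]),
        cap_thickness_profile=lambda th: base_t + amp_t * np.cos(2 * th + phase[1]),
        plaque_arc=(0.5, 2.8),
        seed=seed,
        noise_scale=noise_scale,
    )


class TestCrossSection:
    def test_constant_radial_cap_true_mct(self, geom512):
        spec = VesselPhantomSpec(lumen_radius_profile=1500.0,
                                 cap_thickness_profile=100.0, noise_scale=0.0)
        _, _, gt = generate_cross_section(spec, geom512)
        assert gt.true_mct == pytest.approx(100.0, abs=1e-6)

    def test_same_seed_is_bit_identical(self, geom512):
        spec = VesselPhantomSpec(seed=42)
        f1, m1, g1 = generate_cross_section(spec, geom512)
        f2, m2, g2 = generate_cross_section(VesselPhantomSpec(seed=42), geom512)
        for ch in ("reflectance", "birefringence", "depolarization"):
            assert np.array_equal(getattr(f1, ch), getattr(f2, ch), equal_nan=True)
        assert np.array_equal(m1.labels, m2.labels)
        assert g1.true_mct == g2.true_mct

    def test_noiseless_thresholds_recover_cap_class_map(self, geom512):
        """With noise off, cap/core optics straddle the 0.2 / 35 dB thresholds,
        so thresholding the frame reproduces the cap class-map on plaque
        A-lines below the surface."""
        spec = VesselPhantomSpec(noise_scale=0.0)
        frame, mask, gt = generate_cross_section(spec, geom512)
        p = CapSegParams()
        is_cap_by_threshold = (
            (np.nan_to_num(frame.depolarization, nan=1.0) < p.depol_threshold)
            | (np.nan_to_num(frame.reflectance, nan=-np.inf) > p.refl_threshold)
        )
        plaque_rows = (mask.labels == LABEL_PLAQUE_SHADOW).any(axis=1)
        tissue = mask.labels[plaque_rows] == LABEL_PLAQUE_SHADOW
        assert np.array_equal(
            is_cap_by_threshold[plaque_rows] & tissue,
            (gt.class_map[plaque_rows] == CLASS_CAP),
        )

    def test_plaque_shadow_lies_on_plaque_arc(self, geom512):
        spec = VesselPhantomSpec(seed=3)
        _, mask, gt = generate_cross_section(spec, geom512)
        rows = np.flatnonzero((mask.labels == LABEL_PLAQUE_SHADOW).any(axis=1))
        theta = geom512.angle_of(rows)
        t1, t2 = gt.plaque_arc
        step = geom512.angular_step
        assert ((theta >= t1 - step) & (theta < t2 + step)).all()

    def test_guidewire_arc_is_masked_with_sentinel(self, geom512):
        spec = VesselPhantomSpec(guidewire_arc=(4.2, 4.5), seed=1)
        frame, mask, _ = generate_cross_section(spec, geom512)
        gw = (mask.labels == LABEL_GUIDEWIRE).all(axis=1)
        assert gw.any()
        assert np.isnan(frame.depolarization[gw]).all()
        assert np.isnan(frame.reflectance[gw]).all()

    def test_unresolvable_cap_sets_warning_flag(self, geom512):
        spec = VesselPhantomSpec(cap_thickness_profile=3.0, noise_scale=0.0)
        _, _, gt = generate_cross_section(spec, geom512)
        assert gt.resolution_warning

    def test_no_plaque_frame_has_no_shadow_and_nan_truth(self, geom512):
        spec = VesselPhantomSpec(plaque_arc=None)
        _, mask, gt = generate_cross_section(spec, geom512)
        assert not (mask.labels == LABEL_PLAQUE_SHADOW).any()
        assert np.isnan(gt.true_mct)


class TestTrueMinCapThickness:
    def test_concentric_annulus(self, geom512):
        spec = VesselPhantomSpec(lumen_radius_profile=1500.0,
                                 cap_thickness_profile=100.0, noise_scale=0.0)
        _, _, gt = generate_cross_section(spec, geom512)
        assert true_min_cap_thickness(gt, geom512) == pytest.approx(100.0, abs=1e-6)

    def test_offset_outer_circle_gap(self, geom512):
        lum = circle_lumen_profile(1500.0)
        cap = offset_circle_cap_profile(lum, 1650.0, cx=50.0)
        spec = VesselPhantomSpec(lumen_radius_profile=1500.0,
                                 cap_thickness_profile=cap,
                                 plaque_arc=(2.0, 4.2), noise_scale=0.0)
        _, _, gt = generate_cross_section(spec, geom512)
        # min gap between circles: 1650 - 50 - 1500
        assert gt.true_mct == pytest.approx(100.0, abs=0.05)

    def test_oversampling_convergence_on_harmonic_cap(self, geom512):
        """Ground truth at 10x A-line density agrees with a 100x exhaustive
        search to better than 0.5 µm."""
        spec = harmonic_spec(seed=11, noise_scale=0.0)
        _, _, gt10 = generate_cross_section(spec, geom512, gt_oversample=10)
        _, _, gt100 = generate_cross_section(spec, geom512, gt_oversample=100)
        assert abs(gt10.true_mct - gt100.true_mct) < 0.5

    def test_matches_brute_force_all_pairs(self, geom512):
        spec = harmonic_spec(seed=5, noise_scale=0.0)
        _, _, gt = generate_cross_section(spec, geom512)
        inner = np.stack([gt.inner_radius_dense * np.cos(gt.theta_dense),
                          gt.inner_radius_dense * np.sin(gt.theta_dense)], axis=1)
        outer = np.stack([gt.outer_radius_dense * np.cos(gt.theta_dense),
                          gt.outer_radius_dense * np.sin(gt.theta_dense)], axis=1)
        assert gt.true_mct == pytest.approx(float(cdist(inner, outer).min()), abs=1e-9)

    def test_true_mct_never_exceeds_min_radial_thickness(self, geom512):
        for seed in range(5):
            spec = harmonic_spec(seed, noise_scale=0.0)
            _, _, gt = generate_cross_section(spec, geom512)
            radial_min = float(np.min(gt.outer_radius_dense - gt.inner_radius_dense))
            assert gt.true_mct <= radial_min + 1e-9


class TestPullback:
    def test_designed_mla_frame_is_found(self):
        g = ScanGeometry(n_alines=128, axial_pitch=5.0)
        specs = lesion_spec_sequence(n_frames=21, seed=0)
        pb = generate_pullback(specs, g, n_depth=340)
        assert pb.mla_index == 10

    def test_constant_frames_tie_to_lowest_index(self):
        g = ScanGeometry(n_alines=128, axial_pitch=5.0)
        specs = [VesselPhantomSpec(seed=i) for i in range(4)]
        pb = generate_pullback(specs, g, n_depth=340)
        assert pb.mla_index == 0

    def test_empty_sequence_rejected(self):
        g = ScanGeometry(n_alines=128, axial_pitch=5.0)
        with pytest.raises(ValueError):
            generate_pullback([], g)

    def test_per_frame_truth_matches_profile_recomputation(self):
        """Stored per-frame true MCT equals a brute-force distance search over
        an independently resampled analytic boundary."""
        g = ScanGeometry(n_alines=256, axial_pitch=5.0)
        specs = [harmonic_spec(s, noise_scale=0.0) for s in (0, 1, 2)]
        pb = generate_pullback(specs, g, n_depth=340)
        for spec, gt in zip(specs, pb.ground_truths):
            th = np.linspace(spec.plaque_arc[0], spec.plaque_arc[1], 4001)
            ri = spec.lumen_radius(th)
            ro = ri + spec.cap_thickness(th)
            inner = np.stack([ri * np.cos(th), ri * np.sin(th)], 1)
            outer = np.stack([ro * np.cos(th), ro * np.sin(th)], 1)
            assert gt.true_mct == pytest.approx(float(cdist(inner, outer).min()), abs=0.5)


class TestNoiseDegradation:
    def test_recovery_error_grows_with_noise(self, geom512):
        """Mean |measured - true| MCT over 20 seeds is non-decreasing across
        three noise levels."""
        levels = (0.5, 3.0, 6.0)
        mean_err = []
        for level in levels:
            errs = []
            for seed in range(20):
                spec = VesselPhantomSpec(seed=seed, noise_scale=level)
                frame, mask, gt = generate_cross_section(spec, geom512)
                m = measure_frame(frame, mask)
                errs.append(abs(m.mct - gt.true_mct) if m.has_cap else gt.true_mct)
            mean_err.append(np.mean(errs))
        assert mean_err[0] <= mean_err[1] <= mean_err[2]
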