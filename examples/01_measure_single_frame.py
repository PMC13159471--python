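"""Measure the minimum fibrous-cap thickness on one synthetic cross-section.

Builds a vessel phantom with a 100 µm radial cap over a lipid core, runs the
per-frame pipeline and compares the measured minimum cap thickness (MCT)
against the analytic truth.
"""

from capseg.model import ScanGeometry
from capseg.phantom import VesselPhantomSpec, generate_cross_section
from capseg.pipeline import measure_frame

geometry = ScanGeometry(n_alines=512, axial_pitch=5.0)  # 5 µm depth pixels
spec = VesselPhantomSpec(
    lumen_radius_profile=1500.0,    # circular lumen, µm
    cap_thickness_profile=100.0,    # constant radial cap, µm
    plaque_arc=(0.5, 2.5),          # plaque covers ~115 degrees
)
frame, mask, truth = generate_cross_section(spec, geometry)

m = measure_frame(frame, mask)
print(f"true MCT        : {truth.true_mct:.1f} um")
print(f"measured MCT    : {m.mct:.1f} um")
print(f"measurable lines: {m.measurable_angle_count} A-lines")
print(f"cap birefringence (mean): {m.mean_cap_birefringence:.2e}")
print(f"cap depolarization (mean): {m.mean_cap_depolarization:.3f}")
# The measured MCT should sit within about one axial pixel (5 µm) of truth:
# the inner boundary lands on the first tissue pixel, the outer on the last
# cap pixel, so pixelization shaves a few micrometres.
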