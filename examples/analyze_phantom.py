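"""Simulate a mechanism phantom and run the full kinematic analysis on it.

The phantom's slider-crank stands in for hyoid excursion and its belt-pulley
for epiglottic tilt, so every measured peak has an exact analytic reference.
"""

import math

from deglukin import (
    PhantomConfig,
    SmoothingSpec,
    analyze_recording,
    compute_scale_factor,
    simulate_recording,
)

# 10 mm crank, 50 mm rod, half a crank turn per second, 2 s at 30 fps
cfg = PhantomConfig(crank_radius_r=10.0, rod_length_l=50.0,
                    angular_speed_omega=math.pi, fps=30.0, duration=2.0,
                    noise_sigma_px=0.0)
rec, truth = simulate_recording(cfg)

scale = compute_scale_factor(rec)  # 24 mm coin, first 3 frames
print(f"calibrated scale: {scale.s:.4f} mm/px (rendered at {1/cfg.px_per_mm:.4f})")

result = analyze_recording(rec, scale, smoothing=SmoothingSpec(method="none"))
for peak in result.summary.peaks:
    print(f"  {peak.parameter}: {peak.value:.3f} {peak.units} at frame {peak.frame}")

print(f"analytic slider peak displacement: "
      f"{abs(truth.peaks['slider_peak_displacement_mm']):.3f} mm (= 2r)")
print(f"analytic slider peak velocity:     "
      f"{abs(truth.peaks['slider_peak_velocity_mmps']):.3f} mm/s")
# The measured displacement matches 2r = 20 mm to machine precision; the
# velocity differs only by the central-difference truncation error at 30 fps.
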