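"""End-to-end geometric validation on the synthetic phantom.

Renders the three study projections of the digital head, measures the six
landmark distances on the images, compares them with the analytic
projection oracle, and summarises agreement through a simulated 4-observer
panel (sigma = 1.5 mm, whole-mm readings).  An ICC near 1 and a bias near
zero mean the renderer reproduces the projection geometry.
"""
from pathlib import Path

from isodrr import (DetectorSpec, RenderParams, ValidationRunConfig,
                    run_validation)

cfg = ValidationRunConfig(
    seed=1,
    detector=DetectorSpec(n_u=256, n_v=256, pitch_mm=1.2),
    render=RenderParams(),
    observer_sigma_mm=1.5,
    observer_round_to_mm=True,
    out_dir=Path("example_output/validation"),
)
result = run_validation(cfg)

print("distance (mm)            analytic    image    |diff|")
for name, analytic in result.analytic_mm.items():
    image = result.image_mm[name]
    print(f"{name:24s} {analytic:8.2f} {image:8.2f}   {abs(image - analytic):5.3f}")

r = result.report
print(f"\nICC(A,k) = {r.icc:.3f} (95% CI {r.icc_ci_low:.3f}-{r.icc_ci_high:.3f})")
print(f"Bland-Altman bias = {r.bias_mm:.2f} mm (SD {r.sd_mm:.2f}), "
      f"LoA {r.loa_high_mm:.2f} to {r.loa_low_mm:.2f} mm")
print(f"artifacts in {cfg.out_dir}/")
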