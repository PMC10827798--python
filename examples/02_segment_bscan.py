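"""Segment one B-scan end to end and compare against the planted truth.

The pipeline carves the 1500-um foveal window, calibrates the brightness
floor from the three darkest Haller-layer lumens, rescales to 256
gradations, detects the CC/SL and SL/HL boundaries from intensity change
points, binarizes into luminal/stromal pixels, and reports per-layer
areas and L/C ratios.
"""

import numpy as np

from chorostrat import PhantomSpec, PipelineConfig, generate_phantom, run_single

sample = generate_phantom(PhantomSpec(seed=7))
result = run_single(sample.image, sample.roi, PipelineConfig())

truth = sample.truth_boundaries
est = result.boundaries
print("boundary recovery (mean |error| in pixels):")
print(f"  CC/SL: {np.abs(est.cc_sl - truth.cc_sl).mean():.2f}")
print(f"  SL/HL: {np.abs(est.sl_hl - truth.sl_hl).mean():.2f}")
print(f"brightness floor from reference lumens: {result.reference.combined_mean:.1f} gray")
print(f"threshold record: {result.mask.threshold_record}")
print(f"\n{'layer':>6} {'L/C measured':>13} {'L/C truth':>10}")
for layer in ("total", "cc", "sl", "hl"):
    print(f"{layer:>6} {result.metrics[layer].lc_ratio:13.1f} "
          f"{sample.truth_metrics[layer].lc_ratio:10.1f}")
print("\nSub-pixel boundary errors and L/C agreement within a fraction of a")
print("percentage point mean the binarization and stratification chain")
print("reproduces the planted vascular structure.")
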