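"""Render synthetic impregnation images and summarize them topologically.

Simulates dye uptake into a square apple-slice cross-section (Fickian
diffusion from the boundary), photographs it at three times, and
computes the Euler characteristic curve of each frame.  The Max-Min
spread of the normalized curve tracks how non-uniform the staining is;
the double-peak test flags the Gaussian-field texture signature that
diffusion leaves in the image.
"""

from osmotopo import (
    SimulationConfig,
    detect_double_peak,
    euler_curve,
    generate_impregnation_images,
    max_min_difference,
)

config = SimulationConfig(
    seed=0,
    boundary_value=0.5,  # stain contrast: equilibrium sits at mid-gray
    t_samples=(0.0, 14_400.0, 64_800.0),
)
images = generate_impregnation_images(config)

for t, img in zip(config.t_samples, images):
    curve = euler_curve(img)
    mm = max_min_difference(curve)
    flag, lvl_max, lvl_min = detect_double_peak(curve)
    peaks = f"components peak @{lvl_max}, holes dip @{lvl_min}" if flag else "no"
    print(f"t = {t / 3600:4.1f} h: Max-Min = {mm:.5f}, double peak: {peaks}")
print(
    "-> chi > 0 at bright thresholds counts unstained domains; chi < 0 at\n"
    "   darker thresholds counts stained holes; their spread is the\n"
    "   impregnation-uniformity metric."
)
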