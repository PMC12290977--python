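"""Estimate effective diffusivity with and without shrinkage correction.

Generates a noiseless water-loss curve for a cube (half-edge
L0 = 6.09 mm) shrinking to 60% of its volume, converts it to the
unaccomplished ratio Psi = 1 - Y/Ye, and runs both estimators: the
modified slope method (inverts the cube Fourier series with the
time-varying half-length L = L0 (V/V0)^(1/3)) and the classical slope
method that pretends the cube keeps its size.  e(D) is the factor by
which neglecting shrinkage inflates the estimate.
"""

from osmotopo import (
    SimulationConfig,
    generate_kinetics,
    generate_shrinkage,
    modified_slope_method,
    overestimation_ratio,
    psi_from_kinetics,
    slope_method_no_shrink,
)

config = SimulationConfig(D_true=2e-10, shrink_final=0.6, seed=0)
Ye = 0.436
kinetics = generate_kinetics(config, Y_e=Ye, substance_label="water loss")
psi = psi_from_kinetics(kinetics, Ye=Ye)
shrinkage = generate_shrinkage(config)

with_shrink = modified_slope_method(psi, shrinkage, L0=config.L0)
without = slope_method_no_shrink(psi, L0=config.L0)

print(f"true D                  = {config.D_true:.3e} m^2/s")
print(f"shrinkage-corrected D   = {with_shrink.D_avg:.3e} m^2/s "
      f"(R^2 = {with_shrink.r_squared:.4f})")
print(f"no-shrinkage D          = {without.D_avg:.3e} m^2/s "
      f"(R^2 = {without.r_squared:.4f})")
print(f"e(D) = {overestimation_ratio(without, with_shrink):.3f}")
print("-> ignoring the shrinking diffusion path overstates D; the "
      "corrected estimate recovers the true value.")
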