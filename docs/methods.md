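# Methods

## Scope and model overview

`osmotopo` analyzes osmotic impregnation of a cubic plant-tissue sample along
two routes that are finally correlated:

1. an **image route**: gray cross-section images → intensity filtration →
   Euler characteristic curve (ECC) → Max–Min uniformity metric;
2. a **kinetic route**: uptake increases Y_j(t) per substance j (water loss,
   solute gain, bioactives) → Peleg equilibria → unaccomplished ratio
   Ψ_j = 1 − Y_j/Y_{j,e} → effective diffusivity by slope methods with and
   without shrinkage correction → overestimation factor e(D).

Both routes assume an isotropic homogeneous cube with negligible external
mass-transfer resistance and a single effective diffusivity per substance.

## Euler characteristic of images

Pixels are closed unit squares; the complex of a binary image identifies
shared edges and vertices, so χ = V − E + F. This closed-pixel convention
makes foreground 8-connected and enclosed background (holes) 4-connected, and
χ equals components − holes; border-touching background is never a hole. The
implementation counts V, E, F with shifted boolean masks (O(#pixels)); tests
verify it against an independent flood-fill components-minus-holes oracle.

The ECC evaluates χ on the binarization `intensity ≥ ℓ` (superlevel — stained
dark regions are removed first; a sublevel flag exists because either
direction is defensible) for ℓ = 0…255 by default, restricted to the
foreground mask, and normalizes by the foreground pixel count N. The
normalization constant is a package choice; absolute published curve
magnitudes depend on an unstated normalization and are not reproduced.

**Double-peak detection.** The normalized curve is smoothed by a centered
moving average (default 5 levels). Interior maxima above +tol and minima
below −tol are counted with tol = 1/N (one χ count). Two noise guards are
needed in practice because the finite-sample ECC jitters by a few counts:
an extremum must have prominence ≥ 25% of the smoothed curve's range, and
same-sign extrema closer than the smoothing window are treated as one peak.
The flag is true iff exactly one maximum and one minimum remain.

## Peleg kinetics

Y(t) = Y₀ + t/(k₁ + k₂t); Y_e = Y₀ + 1/k₂. Y₀ is a datum (0 for water loss
and solute gain; the measured initial content for bioactives), never a fitted
parameter. Nonlinear least squares is initialized from the OLS fit of the
linearization t/(Y − Y₀) = k₁ + k₂t, which makes the solver insensitive to
starting values. Standard errors come from the Jacobian-based covariance at
the optimum; R² = 1 − SSE/SST and RMSE are reported. Flat series and fits
with non-positive k₂ raise a degenerate-input error.

## Cube series and diffusivity estimation

The diagonal cube-series solution used throughout is

Ψ(τ*) = (8³/π⁶) Σ_{i≥0} (2i+1)⁻⁶ exp(−3(2i+1)²π²τ*/4),
τ* = ∫₀ᵗ D/L(s)² ds,  L = L₀ (V/V₀)^{1/3},

with L₀ the cube half-edge (default 0.00609 m). Terms are truncated when one
falls below 10⁻¹⁴ (cap 200). Note Ψ(0) = 512/960 = 8/15, not 1: the printed
diagonal series cannot represent early observations with Ψ > 8/15, so those
are excluded from inversion (their count is logged). The full triple-product
cube solution is deliberately out of scope; generator and estimator use the
same series consistently, and the constant τ* offset the 8/15 rescaling
induces cancels in all increment- and slope-based quantities.

Inversion Ψ → τ* uses bracketed Brent root finding on the strictly monotone
series to |Ψ − target| < 10⁻¹⁰.

**Modified slope method (shrinkage-corrected).** Usable observations
(Ψ ≤ 8/15) are inverted to τ*_k. The summary diffusivity D̄ is the OLS slope
of τ*_k against the shrinkage-corrected time g(t) = ∫₀ᵗ L(s)⁻² ds (v_ratio
linearly interpolated, dense trapezoid); the free intercept absorbs the
rescaling offset. This regression was chosen over averaging the stepwise
interval values after a bias analysis: interval estimates
D_k = Δτ*·L̄_k²/Δt share noise between Δτ* and the ΔΨ weights of a
transfer-progress average, which inflated recoveries by ≈10% at 1%
measurement noise, while the regression is exact for constant D and showed
≈1% median error under the same conditions. The stepwise D_k (computed on
the monotone-nonincreasing subsequence; points rising above the running
minimum are dropped with a warning) and their Ψ-weighted average
`D_psi_weighted` (trapezoid over observed Ψ intervals, ends extended at
nearest value — the one-variable reduction of the triple-integral average,
valid because D depends on the single progress variable Ψ) remain available
for inspection and for time-resolved correlation. Goodness of fit is R² and
RMSE between observed Ψ and Ψ(τ*(t; D̄, L(t))), anchored at the first usable
observation.

**Slope method without shrinkage.** OLS of ln Ψ on t;
D = −slope·4L₀²/(3π²). Because the series is numerically single-exponential
for τ* > 0 (the second term is < 10⁻³ of the first already at τ* ≈ 0.01),
including early points costs little accuracy. e(D) is the plain ratio of the
two D̄ values; it exceeds 1 whenever the diffusion path truly shrank.
Published e(D) magnitudes of order 10²–10³ are not reproducible from the
footnote definition and are not targeted.

## Synthetic data generator

The generator emulates the study conditions end to end:

* **Images.** ∂C/∂t = D∇²C on the square cross-section (side 2L₀, nodes at
  the physical boundary), Dirichlet boundary C = boundary_value, C(0) = 0,
  explicit FTCS with dt = 0.2·dx²/D (stability bound dx²/4D, discrete
  maximum principle ⇒ C ∈ [0, C_b]); a shorter final step lands exactly on
  each sampling time. Accuracy vs the separable double-series solution is
  ≲0.1% in mean uptake at the default grid. Rendering:
  intensity = round(255(1 − C)), plus one frozen smoothed-Gaussian texture
  field per run (white noise filtered at texture_scale = 2 px, rescaled to
  texture_amplitude = 20 gray levels — calibrated so near-equilibrium frames
  show the double-peak ECC) and per-frame pixel noise (noise_sigma = 2).
  The linear concentration→gray map is a modeling choice; real staining
  optics are unknown.
* **Kinetics.** Y(t) = Y_e(1 − Ψ(τ*(t))/Ψ(0)) with τ* computed on the exact
  shrinkage path by dense quadrature; the Ψ(0) = 8/15 rescaling makes
  Y(0) = 0 exactly and keeps forward and inverse models consistent. Optional
  multiplicative Gaussian noise (`kinetic_noise_frac`).
* **Shrinkage.** V/V₀(t) = v_f + (1 − v_f)e^{−rt}, defaults v_f = 0.7,
  r = 2×10⁻⁴ s⁻¹ — a monotone decay reaching its plateau well inside the
  810-min (48 600 s) process window, the regime reported for osmodehydrated
  apple.

Default study conditions: D = 2×10⁻¹⁰ m²/s (the order measured for water and
solutes in apple), L₀ = 0.00609 m, 28 samples every 30 min over 810 min,
grid 128². Randomness: texture and pixel-noise streams are spawned from the
seed; the kinetic-noise stream is keyed by (seed, substance) so substances
decorrelate while runs stay bit-reproducible.

**Double-peak study conditions.** Under the linear render map with
boundary_value = 1.0 there is no epoch in which the texture field is fully
visible: the early-time plateau sits at gray 255 and the equilibrium plateau
at gray 0, so one tail of the texture is always clipped and one ECC extremum
is suppressed; mid-time frames are dominated by the radial concentration
gradient. Double-peak demonstrations therefore image with
boundary_value = 0.5 — the equilibrium plateau at mid-gray, as in real
photographs whose stain does not saturate the sensor — at near-equilibrium
times, where the frame is a stationary Gaussian-like field and the signature
is robust across seeds.

**What passing tests do not show.** The generator's tissue is statistically
homogeneous and isotropic, its shrinkage is ideal-exponential and
deformation-free, its kinetics follow the same series the estimator inverts,
and its images lack illumination drift, specular highlights, cell-structure
anisotropy and segmentation artifacts. Recovery results therefore validate
the estimators' correctness, not their robustness to real-photograph or
real-balance error structure.

## Pipeline conventions

`run_pipeline` chains segmentation/ECC, Peleg, both diffusivity methods and
the correlation stage, writing CSV tables and a JSON manifest whose bytes are
identical across reruns of one config. In simulation mode Ψ uses the
configured (generating) Y_e — the Peleg fit is still reported, but fitting
the Peleg hyperbola to Fickian-series data inside a finite window
overestimates Y_e (≈+50% at the default window), and an inflated Y_e puts a
floor under Ψ that collapses slope estimates; with measured inputs, where
Peleg is the model of record for the data, the fitted Y_e is used (an
explicit `Ye` entry overrides). The manifest records the choice per
substance. Metric and stepwise-D series are paired by nearest time within
half the minimum metric sampling interval; Pearson r is reported with a
two-sided t-test p-value and no multiplicity correction.

## Degenerate inputs and tie-breaks

Empty level lists, empty masks, all-background segmentations, flat kinetic
or Ψ series, non-positive k₂, Ψ outside (0, 8/15] at inversion, and
shrinkage series not covering the kinetic span all raise explicit errors.
Ψ values outside [ε, 1] (ε = 10⁻⁹) are clipped with a warning. Nearest-time
pairing breaks ties toward the earlier sample.

## Known limitations

* The diagonal series caps Ψ at 8/15; very early kinetics are unusable for
  inversion by construction.
* Absolute published ECC magnitudes and e(D) magnitudes are not reproducible
  (unstated normalization/scaling); only shapes, signs and directions are.
* 2D images only; no corner-effect deformation, no anisotropic or
  concentration-dependent D beyond the stepwise representation, no external
  resistance.
* The double-peak detector's prominence guard (25% of range) is tuned for
  the generator's texture statistics; heavily multi-modal real textures
  would require adjusting `prominence_frac`.
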