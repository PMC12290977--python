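# osmotopo

Topological and kinetic analysis of osmotic impregnation of plant tissue.

When a fruit cube is immersed in a hypertonic solution (osmodehydration,
optionally vacuum-pulse assisted), water leaves the tissue while solutes and
dissolved bioactives move in. `osmotopo` quantifies that process from two
complementary data streams:

* **Images.** Cross-section photographs are reduced to Euler characteristic
  curves (ECC): at each gray threshold ℓ the image is binarized and
  χ = #components − #holes of the superlevel set is recorded. The spread
  `max(χ/N) − min(χ/N)` of the normalized curve (the **Max–Min metric**) is a
  nonintrusive proxy for impregnation non-uniformity; a diffusion-generated
  Gaussian-like texture shows the characteristic double-peak ECC shape.
* **Kinetics.** Uptake curves Y(t) follow the Peleg model
  Y = Y₀ + t/(k₁ + k₂t) with equilibrium Y_e = Y₀ + 1/k₂. The unaccomplished
  ratio Ψ = 1 − Y/Y_e is inverted through the diagonal cube Fourier series
  Ψ(τ*) = (8³/π⁶) Σ (2i+1)⁻⁶ exp(−3(2i+1)²π²τ*/4) with the
  shrinkage-corrected Fourier number τ* = ∫ D/L(s)² ds,
  L = L₀(V/V₀)^{1/3}, yielding effective diffusivities D̄ (modified slope
  method). The classical slope method (ln Ψ vs t at fixed L₀) quantifies, via
  e(D) = D_no-shrink/D_shrink, how much neglecting shrinkage inflates D.

A synthetic-data generator (finite-difference Fickian images with Gaussian
texture, series-based kinetics, exponential shrinkage) makes the entire
pipeline testable without any experimental download, and a Pearson stage
correlates the image metric with the stepwise diffusivity.

## Worked example

```bash
python examples/diffusivity_shrinkage.py
```

```
true D                  = 2.000e-10 m^2/s
shrinkage-corrected D   = 2.000e-10 m^2/s (R^2 = 1.0000)
no-shrinkage D          = 2.752e-10 m^2/s (R^2 = 0.9996)
e(D) = 1.376
```

A cube shrinking to 60% of its volume shortens the diffusion path; reading
its kinetics as if the path stayed L₀ overstates the diffusivity by 38%,
while the shrinkage-corrected estimator returns the generating value. The
other scripts in `examples/` show the Peleg fit (recovering
k₂ = 2.29 1/(g/g), hence Y_e = 0.4367 g water/g fresh product for apple in
40 °Brix juice), the ECC double-peak detection on simulated stained slices,
and the full CSV-emitting pipeline (`run_pipeline`).

## Layout

- `src/osmotopo/ecc.py` — Euler characteristic, ECC, Max–Min, double peak
- `src/osmotopo/kinetics.py` — mass-balance primitives, Peleg fitting
- `src/osmotopo/diffusivity.py` — cube series, τ* inversion, both slope methods, e(D)
- `src/osmotopo/simulate.py` — synthetic images, kinetics, shrinkage
- `src/osmotopo/correlate.py`, `src/osmotopo/pipeline.py` — Pearson stage and orchestration
- `docs/methods.md` — models, assumptions, numerical choices, limitations
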