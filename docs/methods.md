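# Methods

## Model

### Stokes–Mueller formalism

Light polarization is described by a Stokes vector `S = (S0, S1, S2, S3)`
and a linear medium by a 4×4 Mueller matrix, `S′ = M·S`. Fully polarized
states with unit intensity form the unit Poincaré sphere
`ŝ = (S1, S2, S3)`, `‖ŝ‖ = 1`. Matrices are normalized by `m11` before
analysis so intensity scaling never enters the descriptors.

### Global-polarization Stokes ellipsoid (GPSE)

For every fully polarized incident state `(1, ŝ)` the medium emits
`S′ = M·(1, ŝ)`; we record the intensity-normalized polarization part
`p(ŝ) = (S1′, S2′, S3′)/S0′`. Writing `M` in block form
(`m11 = 1`, first row `(1, dᵀ)`, first column `(1, pᵀ)`, 3×3 block `B`),

```
p(ŝ) = (p + B·ŝ) / (1 + d·ŝ).
```

This is a projective map of the unit sphere; its image satisfies a single
quadric equation exactly, so for noise-free data the point cloud lies on an
ellipsoid to machine precision. The three descriptors of the fitted
ellipsoid with semi-axes `a ≥ b ≥ c` and center `x₀` are

- volume factor `V = ∛(abc)`,
- eccentricity `E = √(1 − (b² + c²)/(2a²))`,
- center displacement `D† = 3‖x₀‖/(a + b + c)`.

Identity gives `V = 1, E = 0, D† = 0`; an isotropic depolarizer
`diag(1, p, p, p)` gives `V = p, E = 0`; a pure retarder leaves the unit
sphere invariant; the ideal depolarizer collapses the image to a point
(`V = 0`, flagged degenerate).

### Ellipsoid fitting

The cloud is fitted by a direct algebraic quadric fit: the 10 coefficients
of `x'Ax + b'x + c = 0` are the smallest-singular-vector of the N×10
design matrix; `A` must be definite (otherwise a fit error is raised with
the residual of the general fit), and center/axes follow from the
eigendecomposition. The reported `fit_residual` is a first-order geometric
residual, RMS of `|F(x)| / ‖∇F(x)‖` over the cloud, so it is comparable
across scales and directly thresholdable (noise-free clouds sit below
1e-14; the acceptance threshold is 1e-8).

Degenerate media map the sphere *many-to-one*, so the image of a rank-
deficient block is a **filled** ellipse or segment, not a curve; no
boundary quadric exists. Rank is detected from the singular values of the
centered cloud (relative tolerance 1e-9), and degenerate clouds are
summarized by half-extents along the principal directions — a measurement
of the filled region, accurate to the sampling density (≈5e-3 at 2000
states), not a curve fit. The degenerate flag is set, and descriptors that
become 0/0 are NaN.

### Lu–Chipman polar decomposition (MMPD)

`M = M_Δ · M_R · M_D` with the diattenuator built from the first row,
the retarder and depolarizer separated from `M′ = M·M_D⁻¹` by a symmetric×
orthogonal (left polar) factorization computed via SVD, with the
`sign(det)` convention fixing the eigenvalue signs of the depolarizer.
Scalars: diattenuation `D = ‖(m12, m13, m14)‖/m11`; total retardance
`R = arccos(tr(M_R)/2 − 1)`; linear retardance
`δ = arccos(√((m22+m33)² + (m32−m23)²) − 1)` evaluated on `M_R`;
depolarization power `Δ = 1 − |tr(M_Δ) − 1|/3`. Ideal polarizers
(`D = 1`) make `M_D` singular; the pseudoinverse path is used and the
result flagged. Arguments of `arccos` are clipped to `[−1, 1]`, warning
if the excursion exceeds 1e-6.

`δ` is only observable up to the triangle fold
`fold(δ) = |remainder(δ, 2π)|` into `[0, π]`. Dual-wavelength unwrapping
assumes the retardance scales as `1/λ` (dispersion-free birefringence):
for measurements at λ₁ = 633 nm and λ₂ = 870 nm the candidate true values
`2πm ± δ_meas` (orders `m ≤ max_order`, default 3) are scored by the
consistency residual `|δ₁λ₁ − δ₂λ₂|/λ₁`; a unique candidate below the
0.05 rad threshold wins, otherwise an ambiguity error lists the top
candidates.

### Dual-rotating-retarder (DRR) polarimeter

Fixed horizontal polarizer/analyzer with quarter-wave plates rotating at
`w` (generator) and `5w` (analyzer); 30 frames at 6° generator steps.
Each frame intensity is linear in the 16 Mueller elements,
`I = G·vec(M)`; the 30×16 system has condition number 13.0484 and is
solved by least squares (the Fourier route — a series in `2nw` up to
`n = 12` followed by coefficient inversion — is provided and agrees to
1e-9). At least 16 frames and a non-aliasing schedule are required.

## Synthetic tissue model

### What it emulates

The `synth` module is a **matrix-level surrogate** for fibrous tissue:
an ensemble average of `K` single-fiber elements

```
M = mean_k  Depol(p) · Retarder(δ_k, θ_k) · Diattenuator(d, θ_k),
δ_k ~ Normal(δ0, σ_δ),   θ_k ~ truncated Normal(θ0, σ_θ),
```

seeded and deterministic. It reproduces the qualitative responses of
tissue polarimetry: retardance jitter causes anisotropic depolarization,
fiber-axis order raises the ellipsoid eccentricity, aligned diattenuation
displaces the center, and an isotropic depolarization floor `p` scales the
whole ellipsoid. When `σ_θ = 0` and `d = 0` the average has the closed
form (used as the `analytic` mode and as a test oracle): the Gaussian
characteristic function gives `E[e^{iδ}] = e^{iδ0}e^{−σ²/2}`, so the
(S2, S3) rotation block shrinks by `e^{−σ_δ²/2}` while the fiber-axis
component is preserved. At `δ0 = 0.7, σ_δ = 0.5, p = 1` this yields
semi-axes `(1, e^{−1/8}, e^{−1/8})`, hence `E = √(1 − e^{−1/4}) = 0.47032`
and `V = e^{−1/12} = 0.92004`.

Defaults (`δ0 = 0.7`, `σ_δ = 0.3`, `θ0 = 0`, `σ_θ = 0`, `d = 0`,
`p = 1`, `K = 10000`, `seed = 0`) are the study conditions: a moderately
birefringent, well-ordered fiber bundle with jitter strong enough to
depolarize measurably but far from the fold.

The **dehydration series** ramps `δ0` over `[0.2, 3π]` in 19 steps with
coupled jitter `σ_δ = 0.1·δ0` and polarization maintenance rising from
0.6 to 0.95 — emulating tissue dehydration, where effective birefringence
grows until the folded MMPD δ wraps repeatedly while the GPSE eccentricity
grows monotonically.

The **phantom** is a 64×64 two-region image (isotropic depolarizer
`p = 0.7` background, fibrous inclusion at `δ0 = 0.7, σ_δ = 0.3, d = 0.1,
p = 0.9`), optionally with seeded Gaussian element noise, with ground
truth and region masks returned alongside.

### What it does not emulate

No photon transport: no scattering coefficients, particle sizes, phase
functions, or path-length distributions, and no wavelength dependence
beyond the `1/λ` retardance scaling assumed by the unwrapper. Absolute
parameter values are not calibrated to any tissue type; only the
qualitative parameter directions are meaningful.

### Known limitation: eccentricity under strong axis disorder

`E` is unsigned — it measures shape, not orientation. For small axis
disorder, increasing `σ_θ` lowers `E` (disorder averages out the fiber
direction), but near `σ_θ ≈ 0.2` (at the default retardance settings) the
two largest semi-axes exchange roles: strong disorder suppresses the
circular (S3) response below the linear ones, the ellipsoid turns oblate,
and `E` **rises again**. The monotone "more order → more eccentricity"
reading is therefore valid only in the ordered regime; the test suite
checks the monotone regime and pins the post-crossover reversal
explicitly.

## Numerical choices

- **State sampling**: deterministic Fibonacci (golden-spiral) lattice,
  default 2000 states for single-matrix analysis and 500 for per-pixel
  maps (a 64×64 map takes a few seconds); a `canonical6` set provides the
  six axis states (0°/45°/90°/135° linear, both circulars).
- **Eccentricity snapping**: `E = √(1 − (b² + c²)/(2a²))` has unbounded
  slope at `E = 0`, so 1e-15 axis noise from the eigen-solve appears as
  `E ≈ 1e-8`. Semi-axes within a relative 1e-12 of each other are snapped
  equal before computing `E`; this cannot mask any real `E > 1e-6`.
- **Degeneracy tolerance** 1e-9 (relative) on cloud singular values; same
  tolerance class for the DoP clip band and physical-realizability
  threshold (smallest coherency eigenvalue ≥ −1e-9·m11).
- **arccos conditioning**: retardance formulas lose precision like √ε
  near the fold points 0 and π; derived retardances are therefore
  trustworthy to ~1e-8 rather than machine precision, and tolerances on
  folded quantities reflect that.
- **Tie-breaking**: the optimal-probe search returns the first state (in
  deterministic sampling order) within a relative 1e-12 of the maximum
  contrast, so results are stable under floating-point jitter.
- **Randomized physical matrices** are built as depolarizer·retarder·
  diattenuator products with the anisotropic depolarizer diagonal
  `(1, p1, p2, p3)` rejection-sampled against the coherency (Cloude)
  realizability conditions `1 ± p_i ∓ p_j − p_k ≥ 0`.
- **I/O**: text matrices use 17 significant digits (exact float64
  round-trip); TIFF stacks are 16-page float32 in row-major element order
  `m11, m12, …, m44` recorded in the file description; PLY meshes are
  ASCII with per-vertex latitude coloring (green north pole → blue south)
  and the fitted ellipsoid as a second element; every CLI run writes a
  JSON provenance file (inputs, configuration, seed, version).

## Limitations

- The ellipsoid summarizes only the *intensity-normalized* response;
  absolute transmittance anisotropy beyond `D†` is not captured.
- Degenerate (rank-deficient) media yield half-extent summaries whose
  accuracy is limited by sampling density, not by the fit.
- The dual-wavelength unwrapper assumes dispersion-free `1/λ` scaling;
  real tissue birefringence dispersion biases the recovered order when
  `δλ/λ` deviates by more than the 0.05 rad consistency threshold.
- The DRR simulator models ideal quarter-wave plates and polarizers —
  no retardance errors, orientation offsets, or source drift.
- The ensemble surrogate has no photon transport (see above) and treats
  depolarization as a diagonal factor commuting assumptions into the
  chosen composition order.
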