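# Methods

This note documents the models, conventions, numerical choices and known
limitations of `tm2d`. It is the reference for anyone extending the package
or interpreting its outputs.

## Conventions

* **Euler angles** are intrinsic ZYZ, degrees: `R = Rz(φ)·Ry(θ)·Rz(ψ)`,
  applied to column vectors of template coordinates; θ ∈ [0°, 180°], φ and
  ψ reduced to [0°, 360°). Pose tables and the experimental STAR export
  depend on this convention.
* **Axes.** Volumes are indexed `[z, y, x]` with the beam along +z; images
  `[y, x]`; positions are 0-based `(x, y)` with x the fast axis, matching
  the MRC fast axis on disk.
* **Defocus** is in angstroms, positive = underfocus. Particle records
  carry defocus *offsets* relative to the micrograph's nominal CTF.
* **Units.** Pixel sizes Å/px, spatial frequency 1/Å (cycles per Å),
  B factors Å².

## Orientation sampling

`uniform_grid` places θ rings every Δθ from 0° to 180° inclusive, with
per-ring azimuth counts

    n_φ(θ) = max(2, round(360·sin θ / Δθ)),

i.e. every ring, including the poles, carries at least two azimuth
samples, and ψ is sampled on [0°, 360°/n) in Δψ steps under Cn symmetry
(symmetry axis along template z; halving the ψ range under C2 is what
produces the factor-two sensitivity gain of symmetric searches). Ordering
is θ-major, then φ, then ψ, which fixes argmax tie-breaking. With Δψ=1.5°,
Δθ=2.5°, C1 this gives 6602 directions × 240 in-plane angles = 1 584 480
orientations; with the 13-plane defocus schedule (−1200…1200 Å, 200 Å) the
search performs 20 598 240 cross-correlations per pixel position. The pole
rule and rounding were chosen so that this printed cardinality is
reproduced exactly; note that at θ ∈ {0°, 180°} the two azimuth samples are
duplicate rotations (φ and ψ are degenerate there), so the grid is unique
as triplets but carries two redundant planes per pole per ψ.

## Scattering simulation

Atoms contribute five-Gaussian elastic electron scattering factors (Peng,
Ren, Dudarev & Whelan, Acta Cryst. A52, 257, 1996; elements H, C, N, O, P,
S), broadened by `B_eff = b_scale·B + extra_b` with per-term real-space
variance `(b_i + B_eff)/(8π²)` per dimension. Hydrogens are accepted in
input but excluded from simulation. Each Gaussian is **integrated over the
voxel** (separable erf differences, cutoff 4σ) rather than point-sampled,
so integrated atom weight is conserved independent of B and pixel size —
the property that makes pixel-size rescaling experiments well behaved even
for sharp atoms below the sampling limit. The finished volume is
mean-subtracted so correlations are zero-mean. Amplitudes are in arbitrary
units proportional to scattering factors; absolute scale cancels in all
z-scores (only relative amplitudes matter), so no per-electron
normalization is attempted.

## Filters and projection

* **CTF**: `CTF(k) = −[√(1−w²)·sin γ + w·cos γ]·exp(−B k²/4)` with
  `γ = πλΔf(α)k² − (π/2)Cs λ³k⁴ + phase`, astigmatism interpolated as
  `Δf(α) = (Δf₁+Δf₂)/2 + (Δf₁−Δf₂)/2·cos 2(α−α_ast)`, and
  `λ = 12.2639/√(V + 0.97845·10⁻⁶ V²)` Å.
* **Whitening** is computed once per micrograph from its radially averaged
  power spectrum (one bin per Fourier-pixel ring, rounded radius; folded
  rfft columns double-weighted): `W(k) = 1/√PSD(k)`, DC zeroed, normalized
  to unit mean square over non-DC bins. Radial profiles are applied to 2D
  grids by linear interpolation in |k|. Whitening is radial only (no
  per-quadrant normalization).
* **Projection** uses central-slice extraction: the volume's centered 3D
  FFT is sampled on the plane `Rᵀ(k_x, k_y, 0)` with trilinear
  interpolation (real and imaginary parts separately, float32), then
  inverse-transformed. Beyond-Nyquist corners read as zero. Oracle checks
  against real-space axis sums agree to <10⁻³ relative for smooth volumes.

## Search engine and the noise model

Per search point the template projection is filtered (CTF × whitening) on
the template-box grid, normalized to zero mean and unit ℓ₂ norm over the
(zero-padded) frame, and circularly cross-correlated with the whitened,
zero-mean, unit-variance image via FFT; a phase ramp recenters correlation
maps on particle centers. Per pixel the engine accumulates the running
maximum and argmax (strict inequality, so ties resolve to the earliest
search index in (orientation, defocus) order), the sum and sum of squares
of all values (float64), and optional tail-exceedance counts. The z map is
`(MIP − μ)/σ` with a variance floor of 10⁻¹².

Under unit white noise each correlation value is standard normal by
construction (unit-norm template dotted into unit-variance noise), and the
measured global value variance on pure-noise micrographs is 1.000 ± 0.001.
Two properties of the per-pixel mean/variance model are worth knowing:

* The **variance map averages below 1** for globular templates (~0.65 for
  the default synthetic blob): the per-pixel mean absorbs the
  orientation-average component common to all projections, and the
  centered values have variance `1 − ‖t̄‖²`. Because candidate templates in
  refinement and constrained search share that common component, their
  centered scores are correctly standardized — this is precisely why the
  empirical per-pixel mean and variance are used rather than the nominal
  (0, 1).
* **Exceedance counts aggregated over a full search are not
  Poisson-dispersed**: the ~10⁴ planes share one noise realization and are
  strongly correlated, so counts fluctuate by a few percent between
  realizations. Counts for a *single* projection plane are effectively
  independent across pixels and match `n·SF(t)` to Poisson accuracy; null
  calibration uses that case for tail checks.

Thresholds: `z*` solves `N·SF(z*) = m` (default m = 1 false positive per
micrograph; `N` = pixels × orientations × defocus planes) via the inverse
survival function. Per-particle false-positive probabilities are
`1 − (1 − SF(z))^N` computed in log space. Peak extraction is greedy
descending-z with a circular exclusion radius (default box/4) and an edge
band of half a template box.

## Refinement

Coarse-to-fine: the three Euler angles are perturbed on {−2…2}·step grids
with the step halved from `angular_step_initial` (default 0.5°) to
`angular_step_final` (default 0.05°); after each angular stage a defocus
line search (default ±100 Å in 20 Å steps) runs at the current angles; the
position is re-localized within ±2 pixels. The input pose is always in the
candidate set and updates require strict improvement, so refined z never
decreases. Scores reuse the whitened image and, when provided, the
mean/variance maps of the original search, so refined z values are on the
search's scale. Particles whose scoring window leaves the image are
returned unchanged with flag `"edge"`.

Angular precision is physics-limited: the argmax deflection scales roughly
as (orientation decorrelation angle of the template)/z. Recovering 1°
perturbations to 0.1° therefore requires the sharp-template, strong-signal
regime (the convergence experiments use z ≈ 100 detections); at z ≈ 10 the
same procedure converges to the achievable ~0.5°.

## Pixel-size optimization

For each offset δ in a coarse grid (±0.05 Å, 0.01 Å) the template is
re-simulated at `pixel_size + δ` (box size unchanged), every input particle
is re-scored at its fixed position and pose (positions are deliberately not
re-extracted), and the objective is the mean z of the top-N particles
(default N=50, after dropping input z < 8) or of all above threshold; a
fine grid (±0.008 Å, 0.001 Å) centered on the coarse optimum follows. The
whitening filter and (optionally) the noise maps of the original search are
reused so z is comparable across δ. The method scales the template to match
the image and is agnostic to which side the calibration error is on. On
synthetic mismatches the objective curve is unimodal and the planted offset
is recovered to about the fine step.

## Constrained two-body search

The constraint geometry is derived from two conformational states of the
mobile body: the Kabsch rotation between the states defines the rotation
axis (frame z); the roll axis (frame y) is the projection of the global y
axis (fallback x) onto the orthogonal plane; and the body-1 → body-2 center
offset `c` (Å) is the difference of centroids. A candidate with offsets
(ψ_off, θ_off) has orientation `R_ref·F·Rz(ψ_off)·Ry(θ_off)·F⁻¹`, position
shifted by the in-plane part of `R_ref·c`, and defocus shifted by its
beam-axis component (positive toward more underfocus — a sign convention
that may need flipping against other packages).

The default four-stage schedule searches ψ_off −13…2.5° (1° steps; the
inclusive arange ends at 2° since 2.5° is off-lattice), θ_off −6…4° (1°),
both ±5° (0.5°) and both ±0.5° (0.1°) with defocus ±100 Å (20 Å), each
stage centered on the previous winner (a single best candidate is carried
forward). Scores are standardized with the mean/variance maps of a prior
full search of the body-2 template on the same micrograph. Each stage
evaluates a (2·window+1)² spatial neighborhood (window default ±2 px) of
the predicted position; `n_comparisons` accumulates stage cardinality ×
window size (default 1799 × 25 = 44 975), and significance is called at
`n_comparisons·SF(z) = 1/200` per particle — far below the full-search
threshold, which is the sensitivity gain of constraining the search.
Rotation-state classification partitions on |ψ_off| ≥ 4°.

## Synthetic data

Generators are pure functions of their arguments including the seed.
Micrographs are built by adding CTF-filtered Fourier-slice projections
(identically filtered to the search path, so self-match is maximal by
construction) at integer pixel positions, plus white Gaussian noise —
white because whitening makes it the natural null; correlated backgrounds
are not modelled. Particle amplitude is set so the nominal matched-filter
z is `snr`: `amplitude = snr·σ_noise/‖filtered projection‖₂`. In dense
fields the realized z falls below nominal because the whitening filter,
estimated from the image, partially suppresses the signal band (e.g. ~25%
area coverage at snr 8 yields z ≈ 6); this mimics the self-whitening of
crowded cellular images and is left uncorrected.

Default study conditions (chosen once, as plausible stand-ins for the
regimes the method targets):

* **default blob** — 800 carbon atoms uniform in a 20 Å-radius sphere,
  B ∈ [20, 60] Å², 64³ box at 1 Å/px: a generic globular particle for
  detection and null-calibration experiments; planted fields use snr 15
  (in-cell z-scores for large complexes span roughly 8–30).
* **sharp bodies** — 2000 atoms / 26 Å / B ∈ [5, 20] Å² (body 1, 64³ box)
  and 900 atoms / 18 Å / B ∈ [5, 20] Å² (body 2, 48³ box): the
  high-resolution-template regime where 0.05°-level refinement and
  0.001 Å-level pixel-size sensitivity are meaningful.
* **two-body fields** — body-2 poses generated through the same constraint
  geometry used in analysis; intersubunit offsets from a 75%/25% mixture,
  ψ_off ~ N(0°, 0.5°) vs N(−8°, 1°), with roll coupled as
  θ_off = 0.15·ψ_off + N(0°, 0.3°); body-2 snr defaults to 8 (a weaker
  subunit of roughly a quarter the mass).
* **CTF** — 300 kV, Cs 2.7 mm, 7% amplitude contrast, 5000 Å defocus, no
  astigmatism, B 0 Ų.

What passing tests on these fixtures do **not** show: performance on
structured (non-white) cellular background, template bias between related
conformations, beam-tilt/magnification anisotropy, or detection limits in
absolute mass units — the synthetic SNR knob abstracts molecular mass and
imaging dose into one number.

## Problem sizes in the test suite and acceptance script

Experiments are sized for a single CPU core: 256²–512² micrographs,
64³/48³ templates, coarse search grids (ψ = θ = 15° with 3 defocus planes
for detection experiments; 20° single-plane searches to build noise maps
for constrained runs). The acceptance script uses 4 null micrographs, one
20-particle recovery field, one 12-particle pixel-size field, 10 exact
rotation-recovery pairs, 100 null decoy sites and 128 mixture pairs; the
test suite uses 10 null micrographs, 200 decoys and 240 mixture pairs.
Statistical tolerances in the tests account for these sizes (e.g. a 240
pair mixture determines the rotated fraction to ±3% binomial s.e.).

## Numerical choices

* FFTs via scipy.fft in float32/complex64 on the hot paths; statistical
  accumulators in float64. Correlation is circular on the full frame;
  peaks in the half-box edge band are discarded.
* Variance floor 10⁻¹² before division; whitening bins with zero power get
  filter value 0.
* `detection_threshold` uses the inverse survival function (equivalent to
  erfc bisection at < 10⁻⁹); `fp_probability` uses log1p/expm1.
* Ties in argmax resolve to the earliest search index; identical inputs
  give bitwise-identical outputs.
* Degenerate inputs (all-zero images, collinear point sets, atoms outside
  the box, particles at the image edge) raise typed errors or return
  flagged records rather than propagating NaNs.

## Known limitations

* Correlation is computed with circular boundary conditions; a bright
  object near one edge can leak into the opposite edge band (which is
  excluded from peak extraction anyway).
* The scaled-MIP statistic is meaningless on noise-free images (the
  variance map degenerates); signal-dominated but noisy fixtures are used
  instead.
* Only cyclic (Cn) symmetry groups are supported, with the symmetry axis
  along template z.
* The STAR export writes this package's ZYZ angles without verifying the
  consuming package's handedness; it is marked experimental.
* GPU acceleration and movie-frame handling are out of scope; the numpy
  backend processes roughly 500–1000 search points per second on 256²
  images on one core.
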