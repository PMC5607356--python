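# Methods

This note documents the models, conventions, numerical choices and known
limitations of `fibredisp`. It is written for a reader who wants to know
exactly what the package computes and what passing its tests does and
does not demonstrate.

## Conventions

All in-plane orientations are **axial** angles in degrees, measured
counter-clockwise from the image +x (column) axis with y pointing up in
the displayed image, reduced mod 180°. FODs (`AxialFOD2D`) are
normalized histograms over half-open bins `[a, b)` covering `[0°, 180°)`,
180 bins by default. Axial statistics are computed in the double-angle
representation (2θ), the standard circular-statistics treatment that
makes 0° and 180° identical.

## Bingham machinery

The 3D Bingham density is `p(n) ∝ exp(−k₁(μ₁·n)² − k₂(μ₂·n)²)` with
orthonormal axes (μ₀, μ₁, μ₂) and k₁ ≥ k₂ ≥ 0. Mass concentrates around
μ₀; a large k along an axis means little spread toward that axis. The
sign/scale convention of the exponent is fixed as above and used
consistently by the fitters and the generators.

**Normalization** is computed by deterministic spherical quadrature: a
product grid of Gauss–Legendre nodes in cos(polar angle) × equispaced
azimuths (64 × 128 = 8192 nodes for evaluation; 24 × 48 inside the
optimizer). At the concentration cap this integrates the density to
better than 1e-6; a series expansion was rejected in favour of
quadrature robustness over the full k range used here (0–128).

**Concentration cap** `K_MAX = 128` (ODI ≈ 0.005): beyond this the
distribution is narrower than any angular binning used in the package,
so larger values are indistinguishable from "parallel". The cap applies
to fitting; synthetic ground truth is not capped.

**In-plane restriction.** Writing the exponent as −nᵀQn with
Q = k₁μ₁μ₁ᵀ + k₂μ₂μ₂ᵀ, the restriction to the great circle of a plane is
again a Bingham with concentration k₂D = (difference of the eigenvalues
of the restricted 2×2 form) and mean axis along its low-eigenvalue
eigenvector (the in-plane projection of μ₀). Note the distinction
between this *restriction* and the *marginal* of the 3D law projected
into the plane: they coincide (to within the tolerances tested, 0.03 in
ODI) only when the out-of-plane axis is strongly concentrated — the
regime of mostly-in-plane fibres that the in-plane comparison is
designed for. The principal axis within 1e-6 of the plane normal is an
error; within 10° a warning.

**In-plane Bingham and ODI.** On the circle,
`p(θ) ∝ exp(−k₂D sin²(θ−µ))`, which in 2θ is exactly a von Mises law
with concentration k₂D/2; its normalization `π e^(−k/2) I₀(k/2)` is
evaluated with the scaled Bessel `i0e` for stability. The orientation
dispersion index is `ODI = (2/π)·arctan(1/k₂D)`. Maximum-likelihood
fitting of a binned FOD takes µ in closed form from the double-angle
trigonometric moment and k by bounded scalar optimization on [0, K_MAX]
(tolerance 1e-6), with endpoint snapping so uniform data fit k = 0
exactly and a delta saturates at the cap.

## Diffusion model

`S(g,b) = S₀[f_iso e^(−b d_iso) + (1−f_iso)∫B(n) e^(−b(d_perp+(d_par−d_perp)(g·n)²))dn]`,
stick response (d_perp = 0) by default. The orientation integral uses the
fixed quadrature grid, so fits are deterministic given their seed. The
default protocol mirrors a post-mortem acquisition: 120 quasi-uniform
directions at b = 5000 s/mm² plus four volumes at b ≈ 8 s/mm².

**Fitting** is bounded nonlinear least squares (Gaussian objective on
magnitudes) over (S₀, f_iso, d_par, d_iso, k₁, k₂, three orientation
angles), with diffusivity bounds [1e-5, 3e-3] mm²/s appropriate to fixed
tissue. The principal axis is initialized from the eigenvector of the
smallest eigenvalue of the signal-weighted orientation tensor (the
along-fibre direction attenuates most); three starts with different
concentration initializations are used by default — on synthetic voxels
a single start already reaches the same accuracy, so this is a safety
margin. k₁ ≥ k₂ is enforced by swapping the dispersion axes after
convergence. Voxels whose anisotropic fraction is below 5% or whose
angular signal contrast is below twice the residual noise level are
flagged `dispersion_unreliable` and propagate as missing values in ODI
maps rather than raising.

**Noise convention.** Synthetic DWI uses Rician (magnitude-detected)
noise with σ defined against the *mean diffusion-weighted signal*
(SNR = mean b=5000 signal / σ), the convention in which the emulated
acquisition's white-matter SNR is ≈ 15. Fitting itself remains Gaussian
least squares, which at this SNR leaves a negligible Rician bias
relative to the tested tolerances.

**fODF 2D projection.** `fodf2d` accepts any sampled spherical function
(including the fitted Bingham fODF — no spherical deconvolution is
implemented), projects sample directions axially into the plane, and
returns the convex hull of the polar point set (amplitude as radius,
antipodes included), resampled by ray–polygon intersection on the FOD
angular grid. A tiny regular polygon at the origin regularizes the hull
for near-delta functions.

**Stick vs cigar.** The forward comparison generates a Watson-dispersed
stick and a coherent cigar. Matching *only* d_perp cannot reproduce
dispersion (its SSD optimum is d_perp ≈ 0, because dispersion also
raises the along-axis signal); the cigar response is therefore matched
over (d_par, d_perp) jointly, which demonstrates the intended partial
mimicry: a lower effective d_par plus a non-zero d_perp.

## PLI

The sinusoid model is `I(ρ) = (I₀/2)(1 + |sin δ| sin(2ρ − 2φ))` with
analyser angles ρ (18 equiangular by default). With equiangular angles
the fit is an exact discrete Fourier solution: I₀ from twice the mean,
retardation and φ from the second-harmonic coefficients. Orientation is
masked where retardation < 0.05 (default): the phase of a near-zero
amplitude is numerically meaningless — this also mimics the black
speckling of through-plane fibres, which this 2D setup cannot recover
(no inclination angle is estimated). Background correction divides by a
tissue-free blank stack where available (zero-blank pixels become
masked, not errors) and otherwise by a unit-mean large-σ Gaussian
illumination estimate per angle. Neighbourhood FODs pool valid
orientations over non-overlapping windows (default 100 px across 6
serial sections, matching an MRI voxel); windows with under 1% valid
pixels are missing. Section-to-section registration is assumed done.

## Histology

PLP (myelin) images use the inverted red channel as stain intensity
(DAB-dark = high signal); GFAP (astrocyte) images the HSV saturation
channel. Nuclei are pixels inside an RGB box (default R < 0.55,
G < 0.55, B > 0.45, matched to the synthetic generator — real data needs
recalibration), dilated by 2 px to cover the partial-volume halo;
they are excluded from all downstream analysis.

The structure tensor is the Gaussian-window average of the outer product
of Gaussian-derivative gradients. Texture runs perpendicular to the
dominant gradient, so orientation is the eigenvector of the *smaller*
eigenvalue; coherence = (λ₁−λ₂)/(λ₁+λ₂) is computed for QC but the FOD
uses all suprathreshold pixels. Scale defaults are σ_grad = 2 px,
σ_window = 10 px at 0.28 µm/px full resolution (resolving ~1 µm fibres
while averaging over several); for the phantom-scale images (≈2 px
fibres) the tests use σ_grad = 0.6, σ_window = 1.2 — the window must
stay of the order of the fibre width, or averaging across neighbouring
fibres compresses the recovered dispersion. Patches are non-overlapping,
anchored at the origin, with partial edge patches dropped; the intensity
threshold defaults to Otsu per patch; the area fraction is the
suprathreshold share of non-nucleus pixels.

## Area → volume mapping and FOD combination

A 6 µm section at 0.28 µm/px projects ≈ 21 px of tissue, so the stained
area fraction overestimates the volume fraction. The mapping is built by
simulation: straight cylinders (default radius 2 px) with uniformly
random orientation and position are unioned into a periodic boolean box
(default 64³) until each target volume fraction is reached; a central
slab of the section thickness is max-projected and its foreground
fraction recorded, averaged over repetitions. Periodic (minimal-image)
geometry keeps the cylinder process stationary — without it, coverage
decays toward the box faces and the central slice is biased high
relative to the whole-box volume fraction, violating the thin-section
stereological identity (area = volume for a 1 px slab) that anchors the
simulation. The averaged curve is made invertible by isotonic L2
regression (a running maximum would accumulate upward Monte-Carlo
drift). Inversion is monotone linear interpolation, clamped with a
warning outside the simulated range. Overlapping (boolean) packing was
chosen because only "randomly oriented fibres at increasing volume
fractions" is specified; hard-core packing, curved fibres and radius
distributions are out of scope.

Compartment volume fractions are rescaled proportionally so
f_M + f_A = 1 exactly (the astrocyte fraction is computed as the
complement to keep the identity exact in floating point), and FODs
combine bin-wise: `FOD_MA = f_M·FOD_M + f_A·FOD_A`.

## Spatial comparison

Deformation fields are inputs (registration itself is out of scope).
The local affine at each grid point is the central-difference Jacobian
of the mapping; its polar-decomposition rotation (closed form
`atan2(J₂₁−J₁₂, J₁₁+J₂₂)` for 2×2) reorients FODs by a circular shift
with linear bin interpolation (mass conserved exactly; exact for shifts
that are bin multiples). Non-positive Jacobian determinants (folding)
are masked with a warning.

Profiles are means along the superior–inferior direction per left–right
position within a mask (≥ 2 voxels per position by default, midline
defined by the mask's bounding box). Correlations are Pearson r
throughout, optionally on the subset below an ODI cutoff (default 0.1).
The astrocyte-contribution question is answered by OLS regression
(statsmodels) of the dMRI profile on the myelin and astrocyte profiles
with intercept; condition number > 1e8 flags collinearity.

## Synthetic data and the phantom

One `PhantomSpec` (default 6 × 16 patches) drives all three generators:
a corpus-callosum-like band (2 rows) whose planted ODI rises from 0.05
laterally to 0.30 at the midline along a Gaussian bump, a coherent
vertical tract (ODI 0.05), a two-component crossing region (two laws 90°
apart, each ODI 0.08; their mixture fits to ODI ≈ 1), and background.
The planted per-patch "ODI" is defined as the Bingham fit to the planted
orientation density (mixture-aware), the same currency every pipeline
reports.

* **Stains**: fibres are rectangles (myelin: straight, width 1.8 px;
  astrocytes: thinner, 4-segment wiggly polylines with 10° jitter —
  wider FODs by construction) with a parabolic cross-sectional intensity
  profile. The profile matters: real overlapping fibres remain
  individually textured, and without an internal gradient the union of
  flat rectangles merges into blobs whose orientation the structure
  tensor cannot recover. Fibres wrap toroidally inside their region's
  bounding rectangle so the pixel count per fibre is independent of its
  orientation (clipping at region borders would preferentially delete
  pixels of off-axis fibres and bias the rasterized truth toward low
  dispersion). Per-fibre stain uptake varies ±20%; blue nuclei ellipses
  and Gaussian noise (σ = 0.02) complete the scene. Fibres are added
  until each patch reaches the target area fraction (default 0.35).
* **PLI**: the sinusoid model evaluated from the per-pixel planted
  orientation (retardation 0.6 and transmittance 150 on tissue, 220 off
  tissue), 6 slices with 2° per-slice orientation jitter, Rician noise
  at SNR 20 (σ = mean intensity / SNR).
* **DWI**: per-patch forward signals from the planted law lifted to 3D
  with the out-of-plane axis 4× as concentrated (k₁ = 4·k₂D, mostly
  in-plane fibres); crossing patches average their two components'
  signals; background is purely isotropic. Rician noise at DW-SNR 15.
* **Deformations**: sums of Gaussian-windowed infinitesimal rotations
  with closed-form Jacobians; the returned ground-truth rotation field is
  the polar angle of the analytic Jacobian, and amplitudes are capped so
  the determinant stays positive.

All generators are deterministic given their seed.

**Problem sizes.** The default phantom uses 96 px stain patches, 32 px
PLI windows and one DWI voxel per patch (96 voxels, 124 volumes) —
deliberately smaller than real acquisitions (1400 px patches, 100 px
windows) so a complete three-modality run with per-voxel model fitting
finishes in minutes; the per-patch fibre and pixel counts were chosen so
that estimator noise stays well inside the tested tolerances. The
stereology maps default to a 64³ box; the thin-slab identity check
averages 16 repetitions.

**What passing tests shows — and does not.** The synthetic data obey the
package's own forward models (sinusoid, stick+Bingham, rectangle
fibres). Recovery therefore validates the inverse machinery, the
conventions linking the modalities, and the statistical pipeline — not
robustness to real-tissue effects absent from the generators:
inclination (through-plane fibres appear only as masked retardation),
section deformation beyond supplied fields, staining heterogeneity, cut
artifacts, axon beading, or model mismatch of the diffusion response.
Region-wise real-data correlations cannot be reproduced at this scale
and are not targets of the test suite.

## Known limitations

* No spherical deconvolution; `fodf2d` operates on user-supplied or
  model-derived spherical samples.
* No 3D PLI (tilting stage / micro-lens); the inclination ambiguity of
  a single-view setup is accepted and masked.
* Whether the emulated acquisition fitted or fixed its diffusivities is
  unknown; both are fitted here, with bounds.
* The crossing region is generated as a two-component mixture but fitted
  with a single Bingham everywhere, by design; its fitted ODI is a
  saturation value, interpretable only as "high dispersion".
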