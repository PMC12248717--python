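# Methods

This note records the models, parameter choices and numerical conventions
behind `savelight`, and what the synthetic test conditions do and do not
demonstrate about real endoscopy data.

## Spectral grids and colorimetry

All spectra live on uniform wavelength grids. The master grid is
400–780 nm at 5 nm (77 bands): the colorimetric integrals that define
tristimulus values run over 400–700 nm only, while the narrow-band stage
needs the 600–780 nm region for its correction bands, so one grid serves
both views and the XYZ integration simply masks wavelengths above 700 nm.

Tristimulus values are left-anchored Riemann sums with uniform weight Δλ,

    X = k Σ S(λ) R(λ) x̄(λ) Δλ,   k = 100 / Σ S(λ) ȳ(λ) Δλ,

which makes results bit-reproducible and gives Y = 100 for a perfect
reflector under any positive illuminant exactly (k cancels the illuminant
normalisation). The packaged CIE 1931 2° observer and D65 tables are 5 nm
CSVs linearly interpolated from the canonical 10 nm tabulations; since the
calibration pipeline is self-consistent (reference XYZ and camera model use
the same tables), sub-percent interpolation error in the tables does not
propagate into any reported statistic.

Gamma linearisation defaults to the IEC 61966-2-1 sRGB piecewise EOTF, with
a pure power-law alternative selectable per capture. CIELAB uses the
standard cube-root/linear-segment switch; CIEDE2000 implements the
reference algorithm (G compensation, piecewise mean-hue rules, blue-region
rotation term) with parametric factors kL = kC = kH = 1, and is validated
against the 34 published verification pairs and an independent
implementation to 1e-4.

The default illuminant and white point are D65 with the 2° observer. The
endoscope lamp spectrum is in principle the right S(λ); it is exposed as a
parameter everywhere, D65 being only the neutral default.

## Calibration model

The variable matrix V contains every trivariate monomial of total degree
≤ 3 in the dark-subtracted, linearised channels plus a constant column —
20 terms in graded-lexicographic order with recorded labels. Third order
is the deliberate ceiling: it is expressive enough to absorb channel
cross-talk and residual nonlinearity while small enough (20 unknowns from
24 patches) to avoid overfitting. The split of V into colour, nonlinear
and dark groups is kept as labels only; all terms enter one joint fit.

Both fits (correction matrix C and spectral transform M) are minimum-norm
least squares with a singular-value cutoff of rcond = 1e-10, so
rank-deficient captures (duplicate patches) produce the well-defined
minimum-norm solution. The expansion feeding M is applied to corrected XYZ
divided by 100, keeping cubic monomials O(1) and the fit well conditioned.

PCA of the chart reflectances is mean-centred SVD; component signs are
fixed by making each component's largest-magnitude element positive, and
six components are kept by default, configurable. PCA runs on the full
400–780 nm grid so the reconstructed spectra carry the long-wavelength
region the NBI stage needs.

The similarity index reported alongside calibration is defined *by this
package* as 1 − RMSE/RMS(reference), clipped to [0, 1]; the name is
conventional but no standard formula exists.

Reconstructed reflectance is hard-clipped into [0, 1.2]; modest overshoot
above 1.0 is tolerated because glossy highlights legitimately exceed the
diffuse-white level, and the clip count is carried on the cube so
saturation is auditable. Reconstruction is a pure function of the 24-bit
pixel value and the bundle, so images are processed through a
unique-colour cache; no per-frame renormalisation is applied.

## Narrow-band synthesis and colour matching

Passbands are Gaussian: 415 nm with FWHM 30 nm and 540 nm with FWHM 20 nm
(Olympus-like widths; only the centres are standard knowledge), normalised
so a perfect reflector returns the band weight. The default display map
routes the 415 nm response to display blue and green (green at 0.85) and
the 540 nm response to display red — the conventional NBI pseudo-colour
scheme; the true device matrix is proprietary, so this is an explicit
package default. Correction bands at 600/700/780 nm (plus an optional
650 nm brown-pigmentation band, off by default) participate with zero
display weight until colour matching assigns them one.

Colour matching minimises mean CIEDE2000 between rendered and target patch
colours over the display-map entries plus one (x0, γ, amplitude)
Cauchy–Lorentz triple per correction band: each correction response is
scaled by amplitude × the Cauchy density peak-normalised at the band
centre, a smooth bell in wavelength that can de-emphasise or shift the
long-wavelength contributions. The optimiser is fast simulated annealing —
temperature T_k = T0/(1+k), standard-Cauchy proposal steps scaled by
step_scale × T_k, Metropolis acceptance, numpy PCG64 generator — preceded
by a linear least-squares warm start of the display map (the rendering is
linear in the map before clamping). Best-ever bookkeeping includes the
incoming spec, so the returned residual can never exceed the initial one.
Note the display map is identifiable only up to response-space metamers:
different maps can render identical colours, so matching guarantees the
colours, not the matrix.

## The synthetic study conditions

The virtual camera integrates S·R·sensitivity per channel, normalised so a
perfect reflector gives 1, then adds Gaussian noise on the linear signal,
gamma-encodes, scales to 0–255, adds the dark-current offset and
quantises with round-half-to-even. The `realistic` preset uses shifted
Gaussian sensitivities (610/545/465 nm, σ 35–40 nm), sRGB gamma, noise
σ = 0.01, dark offset 5 and 8-bit quantisation. The `ideal` preset uses
the (700 nm-masked) CIE observer curves as sensitivities with linear
response and *continuous* output: quantisation alone injects ~0.4% error,
which would swamp the machine-precision loop-closure checks the preset
exists for, so the ideal camera deliberately skips it.

The packaged 24-patch chart is synthetic — measured colour-checker spectra
are not redistributable — and is engineered so that the calibration
pipeline's function class can represent it exactly:

* three smooth blue/green/red basis functions forming a pointwise
  partition of unity, so the six grey patches (equal coordinates) are
  exactly flat;
* three detail components constructed as metameric blacks (zero projection
  on the D65-weighted observer curves over 400–700 nm), orthonormalised
  and scaled to unit peak;
* per patch, detail coefficients that are degree-≤3 polynomials of the
  chromatic coordinates, vanishing on the grey axis.

Consequently XYZ is an invertible affine function of the three chromatic
coordinates while the PCA scores are degree-≤3 polynomials of XYZ —
exactly the class the spectral transform regresses over. An ideal camera
therefore closes chart → capture → calibrate → reconstruct to machine
precision, which turns the whole pipeline into a strong self-test: any
implementation defect breaks the closure. The chart still has rank-6
spectral structure with a realistic decreasing variance profile, and six
components capture 100% of its variance by construction. What this does
*not* show: real reflectance ensembles are not exactly rank 6 and real
scores are not exact polynomials of XYZ, so on measured charts the loop
degrades to the noise-limited regime the `realistic` preset probes (mean
spectral RMSE ≈ 0.005, mean ΔE00 ≈ 1 after correction at σ = 0.01). A
loader accepts user-supplied measured chart CSVs for real use.

Endoscopy scenes are a smooth pinkish mucosa reflectance crossed by
randomly placed vessel polylines whose reflectance is attenuated by
Gaussian dips at 415 nm (depth 0.5, FWHM 30) and 540 nm (depth 0.35,
FWHM 25) — haemoglobin-style absorption, not a tissue-optics model. They
exist to test the contrast ordering (NBI render > WLI render for vessel
visibility), not to look photorealistic.

Smooth random spectra are Gaussian noise filtered with a Gaussian kernel
(correlation length in samples) and squashed through a logistic into
(0, 1).

## Quality and classification metrics

Image quality is computed on [0, 1] intensities: RMSE; PSNR =
20 log10(1/RMSE) with an infinity sentinel for identical images; SSIM with
the standard 11×11 Gaussian window (σ = 1.5, K1 = 0.01, K2 = 0.03),
falling back to a single global window for images smaller than 11 pixels;
and a relative greyscale Shannon-entropy difference (256 bins, BT.601
luma), a statistic defined by this package. Classification metrics are
one-vs-rest precision/recall/F1 in percent and trace accuracy; zero
denominators report 0 with an `undefined` flag rather than raising, so
batch evaluation survives degenerate classes. Average precision is the
area under the right-continuous precision–recall step curve (no 11-point
smoothing; ties broken by stable sort order), and mAP averages over
classes.

## Problem sizes

The test suite and acceptance script run entirely on generated data: a
24-patch chart, 48×48 scenes, 12-patch colour-matching instances and 10^4
annealing iterations — sizes chosen so every stochastic check (5-seed
calibration improvement, annealing convergence, contrast ordering) is
comfortably reproducible while the whole suite completes in seconds.

## Known limitations

* A 3-channel camera can never determine more than three independent
  spectral degrees of freedom per pixel; the polynomial lift interpolates
  within the chart's spectral family and cannot recover arbitrary
  metamers.
* The NBI display mapping and passband widths are package defaults, not
  device measurements; matching to a real device requires target colours
  captured from that device.
* No chromatic adaptation beyond white-point normalisation; no automatic
  chart detection in photographs (explicit patch rectangles only); no
  video streams or vignette masking.
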