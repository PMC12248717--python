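# savelight

Calibrated conversion of white-light endoscopy RGB frames into
hyperspectral-like reflectance cubes and simulated narrow-band (NBI)
images, with the colorimetric, image-quality and classification metrics
needed to evaluate the conversion.

Conventional white-light imaging (WLI) records only three broad channels,
which washes out the narrow spectral signatures — most importantly the
haemoglobin absorption maxima at 415 nm and 540 nm — that make early
mucosal lesions visible. Dedicated narrow-band or hyperspectral hardware
resolves them but is expensive and absent from capsule endoscopes.
`savelight` implements the software alternative: calibrate the camera once
against a 24-patch colour checker, reconstruct a per-pixel reflectance
spectrum from each RGB value, and re-illuminate the reconstructed cube
through narrow passbands to obtain an NBI-like view.

## Method

For each chart patch the reference tristimulus values are obtained from its
measured reflectance R(λ) by the CIE integrals

    X = k ∫ S(λ) R(λ) x̄(λ) dλ     (and likewise Y, Z)
    k = 100 / ∫ S(λ) ȳ(λ) dλ

over 400–700 nm, with S(λ) the illuminant and x̄ȳz̄ the CIE 1931 2°
observer. Calibration then fits, from the chart capture:

1. **Colour correction** — the dark-subtracted, linearised camera channels
   are expanded into every trivariate monomial up to degree 3 (20 terms,
   matrix `V`), and a 3×20 correction matrix is fitted by pseudo-inverse,
   `C = XYZ · pinv(V)`, so that `XYZ_corrected = C · V`.
2. **Spectral basis** — mean-centred PCA of the chart reflectance spectra;
   six components are kept by default.
3. **Spectral transform** — a second pseudo-inverse fit,
   `M = Score · pinv(V_colour)`, mapping the same polynomial expansion of
   the corrected XYZ to PCA scores.

A pixel is then reconstructed as
`spectrum = mean + Σᵢ (M · V_colour)ᵢ · componentᵢ` on a 400–780 nm grid at
5 nm (77 bands). NBI synthesis integrates each pixel spectrum against
Gaussian passbands at 415 nm (FWHM 30) and 540 nm (FWHM 20), maps the
responses to display RGB with the conventional pseudo-colour scheme
(415 → blue and green, 540 → red), and can colour-match the mapping to
target patch colours by minimising mean CIEDE2000 with a Cauchy–Lorentz
re-weighting of long-wavelength correction bands (600/700/780 nm,
optionally 650 nm) refined by fast simulated annealing.

Because no measured chart or endoscope data ships with the package, the
`synthetic_data` module generates the full study offline: a deterministic
24-patch chart, parametric virtual cameras (`ideal` and `realistic`
presets), smooth random reflectance spectra and vessel scenes with
haemoglobin-style absorption dips. See `docs/methods.md` for the model
details and design choices.

## Worked example

```python
import numpy as np
from savelight import *
from savelight.calibration import calibration_report
from savelight.quality import michelson_contrast
from savelight.synthetic_data import SceneSpec, synth_endoscopy_scene

chart = make_reference_chart()                      # 24-patch reference
cam = make_camera_model("realistic", seed=1)        # noisy sRGB camera
cap = simulate_capture(chart, cam)                  # 8-bit chart capture
bundle = calibrate(chart, cap)                      # C, PCA basis, M
rep = calibration_report(bundle, chart, cap)
print(f"mean dE00 before correction: {rep.mean_delta_e_pre:.2f}")
print(f"mean dE00 after correction:  {rep.mean_delta_e_post:.2f}")
print(f"mean spectral RMSE:          {rep.mean_spectral_rmse:.4f}")

scene = synth_endoscopy_scene(SceneSpec(height=48, width=48, seed=1))
img = simulate_capture(scene.cube, cam)             # WLI frame, uint8
cube = rgb_image_to_cube(img, bundle)               # (48, 48, 77) cube
nbi_img = render_nbi(cube)                          # NBI-like render
m = scene.vessel_mask
lum = lambda im, mm: float(im[mm].astype(float).mean())
print(f"vessel contrast NBI: {michelson_contrast(lum(nbi_img, m), lum(nbi_img, ~m)):.3f}")
print(f"vessel contrast WLI: {michelson_contrast(lum(scene.wli, m), lum(scene.wli, ~m)):.3f}")
```

prints

```
mean dE00 before correction: 5.13
mean dE00 after correction:  0.97
mean spectral RMSE:          0.0048
vessel contrast NBI: 0.039
vessel contrast WLI: 0.013
```

The correction step brings the chart colours from a mean CIEDE2000 of 5.13
(raw camera colours interpreted as sRGB) down to 0.97 against the
reference, the reconstructed patch spectra deviate by 0.0048 RMS
reflectance, and the simulated narrow-band render triples the Michelson
contrast of the sub-surface vessels relative to the white-light frame —
the effect the conversion exists to produce. With the noise-free `ideal`
camera preset the same loop closes to machine precision (spectral RMSE
below 1e-6).

## Command line

```sh
savelight synth chart --out chart.csv
savelight calibrate --chart chart.csv --capture capture.csv --out bundle.json
savelight convert --image frame.png --bundle bundle.json --out cube.raw
savelight nbi --cube cube.raw --out nbi.png
savelight metrics --confusion cm.csv --out report.json
savelight imgquality --a a.png --b b.png --out quality.json
```

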