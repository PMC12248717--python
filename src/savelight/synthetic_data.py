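"""Synthetic chart, camera and scene generators.

This module supplies every input the calibration/reconstruction pipeline
needs when no measured data is available: a 24-patch reference chart, a
parametric virtual camera, smooth random reflectance spectra, and
endoscopy-like scenes with haemoglobin-style absorption dips at 415 and
540 nm.  All generators are deterministic for a fixed seed.

Chart construction
------------------
The packaged chart is synthetic (the measured X-Rite patch spectra are not
distributed) but is engineered so the polynomial calibration pipeline is
exactly invertible for an ideal camera:

* three smooth chromatic basis functions forming a partition of unity
  (blue/green/red bands), so greys are exactly flat;
* three "detail" eigen-directions constructed as *metameric blacks* -- they
  integrate to zero against the D65-weighted colour-matching functions, so
  they carry spectral shape without affecting XYZ;
* each patch is  a*f_blue + b*f_green + c*f_red + sum_k p_k(a,b,c) d_k
  where the detail coefficients p_k are polynomials of degree <= 3 that
  vanish on the grey axis a = b = c.

XYZ is then an invertible affine function of (a, b, c) while the PCA scores
are degree-<=3 polynomials of XYZ, which is precisely the function class
the spectral transform regresses over: an ideal (noise-free, linear)
camera closes the loop to machine precision, and the chart still has
rank-6 spectral structure like a real colour checker.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .calibration import CameraPatchCapture, ChartReference, reference_chart_xyz
from .colorimetry import (
    CMFSet,
    COLORIMETRIC_RANGE,
    MASTER_GRID,
    SpectralGrid,
    Spectrum,
    cie_1931_cmfs,
    encode_srgb,
    illuminant_d65,
    reflectances_to_xyz,
    xyz_to_srgb_linear,
)
from .reconstruction import HyperspectralCube

__all__ = [
    "CameraModel",
    "SceneSpec",
    "SceneResult",
    "make_reference_chart",
    "make_camera_model",
    "simulate_capture",
    "synth_spectra",
    "synth_endoscopy_scene",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

# chart layout: (patch id, blue, green, red chromatic coordinates)
_CHART_PATCHES = [
    ("dark_skin", 0.08, 0.13, 0.25),
    ("light_skin", 0.35, 0.45, 0.65),
    ("blue_sky", 0.45, 0.35, 0.25),
    ("foliage", 0.08, 0.25, 0.12),
    ("blue_flower", 0.45, 0.30, 0.40),
    ("bluish_green", 0.40, 0.60, 0.35),
    ("orange", 0.06, 0.25, 0.70),
    ("purplish_blue", 0.55, 0.20, 0.15),
    ("moderate_red", 0.12, 0.15, 0.60),
    ("purple", 0.30, 0.10, 0.25),
    ("yellow_green", 0.12, 0.55, 0.40),
    ("orange_yellow", 0.08, 0.40, 0.65),
    ("blue", 0.55, 0.12, 0.06),
    ("green", 0.10, 0.50, 0.12),
    ("red", 0.06, 0.08, 0.65),
    ("yellow", 0.08, 0.55, 0.70),
    ("magenta", 0.40, 0.12, 0.55),
    ("cyan", 0.50, 0.45, 0.10),
    ("white", 0.90, 0.90, 0.90),
    ("neutral_8", 0.72, 0.72, 0.72),
    ("neutral_65", 0.55, 0.55, 0.55),
    ("neutral_5", 0.38, 0.38, 0.38),
    ("neutral_35", 0.22, 0.22, 0.22),
    ("black", 0.06, 0.06, 0.06),
]

# amplitudes of the three metameric-black detail directions
_DETAIL_AMPLITUDES = (0.05, 0.05, 0.04)


def _chromatic_bases(grid: SpectralGrid) -> np.ndarray:
    """(3, B) smooth blue/green/red bumps normalised to sum to 1 pointwise."""
    wl = grid.wavelengths
    centres = (455.0, 550.0, 630.0)
    widths = (45.0, 50.0, 55.0)
    g = np.stack(
        [np.exp(-0.5 * ((wl - c) / w) ** 2) + 1e-4 for c, w in zip(centres, widths)]
    )
    return g / g.sum(axis=0, keepdims=True)


def _xyz_weight_vectors(
    grid: SpectralGrid, illuminant: Spectrum, cmfs: CMFSet
) -> np.ndarray:
    """(3, B) vectors w such that XYZ = w @ reflectance, zero outside the
    colorimetric integration range."""
    wl = grid.wavelengths
    mask = (wl >= COLORIMETRIC_RANGE[0] - 1e-9) & (wl <= COLORIMETRIC_RANGE[1] + 1e-9)
    w = illuminant.values * cmfs.as_matrix()
    w[:, ~mask] = 0.0
    return w


def _metameric_black_details(
    grid: SpectralGrid, illuminant: Spectrum, cmfs: CMFSet
) -> np.ndarray:
    """Three smooth unit-peak functions orthogonal to the XYZ weights."""
    wl = grid.wavelengths
    seeds = np.stack(
        [
            np.exp(-0.5 * ((wl - 430.0) / 18.0) ** 2)
            - np.exp(-0.5 * ((wl - 480.0) / 18.0) ** 2),
            np.exp(-0.5 * ((wl - 540.0) / 20.0) ** 2)
            - np.exp(-0.5 * ((wl - 600.0) / 20.0) ** 2),
            np.exp(-0.5 * ((wl - 660.0) / 22.0) ** 2)
            - 0.5 * np.exp(-0.5 * ((wl - 730.0) / 25.0) ** 2),
        ]
    )
    W = _xyz_weight_vectors(grid, illuminant, cmfs)
    Q, _ = np.linalg.qr(W.T)  # orthonormal basis of the XYZ weight span
    details = seeds - (seeds @ Q) @ Q.T
    # orthogonalise among themselves for a clean rank-6 chart, unit peak
    Qd, _ = np.linalg.qr(details.T)
    details = Qd.T
    return details / np.max(np.abs(details), axis=1, keepdims=True)


def _detail_coefficients(a: float, b: float, c: float) -> np.ndarray:
    """Degree-<=3 polynomials of the chromatic coordinates, zero for greys."""
    return np.array([(c - b) ** 2, (b - a) ** 2, (c - a) ** 3])


def make_reference_chart(
    grid: SpectralGrid | None = None,
    illuminant: Spectrum | None = None,
    cmfs: CMFSet | None = None,
) -> ChartReference:
    """Deterministic 24-patch synthetic colour checker (18 chromatic + 6
    grey patches) with reference XYZ under D65 / CIE 1931 by default."""
    grid = grid or MASTER_GRID
    illuminant = illuminant or illuminant_d65(grid)
    cmfs = cmfs or cie_1931_cmfs(grid)
    bases = _chromatic_bases(grid)
    details = _metameric_black_details(grid, illuminant, cmfs)
    amp = np.asarray(_DETAIL_AMPLITUDES)

    ids, spectra = [], []
    for name, b_coef, g_coef, r_coef in _CHART_PATCHES:
        coeffs = np.array([b_coef, g_coef, r_coef])
        p = amp * _detail_coefficients(b_coef, g_coef, r_coef)
        vals = coeffs @ bases + p @ details
        if np.any(vals < 0.0) or np.any(vals > 1.0):
            raise AssertionError(f"chart patch {name} escapes [0, 1]")
        ids.append(name)
        spectra.append(Spectrum(grid, vals, name=name))

    mat = np.stack([s.values for s in spectra])
    xyz, white = reference_chart_xyz(mat, grid, illuminant, cmfs)
    return ChartReference(tuple(ids), spectra, xyz, white)


@dataclass
class CameraModel:
    """Parametric virtual RGB camera.

    The forward model is: per-channel linear response
    ``r = sum(S * R * sens) / sum(S * sens)`` (so a perfect reflector maps
    to 1), additive Gaussian noise on the linear signal, gamma encoding,
    scaling to 0-255, dark-current offset, optional 8-bit quantisation
    (round half to even).
    """

    grid: SpectralGrid
    sensitivities: np.ndarray  # (3, B), channels R, G, B
    gamma_mode: str = "srgb"  # 'linear' | 'srgb'
    gamma: float | None = None  # set for a pure power-law camera
    dark_offset: np.ndarray = field(default_factory=lambda: np.zeros(3))
    noise_sd: float = 0.0
    quantize: bool = True
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        self.sensitivities = np.asarray(self.sensitivities, dtype=float)
        self.dark_offset = np.asarray(self.dark_offset, dtype=float)
        if self.sensitivities.shape != (3, self.grid.n_samples):
            raise ValueError("sensitivities must be (3, n_bands)")
        if np.any(self.sensitivities < 0):
            raise ValueError("sensitivities must be non-negative")
        if np.any(self.sensitivities.sum(axis=1) == 0):
            raise ValueError("each channel needs non-zero sensitivity")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.gamma_mode not in ("linear", "srgb", "power"):
            raise ValueError(f"unknown gamma_mode {self.gamma_mode!r}")
        if self.gamma_mode == "power" and not self.gamma:
            raise ValueError("power gamma_mode requires a gamma value")

    @property
    def capture_encoding(self) -> str:
        return {"linear": "linear", "srgb": "srgb", "power": "power"}[self.gamma_mode]


def make_camera_model(
    preset: str | None = None,
    grid: SpectralGrid | None = None,
    **overrides,
) -> CameraModel:
    """Camera presets.

    ``ideal``     -- sensitivities equal to the (D65-range-masked) CIE 1931
                     colour-matching functions, linear response, no noise,
                     no dark current, continuous output (no quantisation);
                     calibration inverts it exactly.
    ``realistic`` -- shifted Gaussian sensitivities, sRGB gamma, additive
                     noise sigma 0.01, dark offset 5, 8-bit quantisation.
    """
    grid = grid or MASTER_GRID
    if preset is None:
        return CameraModel(grid=grid, **overrides)
    wl = grid.wavelengths
    if preset == "ideal":
        cmfs = cie_1931_cmfs(grid)
        sens = cmfs.as_matrix().copy()
        sens[:, wl > COLORIMETRIC_RANGE[1] + 1e-9] = 0.0
        defaults = dict(
            grid=grid,
            sensitivities=sens,
            gamma_mode="linear",
            dark_offset=np.zeros(3),
            noise_sd=0.0,
            quantize=False,
            name="ideal",
        )
    elif preset == "realistic":
        sens = np.stack(
            [
                np.exp(-0.5 * ((wl - 610.0) / 35.0) ** 2),
                np.exp(-0.5 * ((wl - 545.0) / 40.0) ** 2),
                np.exp(-0.5 * ((wl - 465.0) / 35.0) ** 2),
            ]
        )
        defaults = dict(
            grid=grid,
            sensitivities=sens,
            gamma_mode="srgb",
            dark_offset=np.full(3, 5.0),
            noise_sd=0.01,
            quantize=True,
            name="realistic",
        )
    else:
        raise ValueError(f"unknown camera preset {preset!r}")
    defaults.update(overrides)
    return CameraModel(**defaults)


def _encode_camera(linear: np.ndarray, camera: CameraModel) -> np.ndarray:
    v = np.clip(linear, 0.0, 1.0)
    if camera.gamma_mode == "linear":
        return v
    if camera.gamma_mode == "power":
        return v ** (1.0 / camera.gamma)
    return np.where(v <= 0.0031308, 12.92 * v, 1.055 * v ** (1 / 2.4) - 0.055)


def _camera_linear_response(
    reflectances: np.ndarray, camera: CameraModel, illuminant: Spectrum
) -> np.ndarray:
    s = illuminant.values
    num = reflectances @ (s * camera.sensitivities).T  # (n, 3)
    den = (s * camera.sensitivities).sum(axis=1)
    return num / den


def simulate_capture(
    chart_or_cube,
    camera: CameraModel,
    illuminant: Spectrum | None = None,
    seed: int | None = None,
):
    """Forward-simulate a camera capture.

    For a :class:`ChartReference` the result is a
    :class:`~savelight.calibration.CameraPatchCapture`; for a
    :class:`~savelight.reconstruction.HyperspectralCube` it is an RGB
    raster (uint8 if the camera quantises, float 0-255 otherwise).
    """
    illuminant = illuminant or illuminant_d65(camera.grid)
    if (illuminant.grid.start_nm, illuminant.grid.stop_nm, illuminant.grid.step_nm) != (
        camera.grid.start_nm, camera.grid.stop_nm, camera.grid.step_nm,
    ):
        raise ValueError("illuminant grid must match the camera grid")
    rng = np.random.default_rng(camera.seed if seed is None else seed)

    if isinstance(chart_or_cube, ChartReference):
        refl = chart_or_cube.spectra_matrix()
        if refl.shape[1] != camera.grid.n_samples:
            raise ValueError("chart spectra are not on the camera grid")
        linear = _camera_linear_response(refl, camera, illuminant)
        if camera.noise_sd > 0:
            linear = linear + rng.normal(0.0, camera.noise_sd, linear.shape)
        counts = _encode_camera(linear, camera) * 255.0 + camera.dark_offset
        counts = np.clip(counts, 0.0, 255.0)
        if camera.quantize:
            counts = np.rint(counts)  # round half to even
        return CameraPatchCapture(
            chart_or_cube.patch_ids,
            counts,
            camera.dark_offset.copy(),
            encoding=camera.capture_encoding,
            gamma=camera.gamma,
        )

    if isinstance(chart_or_cube, HyperspectralCube):
        cube = chart_or_cube
        if cube.grid.n_samples != camera.grid.n_samples:
            raise ValueError("cube is not on the camera grid")
        h, w, bnd = cube.values.shape
        linear = _camera_linear_response(cube.values.reshape(-1, bnd), camera, illuminant)
        if camera.noise_sd > 0:
            linear = linear + rng.normal(0.0, camera.noise_sd, linear.shape)
        counts = _encode_camera(linear, camera) * 255.0 + camera.dark_offset
        counts = np.clip(counts, 0.0, 255.0).reshape(h, w, 3)
        if camera.quantize:
            return np.rint(counts).astype(np.uint8)
        return counts

    raise TypeError("expected a ChartReference or HyperspectralCube")


def synth_spectra(
    n: int,
    smoothness: float = 4.0,
    seed: int = 0,
    grid: SpectralGrid | None = None,
) -> list[Spectrum]:
    """Gaussian-process-style smooth random reflectance spectra in [0, 1].

    ``smoothness`` is the correlation length in grid samples; larger values
    give flatter curves (smaller mean squared second difference).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    grid = grid or MASTER_GRID
    rng = np.random.default_rng(seed)
    noise = rng.normal(size=(n, grid.n_samples))
    smooth = gaussian_filter1d(noise, sigma=float(smoothness), axis=1, mode="nearest")
    sd = smooth.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (smooth - smooth.mean(axis=1, keepdims=True)) / sd
    vals = 1.0 / (1.0 + np.exp(-z))  # squash into (0, 1)
    return [Spectrum(grid, v, name=f"synth_{i}") for i, v in enumerate(vals)]


@dataclass
class SceneSpec:
    """Endoscopy-like scene: smooth mucosa background crossed by darker
    vessels whose reflectance carries haemoglobin-style absorption dips."""

    height: int = 64
    width: int = 64
    base_reflectance: Spectrum | None = None
    vessel_count: int = 4
    vessel_width_px: int = 2
    # (centre nm, FWHM nm, depth in [0, 1])
    absorption_dips: tuple = ((415.0, 30.0, 0.5), (540.0, 25.0, 0.35))
    seed: int = 0

    def __post_init__(self) -> None:
        for _, _, depth in self.absorption_dips:
            if not 0.0 <= depth <= 1.0:
                raise ValueError("dip depths must lie in [0, 1]")


@dataclass
class SceneResult:
    cube: HyperspectralCube
    wli: np.ndarray  # uint8 white-light sRGB render
    vessel_mask: np.ndarray  # bool (H, W)


def _default_mucosa(grid: SpectralGrid) -> Spectrum:
    wl = grid.wavelengths
    vals = 0.22 + 0.38 / (1.0 + np.exp(-(wl - 585.0) / 22.0))
    return Spectrum(grid, vals, name="mucosa")


def _vessel_mask(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    from skimage.draw import line as draw_line
    from skimage.morphology import dilation, disk

    mask = np.zeros((spec.height, spec.width), dtype=bool)
    for _ in range(spec.vessel_count):
        r0, r1 = rng.integers(0, spec.height, 2)
        c0, c1 = rng.integers(0, spec.width, 2)
        rr, cc = draw_line(int(r0), int(c0), int(r1), int(c1))
        mask[rr, cc] = True
    radius = max(int(spec.vessel_width_px) // 2, 0)
    if radius:
        mask = dilation(mask, disk(radius))
    return mask


def synth_endoscopy_scene(spec: SceneSpec, grid: SpectralGrid | None = None) -> SceneResult:
    """Generate a hyperspectral scene plus its white-light sRGB render.

    Vessel pixels are the background reflectance attenuated by Gaussian
    absorption dips (haemoglobin maxima at 415/540 nm by default)."""
    grid = grid or MASTER_GRID
    base = spec.base_reflectance or _default_mucosa(grid)
    if base.grid.n_samples != grid.n_samples:
        raise ValueError("base reflectance is not on the scene grid")
    wl = grid.wavelengths
    atten = np.ones(grid.n_samples)
    for centre, fwhm, depth in spec.absorption_dips:
        if not (wl[0] - 1e-9 <= centre <= wl[-1] + 1e-9):
            raise ValueError(f"absorption dip at {centre} nm lies outside the grid")
        sigma = fwhm * _FWHM_TO_SIGMA
        atten *= 1.0 - depth * np.exp(-0.5 * ((wl - centre) / sigma) ** 2)
    vessel = base.values * atten

    rng = np.random.default_rng(spec.seed)
    mask = _vessel_mask(spec, rng)
    values = np.where(mask[..., None], vessel, base.values)
    cube = HyperspectralCube(values, grid)

    illuminant = illuminant_d65(grid)
    cmfs = cie_1931_cmfs(grid)
    xyz = reflectances_to_xyz(np.stack([base.values, vessel]), illuminant, cmfs, grid)
    rgb_lin = np.clip(xyz_to_srgb_linear(xyz) , 0.0, 1.0)
    rgb8 = encode_srgb(rgb_lin)
    wli = np.where(mask[..., None], rgb8[1], rgb8[0]).astype(np.uint8)
    return SceneResult(cube, wli, mask)
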