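"""Pixel-wise application of a calibration bundle to RGB images.

Every pixel is an independent pure function of its 24-bit value and the
bundle, so images are processed through a unique-colour cache: each distinct
RGB triple is reconstructed once and scattered back.  Reconstructed
reflectance is hard-clipped into [0, CLIP_MAX] and the number of clipped
samples is accounted on the cube.
"""
from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .calibration import (
    CalibrationBundle,
    apply_correction,
    expand_variables,
    expand_xyz,
    subtract_dark,
)
from .colorimetry import CLIP_MAX, SpectralGrid, Spectrum, linearize_srgb, make_grid

__all__ = [
    "HyperspectralCube",
    "xyz_to_spectrum",
    "reconstruct_spectra",
    "rgb_image_to_cube",
    "write_envi",
    "read_envi",
]


@dataclass
class HyperspectralCube:
    """H x W x B reflectance image on a spectral grid."""

    values: np.ndarray  # (H, W, B) float
    grid: SpectralGrid
    clip_count: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("cube values must be (H, W, B)")
        if self.values.shape[2] != self.grid.n_samples:
            raise ValueError("band count must equal grid sample count")
        if self.values.shape[0] * self.values.shape[1] == 0:
            raise ValueError("cube must contain at least one pixel")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def pixel_spectrum(self, row: int, col: int) -> Spectrum:
        return Spectrum(self.grid, self.values[row, col])


def reconstruct_spectra(
    xyz_rows: np.ndarray, bundle: CalibrationBundle
) -> tuple[np.ndarray, int]:
    """XYZ rows -> reflectance rows via the spectral transform.

    Returns the (clipped) reflectance matrix and the number of samples that
    fell outside [0, CLIP_MAX] before clipping.
    """
    if bundle.transform is None or bundle.basis is None:  # defensive
        raise ValueError("calibration bundle is incomplete")
    v_colour = expand_xyz(np.atleast_2d(xyz_rows), bundle.degree)
    if v_colour.term_labels != bundle.transform.term_labels:
        raise ValueError("bundle transform labels do not match the expansion")
    scores = v_colour.values @ bundle.transform.entries.T
    recon = bundle.basis.synthesize(scores)
    n_clipped = int(np.count_nonzero((recon < 0.0) | (recon > CLIP_MAX)))
    return np.clip(recon, 0.0, CLIP_MAX), n_clipped


def xyz_to_spectrum(xyz, bundle: CalibrationBundle) -> Spectrum:
    """Single tristimulus triple -> reflectance spectrum on the bundle grid."""
    vals, _ = reconstruct_spectra(np.asarray(xyz, dtype=float)[None, :], bundle)
    return Spectrum(bundle.grid, vals[0])


def rgb_image_to_cube(image: np.ndarray, bundle: CalibrationBundle) -> HyperspectralCube:
    """8-bit RGB raster -> hyperspectral reflectance cube.

    Pipeline per pixel: dark-subtract, linearise, polynomial expansion,
    variable-matrix correction to XYZ, spectral transform to PCA scores,
    basis synthesis, clip.  Alpha channels are rejected rather than dropped.
    """
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        if img.ndim == 3 and img.shape[2] == 4:
            raise ValueError("alpha channel present; pass a 3-channel RGB image")
        raise ValueError("image must be an (H, W, 3) RGB raster")
    h, w, _ = img.shape
    flat = img.reshape(-1, 3).astype(float)
    uniq, inverse = np.unique(flat, axis=0, return_inverse=True)
    raw, per_uniq = _raw_spectra(uniq, bundle)
    clipped = np.clip(raw, 0.0, CLIP_MAX)
    cube_vals = clipped[inverse].reshape(h, w, -1)
    # clip accounting counts every pixel, not every unique colour
    clip_count = int(np.sum(per_uniq[inverse]))
    return HyperspectralCube(cube_vals, bundle.grid, clip_count=clip_count)


def _raw_spectra(rgb_rows: np.ndarray, bundle: CalibrationBundle):
    """Unclipped reconstruction plus per-row out-of-range sample counts."""
    lin = subtract_dark(rgb_rows.astype(float), bundle.dark_offset)
    if bundle.encoding == "linear":
        lin = lin / 255.0
    elif bundle.encoding == "power":
        lin = linearize_srgb(lin, gamma=bundle.gamma)
    else:
        lin = linearize_srgb(lin)
    V = expand_variables(lin, bundle.degree)
    xyz = apply_correction(bundle.correction, V)
    v_colour = expand_xyz(xyz, bundle.degree)
    scores = v_colour.values @ bundle.transform.entries.T
    raw = bundle.basis.synthesize(scores)
    per_row = np.count_nonzero((raw < 0.0) | (raw > CLIP_MAX), axis=1)
    return raw, per_row


# ---------------------------------------------------------------------------
# ENVI-style cube container: text header + band-sequential float32 binary
# ---------------------------------------------------------------------------

def write_envi(cube: HyperspectralCube, path) -> None:
    """Write ``path`` (raw BSQ float32, little-endian) and ``path + '.hdr'``."""
    path = Path(path)
    data = np.ascontiguousarray(
        np.moveaxis(cube.values.astype("<f4"), 2, 0)
    )  # (bands, lines, samples)
    data.tofile(path)
    wl = ", ".join(f"{v:g}" for v in cube.grid.wavelengths)
    hdr = (
        "ENVI\n"
        "description = {savelight reflectance cube}\n"
        f"samples = {cube.width}\n"
        f"lines = {cube.height}\n"
        f"bands = {cube.n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = Nanometers\n"
        f"wavelength = {{{wl}}}\n"
        f"clip count = {cube.clip_count}\n"
    )
    path.with_suffix(path.suffix + ".hdr").write_text(hdr)


def _parse_envi_header(text: str) -> dict:
    # collapse brace-delimited multi-line values, then split on '='
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    fields = {}
    for line in text.splitlines():
        if "=" in line:
            key, _, val = line.partition("=")
            fields[key.strip().lower()] = val.strip()
    return fields


def read_envi(path) -> HyperspectralCube:
    """Read a cube written by :func:`write_envi` (bit-exact round trip)."""
    path = Path(path)
    hdr_path = path.with_suffix(path.suffix + ".hdr")
    fields = _parse_envi_header(hdr_path.read_text())
    if fields.get("interleave", "bsq") != "bsq" or fields.get("data type") != "4":
        raise ValueError("only BSQ float32 cubes are supported")
    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    wl = np.array(
        [float(v) for v in fields["wavelength"].strip("{} ").split(",")]
    )
    grid = make_grid(wl[0], wl[-1], wl[1] - wl[0])
    data = np.fromfile(path, dtype="<f4")
    if data.size != samples * lines * bands:
        raise ValueError("binary size does not match header dimensions")
    values = np.moveaxis(data.reshape(bands, lines, samples), 0, 2)
    clip = int(fields.get("clip count", "0"))
    return HyperspectralCube(values.astype(float), grid, clip_count=clip)
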