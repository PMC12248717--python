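"""Colorimetric engine: spectral grids, tristimulus integration, CIELAB, CIEDE2000.

All spectra live on uniform wavelength grids.  Tristimulus values follow the
CIE 1931 convention: X = k * sum(S * R * xbar) * dlambda with the normalising
constant k chosen so a perfect reflector (R = 1 everywhere) yields Y = 100
under the given illuminant.  Colorimetric integrals are restricted to the
400-700 nm range by default even when spectra extend further into the red
(the narrow-band synthesis stage uses bands out to 780 nm).
"""
from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "SpectralGrid",
    "Spectrum",
    "CMFSet",
    "XYZTriple",
    "LabTriple",
    "MASTER_GRID",
    "COLORIMETRIC_RANGE",
    "CLIP_MAX",
    "make_grid",
    "resample_spectrum",
    "linearize_srgb",
    "encode_srgb",
    "reflectance_to_xyz",
    "reflectances_to_xyz",
    "xyz_to_lab",
    "lab_to_lch",
    "ciede2000",
    "cie_1931_cmfs",
    "illuminant_d65",
    "flat_illuminant",
    "srgb_linear_to_xyz",
    "xyz_to_srgb_linear",
    "read_spectra_csv",
    "write_spectra_csv",
]

#: wavelength limits of the Eq-style colorimetric integrals (nm)
COLORIMETRIC_RANGE = (400.0, 700.0)

#: hard ceiling for reconstructed reflectance (overshoot above 1.0 is
#: physically possible for glossy highlights; values are clipped here)
CLIP_MAX = 1.2

# sRGB (IEC 61966-2-1) linear-RGB -> XYZ matrix, D65 white, Y of white = 1
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_XYZ_TO_SRGB = np.linalg.inv(_SRGB_TO_XYZ)


@dataclass(frozen=True)
class SpectralGrid:
    """Uniform wavelength grid [start_nm, stop_nm] with spacing step_nm."""

    start_nm: float
    stop_nm: float
    step_nm: float

    def __post_init__(self) -> None:
        if self.step_nm <= 0:
            raise ValueError(f"step must be positive, got {self.step_nm}")
        if not self.start_nm < self.stop_nm:
            raise ValueError(
                f"start must be < stop, got start={self.start_nm}, stop={self.stop_nm}"
            )
        span = self.stop_nm - self.start_nm
        n = span / self.step_nm
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"step {self.step_nm} does not divide the range "
                f"[{self.start_nm}, {self.stop_nm}] exactly"
            )

    @property
    def n_samples(self) -> int:
        return int(round((self.stop_nm - self.start_nm) / self.step_nm)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_samples)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_samples


def make_grid(start_nm: float, stop_nm: float, step_nm: float) -> SpectralGrid:
    """Uniform grid including both endpoints; step must divide the span."""
    return SpectralGrid(float(start_nm), float(stop_nm), float(step_nm))


#: master grid shared by the calibration and narrow-band stages: 400-780 nm at 5 nm
MASTER_GRID = make_grid(400.0, 780.0, 5.0)


@dataclass
class Spectrum:
    """Per-wavelength reflectance or relative spectral power on a grid."""

    grid: SpectralGrid
    values: np.ndarray
    extrapolated: bool = False
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("spectrum values must be one-dimensional")
        if self.values.size != self.grid.n_samples:
            raise ValueError(
                f"value count {self.values.size} does not match grid "
                f"sample count {self.grid.n_samples}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum contains non-finite values")


@dataclass
class CMFSet:
    """CIE colour-matching functions xbar, ybar, zbar on a shared grid."""

    grid: SpectralGrid
    xbar: np.ndarray
    ybar: np.ndarray
    zbar: np.ndarray

    def __post_init__(self) -> None:
        for attr in ("xbar", "ybar", "zbar"):
            v = np.asarray(getattr(self, attr), dtype=float)
            if v.size != self.grid.n_samples:
                raise ValueError(f"{attr} length does not match grid")
            if np.any(v < 0):
                raise ValueError(f"{attr} must be non-negative")
            setattr(self, attr, v)

    def as_matrix(self) -> np.ndarray:
        """(3, n_samples) array ordered xbar, ybar, zbar."""
        return np.stack([self.xbar, self.ybar, self.zbar])


class XYZTriple(NamedTuple):
    X: float
    Y: float
    Z: float

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


class LabTriple(NamedTuple):
    L: float
    a: float
    b: float

    def as_array(self) -> np.ndarray:
        return np.array(self, dtype=float)


def resample_spectrum(spec: Spectrum, target: SpectralGrid) -> Spectrum:
    """Linear interpolation onto ``target``; out-of-range samples take the
    nearest endpoint value and the result is flagged ``extrapolated``."""
    if spec.values.size == 0:
        raise ValueError("cannot resample an empty spectrum")
    src = spec.grid.wavelengths
    tgt = target.wavelengths
    vals = np.interp(tgt, src, spec.values)
    extrapolated = bool(tgt[0] < src[0] - 1e-9 or tgt[-1] > src[-1] + 1e-9)
    return Spectrum(target, vals, extrapolated=extrapolated or spec.extrapolated,
                    name=spec.name)


def linearize_srgb(encoded, gamma: float | None = None) -> np.ndarray:
    """8-bit channel values (0-255) -> linear intensity in [0, 1].

    Default transfer is the IEC 61966-2-1 sRGB piecewise EOTF; passing a
    ``gamma`` switches to the pure power law (v/255)**gamma.
    """
    x = np.asarray(encoded, dtype=float)
    if np.any(x < 0) or np.any(x > 255):
        raise ValueError("encoded values must lie in [0, 255]")
    u = x / 255.0
    if gamma is not None:
        return u**gamma
    return np.where(u <= 0.04045, u / 12.92, ((u + 0.055) / 1.055) ** 2.4)


def encode_srgb(linear, gamma: float | None = None) -> np.ndarray:
    """Linear intensity in [0, 1] -> 8-bit sRGB code values (uint8)."""
    v = np.clip(np.asarray(linear, dtype=float), 0.0, 1.0)
    if gamma is not None:
        u = v ** (1.0 / gamma)
    else:
        u = np.where(v <= 0.0031308, 12.92 * v, 1.055 * v ** (1 / 2.4) - 0.055)
    return np.rint(u * 255.0).astype(np.uint8)


def _check_shared_grid(*grids: SpectralGrid) -> SpectralGrid:
    first = grids[0]
    for g in grids[1:]:
        if (g.start_nm, g.stop_nm, g.step_nm) != (
            first.start_nm,
            first.stop_nm,
            first.step_nm,
        ):
            raise ValueError("inputs must share one spectral grid; resample first")
    return first


def _integration_weights(
    grid: SpectralGrid, illum: np.ndarray, cmfs: CMFSet, limits
) -> tuple[np.ndarray, np.ndarray, float]:
    wl = grid.wavelengths
    mask = (wl >= limits[0] - 1e-9) & (wl <= limits[1] + 1e-9)
    if not np.any(mask):
        raise ValueError("integration limits exclude every grid sample")
    dl = grid.step_nm
    s = illum[mask]
    denom = float(np.sum(s * cmfs.ybar[mask]) * dl)
    if denom <= 0:
        raise ValueError("illuminant has no power inside the integration range")
    k = 100.0 / denom
    # (3, n_masked) weights such that XYZ = weights @ R[mask]
    w = k * dl * s * cmfs.as_matrix()[:, mask]
    return w, mask, k


def reflectances_to_xyz(
    values: np.ndarray,
    illum: Spectrum,
    cmfs: CMFSet,
    grid: SpectralGrid | None = None,
    limits=COLORIMETRIC_RANGE,
) -> np.ndarray:
    """Vectorised tristimulus integration: (n, bands) reflectances -> (n, 3) XYZ."""
    grid = grid or illum.grid
    _check_shared_grid(grid, illum.grid, cmfs.grid)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape[1] != grid.n_samples:
        raise ValueError("reflectance band count does not match grid")
    w, mask, _ = _integration_weights(grid, illum.values, cmfs, limits)
    return values[:, mask] @ w.T


def reflectance_to_xyz(
    refl: Spectrum, illum: Spectrum, cmfs: CMFSet, limits=COLORIMETRIC_RANGE
) -> XYZTriple:
    """Single-spectrum tristimulus integration (Riemann sum, weight dlambda)."""
    _check_shared_grid(refl.grid, illum.grid, cmfs.grid)
    xyz = reflectances_to_xyz(refl.values[None, :], illum, cmfs, refl.grid, limits)[0]
    return XYZTriple(*xyz)


def _lab_f(t: np.ndarray) -> np.ndarray:
    delta = 6.0 / 29.0
    return np.where(t > delta**3, np.cbrt(t), t / (3 * delta**2) + 4.0 / 29.0)


def xyz_to_lab(xyz, white: XYZTriple) -> np.ndarray | LabTriple:
    """CIELAB forward transform relative to ``white``.

    Accepts a triple or an (..., 3) array; returns a LabTriple for triple input.
    """
    wn = np.asarray(white, dtype=float)
    if np.any(wn <= 0):
        raise ValueError("white point components must be strictly positive")
    arr = np.asarray(xyz, dtype=float)
    single = arr.ndim == 1
    f = _lab_f(np.atleast_2d(arr) / wn)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    lab = np.stack([L, a, b], axis=-1)
    if single:
        return LabTriple(*lab[0])
    return lab.reshape(arr.shape)


def lab_to_lch(lab: np.ndarray) -> np.ndarray:
    """Lab -> (L, C, h_deg), h in [0, 360)."""
    lab = np.asarray(lab, dtype=float)
    C = np.hypot(lab[..., 1], lab[..., 2])
    h = np.degrees(np.arctan2(lab[..., 2], lab[..., 1])) % 360.0
    return np.stack([lab[..., 0], C, h], axis=-1)


def ciede2000(lab1, lab2, kL: float = 1.0, kC: float = 1.0, kH: float = 1.0):
    """CIEDE2000 colour difference between Lab triples or (..., 3) arrays.

    Follows the reference algorithm (hue-rotation term, G compensation of a*,
    piecewise mean-hue rules); parametric factors default to 1.
    """
    lab1 = np.asarray(lab1, dtype=float)
    lab2 = np.asarray(lab2, dtype=float)
    single = lab1.ndim == 1 and lab2.ndim == 1
    shape = np.broadcast_shapes(lab1.shape, lab2.shape)
    lab1 = np.broadcast_to(lab1, shape).reshape(-1, 3)
    lab2 = np.broadcast_to(lab2, shape).reshape(-1, 3)
    L1, a1, b1 = np.moveaxis(lab1, -1, 0)
    L2, a2, b2 = np.moveaxis(lab2, -1, 0)

    C1 = np.hypot(a1, b1)
    C2 = np.hypot(a2, b2)
    Cbar = 0.5 * (C1 + C2)
    G = 0.5 * (1 - np.sqrt(Cbar**7 / (Cbar**7 + 25.0**7)))
    a1p = (1 + G) * a1
    a2p = (1 + G) * a2
    C1p = np.hypot(a1p, b1)
    C2p = np.hypot(a2p, b2)

    h1p = np.where((a1p == 0) & (b1 == 0), 0.0, np.degrees(np.arctan2(b1, a1p)) % 360)
    h2p = np.where((a2p == 0) & (b2 == 0), 0.0, np.degrees(np.arctan2(b2, a2p)) % 360)

    dLp = L2 - L1
    dCp = C2p - C1p

    dh = h2p - h1p
    dhp = np.where(
        C1p * C2p == 0,
        0.0,
        np.where(np.abs(dh) <= 180, dh, np.where(dh > 180, dh - 360, dh + 360)),
    )
    dHp = 2 * np.sqrt(C1p * C2p) * np.sin(np.radians(dhp) / 2)

    Lbp = 0.5 * (L1 + L2)
    Cbp = 0.5 * (C1p + C2p)
    hsum = h1p + h2p
    habs = np.abs(h1p - h2p)
    hbp = np.where(
        C1p * C2p == 0,
        hsum,
        np.where(
            habs <= 180,
            0.5 * hsum,
            np.where(hsum < 360, 0.5 * (hsum + 360), 0.5 * (hsum - 360)),
        ),
    )

    T = (
        1
        - 0.17 * np.cos(np.radians(hbp - 30))
        + 0.24 * np.cos(np.radians(2 * hbp))
        + 0.32 * np.cos(np.radians(3 * hbp + 6))
        - 0.20 * np.cos(np.radians(4 * hbp - 63))
    )
    dtheta = 30 * np.exp(-(((hbp - 275) / 25) ** 2))
    RC = 2 * np.sqrt(Cbp**7 / (Cbp**7 + 25.0**7))
    SL = 1 + 0.015 * (Lbp - 50) ** 2 / np.sqrt(20 + (Lbp - 50) ** 2)
    SC = 1 + 0.045 * Cbp
    SH = 1 + 0.015 * Cbp * T
    RT = -np.sin(np.radians(2 * dtheta)) * RC

    dE = np.sqrt(
        (dLp / (kL * SL)) ** 2
        + (dCp / (kC * SC)) ** 2
        + (dHp / (kH * SH)) ** 2
        + RT * (dCp / (kC * SC)) * (dHp / (kH * SH))
    )
    if single:
        return float(dE[0])
    return dE.reshape(shape[:-1])


def srgb_linear_to_xyz(rgb_linear: np.ndarray) -> np.ndarray:
    """Linear sRGB (..., 3) in [0,1] -> XYZ scaled so white has Y = 100."""
    rgb = np.asarray(rgb_linear, dtype=float)
    return 100.0 * (rgb @ _SRGB_TO_XYZ.T)


def xyz_to_srgb_linear(xyz: np.ndarray) -> np.ndarray:
    """XYZ (Y of white = 100) -> linear sRGB (..., 3); no clipping."""
    return (np.asarray(xyz, dtype=float) / 100.0) @ _XYZ_TO_SRGB.T


# ---------------------------------------------------------------------------
# Packaged reference tables and the CSV spectral-table dialect
# ---------------------------------------------------------------------------

def read_spectra_csv(path) -> tuple[np.ndarray, pd.DataFrame]:
    """Read the spectral-table dialect: first column ``wavelength_nm``,
    one spectrum per remaining column.  Returns (wavelengths, table)."""
    df = pd.read_csv(path)
    if df.columns[0] != "wavelength_nm":
        raise ValueError("first CSV column must be 'wavelength_nm'")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    return wl, df.drop(columns="wavelength_nm")


def write_spectra_csv(path, wavelengths: np.ndarray, columns: dict) -> None:
    df = pd.DataFrame({"wavelength_nm": np.asarray(wavelengths, dtype=float)})
    for name, vals in columns.items():
        df[name] = np.asarray(vals, dtype=float)
    df.to_csv(path, index=False)


def _packaged_table(name: str) -> tuple[np.ndarray, pd.DataFrame]:
    with importlib.resources.files("savelight.data").joinpath(name).open() as fh:
        return read_spectra_csv(fh)


def _table_to_grid(wl: np.ndarray) -> SpectralGrid:
    step = wl[1] - wl[0]
    return make_grid(wl[0], wl[-1], step)


def cie_1931_cmfs(grid: SpectralGrid | None = None) -> CMFSet:
    """Packaged CIE 1931 2-degree observer, resampled onto ``grid`` if given."""
    wl, tbl = _packaged_table("cie1931_2deg_5nm.csv")
    src_grid = _table_to_grid(wl)
    cm = CMFSet(src_grid, tbl["xbar"].to_numpy(), tbl["ybar"].to_numpy(),
                tbl["zbar"].to_numpy())
    if grid is None:
        return cm
    return CMFSet(
        grid,
        resample_spectrum(Spectrum(src_grid, cm.xbar), grid).values,
        resample_spectrum(Spectrum(src_grid, cm.ybar), grid).values,
        resample_spectrum(Spectrum(src_grid, cm.zbar), grid).values,
    )


def illuminant_d65(grid: SpectralGrid | None = None) -> Spectrum:
    """Packaged D65 daylight illuminant, resampled onto ``grid`` if given."""
    wl, tbl = _packaged_table("illuminant_d65_5nm.csv")
    spec = Spectrum(_table_to_grid(wl), tbl["d65"].to_numpy(), name="D65")
    if grid is None:
        return spec
    return resample_spectrum(spec, grid)


def flat_illuminant(grid: SpectralGrid, level: float = 100.0) -> Spectrum:
    """Equal-energy illuminant on ``grid``."""
    return Spectrum(grid, np.full(grid.n_samples, float(level)), name="flat")
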