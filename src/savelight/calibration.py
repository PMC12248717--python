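"""Camera calibration against a 24-patch colour checker.

The pipeline fits three objects from one chart capture:

* a correction matrix ``C`` mapping a polynomial expansion ``V`` of the
  dark-subtracted, linearised camera channels to reference tristimulus
  values (``C = XYZ_spectrum x pinv(V)``);
* a PCA basis of the chart reflectance spectra (six components by default);
* a spectral transform ``M`` mapping the same polynomial expansion of the
  *corrected* XYZ triples to PCA scores (``M = Score x pinv(V_colour)``),
  which is what turns a camera pixel into a full reflectance spectrum.

Pseudo-inverse solves use a singular-value cutoff of 1e-10 so fits are
reproducible; rank-deficient systems get the minimum-norm solution.
"""
from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .colorimetry import (
    CMFSet,
    LabTriple,
    MASTER_GRID,
    SpectralGrid,
    Spectrum,
    XYZTriple,
    cie_1931_cmfs,
    ciede2000,
    illuminant_d65,
    linearize_srgb,
    make_grid,
    reflectances_to_xyz,
    srgb_linear_to_xyz,
    xyz_to_lab,
)

__all__ = [
    "ChartReference",
    "CameraPatchCapture",
    "VariableMatrix",
    "CorrectionMatrix",
    "PCABasis",
    "SpectralTransform",
    "CalibrationBundle",
    "CalibrationReport",
    "RCOND",
    "subtract_dark",
    "expand_variables",
    "expand_xyz",
    "fit_correction_matrix",
    "apply_correction",
    "pca_reflectance",
    "fit_spectral_transform",
    "similarity_index",
    "calibrate",
    "calibration_report",
]

#: singular-value cutoff for all pseudo-inverse fits
RCOND = 1e-10

#: XYZ triples are divided by this before the polynomial expansion feeding M,
#: keeping cubic monomials well conditioned (Y of white is 100).
XYZ_SCALE = 100.0


@dataclass
class ChartReference:
    """Reference description of a 24-patch colour checker: per-patch
    reflectance spectra plus their tristimulus values under the reference
    illuminant/observer."""

    patch_ids: tuple[str, ...]
    spectra: list[Spectrum]
    xyz: np.ndarray  # (n_patches, 3)
    white: XYZTriple  # XYZ of the perfect reflector under the same conditions

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if len(self.patch_ids) != len(self.spectra) or self.xyz.shape != (
            len(self.patch_ids),
            3,
        ):
            raise ValueError("patch ids, spectra and XYZ rows must align")

    @property
    def grid(self) -> SpectralGrid:
        return self.spectra[0].grid

    def spectra_matrix(self) -> np.ndarray:
        return np.stack([s.values for s in self.spectra])


@dataclass
class CameraPatchCapture:
    """Mean camera RGB of each chart patch, on the 0-255 scale (floats are
    allowed so continuous virtual cameras can skip quantisation)."""

    patch_ids: tuple[str, ...]
    rgb: np.ndarray  # (n_patches, 3)
    dark_offset: np.ndarray  # (3,)
    encoding: str = "srgb"  # 'srgb' | 'linear' | 'power'
    gamma: float | None = None

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb, dtype=float)
        self.dark_offset = np.asarray(self.dark_offset, dtype=float)
        if self.rgb.shape != (len(self.patch_ids), 3):
            raise ValueError("rgb must be (n_patches, 3)")
        if np.any(self.rgb < 0) or np.any(self.rgb > 255):
            raise ValueError("rgb values must lie in [0, 255]")
        if self.encoding not in ("srgb", "linear", "power"):
            raise ValueError(f"unknown encoding {self.encoding!r}")
        if self.encoding == "power" and not self.gamma:
            raise ValueError("power encoding requires a gamma value")

    def linear_rgb(self) -> np.ndarray:
        """Dark-subtracted, linearised channels in [0, 1]."""
        v = subtract_dark(self.rgb, self.dark_offset)
        if self.encoding == "linear":
            return v / 255.0
        if self.encoding == "power":
            return linearize_srgb(v, gamma=self.gamma)
        return linearize_srgb(v)


@dataclass
class VariableMatrix:
    """Polynomial expansion of (r, g, b) rows: all monomials of total degree
    <= d in graded-lexicographic order, with an optional constant column."""

    values: np.ndarray  # (n_rows, n_terms)
    term_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.term_labels):
            raise ValueError("values shape must match term labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("variable matrix contains non-finite entries")


@dataclass
class CorrectionMatrix:
    """3 x n_terms matrix C of the variable-matrix correction."""

    entries: np.ndarray
    term_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.shape != (3, len(self.term_labels)):
            raise ValueError("correction matrix must be 3 x n_terms")
        if not np.all(np.isfinite(self.entries)):
            raise ValueError("correction matrix contains non-finite entries")


@dataclass
class PCABasis:
    """Mean spectrum plus orthonormal eigen-spectra of the chart patches."""

    mean_spectrum: Spectrum
    components: np.ndarray  # (n_components, n_bands), unit rows
    explained_variance_fraction: np.ndarray  # (n_components,)

    @property
    def grid(self) -> SpectralGrid:
        return self.mean_spectrum.grid

    @property
    def n_components(self) -> int:
        return self.components.shape[0]

    def synthesize(self, scores: np.ndarray) -> np.ndarray:
        """scores (..., n_components) -> reflectance values (..., n_bands)."""
        return np.asarray(scores, dtype=float) @ self.components + self.mean_spectrum.values


@dataclass
class SpectralTransform:
    """n_components x n_terms matrix M mapping expanded colour vectors to
    PCA scores."""

    entries: np.ndarray
    term_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.ndim != 2 or self.entries.shape[1] != len(self.term_labels):
            raise ValueError("transform shape must match term labels")

    @property
    def n_components(self) -> int:
        return self.entries.shape[0]


@dataclass
class CalibrationBundle:
    """Everything needed to convert one camera's RGB frames into spectra."""

    correction: CorrectionMatrix
    basis: PCABasis
    transform: SpectralTransform
    grid: SpectralGrid
    white: XYZTriple
    dark_offset: np.ndarray
    encoding: str = "srgb"
    gamma: float | None = None
    degree: int = 3
    provenance: str = ""

    def to_json(self, path=None) -> str:
        doc = {
            "format": "savelight-calibration-bundle",
            "version": 1,
            "grid": [self.grid.start_nm, self.grid.stop_nm, self.grid.step_nm],
            "white": list(self.white),
            "dark_offset": self.dark_offset.tolist(),
            "encoding": self.encoding,
            "gamma": self.gamma,
            "degree": self.degree,
            "provenance": self.provenance,
            "correction": {
                "entries": self.correction.entries.tolist(),
                "term_labels": list(self.correction.term_labels),
            },
            "basis": {
                "mean_spectrum": self.basis.mean_spectrum.values.tolist(),
                "components": self.basis.components.tolist(),
                "explained_variance_fraction":
                    self.basis.explained_variance_fraction.tolist(),
            },
            "transform": {
                "entries": self.transform.entries.tolist(),
                "term_labels": list(self.transform.term_labels),
            },
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "CalibrationBundle":
        if hasattr(source, "read"):
            doc = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                doc = json.loads(text)
            else:
                with open(text) as fh:
                    doc = json.load(fh)
        if doc.get("format") != "savelight-calibration-bundle":
            raise ValueError("not a calibration bundle document")
        grid = make_grid(*doc["grid"])
        basis = PCABasis(
            Spectrum(grid, np.array(doc["basis"]["mean_spectrum"])),
            np.array(doc["basis"]["components"]),
            np.array(doc["basis"]["explained_variance_fraction"]),
        )
        return cls(
            correction=CorrectionMatrix(
                np.array(doc["correction"]["entries"]),
                tuple(doc["correction"]["term_labels"]),
            ),
            basis=basis,
            transform=SpectralTransform(
                np.array(doc["transform"]["entries"]),
                tuple(doc["transform"]["term_labels"]),
            ),
            grid=grid,
            white=XYZTriple(*doc["white"]),
            dark_offset=np.array(doc["dark_offset"]),
            encoding=doc["encoding"],
            gamma=doc["gamma"],
            degree=doc["degree"],
            provenance=doc.get("provenance", ""),
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def subtract_dark(rgb, offset) -> np.ndarray:
    """Remove the per-channel dark-current offset, flooring at zero."""
    offset = np.asarray(offset, dtype=float)
    if np.any(offset < 0):
        raise ValueError("dark offset must be non-negative")
    return np.maximum(np.asarray(rgb, dtype=float) - offset, 0.0)


def _monomial_exponents(degree: int) -> list[tuple[int, int, int]]:
    """Exponent triples of total degree 1..degree, graded lexicographic."""
    out = []
    for d in range(1, degree + 1):
        grade = [
            (i, j, k)
            for i, j, k in itertools.product(range(d + 1), repeat=3)
            if i + j + k == d
        ]
        out.extend(sorted(grade, reverse=True))
    return out


def _term_label(expt: tuple[int, int, int]) -> str:
    parts = []
    for sym, p in zip("rgb", expt):
        if p == 1:
            parts.append(sym)
        elif p > 1:
            parts.append(f"{sym}^{p}")
    return "*".join(parts) if parts else "1"


def expand_variables(rows, degree: int = 3, include_constant: bool = True) -> VariableMatrix:
    """Build the variable matrix V: all trivariate monomials of total degree
    <= ``degree`` (20 columns for the full cubic with constant)."""
    if degree not in (1, 2, 3):
        raise ValueError(f"degree must be 1, 2 or 3, got {degree}")
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if rows.shape[1] != 3:
        raise ValueError("rows must have three channels")
    exponents = _monomial_exponents(degree)
    cols = []
    labels = []
    if include_constant:
        cols.append(np.ones(rows.shape[0]))
        labels.append("1")
    for expt in exponents:
        cols.append(np.prod(rows ** np.array(expt), axis=1))
        labels.append(_term_label(expt))
    return VariableMatrix(np.column_stack(cols), tuple(labels))


def expand_xyz(xyz_rows, degree: int = 3) -> VariableMatrix:
    """Expansion used for the spectral transform: XYZ is divided by 100
    first so cubic terms stay O(1).  Labels are prefixed accordingly."""
    vm = expand_variables(np.asarray(xyz_rows, dtype=float) / XYZ_SCALE, degree)
    labels = tuple(
        lbl.replace("r", "X").replace("g", "Y").replace("b", "Z")
        for lbl in vm.term_labels
    )
    return VariableMatrix(vm.values, labels)


def _lstsq(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Minimum-norm least squares with the package-wide singular cutoff."""
    sol, *_ = np.linalg.lstsq(A, B, rcond=RCOND)
    return sol


def fit_correction_matrix(reference_xyz, V: VariableMatrix) -> CorrectionMatrix:
    """Least-squares fit of C such that C @ V_row best reproduces the
    reference XYZ triples (pseudo-inverse solution)."""
    xyz = np.asarray(reference_xyz, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3:
        raise ValueError("reference XYZ must be (n, 3)")
    if xyz.shape[0] != V.values.shape[0]:
        raise ValueError("row counts of reference XYZ and V must match")
    if not np.any(V.values):
        raise ValueError("variable matrix is identically zero")
    C = _lstsq(V.values, xyz).T
    return CorrectionMatrix(C, V.term_labels)


def apply_correction(C: CorrectionMatrix, V: VariableMatrix) -> np.ndarray:
    """Corrected XYZ rows = V @ C.T (no clipping)."""
    if C.term_labels != V.term_labels:
        for a, b in zip(C.term_labels, V.term_labels):
            if a != b:
                raise ValueError(f"term label mismatch: {a!r} != {b!r}")
        raise ValueError("term label count mismatch")
    return V.values @ C.entries.T


def pca_reflectance(
    spectra, n_components: int | None = None
) -> tuple[PCABasis, np.ndarray]:
    """Mean-centred PCA of reflectance spectra via SVD.

    Component sign is fixed so each component's largest-magnitude element is
    positive.  Returns the basis and the per-spectrum scores.
    """
    if isinstance(spectra, np.ndarray):
        mat = np.asarray(spectra, dtype=float)
        grid = None
    else:
        spectra = list(spectra)
        if len(spectra) < 2:
            raise ValueError("PCA needs at least two spectra")
        grid = spectra[0].grid
        for s in spectra[1:]:
            if (s.grid.start_nm, s.grid.stop_nm, s.grid.step_nm) != (
                grid.start_nm, grid.stop_nm, grid.step_nm,
            ):
                raise ValueError("spectra must share one grid")
        mat = np.stack([s.values for s in spectra])
    if mat.shape[0] < 2:
        raise ValueError("PCA needs at least two spectra")
    n, bands = mat.shape
    max_comp = min(n - 1, bands)
    k = max_comp if n_components is None else int(n_components)
    if not 1 <= k <= max_comp:
        raise ValueError(f"n_components must be in [1, {max_comp}]")

    mean = mat.mean(axis=0)
    centred = mat - mean
    U, s, Vt = np.linalg.svd(centred, full_matrices=False)
    total_var = float(np.sum(s**2))
    comps = Vt[:k]
    scores = U[:, :k] * s[:k]
    # deterministic sign: largest-|coefficient| element positive
    for i in range(k):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
            scores[:, i] = -scores[:, i]
    evf = (s[:k] ** 2) / total_var if total_var > 0 else np.zeros(k)
    if grid is None:
        grid = make_grid(0.0, float(bands - 1), 1.0)  # index grid for raw arrays
    basis = PCABasis(Spectrum(grid, mean, name="mean"), comps, evf)
    return basis, scores


def fit_spectral_transform(scores, v_colour: VariableMatrix) -> SpectralTransform:
    """Least-squares fit of M such that M @ v_colour_row best reproduces the
    per-patch PCA scores."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2:
        raise ValueError("scores must be (n_patches, n_components)")
    if scores.shape[0] != v_colour.values.shape[0]:
        raise ValueError("row counts of scores and V_colour must match")
    M = _lstsq(v_colour.values, scores).T
    return SpectralTransform(M, v_colour.term_labels)


def similarity_index(predicted_xyz, measured_xyz) -> float:
    """Agreement between predicted and measured XYZ sets on a 0-1 scale,
    defined as 1 - RMSE / RMS(measured), clipped to [0, 1].

    This statistic is defined by this package (the name is conventional but
    no standard formula exists); 1 means perfect agreement.
    """
    p = np.asarray(predicted_xyz, dtype=float)
    m = np.asarray(measured_xyz, dtype=float)
    if p.size == 0 or m.size == 0:
        raise ValueError("similarity index needs at least one triple")
    if p.shape != m.shape:
        raise ValueError("predicted and measured shapes must match")
    rmse = float(np.sqrt(np.mean((p - m) ** 2)))
    rms_ref = float(np.sqrt(np.mean(m**2)))
    if rms_ref == 0:
        return 1.0 if rmse == 0 else 0.0
    return float(np.clip(1.0 - rmse / rms_ref, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def reference_chart_xyz(
    spectra_matrix: np.ndarray,
    grid: SpectralGrid,
    illuminant: Spectrum | None = None,
    cmfs: CMFSet | None = None,
) -> tuple[np.ndarray, XYZTriple]:
    """Tristimulus values of chart spectra plus the white point (XYZ of the
    perfect reflector) under the same illuminant/observer."""
    illuminant = illuminant or illuminant_d65(grid)
    cmfs = cmfs or cie_1931_cmfs(grid)
    xyz = reflectances_to_xyz(spectra_matrix, illuminant, cmfs, grid)
    white = reflectances_to_xyz(
        np.ones((1, grid.n_samples)), illuminant, cmfs, grid
    )[0]
    return xyz, XYZTriple(*white)


def calibrate(
    chart: ChartReference,
    capture: CameraPatchCapture,
    degree: int = 3,
    n_components: int = 6,
    provenance: str = "",
) -> CalibrationBundle:
    """Fit the full calibration bundle from a chart reference and capture."""
    if chart.patch_ids != capture.patch_ids:
        raise ValueError("chart and capture patch ids must match in order")
    V = expand_variables(capture.linear_rgb(), degree)
    correction = fit_correction_matrix(chart.xyz, V)
    corrected = apply_correction(correction, V)
    basis, scores = pca_reflectance(chart.spectra, n_components)
    v_colour = expand_xyz(corrected, degree)
    transform = fit_spectral_transform(scores, v_colour)
    return CalibrationBundle(
        correction=correction,
        basis=basis,
        transform=transform,
        grid=chart.grid,
        white=chart.white,
        dark_offset=capture.dark_offset.copy(),
        encoding=capture.encoding,
        gamma=capture.gamma,
        degree=degree,
        provenance=provenance,
    )


@dataclass
class CalibrationReport:
    """Per-patch calibration errors plus summary means."""

    table: pd.DataFrame  # patch_id, spectral_rmse, delta_e_pre, delta_e_post
    mean_spectral_rmse: float
    mean_delta_e_pre: float
    mean_delta_e_post: float
    similarity: float


def calibration_report(
    bundle: CalibrationBundle,
    chart: ChartReference,
    capture: CameraPatchCapture,
) -> CalibrationReport:
    """Evaluate a fitted bundle on a chart capture.

    * spectral RMSE between reconstructed and reference patch spectra;
    * colour difference (CIEDE2000) between reference patch colours and
      (pre) the naive sRGB interpretation of the camera channels versus
      (post) the corrected XYZ values.
    """
    if chart.patch_ids != capture.patch_ids:
        raise ValueError("chart and capture patch counts/order must match")
    from .reconstruction import reconstruct_spectra  # cycle-free at runtime

    V = expand_variables(capture.linear_rgb(), bundle.degree)
    corrected = apply_correction(bundle.correction, V)
    recon, _ = reconstruct_spectra(corrected, bundle)
    ref = chart.spectra_matrix()
    rmse = np.sqrt(np.mean((recon - ref) ** 2, axis=1))

    white = bundle.white
    lab_ref = xyz_to_lab(chart.xyz, white)
    lab_post = xyz_to_lab(corrected, white)
    naive_xyz = srgb_linear_to_xyz(capture.linear_rgb())
    lab_pre = xyz_to_lab(naive_xyz, white)
    de_pre = ciede2000(lab_ref, lab_pre)
    de_post = ciede2000(lab_ref, lab_post)

    table = pd.DataFrame(
        {
            "patch_id": list(chart.patch_ids),
            "spectral_rmse": rmse,
            "delta_e_pre": de_pre,
            "delta_e_post": de_post,
        }
    )
    return CalibrationReport(
        table=table,
        mean_spectral_rmse=float(rmse.mean()),
        mean_delta_e_pre=float(de_pre.mean()),
        mean_delta_e_post=float(de_post.mean()),
        similarity=similarity_index(corrected, chart.xyz),
    )
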