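"""Spectral filtering and SNV normalization: cube -> per-pixel feature matrix.

Three steps turn a calibrated reflectance cube into classifier input:

1. band selection — wavelengths above 1600 nm are dropped (low detector
   sensitivity and strong water absorption there);
2. highlight/shadow masking — pixels whose 1300 nm reflectance exceeds 70%
   (specular highlight) or falls below 10% (shadow) are removed;
3. per-spectrum standard normal variate (SNV), z = (x - mean(x)) / std(x),
   applied to absorbance, which removes multiplicative scatter gain and
   additive baseline offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .cube_io import HyperspectralCube, nearest_band, to_absorbance

__all__ = [
    "PixelMask",
    "FeatureMatrix",
    "select_bands",
    "highlight_shadow_mask",
    "snv",
    "preprocess_cube",
]

#: Spectra with population std at or below this are treated as constant.
SNV_STD_TOL = 1e-12


@dataclass
class PixelMask:
    """2-D boolean retention grid (True = pixel kept) with rule provenance."""

    values: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.ndim != 2:
            raise ValueError("mask must be 2-D")

    def __and__(self, other: "PixelMask") -> "PixelMask":
        if self.values.shape != other.values.shape:
            raise ValueError("mask shapes differ")
        return PixelMask(self.values & other.values,
                         list(self.provenance) + list(other.provenance))

    @property
    def n_retained(self) -> int:
        return int(np.count_nonzero(self.values))

    def to_png(self, path) -> None:
        from PIL import Image
        Image.fromarray(self.values.astype(np.uint8) * 255, mode="L").save(path)

    @classmethod
    def from_png(cls, path) -> "PixelMask":
        from PIL import Image
        arr = np.asarray(Image.open(path).convert("L"))
        return cls(arr >= 128, [f"loaded:{path}"])


@dataclass
class FeatureMatrix:
    """One preprocessed spectrum per retained pixel.

    ``X`` rows are SNV-transformed spectra (mean 0, population std 1 each);
    ``pixel_index`` maps each row back to its (row, col) in row-major order;
    ``wavelengths`` are the retained band centers.
    """

    X: np.ndarray
    pixel_index: np.ndarray
    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.pixel_index = np.asarray(self.pixel_index, dtype=np.int64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.X.shape != (self.pixel_index.shape[0], self.wavelengths.size):
            raise ValueError("inconsistent FeatureMatrix shapes")

    def to_csv(self, path) -> None:
        import pandas as pd
        df = pd.DataFrame(self.X, columns=[f"{w:.1f}" for w in self.wavelengths])
        df.insert(0, "col", self.pixel_index[:, 1])
        df.insert(0, "row", self.pixel_index[:, 0])
        df.to_csv(path, index=False)


def select_bands(cube: HyperspectralCube, max_nm: float = 1600.0) -> HyperspectralCube:
    """Retain bands with center wavelength <= ``max_nm``, order preserved."""
    keep = cube.wavelengths <= max_nm
    if not keep.any():
        raise ValueError(
            f"no band at or below {max_nm} nm "
            f"(cube starts at {cube.wavelengths[0]} nm)"
        )
    if keep.all():
        return cube
    meta = dict(cube.meta)
    meta["band_cut_nm"] = float(max_nm)
    return HyperspectralCube(cube.values[:, :, keep], cube.wavelengths[keep], meta)


def highlight_shadow_mask(cube: HyperspectralCube, probe_nm: float = 1300.0,
                          hi: float = 0.70, lo: float = 0.10) -> PixelMask:
    """Mask specular highlights and shadows by their probe-band reflectance.

    A pixel is retained iff ``lo <= R(probe) <= hi`` (the thresholds
    themselves retain: the rule removes reflectance *over* ``hi`` and *below*
    ``lo``).  Calibration-invalid pixels are also dropped.
    """
    if not cube.is_calibrated() or cube.domain() != "reflectance":
        raise ValueError("highlight/shadow masking requires a reflectance cube")
    if not (cube.wavelengths[0] <= probe_nm <= cube.wavelengths[-1]):
        raise ValueError(
            f"probe wavelength {probe_nm} nm outside cube range "
            f"[{cube.wavelengths[0]}, {cube.wavelengths[-1]}] nm"
        )
    band = cube.values[:, :, nearest_band(cube, probe_nm)]
    retained = (band >= lo) & (band <= hi) & cube.valid_mask()
    rule = f"highlight_shadow(probe={probe_nm}nm, hi={hi}, lo={lo})"
    return PixelMask(retained, [rule])


def snv(spectrum: np.ndarray, ddof: int = 0, tol: float = SNV_STD_TOL) -> np.ndarray:
    """Standard normal variate of one spectrum: z = (x - mean(x)) / std(x).

    ``std`` is the population standard deviation by default (``ddof=0``); the
    sample convention differs only by a per-spectrum constant factor and can
    be selected with ``ddof=1``.  Constant spectra are rejected.
    """
    x = np.asarray(spectrum, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("snv expects a 1-D spectrum of length >= 2")
    sd = x.std(ddof=ddof)
    if sd <= tol:
        raise ValueError("constant spectrum: SNV undefined (std below tolerance)")
    return (x - x.mean()) / sd


def _snv_rows(X: np.ndarray, ddof: int, tol: float,
              pixel_index: np.ndarray) -> np.ndarray:
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=ddof, keepdims=True)
    bad = np.nonzero(sd.ravel() <= tol)[0]
    if bad.size:
        r, c = pixel_index[bad[0]]
        raise ValueError(
            f"constant spectrum at pixel (row={r}, col={c}): SNV undefined"
        )
    return (X - mean) / sd


def preprocess_cube(cube: HyperspectralCube, mask: PixelMask,
                    max_nm: float = 1600.0, floor: float = 1e-4,
                    use_absorbance: bool = True, ddof: int = 0) -> FeatureMatrix:
    """Full preprocessing: absorbance -> band selection -> row-wise SNV.

    ``cube`` must be reflectance-calibrated; ``mask`` selects which pixels
    produce feature rows.  Row order is row-major over retained pixels.
    ``use_absorbance=False`` runs SNV on reflectance instead (config option;
    absorbance is the default because layered-tissue contributions add there).
    """
    if not cube.is_calibrated() or cube.domain() != "reflectance":
        raise ValueError("preprocess_cube requires a reflectance-calibrated cube")
    if mask.values.shape != cube.spatial_shape:
        raise ValueError("mask shape does not match cube spatial shape")
    if mask.n_retained == 0:
        raise ValueError("no retained pixels to preprocess")

    work = to_absorbance(cube, floor=floor) if use_absorbance else cube
    work = select_bands(work, max_nm=max_nm)
    rows, cols = np.nonzero(mask.values)           # row-major order
    pixel_index = np.column_stack([rows, cols])
    X = work.values[rows, cols, :]
    X = _snv_rows(X, ddof=ddof, tol=SNV_STD_TOL, pixel_index=pixel_index)
    return FeatureMatrix(X, pixel_index, work.wavelengths)
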