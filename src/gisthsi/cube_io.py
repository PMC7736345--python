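"""Hyperspectral data-cube container, ENVI/portable I/O, calibration, rendering.

A push-broom NIR hyperspectral camera produces a "data cube": a 2-D spatial
grid with a full reflectance spectrum at every pixel.  This module holds the
cube container plus the steps that turn raw sensor counts into calibrated
reflectance, reflectance into absorbance, and a cube into a pseudo-color
picture for display.

Conventions shared by every module in this package: 0-based (row, col)
spatial coordinates, band axis last, wavelengths in nm strictly increasing,
reflectance stored as a fraction (0.70, not 70%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "HyperspectralCube",
    "ReferencePair",
    "RGBImage",
    "read_cube",
    "write_cube",
    "calibrate_reflectance",
    "to_absorbance",
    "nearest_band",
    "pseudo_color",
    "instrument_grid",
]

#: Reflectance values above this after calibration are clipped and counted.
REFLECTANCE_CLIP = 1.5


def instrument_grid(start_nm: float = 1000.0, step_nm: float = 6.3,
                    stop_nm: float = 2350.0) -> np.ndarray:
    """Wavelength grid of the line-scan camera: 1000-2350 nm at 6.3 nm.

    The last band not exceeding ``stop_nm`` is included (2348.2 nm for the
    defaults, 215 bands in total).
    """
    n = int(np.floor((stop_nm - start_nm) / step_nm)) + 1
    return start_nm + step_nm * np.arange(n)


@dataclass
class HyperspectralCube:
    """3-D grid of spectral samples, indexed (row, col, band).

    ``values`` holds raw counts before calibration and unitless reflectance
    in [0, 1] (clipped at :data:`REFLECTANCE_CLIP`) after; ``wavelengths``
    are the band centers in nm; ``meta`` is free-form provenance (specimen
    id, calibration state, source path).
    """

    values: np.ndarray
    wavelengths: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.wavelengths = np.asarray(self.wavelengths, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"cube values must be 3-D, got {self.values.ndim}-D")
        if self.wavelengths.ndim != 1 or len(self.wavelengths) != self.values.shape[2]:
            raise ValueError(
                f"wavelength count {self.wavelengths.size} does not match "
                f"band axis extent {self.values.shape[2]}"
            )
        if len(self.wavelengths) > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.values.shape[:2]

    @property
    def n_bands(self) -> int:
        return self.values.shape[2]

    def is_calibrated(self) -> bool:
        return bool(self.meta.get("calibrated", False))

    def domain(self) -> str:
        """'counts', 'reflectance' or 'absorbance'."""
        return self.meta.get("domain", "counts")

    def valid_mask(self) -> np.ndarray:
        """2-D boolean grid of pixels with usable calibration (default: all)."""
        m = self.meta.get("valid_mask")
        if m is None:
            return np.ones(self.spatial_shape, dtype=bool)
        return np.asarray(m, dtype=bool)


@dataclass
class ReferencePair:
    """White-standard and shutter-closed (dark) reference frames.

    ``white``/``dark`` may be full frames (rows, cols, bands), a per-scan-line
    reference (cols, bands) broadcast along rows, or a single spectrum
    (bands,).  Positions where white <= dark are unusable and get flagged
    during calibration rather than producing NaNs.
    """

    white: np.ndarray
    dark: np.ndarray

    def __post_init__(self) -> None:
        self.white = np.asarray(self.white, dtype=np.float64)
        self.dark = np.asarray(self.dark, dtype=np.float64)
        if self.white.shape != self.dark.shape:
            raise ValueError("white and dark references must share a shape")
        if self.white.ndim not in (1, 2, 3):
            raise ValueError("references must be 1-D, 2-D or 3-D")


@dataclass
class RGBImage:
    """2-D grid of (r, g, b) triples in [0, 1]."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError("RGBImage values must have shape (rows, cols, 3)")
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("RGB channel values must lie in [0, 1]")

    def to_uint8(self) -> np.ndarray:
        return np.round(self.values * 255).astype(np.uint8)


# --------------------------------------------------------------------------
# ENVI + portable-array I/O
# --------------------------------------------------------------------------

_ENVI_DTYPES = {1: np.uint8, 2: np.int16, 3: np.int32, 4: np.float32,
                5: np.float64, 12: np.uint16, 13: np.uint32}
_ENVI_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


def _parse_envi_header(text: str) -> dict:
    """Parse the ``key = value`` / ``key = { ... }`` ENVI header dialect."""
    fields: dict[str, str] = {}
    lines = iter(text.splitlines())
    for line in lines:
        line = line.strip()
        if not line or line.upper() == "ENVI" or "=" not in line:
            continue
        key, _, value = line.partition("=")
        key = key.strip().lower()
        value = value.strip()
        if value.startswith("{"):
            while value.count("{") > value.count("}"):
                try:
                    value += " " + next(lines).strip()
                except StopIteration:
                    raise ValueError(f"unterminated brace list for ENVI key {key!r}")
            value = value[1:value.rindex("}")]
        fields[key] = value
    return fields


def _require(fields: dict, key: str) -> str:
    if key not in fields:
        raise ValueError(f"ENVI header missing required field {key!r}")
    return fields[key]


def read_cube(path: str | Path, format: str | None = None) -> HyperspectralCube:
    """Read a cube from ENVI (``.hdr`` + raw) or the portable ``.npz`` container.

    The format is inferred from the suffix when not given.  ENVI headers must
    declare samples, lines, bands, data type, interleave and wavelength; a
    wavelength list whose length disagrees with the band count is an error.
    """
    path = Path(path)
    if format is None:
        format = "portable-array" if path.suffix == ".npz" else "envi"
    if format == "portable-array":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta_json"]))
            cube = HyperspectralCube(z["values"], z["wavelengths"], meta)
        cube.meta.setdefault("source", str(path))
        if "valid_mask" in cube.meta:
            cube.meta["valid_mask"] = np.asarray(cube.meta["valid_mask"], dtype=bool)
        return cube
    if format != "envi":
        raise ValueError(f"unknown cube format {format!r}")

    hdr_path = path if path.suffix == ".hdr" else path.with_suffix(path.suffix + ".hdr")
    if not hdr_path.exists():
        hdr_path = path.with_suffix(".hdr")
    if not hdr_path.exists():
        raise FileNotFoundError(f"no ENVI header found for {path}")
    data_path = Path(str(hdr_path)[: -len(".hdr")])
    fields = _parse_envi_header(hdr_path.read_text())

    samples = int(_require(fields, "samples"))
    lines = int(_require(fields, "lines"))
    bands = int(_require(fields, "bands"))
    dtype_code = int(_require(fields, "data type"))
    interleave = _require(fields, "interleave").lower()
    wavelengths = np.array(
        [float(w) for w in _require(fields, "wavelength").split(",") if w.strip()]
    )
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type {dtype_code}")
    if wavelengths.size != bands:
        raise ValueError(
            f"ENVI header declares {bands} bands but lists {wavelengths.size} wavelengths"
        )
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unsupported interleave {interleave!r}")
    if min(samples, lines, bands) <= 0:
        raise ValueError("ENVI header declares an empty cube")

    raw = np.fromfile(data_path, dtype=_ENVI_DTYPES[dtype_code])
    if raw.size != samples * lines * bands:
        raise ValueError(
            f"ENVI data size {raw.size} does not match header "
            f"{lines}x{samples}x{bands}"
        )
    if interleave == "bsq":          # (band, line, sample)
        values = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":        # (line, band, sample)
        values = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    else:                            # bip: (line, sample, band)
        values = raw.reshape(lines, samples, bands)

    meta = {"source": str(data_path), "format": "envi", "interleave": interleave}
    if "description" in fields:
        try:
            meta.update(json.loads(fields["description"]))
        except json.JSONDecodeError:
            meta["description"] = fields["description"]
    return HyperspectralCube(values.astype(np.float64), wavelengths, meta)


def write_cube(cube: HyperspectralCube, path: str | Path,
               format: str | None = None, interleave: str = "bsq") -> Path:
    """Write a cube; the result round-trips bit-exactly through :func:`read_cube`."""
    path = Path(path)
    if cube.values.size == 0:
        raise ValueError("refusing to write an empty cube")
    if format is None:
        format = "portable-array" if path.suffix == ".npz" else "envi"
    if format == "portable-array":
        meta = dict(cube.meta)
        if "valid_mask" in meta:
            meta["valid_mask"] = np.asarray(meta["valid_mask"]).astype(bool).tolist()
        np.savez_compressed(path, values=cube.values, wavelengths=cube.wavelengths,
                            meta_json=json.dumps(meta))
        return path
    if format != "envi":
        raise ValueError(f"unknown cube format {format!r}")
    if interleave not in ("bsq", "bil", "bip"):
        raise ValueError(f"unsupported interleave {interleave!r}")

    rows, cols, bands = cube.shape
    if interleave == "bsq":
        flat = cube.values.transpose(2, 0, 1)
    elif interleave == "bil":
        flat = cube.values.transpose(0, 2, 1)
    else:
        flat = cube.values
    meta = {k: v for k, v in cube.meta.items()
            if isinstance(v, (str, int, float, bool))}
    header = "\n".join([
        "ENVI",
        f"description = {{{json.dumps(meta)}}}",
        f"samples = {cols}",
        f"lines = {rows}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {_ENVI_CODES[np.dtype(np.float64)]}",
        f"interleave = {interleave}",
        "byte order = 0",
        "wavelength units = Nanometers",
        "wavelength = {" + ", ".join(f"{w:.6f}" for w in cube.wavelengths) + "}",
    ]) + "\n"
    Path(str(path) + ".hdr").write_text(header)
    np.ascontiguousarray(flat, dtype=np.float64).tofile(path)
    return path


# --------------------------------------------------------------------------
# Calibration and rendering
# --------------------------------------------------------------------------

def calibrate_reflectance(raw: HyperspectralCube, refs: ReferencePair,
                          clip: float = REFLECTANCE_CLIP) -> HyperspectralCube:
    """Flat-field calibration R = (raw - dark) / (white - dark).

    White/dark frames broadcast against the cube (full frame, per scan line,
    or single spectrum).  Positions where white <= dark make the division
    degenerate: those pixels are flagged in ``meta['valid_mask']`` and set to
    zero rather than propagating NaNs.  Reflectance above ``clip`` is clipped
    (and counted in ``meta['n_clipped']``); the common cause is specular
    highlights, which the preprocessing mask removes anyway.
    """
    white = np.broadcast_to(refs.white, raw.shape)
    dark = np.broadcast_to(refs.dark, raw.shape)
    denom = white - dark
    degenerate = denom <= 0
    safe = np.where(degenerate, 1.0, denom)
    refl = (raw.values - dark) / safe
    refl[degenerate] = 0.0

    valid = ~degenerate.any(axis=2) & raw.valid_mask()
    n_clipped = int(np.count_nonzero(refl > clip))
    refl = np.clip(refl, 0.0, clip)

    meta = dict(raw.meta)
    meta.update(calibrated=True, domain="reflectance", valid_mask=valid,
                n_clipped=n_clipped)
    return HyperspectralCube(refl, raw.wavelengths.copy(), meta)


def to_absorbance(cube: HyperspectralCube, floor: float = 1e-4) -> HyperspectralCube:
    """A = -log10(max(R, floor)).

    Absorbance is the representation in which contributions of stacked tissue
    layers add approximately linearly (Beer-Lambert), which is what the
    downstream classifier relies on.  ``floor`` caps the absorbance of
    near-zero reflectance (shadow) pixels; those are masked out later anyway.
    """
    if not cube.is_calibrated() or cube.domain() != "reflectance":
        raise ValueError("to_absorbance requires a reflectance-calibrated cube")
    if floor <= 0:
        raise ValueError("floor must be positive")
    absorb = -np.log10(np.maximum(cube.values, floor))
    meta = dict(cube.meta)
    meta["domain"] = "absorbance"
    return HyperspectralCube(absorb, cube.wavelengths.copy(), meta)


def nearest_band(cube: HyperspectralCube, target_nm: float) -> int:
    """Index of the band center closest to ``target_nm``; ties go to the lower index.

    Needed because operating wavelengths like 1300 or 1065 nm are not exact
    points of the 6.3 nm instrument grid.
    """
    if cube.n_bands == 0:
        raise ValueError("cube has no bands")
    # np.argmin returns the first minimum, which is the lower index on a tie
    return int(np.argmin(np.abs(cube.wavelengths - target_nm)))


def pseudo_color(cube: HyperspectralCube,
                 rgb_nm: tuple[float, float, float] = (1065.0, 1280.0, 1981.0)
                 ) -> RGBImage:
    """Render three reflectance bands as an RGB picture.

    Each channel is the nearest band's reflectance min-max rescaled to [0, 1]
    over valid pixels; a constant channel rescales to all zeros.  The default
    wavelengths are the display convention used for NIR specimen pictures.
    """
    if not cube.is_calibrated():
        raise ValueError("pseudo_color requires a calibrated cube")
    lo, hi = cube.wavelengths[0], cube.wavelengths[-1]
    for nm in rgb_nm:
        if not (lo <= nm <= hi):
            raise ValueError(
                f"requested wavelength {nm} nm outside cube range [{lo}, {hi}] nm"
            )
    valid = cube.valid_mask()
    out = np.zeros(cube.spatial_shape + (3,))
    for ch, nm in enumerate(rgb_nm):
        band = cube.values[:, :, nearest_band(cube, nm)]
        sel = band[valid] if valid.any() else band.ravel()
        bmin, bmax = (sel.min(), sel.max()) if sel.size else (0.0, 0.0)
        if bmax > bmin:
            out[:, :, ch] = np.clip((band - bmin) / (bmax - bmin), 0.0, 1.0)
        # else: degenerate rescale -> channel stays 0
    return RGBImage(out)
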