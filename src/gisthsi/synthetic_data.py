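"""Synthetic NIR-HSI specimens with the statistical structure the pipeline assumes.

No public dataset of submucosal-tumor hyperspectral cubes exists, so every
stage of the pipeline is exercised on simulated specimens instead.  The
generator emulates the physics the analysis relies on, not the full optics:

* absorbance of a pixel is a layered Beer-Lambert mixture of per-tissue
  absorptivity curves — a tumor pixel is covered by 0.4-2.5 mm of mucosa, so
  its spectrum is a depth-weighted blend of the mucosa and tumor signatures,
  while a normal pixel is mucosa/submucosa only;
* tumor and normal absorptivity curves are deliberately *similar*: their
  post-SNV L2 separation delta is a configurable, measured quantity;
* each pixel carries a multiplicative gain and additive offset (the scatter
  artifacts SNV removes) plus Gaussian sensor noise;
* a configurable fraction of pixels are specular highlights or shadows;
* some specimens are tumor-only (no normal region), as happens with real
  resections, to exercise the undefined-specificity reporting path.

Every random draw goes through one seeded generator; the same seed
reproduces the cohort bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import string
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import shapely

from .annotation import (AnnotationSet, Box, LabelImage, GIST, NORMAL,
                         points_in_polygon, rasterize_labels, save_annotations)
from .cube_io import HyperspectralCube, ReferencePair, instrument_grid, write_cube
from .preprocess import select_bands

__all__ = [
    "EndmemberSet",
    "SpecimenConfig",
    "SyntheticSpecimen",
    "make_endmembers",
    "make_specimen",
    "make_cohort",
    "write_cohort",
]


def _snv_vec(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std()


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


@dataclass
class EndmemberSet:
    """Per-tissue absorptivity curves (absorbance per mm of tissue).

    ``gist`` and ``normal`` share the broad water band near 1450 nm and
    differ by a smooth multiplicative perturbation sized so that their SNV
    spectra (over the analysis bands, <= ``max_nm``) are ``separation``
    apart in L2.
    """

    wavelengths: np.ndarray
    gist: np.ndarray
    normal: np.ndarray
    background: np.ndarray
    separation: float
    max_nm: float = 1600.0

    def measured_separation(self) -> float:
        keep = self.wavelengths <= self.max_nm
        if self.separation == 0.0:
            return 0.0
        return float(np.linalg.norm(
            _snv_vec(self.gist[keep]) - _snv_vec(self.normal[keep])))


def make_endmembers(seed: int, separation: float = 1.2,
                    wavelengths: np.ndarray | None = None,
                    max_nm: float = 1600.0) -> EndmemberSet:
    """Build smooth tissue absorptivity curves with a prescribed separation.

    The normal (mucosa/submucosa) curve is a sum of Gaussian bands on a
    gentle baseline, scaled so a few millimetres of tissue land in the
    usable reflectance range at the 1300 nm probe.  The tumor curve is the
    normal curve times ``(1 + a * p)`` with ``p`` a smooth zero-mean
    perturbation that avoids the shared 1450 nm water band; ``a`` is solved
    by bisection so the post-SNV L2 distance over the analysis bands matches
    ``separation`` (within 5%, typically much better).  ``separation = 0``
    returns identical curves — the no-signal null.
    """
    if separation < 0:
        raise ValueError("separation must be >= 0")
    wl = instrument_grid() if wavelengths is None else np.asarray(wavelengths, float)
    rng = np.random.default_rng(seed)

    jit = lambda sd: rng.normal(0.0, sd)
    normal = (
        0.055
        + 0.012 * (wl - wl[0]) / (wl[-1] - wl[0])
        + 0.050 * _gauss(wl, 1195.0 + jit(4.0), 62.0)
        + 0.110 * _gauss(wl, 1450.0 + jit(2.0), 48.0)   # water band, shared
        + 0.028 * _gauss(wl, 1540.0 + jit(4.0), 55.0)
        + 0.340 * _gauss(wl, 1930.0 + jit(5.0), 80.0)   # strong water, cut later
    )
    # scale so ~4 mm of tissue gives A(1300) ~ 0.5 (reflectance ~ 0.3)
    i1300 = int(np.argmin(np.abs(wl - 1300.0)))
    normal = normal * (0.125 / normal[i1300])

    perturb = (
        +1.0 * _gauss(wl, 1120.0 + jit(5.0), 48.0)
        - 0.9 * _gauss(wl, 1230.0 + jit(5.0), 45.0)
        + 0.7 * _gauss(wl, 1345.0 + jit(5.0), 40.0)
        - 0.5 * _gauss(wl, 1560.0 + jit(5.0), 50.0)
    )
    perturb -= perturb.mean()

    keep = wl <= max_nm
    if keep.sum() < 3:
        raise ValueError("separation infeasible: too few analysis bands")

    def dist(a: float) -> float:
        g = normal * (1.0 + a * perturb)
        return float(np.linalg.norm(_snv_vec(g[keep]) - _snv_vec(normal[keep])))

    if separation == 0.0:
        gist = normal.copy()
    else:
        a_hi = 0.05
        while dist(a_hi) < separation:
            a_hi *= 2.0
            if a_hi > 1e3:
                raise ValueError(f"separation {separation} infeasible")
        a_lo = 0.0
        for _ in range(80):
            a_mid = 0.5 * (a_lo + a_hi)
            if dist(a_mid) < separation:
                a_lo = a_mid
            else:
                a_hi = a_mid
        a = 0.5 * (a_lo + a_hi)
        gist = normal * (1.0 + a * perturb)
        if gist.min() <= 0:
            raise ValueError(f"separation {separation} infeasible: curve not positive")
        achieved = dist(a)
        if abs(achieved - separation) > 0.05 * separation:
            raise ValueError(
                f"separation {separation} not achievable "
                f"(closest {achieved:.4f})"
            )

    background = 1.1 + 0.3 * _gauss(wl, 1420.0, 150.0)   # dark stage material
    return EndmemberSet(wl, gist, normal, background, separation, max_nm)


@dataclass
class SpecimenConfig:
    """Study conditions for one synthetic specimen.

    Depth ranges are in mm; the mucosa covering the tumor is 0.4-2.5 mm as
    measured on the resected specimens this simulator emulates.  The default
    grid is 64 x 64 pixels over the full 215-band instrument wavelength
    range, of which 96 bands survive the 1600 nm cut.
    """

    shape: tuple[int, int] = (64, 64)
    separation: float = 1.2
    mucosa_depth_range: tuple[float, float] = (0.4, 2.5)
    deep_layer_range: tuple[float, float] = (2.0, 4.0)
    noise_sd: float = 0.015
    gain_range: tuple[float, float] = (0.85, 1.15)
    offset_range: tuple[float, float] = (-0.05, 0.05)
    highlight_fraction: float = 0.01
    shadow_fraction: float = 0.01
    lesion_axes_range: tuple[float, float] = (16.0, 22.0)
    boundary_thickness_px: float = 2.0
    box_size: int = 8
    boxes_per_class: int = 2
    gist_only: bool = False
    extent_margin_px: float = 2.0
    include_raw: bool = False

    def wavelength_grid(self) -> np.ndarray:
        return instrument_grid()


@dataclass
class SyntheticSpecimen:
    """One simulated specimen: cube, ground truth, annotations, provenance."""

    id: str
    cube: HyperspectralCube
    truth: LabelImage
    annotations: AnnotationSet
    depth_map: np.ndarray
    config: SpecimenConfig
    seed: int
    raw: HyperspectralCube | None = None
    refs: ReferencePair | None = None


def _lesion_polyline(rng, cfg: SpecimenConfig) -> np.ndarray:
    rows, cols = cfg.shape
    if cfg.gist_only:
        m = cfg.extent_margin_px - 0.8          # just outside the extent polygon
        poly = np.array([[m, m], [m, cols - 1 - m],
                         [rows - 1 - m, cols - 1 - m], [rows - 1 - m, m], [m, m]])
        return poly
    cr = rows / 2.0 + rng.uniform(-3.0, 3.0)
    cc = cols / 2.0 + rng.uniform(-3.0, 3.0)
    a = rng.uniform(*cfg.lesion_axes_range) * rows / 64.0
    b = rng.uniform(*cfg.lesion_axes_range) * cols / 64.0
    theta = rng.uniform(0.0, np.pi)
    t = np.linspace(0.0, 2.0 * np.pi, 73)
    r = cr + a * np.cos(t) * np.cos(theta) - b * np.sin(t) * np.sin(theta)
    c = cc + a * np.cos(t) * np.sin(theta) + b * np.sin(t) * np.cos(theta)
    # keep vertices inside the grid with a margin for the extent polygon
    r = np.clip(r, cfg.extent_margin_px, rows - 1 - cfg.extent_margin_px)
    c = np.clip(c, cfg.extent_margin_px, cols - 1 - cfg.extent_margin_px)
    poly = np.column_stack([r, c])
    poly[-1] = poly[0]
    return poly


def _smooth_field(rng, shape, base, amplitude, jitter_sd) -> np.ndarray:
    rows, cols = shape
    rr, cc = np.meshgrid(np.linspace(-1, 1, rows), np.linspace(-1, 1, cols),
                         indexing="ij")
    phi = rng.uniform(0.0, 2.0 * np.pi)
    field = base + amplitude * (rr * np.cos(phi) + cc * np.sin(phi))
    return field + rng.normal(0.0, jitter_sd, size=shape)


def _place_boxes(rng, cfg: SpecimenConfig, in_gist: np.ndarray,
                 in_extent: np.ndarray, dist_to_boundary: np.ndarray,
                 planted: np.ndarray) -> list[Box]:
    """Deterministically place non-overlapping training boxes clear of the
    exclusion corridor and mostly free of planted highlight/shadow pixels
    (a few masked pixels inside a box are fine — the box only contributes
    its valid pixels, as on a real specimen)."""
    rows, cols = cfg.shape
    k = cfg.box_size
    clearance = 2.0 * cfg.boundary_thickness_px + 0.5
    occupied = np.zeros(cfg.shape, dtype=bool)
    boxes: list[Box] = []
    wanted = [("gist", cfg.boxes_per_class)]
    if not cfg.gist_only:
        wanted.append(("normal", cfg.boxes_per_class))

    candidates = [(r0, c0) for r0 in range(2, rows - k - 1, 2)
                  for c0 in range(2, cols - k - 1, 2)]
    for label, n_boxes in wanted:
        region = in_gist if label == "gist" else (in_extent & ~in_gist)
        order = rng.permutation(len(candidates))
        placed = 0
        for idx in order:
            if placed == n_boxes:
                break
            r0, c0 = candidates[idx]
            sl = (slice(r0, r0 + k), slice(c0, c0 + k))
            if not region[sl].all():
                continue
            if dist_to_boundary[sl].min() <= clearance:
                continue
            if occupied[sl].any() or planted[sl].mean() > 0.25:
                continue
            occupied[sl] = True
            boxes.append(Box(label, r0, c0, r0 + k, c0 + k))
            placed += 1
        if placed < n_boxes:
            raise ValueError(
                f"could not place {n_boxes} {label!r} boxes of size {k} "
                f"(placed {placed}); lesion geometry leaves no room"
            )
    return boxes


def make_specimen(config: SpecimenConfig | None = None, seed: int = 0,
                  endmembers: EndmemberSet | None = None,
                  specimen_id: str = "a") -> SyntheticSpecimen:
    """Simulate one specimen.

    Absorbance of a tumor pixel is ``d_muc * eps_mucosa + d_deep * eps_gist``
    (transparent-overburden Beer-Lambert mixing); a normal pixel is
    ``(d_muc + d_deep) * eps_mucosa``, i.e. the same layered geometry with
    normal deep tissue.  Per-pixel gain/offset artifacts and Gaussian
    noise are applied in absorbance, then reflectance is ``10**(-A)``.
    Highlights/shadows are planted afterwards at the configured fractions.
    The boundary polyline is drawn at the lesion margin and training boxes
    are auto-placed clear of its exclusion corridor.
    """
    cfg = config or SpecimenConfig()
    rng = np.random.default_rng(seed)
    rows, cols = cfg.shape
    wl = cfg.wavelength_grid()
    em = endmembers if endmembers is not None else make_endmembers(
        seed=int(rng.integers(2**31)), separation=cfg.separation, wavelengths=wl)

    m = cfg.extent_margin_px - 0.5
    extent = np.array([[m, m], [m, cols - 1 - m],
                       [rows - 1 - m, cols - 1 - m], [rows - 1 - m, m], [m, m]])
    boundary = _lesion_polyline(rng, cfg)

    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    centers = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    in_gist = points_in_polygon(centers, boundary).reshape(cfg.shape)
    in_extent = points_in_polygon(centers, extent).reshape(cfg.shape)
    in_gist &= in_extent
    in_normal = in_extent & ~in_gist

    # Layer thicknesses (mm).  A tissue pixel is a covering mucosa layer on
    # top of a deep layer; inside the lesion the deep layer is tumor, outside
    # it is normal submucosa/muscle with the same absorptivity as mucosa.
    # Both classes share the same thickness fields, so overall optical depth
    # carries no class information (and the separation-0 null is exact).
    d_lo, d_hi = cfg.mucosa_depth_range
    span = d_hi - d_lo
    mucosa = np.clip(
        _smooth_field(rng, cfg.shape,
                      base=rng.uniform(d_lo + 0.2 * span, d_hi - 0.15 * span),
                      amplitude=rng.uniform(0.0, 0.4 * span), jitter_sd=0.05),
        d_lo, d_hi)
    deep = np.clip(
        _smooth_field(rng, cfg.shape, base=rng.uniform(*cfg.deep_layer_range),
                      amplitude=rng.uniform(0.0, 0.5), jitter_sd=0.2), 0.5, None)

    A = np.empty((rows, cols, wl.size))
    A[:] = em.background[None, None, :]
    A[in_normal] = ((mucosa + deep)[in_normal, None] * em.normal[None, :])
    A[in_gist] = (mucosa[in_gist, None] * em.normal[None, :]
                  + deep[in_gist, None] * em.gist[None, :])

    gain = rng.uniform(*cfg.gain_range, size=cfg.shape)
    offset = rng.uniform(*cfg.offset_range, size=cfg.shape)
    A = gain[:, :, None] * A + offset[:, :, None]
    A += rng.normal(0.0, cfg.noise_sd, size=A.shape)
    refl = np.clip(10.0 ** (-A), 1e-6, 1.2)

    # plant specular highlights and shadows on tissue pixels
    tissue_idx = np.column_stack(np.nonzero(in_extent))
    planted = np.zeros(cfg.shape, dtype=bool)
    n_hi = int(round(cfg.highlight_fraction * len(tissue_idx)))
    n_lo = int(round(cfg.shadow_fraction * len(tissue_idx)))
    if n_hi + n_lo > 0:
        pick = rng.choice(len(tissue_idx), size=n_hi + n_lo, replace=False)
        hi_px = tissue_idx[pick[:n_hi]]
        lo_px = tissue_idx[pick[n_hi:]]
        for r, c in hi_px:
            refl[r, c, :] = rng.uniform(0.75, 0.95) + rng.normal(0, 0.01, wl.size)
        for r, c in lo_px:
            refl[r, c, :] = np.clip(
                rng.uniform(0.01, 0.08) + rng.normal(0, 0.005, wl.size), 1e-6, None)
        planted[hi_px[:, 0], hi_px[:, 1]] = True
        planted[lo_px[:, 0], lo_px[:, 1]] = True

    depth_map = np.where(in_gist, mucosa, 0.0)

    line = shapely.LineString(boundary[:, ::-1])
    pts = shapely.points(centers[:, ::-1])
    dist_to_boundary = shapely.distance(pts, line).reshape(cfg.shape)
    boxes = _place_boxes(rng, cfg, in_gist, in_extent, dist_to_boundary, planted)

    ann = AnnotationSet(boundary=boundary, thickness_px=cfg.boundary_thickness_px,
                        boxes=boxes, extent=extent)
    truth = rasterize_labels(ann, cfg.shape)

    meta = {"specimen": specimen_id, "seed": int(seed), "calibrated": True,
            "domain": "reflectance", "config": json.dumps(asdict(cfg)),
            "separation": em.separation}
    cube = HyperspectralCube(refl, wl, meta)

    raw = refs = None
    if cfg.include_raw:
        white = 30000.0 * (0.6 + 0.4 * _gauss(wl, 1500.0, 500.0))
        dark = np.full(wl.size, 500.0)
        raw_vals = dark + refl * (white - dark)
        raw = HyperspectralCube(raw_vals, wl, {"specimen": specimen_id,
                                               "domain": "counts"})
        refs = ReferencePair(white=white, dark=dark)

    return SyntheticSpecimen(id=specimen_id, cube=cube, truth=truth,
                             annotations=ann, depth_map=depth_map, config=cfg,
                             seed=int(seed), raw=raw, refs=refs)


def make_cohort(n: int = 12, config: SpecimenConfig | None = None,
                seed: int = 0, n_gist_only: int = 2) -> list[SyntheticSpecimen]:
    """Simulate a cohort of specimens with independent geometry and depth.

    The last ``n_gist_only`` specimens have no normal region (the whole
    imaged area is tumor), exercising the undefined-specificity path of the
    report.  A single seed controls everything; endmember curves are shared
    across the cohort (one instrument, one tissue model), per-specimen
    randomness is drawn from spawned child seeds.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 specimens")
    if not 0 <= n_gist_only <= n - 1:
        raise ValueError("n_gist_only must leave at least one mixed specimen")
    cfg = config or SpecimenConfig()
    ss = np.random.SeedSequence(seed)
    em_seed, *child = ss.spawn(n + 1)
    em = make_endmembers(seed=int(em_seed.generate_state(1)[0] % (2**31)),
                         separation=cfg.separation,
                         wavelengths=cfg.wavelength_grid())
    ids = (list(string.ascii_lowercase) +
           [f"s{i}" for i in range(26, n)])[:n]
    cohort = []
    for i, (sid, cs) in enumerate(zip(ids, child)):
        spec_cfg = replace(cfg, gist_only=(i >= n - n_gist_only))
        cohort.append(make_specimen(spec_cfg,
                                    seed=int(cs.generate_state(1)[0] % (2**31)),
                                    endmembers=em, specimen_id=sid))
    return cohort


def write_cohort(cohort: list[SyntheticSpecimen], out_dir: str | Path) -> Path:
    """Write each specimen as ENVI cube + annotation JSON + truth PNG, plus a
    manifest listing members and truth checksums."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    members = []
    for sp in cohort:
        cube_path = out / f"{sp.id}.raw"
        write_cube(sp.cube, cube_path, format="envi")
        save_annotations(sp.annotations, out / f"{sp.id}.annotations.json")
        sp.truth.to_png(out / f"{sp.id}.truth.png")
        members.append({
            "id": sp.id,
            "cube": cube_path.name,
            "annotations": f"{sp.id}.annotations.json",
            "truth": f"{sp.id}.truth.png",
            "seed": sp.seed,
            "gist_only": sp.config.gist_only,
            "truth_sha256": hashlib.sha256(sp.truth.values.tobytes()).hexdigest(),
        })
    manifest = out / "manifest.json"
    manifest.write_text(json.dumps({"members": members}, indent=1))
    return manifest
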