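"""Pathologist annotations: boundary line, training boxes, label rasterization.

Ground truth per specimen is a closed freehand boundary polyline separating
the tumor (inside) from normal tissue (outside), plus axis-aligned bounding
boxes guaranteed to contain only one tissue class, which supply the training
spectra.  Because the boundary is drawn freehand, pixels near it are
unreliable: its thickness is doubled on both sides and everything inside
that corridor is excluded from accuracy accounting.

Conventions: 0-based integer pixel centers at (row, col) with no half-pixel
offset; polygon membership by the even-odd rule at pixel centers; boxes are
half-open ``[r0, r1) x [c0, c1)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely

from .preprocess import FeatureMatrix, PixelMask

__all__ = [
    "AnnotationSet",
    "Box",
    "LabelImage",
    "BACKGROUND",
    "NORMAL",
    "GIST",
    "load_annotations",
    "save_annotations",
    "points_in_polygon",
    "rasterize_labels",
    "exclusion_mask",
    "extract_training_set",
]

BACKGROUND, NORMAL, GIST = 0, 1, 2
_LABELS = ("gist", "normal")


@dataclass(frozen=True)
class Box:
    """Axis-aligned training box, half-open [r0, r1) x [c0, c1)."""

    label: str
    r0: int
    c0: int
    r1: int
    c1: int

    def __post_init__(self) -> None:
        if self.label not in _LABELS:
            raise ValueError(f"box label must be one of {_LABELS}, got {self.label!r}")
        if self.r1 <= self.r0 or self.c1 <= self.c0:
            raise ValueError(f"empty box {self}")

    def pixel_centers(self) -> np.ndarray:
        rr, cc = np.meshgrid(np.arange(self.r0, self.r1),
                             np.arange(self.c0, self.c1), indexing="ij")
        return np.column_stack([rr.ravel(), cc.ravel()])

    def contains(self, pixels: np.ndarray) -> np.ndarray:
        r, c = pixels[:, 0], pixels[:, 1]
        return (r >= self.r0) & (r < self.r1) & (c >= self.c0) & (c < self.c1)


def points_in_polygon(points: np.ndarray, vertices: np.ndarray) -> np.ndarray:
    """Even-odd (crossing-number) membership test at the given points.

    ``points``/``vertices`` are (N, 2) arrays of (row, col).  A point on an
    edge is classified by the crossing count — deterministic, though which
    side it lands on depends on the edge geometry.
    """
    pts = np.asarray(points, dtype=np.float64)
    verts = np.asarray(vertices, dtype=np.float64)
    if not np.array_equal(verts[0], verts[-1]):
        verts = np.vstack([verts, verts[0]])
    r, c = pts[:, 0], pts[:, 1]
    inside = np.zeros(len(pts), dtype=bool)
    for (r1, c1), (r2, c2) in zip(verts[:-1], verts[1:]):
        if r1 == r2:
            continue  # horizontal edge never crosses a horizontal ray
        crosses = (r1 > r) != (r2 > r)
        c_int = c1 + (r - r1) * (c2 - c1) / (r2 - r1)
        inside ^= crosses & (c < c_int)
    return inside


def _polygon_area(vertices: np.ndarray) -> float:
    v = np.asarray(vertices, dtype=np.float64)
    if not np.array_equal(v[0], v[-1]):
        v = np.vstack([v, v[0]])
    r, c = v[:, 0], v[:, 1]
    return 0.5 * abs(np.sum(r[:-1] * c[1:] - r[1:] * c[:-1]))


@dataclass
class AnnotationSet:
    """Boundary polyline, labeled training boxes, and the specimen extent.

    ``boundary`` is a closed polyline in (row, col) pixel coordinates with a
    nominal drawn thickness in pixels; everything inside it is tumor.
    ``extent`` separates tissue from the background stage.
    """

    boundary: np.ndarray
    thickness_px: float
    boxes: list[Box] = field(default_factory=list)
    extent: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.boundary = np.asarray(self.boundary, dtype=np.float64)
        if self.boundary.ndim != 2 or self.boundary.shape[1] != 2:
            raise ValueError("boundary must be an (N, 2) array of (row, col)")
        if not np.array_equal(self.boundary[0], self.boundary[-1]):
            raise ValueError("boundary polyline must be closed (first vertex = last)")
        if self.thickness_px < 0:
            raise ValueError("boundary thickness must be >= 0")
        if self.extent is not None:
            self.extent = np.asarray(self.extent, dtype=np.float64)
        self._validate_boxes()

    def _validate_boxes(self) -> None:
        for i, box in enumerate(self.boxes):
            centers = box.pixel_centers()
            in_boundary = points_in_polygon(centers, self.boundary)
            if box.label == "gist" and not in_boundary.all():
                raise ValueError(
                    f"gist box #{i} {box} is not strictly inside the boundary region"
                )
            if box.label == "normal" and in_boundary.any():
                raise ValueError(
                    f"normal box #{i} {box} intersects the boundary interior"
                )
            if self.extent is not None:
                if not points_in_polygon(centers, self.extent).all():
                    raise ValueError(f"box #{i} {box} lies outside the specimen extent")


def load_annotations(path: str | Path) -> AnnotationSet:
    """Load and validate an annotation JSON document.

    Schema: ``{"boundary": {"vertices": [[r, c], ...], "thickness_px": t},
    "boxes": [{"label": "gist"|"normal", "r0":, "c0":, "r1":, "c1":}, ...],
    "extent": {"vertices": [...]}}``.
    """
    doc = json.loads(Path(path).read_text())
    boxes = [Box(b["label"], b["r0"], b["c0"], b["r1"], b["c1"])
             for b in doc.get("boxes", [])]
    extent = doc.get("extent")
    return AnnotationSet(
        boundary=np.asarray(doc["boundary"]["vertices"], dtype=np.float64),
        thickness_px=float(doc["boundary"].get("thickness_px", 0.0)),
        boxes=boxes,
        extent=None if extent is None else np.asarray(extent["vertices"], float),
    )


def save_annotations(ann: AnnotationSet, path: str | Path) -> Path:
    doc = {
        "boundary": {"vertices": ann.boundary.tolist(),
                     "thickness_px": ann.thickness_px},
        "boxes": [{"label": b.label, "r0": b.r0, "c0": b.c0,
                   "r1": b.r1, "c1": b.c1} for b in ann.boxes],
    }
    if ann.extent is not None:
        doc["extent"] = {"vertices": ann.extent.tolist()}
    path = Path(path)
    path.write_text(json.dumps(doc, indent=1))
    return path


@dataclass
class LabelImage:
    """Ground-truth grid with codes background=0, normal=1, gist=2."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2:
            raise ValueError("label image must be 2-D")

    def to_png(self, path) -> None:
        from PIL import Image
        img = Image.fromarray(self.values, mode="P")
        img.putpalette([0, 0, 0, 255, 255, 0, 0, 200, 0])  # bg, normal, gist
        img.save(path)


def rasterize_labels(ann: AnnotationSet, shape: tuple[int, int]) -> LabelImage:
    """Rasterize the annotation into per-pixel class labels.

    Pixels inside the boundary polygon are tumor, pixels outside it but
    inside the specimen extent are normal, everything else is background
    stage.  Membership uses the even-odd rule at integer pixel centers.
    """
    if _polygon_area(ann.boundary) <= 0:
        raise ValueError("degenerate boundary polygon (zero area)")
    rows, cols = shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    centers = np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)
    in_gist = points_in_polygon(centers, ann.boundary)
    if ann.extent is not None:
        in_extent = points_in_polygon(centers, ann.extent)
    else:
        in_extent = np.ones(len(centers), dtype=bool)
    labels = np.full(len(centers), BACKGROUND, dtype=np.uint8)
    labels[in_extent] = NORMAL
    labels[in_gist] = GIST
    return LabelImage(labels.reshape(shape))


def exclusion_mask(ann: AnnotationSet, shape: tuple[int, int]) -> PixelMask:
    """Retain pixels farther than twice the line thickness from the boundary.

    A pixel is excluded iff its center lies within Euclidean distance ``2t``
    of the boundary polyline: the drawn line's thickness doubled on the
    inside and on the outside, reflecting that the freehand line itself is
    uncertain.  With ``t = 0`` only pixels exactly on the line are excluded.
    """
    rows, cols = shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    # shapely geometries use (x, y) = (col, row)
    line = shapely.LineString(ann.boundary[:, ::-1])
    pts = shapely.points(np.column_stack([cc.ravel(), rr.ravel()]).astype(float))
    dist = shapely.distance(pts, line).reshape(shape)
    retained = dist > 2.0 * ann.thickness_px
    return PixelMask(retained, [f"boundary_exclusion(2t={2.0 * ann.thickness_px}px)"])


def extract_training_set(features: FeatureMatrix, ann: AnnotationSet,
                         specimen_id: str = ""):
    """Collect labeled training rows from the annotation boxes.

    Rows of ``features`` whose pixel lies inside a box (and therefore
    survived the validity masks) take the box's class label.  A box that
    yields no valid pixel is an error — it cannot have been usable training
    data.  Returns a :class:`~gisthsi.svm_core.TrainingSet`.
    """
    from .svm_core import TrainingSet

    rows: list[np.ndarray] = []
    labels: list[str] = []
    pixels: list[np.ndarray] = []
    for i, box in enumerate(ann.boxes):
        hit = box.contains(features.pixel_index)
        if not hit.any():
            raise ValueError(
                f"box #{i} {box} yields zero valid pixels "
                "(fully masked or outside the feature domain)"
            )
        rows.append(features.X[hit])
        labels.extend([box.label] * int(hit.sum()))
        pixels.append(features.pixel_index[hit])
    if not rows:
        raise ValueError("annotation has no training boxes")
    X = np.vstack(rows)
    y = np.array(labels)
    pix = np.vstack(pixels)
    ids = np.array([specimen_id] * len(y))
    return TrainingSet(X=X, y=y, specimen_ids=ids, pixels=pix)
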