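"""Polygon annotation handling for root-microscopy images.

Annotations arrive as VGG Image Annotator (VIA) exports, either the JSON
dialect or its CSV twin.  This module normalizes them into plain polygon
records, tiles large annotated images into fixed-size squares with clipped
sub-polygons, repairs self-intersecting rings, and rasterizes polygons to
pixel areas.

Conventions (raster semantics):

* pixel coordinates are 0-based; pixel ``(i, j)`` covers the unit square
  ``[i, i+1) x [j, j+1)`` and is counted when its center ``(i+0.5, j+0.5)``
  lies strictly inside the polygon interior;
* self-intersecting rings are interpreted with the even-odd fill rule and
  dissected into simple polygons.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import GeometryCollection, LineString, MultiPolygon, Point, Polygon, box
from shapely.ops import polygonize, unary_union

__all__ = [
    "CANONICAL_CLASSES",
    "PolygonShape",
    "AnnotatedImage",
    "TileSpec",
    "AnnotationParseError",
    "normalize_class_label",
    "parse_annotations",
    "tile_annotated_image",
    "repair_polygon",
    "rasterized_area",
    "rasterize_pixels",
    "circle_to_polygon",
    "split_dataset",
    "write_via_json",
    "write_polygon_summary",
]

#: The seven canonical annotation classes: plant root, the five AM fungal
#: structures, and a catch-all for non-AM objects.
CANONICAL_CLASSES = ("root", "arb", "exH", "inH", "ves", "sp", "other")

_CLASS_SYNONYMS = {
    "root": "root",
    "plant root": "root",
    "sorghum root": "root",
    "arb": "arb",
    "arbuscule": "arb",
    "amf arbuscule": "arb",
    "exh": "exH",
    "external hypha": "exH",
    "extraradical hypha": "exH",
    "amf external hypha": "exH",
    "inh": "inH",
    "internal hypha": "inH",
    "intraradical hypha": "inH",
    "amf internal hypha": "inH",
    "ves": "ves",
    "vesicle": "ves",
    "amf vesicle": "ves",
    "sp": "sp",
    "spore": "sp",
    "amf spore": "sp",
    "other": "other",
    "others": "other",
    "non-am": "other",
    "non am": "other",
}


class AnnotationParseError(ValueError):
    """Raised when an annotation export cannot be interpreted."""


def normalize_class_label(label: str) -> str:
    """Map a free-text class label onto the canonical seven-class vocabulary.

    Unknown labels are merged into ``"other"`` with a warning, mirroring the
    cleaning rule that rare classes are folded into the catch-all class.
    """
    key = str(label).strip().lower()
    if key in _CLASS_SYNONYMS:
        return _CLASS_SYNONYMS[key]
    warnings.warn(f"unknown class label {label!r} mapped to 'other'", stacklevel=2)
    return "other"


@dataclass(frozen=True)
class PolygonShape:
    """One annotated polygon: an ordered vertex ring plus a class label."""

    vertices: tuple[tuple[float, float], ...]
    class_label: str

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("a polygon needs at least 3 vertices")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.vertices, dtype=float)

    def to_shapely(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area(self) -> float:
        """Unsigned shoelace area (valid for simple rings)."""
        xy = self.array
        x, y = xy[:, 0], xy[:, 1]
        return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2.0)

    def is_simple(self) -> bool:
        return self.to_shapely().is_valid

    def translated(self, dx: float, dy: float) -> "PolygonShape":
        verts = tuple((x + dx, y + dy) for x, y in self.vertices)
        return replace(self, vertices=verts)


@dataclass
class AnnotatedImage:
    """An image identifier with its polygon annotations."""

    image_id: str
    width: int
    height: int
    shapes: list[PolygonShape] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("image dimensions must be positive")

    def clamped(self) -> "AnnotatedImage":
        """Clamp every vertex into ``[0, width] x [0, height]``."""
        out = []
        for s in self.shapes:
            xy = s.array
            xy[:, 0] = np.clip(xy[:, 0], 0.0, self.width)
            xy[:, 1] = np.clip(xy[:, 1], 0.0, self.height)
            out.append(replace(s, vertices=tuple(map(tuple, xy))))
        return AnnotatedImage(self.image_id, self.width, self.height, out)

    def total_area(self) -> float:
        return float(sum(s.to_shapely().area for s in self.shapes))


@dataclass(frozen=True)
class TileSpec:
    """Tiling parameters.

    ``tile_size``
        side length of the square tiles in pixels; boundary tiles are kept
        at reduced size (no padding).
    ``keep_empty``
        keep tiles that contain no annotation.
    ``min_image_side``
        images whose height or width is below this are skipped entirely
        (the filter applied to the prediction set).
    """

    tile_size: int = 512
    keep_empty: bool = False
    min_image_side: int = 100

    def __post_init__(self) -> None:
        if self.tile_size <= 0:
            raise ValueError("tile_size must be positive")
        if self.min_image_side < 0:
            raise ValueError("min_image_side must be >= 0")


# ---------------------------------------------------------------------------
# parsing


def circle_to_polygon(cx: float, cy: float, r: float, n_points: int = 64) -> tuple[tuple[float, float], ...]:
    """Resample a circle as an ``n_points``-gon (area -> pi r^2 as n grows)."""
    t = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    return tuple(zip(cx + r * np.cos(t), cy + r * np.sin(t)))


def _shape_from_attributes(attrs: dict, class_label: str, record_name: str) -> PolygonShape | None:
    """Convert one VIA ``shape_attributes`` dict to a polygon, or drop it.

    Polygons pass through; polylines are closed; circles are resampled;
    point/rect/ellipse shapes and empty segmentations are removed.
    """
    if not attrs:
        return None
    name = attrs.get("name")
    if name in ("polygon", "polyline"):
        xs = attrs.get("all_points_x") or []
        ys = attrs.get("all_points_y") or []
        if len(xs) != len(ys):
            raise AnnotationParseError(f"{record_name}: mismatched vertex arrays")
        verts = list(zip(map(float, xs), map(float, ys)))
        # drop consecutive duplicates and an explicitly closed last vertex
        dedup: list[tuple[float, float]] = []
        for v in verts:
            if not dedup or v != dedup[-1]:
                dedup.append(v)
        if len(dedup) > 1 and dedup[0] == dedup[-1]:
            dedup.pop()
        if len(dedup) < 3:
            return None
        return PolygonShape(tuple(dedup), class_label)
    if name == "circle":
        r = float(attrs.get("r", 0.0))
        if r <= 0:
            return None
        return PolygonShape(circle_to_polygon(float(attrs["cx"]), float(attrs["cy"]), r), class_label)
    # point, rect, ellipse, unknown -> removed by the cleaning rules
    return None


def _class_from_region_attributes(rattrs: dict) -> str:
    if not rattrs:
        return "other"
    for key in ("class", "label", "type", "name"):
        if key in rattrs and rattrs[key] not in (None, ""):
            val = rattrs[key]
            if isinstance(val, dict):  # VIA checkbox attribute
                val = next(iter(val), "other")
            return normalize_class_label(val)
    val = next(iter(rattrs.values()))
    if isinstance(val, dict):
        val = next(iter(val), "other")
    return normalize_class_label(val)


def _infer_size(shapes: Sequence[PolygonShape]) -> tuple[int, int]:
    if not shapes:
        return 1, 1
    allxy = np.vstack([s.array for s in shapes])
    w = int(np.ceil(allxy[:, 0].max())) or 1
    h = int(np.ceil(allxy[:, 1].max())) or 1
    return max(w, 1), max(h, 1)


def parse_annotations(
    path: str | Path,
    image_sizes: dict[str, tuple[int, int]] | None = None,
) -> list[AnnotatedImage]:
    """Parse a VIA JSON export or its CSV twin into :class:`AnnotatedImage`.

    ``image_sizes`` optionally maps filename -> (width, height); VIA exports
    do not carry pixel dimensions, so when absent the size is inferred from
    the annotation extent (sufficient for geometry-only processing).

    Point, rectangle and ellipse shapes are removed; polylines and circles
    are converted to polygons; empty segmentations are dropped; class labels
    are normalized to the canonical vocabulary with unknown labels merged
    into ``"other"``.
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationParseError(f"annotation file not found: {path}")
    if path.suffix.lower() == ".csv":
        per_image = _parse_via_csv(path)
    else:
        per_image = _parse_via_json(path)

    images = []
    for fname, shapes in per_image.items():
        if image_sizes and fname in image_sizes:
            w, h = image_sizes[fname]
        else:
            w, h = _infer_size(shapes)
        images.append(AnnotatedImage(fname, w, h, shapes).clamped())
    return images


def _parse_via_json(path: Path) -> dict[str, list[PolygonShape]]:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationParseError(f"{path}: not valid JSON ({exc})") from exc
    if "_via_img_metadata" in payload:  # full VIA project file
        payload = payload["_via_img_metadata"]
    per_image: dict[str, list[PolygonShape]] = {}
    for key, entry in payload.items():
        if not isinstance(entry, dict) or "regions" not in entry:
            raise AnnotationParseError(f"{path}: record {key!r} lacks a 'regions' field")
        fname = entry.get("filename", key)
        regions = entry["regions"]
        if isinstance(regions, dict):  # old VIA versions index regions by id
            regions = list(regions.values())
        shapes = per_image.setdefault(fname, [])
        for i, region in enumerate(regions):
            label = _class_from_region_attributes(region.get("region_attributes", {}))
            shape = _shape_from_attributes(region.get("shape_attributes", {}), label, f"{fname}[{i}]")
            if shape is not None:
                shapes.append(shape)
    return per_image


def _parse_via_csv(path: Path) -> dict[str, list[PolygonShape]]:
    per_image: dict[str, list[PolygonShape]] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "region_shape_attributes" not in reader.fieldnames:
            raise AnnotationParseError(f"{path}: missing 'region_shape_attributes' column")
        for i, row in enumerate(reader):
            fname = row.get("filename") or row.get("#filename") or f"row{i}"
            shapes = per_image.setdefault(fname, [])
            raw = row.get("region_shape_attributes", "") or "{}"
            try:
                attrs = json.loads(raw)
                rattrs = json.loads(row.get("region_attributes", "") or "{}")
            except json.JSONDecodeError as exc:
                raise AnnotationParseError(f"{path}: row {i} ({fname}): bad JSON field ({exc})") from exc
            label = _class_from_region_attributes(rattrs)
            shape = _shape_from_attributes(attrs, label, f"{fname}[row {i}]")
            if shape is not None:
                shapes.append(shape)
    return per_image


# ---------------------------------------------------------------------------
# geometry


def _polygonal_parts(geom) -> list[Polygon]:
    """Extract positive-area polygonal parts, discarding points and lines."""
    if geom.is_empty:
        return []
    if isinstance(geom, Polygon):
        return [geom] if geom.area > 0 else []
    if isinstance(geom, (MultiPolygon, GeometryCollection)):
        out: list[Polygon] = []
        for part in geom.geoms:
            out.extend(_polygonal_parts(part))
        return out
    return []  # Point / LineString / Multi* of those


def _shape_from_polygon(poly: Polygon, class_label: str) -> PolygonShape:
    verts = tuple(poly.exterior.coords)[:-1]
    return PolygonShape(tuple((float(x), float(y)) for x, y in verts), class_label)


def repair_polygon(shape: PolygonShape) -> list[PolygonShape]:
    """Dissect a (possibly self-intersecting) ring into simple polygons.

    The interior is interpreted with the even-odd fill rule: the ring's
    edges are noded, the arrangement is polygonized, and faces whose
    representative point has odd crossing parity with respect to the
    original ring are kept.  A bowtie therefore becomes its two triangles;
    an already-simple polygon is returned unchanged.  All-collinear input
    yields an empty list.
    """
    poly = shape.to_shapely()
    if poly.is_valid and poly.area > 0:
        return [shape]
    ring = LineString(list(shape.vertices) + [shape.vertices[0]])
    faces = list(polygonize(unary_union(ring)))
    kept = []
    for face in faces:
        p = face.representative_point()
        if _even_odd_inside(shape.array, p.x, p.y):
            kept.append(_shape_from_polygon(face, shape.class_label))
    return kept


def _even_odd_inside(ring: np.ndarray, px: float, py: float) -> bool:
    """Crossing-number (even-odd) point-in-ring test."""
    x, y = ring[:, 0], ring[:, 1]
    x2, y2 = np.roll(x, -1), np.roll(y, -1)
    cond = (y > py) != (y2 > py)
    with np.errstate(divide="ignore", invalid="ignore"):
        xint = x + (py - y) * (x2 - x) / (y2 - y)
    return bool(np.sum(cond & (px < xint)) % 2)


def tile_annotated_image(img: AnnotatedImage, spec: TileSpec = TileSpec()) -> list[AnnotatedImage]:
    """Tile an annotated image into ``tile_size`` squares with clipped polygons.

    Boundary tiles are smaller; each output polygon is the intersection of
    an input polygon with its tile, re-indexed to tile-local coordinates.
    Intersections that degenerate to points or line segments are discarded,
    multi-part intersections are emitted as separate records, and tiles
    without annotations are dropped unless ``spec.keep_empty``.
    """
    if min(img.width, img.height) < spec.min_image_side:
        return []
    ts = spec.tile_size
    geoms = [(shapely.make_valid(s.to_shapely()), s.class_label) for s in img.shapes]
    tiles: list[AnnotatedImage] = []
    for ty in range(0, img.height, ts):
        for tx in range(0, img.width, ts):
            w = min(ts, img.width - tx)
            h = min(ts, img.height - ty)
            window = box(tx, ty, tx + w, ty + h)
            clipped: list[PolygonShape] = []
            for geom, label in geoms:
                inter = geom.intersection(window)
                for part in _polygonal_parts(inter):
                    clipped.append(_shape_from_polygon(part, label).translated(-tx, -ty))
            if clipped or spec.keep_empty:
                tile_id = f"{img.image_id}_x{tx}_y{ty}"
                tiles.append(AnnotatedImage(tile_id, w, h, clipped))
    return tiles


def rasterize_pixels(shape: PolygonShape, width: int, height: int) -> np.ndarray:
    """Integer coordinates of pixels whose centers fall inside the polygon.

    Returns an ``(n, 2)`` array of ``(x, y)`` pixel indices within the
    ``width x height`` raster.  Deterministic pixel-center semantics; a
    polygon entirely outside the raster yields an empty array.
    """
    if width <= 0 or height <= 0:
        raise ValueError("raster dimensions must be positive")
    poly = shape.to_shapely()
    minx, miny, maxx, maxy = poly.bounds
    x0 = max(0, int(np.floor(minx - 0.5)))
    y0 = max(0, int(np.floor(miny - 0.5)))
    x1 = min(width - 1, int(np.ceil(maxx)))
    y1 = min(height - 1, int(np.ceil(maxy)))
    if x1 < x0 or y1 < y0:
        return np.empty((0, 2), dtype=int)
    xs = np.arange(x0, x1 + 1)
    ys = np.arange(y0, y1 + 1)
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(poly, gx.ravel() + 0.5, gy.ravel() + 0.5)
    pts = np.column_stack([gx.ravel()[inside], gy.ravel()[inside]])
    return pts


def rasterized_area(shape: PolygonShape, width: int, height: int) -> int:
    """Number of in-raster pixel centers inside the polygon interior."""
    return int(len(rasterize_pixels(shape, width, height)))


# ---------------------------------------------------------------------------
# utilities and writers


def split_dataset(
    items: Sequence, ratios: tuple[int, int, int] = (8, 1, 1), seed: int = 0
) -> tuple[list, list, list]:
    """Deterministic seeded train/validation/test partition (default 8:1:1)."""
    if any(r < 0 for r in ratios) or sum(ratios) == 0:
        raise ValueError("ratios must be non-negative and not all zero")
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(items))
    n = len(items)
    n_train = int(round(n * ratios[0] / sum(ratios)))
    n_val = int(round(n * ratios[1] / sum(ratios)))
    take = lambda ix: [items[i] for i in ix]
    return (
        take(sorted(idx[:n_train])),
        take(sorted(idx[n_train : n_train + n_val])),
        take(sorted(idx[n_train + n_val :])),
    )


def write_via_json(images: Iterable[AnnotatedImage], path: str | Path) -> None:
    """Write annotations back out in the VIA JSON dialect."""
    payload = {}
    for img in images:
        regions = []
        for s in img.shapes:
            xy = s.array
            regions.append(
                {
                    "shape_attributes": {
                        "name": "polygon",
                        "all_points_x": [float(v) for v in xy[:, 0]],
                        "all_points_y": [float(v) for v in xy[:, 1]],
                    },
                    "region_attributes": {"class": s.class_label},
                }
            )
        payload[img.image_id] = {
            "filename": img.image_id,
            "size": -1,
            "regions": regions,
            "file_attributes": {"width": img.width, "height": img.height},
        }
    Path(path).write_text(json.dumps(payload))


def write_polygon_summary(images: Iterable[AnnotatedImage], path: str | Path) -> None:
    """Per-image class counts and polygon areas as tab-delimited text."""
    with Path(path).open("w") as fh:
        fh.write("image_id\tclass_label\tn_polygons\ttotal_area\n")
        for img in images:
            per: dict[str, list[float]] = {}
            for s in img.shapes:
                per.setdefault(s.class_label, []).append(s.to_shapely().area)
            for label in CANONICAL_CLASSES:
                if label in per:
                    fh.write(f"{img.image_id}\t{label}\t{len(per[label])}\t{sum(per[label]):.6f}\n")
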