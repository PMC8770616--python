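"""Polygon annotations and label maps.

Reads ASAP-dialect annotation XML, rasterizes polygons into integer label
maps, derives the epithelial border class, and round-trips label maps to
single-channel PNG/TIFF with a JSON sidecar carrying the class table and
pixel resolution.

Raster conventions (fixed so that tests are exact): origin at the top-left,
x is the column index, pixel (row, col) is represented by its center point
(col + 0.5, row + 0.5), and image coordinates are half-open ``[0, extent)``.
A pixel belongs to a polygon when its center lies inside the polygon.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from lxml import etree
from scipy import ndimage
from shapely.geometry import Polygon as _ShapelyPolygon

from . import classes as C

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationPolygon",
    "LabelMap",
    "read_annotations",
    "rasterize",
    "build_border_class",
    "read_label_map",
    "write_label_map",
]


@dataclass(frozen=True)
class AnnotationPolygon:
    """A closed annotation polygon in pixel coordinates.

    ``class_name`` is one of the six annotatable tissue types; the first
    vertex implicitly follows the last.
    """

    class_name: str
    vertices: tuple[tuple[float, float], ...]
    group: str | None = None

    def __post_init__(self) -> None:
        if self.class_name not in C.NAME_TO_CODE or self.class_name in (
            "background",
            "border",
        ):
            raise ValueError(f"not an annotatable tissue class: {self.class_name!r}")
        if len(self.vertices) < 3:
            raise ValueError(
                f"polygon needs >= 3 vertices, got {len(self.vertices)}"
            )

    @property
    def code(self) -> int:
        return C.NAME_TO_CODE[self.class_name]


@dataclass
class LabelMap:
    """Integer-coded per-pixel tissue classes plus physical resolution.

    ``codes`` is a (height, width) uint8 array with values from the class
    table; ``resolution`` is micrometers per pixel.
    """

    codes: np.ndarray
    resolution: float = 0.495

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("label map must be 2-D")
        if self.resolution <= 0:
            raise ValueError("resolution must be positive (um/px)")
        bad = set(np.unique(self.codes)) - set(C.ALL_CODES)
        if bad:
            raise ValueError(f"codes outside class table: {sorted(bad)}")
        self.codes = self.codes.astype(np.uint8, copy=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.codes.shape  # type: ignore[return-value]

    def class_pixel_counts(self) -> dict[int, int]:
        counts = np.bincount(self.codes.ravel(), minlength=8)
        return {code: int(counts[code]) for code in C.ALL_CODES}

    def copy(self) -> "LabelMap":
        return LabelMap(self.codes.copy(), self.resolution)


# ---------------------------------------------------------------------------
# ASAP XML reading
# ---------------------------------------------------------------------------

def _canonical_class(raw: str, aliases: dict[str, str] | None) -> str:
    name = raw.strip().lower().replace("-", "_")
    table = dict(C.DEFAULT_ALIASES)
    if aliases:
        table.update({k.strip().lower(): v for k, v in aliases.items()})
    name = table.get(name, name)
    name = name.replace(" ", "_")
    if name not in C.NAME_TO_CODE or name in ("background", "border"):
        raise ValueError(
            f"unknown annotation class {raw!r} (no alias maps it to one of "
            f"{sorted(n for n in C.NAME_TO_CODE if n not in ('background', 'border'))})"
        )
    return name


def read_annotations(
    path: str | Path, aliases: dict[str, str] | None = None
) -> list[AnnotationPolygon]:
    """Read an ASAP-dialect annotation XML file.

    Expects ``Annotations/Annotation/Coordinates/Coordinate`` elements with
    ``Order``, ``X`` and ``Y`` attributes. Class names are taken from the
    Annotation ``PartOfGroup`` attribute when it names a tissue class,
    otherwise from ``Name``; matching is case-insensitive and goes through
    the alias table. An empty document yields an empty list.
    """
    path = Path(path)
    tree = etree.parse(str(path))
    polygons: list[AnnotationPolygon] = []
    for idx, ann in enumerate(tree.iter("Annotation")):
        raw_group = ann.get("PartOfGroup") or ""
        raw_name = ann.get("Name") or ""
        raw_class = raw_group if raw_group.lower() not in ("", "none") else raw_name
        class_name = _canonical_class(raw_class, aliases)
        coords = []
        for coord in ann.iter("Coordinate"):
            try:
                order = int(float(coord.get("Order")))
                x = float(coord.get("X"))
                y = float(coord.get("Y"))
            except (TypeError, ValueError) as exc:
                raise ValueError(
                    f"malformed coordinate in annotation element {idx}"
                ) from exc
            coords.append((order, x, y))
        coords.sort(key=lambda t: t[0])
        vertices = tuple((x, y) for _, x, y in coords)
        group = ann.get("PartOfGroup") if raw_group.lower() not in ("", "none") else None
        polygons.append(
            AnnotationPolygon(class_name=class_name, vertices=vertices, group=group)
        )
    return polygons


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

#: Painting priority; polygons are rendered lowest priority first so that
#: epithelium always overwrites stroma and lumen overwrites both, regardless
#: of annotation order (acini are drawn as epithelium outlines containing
#: their lumens). Classes of equal priority keep annotation order.
_PRIORITY = {
    C.INTRALOBULAR_STROMA: 0,
    C.EXTRALOBULAR_STROMA: 0,
    C.ADIPOSE: 0,
    C.VESSEL: 0,
    C.EPITHELIUM: 1,
    C.LUMEN: 2,
}


def _polygon_mask(
    poly: AnnotationPolygon, height: int, width: int
) -> tuple[slice, slice, np.ndarray] | None:
    """Boolean mask of pixels whose centers fall inside ``poly``.

    Returns (row slice, col slice, mask) restricted to the polygon's
    bounding box, or None when the polygon misses the canvas entirely.
    """
    shp = _ShapelyPolygon(poly.vertices)
    if not shp.is_valid:
        shp = shp.buffer(0)
    minx, miny, maxx, maxy = shp.bounds
    c0 = max(int(math.floor(minx - 0.5)), 0)
    r0 = max(int(math.floor(miny - 0.5)), 0)
    c1 = min(int(math.ceil(maxx + 0.5)), width)
    r1 = min(int(math.ceil(maxy + 0.5)), height)
    if c0 >= c1 or r0 >= r1:
        return None
    cols = np.arange(c0, c1) + 0.5
    rows = np.arange(r0, r1) + 0.5
    xx, yy = np.meshgrid(cols, rows)
    mask = shapely.contains_xy(shp, xx.ravel(), yy.ravel()).reshape(yy.shape)
    return slice(r0, r1), slice(c0, c1), mask


def rasterize(
    polygons: list[AnnotationPolygon],
    extent: tuple[int, int],
    resolution: float = 0.495,
) -> LabelMap:
    """Rasterize annotation polygons into a label map.

    ``extent`` is (height, width). Later polygons overwrite earlier ones,
    except that epithelium always overwrites stroma and lumen overwrites
    everything below it (nesting order stroma < epithelium < lumen).
    Unannotated pixels stay 0; polygons extending past the canvas are
    clipped with a warning.
    """
    height, width = extent
    codes = np.zeros((height, width), dtype=np.uint8)
    ordered = sorted(
        enumerate(polygons), key=lambda t: (_PRIORITY[t[1].code], t[0])
    )
    for idx, poly in ordered:
        xs = [v[0] for v in poly.vertices]
        ys = [v[1] for v in poly.vertices]
        if min(xs) < 0 or min(ys) < 0 or max(xs) > width or max(ys) > height:
            logger.warning(
                "polygon %d (%s) extends outside extent %s; clipping",
                idx,
                poly.class_name,
                extent,
            )
        located = _polygon_mask(poly, height, width)
        if located is None:
            continue
        rsl, csl, mask = located
        codes[rsl, csl][mask] = poly.code
    return LabelMap(codes, resolution)


# ---------------------------------------------------------------------------
# Border class
# ---------------------------------------------------------------------------

def build_border_class(label_map: LabelMap, width_px: int = 3) -> LabelMap:
    """Recode the inner perimeter of epithelial components to border (7).

    The border is carved inward from each epithelium component boundary to a
    depth of ``width_px`` pixels (4-connected erosion per step), so
    epithelium + border pixel counts are conserved and no other class is
    touched. Pixels at the image edge are treated as continuing epithelium
    (the canvas edge is not a tissue boundary). At the default 3 px and
    0.495 um/px the border is ~1.5 um wide.
    """
    if width_px < 1:
        raise ValueError("width_px must be >= 1")
    epi = label_map.codes == C.EPITHELIUM
    if not epi.any():
        raise ValueError("label map contains no epithelium pixels")
    # erode the epithelium-or-border footprint, so a map that already has
    # its border carved is left unchanged (idempotence)
    footprint = epi | (label_map.codes == C.BORDER)
    interior = ndimage.binary_erosion(
        footprint,
        structure=ndimage.generate_binary_structure(2, 1),
        iterations=width_px,
        border_value=1,
    )
    out = label_map.codes.copy()
    out[epi & ~interior] = C.BORDER
    return LabelMap(out, label_map.resolution)


def border_width_um(width_px: int = 3, resolution: float = 0.495) -> float:
    """Physical border width in micrometers (3 px at 0.495 um/px -> 1.5 um)."""
    return width_px * resolution


# ---------------------------------------------------------------------------
# Label-map I/O
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_label_map(label_map: LabelMap, path: str | Path) -> None:
    """Write a label map as a single-channel PNG/TIFF plus JSON sidecar."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), label_map.codes)
    else:
        from PIL import Image

        Image.fromarray(label_map.codes, mode="L").save(str(path))
    sidecar = {
        "resolution_um_per_px": label_map.resolution,
        "classes": {str(k): v for k, v in C.CLASS_NAMES.items()},
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_label_map(path: str | Path) -> LabelMap:
    """Read a label map written by :func:`write_label_map` (lossless)."""
    path = Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"empty label-map file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        codes = tifffile.imread(str(path))
    else:
        from PIL import Image

        codes = np.asarray(Image.open(str(path)))
    resolution = 0.495
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        resolution = float(meta.get("resolution_um_per_px", resolution))
    bad = set(np.unique(codes)) - set(C.ALL_CODES)
    if bad:
        counts = {int(b): int((codes == b).sum()) for b in sorted(bad)}
        raise ValueError(f"label map {path} has out-of-table codes: {counts}")
    return LabelMap(codes, resolution)
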