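"""Annotation and image formats for corneal confocal (IVCM) analysis.

Supports the two annotation formats used when grading subbasal nerve images:

* **NeuronJ ``.ndf`` tracings** — plain-text files storing the polylines an
  observer drew along nerve fibers. We support a minimal dialect: a version
  header, optional further ``//`` header lines (preserved verbatim on
  round-trip), one ``// Tracing`` block per polyline with one coordinate per
  line alternating x and y, and an optional trailer.
* **Labelme-style JSON polygons** — dendritic cell outlines with two classes,
  cells *with* dendrites and cells *without* dendrites.

Both can be rasterized into training masks: nerve tracings as 4-px-wide
strokes on a binary mask, cell polygons as a 3-channel one-hot mask
(background / with dendrites / without dendrites).

Coordinate convention (used everywhere in this package): x = column,
y = row, origin at the top-left pixel centre, 0-based. Pixel (r, c) has its
centre at (x=c, y=r).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile
from PIL import Image

from .units import DEFAULT_PIXEL_PITCH_UM

__all__ = [
    "Eye",
    "CellClass",
    "ImageRecord",
    "NerveTracing",
    "CellAnnotation",
    "SegmentationMask",
    "NdfFormatError",
    "NdfBlockError",
    "LabelmeFormatError",
    "ImageFormatError",
    "parse_ndf",
    "write_ndf",
    "parse_labelme",
    "rasterize_nerve_mask",
    "rasterize_dc_mask",
    "read_image",
    "write_image",
]


class Eye(str, Enum):
    """Laterality, following the clinical OS (left) / OD (right) folder names."""

    OS = "OS"
    OD = "OD"


class CellClass(str, Enum):
    """Dendritic cell morphology classes.

    ``WITH_DENDRITES`` cells show radiating processes (higher immunological
    activity); ``WITHOUT_DENDRITES`` cells are compact ovoid bodies.
    """

    WITH_DENDRITES = "with_dendrites"
    WITHOUT_DENDRITES = "without_dendrites"


DEFAULT_LABEL_MAP: dict[str, CellClass] = {
    "1": CellClass.WITH_DENDRITES,
    "with": CellClass.WITH_DENDRITES,
    "with_dendrites": CellClass.WITH_DENDRITES,
    "2": CellClass.WITHOUT_DENDRITES,
    "without": CellClass.WITHOUT_DENDRITES,
    "without_dendrites": CellClass.WITHOUT_DENDRITES,
}


class NdfFormatError(ValueError):
    """Malformed NDF file (bad header, empty file)."""


class NdfBlockError(NdfFormatError):
    """Malformed tracing block (odd coordinate count, too few points)."""


class LabelmeFormatError(ValueError):
    """Malformed Labelme-style JSON document."""


class ImageFormatError(ValueError):
    """Image is not 8-bit single-channel grayscale."""


@dataclass
class ImageRecord:
    """One 8-bit grayscale IVCM frame plus its acquisition metadata."""

    pixels: np.ndarray
    subject_id: str = ""
    eye: Eye | None = None
    image_id: str = ""
    pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ImageFormatError("image pixels must be a 2-D array")
        if self.pixels.dtype != np.uint8:
            raise ImageFormatError(
                f"image pixels must be 8-bit (uint8), got {self.pixels.dtype}"
            )
        if self.pixel_pitch_um <= 0:
            raise ValueError("pixel_pitch_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class NerveTracing:
    """Ordered nerve-fiber polylines for one image, in pixel coordinates.

    Each polyline is an (n, 2) float array of (x, y) points, n >= 2. Points
    may lie anywhere in the closed box [0, width] x [0, height]; endpoints on
    the far edge are allowed so a full-height fiber can span exactly
    ``height`` pixels of arc length.
    """

    polylines: list[np.ndarray]
    image_shape: tuple[int, int] = (384, 384)
    header_lines: list[str] = field(default_factory=list)
    trailer_lines: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        h, w = self.image_shape
        cleaned = []
        for i, poly in enumerate(self.polylines):
            arr = np.asarray(poly, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
                raise ValueError(f"polyline {i} must be an (n>=2, 2) array of points")
            if (arr[:, 0].min() < 0 or arr[:, 0].max() > w
                    or arr[:, 1].min() < 0 or arr[:, 1].max() > h):
                raise ValueError(
                    f"polyline {i} has points outside [0, {w}] x [0, {h}]"
                )
            cleaned.append(arr)
        self.polylines = cleaned

    def arc_length_px(self) -> float:
        """Total analytic polyline arc length in pixels."""
        total = 0.0
        for poly in self.polylines:
            total += float(np.sum(np.hypot(*np.diff(poly, axis=0).T)))
        return total


@dataclass
class CellAnnotation:
    """Labelled dendritic-cell polygons for one image."""

    polygons: list[tuple[np.ndarray, CellClass]]
    image_shape: tuple[int, int] = (384, 384)

    def __post_init__(self) -> None:
        cleaned = []
        for i, (verts, label) in enumerate(self.polygons):
            arr = np.asarray(verts, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
                raise ValueError(f"polygon {i} must have >= 3 vertices")
            cleaned.append((arr, CellClass(label)))
        self.polygons = cleaned

    def class_counts(self) -> tuple[int, int]:
        """(n_with_dendrites, n_without_dendrites)."""
        n_with = sum(1 for _, c in self.polygons if c is CellClass.WITH_DENDRITES)
        return n_with, len(self.polygons) - n_with


class MaskKind(str, Enum):
    NERVE_BINARY = "nerve_binary"
    DC_ONEHOT = "dc_onehot"


@dataclass
class SegmentationMask:
    """Binary nerve mask or 3-channel one-hot dendritic-cell mask.

    For ``dc_onehot`` the channels are (0) background, (1) cells with
    dendrites, (2) cells without dendrites, and exactly one channel is 1 at
    every pixel.
    """

    kind: MaskKind
    data: np.ndarray

    def __post_init__(self) -> None:
        self.kind = MaskKind(self.kind)
        self.data = np.asarray(self.data, dtype=np.uint8)
        if self.kind is MaskKind.NERVE_BINARY:
            if self.data.ndim != 2:
                raise ValueError("nerve_binary mask must be 2-D")
            if not np.isin(self.data, (0, 1)).all():
                raise ValueError("nerve_binary mask values must be 0 or 1")
        else:
            if self.data.ndim != 3 or self.data.shape[0] != 3:
                raise ValueError("dc_onehot mask must have shape (3, H, W)")
            if not (self.data.sum(axis=0) == 1).all():
                raise ValueError("dc_onehot mask must be one-hot at every pixel")

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.data.shape[-2:]  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# NeuronJ NDF tracings
# ---------------------------------------------------------------------------

_NDF_MAGIC = "// NeuronJ Data File"
_TRACING_PREFIX = "// Tracing"


def _format_coord(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def parse_ndf(ndf_text: str, image_shape: tuple[int, int] = (384, 384)) -> NerveTracing:
    """Parse a NeuronJ ``.ndf`` tracing file (minimal dialect).

    One polyline per ``// Tracing`` block; point order is preserved.
    Unrecognized ``//`` lines before the first block and after the last are
    preserved so that :func:`write_ndf` round-trips the file bit-identically.
    """
    lines = ndf_text.splitlines()
    if not any(line.strip() for line in lines):
        raise NdfFormatError("empty NDF file")
    first = lines[0].rstrip("\n")
    if not first.startswith(_NDF_MAGIC):
        raise NdfFormatError(
            f"line 1: expected header starting with {_NDF_MAGIC!r}, got {first!r}"
        )

    header: list[str] = [first]
    trailer: list[str] = []
    blocks: list[list[float]] = []
    current: list[float] | None = None
    for lineno, raw in enumerate(lines[1:], start=2):
        line = raw.rstrip()
        if not line:
            continue
        if line.startswith(_TRACING_PREFIX):
            current = []
            blocks.append(current)
        elif line.startswith("//"):
            if current is None:
                header.append(line)
            else:
                trailer.append(line)
                current = None
        else:
            if current is None:
                raise NdfFormatError(
                    f"line {lineno}: coordinate outside a tracing block"
                )
            try:
                current.append(float(line))
            except ValueError as exc:
                raise NdfFormatError(f"line {lineno}: not a coordinate: {line!r}") from exc

    polylines = []
    for i, coords in enumerate(blocks):
        if len(coords) % 2:
            raise NdfBlockError(f"tracing block {i}: odd coordinate count ({len(coords)})")
        if len(coords) < 4:
            raise NdfBlockError(f"tracing block {i}: fewer than 2 points")
        polylines.append(np.asarray(coords, dtype=float).reshape(-1, 2))
    return NerveTracing(
        polylines=polylines,
        image_shape=image_shape,
        header_lines=header,
        trailer_lines=trailer,
    )


def write_ndf(tracing: NerveTracing) -> str:
    """Serialize a tracing back to NDF text (inverse of :func:`parse_ndf`)."""
    header = tracing.header_lines or [_NDF_MAGIC + " - v1.4.0"]
    trailer = tracing.trailer_lines or ["// End of NeuronJ Data File"]
    out = list(header)
    for i, poly in enumerate(tracing.polylines, start=1):
        out.append(f"{_TRACING_PREFIX} N{i}")
        for x, y in poly:
            out.append(_format_coord(x))
            out.append(_format_coord(y))
    out.extend(trailer)
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Labelme polygons
# ---------------------------------------------------------------------------

def parse_labelme(
    json_text: str,
    label_map: Mapping[str, CellClass] | None = None,
    image_shape: tuple[int, int] | None = None,
) -> CellAnnotation:
    """Parse a Labelme-style JSON document into a :class:`CellAnnotation`.

    ``label_map`` maps the file's label strings onto the two cell classes;
    the default accepts "1"/"with"/"with_dendrites" and
    "2"/"without"/"without_dendrites". Shapes with fewer than 3 vertices are
    rejected; an empty shape list is valid (images may contain no cells).
    """
    label_map = dict(DEFAULT_LABEL_MAP if label_map is None else label_map)
    try:
        doc = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise LabelmeFormatError(f"invalid JSON: {exc}") from exc
    if not isinstance(doc, dict) or "shapes" not in doc:
        raise LabelmeFormatError("document has no 'shapes' list")
    shapes = doc["shapes"]
    if not isinstance(shapes, list):
        raise LabelmeFormatError("'shapes' is not a list")

    if image_shape is None:
        h = int(doc.get("imageHeight", 384))
        w = int(doc.get("imageWidth", 384))
        image_shape = (h, w)

    polygons: list[tuple[np.ndarray, CellClass]] = []
    for i, shape in enumerate(shapes):
        label = str(shape.get("label", ""))
        if label not in label_map:
            raise LabelmeFormatError(
                f"shape {i}: unknown label {label!r}; permitted: {sorted(label_map)}"
            )
        pts = np.asarray(shape.get("points", []), dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 3 or pts.shape[1] != 2:
            raise LabelmeFormatError(f"shape {i}: polygon needs >= 3 vertices")
        polygons.append((pts, label_map[label]))
    return CellAnnotation(polygons=polygons, image_shape=image_shape)


def write_labelme(annotation: CellAnnotation) -> str:
    """Serialize a :class:`CellAnnotation` as Labelme-style JSON."""
    h, w = annotation.image_shape
    shapes = [
        {
            "label": label.value,
            "points": [[float(x), float(y)] for x, y in verts],
            "shape_type": "polygon",
        }
        for verts, label in annotation.polygons
    ]
    return json.dumps(
        {"shapes": shapes, "imageHeight": h, "imageWidth": w}, indent=2
    )


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def _stroke_segment(mask: np.ndarray, p0: np.ndarray, p1: np.ndarray, half_w: float) -> None:
    """Mark pixels whose centre lies in the stroke band of one segment.

    The band is half-open across the stroke (normal offset in [-w/2, w/2))
    and closed along it (tangential extent [0, L], butt caps), so a width-4
    stroke through integer coordinates covers exactly 4 rows/columns.
    """
    h, w = mask.shape
    v = p1 - p0
    length = float(np.hypot(*v))
    if length == 0.0:
        return
    lo = np.floor(np.minimum(p0, p1) - half_w).astype(int)
    hi = np.ceil(np.maximum(p0, p1) + half_w).astype(int)
    x0, y0 = np.maximum(lo, 0)
    x1 = min(hi[0], w - 1)
    y1 = min(hi[1], h - 1)
    if x1 < x0 or y1 < y0:
        return
    xs = np.arange(x0, x1 + 1, dtype=float)
    ys = np.arange(y0, y1 + 1, dtype=float)
    gx, gy = np.meshgrid(xs, ys)
    rx, ry = gx - p0[0], gy - p0[1]
    t = (rx * v[0] + ry * v[1]) / length
    d = (v[0] * ry - v[1] * rx) / length
    inside = (t >= 0.0) & (t <= length) & (d >= -half_w) & (d < half_w)
    mask[y0:y1 + 1, x0:x1 + 1] |= inside


def _stamp_disk(mask: np.ndarray, centre: np.ndarray, half_w: float) -> None:
    """Round joint at an interior vertex: half-open disk d < w/2."""
    h, w = mask.shape
    x0 = max(int(np.floor(centre[0] - half_w)), 0)
    x1 = min(int(np.ceil(centre[0] + half_w)), w - 1)
    y0 = max(int(np.floor(centre[1] - half_w)), 0)
    y1 = min(int(np.ceil(centre[1] + half_w)), h - 1)
    if x1 < x0 or y1 < y0:
        return
    gx, gy = np.meshgrid(np.arange(x0, x1 + 1, dtype=float),
                         np.arange(y0, y1 + 1, dtype=float))
    inside = np.hypot(gx - centre[0], gy - centre[1]) < half_w
    mask[y0:y1 + 1, x0:x1 + 1] |= inside


def rasterize_nerve_mask(tracing: NerveTracing, line_width_px: int = 4) -> SegmentationMask:
    """Draw nerve polylines as strokes of the given width on a binary mask.

    Each polyline is stroked with butt caps at its ends and round joints at
    interior vertices; overlapping strokes merge (union). The default width
    of 4 px resembles the apparent thickness of subbasal nerve fibers.
    """
    if line_width_px < 1:
        raise ValueError("line_width_px must be >= 1")
    h, w = tracing.image_shape
    mask = np.zeros((h, w), dtype=bool)
    half_w = line_width_px / 2.0
    for poly in tracing.polylines:
        for i in range(len(poly) - 1):
            _stroke_segment(mask, poly[i], poly[i + 1], half_w)
        for vert in poly[1:-1]:
            _stamp_disk(mask, vert, half_w)
    return SegmentationMask(MaskKind.NERVE_BINARY, mask.astype(np.uint8))


def fill_polygon(vertices: np.ndarray, image_shape: tuple[int, int]) -> np.ndarray:
    """Even-odd polygon fill on pixel centres, half-open.

    A pixel centre (x, y) is inside when a ray towards +x crosses an odd
    number of edges; edges are treated half-open in y ([ymin, ymax)) and the
    crossing test is strict in x, so abutting polygons never double-cover a
    pixel and a square with corners (0,0)-(s,s) fills exactly s*s pixels.
    """
    h, w = image_shape
    out = np.zeros((h, w), dtype=bool)
    verts = np.asarray(vertices, dtype=float)
    n = len(verts)
    ymin = max(int(np.ceil(verts[:, 1].min())), 0)
    ymax = min(int(np.floor(verts[:, 1].max())), h - 1)
    for y in range(ymin, ymax + 1):
        crossings = []
        for i in range(n):
            x1, y1 = verts[i]
            x2, y2 = verts[(i + 1) % n]
            if (y1 <= y < y2) or (y2 <= y < y1):
                crossings.append(x1 + (y - y1) * (x2 - x1) / (y2 - y1))
        crossings.sort()
        for j in range(0, len(crossings) - 1, 2):
            a, b = crossings[j], crossings[j + 1]
            lo = max(int(np.ceil(a)), 0)
            hi = min(int(np.ceil(b)) - 1, w - 1)
            if hi >= lo:
                out[y, lo:hi + 1] = True
    return out


def rasterize_dc_mask(annotation: CellAnnotation) -> SegmentationMask:
    """Fill cell polygons into a 3-channel one-hot mask.

    Channel 1 holds cells with dendrites, channel 2 cells without; every
    remaining pixel is background (channel 0). Polygons are drawn in file
    order and the last-drawn class wins where polygons overlap.
    """
    h, w = annotation.image_shape
    labels = np.zeros((h, w), dtype=np.uint8)  # 0 = background
    for verts, cls in annotation.polygons:
        region = fill_polygon(verts, (h, w))
        labels[region] = 1 if cls is CellClass.WITH_DENDRITES else 2
    onehot = np.zeros((3, h, w), dtype=np.uint8)
    for ch in range(3):
        onehot[ch] = labels == ch
    return SegmentationMask(MaskKind.DC_ONEHOT, onehot)


# ---------------------------------------------------------------------------
# Image I/O
# ---------------------------------------------------------------------------

def _infer_subject_eye(path: Path) -> tuple[str, Eye | None]:
    parent = path.parent.name
    if parent in (Eye.OS.value, Eye.OD.value):
        return path.parent.parent.name, Eye(parent)
    return "", None


def read_image(path: str | Path, pixel_pitch_um: float = DEFAULT_PIXEL_PITCH_UM) -> ImageRecord:
    """Read an 8-bit grayscale TIFF or PNG into an :class:`ImageRecord`.

    Subject and eye are inferred from a ``subject/OS|OD/image`` folder
    layout when present. Non-8-bit or multi-channel input raises
    :class:`ImageFormatError` rather than being silently converted.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ImageFormatError(f"{path.name}: expected single-channel image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ImageFormatError(f"{path.name}: expected 8-bit image, got {arr.dtype}")
    subject, eye = _infer_subject_eye(path)
    return ImageRecord(
        pixels=arr,
        subject_id=subject,
        eye=eye,
        image_id=path.stem,
        pixel_pitch_um=pixel_pitch_um,
    )


def write_image(record: ImageRecord, path: str | Path) -> None:
    """Write an :class:`ImageRecord` losslessly as 8-bit TIFF or PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, record.pixels)
    else:
        Image.fromarray(record.pixels, mode="L").save(path)
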