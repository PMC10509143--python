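"""Sponge region-of-interest detection and PASCAL-VOC annotation I/O.

The detection stage isolates the sponge from the (color-contrasting)
background so that downstream feature extraction and CNN regression see
only sponge pixels. Here a deterministic color-distance detector fills the
role of a learned object detector: any callable satisfying the
``Detector`` contract (8-bit RGB image -> single :class:`BoundingBox`,
fully inside the frame) can be plugged into the pipeline in its place.

Coordinate convention everywhere in this package: 0-based, half-open,
row-major. VOC XML files (1-based, inclusive, x-before-y) are converted
at this module's boundary only.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from skimage import measure

__all__ = [
    "BoundingBox",
    "Annotation",
    "SpongeNotFoundError",
    "AnnotationError",
    "Detector",
    "detect_sponge_region",
    "crop",
    "read_annotation",
    "write_annotation",
]

#: Euclidean RGB distance (on the [0, 1] scale) above which a pixel is
#: considered foreground. 30/255 is generous for the synthetic scenes and
#: documented because the underlying study specifies nothing about
#: segmentation robustness.
DEFAULT_COLOR_THRESHOLD = 30.0 / 255.0

#: Connected components smaller than this fraction of the frame are
#: treated as noise and discarded before the bounding box is taken.
DEFAULT_MIN_AREA_FRACTION = 1e-3


class SpongeNotFoundError(ValueError):
    """No foreground pixels survive thresholding and denoising."""


class AnnotationError(ValueError):
    """A VOC XML file is malformed or encodes an invalid box."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned rectangle, 0-based, half-open: rows [row_start, row_end)."""

    row_start: int
    row_end: int
    col_start: int
    col_end: int

    def __post_init__(self) -> None:
        if not (self.row_start < self.row_end and self.col_start < self.col_end):
            raise ValueError(
                f"degenerate box: rows [{self.row_start},{self.row_end}), "
                f"cols [{self.col_start},{self.col_end})"
            )
        if self.row_start < 0 or self.col_start < 0:
            raise ValueError("box extends above/left of the frame origin")

    @property
    def height(self) -> int:
        return self.row_end - self.row_start

    @property
    def width(self) -> int:
        return self.col_end - self.col_start

    @property
    def area(self) -> int:
        return self.height * self.width

    def iou(self, other: "BoundingBox") -> float:
        """Intersection-over-union overlap with another box, in [0, 1]."""
        inter_h = min(self.row_end, other.row_end) - max(self.row_start, other.row_start)
        inter_w = min(self.col_end, other.col_end) - max(self.col_start, other.col_start)
        if inter_h <= 0 or inter_w <= 0:
            return 0.0
        inter = inter_h * inter_w
        return inter / (self.area + other.area - inter)

    def contains(self, other: "BoundingBox") -> bool:
        return (
            self.row_start <= other.row_start
            and other.row_end <= self.row_end
            and self.col_start <= other.col_start
            and other.col_end <= self.col_end
        )


@dataclass
class Annotation:
    """One image's bounding-box annotations, VOC-style.

    ``boxes`` is a list of ``(label, BoundingBox)`` pairs; ``image_size``
    (height, width) is optional metadata recorded in the XML when known.
    """

    image_filename: str
    boxes: list[tuple[str, BoundingBox]] = field(default_factory=list)
    image_size: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        for label, _ in self.boxes:
            if not label:
                raise ValueError("annotation labels must be non-empty strings")


Detector = Callable[[np.ndarray], BoundingBox]


def _as_rgb_array(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an HxWx3 RGB array, got shape {image.shape}")
    return image


def detect_sponge_region(
    image: np.ndarray,
    background_color: Sequence[float],
    *,
    threshold: float = DEFAULT_COLOR_THRESHOLD,
    min_area_fraction: float = DEFAULT_MIN_AREA_FRACTION,
) -> BoundingBox:
    """Tightest box around pixels that are not background-colored.

    Pixels whose Euclidean RGB distance to ``background_color`` (given on
    the [0, 1] scale) exceeds ``threshold`` are foreground; connected
    components smaller than ``min_area_fraction`` of the frame are removed
    as speckle before the box is taken.

    Raises
    ------
    SpongeNotFoundError
        If no foreground component survives.
    """
    image = _as_rgb_array(image)
    scaled = image.astype(np.float64) / 255.0 if image.dtype != np.float64 else image
    if scaled.max(initial=0.0) > 1.0:
        scaled = scaled / 255.0
    bg = np.asarray(background_color, dtype=np.float64).reshape(1, 1, 3)
    dist = np.sqrt(((scaled - bg) ** 2).sum(axis=2))
    fg = dist > threshold
    if not fg.any():
        raise SpongeNotFoundError("no sponge found: all pixels match the background color")

    labels = measure.label(fg, connectivity=2)
    min_area = min_area_fraction * fg.size
    keep = np.zeros_like(fg)
    for region in measure.regionprops(labels):
        if region.area >= min_area:
            keep[labels == region.label] = True
    if not keep.any():
        raise SpongeNotFoundError(
            "no sponge found: every foreground component is below the minimum area"
        )

    rows = np.flatnonzero(keep.any(axis=1))
    cols = np.flatnonzero(keep.any(axis=0))
    return BoundingBox(int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1)


def crop(image: np.ndarray, box: BoundingBox) -> np.ndarray:
    """Half-open sub-array of ``image`` under ``box``."""
    image = _as_rgb_array(image)
    h, w = image.shape[:2]
    if box.row_end > h or box.col_end > w:
        raise ValueError(f"box {box} exceeds the {h}x{w} frame")
    return image[box.row_start : box.row_end, box.col_start : box.col_end]


# ---------------------------------------------------------------------------
# VOC XML annotation I/O (LabelImg dialect: 1-based, inclusive bndbox coords)
# ---------------------------------------------------------------------------


def _int_field(elem: ET.Element, tag: str) -> int:
    child = elem.find(tag)
    if child is None or child.text is None:
        raise AnnotationError(f"missing <{tag}> in <{elem.tag}>")
    try:
        return int(round(float(child.text)))
    except ValueError as exc:
        raise AnnotationError(f"non-numeric <{tag}>: {child.text!r}") from exc


def read_annotation(xml_path: str | Path) -> Annotation:
    """Parse a VOC-dialect XML file into an :class:`Annotation`.

    VOC boxes are 1-based and inclusive; they are converted to the
    package's 0-based half-open convention (row_start = ymin - 1,
    row_end = ymax, and likewise for columns).
    """
    try:
        root = ET.parse(str(xml_path)).getroot()
    except ET.ParseError as exc:
        raise AnnotationError(f"malformed XML in {xml_path}: {exc}") from exc

    filename_elem = root.find("filename")
    if filename_elem is None or not filename_elem.text:
        raise AnnotationError("missing <filename>")

    size: tuple[int, int] | None = None
    size_elem = root.find("size")
    if size_elem is not None:
        size = (_int_field(size_elem, "height"), _int_field(size_elem, "width"))

    boxes: list[tuple[str, BoundingBox]] = []
    for obj in root.findall("object"):
        name_elem = obj.find("name")
        if name_elem is None or not name_elem.text:
            raise AnnotationError("missing <name> in <object>")
        bnd = obj.find("bndbox")
        if bnd is None:
            raise AnnotationError("missing <bndbox> in <object>")
        xmin = _int_field(bnd, "xmin")
        ymin = _int_field(bnd, "ymin")
        xmax = _int_field(bnd, "xmax")
        ymax = _int_field(bnd, "ymax")
        if xmax < xmin:
            raise AnnotationError(f"inverted box: xmax ({xmax}) < xmin ({xmin})")
        if ymax < ymin:
            raise AnnotationError(f"inverted box: ymax ({ymax}) < ymin ({ymin})")
        if xmin < 1 or ymin < 1:
            raise AnnotationError("VOC coordinates are 1-based; got xmin or ymin < 1")
        boxes.append((name_elem.text, BoundingBox(ymin - 1, ymax, xmin - 1, xmax)))

    return Annotation(image_filename=filename_elem.text, boxes=boxes, image_size=size)


def write_annotation(annotation: Annotation, xml_path: str | Path) -> None:
    """Write an :class:`Annotation` as VOC-dialect XML (inverse of read)."""
    root = ET.Element("annotation")
    ET.SubElement(root, "folder").text = str(Path(xml_path).parent.name)
    ET.SubElement(root, "filename").text = annotation.image_filename
    size = ET.SubElement(root, "size")
    h, w = annotation.image_size if annotation.image_size is not None else (0, 0)
    ET.SubElement(size, "width").text = str(w)
    ET.SubElement(size, "height").text = str(h)
    ET.SubElement(size, "depth").text = "3"
    for label, box in annotation.boxes:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = label
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = str(box.col_start + 1)
        ET.SubElement(bnd, "ymin").text = str(box.row_start + 1)
        ET.SubElement(bnd, "xmax").text = str(box.col_end)
        ET.SubElement(bnd, "ymax").text = str(box.row_end)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(str(xml_path), encoding="unicode")
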