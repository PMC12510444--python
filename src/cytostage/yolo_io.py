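"""Reading and writing YOLO-format plain-text annotations.

One object per line: ``class x_center y_center width height [confidence]``,
all coordinates normalized to the image dimensions.  Ground-truth rows have
five fields; detector output may append a sixth confidence field.  Datasets
follow the conventional ``root/images/`` + ``root/labels/`` layout where a
label file shares its basename with its image.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "CellClass",
    "BoundingBox",
    "CellAnnotation",
    "LabeledImageSet",
    "LabelParseError",
    "parse_label_line",
    "read_label_file",
    "write_label_file",
    "load_dataset",
    "IMAGE_EXTENSIONS",
]

#: Image extensions recognized when pairing images with label files.
IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg", ".tif", ".tiff")


class LabelParseError(ValueError):
    """Raised when a YOLO label line or file cannot be parsed."""


class CellClass(enum.IntEnum):
    """Cell types of murine vaginal cytology, with their label-file indices.

    The index/name pairing is fixed: 0 = leukocyte (small round white blood
    cell, dominant in diestrus), 1 = cornified epithelial cell (anucleate,
    dominant in estrus), 2 = nucleated epithelial cell (elevated in
    proestrus).
    """

    LEUKOCYTE = 0
    CORNIFIED = 1
    NUCLEATED = 2

    @property
    def display_name(self) -> str:
        return self.name.capitalize()

    @classmethod
    def from_index(cls, index: int) -> "CellClass":
        try:
            return cls(index)
        except ValueError:
            raise LabelParseError(
                f"unknown cell class index {index!r}; valid indices are 0, 1, 2"
            ) from None


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in normalized image coordinates.

    ``x_center``/``y_center`` locate the box center and ``width``/``height``
    its extent, all as fractions of the image dimensions in [0, 1].  The box
    may overhang the image edge (cells at smear edges are legitimate); the
    extent is clipped to the image on write.
    """

    x_center: float
    y_center: float
    width: float
    height: float

    def __post_init__(self) -> None:
        for name in ("x_center", "y_center", "width", "height"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.width <= 0 or self.height <= 0:
            raise ValueError("box width and height must be positive")

    @property
    def corners(self) -> tuple[float, float, float, float]:
        """(x_min, y_min, x_max, y_max), clipped to the image."""
        return (
            max(0.0, self.x_center - self.width / 2),
            max(0.0, self.y_center - self.height / 2),
            min(1.0, self.x_center + self.width / 2),
            min(1.0, self.y_center + self.height / 2),
        )

    def clipped(self) -> "BoundingBox":
        """Box with its extent clipped to [0, 1] on every side."""
        x0, y0, x1, y1 = self.corners
        return BoundingBox((x0 + x1) / 2, (y0 + y1) / 2, x1 - x0, y1 - y0)

    def iou(self, other: "BoundingBox") -> float:
        ax0, ay0, ax1, ay1 = self.corners
        bx0, by0, bx1, by1 = other.corners
        iw = min(ax1, bx1) - max(ax0, bx0)
        ih = min(ay1, by1) - max(ay0, by0)
        if iw <= 0 or ih <= 0:
            return 0.0
        inter = iw * ih
        union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
        return inter / union


@dataclass(frozen=True)
class CellAnnotation:
    """One labeled or detected cell: class, box, optional confidence.

    Confidence is absent (None) for ground-truth annotations and present in
    [0, 1] for detector output.
    """

    cell_class: CellClass
    box: BoundingBox
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.confidence is not None and not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class LabeledImageSet:
    """Images paired with their annotations, in deterministic order."""

    entries: list[tuple[Path, list[CellAnnotation]]]
    root: Path | None = None

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def annotations(self) -> list[CellAnnotation]:
        """All annotations across the set, flattened."""
        return [a for _, anns in self.entries for a in anns]


def _parse_float(token: str, what: str, line: str) -> float:
    try:
        return float(token)
    except ValueError:
        raise LabelParseError(f"non-numeric {what} {token!r} in line {line!r}") from None


def parse_label_line(line: str) -> CellAnnotation:
    """Parse one YOLO label line into a :class:`CellAnnotation`.

    Accepts 5 fields (ground truth) or 6 (detection with confidence).
    Raises :class:`LabelParseError` for an unknown class index, a
    non-numeric field, a coordinate outside [0, 1], or a wrong field count.
    """
    fields = line.split()
    if len(fields) not in (5, 6):
        raise LabelParseError(
            f"expected 5 or 6 whitespace-separated fields, got {len(fields)} in line {line!r}"
        )
    idx_token = fields[0]
    try:
        index = int(idx_token)
    except ValueError:
        raise LabelParseError(f"non-integer class index {idx_token!r} in line {line!r}") from None
    cell_class = CellClass.from_index(index)
    names = ("x_center", "y_center", "width", "height")
    values = [_parse_float(tok, name, line) for name, tok in zip(names, fields[1:5])]
    for name, v in zip(names, values):
        if not (0.0 <= v <= 1.0):
            raise LabelParseError(f"{name}={v} outside [0, 1] in line {line!r}")
    try:
        box = BoundingBox(*values)
    except ValueError as exc:
        raise LabelParseError(f"{exc} in line {line!r}") from None
    confidence = None
    if len(fields) == 6:
        confidence = _parse_float(fields[5], "confidence", line)
        if not (0.0 <= confidence <= 1.0):
            raise LabelParseError(f"confidence={confidence} outside [0, 1] in line {line!r}")
    return CellAnnotation(cell_class, box, confidence)


def read_label_file(path: str | Path) -> list[CellAnnotation]:
    """Read a YOLO label file: one annotation per non-blank line, in order.

    An empty file maps to an empty list (an image with zero cells).  Parse
    errors are re-raised with the 1-based line number and file name.
    """
    path = Path(path)
    annotations: list[CellAnnotation] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        try:
            annotations.append(parse_label_line(raw))
        except LabelParseError as exc:
            raise LabelParseError(f"{path.name}:{lineno}: {exc}") from None
    return annotations


def write_label_file(
    annotations: Iterable[CellAnnotation],
    path: str | Path,
    include_confidence: bool = False,
) -> None:
    """Write annotations as YOLO label lines, 6-decimal fixed format.

    Boxes overhanging the image edge are clipped to [0, 1] on write.  A
    confidence column is emitted only when ``include_confidence`` is set and
    the annotation carries one.
    """
    lines = []
    for ann in annotations:
        b = ann.box.clipped()
        parts = [
            str(int(ann.cell_class)),
            f"{b.x_center:.6f}",
            f"{b.y_center:.6f}",
            f"{b.width:.6f}",
            f"{b.height:.6f}",
        ]
        if include_confidence and ann.confidence is not None:
            parts.append(f"{ann.confidence:.6f}")
        lines.append(" ".join(parts))
    Path(path).write_text("".join(line + "\n" for line in lines))


def label_path_for(image_path: Path, labels_dir: Path) -> Path:
    return labels_dir / (image_path.stem + ".txt")


def find_images(images_dir: Path) -> list[Path]:
    """Image files under ``images_dir``, lexicographically sorted by name."""
    return sorted(
        (p for p in images_dir.iterdir() if p.suffix.lower() in IMAGE_EXTENSIONS),
        key=lambda p: p.name,
    )


def load_dataset(root_dir: str | Path) -> LabeledImageSet:
    """Load an ``images/`` + ``labels/`` dataset rooted at ``root_dir``.

    Every image is paired with its basename-matched label file, or an empty
    annotation list if none exists.  Entries are in lexicographic image-name
    order.  Orphan label files (no matching image) are reported as warnings,
    never errors.
    """
    root = Path(root_dir)
    images_dir = root / "images"
    labels_dir = root / "labels"
    if not images_dir.is_dir():
        raise FileNotFoundError(f"missing images/ folder under {root}")
    entries: list[tuple[Path, list[CellAnnotation]]] = []
    image_stems = set()
    for image_path in find_images(images_dir):
        image_stems.add(image_path.stem)
        label_path = label_path_for(image_path, labels_dir)
        anns = read_label_file(label_path) if label_path.is_file() else []
        entries.append((image_path, anns))
    if labels_dir.is_dir():
        for label_path in sorted(labels_dir.glob("*.txt")):
            if label_path.stem not in image_stems:
                warnings.warn(
                    f"orphan label file with no matching image: {label_path.name}",
                    stacklevel=2,
                )
    return LabeledImageSet(entries=entries, root=root)
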