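"""Per-cell detection: external YOLO-file ingestion and a classical
morphology detector.

The staging pipeline only needs per-image cell-type counts, so the detector
is a contract, not a particular network.  Two implementations satisfy it:

* :func:`load_external_detections` ingests YOLO-format detection files
  written by any object detector the user has run themselves;
* :func:`detect_cells_classical` segments stained smears with classical
  morphology (thresholding + connected components) and assigns classes by
  the same criteria a cytologist uses: leukocytes are much smaller and
  round, nucleated epithelial cells carry a defined dark nucleus, cornified
  cells are large and anucleate.  It is adequate for well-stained,
  well-separated cells; overlapping clusters merge into single components,
  depressing counts — exactly the failure mode the staging module's
  low-count tag is designed to flag.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.color import rgb2gray
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.transform import resize

from .staging import CellCounts
from .yolo_io import (
    BoundingBox,
    CellAnnotation,
    CellClass,
    LabeledImageSet,
    label_path_for,
    read_label_file,
)

__all__ = [
    "DetectorConfig",
    "ClassicalDetectorParams",
    "load_external_detections",
    "detect_cells_classical",
    "filter_detections",
    "to_counts",
]


@dataclass(frozen=True)
class DetectorConfig:
    """Inference-time detector settings.

    ``confidence_threshold`` 0.25 is the conventional default for YOLO-style
    detectors; ``max_detections`` 1000 and ``working_image_size`` 640 pixels
    (longest side) match common object-detection practice for cytology
    fields of view.
    """

    confidence_threshold: float = 0.25
    max_detections: int = 1000
    working_image_size: int = 640

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence_threshold <= 1.0):
            raise ValueError("confidence_threshold outside [0, 1]")
        if self.max_detections < 1 or self.working_image_size < 1:
            raise ValueError("max_detections and working_image_size must be positive")


@dataclass(frozen=True)
class ClassicalDetectorParams:
    """Morphology thresholds for the classical detector.

    Areas are in pixels^2 at the working image size.  A component is a
    leukocyte when it is small (area <= ``leukocyte_max_area``) and round
    (circularity = 4*pi*area/perimeter^2 >= ``circularity_min_leukocyte``);
    a larger component is nucleated when it contains an interior blob
    darker than its surround by ``nucleus_darkness_delta`` intensity units
    (0-255 scale) covering at least ``nucleus_min_area_fraction`` of the
    cell, else cornified.
    """

    threshold_method: str = "otsu"
    min_object_area: float = 20.0
    max_object_area: float = 40000.0
    leukocyte_max_area: float = 350.0
    circularity_min_leukocyte: float = 0.60
    nucleus_darkness_delta: float = 30.0
    nucleus_min_area_fraction: float = 0.05

    def __post_init__(self) -> None:
        if self.leukocyte_max_area >= self.max_object_area:
            raise ValueError("leukocyte_max_area must be below max_object_area")
        if self.threshold_method not in ("otsu", "mean"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")


def load_external_detections(
    labels_dir: str | Path,
    image_set: LabeledImageSet,
) -> dict[Path, list[CellAnnotation]]:
    """Pair each image of ``image_set`` with its YOLO detection file.

    Detection files are matched by image basename; an image without a file
    maps to an empty list.  Parse errors propagate with file names.
    """
    labels_dir = Path(labels_dir)
    detections: dict[Path, list[CellAnnotation]] = {}
    for image_path, _ in image_set:
        det_path = label_path_for(image_path, labels_dir)
        detections[image_path] = read_label_file(det_path) if det_path.is_file() else []
    return detections


def _to_gray(image: np.ndarray) -> np.ndarray:
    """Grayscale float image in [0, 255]."""
    arr = np.asarray(image)
    if arr.ndim == 3:
        gray = rgb2gray(arr[..., :3]) * 255.0
    else:
        gray = arr.astype(float)
        if gray.max() <= 1.0:
            gray = gray * 255.0
    return gray


def detect_cells_classical(
    image: np.ndarray,
    params: ClassicalDetectorParams | None = None,
    config: DetectorConfig | None = None,
) -> list[CellAnnotation]:
    """Detect and classify cells in a stained smear image.

    Pipeline: rescale to the working size if larger -> foreground
    separation on the stained (dark-on-light) intensity -> connected
    components -> per-component area/circularity/nucleus features -> class
    rule.  Output coordinates are normalized, so detections are scale-free.
    Each detection's confidence is a monotone logistic score of its
    rule margin, always >= 0.5 because the class rule fired.
    """
    if params is None:
        params = ClassicalDetectorParams()
    if config is None:
        config = DetectorConfig()
    gray = _to_gray(image)
    h, w = gray.shape
    longest = max(h, w)
    if longest > config.working_image_size:
        scale = config.working_image_size / longest
        gray = resize(
            gray,
            (max(1, round(h * scale)), max(1, round(w * scale))),
            anti_aliasing=True,
            preserve_range=True,
        )
        h, w = gray.shape

    if params.threshold_method == "otsu":
        # Stains are dark on a light background; guard against blank images
        # where Otsu would split noise.
        if gray.std() < 2.0:
            return []
        thresh = threshold_otsu(gray)
    else:
        thresh = gray.mean() - 2.0 * gray.std()
    foreground = gray < thresh
    if not foreground.any():
        return []

    labeled = cc_label(foreground, connectivity=2)
    detections: list[CellAnnotation] = []
    for region in regionprops(labeled, intensity_image=gray):
        area = region.area
        if area < params.min_object_area or area > params.max_object_area:
            continue
        perimeter = max(region.perimeter, 1.0)
        circularity = min(4.0 * math.pi * area / perimeter**2, 1.0)

        small = area <= params.leukocyte_max_area
        if small and circularity >= params.circularity_min_leukocyte:
            cell_class = CellClass.LEUKOCYTE
            margin = min(
                1.0 - area / params.leukocyte_max_area,
                (circularity - params.circularity_min_leukocyte)
                / (1.0 - params.circularity_min_leukocyte),
            )
        else:
            pixels = region.image_intensity[region.image]
            cytoplasm = float(np.median(pixels))
            nucleus_mask = pixels < cytoplasm - params.nucleus_darkness_delta
            nucleus_fraction = float(nucleus_mask.mean())
            if nucleus_fraction >= params.nucleus_min_area_fraction:
                cell_class = CellClass.NUCLEATED
                margin = (nucleus_fraction - params.nucleus_min_area_fraction) / (
                    1.0 - params.nucleus_min_area_fraction
                )
            else:
                cell_class = CellClass.CORNIFIED
                margin = (
                    params.nucleus_min_area_fraction - nucleus_fraction
                ) / params.nucleus_min_area_fraction
        confidence = float(np.clip(0.5 + 0.5 * margin, 0.0, 1.0))

        r0, c0, r1, c1 = region.bbox
        box = BoundingBox(
            x_center=(c0 + c1) / 2 / w,
            y_center=(r0 + r1) / 2 / h,
            width=(c1 - c0) / w,
            height=(r1 - r0) / h,
        )
        detections.append(CellAnnotation(cell_class, box, confidence))
    return filter_detections(detections, config)


def filter_detections(
    detections: list[CellAnnotation],
    config: DetectorConfig | None = None,
) -> list[CellAnnotation]:
    """Confidence-threshold and cap a detection list.

    Detections below the confidence threshold are dropped (absent
    confidence — ground truth — is kept); if more than ``max_detections``
    remain, the highest-confidence ones are kept.  Output is sorted by
    descending confidence with ties broken by input order; confidence-free
    rows sort as if their confidence were 1.0.
    """
    if config is None:
        config = DetectorConfig()
    kept = [
        (i, d)
        for i, d in enumerate(detections)
        if d.confidence is None or d.confidence >= config.confidence_threshold
    ]
    # descending confidence, stable on input order; no-confidence rows rank top
    kept.sort(key=lambda item: (-(item[1].confidence if item[1].confidence is not None else 1.0), item[0]))
    return [d for _, d in kept[: config.max_detections]]


def to_counts(detections: list[CellAnnotation]) -> CellCounts:
    """Tally detections per cell class; total always equals the list length."""
    tally = Counter(d.cell_class for d in detections)
    return CellCounts(
        n_leukocyte=tally.get(CellClass.LEUKOCYTE, 0),
        n_cornified=tally.get(CellClass.CORNIFIED, 0),
        n_nucleated=tally.get(CellClass.NUCLEATED, 0),
    )
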