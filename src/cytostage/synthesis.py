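"""Synthetic stained-smear generator with exact ground truth.

Emulates the stage-conditioned cell populations of the murine estrous
cycle: leukocyte-dominated diestrus, nucleated-rich proestrus,
cornified-dominated estrus, and a mixed metestrus with no majority class.
Cell morphology follows the cytological criteria the staging rules rest
on — leukocytes are small and round, nucleated epithelial cells carry a
defined dark nucleus, cornified cells are large, irregular and anucleate —
rendered in one of four stain-inspired palettes (Giemsa, H&E, Shorr,
crystal violet).  Every rendered image comes with exact YOLO ground truth,
so detection, staging and evaluation are testable without any external
data.

The generator is deliberately cartoon-like: flat fills plus Gaussian
noise, no texture, no debris, no out-of-focus blur.  What it does model is
the composition signal the classifier consumes (per-stage proportion
distributions), cell clustering (leukocytes preferentially clump, the
dominant real-world failure mode of cell detectors), and the
dark-nucleus/anucleate distinction between the epithelial classes.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage.draw import disk, ellipse, polygon

from .staging import CellCounts, DIESTRUS, ESTRUS, METESTRUS, PROESTRUS, STAGES
from .yolo_io import (
    BoundingBox,
    CellAnnotation,
    CellClass,
    LabeledImageSet,
    load_dataset,
    write_label_file,
)

__all__ = [
    "StagePopulationModel",
    "RenderSpec",
    "PackingError",
    "STAIN_PALETTES",
    "sample_stage_counts",
    "render_image",
    "generate_dataset",
]

#: Fixed RGB palettes per stain: background, epithelial cytoplasm, nucleus,
#: leukocyte.  Giemsa gets the strongest nucleus/cytoplasm contrast, which
#: is also the stain cytologists find defines nuclei best.
STAIN_PALETTES: dict[str, dict[str, tuple[int, int, int]]] = {
    "giemsa": {
        "background": (236, 238, 245),
        "cytoplasm": (168, 158, 212),
        "nucleus": (56, 36, 120),
        "leukocyte": (92, 66, 148),
    },
    "he": {
        "background": (248, 243, 246),
        "cytoplasm": (228, 158, 196),
        "nucleus": (96, 62, 142),
        "leukocyte": (120, 78, 150),
    },
    "shorr": {
        "background": (244, 238, 226),
        "cytoplasm": (206, 130, 112),
        "nucleus": (84, 52, 92),
        "leukocyte": (110, 84, 116),
    },
    "crystal_violet": {
        "background": (242, 240, 247),
        "cytoplasm": (196, 178, 220),
        "nucleus": (94, 74, 134),
        "leukocyte": (106, 88, 150),
    },
}


class PackingError(RuntimeError):
    """Raised when non-overlapping placement fails after bounded retries."""


@dataclass(frozen=True)
class StagePopulationModel:
    """Per-stage cell-composition model.

    Each stage has a mean (leukocyte, cornified, nucleated) proportion
    vector; a per-image composition is a Dirichlet draw around that mean
    with the given concentration (larger = tighter), converted to integer
    counts by largest-remainder rounding so the image composition equals
    the drawn proportions exactly.  The total cell count is uniform on
    ``total_range``.
    """

    means: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            DIESTRUS: (0.75, 0.10, 0.15),
            PROESTRUS: (0.15, 0.25, 0.60),
            ESTRUS: (0.05, 0.90, 0.05),
            METESTRUS: (0.40, 0.35, 0.25),
        }
    )
    concentration: float = 80.0
    total_range: tuple[int, int] = (30, 300)

    def __post_init__(self) -> None:
        for stage, mean in self.means.items():
            if not math.isclose(sum(mean), 1.0, abs_tol=1e-9):
                raise ValueError(f"mean proportions for {stage} do not sum to 1")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        lo, hi = self.total_range
        if lo < 0 or hi < lo:
            raise ValueError("total_range must satisfy 0 <= lo <= hi")


def _largest_remainder(total: int, props: np.ndarray) -> np.ndarray:
    """Integer allocation of ``total`` by proportions, largest remainder."""
    raw = props * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    if short > 0:
        order = np.argsort(-(raw - counts), kind="stable")
        counts[order[:short]] += 1
    return counts


def sample_stage_counts(
    stage: str,
    model: StagePopulationModel | None = None,
    seed: int | np.random.Generator | None = None,
) -> CellCounts:
    """Draw one image's cell counts for a given estrous stage.

    Reproducible per seed; a Generator may be passed to draw from an
    existing stream.
    """
    if model is None:
        model = StagePopulationModel()
    if stage not in model.means:
        raise ValueError(f"unknown stage {stage!r}; expected one of {sorted(model.means)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = model.total_range
    total = int(rng.integers(lo, hi + 1))
    if total == 0:
        return CellCounts(0, 0, 0)
    alpha = np.asarray(model.means[stage]) * model.concentration
    props = rng.dirichlet(alpha)
    counts = _largest_remainder(total, props)
    return CellCounts(int(counts[0]), int(counts[1]), int(counts[2]))


@dataclass(frozen=True)
class RenderSpec:
    """Rendering parameters for one synthetic smear image.

    Geometry is in pixels at ``image_size``.  ``cluster_spread`` is the
    within-cluster placement s.d.; ``leukocyte_cluster_affinity`` /
    ``epithelial_cluster_affinity`` are the probabilities that a cell of
    that kind is placed inside a cluster rather than uniformly (leukocytes
    clump preferentially).  With ``overlap_allowed=False`` all rendered
    cells have pairwise box IoU 0, enforced by bounded-retry packing.
    """

    image_size: int = 640
    stain: str = "giemsa"
    leukocyte_radius: tuple[float, float] = (4.0, 8.0)
    epithelial_major_axis: tuple[float, float] = (16.0, 26.0)
    epithelial_min_minor_axis: float = 12.0
    cornified_radius: tuple[float, float] = (16.0, 30.0)
    cornified_irregularity: float = 0.35
    nucleus_radius_fraction: float = 0.45
    expected_clusters: float = 4.0
    cluster_spread: float = 45.0
    leukocyte_cluster_affinity: float = 0.8
    epithelial_cluster_affinity: float = 0.3
    overlap_allowed: bool = True
    noise_sd: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stain not in STAIN_PALETTES:
            raise ValueError(
                f"unknown stain {self.stain!r}; expected one of {sorted(STAIN_PALETTES)}"
            )
        if self.image_size < 64:
            raise ValueError("image_size must be at least 64 pixels")


def _boxes_disjoint(box: tuple[float, float, float, float], others, gap: float = 1.0) -> bool:
    x0, y0, x1, y1 = box
    for ox0, oy0, ox1, oy1 in others:
        if x0 - gap < ox1 and ox0 - gap < x1 and y0 - gap < oy1 and oy0 - gap < y1:
            return False
    return True


def _jitter(color: tuple[int, int, int], rng: np.random.Generator, amount: float = 8.0) -> np.ndarray:
    return np.clip(np.asarray(color, float) + rng.uniform(-amount, amount, 3), 0, 255)


def render_image(
    counts: CellCounts,
    spec: RenderSpec | None = None,
) -> tuple[np.ndarray, list[CellAnnotation]]:
    """Render a synthetic smear with exactly ``counts.total`` cells.

    Returns the uint8 RGB raster and the exact annotations (correct class
    multiset, tight boxes around each drawn cell).  Identical spec + seed
    gives byte-identical images.  Raises :class:`PackingError` when
    non-overlapping placement fails after bounded retries.
    """
    if spec is None:
        spec = RenderSpec()
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size
    palette = STAIN_PALETTES[spec.stain]
    canvas = np.empty((size, size, 3), dtype=float)
    canvas[:] = palette["background"]

    # Poisson-distributed cluster seeds with Gaussian within-cluster spread;
    # leukocytes join clusters preferentially.
    n_clusters = max(1, int(rng.poisson(spec.expected_clusters)))
    cluster_margin = min(80.0, size / 4)
    cluster_centers = rng.uniform(cluster_margin, size - cluster_margin, size=(n_clusters, 2))

    # Draw epithelial cells first so small leukocytes stay visible on top
    # when overlap is allowed.
    order = (
        [CellClass.CORNIFIED] * counts.n_cornified
        + [CellClass.NUCLEATED] * counts.n_nucleated
        + [CellClass.LEUKOCYTE] * counts.n_leukocyte
    )

    # Sample every cell's geometry up front so the packing extent is known
    # before placement.
    cells: list[dict] = []
    for cell_class in order:
        if cell_class is CellClass.LEUKOCYTE:
            r = rng.uniform(*spec.leukocyte_radius)
            cells.append(
                {
                    "cls": cell_class,
                    "r": r,
                    "ex": r + 1,
                    "ey": r + 1,
                    "affinity": spec.leukocyte_cluster_affinity,
                }
            )
        elif cell_class is CellClass.NUCLEATED:
            a = rng.uniform(*spec.epithelial_major_axis)
            b = rng.uniform(spec.epithelial_min_minor_axis, a)
            theta = rng.uniform(0, math.pi)
            nucleus_off = rng.uniform(-0.2, 0.2, 2) * b
            cells.append(
                {
                    "cls": cell_class,
                    "a": a,
                    "b": b,
                    "theta": theta,
                    "nucleus_off": nucleus_off,
                    "ex": math.hypot(a * math.cos(theta), b * math.sin(theta)) + 1,
                    "ey": math.hypot(a * math.sin(theta), b * math.cos(theta)) + 1,
                    "affinity": spec.epithelial_cluster_affinity,
                }
            )
        else:
            base_r = rng.uniform(*spec.cornified_radius)
            n_vert = int(rng.integers(8, 13))
            angles = np.sort(rng.uniform(0, 2 * math.pi, n_vert))
            radii = base_r * (1 + spec.cornified_irregularity * rng.uniform(-1, 1, n_vert))
            cells.append(
                {
                    "cls": cell_class,
                    "angles": angles,
                    "radii": radii,
                    "ex": float(np.max(radii * np.abs(np.cos(angles)))) + 1,
                    "ey": float(np.max(radii * np.abs(np.sin(angles)))) + 1,
                    "affinity": spec.epithelial_cluster_affinity,
                }
            )

    # Under no-overlap packing, place the largest cells first: random
    # sequential placement in arbitrary order fragments the free space and
    # jams long before the area is actually exhausted.
    if not spec.overlap_allowed:
        cells.sort(key=lambda cell: -(cell["ex"] * cell["ey"]))

    placed_boxes: list[tuple[float, float, float, float]] = []
    annotations: list[CellAnnotation] = []
    max_retries = 500

    for cell_index, cell in enumerate(cells):
        cell_class = cell["cls"]
        ex, ey, affinity = cell["ex"], cell["ey"], cell["affinity"]
        margin_x, margin_y = ex + 2, ey + 2
        center = None
        for attempt in range(max_retries):
            # clustered placement saturates under no-overlap packing, so
            # later retries fall back to uniform positions
            clustered = rng.uniform() < affinity and attempt < 100
            if clustered:
                c = cluster_centers[rng.integers(n_clusters)]
                cand = c + rng.normal(0, spec.cluster_spread, 2)
            else:
                cand = rng.uniform((margin_x, margin_y), (size - margin_x, size - margin_y))
            cand = np.clip(cand, (margin_x, margin_y), (size - margin_x, size - margin_y))
            cand_box = (cand[0] - ex, cand[1] - ey, cand[0] + ex, cand[1] + ey)
            if spec.overlap_allowed or _boxes_disjoint(cand_box, placed_boxes):
                center = cand
                break
        if center is None:
            # exhaustive fallback: scan a fine grid for any free slot
            free = [
                (x, y)
                for x in np.arange(margin_x, size - margin_x, 3.0)
                for y in np.arange(margin_y, size - margin_y, 3.0)
                if _boxes_disjoint((x - ex, y - ey, x + ex, y + ey), placed_boxes)
            ]
            if not free:
                raise PackingError(
                    f"no free slot for cell {cell_index + 1}/{counts.total} "
                    f"after {max_retries} random attempts and a grid scan"
                )
            center = np.asarray(free[int(rng.integers(len(free)))])
        placed_boxes.append((center[0] - ex, center[1] - ey, center[0] + ex, center[1] + ey))
        cx, cy = float(center[0]), float(center[1])

        if cell_class is CellClass.LEUKOCYTE:
            rr, cc = disk((cy, cx), cell["r"], shape=(size, size))
            canvas[rr, cc] = _jitter(palette["leukocyte"], rng)
        elif cell_class is CellClass.NUCLEATED:
            rr, cc = ellipse(
                cy, cx, cell["b"], cell["a"], shape=(size, size), rotation=cell["theta"]
            )
            canvas[rr, cc] = _jitter(palette["cytoplasm"], rng)
            off = cell["nucleus_off"]
            nr, nc = disk(
                (cy + off[1], cx + off[0]),
                spec.nucleus_radius_fraction * cell["b"],
                shape=(size, size),
            )
            canvas[nr, nc] = _jitter(palette["nucleus"], rng)
        else:
            ys = cy + cell["radii"] * np.sin(cell["angles"])
            xs = cx + cell["radii"] * np.cos(cell["angles"])
            rr, cc = polygon(ys, xs, shape=(size, size))
            canvas[rr, cc] = _jitter(palette["cytoplasm"], rng)

        # tight box around the drawn cytoplasm pixels
        r0, r1 = int(rr.min()), int(rr.max())
        c0, c1 = int(cc.min()), int(cc.max())
        box = BoundingBox(
            x_center=(c0 + c1 + 1) / 2 / size,
            y_center=(r0 + r1 + 1) / 2 / size,
            width=(c1 - c0 + 1) / size,
            height=(r1 - r0 + 1) / size,
        )
        annotations.append(CellAnnotation(cell_class, box))

    canvas += rng.normal(0, spec.noise_sd, canvas.shape)
    image = np.clip(canvas, 0, 255).astype(np.uint8)
    return image, annotations


def generate_dataset(
    n_per_stage: int,
    model: StagePopulationModel | None = None,
    spec: RenderSpec | None = None,
    out_root: str | Path = "synthetic_smears",
    seed: int = 0,
) -> LabeledImageSet:
    """Write a stage-balanced synthetic dataset in images/ + labels/ layout.

    Produces ``4 * n_per_stage`` PNG images with exact YOLO labels and a
    ``manifest.csv`` (image, true_stage, true counts).  One master seed;
    each image draws from a child stream keyed by its index, so per-image
    reproducibility survives reordering.
    """
    if model is None:
        model = StagePopulationModel()
    if spec is None:
        spec = RenderSpec(seed=seed)
    out_root = Path(out_root)
    images_dir = out_root / "images"
    labels_dir = out_root / "labels"
    images_dir.mkdir(parents=True, exist_ok=True)
    labels_dir.mkdir(parents=True, exist_ok=True)

    manifest_rows = []
    index = 0
    for stage in STAGES:
        for i in range(n_per_stage):
            child = np.random.default_rng([seed, index])
            counts = sample_stage_counts(stage, model, child)
            image_seed = int(child.integers(0, 2**31))
            image, annotations = render_image(
                counts, spec=dataclasses.replace(spec, seed=image_seed)
            )
            name = f"{stage.lower()}_{i:04d}"
            iio.imwrite(images_dir / f"{name}.png", image)
            write_label_file(annotations, labels_dir / f"{name}.txt")
            manifest_rows.append(
                {
                    "image": f"{name}.png",
                    "true_stage": stage,
                    "n_leukocyte": counts.n_leukocyte,
                    "n_cornified": counts.n_cornified,
                    "n_nucleated": counts.n_nucleated,
                }
            )
            index += 1
    manifest = pd.DataFrame(
        manifest_rows,
        columns=["image", "true_stage", "n_leukocyte", "n_cornified", "n_nucleated"],
    )
    manifest.to_csv(out_root / "manifest.csv", index=False)
    return load_dataset(out_root)
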