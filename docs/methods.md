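# Methods

## The staging model

Vaginal cytology stages the murine estrous cycle from the composition of
three cell types.  `cytostage` treats staging as a deterministic function
of the per-image count vector n = (n_L, n_C, n_N) (leukocytes, cornified
epithelial cells, nucleated epithelial cells).  With p = n / |n|, the rules
are applied in a fixed order, all thresholds inclusive:

| order | rule | stage | default | rationale |
|---|---|---|---|---|
| 1 | p_L ≥ `leukocyte_priority_min` | Diestrus | 0.50 | leukocytes are the diestrus marker; tested first so leukocyte-dominated smears with a moderate nucleated fraction are not routed to proestrus |
| 2 | p_N ≥ `proestrus_nucleated_min` | Proestrus | 0.35 | proestrus depends on a single cell type that rarely reaches a majority; a 35% cutoff markedly improves proestrus recall over a 50% rule |
| 3 | p_C ≥ `majority_min` | Estrus | 0.50 | cornified majority defines estrus |
| 4 | none fired | Metestrus | — | metestrus is the mixed stage with no distinct majority, so it is the residual class |

All four thresholds are unitless fractions, exposed on `StageRuleConfig`
and as hyper-parameters of the sklearn-style `StageRuleClassifier`, and
loadable from a plain-text `key: value` file.

**Low-count branch.** A total below `low_count_total` (default 10 cells,
strictly below; the boundary value is high-count) usually means the
detector merged overlapping cell clusters into background rather than that
the smear was nearly empty.  Such images run through the same ordered rules
on their proportions but the call is tagged (`***` in the output table) for
human review.  The branch structure (two algorithms selected by a count
cutoff) is fixed; the published account of the low-count algorithm does not
pin down its internal decisions, so reusing the ordered rules is this
package's design choice — it is conservative, deterministic, and always
flags.  The cutoff of 10 is likewise this package's round default: the
source work reports that low-count flags marked ~5% of its test images but
not the numeric cutoff.

**Zero cells.** An empty image cannot be staged by composition at all; it
returns `Unclassified` with the tag rather than forcing one of the four
stages.  This is a deliberate deviation from systems that always emit a
stage.

Determinism and totality: every non-negative integer triple yields exactly
one call, identical across repeated invocations, and the high-count branch
depends on proportions only (scale-invariant).  The test suite checks the
engine against an independently coded walk of the same rule statement on
every triple with total ≤ 60 (~39k cases).

## Detection

The detector is a contract: anything that yields per-image cell
annotations works, and counts are the only thing staging consumes.

*External adapter.* YOLO-format text detections (5 or 6 fields; the 6th is
confidence) are read per image basename.  Filtering drops detections below
`confidence_threshold` (default 0.25, the conventional YOLO-family
inference default; confidence-free ground truth always passes) and caps the
list at `max_detections` (default 1000) by descending confidence.

*Classical detector.* For well-stained, well-separated cells, a classical
pipeline suffices: grayscale conversion, Otsu foreground threshold (stains
are dark on a light background; an image with intensity s.d. < 2 is treated
as blank), 8-connected components, then a per-component class rule mirroring
the cytological criteria:

- area ≤ `leukocyte_max_area` (350 px²) **and** circularity
  4πA/P² ≥ 0.60 → leukocyte (small and round);
- otherwise, if pixels darker than the component median by
  `nucleus_darkness_delta` (30 intensity units) cover at least
  `nucleus_min_area_fraction` (5%) of the component → nucleated;
- otherwise → cornified (large, anucleate).

Areas are measured at the working image size (longest side rescaled to 640
px if larger; output coordinates are normalized, so detections are
scale-free).  Confidence is a logistic score of the distance between the
component's features and the rule thresholds, in [0.5, 1.0] by
construction.  Overlapping clusters are intentionally **not** split: they
merge into single components (usually discarded as over-size or counted
once), depressing counts — the same failure mode the low-count tag exists
to flag.

## Synthetic data

The generator defines the study conditions for every end-to-end test.

*Counts.* Each stage has a mean proportion vector — diestrus
(0.75, 0.10, 0.15), proestrus (0.15, 0.25, 0.60), estrus
(0.05, 0.90, 0.05), metestrus (0.40, 0.35, 0.25) as (leukocyte, cornified,
nucleated).  Published descriptions of the per-stage populations are
qualitative; these numbers are this package's quantitative rendering of
"dominant" / "elevated" / "mixed, no majority".  A per-image composition is
a Dirichlet draw around the stage mean with concentration 80 (a
moderate biological spread: component s.d. ≈ 0.05 for a 0.4 mean), turned
into integers by largest-remainder rounding so the image composition equals
the drawn proportions exactly; the total is uniform on [30, 300].  Under
these defaults the rules recover the generating stage for ≈98–99% of images
overall and ≈92–98% of metestrus images (the hardest stage: its mean sits
closest to three rule boundaries) — measured, not tuned per-run, by the
acceptance script.

*Rendering.* 640×640 RGB, flat-filled shapes plus Gaussian noise
(s.d. 3 intensity units): leukocytes are small dark disks (radius 4–8 px),
nucleated cells ellipses (semi-axes 12–26 px) with an off-center dark
nucleus disk (45% of the minor semi-axis), cornified cells irregular
polygons (8–12 vertices, base radius 16–30 px, ±35% vertex jitter).  Four
fixed palettes emulate Giemsa, H&E, Shorr and crystal-violet stains; Giemsa
has the strongest nucleus/cytoplasm contrast.  Cells are placed around
Poisson-distributed cluster seeds with Gaussian within-cluster spread;
leukocytes join clusters with probability 0.8 versus 0.3 for epithelial
cells.  Ground-truth boxes are computed from the actually drawn pixels, so
label fidelity is exact by construction.

*Packing.* With `overlap_allowed=False` cells must have pairwise box IoU 0.
Cells are placed largest-first (random sequential placement in arbitrary
order fragments the free space and jams well below the achievable density),
with up to 500 random candidates per cell and then an exhaustive 3-px grid
scan; only if the scan finds no free slot does rendering raise
`PackingError`.

*What the generator does not model*: overlapping-cell texture, debris,
mucus, out-of-focus blur, uneven illumination, stain variability beyond a
fixed palette with per-cell jitter, or unstained smears.  Passing tests
therefore demonstrate the correctness of the counting-and-rules machinery
and the internal consistency of detector + rules + generator — not
detector performance on real micrographs, which is bounded by exactly the
phenomena the generator omits.

## Evaluation conventions

- Confusion matrices are normalized per **true** class (rows), so the
  diagonal is per-class recall.
- "Mean accuracy" is the **unweighted** mean of per-class accuracies; the
  count-weighted trace/total is reported alongside as `overall_accuracy`.
  On the published per-stage stage accuracies (85, 70, 92, 74% over
  100/100/100/50 test images) the unweighted mean is 80.25% — the published
  headline "80%" — while the weighted mean is 81.1%.
- Cohen's d uses the pooled standard deviation
  s_p = sqrt(((n_a−1)s_a² + (n_b−1)s_b²)/(n_a+n_b−2)); equal-constant
  groups give d = 0 by convention.  The implementation is cross-checked
  against pingouin in the test suite.
- Detection precision/recall/F1 matches predictions to ground truth
  greedily by descending confidence, one-to-one, class-aware, at IoU ≥ 0.5
  — standard object-detection practice.  Undefined ratios (zero
  denominator) are reported as 0 with an `undefined` flag.

## Numerical and interface choices

- Label files are written with 6-decimal fixed-point coordinates; write →
  read round-trips to ≤ 1e-6.  Boxes overhanging the image edge are
  clipped on write, not rejected (edge cells are legitimate).
- Only class indices {0, 1, 2} (leukocyte, cornified, nucleated) are valid;
  anything else is a parse error naming the offending line and line number.
- Table percentages are rounded to 1 decimal and re-sum to 100 ± 0.1.
- Dataset generation derives one child RNG stream per image from the master
  seed and the image index, so per-image reproducibility survives
  reordering; identical seeds give byte-identical datasets.
- The CLI skips unreadable images with a logged warning instead of
  aborting, since the tool targets batch runs.

## Problem sizes

End-to-end checks use a 200-image synthetic dataset (50 per stage, default
generator settings) for stage recovery and 52 non-overlapping images
(13 per stage, totals 20–60 so disjoint packing is geometrically feasible,
all four stains) for classical-detector recovery; the exhaustive rule-engine
check covers all ~39k count triples with total ≤ 60.  At these sizes the
full suite runs in about a minute and the acceptance script in about half a
minute on one CPU.

## Known limitations

- The classical detector is not a substitute for a trained object detector
  on real micrographs; it assumes dark-on-light staining, reasonable
  separation, and nucleus contrast above the configured delta.
- The rule order (diestrus before proestrus) reproduces every published
  textual statement about the rules but cannot be verified against the
  original flowchart node-for-node; it is configurable precisely because it
  is a reconstruction.
- No temporal smoothing across consecutive days of the same animal: each
  image is staged independently.
- Stage proportions and the low-count cutoff are package defaults, not
  measured population parameters; users with their own colony statistics
  should override `StagePopulationModel` and `StageRuleConfig`.
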