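"""Rule-based estrous staging from per-image cell counts.

Vaginal cytology stages the murine estrous cycle from the relative
abundance of three cell types: leukocytes dominate diestrus, cornified
epithelial cells dominate estrus, nucleated epithelial cells are elevated
in proestrus, and metestrus shows a mixed population with no distinct
majority.  The classifier applies a fixed, ordered sequence of inclusive
proportion thresholds to the per-image counts:

1. leukocyte fraction >= ``leukocyte_priority_min``  -> Diestrus
2. nucleated fraction >= ``proestrus_nucleated_min`` -> Proestrus
3. cornified fraction >= ``majority_min``            -> Estrus
4. otherwise                                         -> Metestrus

Leukocyte dominance is tested first so leukocyte-rich diestrus smears with
a moderate nucleated fraction are not routed to proestrus; the proestrus
rule uses a 35% threshold rather than a simple majority, which markedly
improves proestrus recall because proestrus smears rarely reach 50%
nucleated cells.

Images with very few detected cells usually mean the detector merged cell
clusters into background, so a total below ``low_count_total`` routes the
image through a low-count branch: the same ordered rules are applied to the
proportions, but the call carries a biological-impossibility tag (rendered
as ``***`` in the output table) requesting human review.  A zero-cell image
is Unclassified and tagged.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dataclass_fields
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "CellCounts",
    "STAGES",
    "DIESTRUS",
    "PROESTRUS",
    "ESTRUS",
    "METESTRUS",
    "UNCLASSIFIED",
    "StageRuleConfig",
    "StageCall",
    "StageRuleClassifier",
    "IMPOSSIBILITY_TAG",
    "proportions",
    "classify_stage",
    "impossibility_check",
    "stage_table",
]

#: Marker placed in the output table's tag column for flagged images.
IMPOSSIBILITY_TAG = "***"


#: The four estrous stages, plus the degenerate zero-cell outcome.
DIESTRUS = "Diestrus"
PROESTRUS = "Proestrus"
ESTRUS = "Estrus"
METESTRUS = "Metestrus"
UNCLASSIFIED = "Unclassified"

STAGES = (DIESTRUS, PROESTRUS, ESTRUS, METESTRUS)


@dataclass(frozen=True)
class CellCounts:
    """Per-image tally of the three cell types — the sufficient statistic
    for staging."""

    n_leukocyte: int
    n_cornified: int
    n_nucleated: int

    def __post_init__(self) -> None:
        for f in dataclass_fields(self):
            v = getattr(self, f.name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{f.name}={v} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.n_leukocyte + self.n_cornified + self.n_nucleated

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.n_leukocyte, self.n_cornified, self.n_nucleated)


@dataclass(frozen=True)
class StageRuleConfig:
    """Every threshold of the staging flowchart, externalized.

    All thresholds are inclusive (>=).  ``low_count_total`` is the smallest
    total NOT flagged as a biological impossibility (strictly-below
    semantics: total < low_count_total triggers the low-count branch).
    """

    proestrus_nucleated_min: float = 0.35
    majority_min: float = 0.50
    low_count_total: int = 10
    leukocyte_priority_min: float = 0.50

    def __post_init__(self) -> None:
        for name in ("proestrus_nucleated_min", "majority_min", "leukocyte_priority_min"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name}={v} must lie in (0, 1]")
        if self.low_count_total < 0:
            raise ValueError("low_count_total must be non-negative")

    @classmethod
    def from_file(cls, path: str | Path) -> "StageRuleConfig":
        """Load thresholds from a plain-text ``key: value`` file.

        Blank lines and ``#`` comments are ignored; unknown keys raise.
        """
        kwargs: dict[str, float] = {}
        valid = {f.name for f in dataclass_fields(cls)}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key: value', got {raw!r}")
            key, value = (part.strip() for part in line.split(":", 1))
            if key not in valid:
                raise ValueError(f"{path}:{lineno}: unknown rule key {key!r}")
            kwargs[key] = int(value) if key == "low_count_total" else float(value)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [f"{f.name}: {getattr(self, f.name)}" for f in dataclass_fields(self)]
        Path(path).write_text("".join(line + "\n" for line in lines))


@dataclass(frozen=True)
class StageCall:
    """The rule engine's verdict for one image."""

    stage: str
    proportions: tuple[float, float, float]
    branch: str  # "high_count" or "low_count"
    tagged: bool

    @property
    def tag_text(self) -> str:
        return IMPOSSIBILITY_TAG if self.tagged else ""


def proportions(counts: CellCounts) -> tuple[float, float, float]:
    """Class fractions (leukocyte, cornified, nucleated); all zero when the
    image holds no cells."""
    total = counts.total
    if total == 0:
        return (0.0, 0.0, 0.0)
    return (
        counts.n_leukocyte / total,
        counts.n_cornified / total,
        counts.n_nucleated / total,
    )


class StageRuleClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn estimator wrapping the ordered staging rules.

    The rules carry no trainable state — ``fit`` only validates the input
    and records ``classes_`` — but the estimator shape makes the engine
    composable with sklearn model selection and pipelines, and exposes the
    thresholds as ordinary hyper-parameters.

    Parameters
    ----------
    proestrus_nucleated_min : float, default 0.35
        Minimum nucleated-cell fraction for a proestrus call.  35% rather
        than a simple majority, reflecting that proestrus smears depend on
        a single cell type that rarely reaches 50%.
    majority_min : float, default 0.50
        Cornified fraction required for estrus.
    low_count_total : int, default 10
        Totals strictly below this route through the tagged low-count
        branch.
    leukocyte_priority_min : float, default 0.50
        Leukocyte fraction required for diestrus; tested before every
        other rule.

    Attributes
    ----------
    classes_ : ndarray of str
        Stage labels the engine can emit.

    Examples
    --------
    >>> clf = StageRuleClassifier().fit(np.zeros((1, 3)))
    >>> clf.predict([[80, 10, 10], [25, 30, 45]])
    array(['Diestrus', 'Proestrus'], dtype='<U12')
    """

    def __init__(
        self,
        proestrus_nucleated_min: float = 0.35,
        majority_min: float = 0.50,
        low_count_total: int = 10,
        leukocyte_priority_min: float = 0.50,
    ) -> None:
        self.proestrus_nucleated_min = proestrus_nucleated_min
        self.majority_min = majority_min
        self.low_count_total = low_count_total
        self.leukocyte_priority_min = leukocyte_priority_min

    # -- sklearn plumbing ------------------------------------------------

    def _rules(self) -> StageRuleConfig:
        return StageRuleConfig(
            proestrus_nucleated_min=self.proestrus_nucleated_min,
            majority_min=self.majority_min,
            low_count_total=self.low_count_total,
            leukocyte_priority_min=self.leukocyte_priority_min,
        )

    def fit(self, X, y=None) -> "StageRuleClassifier":
        """Validate parameters and declare the label set; X is an (n, 3)
        count matrix and y is ignored."""
        X = check_array(X, ensure_min_features=3)
        if X.shape[1] != 3:
            raise ValueError(f"expected 3 count columns, got {X.shape[1]}")
        self._rules()  # raises on invalid thresholds
        self.n_features_in_ = 3
        self.classes_ = np.array(STAGES + (UNCLASSIFIED,))
        return self

    def predict(self, X) -> np.ndarray:
        """Stage name for each row of an (n, 3) count matrix."""
        return np.array([call.stage for call in self.predict_calls(X)])

    def predict_calls(self, X) -> list[StageCall]:
        """Full :class:`StageCall` (stage, proportions, branch, tag) per row."""
        check_is_fitted(self)
        X = check_array(X)
        if X.shape[1] != 3:
            raise ValueError(f"expected 3 count columns, got {X.shape[1]}")
        rules = self._rules()
        return [
            classify_stage(CellCounts(int(l), int(c), int(n)), rules)
            for l, c, n in X
        ]


def classify_stage(counts: CellCounts, rules: StageRuleConfig | None = None) -> StageCall:
    """Apply the ordered staging rules to one image's cell counts.

    A total function: every non-negative integer triple yields exactly one
    deterministic :class:`StageCall`.  See the module docstring for the
    rule order and the low-count branch.
    """
    if rules is None:
        rules = StageRuleConfig()
    props = proportions(counts)
    total = counts.total
    low_count = total < rules.low_count_total
    branch = "low_count" if low_count else "high_count"
    if total == 0:
        return StageCall(UNCLASSIFIED, props, branch, tagged=True)
    frac_leukocyte, frac_cornified, frac_nucleated = props
    if frac_leukocyte >= rules.leukocyte_priority_min:
        stage = DIESTRUS
    elif frac_nucleated >= rules.proestrus_nucleated_min:
        stage = PROESTRUS
    elif frac_cornified >= rules.majority_min:
        stage = ESTRUS
    else:
        stage = METESTRUS
    return StageCall(stage, props, branch, tagged=low_count)


def impossibility_check(counts: CellCounts, rules: StageRuleConfig | None = None) -> bool:
    """True iff the image's total cell count is implausibly low
    (strictly below ``low_count_total``)."""
    if rules is None:
        rules = StageRuleConfig()
    return counts.total < rules.low_count_total


TABLE_COLUMNS = [
    "image",
    "n_leukocyte",
    "n_cornified",
    "n_nucleated",
    "pct_leukocyte",
    "pct_cornified",
    "pct_nucleated",
    "stage",
    "tag",
]


def stage_table(
    per_image_counts: Mapping[str, CellCounts] | Iterable[tuple[str, CellCounts]],
    rules: StageRuleConfig | None = None,
) -> pd.DataFrame:
    """Classification table: one row per image, in input order.

    Columns: image id, the three counts, percentages (1 decimal), stage,
    and a tag column holding ``***`` for flagged images.
    """
    if rules is None:
        rules = StageRuleConfig()
    items = per_image_counts.items() if isinstance(per_image_counts, Mapping) else per_image_counts
    rows = []
    for image, counts in items:
        call = classify_stage(counts, rules)
        rows.append(
            {
                "image": image,
                "n_leukocyte": counts.n_leukocyte,
                "n_cornified": counts.n_cornified,
                "n_nucleated": counts.n_nucleated,
                "pct_leukocyte": round(100 * call.proportions[0], 1),
                "pct_cornified": round(100 * call.proportions[1], 1),
                "pct_nucleated": round(100 * call.proportions[2], 1),
                "stage": call.stage,
                "tag": call.tag_text,
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
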