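"""Domain types and validation for additive multicriteria value models.

The model follows standard multi-attribute value theory (MAVT): each
criterion carries a *descriptor of performance* (an ordered set of plausible
performance levels, most attractive first), a cardinal value scale anchored
at the Neutral (0 points) and Good (100 points) reference levels, and a
strictly positive weight; weights sum to one.  Alternatives are scored by
converting performance into partial value per criterion and aggregating with
the weighted sum V(a) = sum_j w_j v_j(a).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

log = logging.getLogger("dietmcda")

DIMENSIONS = ("health", "environmental", "economic", "social")
DESCRIPTOR_KINDS = ("quantitative", "categorical")

#: Sum-to-one / anchor tolerance used throughout validation.
TOL = 1e-9


class _Missing:
    """Sentinel for an absent performance cell (blank in delimited files)."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "MISSING"

    def __bool__(self) -> bool:
        return False


MISSING = _Missing()

Performance = Union[float, str, _Missing]


class DataError(ValueError):
    """Raised for malformed or mutually inconsistent model/table inputs."""


# ---------------------------------------------------------------------------
# Value tree
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DescriptorLevel:
    """One performance level of a descriptor.

    ``index`` ranks attractiveness (1 = most attractive).  ``performance``
    is a number for quantitative descriptors or a short label (``"L3"``)
    for categorical ones; ``description`` carries the free-text meaning of
    a categorical level.
    """

    index: int
    performance: Union[float, str]
    is_neutral: bool = False
    is_good: bool = False
    description: str = ""

    @property
    def label(self) -> str:
        return self.performance if isinstance(self.performance, str) else f"L{self.index}"


@dataclass(frozen=True)
class Criterion:
    id: str
    name: str
    dimension: str
    descriptor_kind: str
    unit: str
    levels: tuple[DescriptorLevel, ...]

    def __post_init__(self):
        object.__setattr__(self, "levels", tuple(self.levels))

    @property
    def neutral_level(self) -> DescriptorLevel:
        return next(lv for lv in self.levels if lv.is_neutral)

    @property
    def good_level(self) -> DescriptorLevel:
        return next(lv for lv in self.levels if lv.is_good)

    @property
    def is_quantitative(self) -> bool:
        return self.descriptor_kind == "quantitative"

    def level_by_label(self, label: str) -> DescriptorLevel:
        for lv in self.levels:
            if lv.label == label:
                return lv
        raise DataError(f"unknown level {label!r} for criterion {self.id!r}")


@dataclass(frozen=True)
class ScaleAnchor:
    level_index: int
    performance: Union[float, str]
    value: float


@dataclass(frozen=True)
class ValueScale:
    """Cardinal value scale: ordered (level, performance, value) anchors.

    By convention the Neutral anchor has value 0 and the Good anchor value
    100; values decrease with decreasing attractiveness rank.
    """

    criterion_id: str
    anchors: tuple[ScaleAnchor, ...]

    def __post_init__(self):
        object.__setattr__(self, "anchors", tuple(self.anchors))

    def value_at_level(self, level_index: int) -> float:
        for a in self.anchors:
            if a.level_index == level_index:
                return a.value
        raise DataError(
            f"scale {self.criterion_id!r} has no anchor at level {level_index}"
        )

    def value_at_label(self, label: str) -> float:
        for a in self.anchors:
            if isinstance(a.performance, str) and a.performance == label:
                return a.value
        raise DataError(f"scale {self.criterion_id!r} has no anchor labelled {label!r}")


@dataclass(frozen=True)
class WeightVector:
    """Strictly positive criterion weights summing to one."""

    weights: Mapping[str, float]

    def __post_init__(self):
        object.__setattr__(self, "weights", dict(self.weights))

    def __getitem__(self, criterion_id: str) -> float:
        return self.weights[criterion_id]

    def __iter__(self):
        return iter(self.weights)

    def items(self):
        return self.weights.items()

    @property
    def total(self) -> float:
        return math.fsum(self.weights.values())


@dataclass
class MCDAModel:
    """A reusable additive value model: criteria, scales and weights."""

    criteria: list[Criterion]
    scales: list[ValueScale]
    weights: WeightVector
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.criteria = list(self.criteria)
        self.scales = list(self.scales)
        self._by_id = {c.id: c for c in self.criteria}
        self._scale_by_id = {s.criterion_id: s for s in self.scales}

    @property
    def criterion_ids(self) -> list[str]:
        return [c.id for c in self.criteria]

    def criterion(self, criterion_id: str) -> Criterion:
        try:
            return self._by_id[criterion_id]
        except KeyError:
            raise DataError(f"unknown criterion {criterion_id!r}") from None

    def scale(self, criterion_id: str) -> ValueScale:
        try:
            return self._scale_by_id[criterion_id]
        except KeyError:
            raise DataError(f"no value scale for criterion {criterion_id!r}") from None

    def __eq__(self, other) -> bool:
        if not isinstance(other, MCDAModel):
            return NotImplemented
        return (
            self.criteria == other.criteria
            and self.scales == other.scales
            and self.weights == other.weights
            and self.metadata == other.metadata
        )


# ---------------------------------------------------------------------------
# Alternatives
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Scenario:
    """A dietary substitution alternative (fraction f of the baseline food
    replaced by the substitute)."""

    id: str
    country: str = ""
    substitution_fraction: float = 0.0
    description: str = ""

    def __post_init__(self):
        if not 0.0 <= self.substitution_fraction <= 1.0:
            raise DataError(
                f"substitution fraction {self.substitution_fraction} outside [0, 1]"
            )


class PerformanceTable:
    """Scenario x criterion performance entries.

    Cells hold a quantitative performance (float, in the criterion's
    descriptor units), a categorical level label, or :data:`MISSING`.
    Scenario and criterion order is preserved.
    """

    def __init__(
        self,
        scenarios: Sequence[str],
        criteria: Sequence[str],
        cells: Mapping[tuple[str, str], Performance],
    ):
        self.scenarios = list(scenarios)
        self.criteria = list(criteria)
        self.cells = {}
        for s in self.scenarios:
            for c in self.criteria:
                self.cells[(s, c)] = cells.get((s, c), MISSING)

    def __getitem__(self, key: tuple[str, str]) -> Performance:
        return self.cells[key]

    def row(self, scenario_id: str) -> dict[str, Performance]:
        if scenario_id not in self.scenarios:
            raise DataError(f"unknown scenario {scenario_id!r}")
        return {c: self.cells[(scenario_id, c)] for c in self.criteria}

    def missing_cells(self) -> list[tuple[str, str]]:
        return [k for k, v in self.cells.items() if v is MISSING]

    def __eq__(self, other) -> bool:
        if not isinstance(other, PerformanceTable):
            return NotImplemented
        return (
            self.scenarios == other.scenarios
            and self.criteria == other.criteria
            and self.cells == other.cells
        )

    def validate_against(self, model: MCDAModel) -> None:
        """Check cells against the model's descriptors; raise DataError."""
        for c in self.criteria:
            criterion = model.criterion(c)  # raises for unknown columns
            for s in self.scenarios:
                cell = self.cells[(s, c)]
                if cell is MISSING:
                    continue
                if criterion.is_quantitative:
                    if not isinstance(cell, (int, float)):
                        raise DataError(
                            f"criterion {c!r} is quantitative but cell "
                            f"({s!r}, {c!r}) holds {cell!r}"
                        )
                else:
                    if not isinstance(cell, str):
                        raise DataError(
                            f"criterion {c!r} is categorical but cell "
                            f"({s!r}, {c!r}) holds {cell!r}"
                        )
                    criterion.level_by_label(cell)


@dataclass
class EvaluationResult:
    """Partial values v_j(a), global scores V(a) and the induced ranking."""

    partials: dict[tuple[str, str], float]
    globals_: dict[str, float]
    ranking: list[str]
    missing_cells: list[tuple[str, str]] = field(default_factory=list)

    def partial(self, scenario: str, criterion: str) -> float:
        return self.partials[(scenario, criterion)]

    def global_value(self, scenario: str) -> float:
        return self.globals_[scenario]


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Violation:
    criterion_id: str
    rule: str
    message: str


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def rules(self) -> set[str]:
        return {v.rule for v in self.violations}

    def add(self, criterion_id: str, rule: str, message: str) -> None:
        self.violations.append(Violation(criterion_id, rule, message))


def _validate_criterion(c: Criterion, report: ValidationReport) -> None:
    if c.dimension not in DIMENSIONS:
        report.add(c.id, "dimension", f"unknown dimension {c.dimension!r}")
    if c.descriptor_kind not in DESCRIPTOR_KINDS:
        report.add(c.id, "descriptor_kind", f"unknown kind {c.descriptor_kind!r}")
    idx = [lv.index for lv in c.levels]
    if len(set(idx)) != len(idx):
        report.add(c.id, "index_unique", "duplicate level indices")
    n_neutral = sum(lv.is_neutral for lv in c.levels)
    n_good = sum(lv.is_good for lv in c.levels)
    if n_neutral != 1:
        report.add(c.id, "neutral_unique", f"{n_neutral} levels flagged Neutral")
    if n_good != 1:
        report.add(c.id, "good_unique", f"{n_good} levels flagged Good")
    if n_neutral == 1 and n_good == 1:
        if c.good_level.index > c.neutral_level.index:
            report.add(
                c.id,
                "good_before_neutral",
                "Good level ranked below Neutral in attractiveness order",
            )
    if c.descriptor_kind == "quantitative":
        perf = [lv.performance for lv in sorted(c.levels, key=lambda lv: lv.index)]
        if not all(isinstance(p, (int, float)) for p in perf):
            report.add(c.id, "quantitative_levels", "non-numeric level performance")
        else:
            diffs = [b - a for a, b in zip(perf, perf[1:])]
            if not (all(d > 0 for d in diffs) or all(d < 0 for d in diffs)):
                report.add(
                    c.id,
                    "monotone_performance",
                    "performances not strictly monotone along the level order",
                )
    else:
        labels = [lv.label for lv in c.levels]
        if len(set(labels)) < 2 or len(set(labels)) != len(labels):
            report.add(c.id, "categorical_levels", "needs >=2 distinct level labels")


def _validate_scale(c: Criterion, s: ValueScale, report: ValidationReport) -> None:
    by_index = {a.level_index: a for a in s.anchors}
    if set(by_index) != {lv.index for lv in c.levels}:
        report.add(c.id, "scale_levels", "scale anchors do not match descriptor levels")
        return
    try:
        neutral_v = by_index[c.neutral_level.index].value
        good_v = by_index[c.good_level.index].value
    except (StopIteration, KeyError):
        return
    if abs(neutral_v) > TOL:
        report.add(c.id, "neutral_zero", f"Neutral anchor maps to {neutral_v}, not 0")
    if abs(good_v - 100.0) > TOL:
        report.add(c.id, "good_hundred", f"Good anchor maps to {good_v}, not 100")
    ordered = [by_index[lv.index].value for lv in sorted(c.levels, key=lambda lv: lv.index)]
    if any(b > a + TOL for a, b in zip(ordered, ordered[1:])):
        report.add(
            c.id,
            "monotone_values",
            "values must not increase with decreasing attractiveness rank",
        )


def validate_model(model: MCDAModel) -> ValidationReport:
    """Check every structural invariant; never raises.

    Returns an empty report when the model is valid; otherwise one
    :class:`Violation` per broken rule, tagged with the criterion id
    (empty id for model-level rules).
    """
    report = ValidationReport()
    ids = model.criterion_ids
    if len(set(ids)) != len(ids):
        report.add("", "criterion_ids_unique", "duplicate criterion ids")
    for c in model.criteria:
        _validate_criterion(c, report)
    scale_ids = [s.criterion_id for s in model.scales]
    if sorted(scale_ids) != sorted(ids):
        report.add("", "correspondence", "criteria and scales not one-to-one")
    else:
        for c in model.criteria:
            _validate_scale(c, model.scale(c.id), report)
    wkeys = set(model.weights.weights)
    if wkeys != set(ids):
        report.add("", "correspondence", "criteria and weights not one-to-one")
    if any(w <= 0 for w in model.weights.weights.values()):
        report.add("", "weights_positive", "all weights must be > 0")
    if abs(model.weights.total - 1.0) > TOL:
        report.add("", "weights_sum", f"weights sum to {model.weights.total}, not 1")
    return report
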