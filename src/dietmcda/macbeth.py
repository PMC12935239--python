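"""MACBETH-style derivation of cardinal scales and swing weights.

MACBETH (Measuring Attractiveness by a Categorical Based Evaluation
Technique) turns qualitative pairwise judgments of *difference in
attractiveness* — expressed in seven semantic categories from "null" to
"extreme" — into a cardinal value scale, via linear programming.

The LP family implemented here is the canonical one:

* one variable v(e) >= 0 per judged entity;
* a pair (a, b) judged in category k >= 1 contributes v(a) - v(b) >= k*delta
  (delta = 1);
* "null" judgments force equality v(a) = v(b);
* for two judged pairs whose categories are strictly ordered, the stronger
  pair's value difference must exceed the weaker pair's by at least delta;
* consistency of a judgment matrix *is* feasibility of this system.

The optimum is made deterministic by first minimizing the largest entity
value and then, at that optimum, minimizing the sum of entity values
(both solved with HiGHS).  Scales are finally re-anchored affinely so that
the designated Neutral entity maps to 0 and the Good entity to 100; swing
weights are normalized to sum to one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
from scipy.optimize import linprog

from .model_core import DataError, ScaleAnchor, ValueScale, WeightVector

CATEGORY_NAMES = (
    "null",
    "very weak",
    "weak",
    "moderate",
    "strong",
    "very strong",
    "extreme",
)

#: Minimal value-difference unit per semantic category step.
DELTA = 1.0

_LP_OPTS = {"presolve": True}


@dataclass(frozen=True)
class SemanticCategory:
    """One of the seven MACBETH difference-of-attractiveness categories."""

    index: int

    def __post_init__(self):
        if not 0 <= self.index <= 6:
            raise DataError(f"semantic category index {self.index} outside 0..6")

    @property
    def name(self) -> str:
        return CATEGORY_NAMES[self.index]

    @classmethod
    def parse(cls, spec: Union[int, str, "SemanticCategory"]) -> "SemanticCategory":
        if isinstance(spec, SemanticCategory):
            return spec
        if isinstance(spec, int):
            return cls(spec)
        name = spec.strip().lower()
        if name not in CATEGORY_NAMES:
            raise DataError(f"unknown semantic category {spec!r}")
        return cls(CATEGORY_NAMES.index(name))


CategoryRange = tuple[int, int]


def _parse_category_range(spec) -> CategoryRange:
    """Accept a category, an (lo, hi) pair, or 'weak to moderate' text."""
    if isinstance(spec, tuple) and len(spec) == 2 and not isinstance(spec[0], str):
        lo, hi = int(spec[0]), int(spec[1])
    elif isinstance(spec, tuple) and len(spec) == 2:
        lo = SemanticCategory.parse(spec[0]).index
        hi = SemanticCategory.parse(spec[1]).index
    elif isinstance(spec, str) and " to " in spec:
        a, b = spec.split(" to ", 1)
        lo = SemanticCategory.parse(a).index
        hi = SemanticCategory.parse(b).index
    else:
        k = SemanticCategory.parse(spec).index
        lo = hi = k
    if not (0 <= lo <= hi <= 6):
        raise DataError(f"invalid category range {spec!r}")
    return lo, hi


class JudgmentMatrix:
    """Pairwise qualitative judgments over an ordered set of entities.

    ``judge(a, b, category)`` records that *a* is at least as attractive as
    *b*, with the stated difference category (or a contiguous range such as
    ``"weak to moderate"``).
    """

    def __init__(self, entities: Sequence[str]):
        if len(entities) < 2:
            raise DataError("a judgment matrix needs at least 2 entities")
        if len(set(entities)) != len(entities):
            raise DataError("duplicate entities")
        self.entities: tuple[str, ...] = tuple(entities)
        self.judgments: dict[tuple[str, str], CategoryRange] = {}

    def judge(self, a: str, b: str, category) -> "JudgmentMatrix":
        if a not in self.entities or b not in self.entities:
            raise DataError(f"judged pair ({a!r}, {b!r}) not among entities")
        if a == b:
            rng = _parse_category_range(category)
            if rng != (0, 0):
                raise DataError("diagonal judgments must be null")
            return self
        rng = _parse_category_range(category)
        rev = self.judgments.get((b, a))
        if rev is not None and rev[1] > 0 and rng[1] > 0:
            raise DataError(
                f"pair ({a!r}, {b!r}) judged in both orientations with "
                "nonzero categories"
            )
        self.judgments[(a, b)] = rng
        return self

    def __len__(self) -> int:
        return len(self.judgments)


@dataclass
class ConsistencyReport:
    consistent: bool
    violated_constraints: list[tuple[tuple[str, str], str]] = field(default_factory=list)

    def __post_init__(self):
        assert self.consistent == (not self.violated_constraints)


class InconsistentMatrixError(DataError):
    def __init__(self, report: ConsistencyReport):
        super().__init__("judgment matrix is inconsistent")
        self.report = report


# ---------------------------------------------------------------------------
# LP core
# ---------------------------------------------------------------------------


def _constraints(matrix: JudgmentMatrix, judgments=None):
    """Build (A_ub, b_ub, A_eq, b_eq) for the MACBETH system (rows as lists).

    Convention: inequality rows encode  A_ub @ v <= b_ub.
    """
    ents = matrix.entities
    pos = {e: i for i, e in enumerate(ents)}
    n = len(ents)
    judgments = dict(matrix.judgments if judgments is None else judgments)
    A_ub, b_ub, A_eq, b_eq = [], [], [], []
    for (a, b), (lo, hi) in judgments.items():
        if hi == 0:  # null: indifference
            row = [0.0] * n
            row[pos[a]], row[pos[b]] = 1.0, -1.0
            A_eq.append(row)
            b_eq.append(0.0)
        elif lo >= 1:  # v(a) - v(b) >= lo * delta
            row = [0.0] * n
            row[pos[a]], row[pos[b]] = -1.0, 1.0
            A_ub.append(row)
            b_ub.append(-lo * DELTA)
        else:  # range touching null: only weak ordering
            row = [0.0] * n
            row[pos[a]], row[pos[b]] = -1.0, 1.0
            A_ub.append(row)
            b_ub.append(0.0)
    items = list(judgments.items())
    for i, ((a, b), (lo1, _hi1)) in enumerate(items):
        for (c, d), (_lo2, hi2) in items[:i] + items[i + 1:]:
            if lo1 > hi2 >= 1:  # strictly stronger category => larger difference
                row = [0.0] * n
                row[pos[a]] -= 1.0
                row[pos[b]] += 1.0
                row[pos[c]] += 1.0
                row[pos[d]] -= 1.0
                A_ub.append(row)
                b_ub.append(-DELTA)
    return A_ub, b_ub, A_eq, b_eq


def _solve(matrix: JudgmentMatrix, judgments=None, lower=0.0, extra_ub=None):
    """Feasibility + deterministic optimum of the MACBETH LP.

    Returns a dict entity -> value, or None when infeasible.  ``lower`` is
    the lower bound on every entity value (swing weighting uses DELTA so
    every swing stays strictly positive).
    """
    ents = matrix.entities
    n = len(ents)
    A_ub, b_ub, A_eq, b_eq = _constraints(matrix, judgments)
    if extra_ub:
        for row, rhs in extra_ub:
            A_ub.append(list(row))
            b_ub.append(rhs)
    # Stage 1: minimize t with v_i <= t.
    A1 = [row + [0.0] for row in A_ub] + [
        [1.0 if j == i else 0.0 for j in range(n)] + [-1.0] for i in range(n)
    ]
    b1 = list(b_ub) + [0.0] * n
    E1 = [row + [0.0] for row in A_eq]
    c1 = [0.0] * n + [1.0]
    res = linprog(
        c1,
        A_ub=np.array(A1, dtype=float),
        b_ub=np.array(b1, dtype=float),
        A_eq=np.array(E1, dtype=float) if E1 else None,
        b_eq=np.array(b_eq, dtype=float) if E1 else None,
        bounds=[(lower, None)] * n + [(0, None)],
        method="highs",
        options=_LP_OPTS,
    )
    if not res.success:
        return None
    t_star = res.x[-1]
    # Stage 2: with max value capped at t*, minimize the value sum.
    A2 = list(A_ub) + [
        [1.0 if j == i else 0.0 for j in range(n)] for i in range(n)
    ]
    b2 = list(b_ub) + [t_star + 1e-9] * n
    res2 = linprog(
        [1.0] * n,
        A_ub=np.array(A2, dtype=float),
        b_ub=np.array(b2, dtype=float),
        A_eq=np.array(A_eq, dtype=float) if A_eq else None,
        b_eq=np.array(b_eq, dtype=float) if A_eq else None,
        bounds=[(lower, None)] * n,
        method="highs",
        options=_LP_OPTS,
    )
    if not res2.success:  # pragma: no cover - stage 1 already feasible
        return None
    return {e: float(v) for e, v in zip(ents, res2.x)}


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------


def check_consistency(matrix: JudgmentMatrix) -> ConsistencyReport:
    """Feasibility check of the MACBETH constraint system.

    On inconsistency, single-judgment deletions that restore feasibility are
    reported as the offending subset (every reported pair takes part in some
    infeasible cycle/chain); if no single deletion helps, all judgments are
    reported.
    """
    if not matrix.judgments:
        raise DataError("no judgments")
    if _solve(matrix) is not None:
        return ConsistencyReport(True)
    violated: list[tuple[tuple[str, str], str]] = []
    for pair in matrix.judgments:
        reduced = {k: v for k, v in matrix.judgments.items() if k != pair}
        if not reduced or _solve(matrix, judgments=reduced) is not None:
            violated.append((pair, "removing this judgment restores feasibility"))
    if not violated:
        violated = [(p, "member of an infeasible judgment subset") for p in matrix.judgments]
    return ConsistencyReport(False, violated)


def derive_scale(matrix: JudgmentMatrix, neutral: str, good: str) -> ValueScale:
    """Derive a cardinal scale from a consistent judgment matrix.

    Entity values respect every judged category (strictly larger differences
    for strictly stronger categories; equality for "null") and are affinely
    re-anchored so ``neutral`` maps to 0 and ``good`` to 100.
    """
    for e in (neutral, good):
        if e not in matrix.entities:
            raise DataError(f"anchor entity {e!r} not among entities")
    report = check_consistency(matrix)
    if not report.consistent:
        raise InconsistentMatrixError(report)
    values = _solve(matrix)
    span = values[good] - values[neutral]
    if span <= 0:
        raise DataError(
            f"good entity {good!r} not judged more attractive than {neutral!r}"
        )
    anchors = tuple(
        ScaleAnchor(
            level_index=i + 1,
            performance=e,
            value=100.0 * (values[e] - values[neutral]) / span,
        )
        for i, e in enumerate(matrix.entities)
    )
    return ValueScale(criterion_id="derived", anchors=anchors)


def derive_weights(
    swing_ranking: Sequence[str], swing_matrix: JudgmentMatrix
) -> WeightVector:
    """Swing weights from a ranked list of Neutral->Good swings plus a
    judgment matrix over those swings.

    Every swing is kept strictly positive (each Neutral->Good improvement is
    worth something); the ranking is enforced as weak ordering constraints,
    and a matrix that forces the opposite order raises "ranking violated".
    """
    if set(swing_ranking) != set(swing_matrix.entities):
        raise DataError("ranking entities differ from matrix entities")
    report = check_consistency(swing_matrix)
    if not report.consistent:
        raise InconsistentMatrixError(report)
    pos = {e: i for i, e in enumerate(swing_matrix.entities)}
    n = len(swing_matrix.entities)
    extra = []
    for hi, lo_ent in zip(swing_ranking, swing_ranking[1:]):
        row = [0.0] * n
        row[pos[hi]], row[pos[lo_ent]] = -1.0, 1.0  # v(hi) >= v(lo)
        extra.append((row, 0.0))
    values = _solve(swing_matrix, lower=DELTA, extra_ub=extra)
    if values is None:
        raise DataError("ranking violated")
    total = sum(values.values())
    return WeightVector({e: values[e] / total for e in swing_matrix.entities})


def validation_ratio(scale: ValueScale, a, b, c, d) -> float:
    """Ratio of value differences (v(a)-v(b)) / (v(c)-v(d)).

    Used for facilitator validation questions ("is the improvement from L4
    to L3 twice as attractive as from L3 to L2?").  Entities may be given
    as level indices, "L<k>" strings, or categorical anchor labels.
    """

    def value(entity) -> float:
        if isinstance(entity, int):
            return scale.value_at_level(entity)
        if isinstance(entity, str):
            if entity.startswith("L") and entity[1:].isdigit():
                try:
                    return scale.value_at_level(int(entity[1:]))
                except DataError:
                    pass
            return scale.value_at_label(entity)
        raise DataError(f"cannot resolve scale entity {entity!r}")

    denom = value(c) - value(d)
    if abs(denom) < 1e-12:
        raise DataError("indifferent reference pair")
    return (value(a) - value(b)) / denom
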