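"""Weight-sensitivity and dominance/robustness analysis.

Single-weight sensitivity varies one criterion weight w over [0, 1] while
rescaling the remaining weights proportionally by (1 - w)/(1 - w0).  Each
alternative's global score is then affine in w,

    V_a(w) = (1 - w) * R_a + w * v_j(a),
    R_a    = (V_a(w0) - w0 * v_j(a)) / (1 - w0),

so crossovers of the top-ranked alternative are exact intersections of
straight lines.  Robustness puts closed intervals around partial values;
the minimum of the affine difference V(a) - V(b) over such a box is
attained at a vertex (lower bounds for a, upper bounds for b), which gives
an exact pairwise dominance classification.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .model_core import DataError, MCDAModel

Partials = Union[pd.DataFrame, Mapping[str, Mapping[str, float]]]


def partials_frame(partials: Partials, model: MCDAModel) -> pd.DataFrame:
    """Normalize partial values to a scenario x criterion DataFrame.

    Missing entries (NaN) contribute zero points, consistent with
    :func:`dietmcda.valuation.evaluate`.
    """
    if isinstance(partials, pd.DataFrame):
        frame = partials.copy()
    else:
        frame = pd.DataFrame.from_dict(partials, orient="index")
    unknown = [c for c in frame.columns if c not in model.criterion_ids]
    if unknown:
        raise DataError(f"partial columns not in model: {unknown}")
    for c in model.criterion_ids:
        if c not in frame.columns:
            raise DataError(f"partials missing criterion {c!r}")
    return frame[model.criterion_ids].fillna(0.0).astype(float)


def global_scores(frame: pd.DataFrame, model: MCDAModel) -> pd.Series:
    w = pd.Series(dict(model.weights.items()))
    return frame.mul(w, axis=1).sum(axis=1)


# ---------------------------------------------------------------------------
# Single-weight sensitivity
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Line:
    """V(w) = intercept + slope * w for one alternative."""

    scenario: str
    intercept: float
    slope: float

    def __call__(self, w: float) -> float:
        return self.intercept + self.slope * w


@dataclass(frozen=True)
class Crossover:
    weight: float
    outgoing: str  # top-ranked alternative below the crossover weight
    incoming: str  # top-ranked alternative above it


@dataclass
class SensitivityProfile:
    criterion_id: str
    current_weight: float
    lines: dict[str, Line]
    crossovers: list[Crossover]
    grid: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 1.0, 101))

    def value(self, scenario: str, w: float) -> float:
        return self.lines[scenario](w)

    def top(self, w: float) -> str:
        best, best_v = None, -np.inf
        for s, line in self.lines.items():
            v = line(w)
            if v > best_v + 1e-12:
                best, best_v = s, v
        return best

    def intersections(self, a: str, b: str) -> list[float]:
        """Exact weights in [0, 1] where alternatives a and b swap order."""
        la, lb = self.lines[a], self.lines[b]
        dslope = la.slope - lb.slope
        if abs(dslope) < 1e-15:
            return []
        w = (lb.intercept - la.intercept) / dslope
        return [w] if -1e-12 <= w <= 1 + 1e-12 else []


def weight_sensitivity(
    model: MCDAModel,
    partials: Partials,
    criterion: str,
    grid: Optional[Sequence[float]] = None,
) -> SensitivityProfile:
    """Affine global-score lines and top-alternative crossovers for one
    varied criterion weight (non-varied weights renormalized
    proportionally)."""
    if criterion not in model.criterion_ids:
        raise DataError(f"criterion {criterion!r} not in model")
    frame = partials_frame(partials, model)
    w0 = model.weights[criterion]
    if w0 >= 1.0 - 1e-12:
        raise DataError("varied criterion already carries all the weight")
    nominal = global_scores(frame, model)
    lines = {}
    for s in frame.index:
        vj = float(frame.at[s, criterion])
        rest = (float(nominal[s]) - w0 * vj) / (1.0 - w0)
        lines[s] = Line(s, intercept=rest, slope=vj - rest)
    crossovers = _envelope_crossovers(lines, list(frame.index))
    g = np.asarray(grid, dtype=float) if grid is not None else np.linspace(0, 1, 101)
    if np.any(g < 0) or np.any(g > 1):
        raise DataError("grid weights must lie in [0, 1]")
    return SensitivityProfile(criterion, w0, lines, crossovers, g)


def _envelope_crossovers(lines: dict[str, Line], order: list[str]) -> list[Crossover]:
    """Walk the upper envelope of the lines over [0, 1]; report the exact
    weights where the argmax changes (ties resolved by input order)."""
    eps = 1e-12
    crossovers: list[Crossover] = []

    def top_at(w: float) -> str:
        best, best_v = order[0], lines[order[0]](w)
        for s in order[1:]:
            v = lines[s](w)
            if v > best_v + eps:
                best, best_v = s, v
        return best

    w = 0.0
    current = top_at(0.0)
    while w < 1.0:
        # earliest strictly-later intersection at which some line overtakes
        candidates = []
        la = lines[current]
        for s in order:
            if s == current:
                continue
            lb = lines[s]
            dslope = lb.slope - la.slope
            if dslope <= eps:
                continue  # cannot overtake a line it does not out-climb
            wx = (la.intercept - lb.intercept) / dslope
            # a tangency exactly at w = 1 is a tie, not an overtaking
            if w - eps < wx < 1.0 - 1e-9:
                candidates.append((max(wx, 0.0), s))
        if not candidates:
            break
        wx = min(c[0] for c in candidates)
        nxt = top_at(min(wx + 1e-9, 1.0))
        if nxt != current:
            crossovers.append(Crossover(min(wx, 1.0), current, nxt))
            current = nxt
        w = wx + 1e-9
    return crossovers


@dataclass
class StabilityResult:
    stable: bool
    flip_weight: Optional[float] = None
    min_change: Optional[float] = None
    new_top: Optional[str] = None


def recommendation_stability(
    model: MCDAModel, partials: Partials, criterion: str
) -> StabilityResult:
    """Smallest single-weight change on ``criterion`` that alters the
    top-ranked alternative, or stability over the whole [0, 1] range."""
    profile = weight_sensitivity(model, partials, criterion)
    if not profile.crossovers:
        return StabilityResult(stable=True)
    w0 = profile.current_weight
    best = min(profile.crossovers, key=lambda x: abs(x.weight - w0))
    return StabilityResult(
        stable=False,
        flip_weight=best.weight,
        min_change=abs(best.weight - w0),
        new_top=best.incoming,
    )


# ---------------------------------------------------------------------------
# Robustness under interval uncertainty
# ---------------------------------------------------------------------------


class Relation(enum.IntEnum):
    """Pairwise relations ordered by strength (larger = stronger)."""

    INCOMPARABLE = 0
    PREFERRED = 1
    ROBUSTLY_PREFERRED = 2
    DOMINATES = 3


@dataclass
class UncertaintyBox:
    """Closed intervals on partial values; unlisted cells are points."""

    intervals: Mapping[tuple[str, str], tuple[float, float]]

    def __post_init__(self):
        self.intervals = dict(self.intervals)
        for key, (lo, hi) in self.intervals.items():
            if lo > hi:
                raise DataError(f"empty interval {lo, hi} at {key}")

    @classmethod
    def symmetric(
        cls,
        frame: pd.DataFrame,
        criteria: Sequence[str],
        halfwidth: float,
    ) -> "UncertaintyBox":
        """+-halfwidth intervals around the nominal partials of the given
        criteria, for every scenario."""
        intervals = {}
        for s in frame.index:
            for c in criteria:
                v = float(frame.at[s, c])
                intervals[(s, c)] = (v - halfwidth, v + halfwidth)
        return cls(intervals)

    def bounds(self, frame: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
        lo = frame.copy()
        hi = frame.copy()
        for (s, c), (a, b) in self.intervals.items():
            if s not in frame.index or c not in frame.columns:
                raise DataError(f"box references unknown cell ({s!r}, {c!r})")
            nominal = float(frame.at[s, c])
            if not a - 1e-12 <= nominal <= b + 1e-12:
                raise DataError(
                    f"interval ({a}, {b}) at ({s!r}, {c!r}) excludes the "
                    f"nominal value {nominal}"
                )
            lo.at[s, c] = a
            hi.at[s, c] = b
        return lo, hi


def robustness(
    model: MCDAModel, partials: Partials, box: Optional[UncertaintyBox] = None
) -> dict[tuple[str, str], Relation]:
    """Pairwise dominance classification under interval uncertainty.

    For each ordered pair (a, b):

    * DOMINATES — every partial interval of a lies at or above b's;
    * ROBUSTLY_PREFERRED — min over the box of V(a) - V(b) >= 0 (vertex:
      lower bounds for a, upper bounds for b);
    * PREFERRED — nominal V(a) > V(b) only;
    * INCOMPARABLE — none of the above.
    """
    frame = partials_frame(partials, model)
    box = box or UncertaintyBox({})
    lo, hi = box.bounds(frame)
    w = pd.Series(dict(model.weights.items()))
    nominal = global_scores(frame, model)
    relations: dict[tuple[str, str], Relation] = {}
    for a in frame.index:
        for b in frame.index:
            if a == b:
                continue
            if (lo.loc[a] >= hi.loc[b] - 1e-12).all():
                rel = Relation.DOMINATES
            elif float((w * (lo.loc[a] - hi.loc[b])).sum()) >= -1e-12:
                rel = Relation.ROBUSTLY_PREFERRED
            elif nominal[a] > nominal[b]:
                rel = Relation.PREFERRED
            else:
                rel = Relation.INCOMPARABLE
            relations[(a, b)] = rel
    return relations


def relation_matrix(
    relations: Mapping[tuple[str, str], Relation], scenarios: Sequence[str]
) -> pd.DataFrame:
    """Relations as a scenario x scenario DataFrame of relation names."""
    mat = pd.DataFrame("", index=list(scenarios), columns=list(scenarios))
    for (a, b), rel in relations.items():
        mat.at[a, b] = rel.name.lower()
    return mat
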