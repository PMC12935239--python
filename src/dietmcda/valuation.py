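"""Performance-to-value conversion and additive aggregation.

Partial values come from piecewise-linear value functions over the
descriptor anchors (exact lookup for categorical descriptors); global
scores are the weighted sum V(a) = sum_j w_j v_j(a) with weights summing
to one.  Missing performance cells contribute zero points (the Neutral
reference) and are reported, mirroring how a blank column is handled in
the case-study tables.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional

import numpy as np

from .model_core import (
    MISSING,
    Criterion,
    DataError,
    EvaluationResult,
    MCDAModel,
    Performance,
    PerformanceTable,
    ValueScale,
)

log = logging.getLogger("dietmcda")


def partial_value(
    criterion: Criterion, scale: ValueScale, performance: Performance
) -> float:
    """Convert one performance entry into value points v_j(a).

    Quantitative descriptors: linear interpolation on the performance axis
    between adjacent anchors, linear extrapolation with the terminal
    segment's slope beyond the extreme anchors (no clamping).  Categorical
    descriptors: exact label lookup.
    """
    if performance is MISSING:
        raise DataError("cannot value a MISSING performance cell")
    if not criterion.is_quantitative:
        if not isinstance(performance, str):
            raise DataError(
                f"descriptor mismatch: criterion {criterion.id!r} is categorical "
                f"but got {performance!r}"
            )
        level = criterion.level_by_label(performance)  # raises "unknown level"
        return scale.value_at_level(level.index)
    if isinstance(performance, str):
        raise DataError(
            f"descriptor mismatch: criterion {criterion.id!r} is quantitative "
            f"but got label {performance!r}"
        )
    x = float(performance)
    if not np.isfinite(x):
        raise DataError(f"non-finite performance {performance!r} on {criterion.id!r}")
    pts = sorted(
        ((float(a.performance), a.value) for a in scale.anchors), key=lambda p: p[0]
    )
    xs = np.array([p[0] for p in pts])
    vs = np.array([p[1] for p in pts])
    if x <= xs[0]:
        slope = (vs[1] - vs[0]) / (xs[1] - xs[0])
        return float(vs[0] + slope * (x - xs[0]))
    if x >= xs[-1]:
        slope = (vs[-1] - vs[-2]) / (xs[-1] - xs[-2])
        return float(vs[-1] + slope * (x - xs[-1]))
    i = int(np.searchsorted(xs, x, side="right")) - 1
    frac = (x - xs[i]) / (xs[i + 1] - xs[i])
    return float(vs[i] + frac * (vs[i + 1] - vs[i]))


def evaluate(
    model: MCDAModel,
    table: PerformanceTable,
    partial_overrides: Optional[Mapping[tuple[str, str], float]] = None,
) -> EvaluationResult:
    """Score every scenario of ``table`` against ``model`` (Eq. V = sum w_j v_j).

    ``partial_overrides`` feeds externally supplied partial values (e.g. the
    published case-study partials) directly into the aggregation, bypassing
    the value functions for those cells.  MISSING cells without an override
    contribute 0 points and are collected in ``missing_cells``.
    """
    overrides = dict(partial_overrides or {})
    table.validate_against(model)
    partials: dict[tuple[str, str], float] = {}
    missing: list[tuple[str, str]] = []
    globals_: dict[str, float] = {}
    for s in table.scenarios:
        row = table.row(s)
        has_content = any(cell is not MISSING for cell in row.values()) or any(
            (s, c) in overrides for c in table.criteria
        )
        if not has_content:
            raise DataError(f"empty alternative: scenario {s!r} has no performance data")
        total = 0.0
        for c in table.criteria:
            w = model.weights[c]
            if (s, c) in overrides:
                v = float(overrides[(s, c)])
            elif row[c] is MISSING:
                v = 0.0
                missing.append((s, c))
                log.warning(
                    "missing cell (%s, %s): contributes 0 points (Neutral)", s, c
                )
            else:
                v = partial_value(model.criterion(c), model.scale(c), row[c])
            partials[(s, c)] = v
            total += w * v
        globals_[s] = total
    result = EvaluationResult(partials, globals_, ranking=[], missing_cells=missing)
    result.ranking = rank(result)
    return result


def rank(result: EvaluationResult) -> list[str]:
    """Scenario ids in strictly descending global-score order (stable ties)."""
    if not result.globals_:
        raise DataError("empty evaluation result")
    order = list(result.globals_)
    return sorted(order, key=lambda s: -result.globals_[s])
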