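"""Substitution-scenario construction, packaged case-study data, and
synthetic generators for property testing.

The packaged case study evaluates replacing 0/25/50/75/100% of beef
consumption with an equivalent amount of pulses in Portugal (PT) and
Denmark (DK): a 14-criterion value model across health, environmental,
economic and social dimensions, the published performance evidence, and
the published partial/global scores for cross-checking.

Intermediate substitution scenarios are built by linear blending between
the reference (f = 0) and full-substitution (f = 1) performance rows;
the published intermediate cells agree with this rule to last-digit
rounding for the environmental indicators.  Health (DALY) columns in the
fixtures are carried as published rather than blended, as their published
trajectory is mildly sublinear in f.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .macbeth import JudgmentMatrix
from .model_core import (
    MISSING,
    Criterion,
    DataError,
    DescriptorLevel,
    MCDAModel,
    Performance,
    PerformanceTable,
    ScaleAnchor,
    Scenario,
    ValueScale,
    WeightVector,
)

COUNTRIES = ("PT", "DK")
SCENARIO_IDS = ("0%", "25%", "50%", "75%", "100%")


def _data(name: str):
    return resources.files("dietmcda").joinpath("data", name)


# ---------------------------------------------------------------------------
# Scenario blending
# ---------------------------------------------------------------------------


@dataclass
class SubstitutionDesign:
    """Reference (f = 0) and endpoint (f = 1) performance rows plus the
    substitution fractions to generate."""

    reference_row: Mapping[str, Performance]
    endpoint_row: Mapping[str, Performance]
    fractions: Sequence[float] = field(default_factory=lambda: (0.25, 0.5, 0.75, 1.0))

    def __post_init__(self):
        self.reference_row = dict(self.reference_row)
        self.endpoint_row = dict(self.endpoint_row)
        if set(self.reference_row) != set(self.endpoint_row):
            raise DataError("reference and endpoint rows cover different criteria")
        for f in self.fractions:
            if not 0.0 <= f <= 1.0:
                raise DataError(f"substitution fraction {f} outside [0, 1]")


def blend_scenario(design: SubstitutionDesign, f: float) -> dict[str, Performance]:
    """Convex combination (1-f)*reference + f*endpoint of quantitative
    cells; categorical/missing cells copied from the nearer endpoint
    (tie -> reference)."""
    if not 0.0 <= f <= 1.0:
        raise DataError(f"substitution fraction {f} outside [0, 1]")
    row: dict[str, Performance] = {}
    for c, ref in design.reference_row.items():
        end = design.endpoint_row[c]
        if isinstance(ref, (int, float)) and isinstance(end, (int, float)):
            row[c] = (1.0 - f) * float(ref) + f * float(end)
        else:
            row[c] = end if f > 0.5 else ref
    return row


def blend_table(
    design: SubstitutionDesign, ids: Sequence[str] | None = None
) -> PerformanceTable:
    """Performance table for f = 0, the design fractions, and their rows."""
    fractions = [0.0, *design.fractions]
    if ids is None:
        ids = [f"{round(100 * f):g}%" for f in fractions]
    criteria = list(design.reference_row)
    cells = {}
    for sid, f in zip(ids, fractions):
        for c, v in blend_scenario(design, f).items():
            cells[(sid, c)] = v
    return PerformanceTable(list(ids), criteria, cells)


# ---------------------------------------------------------------------------
# Packaged case study
# ---------------------------------------------------------------------------


@dataclass
class CaseStudy:
    country: str
    model: MCDAModel
    performance: PerformanceTable
    printed_partials: pd.DataFrame
    printed_globals: dict[str, float]
    scenarios: list[Scenario]
    notes: list[str]

    def printed_overrides(self) -> dict[tuple[str, str], float]:
        """Published partials as an override map for reproduction runs
        (blank published cells are omitted)."""
        overrides = {}
        for s in self.printed_partials.index:
            for c in self.printed_partials.columns:
                v = self.printed_partials.at[s, c]
                if pd.notna(v):
                    overrides[(s, c)] = float(v)
        return overrides


def case_study(country: str) -> CaseStudy:
    """Packaged beef->pulses fixtures for ``country`` in {"PT", "DK"}:
    the 14-criterion model, the performance evidence, and the published
    partial and global scores (annotated printed-vs-recomputed)."""
    from . import io  # deferred: io imports sensitivity

    country = country.upper()
    if country not in COUNTRIES:
        raise DataError(f"unknown country code {country!r} (expected PT or DK)")
    with resources.as_file(_data("beef_pulses_model.json")) as p:
        model = io.load_model(p)
    with resources.as_file(_data(f"performance_{country}.csv")) as p:
        performance = io.load_performance(p, model)
    with resources.as_file(_data(f"printed_partials_{country}.csv")) as p:
        printed = io.load_performance(p)
    partials = io.table_as_frame(printed)
    with _data("printed_globals.json").open(encoding="utf-8") as fh:
        gdoc = json.load(fh)
    scenarios = [
        Scenario(
            id=sid,
            country=country,
            substitution_fraction=float(sid.rstrip("%")) / 100.0,
            description=f"{sid} of beef consumption replaced by pulses",
        )
        for sid in SCENARIO_IDS
    ]
    notes = list(gdoc.get("notes", []))
    notes.append(
        "published rows not reproducible from published partials+weights: "
        + ", ".join(gdoc.get("not_reproducible", {}).get(country, []))
    )
    return CaseStudy(
        country=country,
        model=model,
        performance=performance,
        printed_partials=partials,
        printed_globals={k: float(v) for k, v in gdoc[country].items()},
        scenarios=scenarios,
        notes=notes,
    )


# ---------------------------------------------------------------------------
# Synthetic generators
# ---------------------------------------------------------------------------


def synth_model(seed: int, n_criteria: int = 6, n_levels: int = 5) -> MCDAModel:
    """Random valid model: monotone quantitative descriptors (mixed
    orientations) plus occasional categorical ones, scales anchored at
    Neutral=0/Good=100, positive normalized weights.  Deterministic in
    ``seed``."""
    if n_criteria < 2 or n_levels < 3:
        raise DataError("need n_criteria >= 2 and n_levels >= 3")
    rng = np.random.default_rng(seed)
    criteria, scales = [], []
    for i in range(n_criteria):
        cid = f"c{i + 1}"
        categorical = rng.random() < 0.3
        n = int(rng.integers(3, n_levels + 1))
        good_idx = int(rng.integers(1, n))  # 1-based rank of the Good level
        neutral_idx = int(rng.integers(good_idx, n + 1))
        if neutral_idx == good_idx:
            neutral_idx = min(good_idx + 1, n)
            if neutral_idx == good_idx:  # n == good_idx: shift good up
                good_idx -= 1
        if categorical:
            perfs: list[Performance] = [f"L{k}" for k in range(1, n + 1)]
            kind, unit = "categorical", ""
        else:
            steps = rng.uniform(0.5, 3.0, size=n - 1)
            ascending = rng.random() < 0.5
            vals = np.concatenate([[0.0], np.cumsum(steps)])
            perfs = list(vals if ascending else vals[::-1] * -1 + vals[-1])
            kind, unit = "quantitative", "unit"
        levels = tuple(
            DescriptorLevel(
                index=k,
                performance=perfs[k - 1],
                is_good=(k == good_idx),
                is_neutral=(k == neutral_idx),
            )
            for k in range(1, n + 1)
        )
        criteria.append(
            Criterion(cid, f"criterion {i + 1}", "environmental", kind, unit, levels)
        )
        gaps = rng.uniform(0.2, 2.0, size=n - 1)
        raw = np.concatenate([[0.0], -np.cumsum(gaps)])  # strictly decreasing
        span = raw[good_idx - 1] - raw[neutral_idx - 1]
        values = 100.0 * (raw - raw[neutral_idx - 1]) / span
        scales.append(
            ValueScale(
                cid,
                tuple(
                    ScaleAnchor(k, perfs[k - 1], float(values[k - 1]))
                    for k in range(1, n + 1)
                ),
            )
        )
    raw_w = rng.uniform(0.2, 1.0, size=n_criteria)
    raw_w /= raw_w.sum()
    weights = WeightVector({c.id: float(w) for c, w in zip(criteria, raw_w)})
    return MCDAModel(
        criteria, scales, weights, metadata={"name": f"synthetic-{seed}"}
    )


def generate_consistent_matrix(
    seed: int, n_entities: int = 5
) -> tuple[JudgmentMatrix, dict[str, float]]:
    """Judgment matrix drawn from a hidden cardinal scale.

    Pairwise value differences are binned into the six positive semantic
    categories by fixed thresholds (equal sixths of the largest
    difference), which guarantees consistency: a strictly stronger
    category always corresponds to a strictly larger hidden difference.
    Returns the matrix and the hidden scale for recovery tests.
    """
    if n_entities < 2:
        raise DataError("need at least 2 entities")
    rng = np.random.default_rng(seed)
    values = np.sort(rng.uniform(0.0, 100.0, size=n_entities))[::-1]
    while np.min(np.abs(np.diff(values))) < 1e-3:  # ensure distinct levels
        values = np.sort(rng.uniform(0.0, 100.0, size=n_entities))[::-1]
    entities = [f"e{i + 1}" for i in range(n_entities)]
    hidden = {e: float(v) for e, v in zip(entities, values)}
    matrix = JudgmentMatrix(entities)
    max_diff = values[0] - values[-1]
    for i in range(n_entities):
        for j in range(i + 1, n_entities):
            d = values[i] - values[j]
            category = min(6, 1 + int(6.0 * d / (max_diff * (1.0 + 1e-9))))
            matrix.judge(entities[i], entities[j], category)
    return matrix, hidden
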