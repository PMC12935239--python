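"""Readers, writers and report generation.

Model files are a single JSON document (``schema_version`` 1) with top-level
keys ``criteria``, ``scales``, ``weights``, ``metadata``.  Performance and
partial-value tables are comma-separated UTF-8 text: first column the
scenario id, one column per criterion id, blank cell = MISSING.  Numeric
cells tolerate the European decimal comma (``-7,90``) and the U+2212 minus
sign; conversions are logged.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from .model_core import (
    MISSING,
    Criterion,
    DataError,
    DescriptorLevel,
    EvaluationResult,
    MCDAModel,
    PerformanceTable,
    ScaleAnchor,
    ValueScale,
    WeightVector,
)
from .macbeth import JudgmentMatrix
from .sensitivity import UncertaintyBox

log = logging.getLogger("dietmcda")

SCHEMA_VERSION = 1

_DECIMAL_COMMA = re.compile(r"^-?\d+,\d+$")


class SchemaError(DataError):
    """Model/table file does not match the published schema."""

    def __init__(self, path, key, message):
        super().__init__(f"{path}: key {key!r}: {message}")
        self.path = str(path)
        self.key = key


def parse_number(text: str, context: str = "") -> float:
    """Parse a numeric cell, normalizing U+2212 and decimal commas."""
    raw = text.strip()
    cleaned = raw.replace("−", "-")
    if _DECIMAL_COMMA.match(cleaned):
        cleaned = cleaned.replace(",", ".")
    if cleaned != raw:
        log.info("normalized numeric token %r -> %r %s", raw, cleaned, context)
    return float(cleaned)


# ---------------------------------------------------------------------------
# Model files
# ---------------------------------------------------------------------------


def model_to_dict(model: MCDAModel) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "metadata": dict(model.metadata),
        "criteria": [
            {
                "id": c.id,
                "name": c.name,
                "dimension": c.dimension,
                "descriptor_kind": c.descriptor_kind,
                "unit": c.unit,
                "levels": [
                    {
                        "index": lv.index,
                        "performance": lv.performance,
                        "is_neutral": lv.is_neutral,
                        "is_good": lv.is_good,
                        "description": lv.description,
                    }
                    for lv in c.levels
                ],
            }
            for c in model.criteria
        ],
        "scales": [
            {
                "criterion_id": s.criterion_id,
                "anchors": [
                    {
                        "level_index": a.level_index,
                        "performance": a.performance,
                        "value": a.value,
                    }
                    for a in s.anchors
                ],
            }
            for s in model.scales
        ],
        "weights": dict(model.weights.weights),
    }


def _require(d: dict, key: str, path) -> object:
    if key not in d:
        raise SchemaError(path, key, "missing required key")
    return d[key]


def model_from_dict(doc: dict, path: Union[str, Path] = "<memory>") -> MCDAModel:
    if not isinstance(doc, dict):
        raise SchemaError(path, "", "top level must be a JSON object")
    version = _require(doc, "schema_version", path)
    if version != SCHEMA_VERSION:
        raise SchemaError(path, "schema_version", f"unsupported version {version!r}")
    criteria = []
    for cd in _require(doc, "criteria", path):
        levels = tuple(
            DescriptorLevel(
                index=int(_require(ld, "index", path)),
                performance=_require(ld, "performance", path),
                is_neutral=bool(ld.get("is_neutral", False)),
                is_good=bool(ld.get("is_good", False)),
                description=ld.get("description", ""),
            )
            for ld in _require(cd, "levels", path)
        )
        criteria.append(
            Criterion(
                id=str(_require(cd, "id", path)),
                name=str(_require(cd, "name", path)),
                dimension=str(_require(cd, "dimension", path)),
                descriptor_kind=str(_require(cd, "descriptor_kind", path)),
                unit=str(cd.get("unit", "")),
                levels=levels,
            )
        )
    scales = []
    for sd in _require(doc, "scales", path):
        anchors = tuple(
            ScaleAnchor(
                level_index=int(_require(ad, "level_index", path)),
                performance=_require(ad, "performance", path),
                value=float(_require(ad, "value", path)),
            )
            for ad in _require(sd, "anchors", path)
        )
        scales.append(ValueScale(str(_require(sd, "criterion_id", path)), anchors))
    weights_doc = _require(doc, "weights", path)
    if not isinstance(weights_doc, dict):
        raise SchemaError(path, "weights", "must map criterion id -> weight")
    weights = WeightVector({str(k): float(v) for k, v in weights_doc.items()})
    return MCDAModel(criteria, scales, weights, metadata=dict(doc.get("metadata", {})))


def load_model(path: Union[str, Path]) -> MCDAModel:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(path, "", f"not valid JSON: {exc}") from exc
    return model_from_dict(doc, path)


def save_model(model: MCDAModel, path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_to_dict(model), fh, indent=1, ensure_ascii=False)
        fh.write("\n")


def model_checksum(model: MCDAModel) -> str:
    """SHA-256 of the canonical (sorted-key) JSON serialization."""
    blob = json.dumps(model_to_dict(model), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


# ---------------------------------------------------------------------------
# Performance / partial tables (CSV)
# ---------------------------------------------------------------------------


def load_performance(
    path: Union[str, Path], model: Optional[MCDAModel] = None
) -> PerformanceTable:
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    if frame.columns[0] != "scenario":
        raise SchemaError(path, frame.columns[0], "first column must be 'scenario'")
    criteria = list(frame.columns[1:])
    if model is not None:
        known = set(model.criterion_ids)
        for col in criteria:
            if col not in known:
                raise SchemaError(path, col, "column is not a model criterion")
    scenarios = list(frame["scenario"])
    cells = {}
    for _, rec in frame.iterrows():
        s = rec["scenario"]
        for c in criteria:
            raw = str(rec[c]).strip()
            if raw == "":
                cells[(s, c)] = MISSING
                continue
            quantitative = model is None or model.criterion(c).is_quantitative
            if quantitative:
                try:
                    cells[(s, c)] = parse_number(raw, context=f"({s}, {c})")
                except ValueError:
                    if model is not None:
                        raise SchemaError(path, c, f"non-numeric cell {raw!r}")
                    cells[(s, c)] = raw
            else:
                cells[(s, c)] = raw
    table = PerformanceTable(scenarios, criteria, cells)
    if model is not None:
        table.validate_against(model)
    return table


def save_performance(table: PerformanceTable, path: Union[str, Path]) -> None:
    rows = []
    for s in table.scenarios:
        row = {"scenario": s}
        for c in table.criteria:
            cell = table[(s, c)]
            row[c] = "" if cell is MISSING else cell
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def table_as_frame(table: PerformanceTable) -> pd.DataFrame:
    """Performance table as a DataFrame (MISSING -> NaN), scenario-indexed."""
    data = {
        c: [
            float("nan") if table[(s, c)] is MISSING else table[(s, c)]
            for s in table.scenarios
        ]
        for c in table.criteria
    }
    return pd.DataFrame(data, index=table.scenarios)


# ---------------------------------------------------------------------------
# Judgment matrices, uncertainty boxes
# ---------------------------------------------------------------------------


def load_judgments(path: Union[str, Path]) -> JudgmentMatrix:
    """JSON file: {"entities": [...], "judgments": [[a, b, category], ...]}."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    matrix = JudgmentMatrix(_require(doc, "entities", path))
    for item in _require(doc, "judgments", path):
        if len(item) != 3:
            raise SchemaError(path, "judgments", f"expected [a, b, category], got {item!r}")
        a, b, category = item
        matrix.judge(a, b, tuple(category) if isinstance(category, list) else category)
    return matrix


def load_box(path: Union[str, Path]) -> UncertaintyBox:
    """JSON file: list of {"scenario", "criterion", "lo", "hi"} records."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    intervals = {}
    for rec in doc:
        intervals[(rec["scenario"], rec["criterion"])] = (
            float(rec["lo"]),
            float(rec["hi"]),
        )
    return UncertaintyBox(intervals)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def report_dict(
    result: EvaluationResult,
    model: Optional[MCDAModel] = None,
    seed: Optional[int] = None,
    notes: Optional[list[str]] = None,
) -> dict:
    doc = {
        "partials": {f"{s}|{c}": v for (s, c), v in result.partials.items()},
        "globals": dict(result.globals_),
        "ranking": list(result.ranking),
        "missing_cells": [list(k) for k in result.missing_cells],
        "seed": seed,
        "notes": list(notes or []),
    }
    if model is not None:
        doc["model_checksum"] = model_checksum(model)
        doc["model_provenance"] = model.metadata.get("provenance", "")
    return doc


def write_report(
    result: EvaluationResult,
    path: Union[str, Path],
    model: Optional[MCDAModel] = None,
    seed: Optional[int] = None,
    notes: Optional[list[str]] = None,
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report_dict(result, model, seed, notes), fh, indent=1)
        fh.write("\n")


def write_table4_layout(
    result: EvaluationResult, criteria: list[str], path: Union[str, Path]
) -> None:
    """Delimited-text export mirroring the published layout: one row per
    scenario (global score first), criterion partials as columns."""
    rows = []
    for s in result.ranking:
        row = {"scenario": s, "overall": round(result.globals_[s], 2)}
        for c in criteria:
            row[c] = round(result.partials[(s, c)], 2)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
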