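"""Cohort CSV and model/report JSON round-trips.

Cohort files are plain UTF-8 CSV, one row per subject, header mandatory,
empty cell = missing; fractions are stored as fractions (0.94, not 94%).
Every JSON artifact written here embeds the seed and a short config hash so
any output can be traced back to the run that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from pathlib import Path
from typing import Sequence

import pandas as pd

from .battery import ASSESSMENTS, AssessmentSpec, CompositeModel, SubjectRecord
from .errors import InvalidInputError, ParseError

COHORT_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    *ASSESSMENTS,
    "slums",
    "mmse",
    "moca",
    "physician_label",
]

_REFERENCES = ("slums", "mmse", "moca")


def read_cohort(path: str | Path) -> list[SubjectRecord]:
    """Parse a cohort CSV into subject records with row-numbered diagnostics."""
    df = pd.read_csv(path, dtype=str)
    unknown = set(df.columns) - set(COHORT_COLUMNS)
    if unknown:
        raise ParseError(f"unknown columns {sorted(unknown)}")
    if "subject_id" not in df.columns:
        raise ParseError("missing required column subject_id")

    records: list[SubjectRecord] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # header is line 1
        cell = lambda c: None if c not in df.columns or pd.isna(row[c]) or str(row[c]).strip() == "" else str(row[c]).strip()

        sid = cell("subject_id")
        if sid is None:
            raise ParseError("empty subject_id", row=rownum)

        raw: dict[str, float] = {}
        for name in ASSESSMENTS:
            v = cell(name)
            if v is None:
                continue
            try:
                raw[name] = float(v)
            except ValueError:
                raise ParseError(f"non-numeric value {v!r} for {name}", row=rownum)

        refs: dict[str, int] = {}
        for ref in _REFERENCES:
            v = cell(ref)
            if v is None:
                continue
            try:
                score = int(float(v))
            except ValueError:
                raise ParseError(f"non-numeric {ref} score {v!r}", row=rownum)
            if not 0 <= score <= 30:
                raise ParseError(
                    f"{ref}={score} outside the 0-30 scale", row=rownum
                )
            refs[ref] = score

        age = cell("age")
        try:
            record = SubjectRecord(
                subject_id=sid,
                raw_metrics=raw,
                age=float(age) if age is not None else None,
                sex=cell("sex"),
                physician_label=cell("physician_label"),
                **refs,
            )
        except InvalidInputError as exc:
            raise ParseError(str(exc), row=rownum)
        records.append(record)
    return records


def write_cohort(records: Sequence[SubjectRecord], path: str | Path) -> None:
    """Write subject records as a cohort CSV (inverse of :func:`read_cohort`)."""
    rows = []
    for r in records:
        row = {
            "subject_id": r.subject_id,
            "age": r.age,
            "sex": r.sex,
            "slums": r.slums,
            "mmse": r.mmse,
            "moca": r.moca,
            "physician_label": r.physician_label,
        }
        for name in ASSESSMENTS:
            row[name] = r.raw_metrics.get(name)
        rows.append(row)
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    df.to_csv(path, index=False)


def config_hash(obj) -> str:
    """Short stable hash of a (dataclass or dict) configuration."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        obj = dataclasses.asdict(obj)
    payload = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_artifact(path: str | Path, payload: dict, seed: int | None, config=None) -> None:
    """Write a JSON artifact stamped with its seed and config hash."""
    payload = dict(payload)
    payload["seed"] = seed
    if config is not None:
        payload["config_hash"] = config_hash(config)
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, float) and math.isnan(obj):
        return None
    if hasattr(obj, "item"):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    return str(obj)


def model_to_json(model: CompositeModel, path: str | Path, seed: int | None = None) -> None:
    """Serialize a composite model (weights, specs, total) to JSON."""
    payload = {
        "total": model.total,
        "weights": model.weights,
        "specs": {
            name: {
                "metric_kind": s.metric_kind,
                "direction": s.direction,
                "scale_min": s.scale_min,
                "scale_max": s.scale_max,
            }
            for name, s in model.specs.items()
        },
    }
    write_artifact(path, payload, seed=seed, config=payload["weights"])


def model_from_json(path: str | Path) -> CompositeModel:
    """Load a composite model; weight-sum and spec invariants are re-checked."""
    data = json.loads(Path(path).read_text())
    specs = {
        name: AssessmentSpec(
            name=name,
            metric_kind=s["metric_kind"],
            direction=s["direction"],
            scale_min=float(s["scale_min"]),
            scale_max=float(s["scale_max"]),
        )
        for name, s in data["specs"].items()
    }
    return CompositeModel(
        weights={k: float(v) for k, v in data["weights"].items()},
        specs=specs,
        total=float(data["total"]),
    )
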