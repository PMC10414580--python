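"""Readers, writers and configuration loading.

Label files are CSV (columns ``instance_id,truth,prediction`` with
pipe-separated code lists) or JSON (array of ``{id, truth, prediction}``
objects).  Two-file mode joins separate truth and prediction files by
instance id.  Configuration is JSON or YAML with keys ``codes``,
``normal_code``, ``significance`` (map or scalar), ``similarity`` (matrix or
scalar w0), ``contradiction`` (list of code pairs) and ``prevalence_floor``.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import yaml

from .label_model import (
    DiagnosisCatalog,
    InstancePair,
    MetricConfig,
    ValidationError,
)

__all__ = [
    "RunReport",
    "read_label_file",
    "read_label_sets",
    "join_truth_prediction",
    "load_config",
    "write_report",
    "write_label_file",
]

log = logging.getLogger("medtric")

_VERSION = "0.1.0"


# ---------------------------------------------------------------------------
# Label files
# ---------------------------------------------------------------------------


def _split_labels(text: str) -> frozenset[str]:
    parts = [p.strip() for p in text.strip().lstrip("﻿").split("|")]
    labels = [p for p in parts if p]
    if len(labels) != len(set(labels)):
        log.warning("duplicate labels collapsed in field %r", text)
    return frozenset(labels)


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt:
        return fmt
    return "json" if path.suffix.lower() == ".json" else "csv"


def read_label_file(
    path: str | Path,
    fmt: str | None = None,
    catalog: DiagnosisCatalog | None = None,
) -> list[InstancePair]:
    """Read combined truth+prediction instances from CSV or JSON.

    Empty prediction fields are valid (the inactive classifier); empty truth
    fields are rejected.  When a catalog is supplied, unknown codes raise
    immediately, naming the offending instance.
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    pairs: list[InstancePair] = []
    if fmt == "json":
        data = json.loads(path.read_text(encoding="utf-8-sig"))
        for i, row in enumerate(data):
            try:
                pairs.append(
                    InstancePair(
                        str(row.get("id", row.get("instance_id", i))),
                        frozenset(str(c).strip() for c in row["truth"]),
                        frozenset(str(c).strip() for c in row.get("prediction", [])),
                    )
                )
            except (KeyError, TypeError) as exc:
                raise ValidationError(f"{path}: malformed JSON record {i}: {exc}") from exc
    elif fmt == "csv":
        with path.open(newline="", encoding="utf-8-sig") as fh:
            reader = csv.DictReader(fh)
            required = {"instance_id", "truth", "prediction"}
            if reader.fieldnames is None or not required <= set(
                name.strip() for name in reader.fieldnames
            ):
                raise ValidationError(
                    f"{path}: CSV must have columns instance_id,truth,prediction"
                )
            for lineno, row in enumerate(reader, start=2):
                try:
                    pairs.append(
                        InstancePair(
                            row["instance_id"].strip(),
                            _split_labels(row["truth"]),
                            _split_labels(row["prediction"]),
                        )
                    )
                except (AttributeError, KeyError) as exc:
                    raise ValidationError(f"{path}: malformed row at line {lineno}") from exc
    else:
        raise ValidationError(f"unknown label file format {fmt!r}")

    for pair in pairs:
        if not pair.truth:
            raise ValidationError(
                f"{path}: instance {pair.instance_id!r} has an empty ground truth"
            )
        if catalog is not None:
            for code in pair.truth | pair.prediction:
                if code not in catalog:
                    raise ValidationError(
                        f"{path}: instance {pair.instance_id!r}: unknown code {code!r}"
                    )
    return pairs


def read_label_sets(
    path: str | Path, fmt: str | None = None
) -> dict[str, frozenset[str]]:
    """Read a single-column label file (``instance_id,labels``) into a map."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    out: dict[str, frozenset[str]] = {}
    if fmt == "json":
        data = json.loads(path.read_text(encoding="utf-8-sig"))
        for i, row in enumerate(data):
            out[str(row.get("id", row.get("instance_id", i)))] = frozenset(
                str(c).strip() for c in row["labels"]
            )
    else:
        with path.open(newline="", encoding="utf-8-sig") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"instance_id", "labels"} <= set(
                name.strip() for name in reader.fieldnames
            ):
                raise ValidationError(f"{path}: CSV must have columns instance_id,labels")
            for row in reader:
                out[row["instance_id"].strip()] = _split_labels(row["labels"])
    return out


def join_truth_prediction(
    truths: dict[str, frozenset[str]], predictions: dict[str, frozenset[str]]
) -> list[InstancePair]:
    """Join separate truth and prediction maps by instance id (strict)."""
    missing = set(truths) ^ set(predictions)
    if missing:
        raise ValidationError(
            f"truth/prediction ids do not match; unmatched ids: {sorted(missing)[:10]}"
        )
    return [InstancePair(i, truths[i], predictions[i]) for i in sorted(truths)]


def write_label_file(
    pairs: Sequence[InstancePair], path: str | Path
) -> None:
    """Write instances as combined CSV with pipe-separated label sets."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["instance_id", "truth", "prediction"])
        for p in pairs:
            writer.writerow(
                [p.instance_id, "|".join(sorted(p.truth)), "|".join(sorted(p.prediction))]
            )


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> tuple[DiagnosisCatalog, MetricConfig]:
    """Load catalog + metric configuration from JSON or YAML.

    Scalar shorthands broadcast: a scalar ``significance`` applies to every
    class; a scalar ``similarity`` w0 fills the off-diagonal.  All
    MetricConfig invariants (s_j > 0, w in (0,1) off-diagonal with unit
    diagonal, C symmetric binary zero-diagonal) are enforced on load.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8-sig")
    data = yaml.safe_load(text)
    if not isinstance(data, dict) or "codes" not in data:
        raise ValidationError(f"{path}: config must be a mapping with a 'codes' key")
    catalog = DiagnosisCatalog(
        codes=tuple(str(c) for c in data["codes"]),
        normal_code=data.get("normal_code"),
    )
    config = MetricConfig.create(
        catalog,
        significance=data.get("significance", 1.0),
        similarity=data.get("similarity", 0.5),
        contradiction=[tuple(p) for p in data.get("contradiction", [])] or None,
        prevalence_floor=data.get("prevalence_floor", 1),
    )
    return catalog, config


def config_digest(config: MetricConfig) -> str:
    """Stable digest of the resolved configuration, for report provenance."""
    h = hashlib.sha256()
    h.update(",".join(config.catalog.codes).encode())
    h.update(str(config.catalog.normal_code).encode())
    h.update(np.ascontiguousarray(config.similarity).tobytes())
    h.update(np.ascontiguousarray(config.contradiction).tobytes())
    h.update(json.dumps(config.significance, sort_keys=True).encode())
    h.update(str(config.prevalence_floor).encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


@dataclass
class RunReport:
    """Machine-readable record of one scoring or experiment run."""

    command: str
    config_digest: str
    scores: dict[str, Any] = field(default_factory=dict)
    experiments: dict[str, Any] = field(default_factory=dict)
    seed: int | None = None
    version: str = _VERSION
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def to_dict(self) -> dict[str, Any]:
        return {
            "version": self.version,
            "command": self.command,
            "config_digest": self.config_digest,
            "seed": self.seed,
            "timestamp": self.timestamp,
            "scores": _round_floats(self.scores),
            "experiments": _round_floats(self.experiments),
        }


def _round_floats(obj: Any) -> Any:
    if isinstance(obj, float):
        return float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v) for v in obj]
    return obj


def write_report(report: RunReport, path: str | Path, fmt: str = "json") -> None:
    """Write a report as JSON (nested) or CSV (flat key,value rows)."""
    path = Path(path)
    data = report.to_dict()
    if fmt == "json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    elif fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh)
            writer.writerow(["key", "value"])
            for key, value in sorted(_flatten(data).items()):
                writer.writerow([key, value])
    else:
        raise ValidationError(f"unknown report format {fmt!r}")


def _flatten(obj: Any, prefix: str = "") -> dict[str, Any]:
    out: dict[str, Any] = {}
    if isinstance(obj, dict):
        for k, v in obj.items():
            out.update(_flatten(v, f"{prefix}{k}." if prefix else f"{k}."))
    elif isinstance(obj, (list, tuple)):
        for i, v in enumerate(obj):
            out.update(_flatten(v, f"{prefix}{i}."))
    else:
        out[prefix.rstrip(".")] = obj
    return out
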