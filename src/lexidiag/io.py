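"""Configuration loading and report writing.

Configs are YAML or JSON mappings; unknown keys are rejected by name so typos
surface immediately.  Reports are written as machine-readable JSON (with a
``schema_version`` field and the seed that produced them) plus a short
human-readable Markdown summary; trial logs go to CSV and cohorts to JSONL.
All segment coordinates in serialized plans are 0-based, half-open, over the
letters-only stream.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import pandas as pd
import yaml

from ._errors import ConfigurationError
from .causal import CausalClassification, CauseReport
from .segmentation import SegmentPlan
from .staircase import DiagnosticResult, StaircaseConfig, TrialRecord
from .therapy import TherapyOutcome

__all__ = ["SCHEMA_VERSION", "RunConfig", "load_config", "save_config", "write_report", "write_trial_log"]

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Cross-command run settings plus the staircase protocol constants."""

    seed: Optional[int] = None
    out: Optional[str] = None
    log: Optional[str] = None
    language: str = "de"
    verbosity: int = 0
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "out": self.out,
            "log": self.log,
            "language": self.language,
            "verbosity": self.verbosity,
            "staircase": dataclasses.asdict(self.staircase),
        }


def _load_mapping(path) -> Mapping:
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith(".json"):
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    if not isinstance(data, Mapping):
        raise ConfigurationError(f"config root in {path} must be a mapping")
    return data


def _build_staircase(d: Mapping) -> StaircaseConfig:
    known = {f.name for f in dataclasses.fields(StaircaseConfig)}
    unknown = set(d) - known
    if unknown:
        raise ConfigurationError(f"unknown staircase config key: {sorted(unknown)[0]!r}")
    return StaircaseConfig(**d)


def load_config(path) -> RunConfig:
    """Load and validate a run config, applying the protocol defaults for any
    key not given."""
    data = dict(_load_mapping(path))
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigurationError(f"unknown config key: {sorted(unknown)[0]!r}")
    staircase = _build_staircase(data.pop("staircase", {}) or {})
    try:
        return RunConfig(staircase=staircase, **data)
    except TypeError as exc:
        raise ConfigurationError(str(exc)) from exc


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True), encoding="utf-8")


def write_trial_log(log: Sequence[TrialRecord], path) -> None:
    frame = pd.DataFrame(
        [
            {
                "phase": r.phase.value,
                "item": r.item,
                "presentation_ms": r.presentation_ms,
                "allowed_vrt_ms": r.allowed_vrt_ms,
                "correct": r.correct,
            }
            for r in log
        ]
    )
    frame.to_csv(path, index=False)


def _payload(result: Any) -> tuple[str, dict]:
    if isinstance(result, DiagnosticResult):
        return "diagnostic_result", result.to_dict()
    if isinstance(result, CausalClassification):
        return "causal_classification", result.to_dict()
    if isinstance(result, CauseReport):
        return "cause_report", result.to_dict()
    if isinstance(result, SegmentPlan):
        return "segment_plan", result.to_dict()
    if isinstance(result, TherapyOutcome):
        return "therapy_outcome", result.to_dict()
    if hasattr(result, "to_dict"):
        return type(result).__name__, result.to_dict()
    raise TypeError(f"cannot serialize result of type {type(result).__name__}")


def _markdown(kind: str, body: dict, meta: dict) -> str:
    lines = [f"# lexidiag report: {kind}", ""]
    for k, v in meta.items():
        lines.append(f"- {k}: {v}")
    lines.append("")
    for k, v in body.items():
        lines.append(f"- **{k}**: {v}")
    lines.append("")
    return "\n".join(lines)


def write_report(
    result: Any,
    path,
    seed: Optional[int] = None,
    extra_meta: Optional[Mapping] = None,
) -> dict:
    """Write ``result`` as JSON to ``path`` (plus a Markdown twin next to it)
    and return the JSON document.

    A :class:`TherapyOutcome` additionally writes its per-reader table to a
    CSV side-car.
    """
    kind, body = _payload(result)
    meta = {"schema_version": SCHEMA_VERSION, "seed": seed}
    if extra_meta:
        meta.update(extra_meta)
    text = json.dumps({"kind": kind, **meta, "result": body}, indent=2, sort_keys=True)
    doc = json.loads(text)  # round-trip so callers see JSON-normalized keys
    path = Path(path)
    path.write_text(text, encoding="utf-8")
    path.with_suffix(".md").write_text(_markdown(kind, body, meta), encoding="utf-8")
    if isinstance(result, TherapyOutcome):
        result.per_reader.to_csv(path.with_suffix(".readers.csv"), index=False)
    return doc
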