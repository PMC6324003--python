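"""Run configuration: thresholds, alignment scoring, seed, date pin.

A single YAML file configures a run; every field has the documented default
so an empty file (or no file) is valid.  ``date_pin`` fixes the generation
date written into CSV comment lines, making whole-pipeline output
byte-stable.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Union

import yaml

from .errors import InvalidInputError
from .seq import AlignmentParams
from .uniref import (
    CLUSTER_SIZE_CAP,
    COVERAGE_GATE,
    IDENTITY_THRESHOLD,
    OVERLAP_THRESHOLD,
)


@dataclass
class SiftsConfig:
    alignment: AlignmentParams = field(default_factory=AlignmentParams)
    cluster_identity: float = IDENTITY_THRESHOLD
    cluster_overlap: float = OVERLAP_THRESHOLD
    overlap_denominator: str = "seed"  # or "shorter"
    coverage_gate: float = COVERAGE_GATE
    cluster_size_cap: int = CLUSTER_SIZE_CAP
    seed: int = 0
    date_pin: Optional[str] = None  # YYYY-MM-DD; None -> today at run time

    def generation_date(self) -> str:
        if self.date_pin is not None:
            return self.date_pin
        return _dt.date.today().isoformat()

    def to_yaml(self, path: Union[str, Path]) -> None:
        data = asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SiftsConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise InvalidInputError(f"{path}: config must be a mapping")
        align_raw = raw.pop("alignment", {}) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "alignment"}
        unknown = set(raw) - known
        if unknown:
            raise InvalidInputError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(alignment=AlignmentParams(**align_raw), **raw)
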