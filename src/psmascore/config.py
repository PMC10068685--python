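"""Pipeline configuration with lossless JSON round-trip.

Unknown keys are rejected rather than ignored, so a typo in a config
file fails loudly instead of silently running defaults.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from .hotspot import HotspotParams


@dataclass
class PipelineConfig:
    """Everything the quantification/response pipeline needs to run."""

    hotspot: HotspotParams = field(default_factory=HotspotParams)
    reference_choice: str = "blood_pool"
    rounding: str = "half_away_int"  # display rounding of percent changes
    listwise_deletion: bool = False  # pairwise-complete by default
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.reference_choice not in ("blood_pool", "liver"):
            raise ValueError(f"unknown reference_choice {self.reference_choice!r}")
        if self.rounding not in ("half_away_int", "none"):
            raise ValueError(f"unknown rounding mode {self.rounding!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        hs = data.pop("hotspot", {})
        known = {f.name for f in dataclasses.fields(cls)} - {"hotspot"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        hs_known = {f.name for f in dataclasses.fields(HotspotParams)}
        hs_unknown = set(hs) - hs_known
        if hs_unknown:
            raise ValueError(f"unknown hotspot config keys: {sorted(hs_unknown)}")
        return cls(hotspot=HotspotParams(**hs), **data)

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        path = Path(source)
        text = path.read_text() if path.exists() else str(source)
        return cls.from_dict(json.loads(text))
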