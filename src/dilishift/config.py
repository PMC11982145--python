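"""Run configuration for the end-to-end screening pipeline (YAML round-trip)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .categorize import BandingScheme

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    input_csv: str = ""
    column_map: dict[str, str] = field(default_factory=dict)
    active_arm: str = "active"
    comparator_arm: str = "placebo"
    treatment_end_day: int = 336
    followup_lag_days: int = 30
    alt_cut: float = 3.0
    tb_cut: float = 2.0
    extra_tb_band: bool = False
    split_nnn: bool = False
    at_policy: str = "alt"
    waterfall_mode: str = "max_magnitude"
    force_waterfall: bool = False
    active_only: bool = False
    severity_lines: list[float] = field(default_factory=lambda: [300.0, 600.0, 900.0])
    abnormal_fraction_threshold: float = 0.05
    output_dir: str = "dilishift_out"
    seed: int = 0

    def scheme(self) -> BandingScheme:
        return BandingScheme(
            alt_cut=self.alt_cut,
            tb_cut=self.tb_cut,
            extra_tb_band=self.extra_tb_band,
            split_nnn=self.split_nnn,
        )

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)
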