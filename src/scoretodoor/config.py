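"""Run configuration: one YAML file drives the whole pipeline.

Example::

    seed: 7
    output_dir: out
    band_table: news2_scale1        # or news_2012, or a path to a YAML table
    thresholds: {high: 7, floor: 5, cap_hours: 168}
    inputs:
      observations: out/observations.csv
      events: out/events.csv
      covariates: out/covariates.csv
      outcomes: out/outcomes.csv
    columns:                        # optional renames, standard -> file column
      observations: {spo2: SpO2}
    models:
      bootstrap_B: 2000
    simulate:
      n_patients: 500
      frac_ed_direct: 0.5
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .cohort import DerivationConfig
from .simulate import GeneratorConfig


@dataclasses.dataclass
class RunConfig:
    seed: int = 0
    output_dir: str = "out"
    band_table: str = "news2_scale1"
    thresholds: dict = dataclasses.field(default_factory=dict)
    inputs: dict = dataclasses.field(default_factory=dict)
    columns: dict = dataclasses.field(default_factory=dict)
    models: dict = dataclasses.field(default_factory=dict)
    simulate: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.derivation_config()  # validates thresholds eagerly
        return cfg

    def derivation_config(self) -> DerivationConfig:
        t = self.thresholds
        return DerivationConfig(
            high_threshold=int(t.get("high", 7)),
            floor=int(t.get("floor", 5)),
            cap_hours=float(t.get("cap_hours", 168)),
            complete_case=bool(t.get("complete_case", True)),
        )

    def generator_config(self) -> GeneratorConfig:
        kwargs = dict(self.simulate)
        kwargs.setdefault("seed", self.seed)
        kwargs.setdefault("band_version", self.band_table)
        return GeneratorConfig(**kwargs)

    def input_path(self, name: str) -> Path:
        if name in self.inputs:
            return Path(self.inputs[name])
        return Path(self.output_dir) / f"{name}.csv"

    @property
    def bootstrap_B(self) -> int:
        return int(self.models.get("bootstrap_B", 2000))
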