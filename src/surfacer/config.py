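"""Run configuration: a flat YAML schema with strict key validation."""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields
from pathlib import Path

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    fasta: str | None = None
    topology: str | None = None
    surface_predictions: str | None = None
    psm_table: str | None = None
    dialect: str = "generic"
    intensity_matrix: str | None = None
    design: str | None = None
    include_nxc: bool = False
    missed_cleavages: int = 0
    signal_peptide_rule: str = "any"
    fc_threshold: float = 1.5
    alpha: float = 0.05
    fc_scale: str = "log2"
    min_experiments: int = 1
    seed: int = 0
    out_dir: str = "surfacer_out"

    def validate(self) -> "RunConfig":
        if self.dialect not in ("generic", "pd"):
            raise ConfigError(f"unknown dialect {self.dialect!r}")
        if self.signal_peptide_rule not in ("any", "majority"):
            raise ConfigError(
                f"unknown signal_peptide_rule {self.signal_peptide_rule!r}"
            )
        if self.fc_scale not in ("log2", "ratio"):
            raise ConfigError(f"unknown fc_scale {self.fc_scale!r}")
        if not 0 <= self.missed_cleavages <= 2:
            raise ConfigError("missed_cleavages must be in 0..2")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.fc_threshold < 0:
            raise ConfigError("fc_threshold must be >= 0")
        if self.min_experiments < 1:
            raise ConfigError("min_experiments must be >= 1")
        return self

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def validate_config(path: str | Path) -> RunConfig:
    """Load a YAML config, rejecting unknown keys and filling defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw).validate()
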