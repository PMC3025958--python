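"""Pipeline thresholds and their YAML override mechanism."""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable threshold of the pipeline, with its default value.

    Defaults mirror the published analysis settings where one exists
    (flank, window, boot_reps, core_thresh, z_min, fold_min,
    diffscore_min, density_min, detection_p_max); the rest are documented
    open choices.
    """

    flank: int = 1000              # bp added to each side of a peak
    window: int = 10_000           # bp for gene linking and locus proximity
    boot_reps: int = 1000          # bootstrap replicates
    core_thresh: float = 0.75      # minimum core similarity for a PWM hit
    mat_thresh: float = 0.80       # minimum matrix similarity for a PWM hit
    z_min: float = 3.0             # over-representation Z-score cutoff
    fold_min: float = 4.0          # over-representation fold cutoff
    diffscore_min: float = 40.0    # |DiffScore| significance threshold
    density_min: float = 0.5       # minimum tag density (tags / bp)
    detection_p_max: float = 0.01  # detection p-value cutoff (strictly below)
    promoter_bp: int = 1000        # promoter extent upstream of the TSS
    seed: int | None = None

    def validate(self) -> None:
        if self.flank < 0 or self.window < 0 or self.promoter_bp < 0:
            raise ValueError("flank/window/promoter_bp must be >= 0")
        if self.boot_reps < 1:
            raise ValueError("boot_reps must be >= 1")
        for name in ("core_thresh", "mat_thresh"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if not 0.0 < self.detection_p_max <= 1.0:
            raise ValueError("detection_p_max must be in (0, 1]")
        if self.density_min < 0:
            raise ValueError("density_min must be >= 0")


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a config from defaults, an optional YAML file, then kwargs.

    Unknown keys in the YAML file are rejected so typos do not silently
    fall back to defaults.
    """
    config = PipelineConfig()
    if path is not None:
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(PipelineConfig)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        config = replace(config, **data)
    overrides = {k: v for k, v in overrides.items() if v is not None}
    if overrides:
        config = replace(config, **overrides)
    config.validate()
    return config
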