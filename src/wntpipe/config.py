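"""Run configuration: every pipeline parameter with its documented default.

Configs load from YAML, reject unknown keys, and round-trip losslessly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .errors import InputError


@dataclass
class RunConfig:
    """Parameters for a full synthetic pipeline run."""

    out_dir: str = "results"
    seed: int = 0

    # screen
    span: float = 0.7
    excluded_columns: list = field(default_factory=lambda: [1, 2, 23, 24])
    surface: str = "polynomial"
    threshold_sd: float = 3.0
    hit_scope: str = "library"
    n_genes: int = 2000
    gradient_amplitude: float = 1.0
    screen_noise_sd: float = 0.3

    # ITR
    de_threshold: float = 0.05
    z_cutoff: float = 2.0
    effect_mu: float = 2.0
    contrast_noise_sd: float = 0.5
    n_contrasts: int = 5
    n_regulators: int = 10
    targets_per_regulator: int = 20

    # signature / cohort
    min_contrasts: int = 2
    linkage: str = "ward"
    distance: str = "euclidean"
    n_samples: int = 478
    frac_amplified: float = 0.2
    activity_effect: float = 1.0
    cohort_noise_sd: float = 0.5
    hazard_ratio_per_unit: float = 3.0
    censor_rate: float = 0.3

    # survival
    stratify_method: str = "median"
    min_group_frac: float = 0.1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
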