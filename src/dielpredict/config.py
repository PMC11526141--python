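"""Run configuration: validated parameters for the end-to-end pipeline."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources

import yaml


def load_preset(name: str) -> dict:
    """Load one of the bundled site presets (tropical/warm_temperate/cold_temperate)."""
    ref = resources.files("dielpredict").joinpath(f"presets/{name}.yaml")
    try:
        text = ref.read_text()
    except FileNotFoundError as exc:
        raise ValueError(f"unknown preset {name!r}") from exc
    return yaml.safe_load(text)


@dataclass
class RunConfig:
    """Everything a pipeline run needs; unknown keys are rejected.

    Either ``temperature_csv``/``oxygen_csv`` (with ``schema``) point at
    logger files, or ``preset`` names a bundled synthetic regime (optionally
    adjusted through ``synthetic``).
    """

    outdir: str = "dielpredict_out"
    seed: int = 0
    preset: str | None = "warm_temperate"
    temperature_csv: str | None = None
    oxygen_csv: str | None = None
    schema: dict = field(default_factory=dict)
    synthetic: dict = field(default_factory=dict)   # EnvSimParams overrides
    dt: float = 600.0
    max_gap: float = 21600.0
    alpha: float = 0.05
    day_rule_threshold: float = 0.5
    percentile: bool = True
    dj: float = 1.0 / 12
    lt50_link: str = "logit"
    tsm_margin: str = "super"
    n_species: int = 17
    model: str | None = None        # path-model spec text; None = built-in default

    def __post_init__(self):
        checks = [
            (0.0 < self.alpha < 1.0, f"alpha={self.alpha} outside (0, 1)"),
            (0.0 < self.day_rule_threshold < 1.0,
             f"day_rule_threshold={self.day_rule_threshold} outside (0, 1)"),
            (self.dt > 0, f"dt={self.dt} must be positive"),
            (self.max_gap > 0, f"max_gap={self.max_gap} must be positive"),
            (0.0 < self.dj <= 1.0, f"dj={self.dj} outside (0, 1]"),
            (self.lt50_link in ("logit", "probit"), f"lt50_link={self.lt50_link!r}"),
            (self.tsm_margin in ("super", "full"), f"tsm_margin={self.tsm_margin!r}"),
            (self.n_species >= 8, f"n_species={self.n_species} < 8"),
            (0 <= int(self.seed) < 2**31, f"seed={self.seed} outside [0, 2^31)"),
        ]
        bad = [msg for ok, msg in checks if not ok]
        if bad:
            raise ValueError("invalid configuration: " + "; ".join(bad))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def derive_seed(seed: int, stage: int) -> int:
    """Counter-based per-stage seed derivation (stable, < 2^31)."""
    return (int(seed) * 1_000_003 + 7919 * (stage + 1)) % (2**31)
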