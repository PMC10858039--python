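"""Declarative pipeline configuration (YAML dialect) with validation.

One YAML file drives every stage.  Top-level keys:

``seed``        integer used to derive every stage's random stream
``outdir``      directory where stage outputs and manifests are written
``paths``       input artifact paths (fasta, gene_models, mask, panel, calls,
                expression, metadata, cnv, gene_list)
``thresholds``  the analysis thresholds (see :class:`Thresholds`)
``simulate``    keyword overrides for :class:`~estrpipe.simulate.SimulationConfig`

Command-line flags override file values (flags win).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class Thresholds:
    min_lengths: tuple[int, ...] = (9, 4, 4, 3, 3, 3)
    proximity_bp: int = 50
    promoter_bp: int = 5000
    min_depth: int = 20
    max_depth: int = 1000
    min_sample_calls: int = 10000
    min_patients: int = 50
    min_distinct_genotypes: int = 3
    alpha: float = 0.05
    min_repeat_type_obs: int = 25
    mutability_diff_threshold: float = 0.05
    n_permutations: int = 10000

    def validate(self) -> None:
        for name in (
            "proximity_bp",
            "promoter_bp",
            "min_depth",
            "max_depth",
            "min_patients",
            "min_distinct_genotypes",
            "min_repeat_type_obs",
            "n_permutations",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"thresholds.{name} must be positive")
        if self.min_sample_calls < 0:
            raise ConfigurationError("thresholds.min_sample_calls must be >= 0")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigurationError("thresholds.alpha must be in (0, 1)")
        if self.mutability_diff_threshold <= 0:
            raise ConfigurationError("thresholds.mutability_diff_threshold must be positive")
        if len(self.min_lengths) != 6 or any(v <= 0 for v in self.min_lengths):
            raise ConfigurationError("thresholds.min_lengths needs six positive entries")
        if self.max_depth < self.min_depth:
            raise ConfigurationError("thresholds.max_depth must be >= min_depth")


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "estrpipe_out"
    paths: dict[str, str | None] = field(default_factory=dict)
    thresholds: Thresholds = field(default_factory=Thresholds)
    simulate: dict = field(default_factory=dict)

    def validate(self) -> None:
        self.thresholds.validate()

    def path(self, key: str, required: bool = True) -> Path | None:
        value = self.paths.get(key)
        if value is None:
            if required:
                raise ConfigurationError(f"missing input path: {key}")
            return None
        p = Path(value)
        if required and not p.exists():
            raise ConfigurationError(f"input path {key} does not exist: {p}")
        return p

    def to_dict(self) -> dict:
        data = asdict(self)
        data["thresholds"]["min_lengths"] = list(self.thresholds.min_lengths)
        return data


def load_config(path: str | Path | None, **overrides) -> PipelineConfig:
    """Load a YAML config file and apply keyword overrides (flags win)."""
    data: dict = {}
    if path is not None:
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
    thresholds = Thresholds(**{
        **data.get("thresholds", {}),
        **{k: v for k, v in overrides.pop("thresholds", {}).items() if v is not None},
    })
    if isinstance(thresholds.min_lengths, list):
        thresholds.min_lengths = tuple(thresholds.min_lengths)
    config = PipelineConfig(
        seed=overrides.get("seed") if overrides.get("seed") is not None else data.get("seed", 0),
        outdir=overrides.get("outdir") or data.get("outdir", "estrpipe_out"),
        paths={**data.get("paths", {}), **(overrides.get("paths") or {})},
        thresholds=thresholds,
        simulate=data.get("simulate", {}),
    )
    config.validate()
    return config
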