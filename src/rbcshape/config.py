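"""Pipeline configuration: one serializable object, one global seed.

A full run is reproducible from the config plus its seed alone.  The
global seed fans out deterministically to per-stage seeds through
``numpy.random.SeedSequence([seed, stage_tag])``, so changing one stage's
stream never perturbs another's.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .model import ModelSpec
from .synthetic import RenderParams
from .trainer import TrainingConfig

__all__ = ["PipelineConfig", "stage_seed"]

_STAGE_TAGS = {"generate": 11, "split": 13, "init": 17, "train": 19,
               "evaluate": 23, "calibrate": 29}


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global one (< 2**31)."""
    tag = _STAGE_TAGS[stage]
    return int(np.random.SeedSequence([global_seed, tag]).generate_state(1)[0]
               % (2 ** 31))


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, serializable to YAML."""

    seed: int = 0
    # preprocessing
    tukey_alpha: float = 0.25
    sat_frac: float = 0.01
    # architecture (desk-scale default; ``full`` switches to 25 maps/stage)
    arch: str = "small"
    n_kernels: int = 8
    # training
    training: TrainingConfig = field(default_factory=TrainingConfig)
    # synthetic data
    render: RenderParams = field(default_factory=RenderParams)
    train_counts: dict = field(default_factory=lambda: {
        "slipper": 750, "croissant": 750, "sheared_croissant": 500})
    # evaluation sweep
    sweep_n_per_condition: int = 60
    sweep_transition_mbar: float = 400.0
    sweep_other_fraction: float = 0.15
    sweep_sheared_peak: float = 0.2
    # calibration
    bin_width: float = 5.0
    sigma_k: float = 2.0

    def model_spec(self) -> ModelSpec:
        if self.arch == "full":
            return ModelSpec()
        return ModelSpec.small(self.n_kernels)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        ill = d["render"]["illumination_scale"]
        if isinstance(ill, tuple):
            d["render"]["illumination_scale"] = list(ill)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "training" in d and isinstance(d["training"], dict):
            d["training"] = TrainingConfig(**d["training"])
        if "render" in d and isinstance(d["render"], dict):
            r = dict(d["render"])
            if isinstance(r.get("illumination_scale"), list):
                r["illumination_scale"] = tuple(r["illumination_scale"])
            d["render"] = RenderParams(**r)
        return cls(**d)

    def to_yaml(self, path: Path | str) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def with_seed(self, seed: int) -> "PipelineConfig":
        training = replace(self.training, shuffle_seed=stage_seed(seed, "train"))
        render = replace(self.render, rng_seed=stage_seed(seed, "generate"))
        return replace(self, seed=seed, training=training, render=render)
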