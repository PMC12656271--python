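"""Pipeline configuration: dataclasses with YAML round-tripping.

The defaults reproduce the replication configuration: a 3-density x
4-nitrogen x 3-replicate trial over 5 dates (36 plots, 180 samples),
4x4-window GLCM at offset (1, 1) with 32 levels, p < 0.05 screening with
10 retained texture features and 10 texture indices, a PLSR+GBDT stack,
and a sorted 1/3 validation split.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .synthetic import CanopyModel, ExperimentDesign


@dataclass(frozen=True)
class TextureConfig:
    levels: int = 32
    window: int = 4
    offset: tuple[int, int] = (1, 1)
    mode: str = "sliding"
    inner_buffer_frac: float = 0.1


@dataclass(frozen=True)
class SelectionConfig:
    alpha: float = 0.05
    tf_k: int = 10   # texture features kept for index construction
    ti_k: int = 10   # texture indices retained as model inputs


@dataclass(frozen=True)
class ModelConfig:
    pair: str = "plsr+gbdt"  # plsr+svm | plsr+rf | plsr+gbdt
    grids: str = "default"   # default | fast | minimal
    meta_k: int = 5
    inner_cv: int = 5

    @property
    def ml(self) -> str:
        head, _, ml = self.pair.partition("+")
        if head != "plsr" or ml not in ("svm", "rf", "gbdt"):
            raise ValueError(f"pair must be plsr+{{svm,rf,gbdt}}, got {self.pair!r}")
        return ml


@dataclass(frozen=True)
class EvaluationConfig:
    fraction: float = 1 / 3
    map_window: int = 32
    map_stride: int = 32


@dataclass(frozen=True)
class SyntheticConfig:
    design: ExperimentDesign = field(default_factory=ExperimentDesign)
    canopy: CanopyModel = field(default_factory=CanopyModel)


@dataclass(frozen=True)
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    texture: TextureConfig = field(default_factory=TextureConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    seed: int = 0

    def with_seed(self, seed: int) -> "PipelineConfig":
        design = dataclasses.replace(self.synthetic.design, seed=int(seed))
        return dataclasses.replace(
            self,
            seed=int(seed),
            synthetic=dataclasses.replace(self.synthetic, design=design),
        )

    def to_dict(self) -> dict:
        return _plain(dataclasses.asdict(self))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @property
    def hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        syn = d.get("synthetic", {})
        design = ExperimentDesign(**_tupled(syn.get("design", {}), ("densities", "n_rates")))
        canopy = CanopyModel(
            **_tupled(syn.get("canopy", {}), ("leaf_spectrum", "soil_spectrum", "gain_range"))
        )
        return cls(
            synthetic=SyntheticConfig(design=design, canopy=canopy),
            texture=TextureConfig(**_tupled(d.get("texture", {}), ("offset",))),
            selection=SelectionConfig(**d.get("selection", {})),
            model=ModelConfig(**d.get("model", {})),
            evaluation=EvaluationConfig(**d.get("evaluation", {})),
            seed=int(d.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, text_or_path) -> "PipelineConfig":
        try:
            text = open(text_or_path).read()
        except (OSError, TypeError):
            text = text_or_path
        return cls.from_dict(yaml.safe_load(text) or {})


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    return obj


def _tupled(d: dict, keys) -> dict:
    d = dict(d)
    for k in keys:
        if k in d and isinstance(d[k], list):
            d[k] = tuple(d[k])
    return d
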