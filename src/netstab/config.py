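"""Experiment configuration: YAML round-trip and grid bookkeeping."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .cohort import StudyDesign, EffectSizes
from .discrim import HYPOTHESIS_COMPARISONS

__all__ = ["ExperimentConfig", "count_executions", "count_tests"]

PRESETS = ("repeated", "cross", "smoke")


@dataclass(frozen=True)
class ExperimentConfig:
    """Serializable description of one experiment run."""

    preset: str = "smoke"
    seed: int = 0
    out_dir: str = "results"
    # design overrides applied on top of the preset
    design_overrides: dict = field(default_factory=dict)
    effects: dict = field(default_factory=dict)
    # perturbation profile
    t: int = 53
    mca_mode: str = "rr"
    densities: tuple[str, ...] = ("dense", "sparse")
    # analysis settings
    hypotheses: tuple[str, ...] = ("H1", "H2", "H3")
    n_perm: int = 1000
    model_k: tuple[int, ...] = (5,)
    n_repeats: int = 20
    pca_threshold: float = 0.90

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"preset must be one of {PRESETS}")
        if self.mca_mode not in ("rr", "pb", "off"):
            raise ValueError("mca_mode must be rr, pb or off")

    def study_design(self) -> StudyDesign:
        base = {
            "repeated": StudyDesign.repeated_measures,
            "cross": StudyDesign.cross_sectional,
            "smoke": StudyDesign.smoke,
        }[self.preset]()
        return base.replace(**self.design_overrides)

    def effect_sizes(self) -> EffectSizes:
        return replace(EffectSizes(), **self.effects)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("densities", "hypotheses", "model_k"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key in ("densities", "hypotheses", "model_k"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @property
    def config_hash(self) -> str:
        canon = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def count_executions(design: StudyDesign) -> int:
    """Total pipeline executions for a design (references included)."""
    return design.total_executions


def count_tests(
    hypotheses=HYPOTHESIS_COMPARISONS, n_pipelines: int = 2, n_modes: int = 2
) -> int:
    """Distinct discriminability tests in a hypothesis grid."""
    from .discrim import count_tests as _ct

    return _ct(hypotheses, n_pipelines=n_pipelines, n_modes=n_modes)
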