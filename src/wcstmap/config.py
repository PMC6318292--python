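"""Schema-validated pipeline configuration (YAML-backed).

Unknown keys are rejected so that typos in a config file fail loudly
rather than silently falling back to defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .cohort import CohortConfig, GroupSpec, default_cohort_config
from .inference import McmcConfig
from .model import ModelConfig
from .task import DeckConfig, ExaminerConfig

__all__ = ["PipelineConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class DeckSection(_Strict):
    copies: int = 2
    order: str = "shuffle"
    fixed_list: str | None = None
    exclude_key_cards: bool = False
    seed: int = 0

    def build(self) -> DeckConfig:
        return DeckConfig(**self.model_dump())


class ExaminerSection(_Strict):
    run_length: int = 10
    max_categories: int = 6
    rules: tuple[str, ...] = ("color", "form", "number")

    def build(self) -> ExaminerConfig:
        return ExaminerConfig(**self.model_dump())


class ModelSection(_Strict):
    d_max: float = 5.0
    f_max: float = 5.0
    choice_floor: float = 1e-3
    attention_floor: float = 1e-6

    def build(self) -> ModelConfig:
        return ModelConfig(**self.model_dump())


class McmcSection(_Strict):
    n_walkers: int = 24
    n_steps: int = 750
    n_burn: int = 750
    thin: int = 1
    n_diag_chains: int = 4
    rhat_threshold: float = 1.05

    def build(self) -> McmcConfig:
        return McmcConfig(**self.model_dump())


class GroupSection(_Strict):
    name: str
    n: int
    center: tuple[float, float, float]
    radii: tuple[float, float, float]
    param_shift: dict[str, float] = Field(default_factory=dict)


class CohortSection(_Strict):
    n_per_group: int = 50
    groups: list[GroupSection] | None = None
    grid_shape: tuple[int, int, int] = (40, 48, 40)
    voxel_size_mm: float = 4.0
    seed: int = 0

    def build(self, deck: DeckConfig, examiner: ExaminerConfig) -> CohortConfig:
        if self.groups is None:
            return default_cohort_config(
                n_per_group=self.n_per_group,
                seed=self.seed,
                grid_shape=self.grid_shape,
                voxel_size_mm=self.voxel_size_mm,
                deck=deck,
                examiner=examiner,
            )
        groups = tuple(
            GroupSpec(g.name, g.n, tuple(g.center), tuple(g.radii), g.param_shift) for g in self.groups
        )
        return CohortConfig(
            groups=groups,
            grid_shape=self.grid_shape,
            voxel_size_mm=self.voxel_size_mm,
            deck=deck,
            examiner=examiner,
            seed=self.seed,
        )


class VlsmSection(_Strict):
    min_overlap: int = 12
    fdr_q: float = 0.01
    density_threshold: int = 8


class ClusterSection(_Strict):
    k_min: int = 2
    k_max: int = 7
    metrics: tuple[str, ...] = ("euclidean", "cityblock", "correlation")
    n_restarts: int = 20
    standardize: bool = True
    n_boot: int = 1000
    frac: float = 0.5


class PipelineConfig(_Strict):
    """Top-level configuration for every pipeline stage."""

    seed: int = 0
    deck: DeckSection = Field(default_factory=DeckSection)
    examiner: ExaminerSection = Field(default_factory=ExaminerSection)
    model: ModelSection = Field(default_factory=ModelSection)
    mcmc: McmcSection = Field(default_factory=McmcSection)
    cohort: CohortSection = Field(default_factory=CohortSection)
    vlsm: VlsmSection = Field(default_factory=VlsmSection)
    cluster: ClusterSection = Field(default_factory=ClusterSection)

    def dump_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(mode="json"), sort_keys=False))


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML config; ``None`` gives all defaults."""
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    return PipelineConfig.model_validate(data)
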