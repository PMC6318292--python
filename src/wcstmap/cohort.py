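"""Synthetic study cohort: lesion masks, covariates, parameters, behavior.

Generates a full artificial lesion-mapping study so that every downstream
stage (scoring, fitting, VLSM, clustering) is exercisable without patient
data. Each group receives an ellipsoidal lesion territory on a shared
template grid (center and radii jittered per participant) and a shift on
the mean of selected model parameters; the default configuration plants a
punishment-sensitivity (P) reduction in the right-prefrontal group,
mirroring the statistical structure a real frontal-lesion cohort would
carry. Behavior is then forward-simulated with the attention model, so the
planted parameter deficit propagates into elevated perseverative errors.

Parameters are drawn from truncated normals inside the model bounds; the
truncation slightly biases group means, which is accepted and documented.
Covariates (age, education, lesion volume) are weakly coupled to the
parameters so that nuisance residualization is non-trivial but leaves the
behavioral variables essentially intact.

Everything is regenerable byte-identically from the master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import stats

from .model import PARAM_NAMES, ModelConfig, ModelParams, simulate_participant
from .scoring import WCSTScores, score_administration
from .task import AdministrationResult, DeckConfig, ExaminerConfig, build_deck, trials_to_frame

__all__ = [
    "GroupSpec",
    "CohortConfig",
    "SyntheticParticipant",
    "Cohort",
    "default_cohort_config",
    "generate_cohort",
]


@dataclass(frozen=True)
class GroupSpec:
    """One lesion group: territory ellipsoid plus parameter-mean shifts."""

    name: str
    n: int
    center: tuple[float, float, float]  # voxel coordinates
    radii: tuple[float, float, float]  # voxel units
    param_shift: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class CohortConfig:
    groups: tuple[GroupSpec, ...]
    grid_shape: tuple[int, int, int] = (40, 48, 40)
    voxel_size_mm: float = 4.0
    #: baseline (mean, sd) of the truncated-normal parameter draws
    baseline: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "r": (0.25, 0.12),
            "p": (0.70, 0.15),
            "d": (2.0, 0.6),
            "f": (0.75, 0.5),
        }
    )
    center_jitter: float = 1.5  # sd of per-participant center jitter (voxels)
    radius_jitter: float = 1.0  # sd of per-participant radius jitter (voxels)
    #: linear coupling of age (centered, per year) onto parameter means
    age_coupling: Mapping[str, float] = field(default_factory=lambda: {"p": -0.002})
    deck: DeckConfig = field(default_factory=DeckConfig)
    examiner: ExaminerConfig = field(default_factory=ExaminerConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) == 0:
            raise ValueError("cohort needs at least one group")
        shape = np.array(self.grid_shape, dtype=float)
        for g in self.groups:
            c, rad = np.array(g.center), np.array(g.radii)
            if np.any(c - rad < 0) or np.any(c + rad > shape - 1):
                raise ValueError(f"group {g.name!r}: lesion territory extends outside the grid")

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([self.voxel_size_mm] * 3 + [1.0])
        aff[:3, 3] = -(np.array(self.grid_shape) - 1) / 2.0 * self.voxel_size_mm
        return aff


def default_cohort_config(n_per_group: int = 50, seed: int = 0, **kwargs) -> CohortConfig:
    """Four 50-participant groups on the default 40x48x40 grid at 4 mm.

    The right-prefrontal group carries the planted punishment-sensitivity
    deficit (P mean lowered by 0.30); the other three territories are
    behavioral controls.
    """
    groups = (
        GroupSpec("right-pfc", n_per_group, center=(28.0, 34.0, 24.0), radii=(6.0, 7.0, 6.0),
                  param_shift={"p": -0.30}),
        GroupSpec("left-pfc", n_per_group, center=(11.0, 34.0, 24.0), radii=(6.0, 7.0, 6.0)),
        GroupSpec("right-posterior", n_per_group, center=(28.0, 12.0, 22.0), radii=(6.0, 6.0, 6.0)),
        GroupSpec("left-posterior", n_per_group, center=(11.0, 12.0, 22.0), radii=(6.0, 6.0, 6.0)),
    )
    return CohortConfig(groups=groups, seed=seed, **kwargs)


@dataclass
class SyntheticParticipant:
    id: str
    group: str
    mask: np.ndarray  # bool, grid_shape
    covariates: dict[str, float]
    true_params: ModelParams
    deck_seed: int
    sim_seed: int
    result: AdministrationResult
    scores: WCSTScores


@dataclass
class Cohort:
    config: CohortConfig
    participants: list[SyntheticParticipant]

    @property
    def affine(self) -> np.ndarray:
        return self.config.affine

    def masks_array(self) -> np.ndarray:
        """(n_participants, *grid_shape) boolean stack of lesion masks."""
        return np.stack([p.mask for p in self.participants])

    def param_frame(self) -> pd.DataFrame:
        rows = [
            {"participant": p.id, "group": p.group,
             **{name: getattr(p.true_params, name) for name in PARAM_NAMES}}
            for p in self.participants
        ]
        return pd.DataFrame(rows).set_index("participant")

    def score_frame(self) -> pd.DataFrame:
        rows = [{"participant": p.id, "group": p.group, **p.scores.as_dict()} for p in self.participants]
        return pd.DataFrame(rows).set_index("participant")

    def covariate_frame(self) -> pd.DataFrame:
        rows = [{"participant": p.id, **p.covariates} for p in self.participants]
        return pd.DataFrame(rows).set_index("participant")

    def trial_frame(self) -> pd.DataFrame:
        return pd.concat(
            [trials_to_frame(p.result.trials, participant=p.id) for p in self.participants],
            ignore_index=True,
        )

    def nominal_territory(self, group: str) -> np.ndarray:
        """Boolean mask of the group's nominal (unjittered) ellipsoid."""
        spec = next(g for g in self.config.groups if g.name == group)
        return _ellipsoid(self.config.grid_shape, np.array(spec.center), np.array(spec.radii))

    def write(self, outdir: str | Path) -> None:
        """Write masks (NIfTI), cohort table, trial logs, and scores."""
        outdir = Path(outdir)
        (outdir / "masks").mkdir(parents=True, exist_ok=True)
        for p in self.participants:
            img = nib.Nifti1Image(p.mask.astype(np.uint8), self.affine)
            nib.save(img, outdir / "masks" / f"{p.id}.nii.gz")
        cov = self.covariate_frame()
        cov.insert(0, "group", [p.group for p in self.participants])
        for name in PARAM_NAMES:
            cov[f"true_{name}"] = [getattr(p.true_params, name) for p in self.participants]
        cov.to_csv(outdir / "cohort.csv")
        self.trial_frame().to_csv(outdir / "trials.csv", index=False)
        self.score_frame().to_csv(outdir / "scores.csv")


def _ellipsoid(shape: Sequence[int], center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    acc = np.zeros(tuple(shape))
    for g, c, r in zip(grids, center, radii):
        acc += ((g - c) / r) ** 2
    return acc <= 1.0


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Draw the full synthetic cohort deterministically from the master seed."""
    config = config or default_cohort_config()
    model_config = ModelConfig()
    rng = np.random.default_rng(config.seed)
    participants: list[SyntheticParticipant] = []
    shape = config.grid_shape
    voxel_ml = (config.voxel_size_mm / 10.0) ** 3  # mm^3 -> ml via cm^3

    idx = 0
    for group in config.groups:
        for _ in range(group.n):
            pid = f"sub-{idx:03d}"
            idx += 1
            center = np.array(group.center) + rng.normal(0.0, config.center_jitter, 3)
            radii = np.maximum(np.array(group.radii) + rng.normal(0.0, config.radius_jitter, 3), 1.5)
            center = np.clip(center, radii, np.array(shape, dtype=float) - 1 - radii)
            mask = _ellipsoid(shape, center, radii)

            age = _trunc_normal(rng, 55.0, 12.0, 20.0, 89.0)
            education = _trunc_normal(rng, 14.0, 3.0, 8.0, 20.0)
            volume_ml = float(mask.sum()) * voxel_ml * float(1.0 + rng.normal(0.0, 0.05))

            values = {}
            for name in PARAM_NAMES:
                mean, sd = config.baseline[name]
                mean = mean + group.param_shift.get(name, 0.0)
                mean = mean + config.age_coupling.get(name, 0.0) * (age - 55.0)
                lo, hi = model_config.bounds(name)
                values[name] = _trunc_normal(rng, mean, sd, lo, hi)
            params = ModelParams(**values)

            deck_seed = int(rng.integers(2**31))
            sim_seed = int(rng.integers(2**31))
            deck = build_deck(replace(config.deck, seed=deck_seed))
            result = simulate_participant(params, deck, config.examiner, seed=sim_seed)
            scores = score_administration(result, config.examiner)

            participants.append(
                SyntheticParticipant(
                    id=pid,
                    group=group.name,
                    mask=mask,
                    covariates={"age": age, "education": education, "lesion_volume_ml": volume_ml},
                    true_params=params,
                    deck_seed=deck_seed,
                    sim_seed=sim_seed,
                    result=result,
                    scores=scores,
                )
            )
    return Cohort(config=config, participants=participants)
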