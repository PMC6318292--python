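"""Simulation studies validating the model: parameter recovery, posterior
predictive checks, and the score landscape over the parameter grid.

All three studies are fully reproducible from (configuration, seed): every
virtual participant gets deck/behavior/fit seeds spawned deterministically
from the master seed.
"""

from __future__ import annotations

import itertools
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .inference import McmcConfig, PriorSpec, fit_participant
from .model import PARAM_NAMES, ModelConfig, ModelParams, ModelVariant, simulate_participant
from .scoring import SCORE_NAMES, WCSTScores, score_administration
from .task import DeckConfig, ExaminerConfig, build_deck

__all__ = [
    "default_recovery_grid",
    "default_landscape_grid",
    "run_parameter_recovery",
    "recovery_summary",
    "run_posterior_predictive",
    "run_score_landscape",
]

logger = logging.getLogger(__name__)

#: Default grid for the recovery study: low/medium/high rates, spread d and f.
DEFAULT_GRID: dict[str, tuple[float, ...]] = {
    "r": (0.1, 0.5, 0.9),
    "p": (0.1, 0.5, 0.9),
    "d": (0.5, 1.0, 3.0),
    "f": (0.0, 1.0, 3.0),
}


def default_recovery_grid(values: Mapping[str, Sequence[float]] | None = None) -> list[ModelParams]:
    """Full-factorial list of generating parameter vectors."""
    values = dict(DEFAULT_GRID if values is None else values)
    return [
        ModelParams(r, p, d, f)
        for r, p, d, f in itertools.product(values["r"], values["p"], values["d"], values["f"])
    ]


def default_landscape_grid() -> dict[str, tuple[float, ...]]:
    return {k: tuple(v) for k, v in DEFAULT_GRID.items()}


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(seed).spawn(n)]


def run_parameter_recovery(
    grid: Sequence[ModelParams],
    n_virtual: int = 10,
    deck_config: DeckConfig | None = None,
    examiner: ExaminerConfig | None = None,
    mcmc: McmcConfig | None = None,
    priors: PriorSpec | None = None,
    variant: ModelVariant = ModelVariant.RPDF,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Simulate ``n_virtual`` participants per grid point, fit each, and
    tabulate truth vs. MAP.

    Returns a tidy frame with one row per virtual participant: generating
    parameters (``true_*``), MAP estimates (``map_*``), the convergence
    flag, and a ``failed`` flag for fits that raised.
    """
    if len(grid) == 0 or n_virtual < 1:
        raise ValueError("grid must be nonempty and n_virtual >= 1")
    deck_config = deck_config or DeckConfig()
    examiner = examiner or ExaminerConfig()
    rows = []
    seeds = _child_seeds(seed, len(grid) * n_virtual * 3)
    it = iter(seeds)
    for cell, true_params in enumerate(grid):
        for j in range(n_virtual):
            deck_seed, sim_seed, fit_seed = next(it), next(it), next(it)
            deck = build_deck(DeckConfig(**{**deck_config.__dict__, "seed": deck_seed}))
            result = simulate_participant(true_params, deck, examiner, seed=sim_seed, config=config)
            row = {"cell": cell, "virtual": j, "n_trials": result.n_trials}
            for name in PARAM_NAMES:
                row[f"true_{name}"] = getattr(true_params, name)
            try:
                summ = fit_participant(result.trials, variant, priors, mcmc, seed=fit_seed, config=config)
                for name in PARAM_NAMES:
                    row[f"map_{name}"] = getattr(summ.map_params, name)
                row["converged"] = summ.converged
                row["failed"] = False
            except Exception as exc:
                logger.warning("recovery fit failed at cell %d: %s", cell, exc)
                for name in PARAM_NAMES:
                    row[f"map_{name}"] = np.nan
                row["converged"] = False
                row["failed"] = True
            rows.append(row)
    return pd.DataFrame(rows)


def recovery_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter pooled bias and truth-vs-MAP correlations."""
    ok = report[~report.failed]
    rows = []
    for name in PARAM_NAMES:
        truth = ok[f"true_{name}"].to_numpy()
        est = ok[f"map_{name}"].to_numpy()
        bias = float(np.mean(est - truth))
        if np.ptp(truth) > 0:
            rho = float(stats.spearmanr(truth, est).statistic)
            r = float(stats.pearsonr(truth, est).statistic)
        else:
            rho = r = np.nan
        rows.append({"parameter": name, "bias": bias, "spearman": rho, "pearson": r, "n": len(ok)})
    return pd.DataFrame(rows)


def run_posterior_predictive(
    fits: Mapping[str, ModelParams],
    observed: Mapping[str, WCSTScores],
    n_rep: int = 50,
    deck_config: DeckConfig | None = None,
    examiner: ExaminerConfig | None = None,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Simulate ``n_rep`` administrations per participant at the MAP and
    compare mean predicted scores with observed scores.

    Participants present in ``observed`` but missing from ``fits`` are
    skipped with a log warning. Returns one row per retained participant
    with ``obs_*``, ``pred_*`` (replicate means) and ``pred_sd_*`` columns.
    """
    deck_config = deck_config or DeckConfig()
    examiner = examiner or ExaminerConfig()
    rows = []
    pids = [pid for pid in observed if pid in fits]
    for pid in observed:
        if pid not in fits:
            logger.warning("participant %s has no fit; skipped in PPC", pid)
    seeds = _child_seeds(seed, 2 * len(pids) * n_rep)
    it = iter(seeds)
    for pid in pids:
        params = fits[pid]
        reps = []
        for _ in range(n_rep):
            deck_seed, sim_seed = next(it), next(it)
            deck = build_deck(DeckConfig(**{**deck_config.__dict__, "seed": deck_seed}))
            res = simulate_participant(params, deck, examiner, seed=sim_seed, config=config)
            reps.append(score_administration(res, examiner).as_dict())
        rep_df = pd.DataFrame(reps)
        row: dict[str, object] = {"participant": pid, "n_rep": n_rep}
        obs = observed[pid].as_dict()
        for name in SCORE_NAMES:
            row[f"obs_{name}"] = obs[name]
            row[f"pred_{name}"] = float(rep_df[name].mean())
            row[f"pred_sd_{name}"] = float(rep_df[name].std(ddof=1)) if n_rep > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)


def run_score_landscape(
    grid: Mapping[str, Sequence[float]] | None = None,
    n_runs: int = 50,
    deck_config: DeckConfig | None = None,
    examiner: ExaminerConfig | None = None,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> pd.DataFrame:
    """Mean WCST scores over seeded simulations for every grid cell.

    ``grid`` maps each of r, p, d, f to the values to sweep (full
    factorial). Returns one row per cell with the four parameter values and
    ``mean_*`` / ``sd_*`` columns for every score.
    """
    grid = dict(default_landscape_grid() if grid is None else grid)
    model_config = config or ModelConfig()
    for name in PARAM_NAMES:
        lo, hi = model_config.bounds(name)
        for v in grid[name]:
            if not (lo <= v <= hi):
                raise ValueError(f"grid value {name}={v} outside [{lo}, {hi}]")
    deck_config = deck_config or DeckConfig()
    examiner = examiner or ExaminerConfig()
    cells = list(itertools.product(grid["r"], grid["p"], grid["d"], grid["f"]))
    seeds = _child_seeds(seed, 2 * len(cells) * n_runs)
    it = iter(seeds)
    rows = []
    for r, p, d, f in cells:
        params = ModelParams(r, p, d, f)
        scored = []
        for _ in range(n_runs):
            deck_seed, sim_seed = next(it), next(it)
            deck = build_deck(DeckConfig(**{**deck_config.__dict__, "seed": deck_seed}))
            res = simulate_participant(params, deck, examiner, seed=sim_seed, config=config)
            scored.append(score_administration(res, examiner).as_dict())
        sdf = pd.DataFrame(scored)
        row = {"r": r, "p": p, "d": d, "f": f, "n_runs": n_runs}
        for name in SCORE_NAMES:
            row[f"mean_{name}"] = float(sdf[name].mean())
            row[f"sd_{name}"] = float(sdf[name].std(ddof=1)) if n_runs > 1 else 0.0
        rows.append(row)
    return pd.DataFrame(rows)
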