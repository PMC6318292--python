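"""Per-participant Bayesian estimation and DIC model comparison.

Each participant is fit independently: the posterior over the variant's
free parameters (flat priors over their bounded supports by default) is
sampled with an affine-invariant ensemble sampler, summarized by the
posterior mode (MAP; the best sample refined by bounded local
optimization), and screened with split-R̂ and effective-sample-size
diagnostics. Model variants are compared by the deviance information
criterion

    DIC = D̄ + pD,   pD = D̄ − D(θ̄),

with deviance D(θ) = −2 log L(θ) and θ̄ the posterior mean, reported
relative to a uniformly random chooser, ΔDIC = DIC_random − DIC with
DIC_random = −2 log(1/4) per trial summed over all trials; larger ΔDIC
means a better model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import arviz as az
import emcee
import numpy as np
import pandas as pd
from scipy import optimize

from ._kernels import deviance_over_samples, loglik_trace
from .model import ModelConfig, ModelParams, ModelVariant, trials_to_arrays
from .task import TrialRecord

__all__ = [
    "PriorSpec",
    "McmcConfig",
    "PosteriorSummary",
    "DICResult",
    "fit_participant",
    "compute_dic",
    "compare_models",
    "dic_random",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors over the free-parameter supports.

    ``overrides`` narrows the support of named parameters (keyed by free
    name, e.g. ``{"d": (0.5, 3.0)}``); anything else inherits the model
    bounds. Proper by construction on the bounded box.
    """

    overrides: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def bounds(self, variant: ModelVariant, config: ModelConfig) -> np.ndarray:
        base = variant.free_bounds(config)
        out = base.copy()
        for i, name in enumerate(variant.free_names):
            if name in self.overrides:
                lo, hi = self.overrides[name]
                if not (base[i, 0] <= lo < hi <= base[i, 1]):
                    raise ValueError(f"prior override for {name} outside model bounds")
                out[i] = (lo, hi)
        return out


@dataclass(frozen=True)
class McmcConfig:
    """Ensemble-sampler settings.

    ``n_walkers`` walkers are run for ``n_burn + n_steps`` iterations; the
    retained draws are grouped into ``n_diag_chains`` pseudo-chains for
    split-R̂/ESS. Convergence is flagged when any R̂ exceeds
    ``rhat_threshold``.
    """

    n_walkers: int = 24
    n_steps: int = 750
    n_burn: int = 750
    thin: int = 1
    n_diag_chains: int = 4
    rhat_threshold: float = 1.05

    def __post_init__(self) -> None:
        if self.n_walkers % self.n_diag_chains:
            raise ValueError("n_walkers must be divisible by n_diag_chains")


@dataclass
class PosteriorSummary:
    """Posterior draws and point summaries for one participant fit."""

    variant: ModelVariant
    free_names: tuple[str, ...]
    samples: np.ndarray  # (n_draws, n_free) flattened post-burn draws
    map_theta: np.ndarray  # (n_free,)
    map_params: ModelParams
    map_log_posterior: float
    rhat: dict[str, float]
    ess: dict[str, float]
    converged: bool
    mean_deviance: float
    n_trials: int
    flags: list[str] = field(default_factory=list)

    def posterior_mean(self) -> np.ndarray:
        return self.samples.mean(axis=0)


def _make_log_posterior(m, fb, bounds, variant, config):
    lo = bounds[:, 0].copy()
    hi = bounds[:, 1].copy()

    def log_posterior(theta: np.ndarray) -> float:
        if np.any(theta < lo) or np.any(theta > hi):
            return -np.inf
        params = variant.to_params(theta)
        return loglik_trace(
            m, fb, params.r, params.p, params.d, params.f, config.choice_floor, config.attention_floor
        )

    return log_posterior


def _diagnostics(chain: np.ndarray, free_names, n_diag_chains):
    """Split the walker ensemble into pseudo-chains and run arviz R̂/ESS."""
    n_steps, n_walkers, n_free = chain.shape
    per = n_walkers // n_diag_chains
    # (chain, draw): concatenate walkers within each group along the draw axis
    grouped = np.concatenate(
        [chain[:, g * per : (g + 1) * per, :].transpose(1, 0, 2).reshape(1, -1, n_free) for g in range(n_diag_chains)],
        axis=0,
    )
    idata = az.from_dict(posterior={name: grouped[:, :, i] for i, name in enumerate(free_names)})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rhat = az.rhat(idata)
        ess = az.ess(idata)
    return (
        {name: float(rhat[name].values) for name in free_names},
        {name: float(ess[name].values) for name in free_names},
    )


def fit_participant(
    trials: Sequence[TrialRecord],
    variant: ModelVariant = ModelVariant.RPDF,
    priors: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> PosteriorSummary:
    """Sample the posterior of one participant's parameters.

    With flat priors the unnormalized log-posterior equals the sequence
    log-likelihood inside the support. An empty trial log returns prior
    draws with an ``"empty-data"`` flag; non-convergence is flagged, never
    silently dropped.
    """
    priors = priors or PriorSpec()
    mcmc = mcmc or McmcConfig()
    config = config or ModelConfig()
    bounds = priors.bounds(variant, config)
    n_free = variant.n_free
    rng = np.random.RandomState(seed)
    flags: list[str] = []

    if len(trials) == 0:
        draws = bounds[:, 0] + (bounds[:, 1] - bounds[:, 0]) * rng.rand(
            mcmc.n_walkers * mcmc.n_steps, n_free
        )
        theta = draws.mean(axis=0)
        return PosteriorSummary(
            variant=variant,
            free_names=variant.free_names,
            samples=draws,
            map_theta=theta,
            map_params=variant.to_params(theta),
            map_log_posterior=0.0,
            rhat={n: np.nan for n in variant.free_names},
            ess={n: np.nan for n in variant.free_names},
            converged=False,
            mean_deviance=0.0,
            n_trials=0,
            flags=["empty-data"],
        )

    m, fb = trials_to_arrays(trials)
    log_posterior = _make_log_posterior(m, fb, bounds, variant, config)

    n_walkers = max(mcmc.n_walkers, 2 * n_free + 2)
    sampler = emcee.EnsembleSampler(n_walkers, n_free, log_posterior)
    sampler.random_state = rng.get_state()
    p0 = bounds[:, 0] + (bounds[:, 1] - bounds[:, 0]) * rng.rand(n_walkers, n_free)
    sampler.run_mcmc(p0, mcmc.n_burn + mcmc.n_steps, progress=False)

    chain = sampler.get_chain(discard=mcmc.n_burn, thin=mcmc.thin)  # (steps, walkers, free)
    log_prob = sampler.get_log_prob(discard=mcmc.n_burn, thin=mcmc.thin)
    samples = chain.reshape(-1, n_free)

    rhat, ess = _diagnostics(chain, variant.free_names, mcmc.n_diag_chains)
    converged = all(np.isfinite(v) and v <= mcmc.rhat_threshold for v in rhat.values())
    if not converged:
        flags.append("non-convergence")
        logger.warning("fit did not converge (R-hat %s) for variant %s", rhat, variant.value)

    # MAP: best posterior sample refined by bounded local optimization
    i_best = int(np.argmax(log_prob))  # flatten order matches samples
    theta0 = samples[i_best]
    res = optimize.minimize(
        lambda th: -log_posterior(th),
        x0=theta0,
        method="L-BFGS-B",
        bounds=[tuple(b) for b in bounds],
    )
    map_theta = res.x if res.fun <= -log_posterior(theta0) else theta0
    map_lp = float(log_posterior(map_theta))

    full = np.stack([variant.to_params(s).as_array() for s in samples])
    mean_dev = float(
        deviance_over_samples(m, fb, full, config.choice_floor, config.attention_floor).mean()
    )

    return PosteriorSummary(
        variant=variant,
        free_names=variant.free_names,
        samples=samples,
        map_theta=np.asarray(map_theta, dtype=float),
        map_params=variant.to_params(map_theta),
        map_log_posterior=map_lp,
        rhat=rhat,
        ess=ess,
        converged=converged,
        mean_deviance=mean_dev,
        n_trials=len(trials),
        flags=flags,
    )


def dic_random(n_trials: int) -> float:
    """Deviance of the uniformly random 4-option chooser over ``n_trials``."""
    return -2.0 * np.log(0.25) * n_trials


@dataclass(frozen=True)
class DICResult:
    """DIC decomposition for one fit, with the random-chooser reference."""

    dic: float
    mean_deviance: float
    deviance_at_mean: float
    p_d: float
    dic_random: float

    @property
    def delta_dic(self) -> float:
        return self.dic_random - self.dic


def compute_dic(
    summary: PosteriorSummary,
    trials: Sequence[TrialRecord],
    config: ModelConfig | None = None,
) -> DICResult:
    """DIC = D̄ + pD with the posterior-mean plug-in pD = D̄ − D(θ̄)."""
    config = config or ModelConfig()
    m, fb = trials_to_arrays(trials)
    theta_bar = summary.posterior_mean()
    params_bar = summary.variant.to_params(theta_bar)
    dev_at_mean = -2.0 * float(
        loglik_trace(
            m,
            fb,
            params_bar.r,
            params_bar.p,
            params_bar.d,
            params_bar.f,
            config.choice_floor,
            config.attention_floor,
        )
    )
    d_bar = summary.mean_deviance
    if not np.isfinite(d_bar) or not np.isfinite(dev_at_mean):
        raise FloatingPointError("non-finite deviance in DIC computation")
    p_d = d_bar - dev_at_mean
    return DICResult(
        dic=d_bar + p_d,
        mean_deviance=d_bar,
        deviance_at_mean=dev_at_mean,
        p_d=p_d,
        dic_random=dic_random(len(trials)),
    )


def compare_models(
    cohort: Mapping[str, Sequence[TrialRecord]],
    variants: Sequence[ModelVariant] = tuple(ModelVariant),
    priors: PriorSpec | None = None,
    mcmc: McmcConfig | None = None,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit every variant to every participant and rank variants by ΔDIC.

    Returns ``(ranking, per_participant)`` data frames. ``ranking`` has one
    row per variant with summed DIC, summed ΔDIC (relative to the random
    chooser over all trials), and rank 1 = best (largest ΔDIC). Failed fits
    are flagged per participant and excluded from sums.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rows = []
    ss = np.random.SeedSequence(seed)
    part_seeds = {pid: int(s.generate_state(1)[0] % (2**31)) for pid, s in
                  zip(cohort, ss.spawn(len(cohort)))}
    for variant in variants:
        for pid, trials in cohort.items():
            try:
                summ = fit_participant(trials, variant, priors, mcmc, seed=part_seeds[pid], config=config)
                dic = compute_dic(summ, trials, config)
                rows.append(
                    {
                        "participant": pid,
                        "variant": variant.value,
                        "n_trials": len(trials),
                        "dic": dic.dic,
                        "p_d": dic.p_d,
                        "delta_dic": dic.delta_dic,
                        "converged": summ.converged,
                        "failed": False,
                    }
                )
            except Exception as exc:  # propagate as per-participant flag
                logger.warning("fit failed for %s under %s: %s", pid, variant.value, exc)
                rows.append(
                    {
                        "participant": pid,
                        "variant": variant.value,
                        "n_trials": len(trials),
                        "dic": np.nan,
                        "p_d": np.nan,
                        "delta_dic": np.nan,
                        "converged": False,
                        "failed": True,
                    }
                )
    per_participant = pd.DataFrame(rows)
    ok = per_participant[~per_participant.failed]
    ranking = (
        ok.groupby("variant", sort=False)
        .agg(total_dic=("dic", "sum"), total_delta_dic=("delta_dic", "sum"), n_fits=("dic", "size"))
        .reset_index()
    )
    ranking["rank"] = ranking["total_delta_dic"].rank(ascending=False).astype(int)
    ranking = ranking.sort_values("rank").reset_index(drop=True)
    return ranking, per_participant
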