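"""Sequential-attention learning model of WCST performance.

The model maintains a belief state over the three sorting dimensions — a
vector of attention weights ``a`` on the 3-simplex — and has four free
parameters:

r : reward sensitivity in [0, 1]
    Learning rate applied after "right" feedback.
p : punishment sensitivity in [0, 1]
    Learning rate applied after "wrong" feedback.
d : decision consistency in [0, d_max]
    Power-transform exponent mapping attention to choice probabilities;
    d = 0 yields random choice, large d near-deterministic choice.
f : attentional focusing in [0, f_max]
    Exponent concentrating the feedback signal on high-attention
    dimensions; f = 0 spreads the update equally over the eligible
    dimensions.

On each trial the probability of sorting onto pile ``k`` is

    P_k = sum_i m_ik * a_i^d / sum_i a_i^d,

with ``m_ik`` the card-vs-pile match indicator. Because the four key cards
pairwise differ on every dimension, each dimension matches exactly one pile
and the raw probabilities sum to one. After feedback, a signal ``s`` on the
simplex is formed from the matching (after "right") or non-matching (after
"wrong") dimensions, weighted by ``a^f`` and normalized, and the state moves
by a convex step:

    a' = (1 - r) a + r s   after "right"
    a' = (1 - p) a + p s   after "wrong".

Two numerical floors keep the likelihood proper: choices are mixed with a
uniform lapse component (weight ``choice_floor``) because the raw rule
assigns probability zero to the no-match pile, and attention weights are
clamped at ``attention_floor`` and renormalized so that the ``a^f``
weighting never divides by zero. The convention ``0^0 = 1`` makes ``f = 0``
(and ``d = 0``) weight all dimensions equally.

Four variants are fit in model comparison: the full model (RPDF) and three
3-parameter restrictions — shared learning rate (RRDF, r = p), fixed
consistency (RP1F, d = 1), and unfocused updating (RPD0, f = 0).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from ._kernels import loglik_trace
from .task import (
    AdministrationResult,
    Card,
    ExaminerConfig,
    TrialRecord,
    administer,
    match_vector,
)

__all__ = [
    "ModelConfig",
    "ModelParams",
    "ModelVariant",
    "DegenerateFeedbackError",
    "choice_probabilities",
    "feedback_signal",
    "update_attention",
    "sequence_loglik",
    "trials_to_arrays",
    "ModelAgent",
    "simulate_participant",
    "PARAM_NAMES",
]

PARAM_NAMES = ("r", "p", "d", "f")


class DegenerateFeedbackError(ValueError):
    """The feedback signal has empty support (malformed trial)."""


@dataclass(frozen=True)
class ModelConfig:
    """Numerical configuration shared by likelihood and simulation."""

    d_max: float = 5.0
    f_max: float = 5.0
    choice_floor: float = 1e-3  # uniform-lapse mixture weight on the 4 piles
    attention_floor: float = 1e-6  # clamp on attention weights before renormalizing

    def bounds(self, name: str) -> tuple[float, float]:
        return {
            "r": (0.0, 1.0),
            "p": (0.0, 1.0),
            "d": (0.0, self.d_max),
            "f": (0.0, self.f_max),
        }[name]


@dataclass(frozen=True)
class ModelParams:
    """One participant's parameter vector (r, p, d, f)."""

    r: float
    p: float
    d: float
    f: float

    def validate(self, config: ModelConfig | None = None) -> "ModelParams":
        config = config or ModelConfig()
        for name in PARAM_NAMES:
            lo, hi = config.bounds(name)
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(f"parameter {name}={v} outside [{lo}, {hi}]")
        return self

    def as_array(self) -> np.ndarray:
        return np.array([self.r, self.p, self.d, self.f])


class ModelVariant(enum.Enum):
    """The full model and its three one-restriction variants."""

    RPDF = "RPDF"  # full: r, p, d, f free
    RRDF = "RRDF"  # shared learning rate: r = p
    RP1F = "RP1F"  # decision consistency fixed at 1
    RPD0 = "RPD0"  # attentional focusing fixed at 0

    @property
    def free_names(self) -> tuple[str, ...]:
        return {
            ModelVariant.RPDF: ("r", "p", "d", "f"),
            ModelVariant.RRDF: ("rp", "d", "f"),
            ModelVariant.RP1F: ("r", "p", "f"),
            ModelVariant.RPD0: ("r", "p", "d"),
        }[self]

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def free_bounds(self, config: ModelConfig | None = None) -> np.ndarray:
        config = config or ModelConfig()
        rows = []
        for name in self.free_names:
            rows.append(config.bounds("r" if name == "rp" else name))
        return np.array(rows)

    def to_params(self, theta: np.ndarray) -> ModelParams:
        """Materialize a free-parameter vector into the full (r, p, d, f)."""
        t = np.asarray(theta, dtype=float)
        if t.shape != (self.n_free,):
            raise ValueError(f"{self.value} expects {self.n_free} free parameters")
        if self is ModelVariant.RPDF:
            return ModelParams(*t)
        if self is ModelVariant.RRDF:
            return ModelParams(t[0], t[0], t[1], t[2])
        if self is ModelVariant.RP1F:
            return ModelParams(t[0], t[1], 1.0, t[2])
        return ModelParams(t[0], t[1], t[2], 0.0)

    def constrain(self, params: ModelParams) -> ModelParams:
        """Project a full parameter vector onto the variant's constraint."""
        if self is ModelVariant.RRDF:
            return replace(params, p=params.r)
        if self is ModelVariant.RP1F:
            return replace(params, d=1.0)
        if self is ModelVariant.RPD0:
            return replace(params, f=0.0)
        return params


def _check_simplex(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.shape != (3,) or np.any(a < 0) or abs(a.sum() - 1.0) > 1e-6:
        raise ValueError(f"attention state must lie on the 3-simplex, got {a}")
    return a


def choice_probabilities(
    a: np.ndarray,
    d: float,
    card: Card,
    config: ModelConfig | None = None,
) -> np.ndarray:
    """Pile-choice distribution for ``card`` under attention state ``a``.

    Returns the lapse-mixed distribution
    ``(1 - choice_floor) * P + choice_floor / 4`` over the four piles.
    """
    config = config or ModelConfig()
    a = np.clip(_check_simplex(a), config.attention_floor, 1.0)
    a = a / a.sum()
    powered = a**d
    m = np.stack([match_vector(card, k) for k in (1, 2, 3, 4)])  # (4, 3)
    raw = m @ powered / powered.sum()
    return (1.0 - config.choice_floor) * raw + config.choice_floor / 4.0


def feedback_signal(
    a: np.ndarray,
    f: float,
    m: np.ndarray,
    feedback: str,
    config: ModelConfig | None = None,
) -> np.ndarray:
    """Normalized update direction on the simplex given trial feedback.

    After "right" the signal is supported on the matching dimensions, after
    "wrong" on the non-matching ones, each weighted by ``a^f``.
    """
    config = config or ModelConfig()
    a = np.clip(_check_simplex(a), config.attention_floor, 1.0)
    a = a / a.sum()
    m = np.asarray(m, dtype=float)
    support = m if feedback == "right" else 1.0 - m
    w = support * a**f
    total = w.sum()
    if total <= 0.0:
        raise DegenerateFeedbackError(
            f"feedback signal has empty support (feedback={feedback!r}, match={m.tolist()})"
        )
    return w / total


def update_attention(
    a: np.ndarray,
    s: np.ndarray,
    params: ModelParams,
    feedback: str,
    config: ModelConfig | None = None,
) -> np.ndarray:
    """Convex step of the attention state toward the feedback signal."""
    config = config or ModelConfig()
    a = _check_simplex(a)
    s = _check_simplex(s)
    rate = params.r if feedback == "right" else params.p
    out = (1.0 - rate) * a + rate * s
    out = np.clip(out, config.attention_floor, 1.0)
    return out / out.sum()


def trials_to_arrays(trials: Sequence[TrialRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Pack a trial log into the (match, feedback) arrays the kernel uses."""
    T = len(trials)
    m = np.zeros((T, 3), dtype=np.float64)
    fb = np.zeros(T, dtype=np.int64)
    for i, rec in enumerate(trials):
        if rec.pile not in (1, 2, 3, 4) or rec.feedback not in ("right", "wrong"):
            raise ValueError(f"malformed trial record at index {i}: {rec}")
        m[i] = rec.match
        fb[i] = 1 if rec.feedback == "right" else 0
    return m, fb


def sequence_loglik(
    params: ModelParams,
    trials: Sequence[TrialRecord],
    variant: ModelVariant = ModelVariant.RPDF,
    config: ModelConfig | None = None,
) -> float:
    """Log-likelihood of a trial log under the model.

    The attention state is propagated with the *recorded* choices and
    feedback (standard for fitting); the initial state is uniform
    (1/3, 1/3, 1/3). The empty log has log-likelihood 0.
    """
    config = config or ModelConfig()
    params = variant.constrain(params).validate(config)
    if len(trials) == 0:
        return 0.0
    m, fb = trials_to_arrays(trials)
    return float(
        loglik_trace(
            m, fb, params.r, params.p, params.d, params.f, config.choice_floor, config.attention_floor
        )
    )


class ModelAgent:
    """Sampling agent driven by the attention model; use with ``administer``."""

    def __init__(
        self,
        params: ModelParams,
        seed: int = 0,
        config: ModelConfig | None = None,
    ) -> None:
        self.config = config or ModelConfig()
        self.params = params.validate(self.config)
        self.rng = np.random.default_rng(seed)
        self.attention = np.full(3, 1.0 / 3.0)

    def choose(self, card: Card, history: Sequence[TrialRecord]) -> int:
        probs = choice_probabilities(self.attention, self.params.d, card, self.config)
        return int(self.rng.choice(4, p=probs)) + 1

    def notify(self, record: TrialRecord) -> None:
        s = feedback_signal(
            self.attention, self.params.f, np.array(record.match, dtype=float), record.feedback, self.config
        )
        self.attention = update_attention(self.attention, s, self.params, record.feedback, self.config)


def simulate_participant(
    params: ModelParams,
    deck: Sequence[Card],
    examiner: ExaminerConfig | None = None,
    seed: int = 0,
    config: ModelConfig | None = None,
) -> AdministrationResult:
    """Forward-simulate one administration under the model.

    Deterministic given ``seed``: the agent samples piles from its choice
    distribution and updates its attention state from the examiner's
    feedback.
    """
    agent = ModelAgent(params, seed=seed, config=config)
    return administer(agent, deck, examiner)
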