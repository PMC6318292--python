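"""Wisconsin Card Sorting Test administration.

The WCST asks the participant to sort a sequence of stimulus cards onto four
key piles. Each card varies on three dimensions (color, form, number); the
examiner silently enforces a prevailing sorting rule, answers "right" or
"wrong" after every sort, advances the rule after a run of consecutive
correct sorts, and discontinues the test once a maximum number of categories
has been completed or the deck runs out.

This module implements the deck, the deterministic examiner, and a small
agent protocol so that any policy (omniscient, fixed-pile, random, or the
learning model in :mod:`wcstmap.model`) can be run through a full
administration and scored downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Protocol, Sequence

import numpy as np
import pandas as pd

COLORS = ("red", "green", "yellow", "blue")
FORMS = ("triangle", "star", "cross", "circle")
NUMBERS = (1, 2, 3, 4)
DIMENSIONS = ("color", "form", "number")

__all__ = [
    "Card",
    "KEY_CARDS",
    "DeckConfig",
    "ExaminerConfig",
    "TrialRecord",
    "AdministrationResult",
    "Agent",
    "OmniscientAgent",
    "FixedPileAgent",
    "RandomAgent",
    "DeckFormatError",
    "ProtocolError",
    "build_deck",
    "match_vector",
    "administer",
    "prevailing_rule",
    "write_trials",
    "read_trials",
]


class DeckFormatError(ValueError):
    """A fixed-order deck file contains invalid or duplicated cards."""


class ProtocolError(RuntimeError):
    """An agent violated the administration protocol (e.g. invalid pile)."""


class Card(NamedTuple):
    """One stimulus card: a color, a form, and a number of symbols."""

    color: str
    form: str
    number: int

    def validate(self) -> "Card":
        if self.color not in COLORS or self.form not in FORMS or self.number not in NUMBERS:
            raise DeckFormatError(f"invalid card {self!r}")
        return self


#: The four fixed key piles: one red triangle, two green stars, three yellow
#: crosses, four blue circles. They pairwise differ on every dimension, so
#: each attribute value of any card matches exactly one pile.
KEY_CARDS: tuple[Card, ...] = (
    Card("red", "triangle", 1),
    Card("green", "star", 2),
    Card("yellow", "cross", 3),
    Card("blue", "circle", 4),
)


def match_vector(card: Card, pile: int) -> np.ndarray:
    """Binary (color, form, number) match pattern of ``card`` against ``pile``.

    Parameters
    ----------
    card : Card
    pile : int
        Pile index, 1-4.

    Returns
    -------
    numpy.ndarray of shape (3,)
        Entry ``i`` is 1 iff the card equals the key card of ``pile`` on
        dimension ``i``.
    """
    if pile not in (1, 2, 3, 4):
        raise ProtocolError(f"pile must be 1-4, got {pile}")
    key = KEY_CARDS[pile - 1]
    return np.array(
        [int(card.color == key.color), int(card.form == key.form), int(card.number == key.number)],
        dtype=np.int64,
    )


@dataclass(frozen=True)
class DeckConfig:
    """How the stimulus deck is assembled.

    copies
        Number of identical 64-card decks stacked (standard administration
        uses 2, for 128 trials).
    order
        ``"shuffle"`` draws a seeded permutation independently for each
        copy; ``"fixed"`` loads one copy's order from ``fixed_list`` (a CSV
        with columns color, form, number) and repeats it.
    exclude_key_cards
        Drop the four cards identical to key cards (60-card copies).
    """

    copies: int = 2
    order: str = "shuffle"
    fixed_list: str | Path | None = None
    exclude_key_cards: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if self.order not in ("shuffle", "fixed"):
            raise ValueError(f"unknown order mode {self.order!r}")
        if self.order == "fixed" and self.fixed_list is None:
            raise ValueError("order='fixed' requires fixed_list")


def _factorial_cards(exclude_key_cards: bool) -> list[Card]:
    cards = [Card(c, f, n) for c, f, n in itertools.product(COLORS, FORMS, NUMBERS)]
    if exclude_key_cards:
        cards = [c for c in cards if c not in KEY_CARDS]
    return cards


def _read_fixed_list(path: str | Path, exclude_key_cards: bool) -> list[Card]:
    df = pd.read_csv(path)
    missing = {"color", "form", "number"} - set(df.columns)
    if missing:
        raise DeckFormatError(f"fixed deck file missing columns: {sorted(missing)}")
    cards = [Card(str(r.color), str(r.form), int(r.number)).validate() for r in df.itertuples()]
    if len(set(cards)) != len(cards):
        raise DeckFormatError("fixed deck file contains duplicate cards")
    expected = set(_factorial_cards(exclude_key_cards))
    if set(cards) != expected:
        raise DeckFormatError("fixed deck file is not a permutation of the full card set")
    return cards


def build_deck(config: DeckConfig | None = None) -> list[Card]:
    """Assemble the ordered card sequence for one administration.

    Each copy contains every (color, form, number) combination exactly once;
    copies are concatenated. Deterministic given ``config.seed``.
    """
    config = config or DeckConfig()
    if config.order == "fixed":
        copy = _read_fixed_list(config.fixed_list, config.exclude_key_cards)
        return list(copy) * config.copies
    rng = np.random.default_rng(config.seed)
    base = _factorial_cards(config.exclude_key_cards)
    deck: list[Card] = []
    for _ in range(config.copies):
        order = rng.permutation(len(base))
        deck.extend(base[i] for i in order)
    return deck


@dataclass(frozen=True)
class ExaminerConfig:
    """Examiner behavior: run length per category, category cap, rule cycle."""

    run_length: int = 10
    max_categories: int = 6
    rules: tuple[str, ...] = ("color", "form", "number")

    def __post_init__(self) -> None:
        if self.run_length < 1 or self.max_categories < 1:
            raise ValueError("run_length and max_categories must be >= 1")
        for r in self.rules:
            if r not in DIMENSIONS:
                raise ValueError(f"unknown rule {r!r}")

    def rule_at(self, n_completed: int) -> str:
        return self.rules[n_completed % len(self.rules)]


@dataclass(frozen=True)
class TrialRecord:
    """One administered trial, as logged by the examiner."""

    trial: int  # 1-based
    card: Card
    pile: int  # 1-4
    feedback: str  # "right" | "wrong"
    rule: str  # prevailing rule at this trial
    match: tuple[int, int, int]  # card-vs-chosen-pile match vector


@dataclass
class AdministrationResult:
    """Full trial log plus the examiner's termination bookkeeping."""

    trials: list[TrialRecord]
    categories_completed: int
    termination: str  # "discontinued" | "deck_exhausted"

    @property
    def n_trials(self) -> int:
        return len(self.trials)


class Agent(Protocol):
    def choose(self, card: Card, history: Sequence[TrialRecord]) -> int:
        """Return the pile (1-4) to sort ``card`` onto."""


def prevailing_rule(history: Sequence[TrialRecord], examiner: ExaminerConfig) -> str:
    """Reconstruct the examiner's current rule from a trial log.

    Replays the run-of-consecutive-correct bookkeeping, which is fully
    determined by the feedback sequence.
    """
    completed = 0
    streak = 0
    for rec in history:
        if rec.feedback == "right":
            streak += 1
        else:
            streak = 0
        if streak == examiner.run_length:
            completed += 1
            streak = 0
    return examiner.rule_at(completed)


class OmniscientAgent:
    """Testing agent that always sorts by the prevailing rule.

    It infers the rule from its own feedback history (it never errs, so the
    reconstruction is exact); used as the ceiling-performance reference.
    """

    def __init__(self, examiner: ExaminerConfig | None = None) -> None:
        self.examiner = examiner or ExaminerConfig()

    def choose(self, card: Card, history: Sequence[TrialRecord]) -> int:
        rule = prevailing_rule(history, self.examiner)
        dim = DIMENSIONS.index(rule)
        for pile in (1, 2, 3, 4):
            if match_vector(card, pile)[dim] == 1:
                return pile
        raise AssertionError("every attribute value matches exactly one pile")


class FixedPileAgent:
    """Always chooses the same pile, regardless of the card."""

    def __init__(self, pile: int = 4) -> None:
        self.pile = pile

    def choose(self, card: Card, history: Sequence[TrialRecord]) -> int:
        return self.pile


class RandomAgent:
    """Chooses uniformly among the four piles."""

    def __init__(self, seed: int = 0) -> None:
        self.rng = np.random.default_rng(seed)

    def choose(self, card: Card, history: Sequence[TrialRecord]) -> int:
        return int(self.rng.integers(1, 5))


def administer(
    agent: Agent,
    deck: Sequence[Card],
    examiner: ExaminerConfig | None = None,
) -> AdministrationResult:
    """Run one full administration of ``deck`` against ``agent``.

    Feedback follows the prevailing rule; the rule advances silently after
    ``examiner.run_length`` consecutive correct sorts; the test stops when
    ``examiner.max_categories`` categories are completed or the deck is
    exhausted. Agents exposing a ``notify(record)`` method receive each
    trial's record after feedback (used by learning agents).
    """
    examiner = examiner or ExaminerConfig()
    if len(deck) == 0:
        raise ValueError("deck is empty")
    trials: list[TrialRecord] = []
    completed = 0
    streak = 0
    for t, card in enumerate(deck, start=1):
        pile = agent.choose(card, trials)
        if not isinstance(pile, (int, np.integer)) or pile not in (1, 2, 3, 4):
            raise ProtocolError(f"agent returned invalid pile {pile!r} on trial {t}")
        pile = int(pile)
        rule = examiner.rule_at(completed)
        mv = match_vector(card, pile)
        correct = bool(mv[DIMENSIONS.index(rule)])
        rec = TrialRecord(t, card, pile, "right" if correct else "wrong", rule, tuple(int(x) for x in mv))
        trials.append(rec)
        notify = getattr(agent, "notify", None)
        if notify is not None:
            notify(rec)
        streak = streak + 1 if correct else 0
        if streak == examiner.run_length:
            completed += 1
            streak = 0
            if completed == examiner.max_categories:
                return AdministrationResult(trials, completed, "discontinued")
    return AdministrationResult(trials, completed, "deck_exhausted")


# ---------------------------------------------------------------------------
# Trial-log CSV round-tripping

_LOG_COLUMNS = ["trial", "color", "form", "number", "pile", "feedback", "rule"]


def trials_to_frame(trials: Iterable[TrialRecord], participant: str | None = None) -> pd.DataFrame:
    rows = [
        {
            "trial": r.trial,
            "color": r.card.color,
            "form": r.card.form,
            "number": r.card.number,
            "pile": r.pile,
            "feedback": r.feedback,
            "rule": r.rule,
        }
        for r in trials
    ]
    df = pd.DataFrame(rows, columns=_LOG_COLUMNS)
    if participant is not None:
        df.insert(0, "participant", participant)
    return df


def write_trials(trials: Iterable[TrialRecord], path: str | Path, participant: str | None = None) -> None:
    trials_to_frame(trials, participant).to_csv(path, index=False)


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    out = []
    for r in df.itertuples():
        card = Card(str(r.color), str(r.form), int(r.number)).validate()
        pile = int(r.pile)
        if r.feedback not in ("right", "wrong"):
            raise DeckFormatError(f"invalid feedback {r.feedback!r}")
        mv = match_vector(card, pile)
        out.append(
            TrialRecord(int(r.trial), card, pile, str(r.feedback), str(r.rule), tuple(int(x) for x in mv))
        )
    return out


def read_trials(path: str | Path) -> list[TrialRecord]:
    """Read a single-participant trial log written by :func:`write_trials`."""
    return frame_to_trials(pd.read_csv(path))


def read_trials_long(path: str | Path) -> dict[str, list[TrialRecord]]:
    """Read a long-format multi-participant log keyed by participant id."""
    df = pd.read_csv(path)
    if "participant" not in df.columns:
        raise DeckFormatError("long-format log requires a 'participant' column")
    return {str(pid): frame_to_trials(g) for pid, g in df.groupby("participant", sort=True)}
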