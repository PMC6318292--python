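"""Standard WCST scores computed from an administration log.

Five scores are produced:

PSV
    Perseverative errors — errors consistent with a previously correct,
    now-invalid sorting principle.
NPSV
    Non-perseverative errors — all remaining errors.
NCAT
    Number of categories achieved (0 to the examiner's maximum).
FSET
    Failures to maintain set — runs of at least five consecutive correct
    sorts within a category that end in an error before the category is
    completed.
TRSET1
    Trials to complete the first set — 1-based index of the trial on which
    the first category is completed; if it never is, the total number of
    trials administered, with ``trset1_completed`` False so downstream
    statistics can censor.

The perseverated-to principle is identified by a pluggable strategy. The
default ("previous-rule") sets the principle to the previously correct rule
at every rule change and counts any error whose response matches the card on
that dimension; "previous-rule-unambiguous" counts only errors matching the
card *solely* on that dimension. Published manual scoring uses a more
intricate algorithm (three-response establishment, sandwich rule); the
strategies here are deliberately simple, documented approximations.
"""

from __future__ import annotations

from dataclasses import dataclass

from .task import DIMENSIONS, AdministrationResult, ExaminerConfig, TrialRecord

__all__ = ["WCSTScores", "ScoringError", "score_administration", "SCORE_NAMES"]

SCORE_NAMES = ("PSV", "NPSV", "NCAT", "FSET", "TRSET1")


class ScoringError(ValueError):
    """The log is internally inconsistent (feedback contradicts the rules)."""


@dataclass(frozen=True)
class WCSTScores:
    psv: int
    npsv: int
    ncat: int
    fset: int
    trset1: int
    trset1_completed: bool
    trials_administered: int

    def as_dict(self) -> dict[str, float]:
        return {
            "PSV": self.psv,
            "NPSV": self.npsv,
            "NCAT": self.ncat,
            "FSET": self.fset,
            "TRSET1": self.trset1,
            "trset1_completed": self.trset1_completed,
            "trials_administered": self.trials_administered,
        }


def _validate(trials: list[TrialRecord], examiner: ExaminerConfig) -> None:
    completed = 0
    streak = 0
    for rec in trials:
        rule = examiner.rule_at(completed)
        if rec.rule != rule:
            raise ScoringError(f"trial {rec.trial}: logged rule {rec.rule!r}, expected {rule!r}")
        correct = bool(rec.match[DIMENSIONS.index(rule)])
        if (rec.feedback == "right") != correct:
            raise ScoringError(f"trial {rec.trial}: feedback inconsistent with rule {rule!r}")
        streak = streak + 1 if correct else 0
        if streak == examiner.run_length:
            completed += 1
            streak = 0


def score_administration(
    result: AdministrationResult,
    examiner: ExaminerConfig | None = None,
    perseveration_strategy: str = "previous-rule",
    fset_run_length: int = 5,
) -> WCSTScores:
    """Score one administration.

    Parameters
    ----------
    result
        Trial log from :func:`wcstmap.task.administer`.
    examiner
        The configuration the log was produced under (run length, rule
        cycle); used to validate consistency and replay category boundaries.
    perseveration_strategy
        "previous-rule" (default) or "previous-rule-unambiguous"; see module
        docstring.
    fset_run_length
        Minimum run of consecutive correct sorts that counts as an
        established set for FSET.
    """
    if perseveration_strategy not in ("previous-rule", "previous-rule-unambiguous"):
        raise ValueError(f"unknown perseveration strategy {perseveration_strategy!r}")
    examiner = examiner or ExaminerConfig()
    trials = result.trials
    _validate(trials, examiner)

    psv = npsv = fset = 0
    completed = 0
    streak = 0
    trset1 = len(trials)
    trset1_completed = False
    persev_dim: int | None = None  # no perseverated-to principle before the first rule change

    for rec in trials:
        wrong = rec.feedback == "wrong"
        if wrong:
            if streak >= fset_run_length:
                fset += 1
            if persev_dim is not None:
                matches_persev = rec.match[persev_dim] == 1
                if perseveration_strategy == "previous-rule-unambiguous":
                    matches_persev = matches_persev and sum(rec.match) == 1
                if matches_persev:
                    psv += 1
                else:
                    npsv += 1
            else:
                npsv += 1
            streak = 0
        else:
            streak += 1
            if streak == examiner.run_length:
                if completed == 0:
                    trset1 = rec.trial
                    trset1_completed = True
                persev_dim = DIMENSIONS.index(examiner.rule_at(completed))
                completed += 1
                streak = 0

    return WCSTScores(
        psv=psv,
        npsv=npsv,
        ncat=completed,
        fset=fset,
        trset1=trset1,
        trset1_completed=trset1_completed,
        trials_administered=len(trials),
    )
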