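"""Threshold-plus-hysteresis segmentation of symptom traces into episodes.

An agent enters an episode on the first day its symptoms strictly exceed the
diagnostic threshold, and the episode ends on the first subsequent day the
symptoms fall strictly below ``remission_stringency * threshold``. Because
the remission cut-point sits below the onset threshold (hysteresis), days in
between the two cut-points leave the state unchanged. An episode still open
on the final day of the trace is censored.

Day numbering is 1-based throughout; symptoms are undefined before day 14,
so no episode can start earlier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agent_dynamics import SYMPTOM_WINDOW_DAYS, SymptomTrace

__all__ = [
    "DiagnosticRule",
    "Episode",
    "segment_episodes",
    "segment_symptom_matrix",
    "illness_state_matrix",
    "baseline_state",
]


@dataclass(frozen=True)
class DiagnosticRule:
    """Onset threshold and remission stringency of the nominal diagnosis."""

    threshold: float
    remission_stringency: float

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ValueError(f"threshold must be positive, got {self.threshold}")
        if not 0 < self.remission_stringency <= 1:
            raise ValueError(
                "remission_stringency must be in (0, 1], "
                f"got {self.remission_stringency}"
            )

    @property
    def remission_cut(self) -> float:
        """Symptom level below which an open episode ends."""
        return self.remission_stringency * self.threshold


@dataclass(frozen=True)
class Episode:
    """One above-threshold interval of a symptom trace.

    ``start_day`` is the first day symptoms exceed the threshold; ``end_day``
    the first day they drop below the remission cut (``None`` when censored
    at the horizon). For uncensored episodes ``duration_days = end_day -
    start_day`` (the end day itself is already remitted); censored episodes
    count all remaining days, ``horizon - start_day + 1``.
    """

    start_day: int
    end_day: int | None
    duration_days: int
    censored: bool

    def __post_init__(self) -> None:
        if self.censored != (self.end_day is None):
            raise ValueError("end_day must be None exactly when censored")
        if not self.censored and self.duration_days != self.end_day - self.start_day:
            raise ValueError("duration_days inconsistent with start/end days")
        if self.duration_days < 1:
            raise ValueError("episodes last at least one day")


def _as_symptoms(trace: SymptomTrace | np.ndarray) -> np.ndarray:
    if isinstance(trace, SymptomTrace):
        return trace.symptoms
    return np.asarray(trace, dtype=float)


def segment_episodes(
    trace: SymptomTrace | np.ndarray, rule: DiagnosticRule
) -> list[Episode]:
    """Segment one symptom trace into an ordered list of episodes.

    Accepts either a :class:`SymptomTrace` or a raw 1-D symptom array (1-based
    day ``t`` at index ``t - 1``, NaN where undefined). A trace already above
    threshold on its first defined day opens an episode on that day.
    """
    symptoms = _as_symptoms(trace)
    episodes: list[Episode] = []
    ill = False
    start_day = 0
    for i, value in enumerate(symptoms):
        day = i + 1
        if np.isnan(value):
            continue
        if not ill and value > rule.threshold:
            ill = True
            start_day = day
        elif ill and value < rule.remission_cut:
            ill = False
            episodes.append(
                Episode(
                    start_day=start_day,
                    end_day=day,
                    duration_days=day - start_day,
                    censored=False,
                )
            )
    if ill:
        horizon = symptoms.size
        episodes.append(
            Episode(
                start_day=start_day,
                end_day=None,
                duration_days=horizon - start_day + 1,
                censored=True,
            )
        )
    return episodes


def illness_state_matrix(symptoms: np.ndarray, rule: DiagnosticRule) -> np.ndarray:
    """Vectorized two-state machine over a (n_agents, horizon) symptom matrix.

    Returns a boolean matrix that is True on every day each agent is inside
    an episode. Equivalent to running :func:`segment_episodes` row by row.
    """
    symptoms = np.asarray(symptoms, dtype=float)
    if symptoms.ndim != 2:
        raise ValueError("symptoms must have shape (n_agents, horizon)")
    n, horizon = symptoms.shape
    with np.errstate(invalid="ignore"):
        onset = symptoms > rule.threshold
        remit = symptoms < rule.remission_cut
    # last-signal-wins forward fill: +1 on onset days, -1 on remission days
    signal = np.where(onset, 1, np.where(remit & ~np.isnan(symptoms), -1, 0))
    days = np.arange(horizon)
    last = np.where(signal != 0, days, -1)
    np.maximum.accumulate(last, axis=1, out=last)
    rows = np.arange(n)[:, None]
    state = np.where(last >= 0, signal[rows, np.maximum(last, 0)], -1)
    return state == 1


def segment_symptom_matrix(
    symptoms: np.ndarray, rule: DiagnosticRule
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """All episodes of a symptom matrix, flattened across agents.

    Returns ``(agent_index, start_day, end_day, censored)`` arrays, one entry
    per episode, ordered by agent then start day. ``end_day`` is 0 for
    censored episodes. Days are 1-based.
    """
    ill = illness_state_matrix(symptoms, rule)
    padded = np.zeros((ill.shape[0], ill.shape[1] + 1), dtype=bool)
    padded[:, :-1] = ill
    delta = np.diff(padded.astype(np.int8), axis=1, prepend=0)
    starts = np.nonzero(delta == 1)
    ends = np.nonzero(delta == -1)
    # runs alternate start/end within each row, so counts and order align
    agent_idx = starts[0]
    start_day = starts[1] + 1
    end_day = ends[1] + 1
    censored = end_day > ill.shape[1]
    end_day = np.where(censored, 0, end_day)
    return agent_idx, start_day, end_day, censored


def baseline_state(
    trace: SymptomTrace | np.ndarray,
    rule: DiagnosticRule,
    elevated_cut: float,
) -> str:
    """Classify the day-14 symptom level.

    Returns ``"depressed"`` above the diagnostic threshold, ``"elevated"``
    above ``elevated_cut``, and ``"low"`` otherwise.
    """
    if not elevated_cut > 0:
        raise ValueError(f"elevated_cut must be positive, got {elevated_cut}")
    symptoms = _as_symptoms(trace)
    if symptoms.size < SYMPTOM_WINDOW_DAYS:
        raise ValueError("trace too short: day-14 symptoms undefined")
    value = float(symptoms[SYMPTOM_WINDOW_DAYS - 1])
    if np.isnan(value):
        raise ValueError("day-14 symptoms undefined in trace")
    if value > rule.threshold:
        return "depressed"
    if value > elevated_cut:
        return "elevated"
    return "low"
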