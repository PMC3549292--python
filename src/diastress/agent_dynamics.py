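"""Daily stress-burden and symptom dynamics for a single agent.

The burden update combines activation (stress times diathesis, added each
day) with adaptation (a diathesis-dependent fraction of the previous day's
burden, removed each day):

    burden[t] = burden[t-1] + stress[t] * d - burden[t-1] / (1 + c * d)

where ``d`` is the diathesis and ``c`` the adaptation constant. With ``c = 0``
the whole previous burden is cleared every day, so the burden equals that
day's activation. Under constant stress ``s`` the burden converges
geometrically to the fixed point ``s * d * (1 + c * d)``.

Symptom levels are the trailing 14-day mean of the burden (current day plus
the previous 13) and are undefined before day 14.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stress_environment import StressSeries

SYMPTOM_WINDOW_DAYS = 14
"""Trailing moving-average window over the burden, in days (fixed)."""

__all__ = [
    "SYMPTOM_WINDOW_DAYS",
    "AgentParams",
    "SymptomTrace",
    "step_burden",
    "run_agent",
    "burden_matrix",
    "symptoms_from_burden",
]


@dataclass(frozen=True)
class AgentParams:
    """Static parameters of one agent.

    Attributes
    ----------
    diathesis : float
        Positive vulnerability multiplier. Scales activation up and slows
        adaptation down.
    adaptation_constant : float
        Non-negative constant modulating how strongly the diathesis slows
        adaptation; 0 means the full previous burden is cleared daily.
    """

    diathesis: float
    adaptation_constant: float

    def __post_init__(self) -> None:
        if not self.diathesis > 0:
            raise ValueError(f"diathesis must be positive, got {self.diathesis}")
        if self.adaptation_constant < 0:
            raise ValueError(
                f"adaptation_constant must be non-negative, "
                f"got {self.adaptation_constant}"
            )

    @property
    def adaptation_fraction(self) -> float:
        """Fraction of the previous day's burden removed each day."""
        return 1.0 / (1.0 + self.adaptation_constant * self.diathesis)


@dataclass(frozen=True)
class SymptomTrace:
    """Daily stress, burden and symptom series for one agent.

    ``symptoms[t]`` is the mean of ``burden[t-13..t]`` (1-based days); entries
    for days 1-13 are NaN because the 14-day window is incomplete there.
    """

    stress: StressSeries
    burden: np.ndarray
    symptoms: np.ndarray
    window_days: int = SYMPTOM_WINDOW_DAYS

    @property
    def horizon_days(self) -> int:
        return self.burden.size

    def symptoms_on(self, day: int) -> float:
        """Symptom level on a 1-based day; NaN when undefined."""
        if not 1 <= day <= self.horizon_days:
            raise IndexError(f"day {day} outside 1..{self.horizon_days}")
        return float(self.symptoms[day - 1])


def step_burden(prev_burden: float, stress_today: float, params: AgentParams) -> float:
    """One-day burden update: activation added, adaptation removed.

    Raises
    ------
    ValueError
        If ``prev_burden`` is negative (contract violation).
    """
    if prev_burden < 0:
        raise ValueError(f"prev_burden must be non-negative, got {prev_burden}")
    # carried-fraction form of prev + stress*d - prev/(1 + c*d): exact when
    # the adaptation fraction is 1 (c = 0) and matches the vectorized path
    new = prev_burden * (1.0 - params.adaptation_fraction) + (
        stress_today * params.diathesis
    )
    # adaptation fraction <= 1, so the update cannot go negative from a
    # non-negative state; the guard is an assertion, not a behavior change
    assert new >= 0.0
    return new


def burden_matrix(
    diathesis: np.ndarray,
    adaptation_constant: float,
    stress: np.ndarray,
) -> np.ndarray:
    """Vectorized burden recursion for many agents at once.

    Parameters
    ----------
    diathesis : np.ndarray, shape (n,)
        Per-agent diathesis values.
    adaptation_constant : float
        Shared adaptation constant.
    stress : np.ndarray, shape (n, horizon)
        Per-agent daily stress levels.

    Returns
    -------
    np.ndarray, shape (n, horizon)
        Daily burden, starting from burden 0 before day 1.
    """
    diathesis = np.asarray(diathesis, dtype=float)
    stress = np.asarray(stress, dtype=float)
    if stress.ndim != 2 or stress.shape[0] != diathesis.size:
        raise ValueError("stress must have shape (n_agents, horizon)")
    keep = 1.0 - 1.0 / (1.0 + adaptation_constant * diathesis)  # carried fraction
    burden = np.empty_like(stress)
    current = np.zeros(diathesis.size)
    activation = stress * diathesis[:, None]
    for t in range(stress.shape[1]):
        current = current * keep + activation[:, t]
        burden[:, t] = current
    return burden


def symptoms_from_burden(
    burden: np.ndarray, window_days: int = SYMPTOM_WINDOW_DAYS
) -> np.ndarray:
    """Trailing moving average of the burden along the last axis.

    The first ``window_days - 1`` entries are NaN (incomplete window).
    """
    burden = np.asarray(burden, dtype=float)
    cs = np.cumsum(burden, axis=-1)
    symptoms = np.full_like(burden, np.nan)
    head = cs[..., window_days - 1 : window_days]  # window ending exactly at day 14
    symptoms[..., window_days - 1 : window_days] = head / window_days
    if burden.shape[-1] > window_days:
        symptoms[..., window_days:] = (
            cs[..., window_days:] - cs[..., :-window_days]
        ) / window_days
    return symptoms


def run_agent(params: AgentParams, stress: StressSeries | np.ndarray) -> SymptomTrace:
    """Evolve one agent over the full stress series.

    The burden starts at 0 before the first day; symptoms are the trailing
    14-day burden mean, defined from day 14 onward.
    """
    if not isinstance(stress, StressSeries):
        stress = StressSeries(values=np.asarray(stress, dtype=float))
    burden = burden_matrix(
        np.array([params.diathesis]), params.adaptation_constant, stress.values[None, :]
    )[0]
    symptoms = symptoms_from_burden(burden)
    return SymptomTrace(stress=stress, burden=burden, symptoms=symptoms)
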