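"""Daily stress exposure generator.

Each agent experiences one positive stress level per day, drawn i.i.d. from a
lognormal distribution whose underlying normal has mean zero and a
configurable standard deviation. The median stress level is therefore 1 and
the distribution is right-skewed for large standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["StressSeries", "generate_stress_series", "agent_rng"]


@dataclass(frozen=True)
class StressSeries:
    """A per-day stress exposure series for one agent.

    Attributes
    ----------
    values : np.ndarray
        Strictly positive stress levels, one per day; ``values[0]`` is day 1.
    seed_state : str
        Provenance record of the random stream that produced the draws.
    """

    values: np.ndarray
    seed_state: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1:
            raise ValueError("stress series must be one-dimensional")
        if values.size == 0:
            raise ValueError("stress series must cover at least one day")
        if not np.all(values > 0):
            raise ValueError("stress values must be strictly positive")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size


def agent_rng(seed: int, agent_index: int) -> np.random.Generator:
    """Deterministic per-agent random stream.

    Substreams are derived from ``(seed, agent_index)`` via
    :class:`numpy.random.SeedSequence` spawn keys, so an agent's draws do not
    depend on cohort size or simulation order.
    """
    if agent_index < 0:
        raise ValueError("agent_index must be non-negative")
    return np.random.default_rng(
        np.random.SeedSequence(seed, spawn_key=(agent_index,))
    )


def generate_stress_series(
    stress_sd: float,
    horizon_days: int,
    rng: np.random.Generator,
) -> StressSeries:
    """Draw a daily stress series of length ``horizon_days``.

    Each value is ``exp(Z)`` with ``Z ~ Normal(0, stress_sd)``, independent
    across days. The mean of the series is ``exp(stress_sd**2 / 2)`` and the
    median is 1.

    Parameters
    ----------
    stress_sd : float
        Standard deviation of the underlying normal; must be positive.
    horizon_days : int
        Number of days to draw; must be at least 1.
    rng : np.random.Generator
        Seeded random source (see :func:`agent_rng`).
    """
    if not stress_sd > 0:
        raise ValueError(f"stress_sd must be positive, got {stress_sd}")
    horizon_days = int(horizon_days)
    if horizon_days < 1:
        raise ValueError(f"horizon_days must be >= 1, got {horizon_days}")
    values = np.exp(rng.normal(loc=0.0, scale=stress_sd, size=horizon_days))
    return StressSeries(values=values, seed_state=repr(rng.bit_generator.seed_seq))
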