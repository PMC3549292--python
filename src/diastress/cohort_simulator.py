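"""Cohort simulation: heterogeneous agents over a multi-year horizon.

Each agent gets a lognormally distributed diathesis and an independent daily
stress series, is evolved through the burden/symptom dynamics, and has its
symptom trace segmented into diagnostic episodes. The per-agent summary rows
(:class:`AgentRecord`) are the unit of the output CSV and the input to the
epidemiologic analyses.

The default configuration reproduces the reference parameterization:
diathesis SD 0.20, stress SD 0.75, adaptation constant 3.0, threshold 15,
remission stringency 0.5, over a 10-year (3652-day) horizon.
"""

from __future__ import annotations

import csv
import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import yaml

from .agent_dynamics import SYMPTOM_WINDOW_DAYS, burden_matrix, symptoms_from_burden
from .episode_classifier import DiagnosticRule, Episode, segment_symptom_matrix
from .stress_environment import agent_rng

DAYS_PER_YEAR = 365.2
"""Analysis-year length in days (3652-day decade split into 10 equal years)."""

DEFAULT_AGENT_DAY_CAP = 1_000_000_000
"""Resource guard: refuse cohorts above this many agent-days unless overridden."""

_CHUNK_AGENTS = 8_192  # agents simulated per vectorized block (memory bound)

__all__ = [
    "DAYS_PER_YEAR",
    "SimConfig",
    "AgentRecord",
    "draw_diathesis",
    "simulate_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
    "records_to_frame",
    "year10_start_day",
]


@dataclass(frozen=True)
class SimConfig:
    """Full parameter set of one simulation experiment."""

    n_agents: int = 100_000
    horizon_days: int = 3652
    diathesis_sd: float = 0.20
    stress_sd: float = 0.75
    adaptation_constant: float = 3.0
    threshold: float = 15.0
    remission_stringency: float = 0.5
    elevated_cut: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_agents < 0:
            raise ValueError(f"n_agents must be non-negative, got {self.n_agents}")
        if self.horizon_days < SYMPTOM_WINDOW_DAYS:
            raise ValueError(
                f"horizon_days must be >= {SYMPTOM_WINDOW_DAYS} "
                f"(symptoms undefined earlier), got {self.horizon_days}"
            )
        if not self.diathesis_sd > 0:
            raise ValueError(f"diathesis_sd must be positive, got {self.diathesis_sd}")
        if not self.stress_sd > 0:
            raise ValueError(f"stress_sd must be positive, got {self.stress_sd}")
        if self.adaptation_constant < 0:
            raise ValueError("adaptation_constant must be non-negative")
        # delegate threshold/stringency validation
        self.rule()

    def rule(self) -> DiagnosticRule:
        return DiagnosticRule(
            threshold=self.threshold, remission_stringency=self.remission_stringency
        )

    def replace(self, **changes) -> "SimConfig":
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "SimConfig":
        """Load a flat key:value config file (YAML); kwargs override file values."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must hold a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys in {path}: {sorted(unknown)}")
        raw.update(overrides)
        return cls(**raw)


@dataclass(frozen=True)
class AgentRecord:
    """Per-agent summary row of one simulated cohort.

    ``onset_day`` is the start day of the first episode, or ``None`` when the
    agent never has one (censored at the horizon). ``episode_in_year_10``
    counts an episode that is ongoing during year 10 as well as one starting
    in it; ``episode_starting_in_year_10`` is the stricter variant.
    """

    agent_id: int
    diathesis: float
    baseline_symptoms: float
    baseline_state: str
    ever_episode: bool
    onset_day: int | None
    episode_count: int
    episodes_years_1_9: int
    episode_in_year_10: bool
    episode_starting_in_year_10: bool
    first_episode_duration_days: int | None
    first_episode_censored: bool | None


def year10_start_day() -> int:
    """First 1-based day of analysis year 10 (day 3288 of a 3652-day run)."""
    return int(round(9 * DAYS_PER_YEAR)) + 1


def draw_diathesis(diathesis_sd: float, rng: np.random.Generator) -> float:
    """One positive diathesis value, exp(Normal(0, diathesis_sd))."""
    if not diathesis_sd > 0:
        raise ValueError(f"diathesis_sd must be positive, got {diathesis_sd}")
    return float(np.exp(rng.normal(loc=0.0, scale=diathesis_sd)))


def _draw_agent_inputs(
    config: SimConfig, agent_ids: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Diathesis vector and stress matrix for a block of agents.

    Each agent's substream first yields its diathesis, then its stress
    series, so results are independent of cohort size and ordering.
    """
    n = agent_ids.size
    diathesis = np.empty(n)
    stress = np.empty((n, config.horizon_days))
    for row, agent_id in enumerate(agent_ids):
        rng = agent_rng(config.seed, int(agent_id))
        diathesis[row] = draw_diathesis(config.diathesis_sd, rng)
        stress[row] = np.exp(
            rng.normal(loc=0.0, scale=config.stress_sd, size=config.horizon_days)
        )
    return diathesis, stress


def _summarize_block(
    config: SimConfig,
    agent_ids: np.ndarray,
    diathesis: np.ndarray,
    symptoms: np.ndarray,
) -> list[AgentRecord]:
    rule = config.rule()
    horizon = config.horizon_days
    n = agent_ids.size
    y10 = year10_start_day()
    y19_last = y10 - 1

    ep_agent, ep_start, ep_end, ep_cens = segment_symptom_matrix(symptoms, rule)

    episode_count = np.bincount(ep_agent, minlength=n)
    ever = episode_count > 0

    first_mask = np.ones(ep_agent.size, dtype=bool)
    first_mask[1:] = ep_agent[1:] != ep_agent[:-1]
    f_agent = ep_agent[first_mask]
    f_start = ep_start[first_mask]
    f_end = ep_end[first_mask]
    f_cens = ep_cens[first_mask]
    f_duration = np.where(f_cens, horizon - f_start + 1, f_end - f_start)

    onset_day = np.zeros(n, dtype=int)
    onset_day[f_agent] = f_start
    first_duration = np.zeros(n, dtype=int)
    first_duration[f_agent] = f_duration
    first_censored = np.zeros(n, dtype=bool)
    first_censored[f_agent] = f_cens

    in_years_1_9 = (ep_start >= SYMPTOM_WINDOW_DAYS) & (ep_start <= y19_last)
    episodes_y19 = np.bincount(ep_agent[in_years_1_9], minlength=n)

    starts_y10 = np.bincount(ep_agent[ep_start >= y10], minlength=n) > 0
    # ongoing-inclusive: episode overlaps year 10 iff it has not remitted
    # before day y10 (end_day is the first remitted day)
    overlaps = ep_cens | (ep_end > y10)
    ongoing_y10 = np.bincount(ep_agent[(ep_start >= y10) | overlaps], minlength=n) > 0

    baseline = symptoms[:, SYMPTOM_WINDOW_DAYS - 1]
    states = np.where(
        baseline > rule.threshold,
        "depressed",
        np.where(baseline > config.elevated_cut, "elevated", "low"),
    )

    records = []
    for i in range(n):
        has = bool(ever[i])
        records.append(
            AgentRecord(
                agent_id=int(agent_ids[i]),
                diathesis=float(diathesis[i]),
                baseline_symptoms=float(baseline[i]),
                baseline_state=str(states[i]),
                ever_episode=has,
                onset_day=int(onset_day[i]) if has else None,
                episode_count=int(episode_count[i]),
                episodes_years_1_9=int(episodes_y19[i]),
                episode_in_year_10=bool(ongoing_y10[i]),
                episode_starting_in_year_10=bool(starts_y10[i]),
                first_episode_duration_days=int(first_duration[i]) if has else None,
                first_episode_censored=bool(first_censored[i]) if has else None,
            )
        )
    return records


def _block_episodes(
    agent_ids: np.ndarray,
    ep_agent: np.ndarray,
    ep_start: np.ndarray,
    ep_end: np.ndarray,
    ep_cens: np.ndarray,
    horizon: int,
) -> dict[int, list[Episode]]:
    out: dict[int, list[Episode]] = {}
    for a, s, e, c in zip(ep_agent, ep_start, ep_end, ep_cens):
        episode = Episode(
            start_day=int(s),
            end_day=None if c else int(e),
            duration_days=int(horizon - s + 1) if c else int(e - s),
            censored=bool(c),
        )
        out.setdefault(int(agent_ids[a]), []).append(episode)
    return out


def simulate_cohort(
    config: SimConfig,
    return_episodes: bool = False,
    max_agent_days: int = DEFAULT_AGENT_DAY_CAP,
) -> list[AgentRecord] | tuple[list[AgentRecord], dict[int, list[Episode]]]:
    """Simulate a full cohort and summarize each agent into an AgentRecord.

    Deterministic given ``config.seed``. Set ``return_episodes`` to also get
    every agent's full episode list (memory-heavy for large cohorts). Raises
    if ``n_agents * horizon_days`` exceeds ``max_agent_days``.
    """
    total = config.n_agents * config.horizon_days
    if total > max_agent_days:
        raise ValueError(
            f"cohort of {total} agent-days exceeds cap {max_agent_days}; "
            "raise max_agent_days to override"
        )
    records: list[AgentRecord] = []
    episodes: dict[int, list[Episode]] = {}
    for lo in range(0, config.n_agents, _CHUNK_AGENTS):
        agent_ids = np.arange(lo, min(lo + _CHUNK_AGENTS, config.n_agents))
        diathesis, stress = _draw_agent_inputs(config, agent_ids)
        burden = burden_matrix(diathesis, config.adaptation_constant, stress)
        del stress
        symptoms = symptoms_from_burden(burden)
        del burden
        records.extend(_summarize_block(config, agent_ids, diathesis, symptoms))
        if return_episodes:
            parts = segment_symptom_matrix(symptoms, config.rule())
            episodes.update(
                _block_episodes(agent_ids, *parts, horizon=config.horizon_days)
            )
    if return_episodes:
        return records, episodes
    return records


# ---------------------------------------------------------------------------
# CSV round-trip

_COLUMNS = [f.name for f in dataclasses.fields(AgentRecord)]
_BOOL_COLUMNS = {
    "ever_episode",
    "episode_in_year_10",
    "episode_starting_in_year_10",
    "first_episode_censored",
}
_INT_COLUMNS = {
    "agent_id",
    "onset_day",
    "episode_count",
    "episodes_years_1_9",
    "first_episode_duration_days",
}
_FLOAT_COLUMNS = {"diathesis", "baseline_symptoms"}


def _encode(name: str, value) -> str:
    if value is None:
        return ""
    if name in _BOOL_COLUMNS:
        return "1" if value else "0"
    if name in _FLOAT_COLUMNS:
        return repr(float(value))  # shortest round-trip representation
    return str(value)


def _decode(name: str, text: str, line: int):
    if text == "":
        if name in _BOOL_COLUMNS or name == "onset_day" or name.startswith("first_"):
            return None
        raise ValueError(f"line {line}, column {name!r}: value required")
    try:
        if name in _BOOL_COLUMNS:
            if text not in ("0", "1"):
                raise ValueError(text)
            return text == "1"
        if name in _INT_COLUMNS:
            return int(text)
        if name in _FLOAT_COLUMNS:
            return float(text)
    except ValueError:
        raise ValueError(
            f"line {line}, column {name!r}: cannot parse {text!r}"
        ) from None
    return text


def write_cohort_csv(records: Iterable[AgentRecord], path: str | Path) -> None:
    """Write one row per agent; censored/undefined fields become empty strings."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(_COLUMNS)
        for record in records:
            writer.writerow(
                _encode(name, getattr(record, name)) for name in _COLUMNS
            )


def read_cohort_csv(path: str | Path) -> list[AgentRecord]:
    """Read a cohort CSV back into records; lossless inverse of the writer."""
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty file, header row expected") from None
        if header != _COLUMNS:
            raise ValueError(f"{path}: unexpected header {header!r}")
        records = []
        for line_no, row in enumerate(reader, start=2):
            if len(row) != len(_COLUMNS):
                raise ValueError(
                    f"{path}: line {line_no}: expected {len(_COLUMNS)} fields, "
                    f"got {len(row)}"
                )
            values = {
                name: _decode(name, text, line_no)
                for name, text in zip(_COLUMNS, row)
            }
            records.append(AgentRecord(**values))
    return records


def records_to_frame(records: Sequence[AgentRecord]):
    """Cohort records as a pandas DataFrame (one row per agent)."""
    import pandas as pd

    return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=_COLUMNS)
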