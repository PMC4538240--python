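"""Synthetic strategy-following agents and cohort simulation.

Agents stand in for human participants: each applies one fixed strategy
across all sixteen adventures of a session, with an optional *lapse rate*
ε — the probability that a given response is replaced by a uniform random
click on one of the two cards.  The lapse is this package's explicit
formalization of "accidental" deviations from an otherwise consistent
strategy; it is uniform over the two options, so a fully lapsed responder
(ε = 1) scores 2 on each strategy in expectation (each pair's four
equiprobable response paths map onto the four strategies).

A cohort draws each agent's strategy from a mixture, simulates everyone on
independently randomized sessions, and the recovery report compares the
generating strategies with the dominant (arg-max score) recovered ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import Choice
from .design import Adventure, SessionLog, build_session, play_session, score_log
from .strategies import (
    IDENTIFIABLE_STRATEGIES,
    PreBayesVariant,
    StrategyId,
    strategy_choice,
)

__all__ = [
    "AgentSpec",
    "CohortSpec",
    "CohortResult",
    "simulate_agent",
    "simulate_cohort",
    "score_table",
    "recovery_report",
    "RecoveryReport",
]

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class AgentSpec:
    """One agent: a strategy from the identifiable set, a lapse rate ε in
    [0, 1], and a private seed."""

    strategy: StrategyId
    lapse: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.strategy not in IDENTIFIABLE_STRATEGIES:
            raise ValueError(f"{self.strategy} is not identifiable by the design")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError(f"lapse must be in [0, 1], got {self.lapse}")


@dataclass(frozen=True)
class CohortSpec:
    """A cohort: n agents, a strategy mixture over the identifiable set, a
    common lapse rate, and a master seed from which all per-agent and
    per-session seeds derive.  Optional stratification labels (e.g. gender
    and education levels) are carried as inert metadata on the output."""

    n_agents: int
    mixture: Mapping[StrategyId, float]
    lapse: float = 0.0
    seed: int = 0
    strata_labels: Mapping[str, Sequence[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_agents <= 0:
            raise ValueError("n_agents must be positive")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError(f"lapse must be in [0, 1], got {self.lapse}")
        bad = set(self.mixture) - set(IDENTIFIABLE_STRATEGIES)
        if bad:
            raise ValueError(f"mixture contains unidentifiable strategies: {bad}")
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture proportions must sum to 1, got {total}")


def _respond_fn(spec: AgentSpec, rng: np.random.Generator):
    """Responder closure: emit the strategy's prescription on the presented
    counts (ties broken by a fair coin), lapsing to a uniform click with
    probability ε."""

    def respond(adventure: Adventure) -> Choice:
        if rng.random() < spec.lapse:
            return Choice.D1 if rng.random() < 0.5 else Choice.D2
        presented = adventure.presented_counts()
        choice = strategy_choice(presented, spec.strategy, PreBayesVariant.ORDINAL)
        if not choice.definite:  # tie: the agent must still click a card
            return Choice.D1 if rng.random() < 0.5 else Choice.D2
        return choice

    return respond


def simulate_agent(spec: AgentSpec, session=None) -> SessionLog:
    """Play one agent through a session (built from the agent's seed when
    not supplied) and return the full log."""
    rng = np.random.default_rng(spec.seed)
    if session is None:
        session = build_session(int(rng.integers(_MAX_SEED)))
    return play_session(session, _respond_fn(spec, rng))


@dataclass(frozen=True)
class CohortResult:
    """Simulated cohort: per-agent logs, scores, and metadata table."""

    spec: CohortSpec
    logs: tuple[SessionLog, ...]
    frame: pd.DataFrame  # one row per agent: strategy, lapse, scores, labels


def simulate_cohort(spec: CohortSpec) -> CohortResult:
    """Simulate independent agents; reproducible bit-for-bit from the spec.

    Each agent gets a strategy drawn from the mixture and a derived seed;
    its session is randomized independently.  The result's frame has one
    row per agent with the generating strategy and the four 0–8 scores.
    """
    master = np.random.default_rng(spec.seed)
    strategies = sorted(spec.mixture, key=lambda s: s.value)
    probs = np.array([spec.mixture[s] for s in strategies], dtype=float)
    probs = probs / probs.sum()
    draws = master.choice(len(strategies), size=spec.n_agents, p=probs)
    agent_seeds = master.integers(_MAX_SEED, size=spec.n_agents)

    label_rng = np.random.default_rng(master.integers(_MAX_SEED))
    labels = {
        name: label_rng.choice(list(values), size=spec.n_agents)
        for name, values in spec.strata_labels.items()
    }

    logs = []
    rows = []
    for i in range(spec.n_agents):
        agent = AgentSpec(strategies[draws[i]], spec.lapse, int(agent_seeds[i]))
        log = simulate_agent(agent)
        logs.append(log)
        scores = score_log(log)
        row = {
            "agent": i,
            "generating_strategy": agent.strategy.value,
            "lapse": spec.lapse,
        }
        row.update({f"score_{s.value}": scores[s] for s in IDENTIFIABLE_STRATEGIES})
        row.update({name: vals[i] for name, vals in labels.items()})
        rows.append(row)
    return CohortResult(spec, tuple(logs), pd.DataFrame(rows))


def score_table(result: CohortResult) -> pd.DataFrame:
    """Per-strategy score summary (min, max, mean, SD) across the cohort —
    the shape of a descriptive-statistics table for an experimental sample."""
    rows = []
    for s in IDENTIFIABLE_STRATEGIES:
        col = result.frame[f"score_{s.value}"]
        rows.append(
            {
                "strategy": s.value,
                "min": int(col.min()),
                "max": int(col.max()),
                "mean": float(col.mean()),
                "sd": float(col.std(ddof=1)) if len(col) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RecoveryReport:
    """Strategy-recovery audit for a cohort with known generating strategies.

    ``confusion`` is indexed by generating strategy with recovered
    strategies as columns; ``accuracy`` is the fraction of agents whose
    dominant (arg-max score) strategy matches the generating one;
    ``n_ties`` counts agents whose top score was shared and broken at
    random (seeded).
    """

    confusion: pd.DataFrame
    accuracy: float
    n_ties: int


def recovery_report(result: CohortResult, seed: int = 0) -> RecoveryReport:
    """Dominant-strategy recovery: arg-max score per agent versus the known
    generating strategy, with seeded-random tie-breaking."""
    rng = np.random.default_rng(seed)
    names = [s.value for s in IDENTIFIABLE_STRATEGIES]
    confusion = pd.DataFrame(0, index=names, columns=names)
    n_ties = 0
    hits = 0
    for _, row in result.frame.iterrows():
        scores = np.array([row[f"score_{n}"] for n in names])
        top = np.flatnonzero(scores == scores.max())
        if len(top) > 1:
            n_ties += 1
        recovered = names[int(rng.choice(top))]
        confusion.loc[row["generating_strategy"], recovered] += 1
        hits += recovered == row["generating_strategy"]
    return RecoveryReport(confusion, hits / len(result.frame), n_ties)
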