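"""The adaptive two-task experiment: patterns, pair rules, classification.

A session is sixteen "adventures" grouped into eight pairs.  The first
adventure of a pair shows one of two anchor frequency patterns; the
participant's choice there splits the four identifiable strategies into two
camps — {Bayesian, pre-Bayesian} versus {representativeness, evidence-only}
— and the second adventure's pattern is chosen adaptively so that the two
surviving strategies prescribe different options.  Two definite choices
therefore identify exactly one strategy, and over eight pairs each strategy
accumulates a score from 0 to 8; the four scores always sum to 8.

The pre-Bayesian strategy is used in its ORDINAL variant here (always pick
the smaller evidence group): the design requires a definite prescription on
every pattern, which the strict applicability rule would deny on the anchor
patterns.

Presentation details — the order of the eight pairs, a per-adventure
color swap (which option is painted green), and the object contents
(diamonds vs amber) — are randomized from a seed and recorded; they never
affect classification, which is carried out in the canonical count
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import Choice, ElementarySituation
from .strategies import (
    IDENTIFIABLE_STRATEGIES,
    PreBayesVariant,
    StrategyId,
    strategy_choice,
)

__all__ = [
    "PATTERNS",
    "PAIR_RULES",
    "PairRule",
    "Adventure",
    "Session",
    "SessionLog",
    "build_session",
    "second_task",
    "classify_pair",
    "play_session",
    "score_log",
    "validate_design",
    "DesignError",
]


class DesignError(ValueError):
    """The design's structural guarantees are violated."""


#: The six frequency patterns (d, e, f, g) used in the adventures.
PATTERNS: dict[str, ElementarySituation] = {
    "P1": ElementarySituation(2, 1, 3, 1),
    "P2": ElementarySituation(1, 2, 1, 3),
    "P3": ElementarySituation(2, 1, 2, 2),
    "P4": ElementarySituation(2, 1, 1, 3),
    "P5": ElementarySituation(1, 2, 3, 1),
    "P6": ElementarySituation(3, 1, 2, 1),
}

_ALGORITHMIC = (StrategyId.BAYESIAN, StrategyId.PRE_BAYESIAN)
_HEURISTIC = (StrategyId.REPRESENTATIVENESS, StrategyId.EVIDENCE_ONLY)


def prescription(pattern_id: str, strategy: StrategyId) -> Choice:
    """A strategy's canonical-orientation choice on a named pattern
    (pre-Bayesian in its ordinal variant)."""
    return strategy_choice(PATTERNS[pattern_id], strategy, PreBayesVariant.ORDINAL)


@dataclass(frozen=True)
class PairRule:
    """One of the eight pair rules I–VIII.

    ``first`` is the anchor pattern (P1 or P2).  After the first choice the
    two camps part ways: a response matching the Bayesian/pre-Bayesian
    prescription routes to ``algorithmic_pattern``, the other response to
    ``heuristic_pattern``; each second pattern separates its camp.
    """

    pair_id: str
    first: str
    algorithmic_pattern: str
    heuristic_pattern: str

    def branch(self, first_choice: Choice) -> tuple[str, tuple[StrategyId, StrategyId]]:
        """Second pattern and surviving strategy camp for a first choice."""
        if not first_choice.definite:
            raise DesignError(f"first choice must be definite, got {first_choice}")
        algo_choice = prescription(self.first, StrategyId.BAYESIAN)
        if first_choice is algo_choice:
            return self.algorithmic_pattern, _ALGORITHMIC
        return self.heuristic_pattern, _HEURISTIC


#: Pair rules I–VIII.  The anchor is P1 for I–IV and P2 for V–VIII; the two
#: second patterns are the printed options, routed so that each branch's
#: pattern separates the strategies still in contention.
PAIR_RULES: dict[str, PairRule] = {
    "I": PairRule("I", "P1", "P3", "P4"),
    "II": PairRule("II", "P1", "P3", "P5"),
    "III": PairRule("III", "P1", "P6", "P4"),
    "IV": PairRule("IV", "P1", "P6", "P5"),
    "V": PairRule("V", "P2", "P3", "P4"),
    "VI": PairRule("VI", "P2", "P3", "P5"),
    "VII": PairRule("VII", "P2", "P6", "P4"),
    "VIII": PairRule("VIII", "P2", "P6", "P5"),
}


def second_task(rule: PairRule, first_choice: Choice) -> str:
    """The pattern id of the pair's second adventure given the first choice."""
    pattern_id, _ = rule.branch(first_choice)
    return pattern_id


def classify_pair(rule: PairRule, choice1: Choice, choice2: Choice) -> StrategyId:
    """The unique strategy whose prescriptions match both observed choices.

    Choices are in the canonical count orientation (use
    :meth:`Choice.mirrored` first if the adventure was presented
    color-swapped).  Both must be definite; the adaptive construction then
    guarantees exactly one match.
    """
    if not (choice1.definite and choice2.definite):
        raise DesignError("classification needs two definite choices")
    pattern2, camp = rule.branch(choice1)
    matches = [s for s in camp if prescription(pattern2, s) is choice2]
    if len(matches) != 1:
        raise DesignError(
            f"pair {rule.pair_id}: second pattern {pattern2} does not separate {camp}"
        )
    return matches[0]


@dataclass(frozen=True)
class Adventure:
    """One presented task: a pattern, shown possibly color-swapped, with a
    content label (which precious object plays the hypothesis role)."""

    index: int
    pair_id: str
    position: int  # 1 = anchor task, 2 = adaptive task
    pattern_id: str | None  # None until the adaptive task is determined
    swapped: bool
    content: str

    def presented_counts(self) -> ElementarySituation:
        if self.pattern_id is None:
            raise DesignError("adaptive task not yet determined")
        sit = PATTERNS[self.pattern_id]
        return sit.mirrored() if self.swapped else sit


@dataclass(frozen=True)
class Session:
    """A seeded session plan: pair order, per-adventure swap flags, contents.

    The second adventure of each pair has no pattern yet — it is resolved
    from the realized first response when the session is played.
    """

    seed: int
    pair_order: tuple[str, ...]
    adventures: tuple[Adventure, ...]

    @property
    def n_pairs(self) -> int:
        return len(self.pair_order)


@dataclass(frozen=True)
class AdventureRecord:
    """One played adventure: what was shown and what was answered."""

    adventure: Adventure
    response_presented: Choice  # as clicked, in presented orientation
    response_canonical: Choice


@dataclass(frozen=True)
class SessionLog:
    """A fully played session with per-pair classifications."""

    session: Session
    records: tuple[AdventureRecord, ...]
    classifications: tuple[StrategyId, ...]

    def to_jsonable(self) -> list[dict]:
        out = []
        for rec, cls in zip(
            self.records, (c for c in self.classifications for _ in (0, 1))
        ):
            adv = rec.adventure
            out.append(
                {
                    "adventure": adv.index,
                    "pair": adv.pair_id,
                    "position": adv.position,
                    "pattern": adv.pattern_id,
                    "swapped": adv.swapped,
                    "content": adv.content,
                    "presented_counts": adv.presented_counts().counts(),
                    "response": rec.response_presented.value,
                    "classified": cls.value,
                }
            )
        return out


# Two stimulus layouts: which half of the adventures features diamonds vs
# amber.  Chosen per session.
_CONTENT_LAYOUTS = (
    ("diamonds",) * 4 + ("amber",) * 4 + ("diamonds",) * 4 + ("amber",) * 4,
    ("amber",) * 4 + ("diamonds",) * 4 + ("amber",) * 4 + ("diamonds",) * 4,
)


def build_session(seed: int) -> Session:
    """Build a session plan: the eight pair rules in seeded-random order,
    independent per-adventure color-swap flags, and one of the two content
    layouts.  Deterministic in the seed."""
    rng = np.random.default_rng(seed)
    order = tuple(rng.permutation(sorted(PAIR_RULES)).tolist())
    swaps = rng.random(16) < 0.5
    layout = _CONTENT_LAYOUTS[int(rng.integers(2))]
    adventures = []
    for i in range(16):
        pair_id = order[i // 2]
        position = i % 2 + 1
        pattern_id = PAIR_RULES[pair_id].first if position == 1 else None
        adventures.append(
            Adventure(
                index=i + 1,
                pair_id=pair_id,
                position=position,
                pattern_id=pattern_id,
                swapped=bool(swaps[i]),
                content=layout[i],
            )
        )
    return Session(seed=seed, pair_order=order, adventures=tuple(adventures))


def play_session(session: Session, respond) -> SessionLog:
    """Run a session against a responder.

    ``respond(adventure)`` is called for each adventure in order and must
    return a definite :class:`Choice` in the *presented* orientation (what
    a participant clicks).  The adaptive second task of each pair is
    resolved from the realized first response before the responder sees it.
    """
    records: list[AdventureRecord] = []
    classifications: list[StrategyId] = []
    for k in range(session.n_pairs):
        first_adv = session.adventures[2 * k]
        rule = PAIR_RULES[first_adv.pair_id]

        r1_presented = respond(first_adv)
        r1 = r1_presented.mirrored() if first_adv.swapped else r1_presented
        if not r1.definite:
            raise DesignError("responses must be definite (a card must be clicked)")

        pattern2 = second_task(rule, r1)
        second_adv = replace(session.adventures[2 * k + 1], pattern_id=pattern2)
        r2_presented = respond(second_adv)
        r2 = r2_presented.mirrored() if second_adv.swapped else r2_presented
        if not r2.definite:
            raise DesignError("responses must be definite (a card must be clicked)")

        records.append(AdventureRecord(first_adv, r1_presented, r1))
        records.append(AdventureRecord(second_adv, r2_presented, r2))
        classifications.append(classify_pair(rule, r1, r2))
    return SessionLog(session, tuple(records), tuple(classifications))


def score_log(log: SessionLog) -> dict[StrategyId, int]:
    """Per-strategy scores 0–8 for a played session; they sum to the number
    of pairs."""
    if len(log.classifications) != log.session.n_pairs:
        raise DesignError("incomplete session: not every pair is classified")
    scores = {s: 0 for s in IDENTIFIABLE_STRATEGIES}
    for cls in log.classifications:
        scores[cls] += 1
    return scores


def validate_design() -> None:
    """Check the structural guarantees the classification relies on.

    Raises :class:`DesignError` if (1) any identifiable strategy lacks a
    definite prescription on some pattern, or (2) some pair rule's second
    pattern fails to separate the two strategies still in contention after
    either first choice.
    """
    for pid in PATTERNS:
        for s in IDENTIFIABLE_STRATEGIES:
            if not prescription(pid, s).definite:
                raise DesignError(f"{s.value} has no definite choice on {pid}")
    for rule in PAIR_RULES.values():
        camp_choice = {
            _ALGORITHMIC: prescription(rule.first, StrategyId.BAYESIAN),
            _HEURISTIC: prescription(rule.first, StrategyId.REPRESENTATIVENESS),
        }
        if camp_choice[_ALGORITHMIC] is camp_choice[_HEURISTIC]:
            raise DesignError(f"pair {rule.pair_id}: anchor does not split the camps")
        for camp, first_choice in camp_choice.items():
            for s in camp:
                if prescription(rule.first, s) is not first_choice:
                    raise DesignError(
                        f"pair {rule.pair_id}: {s.value} disagrees with its camp on {rule.first}"
                    )
            pattern2, surviving = rule.branch(first_choice)
            p, q = (prescription(pattern2, s) for s in surviving)
            if p is q:
                raise DesignError(
                    f"pair {rule.pair_id}: {pattern2} does not separate "
                    f"{[s.value for s in surviving]}"
                )
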