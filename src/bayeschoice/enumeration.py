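"""Exhaustive conformity analysis of heuristic strategies against Bayes' rule.

For a given sampling volume ``a`` we enumerate every elementary situation
(d, e, f, g) with all four counts positive — every combination of datum and
hypothesis experienced at least once — and ask, for each heuristic, whether
its choice prescription agrees with the Bayesian one.  Results are
aggregated per volume, per base-rate stratum (rare / medium / frequent),
and averaged over a range of volumes.

Conformity convention: a heuristic conforms when its choice is definite and
equals the Bayesian choice.  A heuristic answering ANY against a definite
Bayesian choice does not conform.  When the Bayesian choice itself is ANY
(both posteriors equal) no definite choice can violate Bayes' rule, so by
default every definite or ANY heuristic choice counts as conforming; set
``tie_policy="exclude"`` to drop Bayesian-tie situations from denominators
instead and measure the sensitivity.  NA choices are excluded from the
denominator (the strategy is not applicable).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterator, Literal, Sequence

import pandas as pd

from .core import Choice, ElementarySituation
from .strategies import PreBayesVariant, StrategyId, strategy_choice

__all__ = [
    "HEURISTICS",
    "Stratum",
    "StratumSpec",
    "DEFAULT_STRATA",
    "ConformityRecord",
    "ConformitySummary",
    "enumerate_situations",
    "conformity_table",
    "conformity_records",
    "conformity_summary",
    "average_conformity",
    "audit_noninverse_equivalence",
]

#: The fallacious heuristics audited against the Bayesian choice.
HEURISTICS: tuple[StrategyId, ...] = (
    StrategyId.REPRESENTATIVENESS,
    StrategyId.EVIDENCE_ONLY,
    StrategyId.PRE_BAYESIAN,
)

TiePolicy = Literal["conform", "exclude"]


@dataclass(frozen=True)
class StratumSpec:
    """Base-rate strata: rare b/a <= rare_max, frequent b/a >= frequent_min,
    medium strictly between.  Boundaries are compared as exact rationals."""

    rare_max: Fraction = Fraction(1, 4)
    frequent_min: Fraction = Fraction(3, 4)

    def classify(self, base_rate: Fraction) -> "Stratum":
        if base_rate <= self.rare_max:
            return Stratum.RARE
        if base_rate >= self.frequent_min:
            return Stratum.FREQUENT
        return Stratum.MEDIUM


class Stratum(enum.Enum):
    RARE = "rare"
    MEDIUM = "medium"
    FREQUENT = "frequent"
    OVERALL = "overall"


DEFAULT_STRATA = StratumSpec()


@dataclass(frozen=True)
class ConformityRecord:
    """One enumerated situation with the Bayesian choice and, per heuristic,
    its choice and conformity flag (True / False / None for not-applicable)."""

    situation: ElementarySituation
    bayes_choice: Choice
    choices: dict[StrategyId, Choice]
    conformity: dict[StrategyId, bool | None]


@dataclass(frozen=True)
class ConformitySummary:
    """Aggregated conformity for one (volume, stratum, strategy) cell.

    ``percentage`` is 100·conforming/applicable, or None when no situation
    in the cell is applicable.
    """

    a: int
    stratum: Stratum
    strategy: StrategyId
    conforming: int
    applicable: int

    @property
    def percentage(self) -> float | None:
        if self.applicable == 0:
            return None
        return 100.0 * self.conforming / self.applicable


def enumerate_situations(a: int) -> Iterator[ElementarySituation]:
    """All compositions of ``a`` into four positive parts, lexicographic in
    (d, e, f, g).  There are C(a−1, 3) of them; a < 4 is an empty domain."""
    if a < 4:
        raise ValueError(f"no elementary situation with positive counts has a = {a} < 4")
    for d in range(1, a - 2):
        for e in range(1, a - d - 1):
            for f in range(1, a - d - e):
                yield ElementarySituation(d, e, f, a - d - e - f)


def _conforms(bayes: Choice, heuristic: Choice, tie_policy: TiePolicy) -> bool | None:
    if heuristic is Choice.NA:
        return None
    if bayes is Choice.ANY:
        if tie_policy == "exclude":
            return None
        return True  # equal posteriors: no definite choice violates Bayes' rule
    return heuristic is bayes


def conformity_records(
    a: int,
    variant: PreBayesVariant = PreBayesVariant.STRICT,
    tie_policy: TiePolicy = "conform",
    heuristics: Sequence[StrategyId] = HEURISTICS,
) -> list[ConformityRecord]:
    """Per-situation prescriptions and conformity flags at volume ``a``."""
    records = []
    for sit in enumerate_situations(a):
        bayes = strategy_choice(sit, StrategyId.BAYESIAN)
        choices = {s: strategy_choice(sit, s, variant) for s in heuristics}
        conf = {s: _conforms(bayes, c, tie_policy) for s, c in choices.items()}
        records.append(ConformityRecord(sit, bayes, choices, conf))
    return records


def conformity_table(
    a: int,
    variant: PreBayesVariant = PreBayesVariant.STRICT,
    tie_policy: TiePolicy = "conform",
    heuristics: Sequence[StrategyId] = HEURISTICS,
) -> pd.DataFrame:
    """The conformity table at volume ``a`` as a DataFrame.

    Columns: a, d, e, f, g, base_rate, bayes_choice, then per heuristic a
    ``<name>_choice`` and ``<name>_conformity`` column ("Yes"/"No"/"n/a").
    """
    rows = []
    for rec in conformity_records(a, variant, tie_policy, heuristics):
        sit = rec.situation
        row: dict = {
            "a": sit.a,
            "d": sit.d,
            "e": sit.e,
            "f": sit.f,
            "g": sit.g,
            "base_rate": float(sit.base_rate),
            "bayes_choice": rec.bayes_choice.value,
        }
        for s in heuristics:
            row[f"{s.value}_choice"] = rec.choices[s].value
            c = rec.conformity[s]
            row[f"{s.value}_conformity"] = "n/a" if c is None else ("Yes" if c else "No")
        rows.append(row)
    return pd.DataFrame(rows)


def _tally(
    records: list[ConformityRecord],
    strata: StratumSpec,
    heuristics: Sequence[StrategyId],
) -> dict[tuple[Stratum, StrategyId], tuple[int, int]]:
    counts: dict[tuple[Stratum, StrategyId], list[int]] = {
        (st, s): [0, 0]
        for st in Stratum
        for s in heuristics
    }
    for rec in records:
        stratum = strata.classify(rec.situation.base_rate)
        for s in heuristics:
            c = rec.conformity[s]
            if c is None:
                continue
            for key in ((stratum, s), (Stratum.OVERALL, s)):
                counts[key][1] += 1
                if c:
                    counts[key][0] += 1
    return {k: (v[0], v[1]) for k, v in counts.items()}


def conformity_summary(
    a_min: int = 5,
    a_max: int = 50,
    strata: StratumSpec = DEFAULT_STRATA,
    variant: PreBayesVariant = PreBayesVariant.STRICT,
    tie_policy: TiePolicy = "conform",
    heuristics: Sequence[StrategyId] = HEURISTICS,
) -> list[ConformitySummary]:
    """Per-volume, per-stratum conformity for each heuristic over a range.

    Cells with no applicable situation (e.g. pre-Bayesian in the frequent
    stratum, where applicability forces base rate <= 1/2) are emitted with
    applicable = 0 and percentage None.
    """
    if not 4 <= a_min <= a_max:
        raise ValueError(f"need 4 <= a_min <= a_max, got {a_min}..{a_max}")
    out = []
    for a in range(a_min, a_max + 1):
        records = conformity_records(a, variant, tie_policy, heuristics)
        tally = _tally(records, strata, heuristics)
        for (stratum, s), (conf, appl) in tally.items():
            out.append(ConformitySummary(a, stratum, s, conf, appl))
    return out


def summary_frame(summaries: list[ConformitySummary]) -> pd.DataFrame:
    """Tabulate ConformitySummary records."""
    return pd.DataFrame(
        {
            "a": s.a,
            "stratum": s.stratum.value,
            "strategy": s.strategy.value,
            "conforming": s.conforming,
            "applicable": s.applicable,
            "percentage": s.percentage,
        }
        for s in summaries
    )


def average_conformity(
    a_min: int = 5,
    a_max: int = 50,
    variant: PreBayesVariant = PreBayesVariant.STRICT,
    tie_policy: TiePolicy = "conform",
    heuristics: Sequence[StrategyId] = HEURISTICS,
    weighting: Literal["per_volume", "pooled"] = "pooled",
) -> dict[StrategyId, float]:
    """Average Bayes-conformity percentage per heuristic over a volume range.

    The default ("pooled") divides the total conforming count by the total
    applicable count across all volumes in the range — each situation
    weighs equally.  "per_volume" instead takes the unweighted mean of the
    per-a overall percentages (each volume weighs equally, as when reading
    a per-volume conformity curve).  The two differ by a point or two
    because large volumes contribute vastly more situations.
    """
    per_a: dict[StrategyId, list[float]] = {s: [] for s in heuristics}
    pooled: dict[StrategyId, list[int]] = {s: [0, 0] for s in heuristics}
    for summ in conformity_summary(a_min, a_max, DEFAULT_STRATA, variant, tie_policy, heuristics):
        if summ.stratum is not Stratum.OVERALL:
            continue
        pooled[summ.strategy][0] += summ.conforming
        pooled[summ.strategy][1] += summ.applicable
        if summ.percentage is not None:
            per_a[summ.strategy].append(summ.percentage)
    if weighting == "pooled":
        return {s: 100.0 * c / n for s, (c, n) in pooled.items() if n > 0}
    return {s: sum(v) / len(v) for s, v in per_a.items() if v}


def audit_noninverse_equivalence(a_min: int = 5, a_max: int = 50) -> int:
    """Count situations where the non-inverse choice differs from the
    Bayesian choice over the full enumeration of a range.  Zero is the
    algebraic expectation: d/(d+e) > f/(f+g) iff d·g > e·f iff
    d/(d+f) > e/(e+g)."""
    mismatches = 0
    for a in range(a_min, a_max + 1):
        for sit in enumerate_situations(a):
            if strategy_choice(sit, StrategyId.NON_INVERSE) is not strategy_choice(
                sit, StrategyId.BAYESIAN
            ):
                mismatches += 1
    return mismatches


def situation_count(a: int) -> int:
    """C(a−1, 3): the number of elementary situations at volume a."""
    return math.comb(a - 1, 3)
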