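"""The six cognitive strategies as pure functions over elementary situations.

Each strategy is a rule a decision maker might apply after experiencing the
four joint counts (d, e, f, g).  Two modes are supported:

* **choice mode** — which datum option (D1 or D2) maximizes the chance of
  the preferred outcome H;
* **estimate mode** — a single-number estimate of P(H | D1).

All comparisons use exact integer cross-multiplication, so ties
(d·g = e·f and friends) are detected exactly and reported as ANY.
Randomizing a tie is the agent simulator's job, never the strategy's.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction

from .core import Choice, ElementarySituation

__all__ = [
    "StrategyId",
    "PreBayesVariant",
    "Estimate",
    "strategy_choice",
    "strategy_estimate",
    "IDENTIFIABLE_STRATEGIES",
    "parse_strategy",
]


class StrategyId(enum.Enum):
    """The closed set of strategies.

    BAYESIAN compares the two posteriors d/(d+f) vs e/(e+g).
    NON_INVERSE compares the likelihoods d/(d+e) vs f/(f+g) — no inversion
    of conditions, yet provably choice-equivalent to Bayes in elementary
    situations.  REPRESENTATIVENESS compares d/b vs e/b (how typical each
    datum is of H).  EVIDENCE_ONLY compares the overall datum frequencies
    (d+f) vs (e+g).  PRE_BAYESIAN compares b/(d+f) vs b/(e+g), the
    hypothesis count over each datum count.  CONSERVATISM sticks with the
    prior b vs c and hence prescribes no datum option.
    """

    BAYESIAN = "bayesian"
    NON_INVERSE = "non_inverse"
    REPRESENTATIVENESS = "representativeness"
    EVIDENCE_ONLY = "evidence_only"
    PRE_BAYESIAN = "pre_bayesian"
    CONSERVATISM = "conservatism"


class PreBayesVariant(enum.Enum):
    """How the pre-Bayesian strategy treats ratios exceeding one.

    STRICT declares the strategy inapplicable (returns NA) whenever
    b/(d+f) or b/(e+g) exceeds one — an estimate above one is not a
    probability.  ORDINAL always compares the two ratios (equivalently,
    picks the smaller evidence group), which makes the strategy the exact
    opposite of evidence-only.  Enumeration analyses default to STRICT;
    the adaptive design uses ORDINAL.
    """

    STRICT = "strict"
    ORDINAL = "ordinal"


#: Strategies the adaptive two-task design can tell apart from choices.
IDENTIFIABLE_STRATEGIES: tuple[StrategyId, ...] = (
    StrategyId.BAYESIAN,
    StrategyId.PRE_BAYESIAN,
    StrategyId.REPRESENTATIVENESS,
    StrategyId.EVIDENCE_ONLY,
)

_ALIASES = {
    "bayes": StrategyId.BAYESIAN,
    "noninverse": StrategyId.NON_INVERSE,
    "repr": StrategyId.REPRESENTATIVENESS,
    "evidence": StrategyId.EVIDENCE_ONLY,
    "prebayes": StrategyId.PRE_BAYESIAN,
}


def parse_strategy(name: str) -> StrategyId:
    """Resolve a strategy name (case-insensitive, hyphen/underscore agnostic)."""
    key = name.strip().lower().replace("-", "_")
    if key in _ALIASES:
        return _ALIASES[key]
    try:
        return StrategyId(key)
    except ValueError:
        raise ValueError(f"unknown strategy {name!r}") from None


def _compare(left_num: int, left_den: int, right_num: int, right_den: int) -> Choice:
    """Pick the option whose ratio is larger; exact via cross-multiplication.

    Denominators must be positive.  Equal ratios give ANY.
    """
    lhs = left_num * right_den
    rhs = right_num * left_den
    if lhs > rhs:
        return Choice.D1
    if lhs < rhs:
        return Choice.D2
    return Choice.ANY


def strategy_choice(
    sit: ElementarySituation,
    strategy: StrategyId,
    variant: PreBayesVariant = PreBayesVariant.STRICT,
) -> Choice:
    """The option a strategy prescribes in a situation, or ANY / NA.

    A zero denominator in a required ratio makes the strategy inapplicable
    (NA) rather than raising: the decision maker simply has nothing to
    compare.  Conservatism compares hypotheses, not datum options, so in
    choice mode it is always NA.
    """
    d, e, f, g = sit.counts()

    if strategy is StrategyId.BAYESIAN:
        if d + f == 0 or e + g == 0:
            return Choice.NA
        return _compare(d, d + f, e, e + g)

    if strategy is StrategyId.NON_INVERSE:
        # d/(d+e) vs f/(f+g): is D1 more characteristic of H or of not-H?
        # The larger first ratio favors D1 (D1 points toward H).
        if d + e == 0 or f + g == 0:
            return Choice.NA
        return _compare(d, d + e, f, f + g)

    if strategy is StrategyId.REPRESENTATIVENESS:
        if d + e == 0:
            return Choice.NA
        return _compare(d, d + e, e, d + e)

    if strategy is StrategyId.EVIDENCE_ONLY:
        return _compare(d + f, sit.a, e + g, sit.a)

    if strategy is StrategyId.PRE_BAYESIAN:
        b = sit.b
        if d + f == 0 or e + g == 0:
            return Choice.NA
        if variant is PreBayesVariant.STRICT and (b > d + f or b > e + g):
            return Choice.NA
        return _compare(b, d + f, b, e + g)

    if strategy is StrategyId.CONSERVATISM:
        return Choice.NA

    raise ValueError(f"unknown strategy {strategy!r}")


@dataclass(frozen=True)
class Estimate:
    """A strategy's point estimate of the chance that H holds given D1.

    ``is_probability`` is False when the value exceeds one (possible only
    for the pre-Bayesian ratio b/(d+f)); the value is returned unclipped so
    the pathology stays visible.
    """

    value: Fraction
    is_probability: bool

    def __float__(self) -> float:
        return float(self.value)


def strategy_estimate(strategy: StrategyId, sit: ElementarySituation) -> Estimate:
    """Single-number estimate of P(H | D1) under each strategy.

    conservatism b/a; evidence-only (d+f)/a; representativeness d/b;
    pre-Bayesian b/(d+f), possibly > 1; Bayesian (and non-inverse, which
    has no estimate of its own and defers to the posterior) d/(d+f).
    """
    d, e, f, g = sit.counts()
    a, b = sit.a, sit.b

    def frac(num: int, den: int) -> Fraction:
        if den == 0:
            raise ZeroDivisionError(
                f"{strategy.value} estimate undefined: zero denominator in {sit.counts()}"
            )
        return Fraction(num, den)

    if strategy is StrategyId.CONSERVATISM:
        value = frac(b, a)
    elif strategy is StrategyId.EVIDENCE_ONLY:
        value = frac(d + f, a)
    elif strategy is StrategyId.REPRESENTATIVENESS:
        value = frac(d, b)
    elif strategy is StrategyId.PRE_BAYESIAN:
        value = frac(b, d + f)
    elif strategy in (StrategyId.BAYESIAN, StrategyId.NON_INVERSE):
        value = frac(d, d + f)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return Estimate(value=value, is_probability=value <= 1)
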