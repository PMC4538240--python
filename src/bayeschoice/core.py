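"""Exact calculus for elementary Bayesian situations.

An *elementary situation* is a world with two hypotheses (H, not-H) and two
data values (D1, D2), fully described by four joint natural-frequency counts

    d = #(H, D1)   e = #(H, D2)   f = #(not-H, D1)   g = #(not-H, D2)

The same world can be stated in probability format as a prior P(H) and the
two likelihoods P(D1|H), P(D1|not-H).  Everything here is computed with
exact rational arithmetic (`fractions.Fraction`); floating point appears
only when a caller explicitly asks for a rounded percentage.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from fractions import Fraction
from typing import Union

Number = Union[int, float, Fraction]

__all__ = [
    "Choice",
    "ElementarySituation",
    "BayesProblem",
    "UndefinedPosteriorError",
    "IncompatiblePopulationError",
    "posterior",
    "posterior_from_counts",
    "situation_from_problem",
    "round_percent",
    "WORKED_PROBLEMS",
]


class UndefinedPosteriorError(ZeroDivisionError):
    """The conditioning datum has probability zero: the posterior is undefined."""


class IncompatiblePopulationError(ValueError):
    """The requested population size does not make every joint count integral."""


class Choice(enum.Enum):
    """A strategy's prescription in an elementary situation.

    D1 is the option associated with counts d and f (rendered green in the
    card tasks), D2 with e and g (yellow).  ANY marks indifference (a tie),
    NA marks a strategy that prescribes nothing for the situation.  The
    D1/D2 orientation is fixed by the count layout; colors are presentation
    metadata only.
    """

    D1 = "D1"
    D2 = "D2"
    ANY = "Any"
    NA = "n/a"

    @property
    def definite(self) -> bool:
        return self in (Choice.D1, Choice.D2)

    def mirrored(self) -> "Choice":
        """Swap D1 and D2; ANY and NA are fixed points."""
        if self is Choice.D1:
            return Choice.D2
        if self is Choice.D2:
            return Choice.D1
        return self


def _to_fraction(x: Number) -> Fraction:
    """Exact rational from a number; floats go through their shortest decimal
    repr so 0.096 becomes 96/1000, not its binary approximation."""
    if isinstance(x, float):
        return Fraction(str(x))
    return Fraction(x)


@dataclass(frozen=True)
class ElementarySituation:
    """Four joint counts (d, e, f, g) of a binary-hypothesis, binary-datum world.

    Derived quantities: ``a`` the total sampling volume, ``b`` the number of
    hypothesis-true cases, ``c`` the hypothesis-false cases, and the base
    rate b/a as an exact fraction.
    """

    d: int
    e: int
    f: int
    g: int

    def __post_init__(self) -> None:
        for name in ("d", "e", "f", "g"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValueError(f"count {name} must be a non-negative integer, got {v!r}")
        if self.a == 0:
            raise ValueError("empty situation: all four counts are zero")

    @property
    def a(self) -> int:
        return self.d + self.e + self.f + self.g

    @property
    def b(self) -> int:
        return self.d + self.e

    @property
    def c(self) -> int:
        return self.f + self.g

    @property
    def base_rate(self) -> Fraction:
        return Fraction(self.b, self.a)

    def counts(self) -> tuple[int, int, int, int]:
        return (self.d, self.e, self.f, self.g)

    def mirrored(self) -> "ElementarySituation":
        """The color-swapped situation (e, d, g, f): D1 and D2 exchange roles."""
        return ElementarySituation(self.e, self.d, self.g, self.f)


@dataclass(frozen=True)
class BayesProblem:
    """A probability-format problem: prior P(H) and likelihoods P(D|H), P(D|not-H)."""

    prior: Number
    likelihood_h: Number
    likelihood_not_h: Number

    def __post_init__(self) -> None:
        for name in ("prior", "likelihood_h", "likelihood_not_h"):
            v = _to_fraction(getattr(self, name))
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {getattr(self, name)!r}")


def posterior(problem: BayesProblem) -> Fraction:
    """Posterior probability P(H|D) by Bayes' rule.

    P(H|D) = P(H)P(D|H) / [P(H)P(D|H) + P(not-H)P(D|not-H)]

    Returns an exact fraction.  Raises :class:`UndefinedPosteriorError` when
    the datum has probability zero.
    """
    p = _to_fraction(problem.prior)
    lh = _to_fraction(problem.likelihood_h)
    ln = _to_fraction(problem.likelihood_not_h)
    num = p * lh
    den = num + (1 - p) * ln
    if den == 0:
        raise UndefinedPosteriorError("datum has probability zero; posterior undefined")
    return num / den


def posterior_from_counts(sit: ElementarySituation, option: Choice) -> Fraction:
    """Posterior P(H | option) from natural frequencies.

    D1 gives d/(d+f), D2 gives e/(e+g) — the proportion of hypothesis-true
    cases among the cases showing that datum.  Exact rational result.
    """
    if option is Choice.D1:
        num, den = sit.d, sit.d + sit.f
    elif option is Choice.D2:
        num, den = sit.e, sit.e + sit.g
    else:
        raise ValueError(f"option must be D1 or D2, got {option}")
    if den == 0:
        raise UndefinedPosteriorError(f"no observations of {option.value}; posterior undefined")
    return Fraction(num, den)


def situation_from_problem(problem: BayesProblem, population: int) -> ElementarySituation:
    """Render a probability-format problem as joint counts in a population.

    d = N·P(H)·P(D|H), e = N·P(H)·(1−P(D|H)), f = N·(1−P(H))·P(D|not-H),
    g = the remainder.  Every joint count must come out integral; otherwise
    :class:`IncompatiblePopulationError` is raised.
    """
    if not isinstance(population, int) or population <= 0:
        raise ValueError(f"population must be a positive integer, got {population!r}")
    p = _to_fraction(problem.prior)
    lh = _to_fraction(problem.likelihood_h)
    ln = _to_fraction(problem.likelihood_not_h)
    joints = {
        "d": population * p * lh,
        "e": population * p * (1 - lh),
        "f": population * (1 - p) * ln,
        "g": population * (1 - p) * (1 - ln),
    }
    counts = {}
    for name, value in joints.items():
        if value.denominator != 1:
            raise IncompatiblePopulationError(
                f"population {population} gives non-integral joint count {name} = {value}"
            )
        counts[name] = int(value)
    return ElementarySituation(**counts)


def round_percent(value: Number, decimals: int = 0) -> float:
    """Report a probability as a percentage, rounded half-away-from-zero.

    Used only at reporting boundaries; internal values stay exact.

    >>> round_percent(Fraction(8, 17))
    47.0
    """
    pct = Decimal(_to_fraction(value).numerator * 100) / Decimal(_to_fraction(value).denominator)
    quantum = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(quantum, rounding=ROUND_HALF_UP))


#: Worked single-question problems with their textbook parameters.
#: Keys: red_nose (does a red-nosed villager lie?), mammography (cancer given
#: a positive mammogram), taxi_cab_blue (cab was blue given the witness said
#: blue), taxi_cab_green (the reversed question: green given witness said green).
WORKED_PROBLEMS: dict[str, BayesProblem] = {
    "red_nose": BayesProblem(prior=Fraction(10, 100), likelihood_h=Fraction(8, 10), likelihood_not_h=Fraction(9, 90)),
    "mammography": BayesProblem(prior=Fraction(1, 100), likelihood_h=Fraction(80, 100), likelihood_not_h=Fraction(96, 1000)),
    "taxi_cab_blue": BayesProblem(prior=Fraction(15, 100), likelihood_h=Fraction(80, 100), likelihood_not_h=Fraction(20, 100)),
    "taxi_cab_green": BayesProblem(prior=Fraction(85, 100), likelihood_h=Fraction(80, 100), likelihood_not_h=Fraction(20, 100)),
}
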