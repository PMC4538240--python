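"""Conformity-curve plots, regenerated from computed summary tables.

matplotlib is imported lazily; install the ``plot`` extra to use this
module.
"""

from __future__ import annotations

from .enumeration import ConformitySummary, Stratum, StrategyId


def plot_conformity_curves(
    summaries: list[ConformitySummary],
    stratum: Stratum = Stratum.OVERALL,
    ax=None,
):
    """Percentage of situations conforming to the Bayesian choice versus
    sampling volume, one line per heuristic, for one base-rate stratum."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    strategies = sorted({s.strategy for s in summaries}, key=lambda s: s.value)
    for strategy in strategies:
        points = [
            (s.a, s.percentage)
            for s in summaries
            if s.strategy is strategy and s.stratum is stratum and s.percentage is not None
        ]
        if points:
            xs, ys = zip(*points)
            ax.plot(xs, ys, marker=".", label=strategy.value.replace("_", "-"))
    ax.set_xlabel("sampling volume a")
    ax.set_ylabel("% of situations conforming to Bayes' rule")
    ax.set_ylim(0, 105)
    ax.set_title(f"base-rate stratum: {stratum.value}")
    ax.legend()
    return ax
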