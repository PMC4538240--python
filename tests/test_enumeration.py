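"""The exhaustive conformity analysis: enumeration, the volume-7 table,
stratified curves, range averages, and the non-inverse equivalence audit."""

import math
from fractions import Fraction

import numpy as np
import pytest

from bayeschoice import (
    Choice,
    ElementarySituation,
    PreBayesVariant,
    StrategyId,
    audit_noninverse_equivalence,
    average_conformity,
    conformity_records,
    conformity_summary,
    conformity_table,
    enumerate_situations,
    situation_count,
    strategy_choice,
)
from bayeschoice.enumeration import DEFAULT_STRATA, Stratum

# The complete volume-7 reference table: (d, e, f, g), Bayesian choice, then
# (choice, conformity) for representativeness, evidence-only, pre-Bayesian.
# "-" marks not-applicable.
VOLUME7_TABLE = [
    ((1, 1, 1, 4), "D1", ("Any", "No"), ("D2", "No"), ("D1", "Yes")),
    ((1, 1, 2, 3), "D1", ("Any", "No"), ("D2", "No"), ("D1", "Yes")),
    ((1, 1, 3, 2), "D2", ("Any", "No"), ("D1", "No"), ("D2", "Yes")),
    ((1, 1, 4, 1), "D2", ("Any", "No"), ("D1", "No"), ("D2", "Yes")),
    ((1, 2, 1, 3), "D1", ("D2", "No"), ("D2", "No"), ("n/a", "-")),
    ((1, 2, 2, 2), "D2", ("D2", "Yes"), ("D2", "Yes"), ("D1", "No")),
    ((1, 2, 3, 1), "D2", ("D2", "Yes"), ("D1", "No"), ("D2", "Yes")),
    ((1, 3, 1, 2), "D2", ("D2", "Yes"), ("D2", "Yes"), ("n/a", "-")),
    ((1, 3, 2, 1), "D2", ("D2", "Yes"), ("D2", "Yes"), ("n/a", "-")),
    ((1, 4, 1, 1), "D2", ("D2", "Yes"), ("D2", "Yes"), ("n/a", "-")),
    ((2, 1, 1, 3), "D1", ("D1", "Yes"), ("D2", "No"), ("D1", "Yes")),
    ((2, 1, 2, 2), "D1", ("D1", "Yes"), ("D1", "Yes"), ("D2", "No")),
    ((2, 1, 3, 1), "D2", ("D1", "No"), ("D1", "No"), ("n/a", "-")),
    ((2, 2, 1, 2), "D1", ("Any", "No"), ("D2", "No"), ("n/a", "-")),
    ((2, 2, 2, 1), "D2", ("Any", "No"), ("D1", "No"), ("n/a", "-")),
    ((2, 3, 1, 1), "D2", ("D2", "Yes"), ("D2", "Yes"), ("n/a", "-")),
    ((3, 1, 1, 2), "D1", ("D1", "Yes"), ("D1", "Yes"), ("n/a", "-")),
    ((3, 1, 2, 1), "D1", ("D1", "Yes"), ("D1", "Yes"), ("n/a", "-")),
    ((3, 2, 1, 1), "D1", ("D1", "Yes"), ("D1", "Yes"), ("n/a", "-")),
    ((4, 1, 1, 1), "D1", ("D1", "Yes"), ("D1", "Yes"), ("n/a", "-")),
]


class TestEnumerateSituations:
    @pytest.mark.parametrize("a, expected", [(4, 1), (5, 4), (7, 20), (10, 84)])
    def test_known_counts(self, a, expected):
        sits = list(enumerate_situations(a))
        assert len(sits) == expected == situation_count(a)

    @pytest.mark.parametrize("a", [4, 6, 12, 25])
    def test_count_formula_and_validity(self, a):
        sits = list(enumerate_situations(a))
        assert len(sits) == math.comb(a - 1, 3)
        assert all(s.a == a and min(s.counts()) >= 1 for s in sits)
        assert len(set(sits)) == len(sits)

    def test_deterministic_lexicographic_order(self):
        counts = [s.counts() for s in enumerate_situations(6)]
        assert counts == sorted(counts)

    def test_empty_domain_rejected(self):
        with pytest.raises(ValueError):
            list(enumerate_situations(3))


@pytest.fixture(scope="module")
def table():
    return conformity_table(7, PreBayesVariant.STRICT)


@pytest.fixture(scope="module")
def summaries():
    return conformity_summary(5, 30)


class TestVolume7Table:
    def test_reproduces_reference_row_for_row(self, table):
        assert len(table) == 20
        for row, (counts, bayes, rep, evid, preb) in zip(
            table.itertuples(index=False), VOLUME7_TABLE
        ):
            assert (row.d, row.e, row.f, row.g) == counts
            assert row.bayes_choice == bayes
            for (choice, conf), prefix in [
                (rep, "representativeness"),
                (evid, "evidence_only"),
                (preb, "pre_bayesian"),
            ]:
                assert getattr(row, f"{prefix}_choice") == choice
                expected_conf = "n/a" if conf == "-" else conf
                assert getattr(row, f"{prefix}_conformity") == expected_conf

    def test_conformity_ratios(self, table):
        assert (table.representativeness_conformity == "Yes").sum() == 12
        assert (table.evidence_only_conformity == "Yes").sum() == 10
        assert (table.pre_bayesian_conformity == "Yes").sum() == 6
        assert (table.pre_bayesian_conformity != "n/a").sum() == 8


class TestConformityConvention:
    def test_heuristic_any_against_definite_bayes_does_not_conform(self):
        records = conformity_records(7)
        rec = next(r for r in records if r.situation.counts() == (1, 1, 1, 4))
        assert rec.choices[StrategyId.REPRESENTATIVENESS] is Choice.ANY
        assert rec.conformity[StrategyId.REPRESENTATIVENESS] is False

    def test_bayes_tie_policies_bound_each_other(self):
        # (1,1,2,2) is a Bayesian tie; under the default policy a definite
        # heuristic conforms, under "exclude" the situation leaves the
        # denominator entirely.
        for rec in conformity_records(6, tie_policy="conform"):
            if rec.bayes_choice is Choice.ANY:
                definite = [
                    s for s, c in rec.choices.items() if c.definite or c is Choice.ANY
                ]
                assert all(rec.conformity[s] for s in definite)
        for rec in conformity_records(6, tie_policy="exclude"):
            if rec.bayes_choice is Choice.ANY:
                assert all(c is None for c in rec.conformity.values())

    def test_color_swap_preserves_every_conformity_flag(self):
        by_counts = {r.situation.counts(): r for r in conformity_records(8)}
        for counts, rec in by_counts.items():
            mirror = by_counts[rec.situation.mirrored().counts()]
            assert rec.conformity == mirror.conformity


class TestStratifiedSummary:
    def test_strata_partition_base_rates(self):
        for br in [Fraction(0), Fraction(1, 4), Fraction(26, 100), Fraction(74, 100), Fraction(3, 4), Fraction(1)]:
            assert DEFAULT_STRATA.classify(br) in (Stratum.RARE, Stratum.MEDIUM, Stratum.FREQUENT)
        assert DEFAULT_STRATA.classify(Fraction(1, 4)) is Stratum.RARE
        assert DEFAULT_STRATA.classify(Fraction(3, 4)) is Stratum.FREQUENT
        assert DEFAULT_STRATA.classify(Fraction(1, 2)) is Stratum.MEDIUM

    def test_stratum_counts_sum_to_total(self, summaries):
        for a in (7, 12, 25):
            for strategy in (StrategyId.REPRESENTATIVENESS, StrategyId.EVIDENCE_ONLY):
                per = {
                    s.stratum: s.applicable
                    for s in summaries
                    if s.a == a and s.strategy == strategy
                }
                assert per[Stratum.RARE] + per[Stratum.MEDIUM] + per[Stratum.FREQUENT] == per[
                    Stratum.OVERALL
                ] == situation_count(a)

    def test_heuristics_perfect_in_frequent_stratum_at_small_volumes(self, summaries):
        for s in summaries:
            if s.stratum is Stratum.FREQUENT and s.a <= 11 and s.applicable > 0:
                if s.strategy in (StrategyId.REPRESENTATIVENESS, StrategyId.EVIDENCE_ONLY):
                    assert s.percentage == 100.0

    def test_prebayes_never_applicable_in_frequent_stratum(self, summaries):
        assert all(
            s.applicable == 0
            for s in summaries
            if s.strategy is StrategyId.PRE_BAYESIAN and s.stratum is Stratum.FREQUENT
        )

    def test_evidence_only_and_strict_prebayes_complementary_when_applicable(self):
        """Where strict pre-Bayesian applies and both Bayesian and heuristic
        choices are definite, exactly one of evidence-only and pre-Bayesian
        conforms."""
        for rec in conformity_records(9):
            pb = rec.conformity[StrategyId.PRE_BAYESIAN]
            eo = rec.conformity[StrategyId.EVIDENCE_ONLY]
            if pb is None or rec.bayes_choice is Choice.ANY:
                continue
            if rec.choices[StrategyId.EVIDENCE_ONLY].definite:
                assert pb != eo

    def test_curves_plateau_at_large_volumes(self):
        """Per-volume overall conformity stabilizes: for a >= 30 the change
        between volumes of equal parity is < 2 points.  (Odd and even
        volumes admit different tie structures, so the raw curve carries a
        persistent parity ripple — evidence-only and pre-Bayesian oscillate
        by several points between adjacent a for that reason.)"""
        summaries = conformity_summary(30, 38)
        for strategy in (StrategyId.REPRESENTATIVENESS, StrategyId.EVIDENCE_ONLY, StrategyId.PRE_BAYESIAN):
            curve = [
                s.percentage
                for s in summaries
                if s.strategy is strategy and s.stratum is Stratum.OVERALL
            ]
            steps = [abs(x - y) for x, y in zip(curve[2:], curve[:-2])]
            assert max(steps) < 2.0


class TestAverageConformity:
    def test_small_range_matches_hand_tally(self):
        """Over a=7 alone the pooled and per-volume averages coincide with
        the reference ratios."""
        for weighting in ("pooled", "per_volume"):
            avg = average_conformity(7, 7, weighting=weighting)
            assert avg[StrategyId.REPRESENTATIVENESS] == pytest.approx(60.0)
            assert avg[StrategyId.EVIDENCE_ONLY] == pytest.approx(50.0)
            assert avg[StrategyId.PRE_BAYESIAN] == pytest.approx(75.0)

    def test_weightings_agree_roughly_but_not_exactly(self):
        pooled = average_conformity(5, 15, weighting="pooled")
        per_a = average_conformity(5, 15, weighting="per_volume")
        for s in pooled:
            assert abs(pooled[s] - per_a[s]) < 6.0


class TestNonInverseAudit:
    def test_exhaustive_audit_small_range(self):
        assert audit_noninverse_equivalence(4, 20) == 0

    def test_trivial_single_situation(self):
        assert audit_noninverse_equivalence(4, 4) == 0

    def test_randomized_large_count_spot_check(self):
        """10^4 random situations with counts up to 10^6, against the
        cross-multiplication oracle."""
        rng = np.random.default_rng(20150817)
        counts = rng.integers(1, 10**6, size=(10_000, 4))
        for d, e, f, g in counts:
            s = ElementarySituation(int(d), int(e), int(f), int(g))
            ni = strategy_choice(s, StrategyId.NON_INVERSE)
            assert ni is strategy_choice(s, StrategyId.BAYESIAN)
            oracle = d * g - e * f
            assert ni is (Choice.D1 if oracle > 0 else Choice.D2 if oracle < 0 else Choice.ANY)
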