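# Methods

## The model

An elementary situation is a 2×2 world: hypotheses {H, not-H} and data
{D1, D2}, with joint counts (d, e, f, g), volume a = d+e+f+g, hypothesis
count b = d+e, and base rate b/a. A chooser who wants H picks the datum
option with the larger posterior; by Bayes' rule in natural frequencies
these are P(H|D1) = d/(d+f) and P(H|D2) = e/(e+g), so the Bayesian choice
reduces to the exact integer comparison d·g vs e·f.

Six strategies are modelled as pure functions of the counts:

| strategy           | choice comparison             | point estimate of P(H\|D1) |
|--------------------|-------------------------------|----------------------------|
| Bayesian           | d/(d+f) vs e/(e+g)            | d/(d+f)                    |
| non-inverse        | d/(d+e) vs f/(f+g)            | — (defers to the posterior)|
| representativeness | d vs e                        | d/b                        |
| evidence-only      | (d+f) vs (e+g)                | (d+f)/a                    |
| pre-Bayesian       | b/(d+f) vs b/(e+g)            | b/(d+f), may exceed 1      |
| conservatism       | b vs c (no datum option)      | b/a                        |

The non-inverse rule compares likelihoods instead of posteriors — it never
inverts conditions — yet is choice-equivalent to Bayes in every elementary
situation, because d/(d+e) > f/(f+g) ⟺ d·g > e·f ⟺ d/(d+f) > e/(e+g).
The package verifies this identity exhaustively and on random large counts
rather than taking the algebra on faith.

### Conventions and numerical choices

- **Exact arithmetic everywhere.** Counts are integers; all ratio
  comparisons are integer cross-multiplications and all probabilities are
  `fractions.Fraction`. Ties (equal posteriors, equal evidence counts) are
  therefore detected exactly and returned as ANY, never broken inside a
  strategy function. Floats appear only in report output, where percentages
  are rounded half-away-from-zero to the precision being printed.
- **Ties and applicability.** A strategy with a zero denominator in a
  required ratio, or conservatism in choice mode (it compares hypotheses,
  not options), returns NA. The pre-Bayesian strategy has two variants:
  STRICT returns NA whenever b > d+f or b > e+g (an "estimate" above one is
  not a probability), which confines applicability to base rates ≤ 1/2;
  ORDINAL always compares, which makes it the exact mirror of
  evidence-only. Enumeration analyses default to STRICT, the adaptive
  design to ORDINAL (the design needs a definite prescription on its anchor
  patterns, where the strict rule would abstain).
- **Conformity.** A heuristic conforms in a situation when its choice is
  definite and equals the Bayesian choice. ANY against a definite Bayesian
  choice does not conform. When the Bayesian choice is itself a tie, no
  definite choice can violate Bayes' rule, so such situations count as
  conforming by default; a `tie_policy="exclude"` switch drops them from
  denominators instead, bounding the (small) sensitivity of every
  percentage to this convention.
- **Strata.** Base-rate strata use exact rational boundaries with the
  inclusive reading: rare b/a ≤ 1/4, frequent b/a ≥ 3/4, medium strictly
  between.
- **Aggregation over volumes.** The "average conformity" over a volume
  range is, by default, the pooled ratio: total conforming situations over
  total applicable situations across all volumes, each situation weighing
  equally. The alternative (`weighting="per_volume"`) averages the per-a
  percentages, each volume weighing equally. The two differ by one to three
  points because the number of situations grows as C(a−1, 3); the pooled
  form is the default because it is the one the published stratum figures
  (e.g. pre-Bayesian ≈ 56% at medium base rates) and range averages
  (≈ 73 / 50 / 63 percent for representativeness / evidence-only /
  pre-Bayesian over volumes 5..50) are consistent with. The per-volume
  curves also carry a persistent odd/even ripple (parity changes which tie
  configurations exist), which the pooled ratio integrates out.

## The adaptive two-task design

Six frequency patterns P1 = (2,1,3,1), P2 = (1,2,1,3), P3 = (2,1,2,2),
P4 = (2,1,1,3), P5 = (1,2,3,1), P6 = (3,1,2,1) are arranged into eight
pair rules. On an anchor pattern (P1 or P2) the Bayesian and pre-Bayesian
strategies prescribe one option and representativeness and evidence-only
the other; the second task's pattern is then chosen so that the two
strategies still in contention disagree on it. Two definite choices hence
identify exactly one of the four strategies, and eight pairs give each
strategy a 0–8 score; the four scores always sum to 8, and a uniform
random responder scores 2 per strategy in expectation.

The pairing of second patterns to first-choice branches is completed by
construction — the branch left with {Bayesian, pre-Bayesian} receives a
pattern on which those two disagree (P3 or P6), the branch left with
{representativeness, evidence-only} one on which those two disagree (P4 or
P5) — and `validate_design()` machine-checks that every pattern gives all
four strategies definite prescriptions and that every branch of every pair
separates its surviving camp. This structural validation is the authority
for the completed maps; no other routing of the printed pattern options
yields a disambiguating design.

Sessions randomize pair order, a per-adventure color swap (which option is
painted green) and the object contents from a seed. All of this is
presentation metadata: responses are recorded in presented orientation and
un-mirrored before classification, and tests check that classification is
invariant to it.

## Synthetic agents

The generator emulates a participant who applies one fixed strategy across
all sixteen adventures — consistency is the design's own working
assumption — with deviations modelled explicitly as a *lapse rate* ε: each
response is, with probability ε, replaced by a uniform random click on one
of the two cards. The lapse is uniform over options (not over strategies),
which keeps the fully-lapsed benchmark at the design's chance level of 2
per strategy. Tied prescriptions (which the six design patterns never
produce, but arbitrary situations can) are resolved by a seeded fair coin,
since a participant must click something. Default cohort conditions mirror
the experimental samples the machinery was built for: 60 agents and
stratification labels (gender × education) carried as inert metadata — no
demographic effects are modelled because none are part of the model.

Everything is reproducible bit-for-bit from the cohort seed; per-agent
seeds derive from it and stay below 2³¹.

What the generator does *not* emulate: learning or practice effects across
adventures, strategy switching within a session, content effects
(diamonds vs amber), or response times. Recovery results on synthetic
cohorts therefore show that the design identifies *consistent* strategy
users under random noise — they say nothing about humans who mix
strategies, which the identification logic cannot express (its log format
reserves an UNCLASSIFIED code only for alternative designs).

## Problem sizes

The enumeration sweep covers volumes 5..50 (230,299 situations), computed
exactly in a few seconds. Acceptance-level recovery sweeps use five lapse
levels × 1,000 agents; chance-level checks use a few hundred sessions.
These sizes give Monte-Carlo standard errors well below the asserted
tolerances (e.g. ±0.05 on a chance score of 2 needs ~400 sessions).

## Known limitations

- Two hypotheses, two data values only. The non-inverse equivalence does
  not generalize to larger hypothesis or data sets, and none of the
  machinery here attempts it.
- The pre-Bayesian estimate b/(d+f) is returned unclipped with an
  `is_probability` flag when it exceeds one; the package deliberately does
  not reciprocate or clip it, so downstream code must check the flag.
- Strategy mixtures are not fitted to empirical score tables: per-strategy
  session scores under-determine the (mixture, ε) pair, so the package
  offers forward simulation and recovery, not inference.
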