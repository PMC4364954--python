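# Methods

## The setting

Pairs of preschool children (dyads) jointly choose between two baited
trays: an *equal* tray paying E gummy bears to each child and an *unequal*
tray paying L to the child at the large plate and S to the other, L > S.
Both children must pull simultaneously, so every outcome is a joint
decision. A trial ends in one of three ways: no agreement, an agreed tray
that the pair failed to retrieve (coordination failure), or a successful
retrieval, which alone delivers rewards. The package analyses trial-level
records of such experiments: the low-stakes design is (E, L, S) = (2, 3, 1)
and the high-stakes design (2, 6, 1), four test trials per dyad, 12 dyads
per age group (3.5- and 5-year-olds), with gender and partner familiarity
as covariates.

The original trial-level data are not public. The `simulate` module
therefore generates datasets with exactly this structure, and every
statistical claim the test suite makes is a claim about computations on
that stated world, not a reproduction of the original sample.

## Statistics

### Monte Carlo strategy tests

Both tests simulate dyads choosing trays by fair coin, each simulated dyad
making as many decisions as that dyad's observed number of successful
trials, 10,000 replicates by default. Writing p_i for dyad i's observed
share of unequal-tray choices among its successes:

* **pure-strategy test** — statistic mean_i |p_i − 1/2|, expectation 0 at
  random. Significance says *individual* dyads are deterministic, in
  either direction.
* **common-strategy test** — statistic mean_i p_i, expectation 1/2.
  Significance says dyads lean the *same* way.

The p-value is the proportion of simulated statistics at least as far
(non-strict ≥) from the expectation as the observed one. The observed and
simulated statistics pass through identical arithmetic, so the non-strict
comparison is exact in floating point and needs no tolerance. The plain
b/m proportion can be exactly zero; a (b+1)/(m+1) convention is available
(`p_convention="plus_one"`) for users who prefer a positively biased but
never-zero estimate. Dyads with zero successful trials carry no choice
information and are excluded (and listed in the result).

Because the statistic is discrete at these sample sizes, the tests are
slightly conservative: with 12 dyads of exactly 4 successes the exact
type-I error at α = 0.05 is ≈ 0.026 (pure) and ≈ 0.030 (common); with the
generator's default failure processes diversifying the per-dyad success
counts it rises to ≈ 0.043 and ≈ 0.045. The calibration driver
(`analysis/06_calibration.py`) measures this empirically.

### Exact Wilcoxon signed-rank test

Zero differences are ties: dropped before ranking and reported. Tied
magnitudes receive midranks. The null distribution of the positive-rank
sum T+ is computed exactly over all 2^m sign assignments via a subset-sum
polynomial over the (doubled, hence integer) ranks; the suite checks this
against an explicit enumeration oracle and, on tie-free inputs, against an
established exact implementation. Two-sided p = min(1, 2·min(P(T+ ≤ t),
P(T+ ≥ t))); a one-sided (greater) variant exists because one published
use of the test does not state its sidedness. Enumeration is capped at
m = 20 nonzero differences (the analyses here never exceed 15). When every
difference is zero the result is flagged degenerate with p = 1.

### Expected inequality under random roles

If a dyad took the unequal tray k times and the large plate were assigned
by fair coin each time, the within-dyad reward difference is a simple
random walk of k steps of size δ = L − S. Averaging |final displacement|
over all 2^k equally likely role sequences gives

    E|Δ| = δ · k · C(k−1, ⌊(k−1)/2⌋) / 2^(k−1),

computed in exact rational arithmetic and verified against brute-force
enumeration for k ≤ 12 in the suite. Equal-tray trials are symmetric and
contribute nothing. The observed-vs-expected test pairs each dyad's
observed |reward difference| with this expectation at its own k and feeds
the differences to the exact Wilcoxon test: significance with positive
differences means dyads were more unequal than random role assignment
would produce.

### Two-sided exact binomial test

p = min(1, 2·min(P(X ≤ k), P(X ≥ k))), X ~ Binomial(n, p0). Tail doubling
reproduces every published first-choice p-value at p0 = 1/2 (2/12 → 0.039,
1/12 → 0.006, 7/12 → 0.774, 6/12 → 1) and stays well defined for
asymmetric nulls, which the minimum-likelihood construction would handle
differently. First choices are the trial-1 trays; dyads with no coded
trial-1 tray (no agreement) drop out of n.

### Theoretical outcome curves

For a dyad with u unequal-tray successes of n, total rewards are
u(L+S) + (n−u)·2E and the highest earner's predicted share is

* monopoly: (uL + (n−u)E) / total — one child always at the large plate;
* alternation: (⌈u/2⌉L + ⌊u/2⌋S + (n−u)E) / total.

Both equal 1/2 at u = 0; monopoly reaches L/(L+S) at u = n (3/4 low
stakes, 6/7 high stakes); alternation never exceeds monopoly, strictly so
for u ≥ 2.

### Pattern classification

Labels are assigned from successful trials only — the threshold τ = 0.66
is deliberately below 2/3 so that a dyad succeeding in just 3 trials can
still qualify with 2 of 3. Evaluation order: undetermined (no successes) →
equality (equal share ≥ τ) → reciprocal (≥ 2 unequal successes, large
reward split exactly evenly) → inequality (one child's large-reward share
≥ τ) → mixed. The ordering only matters in degenerate collisions; placing
reciprocal before inequality treats turn-taking among unequal choices as
the fair outcome it is. Requiring ≥ 2 unequal successes for reciprocal
prevents a single unequal trial from counting as alternation. Neither the
precedence nor the minimum count is externally fixed; both are recorded in
the classification output metadata.

## The synthetic-data generator

Per trial: no agreement with probability `p_no_agreement`; otherwise a
tray (unequal with `p_unequal`); then coordination failure with
`p_coordination_failure` (tray recorded, no rewards); on an unequal
success the large plate goes to the dyad's dominant child with
`p_dominant_large`, except for the alternator archetype, whose large plate
alternates deterministically and whose turn state does not advance on
failed trials. Protests are drawn per context (against the small amount on
unequal trials, against the equal split on equal trials) independently of
everything else; so is change-of-tray. There is no within-dyad learning
across trials.

Defaults state the world the analyses assume: failure rates
`p_no_agreement = p_coordination_failure = 0.06` (the study reports
agreement in ~88–98% of trials and success in ~91–98% of agreed trials),
protest rate 0.45 on unequal trials vs 0.10 on equal trials (protests were
reported in ~36–52% of trials, overwhelmingly against the small amount),
change-of-tray 0.20. `STUDY_MIXTURES` composes group-level populations
from the archetypes with weights following the reported per-group pattern
counts. These values were fixed once, before any test was run against
them.

What a green test does establish: the pipeline's statistics behave as
designed — calibrated type-I error under the random world, total power
against deterministic strategies, the pure/common dissociation, perfect
recovery of deterministic archetypes. What it does not establish: anything
about the original children, whose trial-level behaviour (dominance,
learning, partner-specific dynamics, protest–choice dependence) the
generator deliberately does not model.

## Numerical and design choices

* Group statistics use the sample (n−1) SD across dyads; proportions are
  computed per dyad first and then averaged. Undefined proportions
  (denominator zero) propagate as explicit nulls, never as zeros.
* Proportion denominators: unequal share and change-of-tray use successful
  trials; protest proportion uses all trials (protest coding starts at
  room entry). The choice for protests is not externally fixed and is
  flagged in the report output.
* Child identity within a dyad is positional (A/B); every statistic is
  symmetric in A/B except the large-recipient bookkeeping.
* Unsuccessful agreements keep their agreed tray: they count toward
  agreement proportions but never enter reward or choice denominators.
* Trials CSV is canonical (fixed column order, lowercase enums,
  `true`/`false` booleans, `\n` newlines), so write∘read and read∘write
  are bit-exact identities — property-tested over generated datasets.
* Monte Carlo results, reports and generated datasets carry their seeds;
  per-group seeds inside the pipeline derive deterministically from the
  configured base seed via a seed sequence.
* The reader infers the tray design from the file's `experiment` column
  (required unique per file); files mixing experiments need an explicit
  design, since a dataset carries exactly one payoff structure.

## Known limitations

* The exact Wilcoxon is limited to 20 nonzero differences by design;
  beyond that an asymptotic test (out of scope here) would be appropriate.
* Published group-level test statistics that depend on the unavailable
  trial-level data (Wilcoxon T values on the real sample, the Monte Carlo
  p-values of the original runs, GLM effects) are not reproducible and are
  not claimed; only values fully determined by printed counts are
  recomputed exactly.
* The generator's mixture weights emulate reported *pattern counts*, not a
  fitted model; simulated test results should match the originals in
  direction and rough magnitude, not digit for digit.
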