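# Methods

## The modelling problem

A listener hears a short sequence of 2–4 major triads and rates how well the
final chord belongs to the preceding context on a 9-point Degree-of-Relatedness
(DOR) scale (1 = least appropriate, 5 = neutral, 9 = most appropriate).
`harmex` models the internal fitness `E(c_τ) ∈ [0, 1]` of the final chord
given its context and assumes a linear response map `A = 10·E`, so a neutral
rating of 5 corresponds to `E = 0.5` and the expressible fitness range under
ratings 1–9 is `[0.1, 0.9]`.

Chords are pitch-class objects: each is one of the 12 major triads, identified
by its root (0 = A … 11 = G♯ internally; the CSV dialect codes roots 1–12).
Intervals are directed root distances reduced mod 12.

## The six models

| model | E depends on | free parameters |
|-------|--------------|-----------------|
| 1P | root of the final chord | 12 profile entries |
| 2P | pitch pair (penultimate, final) | 132 matrix cells (diagonal excluded) |
| 1M | final root interval | 11 interval entries (unison excluded) |
| 2M | intervals from the two preceding chords to the final chord | 121 cells (unison column and diagonal excluded) |
| BU | reference-relative transition + belief over a hidden reference | 132 cells + κ |
| BS | as BU with confidence-triggered prior resets | 132 cells + κ + θ |

BU and BS posit a hidden tonal reference `X` — one of the 12 triads, playing
the role of a key centre — with a belief distribution `P(X)`.  A transition
matrix `T(i, j)` holds the fitness of moving from a chord labelled `i` to one
labelled `j`, where labels are intervals from the reference (`label(c|X) =
interval(X, c)`, 0-based).  After the first chord the belief is

    P(X = c₁) = κ,    P(X = other) = (1 − κ)/11,      0 < κ ≤ 1,

so κ measures how strongly the opening chord is taken as the tonal anchor
(κ = 1/12 is complete agnosticism, κ = 1 certainty).  Each subsequent chord
updates the belief by Bayes' rule with the reference-relative transition as
likelihood; the expectancy of the final chord marginalizes the transition
fitness over the belief carried up to the penultimate chord.  BS additionally
monitors the maximum of the provisional normalized posterior: if it falls
below θ the prior is reset to the initial-state form anchored on the previous
chord (same κ) before the update, modelling a perceived key change.  θ = 0
makes BS extensionally identical to BU.

All transition entries are free fitness values in `[0, 1]`; rows are *not*
normalized, because the rating map requires `E` to reach 0.9 and the discrete
estimation grid treats entries independently.  Cells that would describe an
immediately repeated chord (unstable to rate) are excluded from every model,
and trials containing an immediate repetition are dropped before fitting and
evaluation.  For 2M at sequence length 2 the unobserved earlier chord is
marginalized with a flat prior, i.e. the matrix column is averaged over its
defined rows.

## Cost function

Each trial's normalized rating `A′ = A/10` is treated as a target probability
and compared with the model output through the Bernoulli cross-entropy

    h(A′, E) = −[A′·ln E + (1 − A′)·ln(1 − E)],

summed over trials.  Each term is strictly convex in `E` with its minimum at
`E = A′`, which gives the cost the two properties the analysis rests on: data
generated through `A = 10·E` from on-grid parameters are refit exactly, and
the planted parameters are a coordinatewise optimum of the cost on their own
data.  A one-sided weighted log-score (`−A′·ln E` alone) would instead be
minimized by saturating every entry at 1 regardless of the data, so it cannot
serve as a fitting criterion here.  `E` is clamped to `[1e−12, 1 − 1e−12]`
inside the cost, and likelihoods are clamped below at `1e−12` during belief
updates, since the grid admits entries of exactly 0.

## Estimation

All parameters live on discrete grids — transition entries step 0.1 on
`[0, 1]`, κ step 1/12 on `(0, 1]`, θ step 0.05 on `[0, 1]` — and are
estimated by coordinate descent: every free parameter is initialized
uniformly at random on its grid; parameters are visited in a freshly shuffled
order each sweep; each parameter is compared against its ±1-step grid
neighbours and moved only on strict improvement (ties keep the current
value, which guarantees termination on the finite lattice); sweeps repeat
until none moves.  The library default is 100 random restarts; the tests and
the acceptance script use 2–5 restarts with correspondingly small problem
sizes.  One root seed drives a deterministic per-restart stream, so fits are
exactly replayable.  Restart 0 can optionally start from supplied parameters,
which is how the nesting check (BS initialized at the fitted BU solution with
θ = 0 can only match or improve the training cost) is implemented.

## Evaluation

Two held-out schemes: the *individual* split trains per participant on the
2- and 3-chord conditions (288 trials on the complete design) and tests on
the 4-chord condition (64 trials); the *k-fold* scheme pools all participants
and conditions into a seeded random 10-fold cross-validation.  Paired
per-unit test cross-entropies (units = participants or folds) are compared
with the exact two-sided binomial sign test — ties excluded,
`p = min(1, 2·P(X ≤ min(n₊, n₋)))` with `X ~ Binomial(n₊+n₋, ½)` — and, for
the k-fold scheme, a classical paired t-test.  Information-criterion
comparison is deliberately out of scope: the rating-to-probability map makes
likelihood and penalty terms incommensurable.

## Pre-modeling statistics

All behavioural tests operate on DORs averaged across participants per
distinct stimulus pattern.  The 2-chord design (all 144 ordered root pairs)
is tested factor-by-factor with tie-corrected Kruskal–Wallis tests (12 groups
of 12, df = 11); the 3-chord design (complete 12×12 grid of successive
intervals) with Friedman tests where treatments are the levels of the tested
interval and blocks the levels of the other — for the first-to-final interval
the grid is re-indexed by the total interval, which is a bijection for fixed
final interval and keeps the block design complete.  Six interval profiles
(mean DOR at the shared intervals {2, 5, 7, 10} semitones for each
preceding-chord position) are compared through their Euclidean distance
matrix by non-metric MDS (SMACOF with isotonic regression, 50 random starts,
convergence threshold 1e−12, Kruskal stress-1) and complete-link hierarchical
clustering.  The context-gain analysis subtracts from each 3-chord pattern
the mean 2-chord DOR matched on the final interval (interval matching, not
pitch matching, because the 2-chord results show interval dominance), tests
the first-to-final-interval effect with a Friedman test, and runs pairwise
mean-rank (Nemenyi-style) post-hoc comparisons Bonferroni-corrected over the
66 treatment pairs (threshold 0.05/66 ≈ 0.000758).

## Synthetic data and recovery

The generator emulates the behavioural design: 144 two-chord sequences (all
ordered root pairs), 144 three-chord sequences (all ordered interval pairs,
random initial roots), 64 four-chord sequences (all triples over the shared
intervals), rated by any number of simulated participants.  Planted
parameters are drawn uniformly from their grids, with transition entries
restricted to {0.1, …, 0.9} so that `10·E` stays on the rating scale.  The
default rating channel is continuous (`A = 10·E` exactly); discretization to
the 9-point scale plus additive Gaussian noise (in rating points) is opt-in.
Repeated-chord trials, for which the models define no expectancy, receive a
neutral base rating of 5 when the full design is emulated.

The recovery study re-estimates planted parameters from data simulated on
the 253 repetition-free 2- and 3-chord patterns (all 132 distinct-root pairs
plus all 121 interval pairs with both steps nonzero, anchored at root 0 —
the interval-indexed models are transposition-invariant; for the
pitch-indexed models the 3-chord roots are randomized instead).  With the
lossless continuous channel, recovery is exact (zero bias, zero spread) for
1P, 2P, 1M and 2M; BU and BS carry finite reported bias because belief
updating couples the parameters.  θ is structurally unidentifiable from
sequences of length ≤ 3: the only reset opportunity is the second chord,
where the reset prior coincides with the initial prior by construction, so
BS recovery reports a large θ dispersion.  This is a property of the
stimulus set, not of the estimator.

What passing these simulations shows — and does not show: the generator
reproduces the design, the response map, and (optionally) rating
discretization and i.i.d. Gaussian rating noise, so the tests certify the
estimator and the evaluation machinery.  It does not emulate inter-rater
criterion differences, sequential dependencies between trials, attention
lapses, or any mismatch between the assumed linear rating map and real
behaviour, so performance on real data can differ.

## Scaled-down study conditions

The model-comparison check runs on data from a planted BU model over the 253
recovery sequences replicated across 3 simulated participants, with 5
restarts and 10-fold cross-validation.  Replication mirrors the pooled
cross-validation design, where every stimulus pattern recurs across folds;
with a single replicate the residual fitting error of the 133-parameter BU
model exceeds its structural advantage over the 11-parameter interval model
and no restart budget recovers the ordering.  Under replication BU and BS
attain lower mean held-out cross-entropy than 2M, 1M, 2P and 1P.

## Known limitations

- Only major triads with a fixed duration are modelled; chord quality,
  voicing, rhythm and loudness are out of scope.
- The BS reset criterion compares the *maximum* of the provisional posterior
  with θ; comparing the normalizing constant or per-candidate probabilities
  are defensible alternatives and the criterion is isolated in one function.
- The key-profile reduction averages the transition matrix over its 11
  defined preceding labels (keeping the result on the fitness scale, hence
  mappable to an ideal DOR via ×10); the literal column sum is exposed as an
  option.
- Coordinate descent on a grid has no optimality guarantee for the coupled
  BU/BS costs; random restarts are the only safeguard, as reflected in the
  reported recovery bias.
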