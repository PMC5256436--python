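# Methods

## Evidence model

All simulations share one generative model: filler and innocent-suspect
memory strengths are i.i.d. N(0, 1); the guilty suspect's strength is
N(d′, σ).  Default parameters are d′ = 1.5 and σ = 1 (equal variance);
σ = 1.2 is the conventional unequal-variance setting, and d′ ∈
{0.5, 1, 1.5, 2} spans the levels used in the canonical experiments.
Strengths within a lineup are sampled independently — the model contains
no within-lineup correlation, no witness-level heterogeneity in d′ or
criterion placement, and no non-Gaussian tails.  Passing tests therefore
validate the decision and measurement machinery under these idealized
conditions; they do not certify behaviour on real witness data, where all
three complications are plausible.

The guilty sample occupies a uniformly random position in each
target-present lineup.  Position is irrelevant for strength-ordering rules
(showup, simultaneous, any-ID sequential) but decisive for the first-ID
sequential rule, whose presentation order is additionally re-randomized on
every trial.

## Confidence criteria

Confidence is assigned from a strictly increasing criterion ladder
c₁ < … < c_k (default: the seven-step ladder 0.18, 0.23, 0.27, 0.39,
0.67, 1.15, 1.53).  A strength at or below c₁ is level 0 — no
identification.  Otherwise the level is the 1-based index of the lowest
criterion at or above the strength, capped at k: a strength of 1.0 falls
between the fifth and sixth criteria and receives level 6; anything above
c₇ receives level 7.  Ties at a criterion classify downward, a measure-zero
choice for continuous evidence fixed so unit tests are deterministic.

## Common random numbers

Each procedure's entire criterion sweep runs on a single fixed pool of
trials (default 10,000 per trial type), so adjacent operating points differ
only in the criterion.  This makes H and F *exactly* non-increasing in the
criterion for every threshold-style procedure, not just in expectation, and
it is also why the relative-guess rule draws its per-trial guess once and
reuses it across the sweep.  Lineup-size comparisons use nested pools: the
size-N lineup reuses the guilty draw and the first N−1 filler draws of the
largest lineup, isolating the pure effect of the number of photographs.

The default sweep is 161 evenly spaced criteria on
[−3, d′ + 3·max(1, σ)], dense enough that figure-level curves are smooth
and trapezoidal pAUCs are grid-converged at the fourth decimal.

## Decision rules

"Next-best photograph" in the relative rules means the second-highest
sampled strength regardless of whether it clears the criterion; this
reading makes Δ = 0 reduce exactly to the absolute rule, which the test
suite asserts.  The relative-guess rule guesses uniformly between exactly
the two strongest photographs.  The default margin is Δ = 0.15, one tenth
of the reference d′.

Target-absent convention: by default any positive response to a TA lineup
counts and the rate is divided by N, applied uniformly at every criterion
(equivalently, every confidence level).  The alternative
`designated_innocent` convention scores only identifications of a fixed
position; the two agree in expectation by exchangeability, which is tested
within Monte Carlo error.

## Sequential stopping rules

The first-ID rule ends the trial at the first above-criterion photo, one
lap only.  Its hit rate is non-monotone in the criterion: liberal criteria
let early fillers steal the identification, and in the limit the hit rate
equals the probability the guilty suspect leads the sequence, 1/N.  The
any-ID rule flags every above-criterion photo and keeps the strongest; it
is implemented as that literal process (masked argmax per criterion), not
by delegating to the simultaneous code, and the equality of the two on
shared samples is verified as a dual-route test.

## 2AFC

The 2AFC decision variable is the strength difference target − lure,
distributed N(d′, √(1 + σ²)).  The rating ROC sweeps a criterion on the
difference with the mirrored class (target in the other slot) on the
false-alarm axis; its closed form is H = Φ(z(F) + 2d′/√(1 + σ²)).  The
task's accuracy is reported as the probability the target beats the lure,
P(diff > 0) = Φ(d′/√(1 + σ²)), which by the area theorem estimates the
full area under the underlying guilty-vs-innocent yes/no ROC.  The two
summaries answer different questions and both are exposed; they are kept
deliberately distinct because conflating lineup and 2AFC sensitivity
measures is itself one of the errors this package exists to demonstrate.

## ROC integration and pAUC

pAUC is the raw trapezoidal area from F = 0 to F_max (default 0.10 or
0.16), with linear interpolation at F_max and the origin prepended.  It is
not rescaled to [0.5, 1]: raw areas are what the reference-square
comparisons in the canonical figures use.  A curve ending short of F_max
(lineup curves terminate near F = 1/N) is extended horizontally at its
last hit rate.  A curve that is not monotone in both coordinates — the
first-ID sequential ROC droops at liberal criteria — is reduced to its
upper envelope in F before integration, with a loud warning, because area
under a self-folding path is otherwise ill-defined.

The bootstrap resamples TP and TA trials with replacement, independently
of each other (not confidence bins, and with no number sharing between
procedures), rebuilds the ROC per replicate via each trial's response
threshold, and reports percentile intervals (2.5/97.5 by default,
2000 replicates).  First-ID sequential curves are excluded from the
bootstrap because they have no per-trial threshold representation.

Empirical rates fed to z-transforms can sit at 0 or 1; `bias_stats`
optionally clamps p to [1/(2n), 1 − 1/(2n)] to keep d′ and c finite, and
flags the diagnosticity ratio as undefined (NaN with a warning) at F = 0
rather than returning infinity silently.

## Bayesian measures

Posterior of guilt after an identification is bH/(bH + (1−b)F); after a
negative outcome (filler identification and rejection merged) it is
b(1−H)/(b(1−H) + (1−b)(1−F)); 0/0 cases return the prior.  Information
gain is posterior − base rate, pinned to 0 at b ∈ {0, 1}.  Criterion
placement for these curves is parameterized as an offset k from the guilty
mean in guilty-SD units (c = d′ + k·σ, so H = Φ(−k), F = Φ(−c) under the
one-photo closed form); the default illustrative offsets are k ∈ {0, 1}
with d′ ∈ {1.0, 1.5}.  The exact (d′, bias) pairs behind the canonical
posterior figures are not published, so those curves are reproduced
qualitatively — the tested properties are the endpoint pinning, the
monotone effect of d′ at fixed offset, and the existence of
conservative-low-d′ conditions that out-gain liberal-high-d′ ones.

## Problem sizes and determinism

Default problem sizes are 10,000 trials per trial type, 161-point sweeps
and 2000 bootstrap replicates; unit tests use the same sizes where a
quantitative claim is checked (binomial tolerances are stated as 3–4
standard errors at the simulated n) and smaller pools for structural
checks.  Every random stream derives from a single seed recorded in all
outputs; identical seeds give byte-identical CSV bundles.

## Known quantitative limits

At d′ = 1.5 the model-level gap between showup and six-person-lineup pAUC
over F ∈ [0, 0.10] is 0.0014 (by numerical integration of the closed
forms); it is 0.0002 at d′ = 0.5 and 0.0008 at d′ = 1.0.  "Differences in
the fourth decimal place" is therefore a property of the lower
discriminability range, not of d′ = 1.5, and the corresponding equivalence
check in the test suite documents this in its docstring.  Monte Carlo
noise at 10,000 trials adds roughly ±0.0007 to any single-seed estimate of
that gap.
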