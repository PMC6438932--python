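# Methods

## The personal utility function

The descriptive system is a 3-level reduction of EQ-5D: five dimensions
(MO, SC, UA, PD, AD, in that fixed order) at levels 1/2/3 (no, moderate,
extreme problems), 243 states. A respondent's utility is additive in
per-dimension decrements:

u(s) = 1 − Σ_d δ_{d,level_d(s)}, with δ_{d,1} = 0, δ_{d,3} = w_d and
w_d the swing ratings normalised to sum to 1. Because the level-3
decrements exhaust the unit interval, u(11111) = 1 and u(33333) = 0 on the
raw scale for every respondent. Weights are obtained by proportional
normalisation even when no rating of 100 was given (or several were) —
only relative magnitudes matter. The model deliberately carries no
interaction terms: the section G tasks *measure* evidence of interactions
but their answers do not enter the utility function or the value set.

### The level-2 mapping convention

Section D asks respondents to split 100 points between the extreme→moderate
improvement (p_d) and the moderate→none improvement (100 − p_d). Two
readings of how p_d scales the intermediate decrement are defensible:

* **share_of_swing** (default): δ_{d,2} = w_d · p_d/100. The points given
  to the extreme→moderate improvement are the share of the dimension's
  swing already recovered at the moderate level.
* **remaining_badness**: δ_{d,2} = w_d · (1 − p_d/100). The literal reading
  of the allocation instruction (more points to the first improvement ⇒ the
  moderate level retains less badness).

The two coincide at p_d = 50, where most empirical answers sit. The default
follows the observed relationship in published pilot summaries, where the
ratio of mean level-2 to level-3 decrements tracks the mean intermediate
allocation dimension by dimension; the alternative remains available via
`level2_mapping="remaining_badness"` everywhere a PUF is constructed, and
the choice is recorded in study-file metadata. The discrepancy between the
two readings is a genuine ambiguity of the instrument, not resolved here.

### Ranking

All 243 states are sorted by utility, descending; exact ties break by
ascending state code. Ranks are 1-based with rank 1 = best (so the worst
state is "ranked 243rd"). The tie-break is an arbitrary but deterministic
convention; any order-preserving alternative would change only the labels
of exactly-tied states.

## Adaptive task generation

**Validation pairs (section E).** The easy pair starts from the outer
decile ranks (⌈0.1·243⌉ = 25 and ⌈0.9·243⌉ = 219) and scans outward,
widening the rank gap, to the first pair in which neither state dominates
the other; the hard pair is a non-dominating adjacent-rank pair of minimal
utility gap, preferring pairs nearest the median rank (122). The decile
targets are this package's choice: they are far enough apart that, across
simulated cohorts, the easy pair's better option has a level-sum severity
score at least three units below the worse option's for a clear majority of
respondents — the qualitative signature the task is meant to have — while
quartile targets (ranks 61/183) turn out to produce that contrast for only
about a third of simulated respondents.

**Dead search (section F).** Five choices between "10 years in state X
then death" and "dying now". X starts at rank 243; a choice to live there
ends the search (dead lies below every describable state, and no anchored
PUF can be built by present methods). Otherwise each answer bisects the
rank interval: the next rank presented is the round-half-up midpoint of the
current bounds, with rank 1 standing in while no lower bound exists. This
rounding convention is calibrated to two fixed points of the protocol — the
second task sits at rank 122, and the sequence B,A,A,A,A terminates with
dead bracketed between ranks 228 and 243 (floor rounding would end at 227
and is therefore rejected). After a complete search the bracket spans a
rank difference of 15 or 16 (reported as the rank difference; the
enumeration of all 16 completed paths is in the test suite and the
acceptance script). Respondents answering "die" throughout have dead placed
between full health and the mildest state presented (rank 17 under this
rounding).

**Interaction tasks (section G).** The most/least important dimensions come
from the section B ranking under the AVG tie convention, ties broken by the
higher (for most) or lower (for least) section C rating, then by fixed
dimension order — the instrument says only "as indicated in section B", so
the tie rule is ours. Tallies report counts and percentages of
A/B/indifferent/missing over an explicit respondent denominator.

## Anchoring and aggregation

u_dead is the midpoint of the raw utilities of the two bracketing states
(or of 1 and the mildest presented state's utility for never-switchers at
the mild end). Rescaling is affine: v(s) = (u(s) − u_dead)/(1 − u_dead),
equivalently all decrements divide by (1 − u_dead); it preserves the state
ordering exactly.

Respondents for whom no state is worse than dead cannot be rescaled; by
default they enter aggregation with their raw 0–1 values, which is
equivalent to anchoring dead exactly at 33333 — a conservative lower bound
on their (unobservable) dead location. `include_unrescaled=False` drops
them instead. The outlier rule is an explicit threshold (default −10) on
the anchored value of 33333, replacing the judgemental exclusion a human
analyst would make for a respondent whose dead sits implausibly close to
full health; the threshold is configurable and recorded in metadata.

Aggregation operates on decrements, not state values: per dimension-level
cell we report min, quartiles (linear interpolation between order
statistics — the common spreadsheet convention), median, mean, max, SD
(n − 1 denominator) and SE = SD/√n. The value set is 1 minus the sum of
the chosen central decrements; with mean aggregation of unanchored PUFs the
level-3 decrements sum to exactly 1 by conservation, so 33333 values
exactly 0. Note that for the embedded published fixtures the printed SEs
imply a smaller contributing n than the stated sample size; the fixture
stores the printed numbers verbatim and this package always computes
SE = SD/√n from its own data.

## The simulator

Synthetic respondents carry latent preferences: Dirichlet(4,…,4) dimension
weights (moderate heterogeneity), Beta(4,4) level-2 fractions (centred on
0.5, as observed allocations are), a 24% subpopulation for whom no state is
worse than dead, and otherwise a latent dead utility drawn Beta(2,6) on the
raw scale (mass near the severe end, where observed brackets concentrate).
Responses are then constructed as the instrument would elicit them: ratings
proportional to latent weights rounded to a grid (default 5, emulating
round-number bias; 0 disables), rankings derived from the rounded ratings
(equal rounded ratings tie), and choice tasks answered by comparing latent
utilities with logistic noise of configurable scale (0 = deterministic).
All randomness flows from one seed through per-respondent spawned streams,
so extending a cohort never changes earlier respondents.

What the simulator does *not* emulate: interviewer effects, anchoring/order
effects, preference construction during deliberation, inconsistent or
missing answers, and any systematic dependence between dimension weights
and dead location. Passing recovery tests therefore shows the pipeline's
arithmetic is faithful — stated inputs are recovered exactly when responses
are noiseless, and gracefully degrade under rounding and choice noise — not
that real respondents behave like the generator.

A note on the noise-free pipeline test: the five-task search can only ever
bracket a latent dead utility, so the "latent truth" against which the
pipeline's anchored decrements are compared is the latent PUF anchored at
the bracket midpoint that exact bisection yields — under zero noise the
pipeline must (and does) reproduce that to float precision; recovering the
latent dead utility itself is limited by the bracket width (about 0.06 on
the raw scale), visible as the irreducible RMSE in `recovery_report`.

## Numerical choices and degenerate inputs

* Weight conservation is enforced at 1e-9; utilities are plain float64
  arithmetic with no rescaling tricks.
* All-zero swing ratings are rejected (weights undefined); a zero rating on
  some dimensions is legal and zeroes that dimension's contribution.
* Allocations of 0 or 100 are legal endpoints (a 0 intermediate allocation
  under the default mapping makes moderate problems costless).
* The bisection raises on an exhausted interval (cannot occur within the
  five-task protocol over 243 states).
* Default-task respondents (adaptive tasks generated from the uniform
  fallback PUF — every rating 100, every allocation 50 — rather than their
  own answers) are excluded from value-set aggregation by default, since
  their dead search indexes a ranking that is not theirs; their sections
  A–D remain usable.

## Known limitations

* No interaction-adjusted utilities or value sets; section G data are
  tallied only.
* Dead location is estimated only as a bracket midpoint; no interpolation
  from choice response times, no lead-time TTO style alternatives.
* The 10-year duration framing of the dead search is carried as metadata
  and does not enter the arithmetic, but the elicited locations of dead are
  only meaningful relative to some stipulated duration.
* Aggregation treats PUFs as interpersonally comparable and offers only
  mean/median centrals; preference-type clustering is out of scope.
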