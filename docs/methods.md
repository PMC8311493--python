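# Methods

This note documents the statistical procedure the package implements,
the choices that were genuinely open, and what the synthetic-data
experiments do and do not establish.

## Data model and discretization

A study record holds continuous psychosocial indexes (multi-item scale
means, expected in [1, 7]) at two time points, demographics, and a
four-level message-frame assignment.  The prediction target is the
intention-change index, Time-2 minus Time-1 intention; it is derived
before any discretization and the raw Time-2 intention column never
enters the network (only the change does), which removes an obvious
target-leakage route.

Continuous variables are cut at empirical quantiles: tertiles for
ordinary indexes, quintiles (20% steps) for the target.  Conventions the
questionnaire literature does not pin down are fixed here once:

* **Quantile estimator** — linear interpolation of order statistics
  (the ubiquitous "type 7"); deterministic and the default of every
  mainstream numerical library.
* **Breakpoint ties** — a value exactly equal to a breakpoint falls in
  the *lower* bin.  Likert-scale means make exact hits common enough
  that an unstated rule would silently move records between bins.
* **Coincident breakpoints** — heavy ties can collapse two quantiles to
  the same value; the affected bins are merged with a warning and the
  variable proceeds with fewer effective levels.  Every downstream
  component works from the per-variable level list, so reduced arity is
  handled uniformly.
* **Demographics** sit in the Time-1 slice (age tertile-discretized,
  sex and education native categoricals): they are baseline properties
  regardless of where in the questionnaire they were asked.

## The network and exact inference

The DBN is an acyclic parenthood map over four ordered pseudo-slices
(Time 1 < intervention < Time 2, with the target treated as Time 2).
Structural validity means: acyclic, no arc against time order, the
intervention node parentless (frames are assigned by design) and the
target childless.

The only inference the pipeline needs is the posterior of the target
given Time-1 and intervention evidence, with all Time-2 mediators
latent.  This is computed exactly: barren nodes — unobserved non-target
nodes without observed descendants, whose factors sum to one — are
pruned, and the surviving free variables (the target's Time-2 ancestors,
at most a handful) are summed out by enumeration.  On networks of this
size enumeration after pruning is indistinguishable in cost from
variable elimination and considerably easier to audit; a test suite
oracle checks it against full-joint summation to 1e-12.

Zero-probability evidence can occur under unsmoothed parameters (a
held-out record may show a parent configuration absent from training).
The posterior then falls back to uniform and the record is flagged; the
flag count surfaces in evaluation reports so the event is never silent.

## Parameter estimation

Complete data: closed-form MLE, `p(x|u) = (N(x,u) + α) / (N(u) + αK)`,
with pseudocount α ≥ 0.  The default α = 1 keeps leave-one-out
posteriors proper; α = 0 is used wherever an exact identity is asserted
(see the decomposition below).  Missing cells (assumed missing at
random): exact EM.  The E-step groups records by missing pattern and,
per pattern, enumerates the missing variables' configurations to
distribute fractional counts to every family touching a missing cell;
fully observed families contribute fixed counts computed once.
Initialization is uniform CPTs perturbed by seeded noise of magnitude
0.01 (one restart by default — the categorical likelihood at study
scale is benign); convergence is declared when no parameter moves more
than 1e-6.  The whole fit is a pure function of (structure, data,
config), and on complete data the first M-step already reproduces the
smoothed MLE exactly.

## Scores

All information scores are empirical frequency-table quantities in
natural log.  Records missing any variable of a scored subset are
dropped *for that score only*, which keeps every score well defined and
deterministic under arbitrary missingness.  Information gain is
implemented in its conventional non-negative orientation,
`IG = H(X) − H(X|parents)`: this is the sign the likelihood
decomposition requires,

    l(θ_MLE, D) = N · (Σ_i IG(X_i; π(X_i)) − Σ_i H(X_i)),

and the decomposition itself — checked to a residual below 1e-9·N on
random fixtures — is the package's license for using IG as a cheap
structure-scoring surrogate.  BIC (with |B| = Σ_i (K_i−1)·Π_{j∈π(i)} K_j
free parameters as the description length) is provided for completeness
but is *not* the selection score.

Interaction strength `IS(X;S) = IG(X;S) − Σ IG(X;Y_i)` is zero for
singletons, `−log K` for a duplicated K-level parent (pure redundancy)
and `log 2` for an XOR pair (pure synergy); unlike IG it peaks at the
strongest interacting sub-parenthood rather than growing with subset
size, which is what makes it usable for the reduced-structure analysis.

## Evaluation

The predictor under evaluation is always `p(target | Time-1 cells,
message)`.  Accuracy takes the posterior argmax (ties to the lowest
level index, logged).  The multivalued ROC is one one-vs-rest curve per
class, sweeping the acceptance threshold γ over all distinct posterior
values (a record counts as accepted when its class score is ≥ γ); the
scalar ranking score, however, is the Hand–Till multiclass AUC — the
average over unordered class pairs of rank-based separation
probabilities with half-credit ties — computed from pairwise record
comparisons, not from the plotted curves.  Class levels absent from a
fold are skipped with the pair count adjusted and the event logged; a
five-level target easily loses a level in small folds.

Two protocols: *in-sample* (fit once on everything, score every record
from its partial observations) and *leave-one-out* (N single-record-
deleted refits, each scored on its held-out record).  On complete data
with (smoothed) MLE fitting the leave-one-out refits are computed by
decrementing the full-data family counts by the held-out record's
contribution — algebraically identical to refitting and linear instead
of quadratic in N; a test pins the equality against literal refits.
With missing data the literal per-record EM refit is used.  The
selection score is the arithmetic mean of the two mAUCs.

A calibration fact worth knowing when reading scores: for a data-
generating process in which the target is independent of everything,
the *statistic* sits at 0.5 (exactly 0.5 for the literally uniform
model, where every comparison ties), but the in-sample protocol on a
refitted model drifts above 0.5 (fit noise is rewarded) and
leave-one-out drifts below it (the held-out record's own contribution
is subtracted from training).  These are properties of the protocols,
not estimator defects, and they are why the selection score averages
the two.

## Deterministic search

Subset enumeration is lexicographic over sorted variable names with
strict-improvement updates, so equal scores resolve to the
lexicographically first subset; the candidate grid is traversed in
row-major (target size, Time-2 size) order and equal combined scores
resolve to the earlier cell.  The Time-2 expansion worklist processes
the target's Time-2 parents in lexicographic order, then newly
referenced Time-2 nodes in discovery order; candidate parents of a
Time-2 node are Time-1 variables, the intervention, or Time-2 peers
(never the target), and nodes whose inclusion would close a directed
cycle are removed from the pool before enumeration.  A grid cell with
no acyclic parenthood of the required size is marked infeasible and
logged.  The result is byte-identical across reruns; the run manifest
records SHA-256 hashes of config, inputs and every artifact (its
timestamp field sits outside the hashed payload).

The default size range is [2, 8]; tests and desk-scale experiments use
[2, 3], which keeps a full search with leave-one-out selection at
n = 5000 around one second.

## Synthetic ground truth

Planted models give every child's CPT the mixture
`(1−s)·uniform + s·peak(u)`, where the peak level is a seeded random
function of the parent configuration `u` and `s` is a single
dependence-strength knob (0 = independence, 1 = deterministic).  Roots
are uniform.  Three stock configurations:

* a **17-variable study-shaped model** (ten Time-1 indexes, the
  four-frame message, five Time-2 variables of which two mediate, a
  five-level target) for structure-recovery experiments.  Both
  mediators carry three parents, as does the target, so a search over
  sizes [2, 3] can recover every planted parenthood exactly — the
  search's common-size constraint on Time-2 parenthoods makes mixed
  mediator sizes unrecoverable *by construction*, so planting them
  equal-sized is the only fair recovery condition.  Strength 0.9; at
  n = 5000 the full search recovers all planted sets in 10/10 seeds.
* a **compact 6-variable model** (max 12 parent configurations per
  family) for parameter-recovery experiments.  At n = 5000 every CPT
  cell rests on hundreds of observations, so estimation error isolates
  the estimator; on the 17-variable model the unmasked MLE itself has
  ~0.05 max cell error at that n, which would mask what EM does.
* a **full study-roster model** mirroring the questionnaire (ten Time-1
  indexes + age/sex/education, message, six Time-2 perceptions,
  target) for CLI demos and pipeline runs at n = 272.

The continuous emitter writes each tertile level into a disjoint
interval of the 1–7 scale, encodes the target as an intention
difference in [−1.47, 1.47] via `intention_t2 = intention_t1 + change`
(the Time-1 intention value is drawn inside its own level bin
intersected with the interval that keeps both columns in range), and
defines its reference categorical dataset as the quantile binning of
the noiseless values.  That last point matters: empirical quantile
refitting pins ~p·n records below each breakpoint regardless of the
latent level counts, so *no* emitter can make refitted bins reproduce
arbitrary sampled levels exactly; defining the reference through the
same binning makes the noiseless round trip exact by construction while
changing at most a few boundary-rank cells of the planted dependence.
Gaussian noise (default SD 0.25, small against the bin width of 2) is
added after the reference is fixed; at n = 1000 about 93–94% of cells
survive re-discretization, which is what the ≥ 90% recovery check
asserts.

What the synthetic experiments do **not** show: real questionnaire data
have correlated measurement error, ordinal (not interval) scale
behaviour, non-MCAR missingness and effect sizes far below strength
0.9.  Passing recovery tests establishes the *procedure's* correctness
and determinism, not that a real study of n ≈ 272 yields a stable
structure — on realistic signal strengths the out-of-sample mAUC
visibly lags the in-sample value, exactly as the demo run shows.

## Known limitations

* Leave-one-out with missing data performs N literal EM refits; fine at
  fixture scale, slow for large studies (the complete-data fast path
  does not apply).
* Interaction-strength profiling enumerates all parent sub-combinations
  and is exponential in the parenthood size (57 subsets at six parents;
  acceptable throughout the intended range).
* The strongest-interacting-subset reduction requires the target to
  keep at least one parent; a profile that empties the target's
  parenthood is rejected rather than repaired.
* mAUC is undefined when only one target level occurs; evaluation
  raises rather than returning a placeholder.
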