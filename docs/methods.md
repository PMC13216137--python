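# Methods

## The measurement problem

Best–worst scaling asks a rater to mark the best and worst of a small menu
of alternatives. For lexical norming at scale, menus of m = 6 words and
multiword expressions are shown, and the judgment of interest is *expected
utility*: which items are most and least useful to know. Each judgment
implies 2m − 3 = 9 pairwise preferences — the chosen best beats the other
five, and the four unchosen middles beat the chosen worst; middle-vs-middle
pairs carry no information and are not extracted. Scoring converts the
pooled preference stream into one continuous scale over the pool.

## Design generation

### Contract

For N items, k presentations per item and sets of m, the design holds
exactly N·k/m sets in which

* every item appears exactly k times,
* no unordered pair of items occurs in more than one set (globally, across
  batches), hence every item is compared against exactly k(m − 1) distinct
  others,
* the sets partition into b batches with exactly k/b appearances per item
  per batch, so each batch is a complete parallel measurement.

A necessary bound is N − 1 ≥ k(m − 1): an item cannot have more distinct
comparators than there are other items. This bound is enforced as a
precondition. It is not sufficient: when k/b = 1 each batch is a partition
of the pool, and any set can take at most one item from each earlier set,
which makes N ≥ m² necessary from the second batch on. Rather than encode
every structural corner case, requests beyond the constructor's reach
surface as a capped-restart error.

### Algorithm

Construction is randomized in two phases per batch. *Greedy seeding* fills
sets item-by-item, always preferring the items with the most remaining
appearance quota (random tie-break) and skipping candidates that would
repeat a used pair; when no conflict-free candidate exists the best
conflicting one is taken anyway. *Min-conflicts repair* then swaps item
tokens between sets — which preserves all appearance counts exactly —
until no pair is repeated: each move picks a currently conflicted pair,
evaluates eight candidate swap partners, applies the best when it does not
increase the conflict count, and occasionally (p = 0.02) accepts an uphill
move to escape plateaus. A batch whose repair stagnates is rebuilt from a
fresh substream; repeated failure escalates to rebuilding all batches
(earlier batches can freeze an unworkable pair structure), with 100 total
restarts before giving up. Everything derives from one seed, so identical
spec + seed gives byte-identical output.

At the study's density (N in the thousands, 90 comparators per item) the
seeding phase is already nearly conflict-free and construction takes
seconds; the repair phase is what makes dense small designs (e.g. N = 60,
k = 6, m = 6) solvable at all.

### Catch trials and lists

Catch trials are m-item sets with a designated best (drawn from the
highest-prevalence items) and a designated worst whose prevalence is below
1% — an item almost nobody knows. The same catch sets are reused in every
list, at seeded-random trial positions; within-trial display order is a
seeded shuffle. Real sets are partitioned into lists of 45 drawn from a
single batch; the per-batch set count must divide evenly (the constructor
suggests the nearest feasible list size otherwise) — deliberately stricter
than the original megastudy, which padded three extra lists to cover a
non-divisible remainder.

## Rater simulation

Raters follow a Thurstonian (random-utility) model: on each trial the
perceived value of item i is u_i + ε_i with ε_i ~ Gumbel(0, τ), one shared
draw per trial; best is the argmax and worst the argmin of the same draw
(the simplest joint maxdiff model). With m = 2 this yields the logistic
closed form P(i best) = σ((u_i − u_j)/τ), which the tests use as an
independent oracle. Defaults: τ = 1 and standard-normal true utilities —
a unit latent scale on which τ = 1 reproduces the inter-batch reliability
actually observed in human data of this kind (r in the mid-.5s to low-.6s
per 6-observation batch).

Two deviations from the ideal rater are modeled because the pipeline's
quality control targets them:

* **Limited knowledge.** Each rater independently knows item i with
  probability equal to its prevalence. Unknown items are forced below all
  known items (ties among several unknowns broken uniformly),
  implementing the instruction to mark unknown words least useful. If the
  entire menu is unknown the trial is a uniform guess.
* **Carelessness.** With the configured probability a rater answers every
  trial uniformly at random without replacement — the worst case for
  catch-trial detection.

Per-participant RNG streams are spawned from one master seed, so the
response table is reproducible regardless of execution order.

## Quality control

Per catch trial, the best slot scores 3 if the designated worst was chosen,
1 for any middle alternative, 0 for the designated best; the worst slot is
symmetric; the trial penalty is the sum. Exhaustively over all 30 ordered
choice pairs the reachable per-trial penalties are {0, 1, 2, 4, 6}: an
isolated 3 (or 5) is impossible because a 3 in one slot occupies a
designated item the other slot would need for its 0 (or 3). Penalties sum
over the five catch trials; totals strictly greater than 5 exclude the
participant. A missing catch trial marks the participant unscorable (and
excluded) rather than silently passing. By default catch-trial responses
are dropped from the scoring stream — they are probes with deliberately
extreme items — with an `include_catch` flag to score the full pool
instead.

## Scoring

**Value Learning** initializes every value at 0.5 and streams over the
preference pairs: for (winner w, loser l), p = σ(v_w − v_l) and both move
by α(1 − p), winner up, loser down. The stream is reshuffled each epoch
from a seeded generator; defaults are α₀ = 0.1 with harmonic decay
α_e = α₀/(1 + e) over 50 epochs. Final values are min–max rescaled to
[0, 1]. A raw spread below ten times the final epoch's step size is
sequential-update residue rather than signal (perfectly symmetric data
never converge to exactly equal values in finite time), so such scales are
emitted as a flat 0.5 instead of having noise amplified across the unit
interval. Items with no observations get a missing score, never a
fabricated one.

**Bradley–Terry MLE** (P(i beats j) = s_i/(s_i + s_j), Hunter's MM
iteration, pseudo-win regularization 0.1 on every compared pair to keep
the comparison graph effectively connected) is deliberately a separate
code path used to cross-validate Value-Learning rankings; on simulated
studies the two agree at Spearman ≈ 0.9998. A counting baseline,
(#best − #worst)/appearances min–max rescaled, is also provided.

Batch scales are fitted independently per batch (6 observations/item) and
pooled (18); per-batch scales are rescaled independently, which is
harmless because batches are only ever compared by correlation.

## Reliability

Standardized Cronbach's alpha is computed from the batch correlation
matrix, α = k·r̄/(1 + (k − 1)·r̄) with r̄ the mean off-diagonal Pearson
correlation (Spearman matrices are reported alongside; Pearson is
primary). The closed form is identical to the variance-decomposition alpha
on z-scored batch scales, and the test suite holds the two routes to
within 10⁻¹². At three batches correlating at .57 the form gives
α = 0.799 ≈ .80. Items missing from any batch are dropped listwise.

## Synthetic covariates and what they stand for

`synthesize_predictor_table` draws multivariate-Gaussian lexical
covariates with a correlation structure emulating real norm databases — a
frequency/familiarity/prevalence cluster opposed by age of acquisition,
plus weakly coupled concreteness/valence/arousal — and a planted linear
utility (positive frequency, negative AoA and concreteness effects,
Gaussian noise). Prevalence is mapped through a probit so that nearly all
items are known to ≥ 90% of raters, as befits a familiarity-pruned pool,
with a thin less-known tail. Simulated catch trials additionally plant
deliberately obscure probe items (prevalence 0.3%) and lift the designated
bests' utilities clear of the pool, mirroring how real catch items are
chosen to have obvious answers.

What passing tests on this generator do **not** show: real covariate
distributions are skewed and heavy-tailed, not Gaussian; real utility
almost certainly relates to predictors nonlinearly (the generator is
linear by construction); and human careless responding is more varied than
the uniform-random model. Empirical quantities that depend on the human
response data or the external norm databases (observed utility values,
regression R² on real predictors, US/UK prevalence contrasts) are out of
reach by design; the package reproduces the report *shapes* (norms file,
clustered matrices, 20-row residual-extreme tables with Word / Utility /
Predicted Utility columns) so real data can be dropped in.

## Problem sizes and numerical choices

* Analysis drivers: N = 1,800 items, 120 lists; every script finishes in
  seconds. Recovery evaluations: N = 1,000 items at the full 18-observation
  schedule; design validity checks: N = 3,000 with exhaustive pair
  enumeration. The full-scale arithmetic (82,880 items → 248,640 sets) is
  validated by formula rather than materialization.
* At the unit-scale/τ = 1 operating point the information in 18
  observations per item bounds recovery near Spearman ≈ 0.9 — the
  Bradley–Terry MLE lands on the same value as Value Learning, and
  Spearman–Brown applied to the observed batch correlations predicts the
  same ceiling. Claims of near-perfect recovery at this schedule
  correspond to a quieter noise regime (smaller τ relative to the latent
  spread), where both estimators do reach ≥ 0.95. Recovery is monotone in
  observations per item (6 < 12 < 18) throughout.
* OLS uses statsmodels; rank-deficient design matrices are rejected with
  the most collinear column pair named. Part-of-speech enters as treatment
  contrasts with the most frequent category as reference.
* Hierarchical clustering of correlation matrices: average linkage on the
  distance 1 − r (Pearson), order by scipy's leaf list; constant columns
  are dropped with a warning.
* Serialized ids and batch labels are 1-based throughout; all tables are
  UTF-8 TSV.

## Known limitations

* The tuple-design constructor is stochastic search, not a combinatorial
  existence proof: near the feasibility boundary it may fail on designs
  that exist (and the error says so) — acceptable because norming studies
  operate far from the boundary.
* Value-Learning hyperparameters (α₀, decay, epochs) are package defaults
  validated by recovery and oracle agreement, not a claim about any
  particular prior software's settings.
* Random-forest variable importance from the original analysis toolchain
  is replaced by a generic, model-agnostic permutation importance over the
  OLS fit, which is not numerically comparable. Restricted-cubic-spline
  checks are omitted; regressions are linear.
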