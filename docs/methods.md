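# Methods

## The model

Each milestone item is treated as an independent binary outcome whose success
probability rises with age. For a child of age *x* days,

P(Y = 1 | x) = 1 / (1 + exp(−(α + βx))),  β > 0,

so −α/β is the age at 50% pass probability (the item's location) and 1/β
scales the width of the mastery window. Ages enter in raw days, uncentred:
α is then the logit of the pass probability at birth, and estimates remain
directly comparable with analyses that use the same parameterization. Each
item is fitted separately by maximum likelihood (Newton iteration, gradient
tolerance 1e−8, at most 100 iterations). This is a per-item regression, not
a joint IRT model: no latent ability dimension is estimated, and the only
"ability" proxy is age itself — appropriate for norming, where the question
is "at what age do children typically pass this item", not "how able is this
child".

Inverting the fitted curve gives the age at any pass probability p:
age(p) = (logit(p) − α̂)/β̂. The package computes p = .25, .50, .75, .90.
By logit symmetry the .25→.50 and .50→.75 intervals are always equal. The
P90 age is the sort key for the data-driven item order, and the norm bands
(.25–.50, .50–.75, .75–.90) are the plotted age references.

Model fit per item is a likelihood-ratio test of the age model against the
intercept-only model (χ², 1 df); a Wald p-value on β̂ is reported alongside
because a published "good fit, p < .05" could be either statistic. Items
with no response variation (degenerate) or with complete separation (no
finite MLE; detected via the optimizer's separation error or estimates
exceeding |β̂| > 5 logit/day or |α̂| > 500) are flagged and retained, never
dropped: downstream stages treat them as invalid, and reordering freezes
them at their original positions rather than sorting them on meaningless
estimates.

## Adaptive administration and imputation

The administration model mirrors screeners in the MDAT family:

- **Start rule.** Begin at the largest item index whose norm age
  (age-at-P90 by default; configurable) does not exceed the child's age;
  item 1 if none qualifies. In simulation the generator's true parameters
  play the role of the prior norms the instrument ships with.
- **Basal (backward) rule.** Present the start item, then walk downward
  until three *consecutive* passes are observed or item 1 has been
  presented. The start item's own outcome counts toward the run. The
  consecutive reading mirrors the explicitly consecutive ceiling rule; a
  cumulative variant (three passes in total during the backward walk) is
  available as `backward_rule="cumulative"`.
- **Ceiling (forward) rule.** Resume at start+1 and walk upward until three
  consecutive misses or the last item. Misses seen during the backward walk
  do not count toward the ceiling run.
- **Imputation.** Items below the lowest presented index are scored 1 only
  when a basal was established; items above the highest presented index are
  scored 0 only when a ceiling was established. When the walk reaches the
  subscale floor without a basal (or the top without a ceiling) there is
  nothing unobserved on that side, so the guard is exact.

On a perfectly difficulty-ordered (Guttman) response vector this scoring is
lossless: the imputed total equals the true total for every start index
(verified exhaustively for k ≤ 12). On stochastic responses the imputation
is biased in a known direction — imputed passes below the basal overstate,
and imputed fails above the ceiling understate, the tails of each item's
curve — which slightly compresses recovered thresholds toward the start
region. Calibrating on imputation-completed vectors is also mildly circular
(the imputations presuppose the item order under validation), so an
observed-cells-only calibration mode exists (`use_imputed=False`); on
synthetic data the two modes' P50 ages correlate above 0.95.

## Synthetic cohorts

The generator is a recovery testbed with the validation study's shape:
948 children by default, ages uniform over [60, 1825] days (the service
population effectively excludes younger infants, which is also why the
0–2-month group is nearly empty), 45.1% girls, CAIPI:CAFI service split
36:64, 40 evaluators assigned round-robin, and the 133-item four-subscale
bank. Responses are independent Bernoulli draws from the logistic model at
the child's age.

True item parameters per domain: P50 ages on an even grid spanning
[30, 1400] days, slopes log-uniform in [0.005, 0.05] logit/day assigned in
decreasing order along the subscale. Three properties motivate this
construction:

- even P50 spacing keeps adjacent items separated by a constant margin, so
  ordering-recovery results measure estimation quality, not whether the
  truth was identifiable at all;
- decreasing slopes reproduce the robust empirical pattern that mastery
  windows widen with age, and make age-at-p monotone in the item index for
  *every* p — the subscale is ascending in difficulty under any probability
  criterion, so the generating order is the unambiguous target of the
  reordering stage;
- the grid's upper end puts the hardest item's P90 age near the 60-month
  instrument ceiling (1400 + logit(.9)/β at the shallowest typical slope
  ≈ 1815 days), so the oldest age group scores near-ceiling on every
  subscale, as real validation cohorts do on instruments that cover their
  age range.

All randomness flows from one integer seed through named substreams
(parameters / cohort / responses), so each component can be varied
independently and every fixture is reproducible.

What the generator does **not** emulate: covariate effects on item success
(sex, service, socioeconomic position — the analysis conditions on age
only), local dependence between items, informant-report measurement error,
and evaluator effects (evaluator labels are pure noise, which is exactly
what the homogeneity ANOVA should conclude). Passing recovery tests
therefore demonstrates that the pipeline's estimates are faithful when the
model holds; they say nothing about model misfit in real cohorts.

At the study scale the recovery run gives a median absolute error of the
P90 age around 15 days and reproduces the generating item order for ~95% of
items; the residual discordance is concentrated in adjacent pairs whose true
P90 gap (~45–75 days) is within sampling noise of the threshold estimates
at n = 948.

## Reliability and descriptives

Cronbach's α uses the standard ratio of summed item variances to total-score
variance (ddof = 1 throughout; the coefficient is invariant to the shared
denominator convention). Split-half reliability scores two half-tests by
summation and reports both the raw half-score correlation and its
Spearman–Brown correction 2r/(1+r); the default split is odd–even item
positions, with first–last and seeded random splits available, since
published split-half values rarely state the scheme and the choice matters.

Age groups are the study's 14 month-bins partitioning 0–60 months. Days
convert to months at 30.4375 d/month (365.25/12); bins are
left-closed/right-open with the last bin closed at 60. Group descriptives
use the n−1 SD; groups under 5 children are flagged unreliable rather than
dropped, mirroring how validation reports footnote under-sampled cells, and
monotonicity-of-means checks consider only reliable groups.

The evaluator-homogeneity check runs a one-way between-evaluator ANOVA on
subscale totals within each (age group × domain) cell, using evaluators with
at least two children in the cell; cells with fewer than two such evaluators
are flagged insufficient. Under the null of no evaluator effect the test's
rejection rate at .05 is calibrated (≈5% over 1,000 simulated cells), as is
the likelihood-ratio fit test under age-independent responses.

## Numerical and design choices

- **Reordering tie-break:** ascending P90 age, then P50 age, then original
  index; the sort is stable, so an already-correct order is never perturbed.
- **Degenerate inputs:** all-0/all-1 items raise a distinct error from the
  single-item API and are recorded as flagged calibrations by the batch API;
  zero-variance matrices raise from the reliability coefficients.
- **Pipeline determinism:** a run is a pure function of (config, seed); the
  manifest records SHA-256 checksums of every artifact, and repeated runs
  are byte-identical.
- **Problem sizes:** tests exercise the full 948 × 133 study scale (a run
  takes seconds); null calibrations use 1,000 replicates, Monte-Carlo curve
  checks 5,000 draws per point.

## Known limitations

- Per-item calibration ignores the multivariate structure of the response
  vector; items are conditionally independent given age by assumption.
- The imputation-completed default inherits the circularity noted above;
  results for items far from the typical start region lean on imputed cells.
- Thresholds beyond the sampled age range (possible for very shallow items)
  are extrapolations with inflated variance.
- No developmental-delay cut-offs are produced; the package norms items, it
  does not classify children.
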