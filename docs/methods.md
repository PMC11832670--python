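# Methods

This note documents the statistical procedures implemented in `vocat`, the
defaults they ship with, and the design choices made where more than one
defensible option existed.

## Measurement model and calibration

Responses are dichotomous (1 = endorsed). The Rasch model gives person *p*
probability `expit(θ_p − α_i)` of endorsing item *i*; the 2PL multiplies the
kernel by an item slope `a_i`. Item parameters are estimated by marginal
maximum likelihood (MML): the latent ability is integrated against a
standard normal with Gauss–Hermite quadrature (61 nodes by default) and the
marginal likelihood is maximised by L-BFGS-B with analytic gradients.

Identification deserves a note. On the quadrature scale the latent is
N(0, 1). For the 2PL that, together with the free slopes, fixes the scale.
For the Rasch model, fixing *both* the latent variance and all slopes to 1
would over-constrain the model: genuinely Rasch data whose ability spread is
not 1 would then masquerade as "2PL-preferred". The Rasch fit therefore
estimates one **common slope** `s` — exactly equivalent to a free latent
variance `s²` — and the public item bank is reported in the Rasch metric:
unit slopes, difficulties `s·α` and abilities `s·z`, which leaves every
response probability unchanged and puts difficulties on the data's own logit
scale. Internal computations (ability posteriors, fit statistics, predictive
densities) use the quadrature-scale parameters.

Further choices:

* Convergence: projected-gradient infinity norm below 1e-6 on the
  per-person mean log-likelihood scale; non-convergence is flagged on the
  result and warned, never silent.
* Slopes are box-constrained to [0.05, 10]; a pinned slope triggers a
  warning and does not spoil the convergence check (the projected gradient
  is used).
* Constant (all-0/all-1) item columns carry no information about a finite
  difficulty; they are excluded before fitting and reported.
* Standard errors come from the outer-product-of-gradients (OPG) estimate of
  the information; Rasch difficulty SEs use the delta method through the
  `s·α` rescaling.
* Person abilities after calibration are EAP posterior means with posterior
  SDs.

Ability estimation during adaptive testing is one-dimensional maximum
likelihood (bounded line search on [−10, 10], bracket tolerance 1e-9
logits). A uniform response pattern has no finite maximiser; the
conventional values −10 (all "no") / +10 (all "yes") are returned and
marked as such. The ability SE is `1/sqrt(Σ a_i² P_i(1−P_i))` — for the
Rasch banks the CAT uses, exactly the textbook `1/sqrt(Σ P_i(1−P_i))`.

## Item-fit statistics

Outfit is the mean squared standardised residual, Infit its
information-weighted counterpart; both have expectation ≈ 1 under the
model. Abilities are latent, and plugging point estimates (EAP or ML) into
the residuals deflates both statistics measurably (mean Outfit ≈ 0.90–0.94
under the true model at n = 1000 × 30 items). The implementation therefore
averages the residual terms over each person's **ability posterior** given
the calibrated item parameters, which restores the centring at 1; the
plug-in form remains available as `point_estimate_mean_squares` for
comparison. The screening band defaults to [0.7, 1.3], boundary values
retained.

The modification index is a score (Lagrange-multiplier) test for freeing
one item's slope from the common Rasch value, evaluated at the Rasch
estimates with OPG information and a Schur-complement adjustment for the
jointly estimated difficulties and common slope. It is asymptotically a
1-df chi-square and tracks the likelihood-ratio refit almost perfectly
(r > 0.99 in the test suite) at a fraction of the cost.

## Pool selection

The selection objective combines four components with fixed weights and a
negative sign: spacing (sample SD of adjacent sorted-difficulty gaps,
weight 1/3), Infit (weight 4), Outfit (weight 2) and modification index
(weight 1/100). By default the fit components enter as mean absolute
deviations from their ideal value 1 (and the MI as a plain mean), so a
perfectly fitting, evenly spaced subset scores exactly 0 and every other
subset scores below it; a literal raw-sum aggregation is available behind
`SelectionWeights(aggregation="raw_sum")`. The deviation form was chosen
because raw sums penalise items with Infit *below* 1 in the wrong direction
and scale with subset size.

Subset search is Metropolis simulated annealing: swap 1–3 items per
proposal, accept improvements always and deteriorations with probability
`exp(Δ/T)`, cool geometrically (defaults: T from 1.0 to 1e-3, factor 0.95,
200 proposals per temperature), track and return the best subset ever
visited. A majority-vote wrapper re-runs the search (default 20 restarts)
and keeps the items returned most often, ties broken by objective then item
id. Fit statistics are computed once on the filtered pool and reused across
subsets; refitting per candidate subset would be circular inside the search.

## Rasch-vs-2PL comparison

Pool size is chosen by predictive equivalence: person-level k-fold
cross-validation (default 5 folds), each fold refitting both models and
scoring held-out persons by the log predictive density of their whole
response vector with ability integrated out. The decision statistic is the
summed pointwise difference plus a first-order complexity correction
`(p_2PL − p_Rasch)/2 · k/(k−1)`: a model fitted by maximum likelihood
scores about p/2 log-density units below its own expected log predictive
density out of sample (the test-side half of the AIC optimism), so without
the correction the raw difference is biased against the richer model by
that amount even when the two models are predictively identical — data
generated exactly from the Rasch model would be classified as *favouring*
Rasch rather than as equivalent, which is not what an equivalence rule
should report. Bayesian cross-validation with posterior-integrated
predictives does not carry this asymmetry, and the corrected statistic
reproduces its behaviour: under the null the difference centres at 0 and
the 2×SE rule returns "equivalent"; under strongly 2PL data the difference
is two orders of magnitude larger than the correction. (A
Laplace-approximate posterior predictive was evaluated as an alternative
and changes nothing to first order, as theory predicts.)

The standard error is `sqrt(n · var(pointwise diffs))` and models are
called equivalent while |ΔELPD| ≤ 2·SE.

## DIF screening

Each group is calibrated separately; scales are equated by matching mean
difficulty over the shared items; an item is flagged when the two groups'
95% Wald intervals do not overlap. Non-overlap of two 95% intervals is a
conservative criterion, so the null flag rate sits well below the nominal
5% (≈ 0–3% in the test suite), while a 1.5-logit shift at n ≈ 500 per group
is detected reliably.

## Reliability

KR-20 is the classical internal-consistency formula with sample (n−1)
variance of total scores. Person-separation ("Andrich") reliability is
`(Var(θ̂) − mean(se²)) / Var(θ̂)`, floored at 0, computed from EAP abilities
and their posterior SDs; persons with divergent (convention-valued)
estimates are excluded, as their pseudo-values would corrupt the observed
variance.

## Adaptive engine

Item selection is nearest-difficulty, which coincides with maximum Fisher
information for Rasch banks; ties go to the lower difficulty, then the
smaller item id, so sessions are fully deterministic given a response
script. The SE stopping rule is evaluated only once the response pattern is
mixed (the ML estimate is finite); convention-valued abilities never
terminate a session. A `max_items` budget (default: pool size) guarantees
termination on pathological banks. The transcript records each administered
item (id, word, difficulty), the responses, the ability/SE trajectory and
the stop reason, and is sufficient to re-derive the final ability exactly.

## Synthetic-data generator

The generator emulates the structure of a large caregiver-report
calibration study and is the test bed for everything above. Defaults: 379
items (197 nouns, 92 verbs, 90 adjectives) whose difficulties increase
strictly with a simulated age-of-acquisition grade, mapped affinely onto
[−4, 4] logits; 1190 respondents with ages uniform on [3, 8] years;
abilities `θ = −5.5 + 1.0·age + N(0, 1)` (centred near 0 at age 5.5, total
SD ≈ 1.8 — the common-slope Rasch fit recovers exactly this spread); a
random binary group label for DIF experiments. `misfit_fraction` (default
0.25, reflecting that roughly two-fifths of a raw word pool typically fails
the fit screen) assigns alternating slopes 0 (ability-independent noise)
and 3 (over-discriminating) to a random subset of items; `dif_items`
injects per-group difficulty shifts. All randomness flows from a single
seed and equal configurations are bit-identical.

What the generator does *not* emulate: real lexical content, caregiver
response styles (acquiescence, skipping), local dependence between
semantically related words, and non-uniform age sampling. Passing tests
therefore demonstrate that the machinery is correct under the model, not
that any particular real dataset fits the model.

## Problem sizes and numerical conventions

The test suite and the acceptance script run at desk scale, chosen so each
check is statistically decisive yet the whole suite completes in about a
minute: parameter recovery at n = 2000 × 40 items, fit-statistic
calibration and model comparison at n = 1000 × 30 (20 replicates for rate
estimates), DIF at n = 1000 split into two groups, adaptive simulations on
an 89-item bank spanning [−3, 3] with ≥ 100 sessions. Probabilities are
clamped to [1e-10, 1−1e-10] wherever a residual is standardised; floats are
serialised with 6 decimals; every writer is deterministic given its inputs.

## Known limitations

* Point estimation only: no posterior distributions or credible intervals
  beyond Wald/delta-method SEs.
* The OPG information can understate uncertainty at small n.
* Dichotomous, unidimensional models only; no polytomous or multidimensional
  extensions, no person-fit statistics.
* DIF equating is a mean shift; a genuine group difference in latent
  variance would leak into the per-item comparison.
* The complexity correction in the model comparison is first-order; at very
  small n or with many slope estimates pinned at bounds it is approximate.
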