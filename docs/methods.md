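# Methods

`ralisim` is a simulation laboratory for a specific, practically common
measurement problem: tracking growth of a latent competence over four
assessment waves when each wave uses a short (25-item) Rasch-scaled test form
and adjacent forms overlap only in a small set of common ("anchor") items.
This note documents the models, algorithms, numerical choices and known
limitations; everything quantitative it mentions is computed by the test
suite or by `scripts/acceptance.py`.

## Response model and data generation

Responses are dichotomous. The generating model is the 2PL,

    P(X_ni = 1 | beta_n, delta_i, alpha_i) = logistic(alpha_i (beta_n - delta_i)),

with person ability `beta`, item difficulty `delta` and item discrimination
`alpha`, all on the logit scale. The *fitted* model is always the Rasch
model (`alpha_i = 1`), so generating with `alpha_i != 1` creates
model-data misfit of a controlled degree.

The default study design emulates a longitudinal educational panel:

- four test forms of 25 items at waves t1-t4;
- abilities drawn i.i.d. normal per wave with means 0.0, 0.7, 1.2, 1.5
  logits (decelerating growth of 0.7/0.5/0.3) and unit variances;
- unique items of wave t drawn from N(mean_t, 1), so targeting is good at
  every wave;
- each adjacent pair of forms shares a block of nine candidate anchor
  items whose difficulties are drawn from a normal centred at the midpoint
  of the two adjacent ability means (unit variance), because an anchor must
  serve both distributions; anchors reuse one parameter draw in both forms
  (measurement invariance);
- form composition: end forms hold 9 anchor slots + 16 unique items,
  interior forms 9 + 9 + 7 (the only arrangement consistent with 25-item
  forms and nine candidate anchors per pair);
- anchor-count conditions use 3, 5, 7 or 9 of the block's slots at fixed
  positions; the unselected slots are still administered but relabelled as
  form-unique items, keeping form length and targeting constant so only the
  amount of linking information varies;
- difficulties are independent univariate normal draws (no covariance
  structure among items is modelled).

**Balanced misfit.** Under the misfit condition, discriminations are drawn
from N(1, 0.14^2) — a moderate, operationally realistic dispersion — and
each draw group (an anchor block, or a form's unique-item set) is
standardized to mean exactly 1 and SD exactly `alpha_sd`. Every form
therefore has mean discrimination exactly 1: misfit distorts item-level
measurement but never makes one wave's form systematically more or less
discriminating than another's. Without this balance the latent-variance
estimate inherits form-level mean-discrimination noise of roughly
`2 * 0.14 / sqrt(25) ~ 5.6%` per replication (or, with a single fixed bank,
a bias of that typical size), which would dominate the variance outcomes and
confound the anchor-count and method factors the study isolates. Draws are
truncated below at 0.05 as a 2PL-validity guard (a ~1e-12 event).

**Bank realization.** By default a fresh item bank is drawn for every
replication, so outcome summaries average over the item-sampling
distribution as well as over persons. `StudyConfig(bank_per_replication=False)`
instead realizes one bank per master seed and reuses it for every condition
and replication — the design of an operational study with a single printed
item-parameter table — sharing difficulties between the misfit arms
(discriminations reset to 1 when misfit is off). Results under a single
bank are conditional on that realization; per-replication redraw is the
default because it makes summaries reproducible in distribution rather than
hostage to one draw.

Randomness uses one master seed with named, order-insensitive substreams per
(purpose, condition, replication), so any record is bit-reproducible in
isolation and results do not depend on execution order or worker count.

## Estimation: marginal maximum likelihood by EM

All calibrations maximize the marginal likelihood of the Rasch model with a
normal latent distribution, approximated on quadrature nodes (Bock-Aitkin).
For the Rasch model the posterior over nodes depends on a person's data only
through the raw sum score, so the E-step collapses the N persons into at
most I+1 score groups — the main reason a full study runs in minutes.

- **E-step:** posterior node weights per score group under the current
  parameters; expected per-node person counts and per-item correct counts.
- **M-step (items):** each free difficulty solves its expected-count
  equation `sum_q f_q P_iq = T_i` by damped Newton iteration to 1e-11
  (steps clipped at ±2 for safety far from the solution), making the step
  an exact conditional maximizer rather than a single Newton update.
- **M-step (latent):** the normal's parameters update from posterior
  moments; nodes are rescaled to the new (mu, sigma) each cycle.

Calibration modes:

- `free` — one form; `mu` fixed at 0 for identification, `sigma^2`
  estimated, all difficulties free.
- `fixed_anchor` — one form; listed items held exactly at supplied values
  while `mu`, `sigma^2` and the remaining difficulties are estimated
  (fixed parameter calibration).
- `concurrent` — all forms jointly; difficulties shared across forms via
  common item ids, one latent normal per wave with `mu_1 = 0`.

Quadrature defaults: 41 rescaled Gauss-Hermite nodes for single-form
calibrations; 1,000 equal-weight quasi-Monte-Carlo nodes (Halton sequence
through the normal inverse CDF, the u=0 point dropped) for the concurrent
estimator, whose per-wave node sets share one low-discrepancy base set.
Both are configurable; 41 GH nodes integrate the relevant integrands to
well below the Monte-Carlo noise floor.

Convergence is declared when the largest absolute parameter change falls
below 1e-4 *and* the relative log-likelihood change below 1e-6, with a
1,000-iteration cap. Non-convergence is a recorded outcome
(`converged=False`, finite log-likelihood reported), never an exception,
because convergence rates are an outcome of the study. Zero-variance items
(all-correct or all-wrong columns) are excluded with a warning before
estimation. The marginal log-likelihood is exposed as
`marginal_loglik(...)` so the EM optimum can be audited against generic
numerical optimizers; the test suite does exactly that on tiny instances.

Degenerate cases worth knowing about: with very few items the profile
likelihood in `sigma^2` can peak at the boundary 0 (a weakly associated
2-item sample), where EM approaches the optimum arbitrarily slowly; the
variance is floored at 1e-6 and such fits simply exhaust `max_iter`.

**Standard errors.** Item-difficulty SEs come from the cross-product
(outer product of per-person scores) approximation to the expected Fisher
information of the marginal likelihood at the solution, inverting the
free-difficulty block. SEs exist to serve as weights in weighted mean/mean
linking and as diagnostics; latent-parameter cross-terms are ignored in the
block inverse, which is the standard cheap choice and does not affect the
weighting's scale-invariance. Fixed items report SE 0; a singular
information matrix yields NaN SEs with a warning.

## Linking

Rasch-compatible links are pure translations, so one additive constant per
adjacent form pair carries all linking information; t1 defines the
reference scale and constants accumulate along the chain t2->t1, t3->t2,
t4->t3 (adjacent pairs share different anchor sets, so direct linking of
distant waves is not available by design).

- **mean/mean:** `v = mean(delta_B,anchors) - mean(delta_A,anchors)`; after
  applying `v` the linked anchor means match exactly (asserted to machine
  precision in the tests).
- **weighted mean/mean:** anchors weighted by inverse squared SEs. Two
  conventions are implemented. `per_side` normalizes each form's weighted
  anchor mean separately. When anchor precision correlates with difficulty
  — which midpoint-targeted anchor blocks *guarantee*, with opposite signs
  on the two sides of a link — the two weighted means shift in opposite
  directions and the constant is systematically attenuated (measured: up to
  -0.3 logits of cumulative growth in this design, a -20% relative bias).
  `pooled_difference` weights each anchor's *difference* by
  `1/(SE_A^2 + SE_B^2)`, which is immune to that attenuation, reduces to
  the per-side form (and to plain mean/mean) under equal SEs, and is the
  convention the study pipeline uses. The per-side form is retained for
  comparison because it is the more literal reading of "weighting each
  side's anchor mean".
- **fixed parameter calibration:** form t is calibrated with its anchors
  fixed at form t-1's already-linked estimates while its latent mean and
  variance are estimated, so the chain is carried by the fixing itself and
  no explicit constant appears.
- **concurrent calibration:** one joint fit; common-scale moments are read
  directly from the per-wave latent normals.

Common-scale moments for the separate methods: the latent mean at wave t is
the accumulated constant (each free calibration's own mean being identified
at 0) and the variance is the wave's own estimate — the unique
translation-consistent choice. Anchor matching is by item id,
order-insensitive.

## Outcome variables and the truth reference

Per condition and wave: bias `mean(tau_hat) - tau`, relative bias
`bias / tau` (undefined and reported NA where `tau = 0`, i.e. the latent
mean at t1), and RMSE `sqrt(mean((tau_hat_k - tau)^2))` with divisor c (no
c-1 correction), so `rmse^2 = bias^2 + var(estimates)` exactly. Relative
bias below 10% is the conventional acceptability bound. Convergence rates
are computed over all replications; parameter summaries use converged fits
only (mirroring how failed calibrations are handled in practice).

Replication records carry **two truth references** and `aggregate()`
selects one:

- `population`: tau is the generating parameter (0.7, 1.2, 1.5; variance 1).
- `sample`: tau is the realized sample's moments on the common scale — the
  mean of wave t's drawn abilities *minus the t1 sample mean* (the link
  chain is anchored at the t1 sample, so its realized mean is the scale
  origin), and the realized sample variance (ddof=1).

The sample reference isolates what linking can actually influence: against
the population reference every estimate additionally carries person-sampling
noise of SD `1/sqrt(N)` per wave (~0.045 at N=500), an irreducible floor no
linking method can pass. Headline summaries and the acceptance script use
the sample reference; both sets of columns are in every output table.

## Study runner

The full grid is 2 (misfit) x 4 (anchor counts) x 2 (N in {500, 3000}) = 16
data conditions, each evaluated by up to four methods on the *same*
generated data (method is a within-sample factor), 100 replications by
default. Within a replication the three separate methods share free
calibrations: mean/mean and weighted mean/mean consume identical fits and
FPC reuses the t1 fit. Per-method failures are recorded, never fatal.
`run_study` persists tidy per-replication estimates, paper-style summary
tables and run metadata, and resumes interrupted runs by skipping completed
(condition, replication) cells. The CLI (`ralisim run / summarize / demo`)
is a thin layer over these functions.

Problem sizes used by the shipped checks: the test suite's shared fixture
runs the 16-condition grid at 40 replications (~1.5 min); the acceptance
script runs it at the full 100 replications (~4 min). Concurrent
calibration is exercised in dedicated tests; the headline outcome pools the
three separate-calibration methods, which is also how the study's summary
statistics are defined (concurrent calibration's convergence behaviour is
implementation-specific, and the package reports its own rate rather than
assuming one).

## What the generator does and does not emulate

It emulates: short forms with good targeting, decelerating mean growth,
invariant anchors placed between adjacent ability distributions, balanced
moderate discrimination misfit, and both small and large samples. It does
not emulate: missing data, differential item functioning in anchors,
memory/practice effects from repeated administration, unbalanced or
systematically drifting misfit, difficulty-discrimination correlations, or
non-normal ability distributions. Passing results therefore speak to
linking behaviour under clean longitudinal conditions, not to robustness
against those complications.

## Known limitations

- The concurrent estimator is a straightforward multi-group Bock-Aitkin EM;
  its convergence behaviour is far more stable than what heavily
  node-limited quasi-Monte-Carlo implementations report, so convergence-rate
  comparisons across software are not meaningful.
- SEs ignore latent-parameter cross-terms; they are adequate as linking
  weights, not as inferential variances for the difficulties.
- The per-side weighted mean/mean variant is biased in this design (see
  above) and is not used by the pipeline; it exists for methodological
  comparison.
- Relative bias is undefined at the reference wave's mean; tables report NA
  there rather than a substitute.
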