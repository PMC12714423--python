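# Methods

This note records the models and procedures the package implements, the
parameter choices that matter, what the synthetic data do and do not
emulate, and the numerical decisions a maintainer would want written down.

## Activity encoding

The encoder reproduces the on-collar "Activity Mode 1" computation stage by
stage. At 128 Hz, each second is averaged into 32 block means of 4
consecutive readings and block means 1, 9, 17 and 25 (1-based) are
retained; at 64 Hz a single reading per second is retained. The retained
readings of each 5-min window are differenced, absolute values averaged,
and the average divided by the quantization unit (0.16 m/s² or 0.016 g),
multiplied by 10, rounded half-away-from-zero, and truncated at 255.

Decisions where the vendor description is silent or ambiguous:

- **Which single reading the 64 Hz collar keeps** is undocumented; the
  package takes the first reading of each second, consistent with the
  128 Hz path retaining the leading block of each stride.
- **The order of scaling and rounding**: the adopted reading is
  `a = round(10·d/u)`; the alternative `round(10·d)·(1/u)` is dimensionally
  inconsistent and rejected.
- **Unit constants**: the vendor equates 0.016 g with 0.16 m/s² (g ≈ 10
  m/s²). Both constants are used literally so the published conversion
  contract is reproduced exactly; `strict_si=True` instead converts g input
  through 9.80665 before quantizing.
- **Rounding** is centralized as half-away-from-zero so banker's rounding
  can never leak in from numpy defaults.
- **Window alignment**: 5-min windows are aligned to the stream start and
  first differences never cross window boundaries, matching per-interval
  storage; whether the collar differences across boundaries is unknown.

## Label construction

Observation bouts are reduced per 5-min activity record to the modal
behavior and its time-coverage fraction ("purity"). A record becomes a
training segment iff the modal behavior is one of the three classifier
states and purity ≥ `min_purity`; `min_purity=1.0` expresses the strict
single-behavior rule and `0.6` the relaxed ≥3-of-5-min rule used where
samples are scarce. "Other" behaviors (grooming, alert, drinking, ...) are
short-duration and never enter training.

GPS travel labeling computes planar step speeds between fixes and marks
every 5-min record *fully contained* between the two fixes of a step at or
above the threshold (default 2.5 km/h, inclusive) as traveling. Strict
containment is deliberately conservative: partially overlapped records are
left unlabeled rather than risking label noise. A 10-min step therefore
labels exactly the two records it spans when the fix and record grids
align. Distances are planar Euclidean on projected coordinates;
longitude/latitude input must be projected upstream.

## Balanced-forest classifier

Trees are CART classification trees (gini impurity, unlimited depth,
minimum node size 1 — the classical forest defaults). The ensemble departs
from the vanilla forest only in its bootstrap: for every tree, an equal
number of segments is drawn *with replacement within each class*, that
number being the size of the smallest class. Sampling with replacement is
the classical balanced bootstrap; the alternative (without replacement for
the minority class) is not offered. With three features, `mtry = ⌊√3⌋ = 1`:
every split considers a single random axis.

1001 trees (odd) prevent tied binary votes; three-way ties remain possible
and are broken toward the first class in the fixed alphabetical order
(foraging, stationary, traveling) so prediction is deterministic.
Out-of-bag error is the misclassification rate of each training segment by
the majority vote of trees whose bootstrap excluded it.

The packaged species-tagged models are trained at first use on seeded
synthetic reference data and tagged `synthetic:<species>`; they demonstrate
the prediction workflow and are not field-calibrated. Models persist as a
self-describing joblib archive carrying a format version, class order and
training summary; loading rejects corrupt files and format mismatches.

## Evaluation

Cross-validation leaves out one whole animal per fold, so within-individual
correlation cannot inflate the estimates. Folds whose training split loses
a class are skipped with a warning rather than imputed. Per-animal metrics
are aggregated as means and medians over animals with ≥ `n_min` (default
30) held-out segments; the filter applies to both aggregates by default and
is togglable for the median. Pooled metrics are computed on the
concatenated held-out predictions, so pooled accuracy equals the
segment-weighted mean of per-animal accuracies. The training-vs-testing
accuracy gap of the full-data model is reported as an overfitting check.

The multiclass AUC follows the pairwise construction: for each class pair
(i, j), `Â(i|j)` is the probability (ties ½) that a random class-i item
outranks a random class-j item on the class-i score, `Â(i,j)` the average
of `Â(i|j)` and `Â(j|i)`, and `M` the mean over pairs. Scores are the
forest's vote fractions — the natural score the forest provides. Because
pooled-versus-per-animal averaging of the AUC is a genuine choice, both are
emitted, labeled `auc_pooled_scores` and `auc_mean_per_animal`.

## Movement HMM

Three states with state-dependent emissions: step length ~ gamma
(parameterized (mean, sd) at the interface, converted to shape/scale
internally, matching movement-ecology convention), turning angle ~
wrapped-Cauchy (location m, concentration ρ ∈ [0,1)), optional gamma
activity streams (hourly means of the 12 constituent 5-min records; hours
with fewer than 9 records are dropped). Streams are conditionally
independent given the state; missing values (the undefined first angle,
gap boundaries) contribute likelihood 1.

Fitting maximizes the scaled forward log-likelihood on unconstrained
parameters: multinomial logit per transition row (6 free) and for the
initial distribution (2 free, estimated rather than fixed at stationarity),
log for gamma means/sds, logit for ρ; the angle location is fixed at 0 by
default with a free-location option. The optimizer is L-BFGS-B (ftol 1e-8,
max 500 iterations). Restart 0 starts from the supplied template (so a fit
seeded at the truth can only improve); later restarts draw step/activity
means near the 10/50/90% data quantiles (jittered ×0.5–1.5), ρ ~
uniform(0.1, 0.9), and a diagonal-dominant transition matrix.
Non-converged restarts are logged and excluded; the best converged restart
is reported. The default 50 restarts suits production fits; tests and the
acceptance script use 3–5 because the likelihood surface of well-separated
synthetic data is benign — a problem-size choice, recorded here.

AIC is `−2·loglik + 2k` with k = 6 (transitions) + 2 (initial) + emission
parameters actually estimated. AIC comparison between GPS-only and
GPS+activity models follows field practice: the two likelihoods are over
different observation sets, which is why such comparisons produce very
large ΔAIC values; the comparison selects the lower-AIC fit and breaks
exact ties toward fewer parameters. Zero step lengths cannot arise from the
continuous simulator; real data with exact zeros would need a zero-mass
component, which is out of scope here. Viterbi decoding is standard
log-space dynamic programming with ties broken toward the lower state
index. Forward and Viterbi inner loops are numba-compiled with an
equivalent pure-Python fallback.

## Budgets

A budget is the label-count proportion per state over a uniform grid;
budgets from 5-min classifier labels and hourly Viterbi decodings are
compared per state with classical two-sided paired t-tests across animals
(df = n−1), mean differences reported in percentage points. No multiplicity
correction is applied (none is standard for this three-test contrast); the
significance threshold is a parameter. Zero-variance differences make t
undefined and are reported as such, never ±∞ — note this means a perfectly
constant shift across animals is reported as an undefined t with its mean
difference intact. The 2-week comparison-window selector is seeded.

## Synthetic data: what it emulates and what it does not

The simulator generates, per animal, a first-order Markov behavior chain at
1-min resolution over four states (the fourth, "other", as brief ≤2-min
interruptions so the purity filter has heterogeneous intervals to reject);
a raw acceleration stream (gravity offset + state-dependent sinusoid +
Gaussian noise) whose encoded activity is ordered by state intensity;
5-min activity triplets drawn from per-state negative binomials clipped at
255 (the convention for simulating overdispersed 8-bit activity data; a
discretized Gaussian is available); and a planar GPS track with
state-dependent gamma steps and wrapped-Cauchy turns — exactly the
structure the movement HMM assumes.

Default conditions (chosen once as a realistic regime, since no
distributional description of real per-behavior activity values exists to
estimate from): 10 animals × 12 h; activity means (4,3,5) stationary,
(45,40,35) foraging, (130,120,110) traveling on the 0–255 scale with
negative-binomial sizes 1–3, which places grouped-LOOCV accuracy in the
low-to-mid 90s, AUC near 0.99 and OOB error around 5% — the regime
field-trained models of this kind occupy; steps per 10-min fix of gamma
mean 8/60/600 m with turning-angle concentrations 0/0.3/0.85. Behavior
switching at 1-min resolution; transition diagonals 0.88–0.90 give
multi-minute dwell times.

What passing tests on these data show: the machinery — encoding, labeling
rules, balanced sampling, grouped validation, likelihood maximization,
decoding, budget arithmetic — is correct under the model's own
assumptions. What they do not show: performance on real animals, where
per-behavior activity distributions overlap in ways the negative binomial
need not capture, collar orientation drifts, gaits are not sinusoids,
terrain shapes movement, and GPS fixes have error. The packaged synthetic
models must not be used for inference on field data.

## Degenerate inputs and tie-breaking (summary)

- Vote ties → first class in fixed alphabetical order.
- Viterbi ties → lower state index; exhaustive-enumeration oracle uses
  lexicographic order, which is equivalent.
- Modal-behavior ties in labeling → more seconds wins, then state name.
- AIC ties → fewer parameters.
- Zero-variance paired differences → t undefined (reported as missing).
- Classes with zero instances → excluded from AUC pairs with a warning;
  per-class error NaN, never silently 0.
- All-missing time steps in HMM input → rejected with their indices.
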