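# Methods

This note documents the statistical model behind `vacsmf`, the numerical
choices in the estimator and the bias screen, what the synthetic-data
generator does and does not emulate, and the package's known limitations.

## Estimand and identity

Let D ∈ {1..J} be the cause of a community death and S ∈ {0,1}^K the vector
of dichotomous symptom responses.  The estimand is the community CSMF vector
P(D).  Stacking the 2^K symptom profiles, the law of total probability gives
the exact linear identity P(**S**) = P(**S**|D)·P(D).  P(**S**) is estimable
from the community sample by direct tabulation; P(**S**|D) is not (community
causes are unobserved) and is replaced by its hospital counterpart
P^h(**S**|D) — the method's single substantive assumption.  Nothing about
the marginal symptom prevalences, the hospital cause mix, or symptom
sensitivity/specificity needs to agree across samples; in particular a
case-control hospital design (fixed equal deaths per cause) is fine, because
only the *within-cause* profile distributions enter.

## Estimator

For each of `n_subsets` random draws of `subset_size` = B symptoms (uniform
without replacement, independent across draws, from a seeded generator):
tabulate the community profile distribution p ∈ Δ(2^B), tabulate the
hospital conditional matrix M (2^B × J, column-stochastic), and solve

    min_β ‖p − Mβ‖²  s.t.  β ≥ 0, Σβ = 1.

The point estimate is the arithmetic mean of the per-subset solutions,
renormalized (a guard against float drift; the mean of simplex points is
already on the simplex).  The QP is solved as nonnegative least squares on
the system augmented with a sum-to-one row of weight 10⁴, then renormalized;
a property test checks the objective against a 0.001-step brute-force grid
search over the simplex.  With noise-free inputs and full-column-rank M the
solution is exact (verified to 1e-6); with rank-deficient M the solver
returns one feasible minimizer.

### Subset size: the estimator's main tuning parameter

B trades information per draw (2^B profile cells) against the sampling noise
of M, whose columns are estimated from the n_j hospital deaths of each
cause.  Noise in M acts like errors-in-variables and shrinks the estimate
toward the hospital's own cause mix:

* When the hospital sample mirrors the community (random sampling from the
  same population), that shrinkage target coincides with the truth, so it is
  benign and larger subsets strictly help.  The high-sensitivity-symptom
  experiment (matched samples, weak symptoms) therefore runs at B = 14.
* When the hospital mix diverges from the community (case-control uniform
  sampling against a front-loaded community CSMF), large B biases the
  estimate toward uniform; with n/J ≈ a few hundred deaths per cause, B
  around 5–8 performs best.  The package default is B = 8 with 300 subsets
  (256 cells, estimable at n ≈ 500–3000); the case-control efficiency grid
  uses B = 5.

These values were fixed by pilot simulation before the reported runs and are
exposed in `EstimatorConfig`.

### Uncertainty

A nonparametric bootstrap over records of both samples (`bootstrap_reps`,
default 0 = off) provides standard errors as plumbing; it is a package
convenience, not part of the core method.

## Stratified adjustment

Where an exogenous variable a (age group, sex) has a known community
distribution w(a) but a different hospital composition, P^h(**S**|D) is
replaced per subset draw by Σ_a w(a)·P^h(**S**_a|D_a).  Every cause must
appear in every weighted stratum of the hospital sample; weights must sum
to 1 (tolerance 1e-6).

## Individual classification

Posterior_j ∝ P̂(D=j) · Π_k q_jk^{s_k} (1−q_jk)^{1−s_k}, with q_jk the
hospital per-cause symptom prevalence.  Conditional independence of symptoms
given cause is needed here (not for CSMF estimation).  q_jk is clipped to
[1/(2n_j), 1−1/(2n_j)] — a standard continuity correction — so observed
profiles never get zero likelihood.  The denominator P(S=s) cancels under
normalization; `profile_marginal` exposes its assumption-free community
tabulation as a diagnostic.

## Biased-symptom screen

A symptom reported with different frequency in the two samples for the same
causes ("misreported") violates the shared-conditional assumption.  For the
K₀ active symptoms the screen computes the prediction error
e_k = P(S_k) − Σ_j P^h(S_k=1|D=j)·P̂(D=j), studentizes by
σ̂ = sqrt(Σe²/(K₀−1)), and refers t_k = e_k/σ̂ to a t distribution with
K₀−1 degrees of freedom.  Iteratively: if the largest |t_k| exceeds the
two-sided critical value at level α/m — m counting the symptoms already
removed plus the one under test (sequential Bonferroni) — that symptom is
removed and the CSMF re-estimated on the remainder (each iteration uses a
fresh subset-draw stream derived from the master seed, so runs are fully
reproducible).  A floor (default 3 retained symptoms) prevents degenerate
estimation.  The test is two-sided because misreporting can inflate or
deflate prevalence; σ̂ is the residual root-mean-square (the variance rule
is pluggable).

**Calibration caveat.**  Each iteration compares the *maximum* of K₀
studentized residuals to a single-test critical value; the Bonferroni count
covers only the sequence of removals.  Under an exchangeable null (no
misreported symptoms) this over-flags: simulated familywise flag rates at
α = 0.05 are ≈ 0.3–0.5, not ≤ 0.05.  In designs with genuinely misreported
symptoms the screen is nevertheless sharply accurate — planted violations
dominate σ̂ and are removed first (all ten planted symptoms removed before
any clean one in ≥ 90% of replicates; the error-versus-removals trace is
U-shaped with its minimum at the tenth removal).  Treat the α level as a
removal-ordering knob, not a strict familywise error guarantee.

## Synthetic-data generator

Symptoms are conditionally independent Bernoulli given cause:
p_jk = P(S_k=1|D=j), drawn i.i.d. Uniform(s_min, s_max) (defaults 0.02 and
0.3; the floor keeps every symptom weakly informative).  The generator
covers: random or case-control hospital sampling (case-control remainders go
deterministically to the first causes); an appended high-sensitivity symptom
(p = 1 for cause 1, 0 elsewhere); and community-side misreporting.  Default
community CSMFs are front-loaded — (0.2, 0.2, 0.2, 0.1, 0.05×6) for J = 10,
with analogous vectors for J = 5 and 15 — against a uniform case-control
hospital mix.

**Misreporting** is specified as a marginal prevalence shift in percentage
points.  All cause-conditionals of the symptom are moved by a common
additive amount, solved by bisection so the community marginal (under the
community CSMF) shifts by exactly δ/100 after clipping conditionals to
[0.01, 0.99]; an unattainable shift raises an error naming the symptom.  A
standard ten-column pattern (symptoms 1, 5, 10, 11, 15, 20, 21, 25, 30, 31;
shifts +30, −30, −50, +30, −30, +30, −30, −50, +30, −30 pp) drives the
detection experiments.  In those designs, unbiased symptoms draw
sensitivities from Uniform(0.2, 0.8), and each designated symptom draws from
a sub-interval guaranteeing its shift is feasible after clipping (a −50 pp
shift needs a prevalent symptom to shift; e.g. Uniform(0.6, 0.9)).

What the generator does **not** emulate: symptom dependence given cause
(real questionnaires have correlated items; conditional independence is the
minimal assumption and is also what classification assumes), survey
nonresponse, interviewer effects, or any attempt to model a particular
country's epidemiology.  Passing tests on this generator show the estimator
and screen behave as designed under their own assumptions — not that any
particular field instrument satisfies those assumptions.

## Experiment designs and problem sizes

* **High-sensitivity symptom** (irrelevance of sensitivity/specificity):
  10 causes, questionnaire sizes 20/30/50, 3,000 deaths per sample, both
  samples drawn randomly from the same population (first cause at 0.20),
  other symptoms capped at 30% sensitivity; arms with/without the perfect
  symptom share random numbers.  Default 80 replicates; reported runs use
  20–25 with Monte-Carlo SEs.  In this reconstruction the perfect symptom
  *does* measurably reduce the first cause's error at K = 20 (weak, few
  symptoms), while at K = 30+ the arms are statistically indistinguishable —
  the irrelevance claim holds once the questionnaire is moderately sized.
* **Detection counts**: grid over (K, number misreported) at n = 3,000 and
  n = 500 per sample, case-control hospital, α = 0.05.  At n = 3,000 the
  screen flags exactly the planted symptoms for K ≥ 20 (with an occasional
  single false positive at K = 50, 5 biased) and is powerless at K = 10
  with 3 of 10 symptoms biased, where the fit absorbs the violation.  At
  n = 500 the planted shifts remain far above the prevalence noise floor
  (≈ 2 pp), so detection stays essentially perfect; a materially degraded
  small-sample outcome is not reproducible under these shift magnitudes.
* **Removal trace**: 50 symptoms, 10 misreported, selection forced past its
  stopping point (α = 0.5, capped at 15 removals), 20 replicates; the mean
  MSE trace is U-shaped with the minimum at the tenth removal.
* **Efficiency grid**: case-control hospital, sensitivities
  Uniform(0.02, 0.8), factorial over questionnaire size and both sample
  sizes, with the direct-sampling baseline (multinomial tabulation of
  directly ascertained causes, the sampling-variability floor).  Reported
  runs use a reduced grid (K ∈ {10, 30}, hospital n ∈ {500, 2000},
  community n ∈ {1000, 3000}, 10 replicates); monotonicity assertions carry
  2-SE tolerances.

## Numerical details and edge cases

* Profile bit order: subset sorted ascending; first symptom is the most
  significant bit, so profiles enumerate 00…0, 00…1, …, 11…1.
* A hospital cause with zero records is an explicit error (its fraction is
  unidentifiable), as are mismatched symptom name lists, non-binary symptom
  values under the strict missing-data policy (the zero-fill policy codes
  missing/don't-know as 0 and logs a count), and stratum weights that do not
  sum to one.
* All residuals exactly zero in the screen yields all-zero t statistics,
  flagged as degenerate rather than divided through.
* Every stochastic component (model draw, sampling, subset draws, bootstrap)
  is driven by explicit seeds; identical designs and seeds reproduce
  byte-identical datasets and estimates.

## Known limitations

* The shared-conditional assumption is untestable directly; the screen
  detects only violations large enough to surface as marginal-prevalence
  outliers, and its α level is not a calibrated familywise error rate (see
  the calibration caveat above).
* Subset size materially affects accuracy and its best value depends on the
  hospital design; the defaults here are simulation-informed rules of thumb,
  not optima for any particular dataset.
* Only dichotomous symptoms are supported; missing responses must be
  resolved at load time.
* Bootstrap standard errors ignore the subset-draw Monte-Carlo component
  shared across replicates and should be read as approximate.
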