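# Methods

This note documents the statistical models behind `markercut`, the
defaults and why they were chosen, the numerical decisions, and what the
synthetic-data generator does and does not emulate.

## Dichotomization semantics

A cutoff `c` assigns a patient to the **high** group iff `marker >= c`;
"high" is the reference (marker-positive) group in every effect size, so
an odds ratio above 1 means high marker values predict the positive
outcome and a hazard ratio below 1 means they are protective. Candidate
cutoffs are the distinct observed marker values whose split leaves at
least `min_group` patients on each side. Observed values (rather than,
say, midpoints between adjacent order statistics) keep reported cutoffs
directly interpretable on the marker's scale; the global minimum is never
a candidate because it leaves the low group empty. `min_group` defaults
to 1 — every possible split is examined — but is exposed because
logistic and Cox fits on groups of one or two patients are unstable;
analyses in this package's own examples use `min_group = 5`.

Rows missing the marker are dropped globally and counted; rows missing
only the outcome or only the survival pair are dropped only for analyses
that need those variables, with counts in the run log.

## Mixture-model cutoff

The marker is modelled as `pi1*N(mu1, s1^2) + pi2*N(mu2, s2^2)`, fitted
by EM on the raw observations. Maximum likelihood on raw values is used
rather than a fit to binned histogram counts: it is strictly more
informative and makes the result independent of an arbitrary bin width.
The fit is deterministic given a seed: the first EM start splits the
sample at its median (each half's mean/SD initialize one component), the
remaining `n_starts - 1` starts draw random component means from the
data; the best final log-likelihood wins.

Numerical choices:

* convergence when the log-likelihood improves by less than `1e-8`
  (relative) or after 500 iterations; the per-iteration log-likelihood
  trace is retained and is non-decreasing (EM guarantee, asserted in
  tests);
* component SDs are floored at `1e-4` of the sample SD so a component
  cannot collapse onto a single point and blow up the likelihood;
* the cutoff solves `pi1*phi1(x) = pi2*phi2(x)` in closed form (the
  log-density difference is quadratic for unequal variances, linear for
  equal ones). Two crossings exist when variances differ; the root
  inside the open interval `(mu1, mu2)` is the decision boundary and is
  returned. If neither root lies in that interval — which happens when
  the fitted mixture is effectively unimodal — the root closest to the
  interval is returned with a warning, because no interior decision
  boundary exists.

At `n = 500` and 4-SD component separation the plug-in crossing
estimator has a sampling SD of roughly `0.14` marker SDs (the tests
verify its median absolute error and its agreement with an independent
EM implementation); mixture cutoffs on cohorts of a few hundred patients
should be read with that imprecision in mind. The method is not designed
for coarse ordinal scores with few levels, where a continuous mixture is
a poor description.

## Binary-outcome cutoffs

Per candidate the 2×2 table of dichotomized marker against outcome is
summarized by:

* two-sided Fisher exact p (hypergeometric summation) — this drives the
  minimal-p selection;
* the odds ratio `(tp*tn)/(fp*fn)`, which is the logistic-regression MLE
  for a single binary predictor, with a 95% Wald CI on the log scale;
  any zero cell triggers the Haldane–Anscombe `+0.5` correction with a
  flag, so the reported OR is always finite;
* sensitivity and specificity with Wilson score intervals, which keep
  sensible coverage near 0 and 1 where the Wald interval degenerates.

The optimization p (Fisher) and the effect-size machinery (Wald) can
disagree near degenerate tables; both are reported per candidate rather
than reconciled.

**Orientation.** Which marker direction predicts the positive outcome is
resolved automatically as the direction giving an empirical AUC of at
least 0.5 (Mann-Whitney), overridable by flag.

**Ties.** Ties in the minimal p or the ROC distance break toward the
lowest cutoff (with a `1e-12` absolute tolerance, since equal distances
reached through different floating-point routes differ in the last ulp).

**Constrained methods.** Among candidates whose sensitivity (or
specificity) strictly exceeds the requested level, the one maximizing
the complementary measure is returned. Ties in the complementary
measure break toward the most stringent qualifying cutoff — the largest
for a sensitivity constraint, the smallest for a specificity constraint —
so the sensitivity-constrained cutoff sits below the
specificity-constrained one for a positively oriented marker, and the
interval between them forms the equivocal zone: markers below the lower
cutoff are called negative, at or above the upper cutoff positive, in
between indeterminate. With very concordant data the two constrained
cutoffs can invert (the zone is empty); this is reported as a warning
with both cutoffs.

**Robustness.** `proportion_significant` reports the fraction of
candidate cutoffs with p below `alpha` (default 0.05, two-sided). A
dichotomization that is significant over most of the marker's range is
less likely to be an artifact of minimal-p selection — which, being a
maximally selected statistic, is anti-conservative: in the package's own
null simulations (marker independent of outcome, n = 60) the selected
cutoff's p falls below 0.05 in roughly a third of runs. No corrected
p-values for maximally selected statistics are computed; the overview
plots and this proportion are the intended mitigation.

## Survival cutoffs

Kaplan-Meier estimation and the two-group log-rank test are delegated to
`lifelines`; the log-rank p drives the minimal-p selection. Hazard
ratios come from a univariate Cox proportional-hazards fit (statsmodels
`PHReg`) with Efron tie handling by default, switchable to Breslow.
When every event falls in one group the partial likelihood is monotone;
the HR is then reported at the boundary (0 or infinity) with an infinite
CI and a flag instead of a spurious finite estimate.

Restricted mean survival time is the area under the KM step function up
to a uniform horizon `tau` equal to the **maximum observed time in the
full dataset** — not per-arm maxima, which would make the two areas
incomparable. Where an arm's own follow-up ends before `tau` its curve
is held constant, with a warning. The RMST variance is the
Greenwood-type sum `sum_i A_i^2 d_i / (n_i (n_i - d_i))` with `A_i` the
area under the curve from the i-th event time to `tau`; the difference
CI treats the two arms as independent. A bootstrap CI is available as a
cross-check (and is used as one in the tests). An arm with no events
contributes zero estimated variance and flags the CI unreliable.

## Synthetic cohorts

The generator produces the structure each method assumes, on the scale
of a log2 microarray expression marker:

* marker: two-Gaussian mixture, defaults `pi1 = 0.3`, means 5 and 10,
  unit SDs — a bimodal hormone-receptor-like profile with a ~30%
  low-expressing subpopulation;
* binary status: a step at the true changepoint (default 7.5, the
  component midpoint and, for equal SDs and these weights, close to the
  density crossing) with independent label flips (default 5%) emulating
  an imperfect gold standard; alternatively a logistic link, whose zero
  slope provides exact null data;
* survival: exponential event times whose hazard is multiplied by a true
  HR (default 0.5) at and above the changepoint — proportional hazards
  by construction — with independent exponential censoring whose rate is
  calibrated by root-finding so the expected censored fraction hits the
  target (default 30%);
* the default cohort size is 286 patients.

What this does **not** emulate: probe-level measurement noise,
correlated censoring, non-proportional hazards, batch effects, or
ordinal discretization. Passing tests therefore demonstrate correctness
of the estimators and optimizers under their stated assumptions, not
robustness to violations of those assumptions.

Simulation sizes in the test suite (50 random instances of n ≤ 60 for
the exhaustive-oracle checks, 100 cohorts of n = 500 for recovery
experiments, 200 null simulations) were chosen to keep the full suite
around five minutes on one CPU while leaving the Monte-Carlo margins
comfortable.

## Input handling

Tab-separated tables with a header row; at most 5000 rows and 50
columns by default (a deliberate fidelity-to-origin limit from the
interactive workflow this tool descends from; `--no-limits` disables
it). Decimal points only — no locale-specific parsing. When no positive
outcome level is named, the lexicographically larger level is assumed
and logged. Result files are byte-reproducible for a fixed configuration
and seed; timestamps appear only in `run.log`.

## Known limitations

* Minimal-p selection reports uncorrected p-values (by design, see
  above); the selected cutoff's significance and effect size are
  optimistically biased and require validation on independent data.
* The mixture method assumes exactly two Gaussian components; no model
  selection over the number of components is attempted.
* Cox and logistic effect sizes are univariate; no covariate adjustment.
* Two-group stratification only: a three-group split is obtained by two
  sequential constrained runs (the equivocal zone), not by simultaneous
  two-cutoff optimization.
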