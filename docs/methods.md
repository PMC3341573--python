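# Methods

## The updating model

Diagnostic probability revision is Bayes' theorem in odds form. For a
target proposition *T* (a disease, or a category of diseases) with pre-test
probability *p*:

    pre-test odds   o0 = p / (1 − p)
    post-test odds  o  = o0 × Π_i LR_i
    post-test prob  p' = o / (1 + o)

where LR_i is the likelihood ratio of the *i*-th observed finding: LR(+) =
sens/(1−spec) if the finding is present, LR(−) = (1−sens)/spec if absent,
unknown findings contributing nothing. Multiplying LRs is exact when
findings are conditionally independent given *T* versus not-*T*; otherwise
it is a naive-Bayes approximation (quantified below).

All computation is at full double precision. Probabilities 0 and 1 are
representable; they are absorbing states of Bayes' rule, so an updating
chain returns them unchanged and records a warning on the trace.
Probability 1 maps to an infinite-odds flag (`math.inf`), which converts
back to probability 1.

Rounding is strictly a display-layer concern: `round_half_even` (banker's
rounding on the decimal representation) backs `format_odds` (default 2
decimals) and `format_percent` (default integer percent). Published worked
examples chain *printed* (rounded, sometimes truncated) intermediates; this
engine never does. To reproduce a printed chain, replay it from its printed
intermediates (e.g. start from prior odds 0.13 rather than probability
0.12); the bundled examples and the acceptance script do exactly that.
Printed values produced by truncation rather than rounding (a 4.76%
posterior printed as "4%") cannot be reproduced by any consistent rounding
rule and are not asserted anywhere.

### LR strength bands

The conventional rule of thumb is implemented as a three-level band:
positive direction — LR > 10 conclusive, 5–10 moderate, below small;
negative direction — LR < 0.1 conclusive, 0.1–0.2 moderate, above small.
Boundary values fall in the moderate band, reading "5 to 10" inclusively.

### Dependent findings

Findings that are statistically dependent (e.g. vaginal discharge and
vaginal irritation) must not have their LRs multiplied together. Rows of an
accuracy table may share a `dependence_group`; within a group only the
single applicable LR with the largest |ln LR| is applied. |ln LR| is the
operationalization of "better discriminatory value": it treats LRs above
and below 1 symmetrically, and prefers an LR(−) of 3.1 over 2.7 as
expected. Ties break toward the earlier table row, keeping selection
deterministic.

## Category-oriented likelihood ratios

A category-oriented LR measures how much more likely a finding is in a
patient whose disease belongs to a category than in one whose disease does
not. The operational definition adopted here is the prevalence-weighted
mixture over the cohort sampling model (one disease per patient, drawn with
prevalence π_d; finding present with probability p_d given disease d):

    sens(C) = Σ_{d∈C} π_d p_d / Σ_{d∈C} π_d          = P(finding | C)
    spec(C) = 1 − Σ_{d∉C} π_d p_d / Σ_{d∉C} π_d      = P(no finding | ¬C)

This is the unique definition consistent with "patients with one of the
diseases of the category" under that sampling model; the package's
enumeration oracle and the empirical cohort estimates both converge to it.
The complement ¬C is taken over *all* non-member diseases in the taxonomy,
including symptomatic-but-undiagnosed rows, because the prevalence table
itself lists those under a category.

Categories are hierarchical: a disease with path `organic/neoplasm` is a
member of both `organic` and `organic/neoplasm`, and a category's prior is
the sum of its members' prevalence fractions. Prevalence files store
percentages (as published tables print them) and convert to fractions at
load; the bundled abdominal table's rows sum to 99.6%, which the generative
model renormalizes to a simplex.

### Exactness and approximation

Sequential category updating with category-oriented LRs is **exact** in two
regimes, and the package proves both against the enumeration oracle:

* a single finding (any generative model), and
* homogeneous categories — finding probabilities constant within C and
  within ¬C, findings independent given the membership side.

With heterogeneous categories and several findings it is a naive-Bayes
approximation at the category level: the category likelihood ratio of a
second finding is no longer independent of the first, because the first
finding shifts the posterior *within*-category disease mix. The simulator's
`naive_vs_exact` and `discrepancy_summary` report the absolute and log-odds
error instead of hiding it; on the bundled heterogeneous demo model the mean
absolute error across a simulated cohort is of order 1e-3.

Exact sub-category posteriors never exceed their parent's (probabilities of
nested events); the *approximate* sequential posteriors need not obey this,
which is one more reason the oracle ships alongside the engine.

## Scheme trees

A scheme is a tree of branching points: **routers** read a categorical
attribute of the patient profile (e.g. `onset`); **revisers** revise a named
category's probability with the patient's findings and branch `above` or
`below` an explicit action threshold; leaves carry terminal actions.
Because published schemes invoke a "predefined diagnostic threshold"
without quantifying it, thresholds are configuration in the scheme file
(default 0.10), never hidden constants. A reviser's prior can come from the
disease table, from the previous reviser's posterior (`carried`), or be
fixed in the file — the bundled scheme fixes the neoplasm sub-category
prior at 4% because the published example states that value even though the
neoplasm-tagged prevalence rows sum to 3.3%; the discrepancy is deliberate
and documented rather than resolved by guessing which diagnoses the
original authors counted.

Patient profiles therefore carry two maps: `findings` (present / absent /
unknown) and `attributes` (free categorical facts for routers). Traversal
is fully deterministic given profile and scheme.

## The synthetic-cohort generator

`simulate_cohort(model, n, seed)` draws each patient's disease i.i.d. from
the renormalized prevalence vector and each binary finding independently
given the disease, from a single `numpy.random.default_rng(seed)` stream —
identical (model, n, seed) gives byte-identical cohorts. The generator
emulates a cross-sectional primary-care cohort; it does **not** emulate
correlated findings (dependence enters only through dependence-group
selection at updating time), covariate-dependent prevalence, measurement
error in finding ascertainment, or verification bias in who gets the
reference standard. Passing tests therefore demonstrate internal
consistency of the estimators and the updating calculus under the stated
sampling model, not robustness to those real-data features.

Empirical sensitivities/specificities carry Wilson 95% intervals
(well-behaved at the extreme proportions small strata produce). Empirical
category LRs use the plug-in ratio of stratum proportions; consistency is
checked at n = 200,000, where every bundled finding's empirical log-LR must
lie within 3 delta-method standard errors of its analytic value. A
calibration audit bins patients by their sequential category posterior
(width 0.1) and requires each bin's empirical category frequency to fall in
the exact binomial 99% interval around the bin's mean predicted posterior.

The packaged demo model (`demo_abdominal_model`) inverts each published
category LR pair to its unique (sens, spec) pair — sens = LR+(1−spec),
spec = (LR+−1)/(LR+−LR−) — and uses those as the within-/outside-category
finding probabilities. At `heterogeneity=0` the analytic category LRs
reproduce the published values exactly; the default `heterogeneity=0.15`
adds per-disease Gaussian noise on the logit scale so the category is
realistically heterogeneous and the analytic LRs only *approximate* the
published ones. This is a demonstration model: the true per-disease
accuracies behind the published table were never printed, so no equality
with them is asserted.

## Numerical choices

* Odds and LR chains run in linear space scalar-wise; the vectorized cohort
  paths work in log space with probabilities clipped at 1e-300 to keep
  degenerate model entries (p = 0 or 1) well-defined, and the exact oracle
  normalizes after subtracting the row-wise max log-likelihood.
* Accuracy rows stating both an LR pair and a sens/spec pair must agree
  within 5% relative tolerance (published tables round aggressively).
* Prevalence columns may exceed 100% by at most 0.5 (row rounding slack);
  more is a parse error.
* Zero-probability evidence raises a dedicated error rather than returning
  NaNs; empty estimation strata likewise.

## Problem sizes

The test suite and acceptance script use cohorts of n = 200,000 for
consistency and calibration checks (sufficient for 3-SE resolution on every
bundled LR) and n = 10,000 for frequency-bound checks; enumeration oracles
run on models of ≤ 7 diseases × ≤ 5 findings, where the full joint table is
trivially enumerable. The whole suite completes in a few seconds on one
CPU.
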