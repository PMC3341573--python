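# catlr

Likelihood-ratio diagnostic reasoning, for both single diseases and whole
**categories** of diseases.

`catlr` is a small toolkit for evidence-based diagnostic probability
revision, aimed at clinical-epidemiology researchers and medical educators.
It implements:

* **Disease-oriented updating** — Bayes' theorem in odds form. A pre-test
  probability *p* becomes pre-test odds *p*/(1−*p*); each clinical finding
  multiplies the odds by its likelihood ratio, LR(+) = sens/(1−spec) for a
  present finding or LR(−) = (1−sens)/spec for an absent one; post-test
  probability is *o*/(1+*o*). Statistically dependent findings are grouped,
  and only the most discriminative LR in a group (largest |ln LR|) is
  applied.
* **Category-oriented likelihood ratios** — the diagnostic value of a
  finding for a whole *category* of diseases (e.g. "organic causes of
  non-acute abdominal pain") rather than one disease. Under cross-sectional
  cohort sampling with prevalences π_d and per-disease finding probabilities
  p_d, the category-level accuracy is the prevalence-weighted mixture

      sens(C) = Σ_{d∈C} π_d p_d / Σ_{d∈C} π_d
      spec(C) = 1 − Σ_{d∉C} π_d p_d / Σ_{d∉C} π_d

  and the category LR pair follows from the usual formulas.
* **Scheme trees** — the branching structure experts use for nonspecific
  complaints: deterministic routers (acute vs non-acute onset) and
  probabilistic revisers that update a category probability and compare it
  with an explicit action threshold.
* **A virtual-cohort simulator with an exact-Bayes oracle** — one disease
  per patient drawn from a prevalence vector, binary findings conditionally
  independent given the disease. The simulator estimates empirical category
  LRs (with Wilson intervals), and the enumeration oracle computes the exact
  posterior so that the naive-Bayes error of sequential category updating is
  *measured*, not assumed away.

Bundled fixtures transcribe published worked examples: a urinary-tract-
infection (UTI) accuracy table, a category-oriented LR table and a
final-diagnosis prevalence table for non-acute abdominal pain, an example
scheme tree, and the two worked patient cases.

## Worked example

The bundled UTI case: a woman with dysuria and frequency, no vaginal
discharge or irritation, who self-diagnoses "just like the previous one".
Vaginal discharge and irritation are dependent findings, so only the more
discriminative LR (discharge, LR(−) 3.1 > irritation's 2.7) enters the
chain:

```bash
catlr update \
  --accuracy-table src/catlr/data/uti_findings.csv \
  --profile src/catlr/data/case1_profile.json \
  --prior-odds 0.13
```

prints

```
Pre-test probability = 12%   (odds 0.13)
  x 1.5  [dysuria present]   -> odds 0.20
  x 1.8  [frequency present]   -> odds 0.35
  x 3.1  [vaginal_discharge absent]   -> odds 1.09
  x 4  [self_diagnosis present]   -> odds 4.35
Post-test odds = 4.35
Post-test probability = 81%
```

i.e. a 12% pre-test probability of uncomplicated UTI rises to 81% after
four findings. The same machinery runs the abdominal-pain case through the
scheme tree (`catlr scheme-run`), where six negative history findings and
three normal laboratory results shrink the organic-category probability
from 14% to about 3%, and the neoplasm sub-category chain ends near 1%.

The Python API mirrors the CLI:

```python
from catlr import data, sequential_update, select_lrs

table = data.load_uti_findings()
case = data.load_case1_profile()
trace = sequential_update(select_lrs(case, table), prior_odds=0.13)
trace.posterior_prob        # 0.8131679...
```

Simulator commands: `catlr simulate` writes a reproducible cohort CSV from
a generative-model JSON; `catlr validate` compares empirical against
analytic category LRs and reports the naive-vs-exact discrepancy and a
posterior-calibration table; `catlr category-lr` prints the analytic
category LR pair of every finding in a model.

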