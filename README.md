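# hdprog — Bayesian dynamical modelling of brain atrophy around Huntington's disease onset

Huntington's disease (HD) gene carriers lose regional brain volume for
years around the clinical onset of motor symptoms, but 3–7 annual MRI
visits per person are too few to characterize ten years of progression
subject by subject. `hdprog` implements a hierarchical Bayesian
dynamical-systems pipeline for exactly this setting: subject-level
state-space models of 55 regional volumes driven by 28 bilateral latent
states,

```
dx/dt = A x(t) + C u(t, θu),        y(t) = g(x(t), θg) + ε,
```

inverted per subject by variational Laplace, pooled across subjects with
parametric empirical Bayes (PEB) over a covariate design (diagnostic
group, CAG-repeat length, gender, age orthogonalized to CAG, TIV, site),
compared across candidate dynamics (constant rate, accelerating, simple
exponential decay `dx/dt = Ax`, sigmoidal-input), pruned by Bayesian model
reduction/averaging at the posterior-probability threshold Pp > .95, and
validated by leave-one-out prediction of group membership and CAG from
brain data alone. Self-connections are parameterized `a = -exp(λ)` so every
state is negatively self-connected: region-specific exponential atrophy,
with the decade loss `100·(1 − e^{10a})` as the headline summary.

Because the motivating cohort data (conversion-aligned longitudinal
volumetrics) are not publicly distributable, the package is driven by a
first-class synthetic-cohort generator calibrated to the published summary
statistics of that design: 49 + 49 subjects, 3–7 annual visits (HD mean
5.84), CAG ~ 43.67 (2.77) on [39, 50], CAG–onset-age correlation −.85,
striatal decade losses of 18.7% (putamen) and 15.4% (caudate) versus <3%
in controls, and TMS/SDMT scores on a [0, 100] worsening scale generated
from the latent states (decade changes 57.80 and 16.78 points). Every
stage of the pipeline is tested by recovering these quantities from its
own simulations. The intended users are researchers in longitudinal
neuroimaging and disease-progression modelling who want a transparent,
fully testable reference implementation of this model class.

## Worked example

```python
from hdprog import (CohortConfig, generate_cohort, StateModelSpec, PriorSpec,
                    fit_subject, build_design_matrix, fit_peb, bma_average,
                    decade_loss_summary, loo_predict)

config = CohortConfig(seed=42)                 # calibrated 49+49 cohort
subjects, series = generate_cohort(config)

summary = decade_loss_summary(subjects, series)
spec = StateModelSpec(form="dynamic")          # dx/dt = Ax, 28 states
priors = PriorSpec.default(spec)
posts = [fit_subject(ts, spec, priors) for ts in series]
X = build_design_matrix(subjects)
peb = fit_peb(posts, X, priors, param_names=spec.param_names)
bma = bma_average(peb)
```

The numbered drivers under `analysis/` run the same stages end to end and
narrate what they find. On the default seed they print:

```
$ python analysis/01_simulate_cohort.py
cohort: 49 HD + 49 controls -> results/cohort
visits per HD subject: mean 5.69 (calibration target 5.84)
CAG: mean 43.84, sd 2.80 (targets 43.67 / 2.77)
CAG vs age at conversion: r = -0.87 (target -0.85)

$ python analysis/05_summaries.py
median decade loss (nonhierarchical):
  putamen: HD 18.3% (targets 18.7 / 15.4), control 1.4% (< 3)
  caudate: HD 15.8% (targets 18.7 / 15.4), control 0.8% (< 3)
brain-behavior fit:
  TMS: R^2 0.98, model-implied decade change 59.2 points (targets 57.80 / 16.78)
  SDMT: R^2 0.78, model-implied decade change 17.1 points (targets 57.80 / 16.78)
```

i.e. the generator reproduces the demographics it is calibrated to, the
nonhierarchical decade-loss summary recovers the striatal losses the decay
rates were set from, and the brain–behavior readout recovers the score
trajectories. `analysis/03_model_comparison.py` reruns the four-way model
selection (the simple dynamic model wins) and the connectivity comparison
(models without interregional spread win); `analysis/06_loo_prediction.py`
reports leave-one-out group assignment accuracy and the CAG prediction
correlation.

A `hdprog` command-line interface wraps the same stages
(`simulate`, `fit`, `peb`, `compare-models`, `bma`, `summaries`, `loo`,
`run-all`), each taking `--config config.yaml --seed N --out DIR` and
writing tidy TSV tables plus a JSON run manifest with checksums.

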