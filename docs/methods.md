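# Methods

`hdprog` models longitudinal regional brain volumes around the clinical
motor onset of Huntington's disease (HD) with a two-level Bayesian
dynamical-systems framework, and ships a synthetic-cohort generator whose
defaults reproduce the summary statistics of the conversion-aligned study
design it emulates. This note records the model, the defaults and the
numerical choices, so that every number the package produces can be traced
to an assumption.

## Subject-level generative model

Each subject carries 28 latent states `x(t)` — 25 bilateral cortical
regions, bilateral caudate, bilateral putamen and one global white-matter
compartment — evolving over progression time `t` in years relative to motor
conversion (`t = 0`, the first visit with unequivocal motor signs; controls
are aligned at the age-matched time point). The state equation is the linear
dynamical system

    dx/dt = A x(t) + C u(t, theta_u)

and the observation model reads the 55 regional volume columns (both
hemispheres of a bilateral pair read the same state; atrophy is assumed
bilaterally symmetric) plus optional behavioral channels:

    y(t) = g(x(t), theta_g) + eps,   eps ~ N(0, exp(-lambda_noise) I).

Four forms of the state equation are compared:

| form             | structure                              | interpretation            |
|------------------|----------------------------------------|---------------------------|
| `constant_rate`  | A = 0, u = c0                          | linear volume change      |
| `quadratic_rate` | A = 0, u = c0 + c1 t                   | accelerating change       |
| `dynamic`        | A ≠ 0 (negative diagonal), C = 0       | exponential regional decay|
| `dynamic_sigmoid`| dynamic + logistic input u(t; t0, tau) | phase-transition dynamics |

Self-connections are parameterized `a_i = -exp(lambda_i)`, which enforces
negative self-connection (decay) by construction and puts the decay rate on
a log scale. The `dynamic` form optionally carries directed between-region
edges (striatal→cortical and within-lobe cortical→cortical presets) to test
interregional spread of atrophy. The sigmoid input uses the logistic
function; the literature uses "sigmoidal" generically and the logistic is
the conventional concrete choice.

Trajectories are exact closed forms where they exist (polynomial forms;
diagonal dynamic; non-diagonal dynamic via eigendecomposition of A with a
`scipy` matrix-exponential fallback). The sigmoid-input model is integrated
by fixed-step RK4 from the anchor `t = 0` outward (step 0.05 years for
trajectory queries, 0.1 years inside iterative fitting, where the O(h^4)
error is orders of magnitude below measurement noise). Analytic Jacobians
are provided for every form — including first-order perturbation of the
matrix exponential for edge parameters and forward sensitivity equations
for the sigmoid input — which is what makes whole-cohort refits cheap
enough for repeated model comparison.

## Subject-level inversion (variational Laplace)

`fit_subject` maximizes the free energy

    F = log p(y | m) + log p(m) + 1/2 log |2 pi Sigma|

over a Gaussian posterior `q = N(m, Sigma)` by Gauss–Newton ascent with
Levenberg–Marquardt damping; `Sigma` is the inverse curvature at `m`. Steps
are accepted only if F increases, so F is monotone across accepted
iterations; convergence is declared after 4 consecutive accepted steps with
|dF| < 1e-3 (cap 128 iterations), and non-convergence is reported, never
silent. A mean-field partition separates structural parameters from the
noise log precisions: the cross curvature (-w J'r) is dropped from the
Hessian, keeping it positive definite far from the mode where the full
Gauss-Newton curvature is indefinite; the dropped term vanishes at the mode.
In the linear-Gaussian fixed-noise case the procedure is exact: posterior
and free energy equal the conjugate solution and the analytic log evidence
(asserted to 1e-6 in the tests).

Default priors (diagonal, on the % volume scale): `x0 ~ N(100, 10^2)`,
`lambda ~ N(log 0.005, 1.5^2)` (0.1%–60% loss per decade within 2 sd, wide
enough to cover both manifest striatal atrophy and healthy aging — a prior
centered on 10%/decade with unit variance puts healthy-control decay 2.3 sd
out and visibly biases model comparison), `c0 ~ N(0, 1)`, `c1 ~ N(0, 0.5^2)`,
`t0 ~ N(0, 2^2)`, `log tau ~ N(0, 0.5^2)`, edge weights `N(0, 0.1^2)`, input
sensitivities `N(0, 1)`, behavioral readout weights `N(0, 1)` with intercept
`N(50, 30^2)`, log noise precisions `N(0, 1)`. Volumes share one noise
precision; behavioral channels share a second (scores and volumes live on
different scales). All priors are exposed through `PriorSpec`.

## Group level (parametric empirical Bayes)

Subject parameters are embedded in the second-level linear model
`theta_i = B x_i + eps_i` with design row `x_i` = (mean, diagnostic group
+1/-1, CAG z-scored among gene carriers with controls at the centered value
0, gender ±1 centered, age z-scored and orthogonalized with respect to CAG
(they are strongly correlated by construction of a conversion-aligned
cohort), TIV z-scored, site one-hot with the reference level dropped and
centered). Nuisance columns that are constant or collinear in a small
sample are dropped with a logged notice; mean, group and CAG are mandatory.

Each subject enters through a Gaussian likelihood summary with
data-information precision `Lambda_i = Sigma_i^-1 - Sigma0^-1` (clipped to
positive semidefinite) centered at the posterior mean. Centering at the
extrapolated maximum-likelihood point is exact for linear models but
unstable along weakly identified nonlinear ridges (near-zero decay rates,
noise precisions), where the quadratic extrapolation leaves the region in
which the Laplace approximation holds; posterior-mean centering trades a
small attenuation — negligible for well-identified parameters — for
stability, and the hierarchical empirical-Bayes update
(`eb_updated_posteriors`) recovers most of the residual subject-level
shrinkage by pooling.

Between-subject covariance is diagonal with prior expectation
(first-level prior variance)/16, scaled by one empirically estimated log
precision per parameter block (initial states / dynamics / behavioral
readout / noise). A single global precision scalar proportional to the
first-level prior variances lets the x0 block (prior variance 100) absorb
all residual heterogeneity and collapses the group effects; the per-block
scheme recovers simulated effects to within a few percent. The block log
precisions get `N(0, 1)` priors and are optimized by coordinate descent
with bounded line searches, followed by a diagonal Laplace correction.

The effect matrix B is given a Gaussian prior whose mean-column expectation
is the first-level prior mean (covariate columns are a priori zero) and
whose variances inherit the first-level prior variances row-wise. The
evidence over B is then analytic, and the total hierarchical free energy
used for model comparison is

    F = sum_i F_i + [second-level evidence under the empirical prior
                     - evidence under the independent first-level priors],

a Bayesian-model-reduction re-evaluation of the subject posteriors under
the group prior.

## Model selection, reduction and averaging

Candidate models (the four state-equation forms; diagonal vs edge-preset
connectivity) are compared by total hierarchical free energy; differences
are log Bayes factors, mapped to posterior model probabilities by softmax
under equal model priors. Note an identifiability caveat quantified in the
tests: at small decay rates the exponential and linear forms predict
trajectories that differ by far less than measurement noise within a
3-7 visit window, so form recovery is only meaningful (and only asserted)
at effect sizes where the forms are distinguishable.

Bayesian model reduction scores reduced group-level models analytically:
"switching off" a (parameter, covariate) entry collapses its prior variance
to 1e-8 (exactly zero would make the algebra singular) at prior mean 0.
Each entry's posterior probability Pp is the softmax of its on/off evidence
pair on the full model — the per-parameter comparison the thresholding rule
Pp > .95 is defined on. Averaged estimates come from an evidence-weighted
average over the greedily searched family (iteratively switch off the entry
whose removal most increases evidence); greedy single-entry evaluations use
Sherman–Morrison rank-one updates, verified against the dense formula and
against direct conjugate refits. An exhaustive search is available up to 20
switchable entries and agrees with greedy on toy problems.

## Leave-one-out covariate prediction

For each held-out subject the group model is re-estimated on the rest
(between-subject precisions reused from the full fit; they move negligibly
when one subject is dropped, and re-optimizing them per fold would dominate
the cost). The held-out subject's covariate is then inferred from which
group-conditional prior `N(B x_i(c), Sigma_b + design uncertainty)` best
explains their already-inverted data summary: for group, the posterior
probability over {HD, control} (a control candidate carries no CAG burden);
for CAG, a posterior mean over the integer support 39-50 under a uniform
grid prior. Covariate standardization constants come from the full sample;
the held-out subject's imaging data never touch the group stage (asserted
by an outlier-injection test).

## Synthetic cohort: what it emulates, and what it does not

The generator produces a conversion-aligned two-group cohort: 49 HD gene
carriers and 49 age-matched controls, 3-7 annual visits inside t in [-6, 5]
years, volumes as % of the cohort mean at diagnosis. Calibrated defaults
(all derived once from the published summary statistics of the design):

- **Visit counts.** HD law {3: .18, 4: .10, 5: .04, 6: .07, 7: .61} (mean
  5.83, sd 1.63), control law {3: .13, 4: .07, 5: .05, 6: .08, 7: .67}
  (mean 6.09, sd 1.47). Window placement is uniform over annual alignments
  that keep all visits inside the window and include t = 0. Missingness is
  completely at random through the count law.
- **CAG and onset age.** CAG is a discretized truncated normal on the
  integers [39, 50] with location 43.242 and scale 3.449, whose discretized
  moments are exactly mean 43.67 / sd 2.77; age at conversion is
  N(44.59, 9.28^2), coupled to CAG through a Gaussian copula with latent
  correlation -0.8636 so that the sample Pearson correlation averages
  -0.85 after discretization attenuation (measured factor 0.9843). Each
  control copies the age of its matched HD partner.
- **Decay rates** (per-year, `a = -(rate + cag_slope (CAG - 42))`): putamen
  ln(1-0.187)/10, caudate ln(1-0.154)/10 (set from the published striatal
  decade losses of 18.7% and 15.4%); cortical rates by lobe — occipital
  6.5%/decade, parietal 6.0%, frontal 3.5%, temporal and limbic 3.0%, white
  matter 5.0% (package choices following the published ordering: posterior
  regions fastest); controls 1%/decade everywhere (published bound: <3%).
  CAG slopes concentrate in occipital (8e-4 per CAG unit), striatal (5e-4)
  and parietal (4e-4) states, centered at CAG 42.
- **Group offsets at t = 0** (HD - control, split symmetrically around
  100%): caudate -10, putamen -12, occipital -3, parietal -2.5,
  frontal/temporal -2, limbic -1.5, white matter -3 percentage points.
- **Noise.** Additive i.i.d. Gaussian measurement noise, sd 1.0 percentage
  point (unreported in the source; chosen so subject-level recovery is
  nontrivial but achievable).
- **Behavior.** TMS and SDMT scores on the worsening-oriented [0, 100]
  scale are linear readouts of the latent states plus noise (sd 2 points),
  clipped to the scale after noise. Readout patterns put TMS weight on the
  motor/visual regions reported to predict motor worsening and SDMT weight
  on a cortical-minus-striatal contrast; each pattern is rescaled once, in
  closed form against the exact CAG-law expectation of the latent decade
  change, so the noise-free mean TMS change over t = -6..+4 is 57.80 points
  and the SDMT change 16.78. Intercepts anchor the expected score at
  t = -6 to 20 points, keeping clipping inactive in practice.

Not emulated: subject-level random effects beyond CAG (x0 and decay are
exact functions of group and CAG), site effects on volumes (the site
covariate exists but its simulated effect is zero), informative missingness,
scanner drift, and any hemispheric asymmetry. Passing the recovery tests
therefore shows the estimator chain is correct and calibrated under the
stated design — not that real registration/segmentation pipelines meet
these assumptions.

## Summary analyses

- **Decade loss (nonhierarchical).** Per subject and region, an OLS line of
  volume against time; loss = slope x 10 years as % of the fitted volume at
  the window start t = -6 (the scale on which a 10-year loss is defined);
  group summary is the median. Relative to t = -6 the linearization bias of
  this estimator is ~0.3 points at striatal rates (quantified in the tests);
  relative to each subject's first visit it would be ~+1 point.
- **CAG R^2 over time.** At each integer t, R^2 of the cross-subject
  regression of model-predicted (denoised) volume on CAG among gene
  carriers; with x0 common and decay CAG-dependent this vanishes exactly at
  the conversion anchor and grows with |t|. An option computes the same on
  raw volumes.
- **Brain-behavior metrics.** One shared readout weight vector per channel
  (plus intercept) over the 28 states, estimated by Bayesian linear
  regression (evidence-optimized noise) of pooled observed scores on the
  subjects' empirical-Bayes updated state trajectories; this matches the
  generator, whose behavior weights are cohort-level. Reported: pooled R^2
  over subject-visits and the mean model-implied score change over the
  10-year span t = -6..+4. Subject-level joint state+readout inversion is
  also supported by `fit_subject` (behavioral channels with their own noise
  precision) and tested, but the cohort metrics use the shared readout.

## Problem sizes

Unit and property tests run at 3-20 subjects; recovery and calibration
suites use 20+20 subjects over 20 seeds (model selection, reduction
calibration, connectivity null, leave-one-out) and the full 49+49 design
where no model fitting is involved or only one model is fitted (decade
loss, behavior calibration, demographics). These sizes are the package's
chosen desk-scale design points; headline effect recovery is insensitive to
doubling them.

## Known limitations

- The free energy is a Laplace approximation; for strongly nonlinear
  regimes (steep sigmoid inputs, large edge weights) it can misrank models
  with small evidence differences.
- Posterior-mean-centered likelihood summaries attenuate weakly identified
  group effects (quantified at ~10-15% for CAG-on-decay effects in the
  recovery tests); effects on well-identified parameters are unaffected.
- Between-subject covariance is diagonal per parameter block; no
  region-to-region covariance priors at the group level.
- The LOO scheme reuses full-sample standardization constants and
  between-subject precisions (never outcome data); at n ~ 40 this is
  negligible, at very small n it would be optimistic.
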