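# Methods

## The model

`hipmsm` implements a continuous-time Markov multi-state model for
panel-observed hip osteoarthritis (OA) histories. A person occupies one
of five states:

| state | meaning |
|---|---|
| A | no radiographic hip OA (rHOA), no hip symptoms |
| B | asymptomatic rHOA (Kellgren–Lawrence grade ≥ 2, no symptoms) |
| C | hip symptoms only (no rHOA) |
| D | symptomatic hip OA (rHOA + symptoms in the same hip) |
| E | death (absorbing) |

Ten instantaneous transitions are allowed: A→B, A→C, C→A, C→D, B→D,
D→B among the living states plus death from each of A–D. Direct A↔D and
C↔B jumps are structural zeros — radiographic damage and symptoms are
modeled as arriving or resolving one at a time — but the corresponding
*panel* patterns (e.g. A at one visit, D at the next) keep positive
probability through intermediate states and stay in the likelihood.
rHOA itself never resolves, so states A and C are unreachable from B
and D; a panel file containing such a pair is reported as structurally
impossible rather than silently dropped.

Transition intensities follow the proportional-intensity convention

    q_rs(z, t) = q_rs0 · exp( β_rs' z(t) + γ_rs · 1{age(t) ≥ 65} ),

so `exp(β)` is a transition-specific adjusted hazard ratio (aHR) and
the indicator term makes the process piecewise exponential with one
changepoint at age 65, the age-inhomogeneity device of the source
study design. The changepoint is implemented as a transition-specific
coefficient on a time-dependent indicator rather than as fully separate
parameter sets per age band; the two parameterizations are equivalent
and the coefficient form avoids duplicating sparse cells. The process
time scale is years since each subject's baseline visit; baseline age
enters both as an adjustment covariate and through the changepoint
crossing time (the threshold is configurable).

## Likelihood

States are interval-censored: observed only at visits. Each consecutive
visit pair (t₀,s₀)→(t₁,s₁) contributes `log P[s₀,s₁](t₀,t₁)`, where `P`
is the product of matrix exponentials `exp(Q·Δ)` over the
constant-intensity segments of the interval. Segments arise from two
sources only: time-dependent covariates are carried forward from the
interval-start visit (so they never split an interval), and the age-65
crossing splits it at most once. A subject turning 65 exactly at the
interval end stays "under 65" for that interval (half-open convention).

Death times are exact (death-registry ascertainment). A death at t_d
after a last visit in state s contributes the density

    Σ_k  P[s,k](t_last, t_d) · q_kE(t_d),    k over living states,

with death-instant covariates taken from the last pre-death visit.
Subjects with fewer than two time points (visits plus the death event)
carry no transition information and are excluded with a warning.
Right-censoring at the last visit adds no extra term: living states are
fully observed at visits, so the final observed pair already carries
all the information.

## Estimation

Maximum likelihood on the unconstrained scale (log intensities, raw
coefficients). The fitting engine de-duplicates covariate patterns,
eigendecomposes each pattern's generator once per evaluation, and forms
every segment probability as `U diag(e^{wΔ}) U⁻¹`; the score is
analytic, via the eigenform of the Fréchet derivative of the matrix
exponential with a `sinh(x)/x` formulation near coincident eigenvalues.
Near-defective generators (eigenvector condition above 1e8) fall back
to scaling-and-squaring `expm`/`expm_frechet` segment by segment. The
public `transition_probability` always uses scaling-and-squaring; the
eigen fast path is cross-checked against it and against an independent
brute-force likelihood in the tests.

Optimization is deterministic: an intercepts-only L-BFGS-B warm-up,
L-BFGS-B on all free parameters (box bounds: log intensities in
[−16, 4], coefficients in [−8, 8], wide enough to be inactive at any
interior MLE), then Newton polishing with the finite-difference
observed information until the bound-projected gradient max-norm is
below 1e−5. Outside the box-feasible smooth region the objective is
kept finite by clipping log-intensities at 30 and flooring underflowed
probabilities at 1e−300-scale values; both devices are inactive at any
reasonable optimum and exist so line searches can recover from
overshoots. Transitions with no directly observed supporting pair are
frozen at the initialization floor (1e−3/year) with a warning, and
their rows are reported "not estimable". Crude initial values are
observed-pair counts divided by person-time in the source state.

Uncertainty: observed information by central finite differences of the
analytic score (step 1e−4), Wald 95% intervals on the log scale
(`exp(β̂ ± 1.96·SE)`). A result is flagged significant iff the 95% CI
excludes 1; no multiple-testing correction is applied, matching the
reporting convention of the analysis this package reproduces. In sparse
exposure cells the MLE can diverge (no events among the unexposed, for
example); the box bound then truncates it, the SE is large, and the
count columns in the output table make the degeneracy visible.

## Synthetic cohorts

The generator emulates a two-cohort community study of hip OA with
~6-year visit spacing. Defaults: baseline state mix 45/19/25/11%
(A/B/C/D); 33% African American, 39% men, 37% with under 12 years of
education, 71% original-cohort membership; baseline age N(62.2, 9.8)
truncated at 45; baseline obesity 40%, diabetes 14%, CVD 22%, hip
injury 6%; per-visit incidences 9% (DM), 12% (CVD), 3% (injury),
obesity onset 10% and remission 6% (DM/CVD/injury are absorbing,
obesity reversible); three follow-ups spaced max(2, N(6.0, 1.2)) years
with per-visit dropout 0.22 and a 19-year horizon. Baseline calendar
year is drawn per cohort (original ≈ U(1991, 1997), enrichment ≈
U(2003, 2004)) so mean-centered birth year is not collinear with
baseline age. Continuous covariates are written scaled: `age_base_c` =
(age − 62.2)/10 and `byear_c` = (birth year − 1935)/10, so coefficients
are per-decade log-HRs.

True baseline intensities (per person-year, reference person under 65)
are 0.020 (A→B), 0.026 (A→C), 0.035 (B→D), 0.090 (C→A), 0.020 (C→D),
0.060 (D→B), and 0.015/0.022/0.019/0.030 into death from A/B/C/D, with
age-65 log-multipliers of 0.3 on the progression transitions and ln 2
on the death transitions. These were calibrated once so that roughly a
quarter of state-A starters transition to OA/symptom states and ~43% of
them die over the horizon, with comorbidity frequencies roughly
doubling — the descriptive profile the generator emulates. Planted
comorbidity effects are literature-scale aHRs (obesity 1.33 on A→C,
1.46 on C→D; DM 0.74 on C→A, 0.64 on D→B; CVD 0.61 on C→A, 1.34 on
A→B, …); demographic coefficients default to zero.
`comorbidity_only_truth()` provides the same truth restricted to the
three comorbidity covariates for recovery and calibration studies
(well-specified because the omitted demographic effects are zero).

Simulation is exact: within each constant-intensity segment, sojourns
are competing exponentials (`Exponential(−Q[s,s])`, categorical
destination), so simulated panel frequencies converge to the matrix
exponential — the central simulator/engine consistency property that
the tests exploit in both directions. Death is ascertained to the
horizon even after dropout, like a death-registry linkage. Covariate
paths are updated only at retained visits, so the generated data follow
the carried-forward covariate model exactly and generate→fit studies
are well-specified.

What the generator does *not* emulate: radiographic reading error or
KLG grading, hip-level (versus person-level) status, hip replacement
events, informative dropout, and any real dependence of comorbidity
incidence on disease state or demographics. Passing recovery tests
therefore demonstrate correctness of the estimator under the stated
model, not robustness to those real-data features.

## Assessment

Model fit is assessed qualitatively by observed-versus-expected
prevalence: at each grid time (default yearly, 0–18), each living
subject contributes their most recent visit state, deaths occupy E from
their exact death time, and subjects past their last visit who are not
known dead leave the denominator. Expected curves propagate each
subject's baseline state through their own covariate path and average
over the same denominator. Note a property of this (standard)
convention: under loss to follow-up the denominator is informative —
a subject past their last visit re-enters only by dying — which tilts
observed death prevalence upward relative to the model expectation at
late times. Self-consistency checks of the machinery therefore use
dropout-free cohorts over the first ten years, where the selection is
negligible; on real-style data the curves are read qualitatively, as
intended.

## The analysis suite

`run_analysis` mirrors the full study design: one *individual* model
with obesity, DM and CVD entered jointly (time-dependent), three
*pairwise* models re-coding each pair into mutually exclusive
first-only/second-only/both indicators against the doubly-unexposed
reference while adjusting for the third comorbidity, and a *triple*
model coding an all-three indicator plus a partial (one-or-two)
indicator against the none-of-the-three reference — the partial group
keeps intermediate subjects from contaminating either extreme, and the
reported contrast is all-three versus none. All models share the
person-based adjustment set (baseline age, sex, race, education,
cohort, mean-centered birth year, time-dependent hip injury). Sex and
race strata re-fit the individual model on the subset with the
stratifying variable dropped; covariates constant within any fitted
subset are dropped with a log entry. Effects on death transitions are
estimated but excluded from default tables (`include_death_rows`
exposes them). A loss-to-follow-up sensitivity analysis re-fits the
plan on subjects with at least a given number of post-baseline visits
and tabulates aHR shifts side by side.

## Numerical choices and problem sizes

Tolerances: transition-probability rows sum to 1 within 1e−10 (the
kernel is clipped at 0 and renormalized, touching entries only at
round-off scale); expm agrees with a Kolmogorov-forward ODE oracle to
1e−8; convergence requires projected-gradient max-norm < 1e−5;
reparameterization invariance holds to ~1e−6 in the maximized
log-likelihood. The validation suite and `scripts/acceptance.py` use
simulation sizes chosen for a single CPU: 100 random generators for the
ODE oracle; 10 parameter sets × 10⁶ chains (tests) or 4 × 5·10⁵
(script) for Monte-Carlo likelihood checks; 100 replicates of n = 2000
(tests) or 40 (script) for recovery and coverage; 40 × n = 1000 (tests)
or 30 (script) for null calibration; n = 450–800 for the end-to-end
pipeline runs. Statistical tolerances are fixed by the check itself
(3 Monte-Carlo or binomial SEs; Wald coverage within [0.90, 0.98];
binomial test at α = 0.01) rather than by the problem size.

## Known limitations

* Interval-censored death (as opposed to exact death times) is not
  implemented; death ascertainment is assumed registry-exact.
* No hidden-Markov misclassification layer, semi-Markov sojourns, or
  more than two age bands.
* Wald intervals only (no profile likelihood or bootstrap); in very
  sparse exposure cells the bounded MLE and its Wald interval are
  untrustworthy and the table flags or exposes these via counts.
* The age-65 changepoint applies to all subjects at the same age, and
  covariate paths are step functions between visits by assumption.
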