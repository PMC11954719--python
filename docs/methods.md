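# Methods

## The interaction model

Atorvastatin disposition is a linear two-compartment system with first-order
elimination and zero-order (constant-rate) absorption into the central
compartment.  For a dose *A* given at time *t_d* the input rate is
`A·F(t_d)/D(t_d)` for a duration `D(t_d)`.  Micro-constants are
`k10 = CL/Vc`, `k12 = Q/Vc`, `k21 = Q/Vp`, and the hybrid rate constants
α > β > 0 satisfy α+β = k10+k12+k21 and αβ = k10·k21; the terminal
half-life is ln2/β.

Ritonavir acts through a CYP enzyme-turnover state E ∈ (0, 1] per pool
(gut wall and liver), the fraction of functional enzyme:

    dE/dt = k_deg·(1 − E) − k_inact·R(t)·E,   E(0) = 1

R(t) is the ritonavir presence function.  The default is a square wave equal
to 1 for 12 h after each ritonavir dose (so twice-daily dosing gives
continuous coverage); an optional driver replaces the square wave by a
normalized one-compartment ritonavir concentration.  While ritonavir is
continuously present E relaxes toward k_deg/(k_deg + k_inact); after the
last dose it recovers as 1 − (1−E₀)·exp(−k_deg·Δt) — mechanism-based
(irreversible) inhibition recovers only by enzyme synthesis.

The gut pool modulates each statin dose, with both mappings *frozen at the
dose time*:

    F(t_d) = F_base / (θ_F + (1 − θ_F)·E_gut(t_d))
    D(t_d) = D₀ · (1 + (θ_D − 1)·(1 − E_gut(t_d)))

These are the simplest saturable-free linear anchors with the right end
points: an untouched enzyme pool (E = 1) gives the baseline bioavailability
and absorption duration, a fully inactivated pool (E = 0) gives the fitted
modulation factors 1/θ_F = 1/0.57 = 1.75 and θ_D = 1.71.  Elimination is
constant by default; an optional clearance modulation
CL(t) = CL·(θ_CL + (1−θ_CL)·E_liver(t)) is retained as a testable switch
because the trial analysis tested and rejected a CL effect.

### Numerical solution

Because the disposition system is linear and time-invariant and F/D are
frozen per dose, the concentration is an exact superposition of
bi-exponential zero-order-infusion solutions: for each dose,

    C(τ) = (R₀/Vc)·[C₁(1−e^{−ατ})/α + C₂(1−e^{−βτ})/β]            (τ ≤ D)

with C₁ = (α−k21)/(α−β), C₂ = (k21−β)/(α−β), and the post-infusion tail
obtained by subtracting the same expression delayed by D.  The enzyme ODE
under square-wave R(t) has an exact piecewise-exponential solution.  The
default engine evaluates these closed forms (machine-precision accurate and
fast enough for repeated fitting); a stiff-capable `solve_ivp` integrator
(`engine="ode"`, LSODA, rtol 1e-8/atol 1e-10, dose times as breakpoints) is
kept as an independent cross-check — the test suite verifies agreement to
1e-6 relative — and is selected automatically when clearance modulation
makes the system time-varying.

### Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| CL/F | 561.2 | L/h | = 9353 mL/min, the baseline NCA apparent clearance of a 10-mg dose |
| Vc/F | 3500 | L | calibrated with Q, Vp so the baseline profile reproduces Cmax ≈ 2.3 ng/mL at Tmax ≈ 1.5 h and t½ ≈ 9.1 h on the trial's 17-point schedule |
| Q/F | 700 | L/h | see above |
| Vp/F | 2700 | L | see above |
| D₀ | 1.5 | h | apparent zero-order absorption time consistent with the observed Tmax |
| θ_F | 0.57 | – | fitted bioavailability denominator (1/0.57 = 1.75-fold at full inhibition) |
| θ_D | 1.71 | – | fitted absorption-duration factor |
| k_deg | 0.03 | 1/h | CYP3A turnover half-life ≈ 23 h, the conventional literature value |
| k_inact | 0.3 | 1/h | sized so gut enzyme falls below 10% of baseline within ~24 h of coverage, matching near-maximal inhibition after 24–48 h |
| ω (F_rel, CL/F, Vc/F) | 0.4 | log-SD | chosen to reproduce the spread of the reported 95% CIs within a factor ~2 |
| σ_prop | 0.15 | – | proportional residual error, typical for validated UPLC-MS/MS assays |

All defaults are overridable; ω and σ are assumptions (the trial's fitted
variability magnitudes are not published in the main text) and are labelled
as such.

### What the model does and does not reproduce

With the main-text parameterization the day-5/baseline AUC∞ ratio is capped
at 1/θ_F = 1.75 (the simulated trial gives ≈ 1.65 because gut enzyme sits at
≈ 0.09, not 0).  The observed 4.76-fold AUC increase therefore cannot be
reproduced from the absorption-side mechanism alone; the missing
contribution (hepatic OATP uptake inhibition) is not parameterized in the
published main-text model and we deliberately do not invent one.
`day5_exposure_ratio` exposes this gap rather than hiding it, and the
scenario-simulation checks are therefore property-based (orderings,
recovery, linearity) rather than anchored to the published fold-changes.

## Noncompartmental analysis

Lin-up/log-down trapezoid by default (linear when concentration rises or an
endpoint is zero, logarithmic between falling positive samples; the log
segment is exact for mono-exponential decay), pure-linear available by
flag.  λz is the log-linear OLS slope over the terminal subset of ≥3 points
strictly after Tmax (Cmax excluded) that maximizes adjusted R², ties broken
toward more points; a manual time-range override reproduces fixed choices.
AUC∞ adds C_pred(t_last)/λz using the regression-predicted (not observed)
last concentration, switchable.  CL/F = Dose/AUC∞ (reported in mL/min),
Vz/F = CL/λz (reported in L).  Tmax ties resolve to the earliest time.

BLQ handling: the default censoring rule sets BLQ samples before the first
quantifiable observation to zero and drops BLQ samples after it; drop-all
and half-LLOQ imputation are available.  The rule is a convention, not a
documented choice of the original analysis.

Total HMG-CoA-reductase inhibitory activity is the potency-weighted sum of
molar AUC∞ values (h·nmol/L); atorvastatin and its hydroxy metabolites carry
weight 1, N-desmethyl rosuvastatin 0.5, lactones 0.  The reported absolute
activity values cannot be reconstructed from per-analyte geometric means
(per-subject sums do not commute with geometric means and the printed unit
appears inconsistent by ~10⁶), so the operation implements the definition
and no test asserts the printed numbers.

## Exposure statistics

GMR = exp(mean of paired log differences) with a t-based CI (n−1 df, 90% by
default, standard bioequivalence practice) and a two-sided paired t-test on
the log scale.  Incomplete pairs are dropped listwise for GMR; geometric
means use all available values, mirroring per-parameter n.  The CI is
classified against the 0.80–1.25 bioequivalence bounds as
within/above/below/straddles.  The ratio–ratio regression runs on log ratios
by default.  Degenerate inputs (all paired differences identical) are
flagged rather than silently producing a zero-width CI from noise.

## Estimation

The original analysis used FOCEI mixed-effects estimation; this package
deliberately substitutes two transparent estimators:

* **Pooled**: all subjects share one parameter vector; Gaussian likelihood
  on log concentrations (proportional error ≡ additive on log scale) with
  the residual variance profiled out, so the optimizer minimizes log-scale
  SSR.  Parameters are transformed to enforce domains (log; logit for θ_F;
  log(θ_D − 1)).  Nelder–Mead (adaptive) followed by an L-BFGS-B polish;
  standard errors from a central-difference Hessian of −2LL via the delta
  method.  BLQ observations are excluded (M1 convention).
* **Two-stage**: per-subject fits of {F_rel, CL/F, Vc/F} with the remaining
  parameters at their initial values; the population estimate is the
  geometric mean of subject estimates and ω is the SD of subject log
  estimates.

With 17 samples per occasion the pooled estimates of the shared modulation
factors are comparable to mixed-effects estimates; the 20-seed recovery
experiment (see `scripts/acceptance.py`) recovers θ_D and 1/θ_F with medians
within a few percent of the generating values.  Caveats, verified by the
test suite: (i) with data truncated at 49 h the structural parameters CL,
Vp, Q lie on a likelihood ridge (slow distribution can mimic elimination),
so their pooled point estimates can wander while the θ factors — identified
by the within-subject occasion contrast — stay stable; (ii) two-stage ω
estimates inflate with residual noise because the subject-level
{F_rel, CL, Vc} estimates share the same ridge, so the degenerate-IIV check
(ω̂ < 0.02 when ω = 0) is run on noise-free subjects; (iii) pooled model
comparison on data with unmodeled IIV rewards any extra parameter, so the
no-clearance-modulation preference check runs without IIV.

## Regimen simulation

Once-daily statin at hour 0 of each day; ritonavir at hours 0 and 12 of
days 1–5 (clock times are grid conventions, not published).  A 7-day run-in
(≫ 5 half-lives of ~9 h) establishes steady state; the last run-in day is
the reference and its day-over-day AUC24 drift must be < 1%.  Metrics are
computed on a 0.05-h grid: per-day Cmax, Cmin, AUC24 and their ratios to the
reference day.  "Subtherapeutic" defaults to daily AUC24 below 50% of the
steady-state value (the threshold is configurable; the source uses the word
without a number).  The interruption scenario resumes the original dose on
day 8, two days after the last ritonavir dose; named scenarios restrict
fractions to {0, ¼, ½, 1} and the mixed taper encodes full/half/quarter/
half/full over days 1/2/3–6/7–9/10+.

## Virtual-trial generator

Emulates the paired trial: 8 subjects, 17-point schedule (0–49 h), 10-mg
doses, baseline and day-5 occasions, log-normal IIV on F_rel/CL/Vc
(ω = 0.4), residual error applied as exp(σ·z) (log-normal, the additive
log-scale counterpart of a proportional model), LLOQ censoring at the assay
limits (0.1 / 0.05 ng/mL).  Rosuvastatin occasions come from an empirical
one-compartment model in which ritonavir raises ka (0.65 → 6 /h) and shrinks
apparent V (÷1.65) with F and CL untouched — AUC preserved, Cmax ≈ 1.94-fold
up, Tmax earlier.  A one-compartment model cannot simultaneously match the
published baseline Cmax, Tmax and t½; the calibration preserves AUC∞, Tmax
and t½ and accepts a low absolute Cmax, since only statistics-level
behaviour (ratios) is asserted for rosuvastatin.  An optional outlier
injection rescales one subject's ritonavir-occasion concentrations to a
target exposure ratio (default 0.45), emulating the homozygous
poor-function-transporter carrier whose exposure fell during ritonavir.

What passing tests on generated data do **not** show: correctness of the
generator's variability magnitudes for real cohorts (ω, σ are assumptions),
any transporter genetics beyond the injected label, absorption-model
misspecification (real absorption is not exactly zero-order), or the
in-vivo fold-changes that depend on the unpublished hepatic-uptake
component.

## Problem sizes used in checks

Monte-Carlo scale choices made once for the shipped suites: the recovery
experiment uses 20 virtual trials; the GMR CI coverage check uses 1,000
simulated null cohorts; two-stage ω recovery uses 5 seeds and the
rosuvastatin no-AUC-change coverage check 10 seeds (both medians/counts, so
modest replication suffices); dense-grid AUC oracles use a 0.001-h grid.
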