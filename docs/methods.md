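# Methods

## Model

The package models the co-culture of cancer cells (density X) and CAR
T-cells (density Y) as a Lotka–Volterra variant:

    dX/dt = ρ X (1 − X/K) − κ₁ X Y
    dY/dt = κ₂ X Y − θ Y

Assumptions: the populations are well mixed; cancer growth is logistic
(space/media limited); killing follows mass action; tumour contact either
stimulates CAR T-cell proliferation (κ₂ > 0) or drives net exhaustion /
hypoactivation (κ₂ < 0), folded into the single rate κ₂; T-cell death is
first-order and independent of tumour density.  ρ, K, κ₁, θ ≥ 0; κ₂ is
free in sign.  Time is carried internally in days; plate readers report
hours, converted at ingestion.

Densities default to cell-index (CI) units, the impedance readout of an
RTCA instrument, which is approximately affine in adherent cell number up
to ~80% of confluency.  An affine calibration (slope in CI per cell)
converts between CI and cells at I/O; all density-scaled rates share the
unit of the instance (`unit_label`).

Rescaling τ = ρt, x = X/K, y = (κ₁/ρ)Y gives

    dx/dτ = x(1 − x) − xy,   dy/dτ = B xy − A y,
    A = θ/ρ,  B = κ₂K/ρ.

Equilibria: P1 = (0,0), P2 = (1,0), and P3 = (A/B, 1 − A/B) when
0 < A ≤ B.  When A ≈ 0 the whole y-axis is a line of equilibria; a point
(0, y) on it attracts iff y > 1 (dimensionally Y > ρ/κ₁).  Stability is
read from the analytic Jacobian; at P2 the eigenvalues are exactly
{−1, B − A}.  Case labels: A ≈ 0 & B > 0 → success, A ≈ 0 & B < 0 →
failure, 0 < A ≤ B → coexistence (damped oscillation into P3); all other
sign regions are reported as "other" rather than forced into a named
case.  A is "≈ 0" below 10⁻⁶ by default; the pipeline labels *fitted*
wells with a_tol = max(10⁻⁶, 10⁻³/ρ) because a fitted θ below
10⁻³ day⁻¹ — the resolution of a 4-day assay — is indistinguishable from
zero, and with the raw 10⁻⁶ threshold no real well would ever receive a
case-1/2 label.  Negative A is accepted by the phase-plane code for
exploration but lies outside the biological domain.

The initial-condition inequality Y₀ ≷ (ρ/κ₁)(1 − X₀/K) — algebraically
the sign of dX/dt at t = 0 — combined with the long-run regime yields the
transient labels (transient progression = pseudo-progression, transient
regression, monotone response/failure, boundary).

## Numerics

`solve_ivp` with LSODA, rtol 10⁻⁸ / atol 10⁻¹⁰ by default: trajectories
hug the invariant axes X = 0 and Y = 0, where mild stiffness appears.
Negative solver excursions are clamped to zero (the axes are invariant in
the exact system) and logged when they exceed atol.  The
simulation-based stability oracle integrates to τ = 400 with a terminal
escape event at radius 0.5, so exponential blow-ups of unstable
directions terminate early instead of overflowing.

## Preprocessing of plate data

The fit window for every well starts at the first sample at or after
`treat_time + spike_halfwidth` (default 24 h + 1 h): the first 24 h are
the attachment phase, and the sample at the treatment time carries a
plate-handling spike whose removal method is not standardised, so a 1-h
exclusion zone covers it.  The window ends before the first sample whose
CI exceeds `confluency_frac` (default 0.8) of a reference maximum,
because the CI–cell-number linearity fails near confluency.  The
reference is the well's own maximum by default; the pipeline passes the
cell line's untreated-well plateau for treated wells.  The plateau is a
property of the well packing, not of the treated trajectory: a
successfully killed well peaks far below confluency, and trimming at 80%
of its own low peak would discard the entire kill phase (measured: a
3-h window on wells whose CI peaks at ~25% of the plateau) while leaving
θ unidentifiable.  Untreated and failed-treatment wells are unaffected —
their own maximum is the plateau.

Down-sampling keeps, for each absolute multiple of the requested interval
(anchored at seeding, t = 0), the nearest sample, plus the first and last
samples of the series; anchoring at absolute multiples makes windowing
and down-sampling commute on aligned grids.

## Estimation

Stage 1 (untreated wells): ρ and K by bounded least squares on the
logistic closed form over the fit window, with X₀ fixed at the first
windowed observation (a two-parameter fit).  Analytic Jacobian; bounds
ρ ∈ [10⁻⁴, 50] day⁻¹, K ∈ (max CI, 10⁴ max CI).  Treated wells of a line
use the mean (ρ, K) of its untreated replicates; replicates are fitted
individually and summarised as mean ± sd.

Stage 2 (treated wells): κ₁, κ₂, θ by bounded least squares
(`scipy.optimize.least_squares`, trust-region reflective) on the
simulated X(t) against the windowed CI, i.e. RMSE minimisation.  Bounds:
κ₁ ∈ [0, 10³ρ/K], κ₂ ∈ [−10³ρ/K, 10³ρ/K], θ ∈ [0, 10] day⁻¹.  The
optimizer receives an exact Jacobian from the forward sensitivity
equations (an augmented 8-state ODE); this matters because θ is a nearly
flat direction on a 4-day horizon and finite-difference gradients stall
in it.  Initial conditions: X₀ is the observed CI at the window start
(not a free parameter); the T-cell inoculum Y₀ = seeding_count × E:T is
known at the treatment time, in CI units via the calibration slope (the
intercept models well-level offset, not per-population density, and is
not applied).  Because the window starts after the spike-exclusion gap,
Y at the window start is bridged from the dose with the exponential
predator solution Y(t₀) = Y₀ exp((κ₂·x̄ − θ)Δt), where x̄ is the
trapezoid average of the clean observed CI over the gap (the value at
the treatment time interpolated across the spiked samples; X is
continuous across the dose).  Taking Y₀ at the window start directly
would alias the gap's predator growth (~8% at these rates) into κ₁.  The
bridge's initial-condition sensitivities are propagated into the
Jacobian.  Integration failures inside the optimizer return a penalised
residual and are logged.

Convergence of a run requires optimizer success and no parameter pinned
at a non-trivial bound (κ₁ = 0 and θ = 0 are legitimate boundary optima
of the physical constraints and do not count as pinning).

R² is the squared Pearson correlation of observed versus predicted over
the fit window (the window, not the whole curve, because only windowed
samples enter the objective).

Multi-start uniqueness: log-uniform draws spanning ≥ 3 orders of
magnitude per parameter (sign-symmetric for κ₂), a fixed recorded seed,
and the per-parameter dispersion (max − min spread among converged runs
relative to the median magnitude) with a "unique" verdict below 1%.

θ resolution floor: fitted death rates below 10⁻³ day⁻¹ cannot be
distinguished from zero over 4 days, so dispersions and down-sampling
deviations of θ are measured against max(|θ|, 10⁻³ day⁻¹); a raw ratio
of two near-zero estimates is noise.

Down-sampling robustness refits each well on 2/5/10-h grids.  Coarse
refits are warm-started at the native estimate (refitting a sparser view
of the same recording is a refinement, not a fresh search) and reuse the
native-resolution dose bridge — the full-resolution trace always exists
when one down-samples it.  Deviations are reported per well relative to
the native fit, with the repeated-measures ANOVA p-value across wells
(interval as the within factor) alongside; the 10% deviation bound is
the gate, the ANOVA the context.

## Identifiability

Only X is observed: impedance does not separate the two adherent
populations.  The structural question — can (κ₁, κ₂, θ) be resolved from
X(t) alone — is answered locally and numerically: the sensitivity matrix
S[i,j] = ∂X(tᵢ)/∂pⱼ by central differences (relative step 10⁻⁶, solver
at rtol 10⁻¹² so integration noise stays far below the quotient), its
numerical rank (singular values above 10⁻⁸σ_max after scaling columns by
parameter magnitude), the condition number, and the smallest prefix of
observation times reaching full rank.  Together with multi-start
dispersion this tests the practical claim — a converged fit is unique —
without a symbolic differential-algebra derivation, which is out of
scope.

## Synthetic plates

`generate_plate` emulates the statistical structure the pipeline
assumes: a smoothstep attachment ramp reaching 1 exactly at 24 h (its
precise shape is immaterial — it lies outside every fit window), logistic
growth in CI units, predator–prey dynamics from the treatment time with
Y₀ = seeding × E:T, a single-sample +10% spike at the treatment sample
(applied plate-wide whenever the plate contains treated wells),
independent multiplicative (sd 2%) plus additive (sd 0.01 CI) Gaussian
noise, and an affine CI calibration (8 × 10⁻⁵ CI/cell, so 12.5 × 10³
seeded cells read ~1 CI).  Each well draws noise from a named substream
of the plate seed, so adding wells never perturbs existing ones.

The default plate encodes the study conditions the analysis targets:
three lines with growth rates 0.72, 1.07 and 2.1 day⁻¹ (seeded at
12.5 × 10³, 12.5 × 10³ and 2 × 10³ cells), E:T 1:5/1:10/1:20 in
triplicate, treatment at 24 h, 96 h of recording at 15-min resolution,
θ = 5 × 10⁻⁴ day⁻¹ (below the assay's 10⁻³ resolution), κ₁ decreasing
and κ₂ increasing with dose, and net exhaustion (κ₂ < 0) for the
fastest line — which also builds in the strong negative growth-rate–κ₂
correlation across lines.  The default arm is the BBζ product;
multipliers for a 28ζ arm and a hypoactivated mock arm (κ₂ < 0, ~5%
killing) are available but off by default so a default plate stays at
96-well scale.  κ-truths are chosen to reproduce the observed
qualitative kinetics (killing completes within ~60–100 h at high dose;
the exhaustion line shows transient regression then regrowth to
capacity).

What the generator does **not** emulate: autocorrelated drift in the
impedance readout (noise is independent sample to sample), CI
nonlinearity above confluency, cell detachment, attachment-phase spatial
dynamics, and any cytokine or microenvironment coupling.  Consequently,
passing recovery tests show the estimation machinery is correct and
well-conditioned under the assumed noise; they do not certify the model
against real-plate artefacts.  One measured consequence: under
independent 2% noise, coarsening a well to 8–16 samples inflates the
(κ₂, θ) estimator scatter by roughly √(n_native/n_coarse) ≈ 6×, so
per-well 10-h refits move κ₂ by ~18% and θ by more than its floor even
though the across-well ANOVA (the population-level claim) finds no
significant interval effect (p > 0.1 for all three rates).  With the
noise switched off, deviations are < 10⁻³ at all intervals.

## In vivo workflow

Tumour volumes from contrast-enhanced MRI segmentation are converted to
cell counts by dividing by the volume of a 20-µm sphere,
(4π/3)(10 µm)³ ≈ 4.19 × 10³ µm³ (1 mm³ ≈ 2.39 × 10⁵ cells).  ρ comes
from the first two pre-treatment scans as ln(N₂/N₁)/Δt — an exponential
approximation, because two points cannot constrain K and young lesions
sit far below capacity.  K is fixed at 10⁹ cells (tissue-scale order of
magnitude) and configurable.  Each infusion adds a fixed configured
fraction of the dose — 5–10%, the assumed share reaching any single
lesion — to Y instantaneously; the fraction is not fitted (it is
confounded with κ₁).  The state plus sensitivities are integrated
piecewise across dose events (X continuous, Y jumps; sensitivities are
continuous because the jump is parameter-free) and κ₁, κ₂, θ minimise
the RMSE on cell counts, with a small internal multi-start.  Annotated
therapy intervals (e.g. radiotherapy) are masked from the objective
rather than modelled.  Responding lesions of one patient can be fitted
jointly with shared kinetics (concatenated residuals, per-lesion ρ, X₀
and schedule).  Fitted per-cell rates multiplied by K land on the same
dimensionless B scale as the in vitro CI-unit fits, which is the sanity
check applied in the tests.  Without printed per-patient dose sizes and
volumes, the in vivo stage is validated by generate-then-fit recovery at
the clinically reported parameter magnitudes (κ₁ ~ 6 × 10⁻⁹, κ₂ ~
3 × 10⁻¹¹ day⁻¹cell⁻¹, θ ~ 10⁻⁶ day⁻¹), not against patient data.

## Problem sizes

The test suite and the acceptance script run everything at the study's
own scale: 36-well plates (27 treated fits), a 21 × 21 phase-plane grid
with a simulation oracle at every hyperbolic equilibrium, 100-start
uniqueness checks, down-sampling of all treated wells, and 12-point
lesion series — about a minute each on one core.

## Known limitations

* Local identifiability and multi-start dispersion substitute for a
  structural (symbolic) identifiability proof.
* θ is reported but effectively censored below 10⁻³ day⁻¹; analyses
  should treat small fitted θ as "≤ floor", not as an estimate.
* Under the independent-noise default, single-well parameter estimates
  from 10-h-sampled data are statistically unstable (see above); trust
  plate-level summaries at coarse sampling.
* The CI→cell calibration is affine and global per plate; per-line
  calibration differences are not modelled.
* No spatial, cytokine, myeloid or repeated-treatment extensions; no
  radiotherapy model (masked instead).
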