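# Methods

## Scales, cutoff and the voxelwise load estimator

Amyloid burden is carried on the amyloid-load scale (Aβ_L) and converted to
Centiloids by the affine map CL = 2.27·Aβ_L − 12.1. The A+ cutoff is
13.3 Aβ_L; the conversion puts this at 18.091 CL while the conventional
printed value is 18.0 CL — the 0.09 CL discrepancy comes from the printed
precision of the coefficients and is accepted (the constants class enforces
consistency only to 0.1 CL). A+ classification is boundary-inclusive
(burden ≥ 13.3 is positive), consistent with chronicity 0 being defined *at*
the cutoff.

At the image level, amyloid load is the specific-binding coefficient of an
ordinary least-squares decomposition of a masked SUVR image onto two
templates (Aβ carrying capacity and nonspecific binding). The fit is
deliberately unconstrained: a negative fitted load is physically implausible
but is reported as-is with a warning rather than clipped, so that QC can see
it. Which voxels count as "Aβ-carrying" is the caller's responsibility via
the mask.

## The SILA trajectory model

**Rate sampling.** Default strategy: adjacent-scan finite differences,
rate = Δburden/Δage assigned at the pair's mean burden. This keeps
within-subject curvature when a subject has 3–5 scans. A per-subject OLS
slope (assigned at the subject's mean burden) is available as
`rate_strategy="ols"` for cohorts where pairwise differences are too noisy.

**Field smoothing.** Windowed mean and SD over burden, window 5 Aβ_L, grid
step 1 Aβ_L by default. Empty windows are filled by linear interpolation
between populated neighbours, with constant extrapolation beyond the sampled
burden range. The smoothed mean rate is clipped below at 0.01 Aβ_L/yr before
integration: a zero or negative rate plateau would make the integrated curve
non-invertible, and the backward (pre-onset) branch must remain a bijection
for single-scan placement to be well defined.

**Integration.** Forward Euler with step 0.25 yr and at most 200 iterations
*per direction* (50 modeled years forward), anchored at
(chronicity 0, 13.3 Aβ_L). Each direction stops on a non-positive
interpolated rate, on a non-positive burden (backward), or at the iteration
cap. The per-direction reading of the iteration cap follows the forward
span's identification with "50 years of disease time"; the backward branch
in practice terminates earlier, where the floored rate drives burden toward
zero. Euler is first order: against a closed-form logistic rate field
(ρ = 0.1/yr, K = 100) the maximum deviation is ≈0.24 Aβ_L at the 0.25-yr
step and halves with the step (0.12 at 0.125 yr), peaking at the logistic
inflection. The production step is kept at 0.25 yr for fidelity to the
procedure being modeled, not because it is the most accurate choice.

**Placement.** Curve inversion uses monotone piecewise-linear interpolation.
Multi-scan subjects with an A+ scan are aligned rigidly at the first A+ scan
(ties at the exact cutoff broken by earliest age); multi-scan never-A+
subjects at their most recent scan; single-scan subjects by direct inversion
regardless of A+ status. Burdens outside the modeled range are clamped to
the nearest curve end and flagged `truncated` — those chronicities are
censoring bounds, not estimates, and downstream accuracy summaries exclude
them. Estimated onset age is exactly reference age minus reference
chronicity, so within-subject chronicity differences equal age differences.

## Tau analysis choices

Annualized percent change is relative to the baseline SUVR:
100·(f − b)/(b·Δt). Chronicity bins are left-closed/right-open. Bin CIs are
t-based (mean ± t₀.₉₇₅,ₙ₋₁·sd/√n); a bootstrap would also be defensible but
the t interval is exactly reproducible and adequate at these bin sizes.
Cohen's d uses the independent-groups form (pooled SD over baseline and
follow-up) with the normal-approximation CI se = √(2/n + d²/(4(2n−2))); the
paired form would give much narrower intervals than the wide intervals this
kind of small-bin analysis reports. Pearson CIs use the Fisher z transform;
empirical coverage at r = 0.5, n = 50 is ≈94–95% over 2000 simulations.
Comparisons between predictors (chronicity vs. age) are descriptive — no
dependent-correlation test is performed. Stage composites are
volume-weighted means over FreeSurfer regions; the default region→stage map
follows the common Braak-composite convention and is caller-replaceable.
Longitudinal extraction uses the baseline scan's stage membership for both
time points.

## What the synthetic generator emulates — and what it does not

The generator reproduces the study conditions the analysis assumes: 177
subjects; amyloid scan counts fixed exactly at {1: 58, 2: 64, 3: 15, 4: 30,
5: 10} and tau scan counts at {1: 75, 2: 92} (tau visits co-scheduled with
amyloid visits — baseline, plus the final visit for two-scan tau subjects);
visit gaps uniform on 2–3 yr; onset ages Gaussian (mean 41, SD 7) truncated
to the eligibility range [25, 70], giving the ~30–60-yr onset spread; first
visit ages drawn so the all-scan age distribution lands near 39 ± 8 yr.

The latent amyloid process solves dA/dt = r₀ + (r_max − r₀)·σ((A − m)/s)
with r₀ = 0.2, r_max = 3.73 Aβ_L/yr, m = 30 Aβ_L, s = 8 Aβ_L, anchored to
cross 13.3 Aβ_L at each subject's onset age — a rate plateau with no burden
plateau, matching the observed cohort-level shape. The rate field is a
function of burden, not of time, which is exactly the assumption SILA makes;
this means generator-based recovery tests validate the estimation machinery,
not that assumption itself. Tau SUVR per stage is hinge-linear in
chronicity: base + slope·max(0, chronicity − lag), lags (0, 0, 1, 3, 4, 5)
yr non-decreasing across stages I→VI (Braak ordering), slopes ≈2–3%/yr of
base for early stages. Noise is additive homoscedastic Gaussian: SD 1.5 Aβ_L
on burden and 0.05 SUVR on tau — the source study reports no noise model, so
these are stand-ins exposed in the config.

Features of real data deliberately *not* emulated: APOE effects on onset
(reported non-significant), dropout/attrition, scanner/site effects,
choroid-plexus spill-in and atrophy-driven late declines in medial-temporal
tau, and heteroscedastic or burden-dependent noise. Passing recovery tests
therefore show the pipeline is correct under its own assumptions, not that
those assumptions hold in any particular cohort.

## Numerical choices and degenerate inputs

Latent trajectories are solved with an adaptive Runge–Kutta integrator at
rtol/atol 1e-9, so the cutoff anchoring holds to <1e-6 Aβ_L; tests check it
against an independent fixed-step RK4 reference at dt = 0.001 yr. SUVR draws
are floored at 1e-3 (a ratio cannot be ≤ 0). Perfect correlations collapse
the Fisher CI to a point; zero pooled SD makes Cohen's d NA; empty bins and
cohorts with no multi-scan subject raise typed errors that the CLI maps to
exit code 3 (model) versus 2 (input/schema).

## Problem sizes

The test suite and acceptance checks run the full pipeline (177 subjects) at
20 seed replicates for the noise-recovery and tau-emergence properties, and
2000 simulations for CI coverage — sizes chosen to make the Monte-Carlo
assertions stable at fixed seeds while the whole suite stays fast
(≈20 s on one CPU).

## Known limitations

- Onset-age accuracy degrades for subjects far below the cutoff: burden
  noise (SD 1.5 Aβ_L) divided by pre-onset rates (~0.2–0.6 Aβ_L/yr) maps to
  several years of chronicity uncertainty, and below the sampled burden
  support the field is a constant extrapolation. Deep-subthreshold
  chronicities should be read as coarse.
- The rate field ignores covariates (age, sex, genotype) by design.
- `estimate` assumes one reference scan per subject; serial re-estimation as
  new scans arrive simply refits.
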