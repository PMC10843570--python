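# amychron

Amyloid-PET chronicity modeling and NFT-stage tau change analysis for
Down-syndrome-like longitudinal cohorts.

Nearly all adults with Down syndrome develop Alzheimer's-disease pathology,
but the age at which amyloid becomes abnormal varies by decades (~30–60
years), which makes chronological age a poor disease clock. `amychron`
replaces age with **A+ chronicity** — the estimated number of years an
individual has been amyloid-positive — and uses it to time the emergence of
tau pathology. It is aimed at imaging/biostatistics researchers who work with
longitudinal amyloid (PiB) and tau (flortaucipir) PET.

## The model

Global amyloid burden is the amyloid load metric Aβ_L, linearly related to
Centiloids by CL = 2.27·Aβ_L − 12.1, with amyloid positivity (A+) at
13.3 Aβ_L ≈ 18.0 CL. The trajectory model is a **sampled iterative local
approximation (SILA)**:

1. For every participant with ≥ 2 amyloid scans, sample the accumulation rate
   dA/dt discretely from burden-versus-age data (adjacent scan pairs,
   assigned at the pair's mean burden).
2. Smooth the samples into a rate-versus-burden field r(A) with a sliding
   burden window (mean ± SD per grid point).
3. Integrate r(A) by Euler's method (0.25-yr steps, ≤ 200 iterations per
   direction ≈ 50 modeled years forward) with the initial condition
   A(chronicity = 0) = 13.3 Aβ_L, giving one monotone burden-versus-time
   curve for the cohort.

Each participant is then placed on the curve — single-scan participants by
inverting the curve at their burden, multi-scan participants by rigid
alignment at their first A+ scan (or most recent scan if never A+) — and
their estimated A+ onset age is the age at the reference scan minus the
chronicity there. Longitudinal tau change in the six Braak/NFT stage
composites is annualized (% change relative to baseline per year), binned by
chronicity (<0, 0–2.5, 2.5–5, 5–10, >10 years) and summarized with t-based
95% CIs and Cohen's d effect sizes; cross-sectional tau is correlated with
age, burden and chronicity using Fisher-z CIs.

Because real cohort data of this kind are access-restricted, the package
ships a first-class synthetic cohort generator whose defaults emulate the
study conditions (177 participants, published amyloid/tau scan-count
distributions, 2–3-yr visit gaps, heterogeneous onset ages, a rate field that
plateaus at 3.73 Aβ_L/yr, and hinge-linear stage-ordered tau emergence).

## Worked example

```python
from amychron import CohortConfig, generate_cohort, SILAModel, run_tau_analysis

visits = generate_cohort(CohortConfig(seed=1))   # 177 subjects, long format
model = SILAModel().fit(visits)                   # rate field + trajectory curve
est = model.estimate(visits)                      # per-subject chronicity/onset
print(model.curve_.burden_at(0.0))                # 13.3  (anchored at the A+ cutoff)
print(est.onset_age.mean())                       # 41.1  yr mean estimated onset

res = run_tau_analysis(visits, est)
print(res["correlations"].query("stage == 1").round(2))
```

prints, for NFT stage I:

```
 predictor  stage    r  ci_low  ci_high   n
       age      1 0.62    0.52     0.71 167
       abl      1 0.88    0.84     0.91 167
chronicity      1 0.74    0.66     0.80 167
```

i.e. stage-I tau burden is more strongly associated with amyloid burden and
A+ chronicity than with chronological age. The bin summaries
(`res["bin_summaries"]`) show the same early emergence in time: stage-I
annualized % change is 0.66 [0.09, 1.22] %/yr before A+ onset versus
3.04 [1.95, 4.12] %/yr in the first 0–2.5 years after it.

The same pipeline is available from the shell:

```bash
amychron run-all --seed 1 --out-dir results/
# writes cohort.csv, curve.csv, estimates.csv,
#        correlations.csv, changes.csv, bin_summaries.csv
```

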