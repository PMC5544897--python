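# idioplan

Idiographic treatment planning and psychotherapy process monitoring from a
single patient's intensive symptom time series.

## The problem

Standard psychiatric diagnosis is cross-sectional: one retrospective
assessment, compared against group norms. For planning an individual
patient's psychotherapy this throws away the structure that matters — which
symptoms move together, and which symptoms *drive* other symptoms over
time. With smartphone-based ecological momentary assessment (EMA), a
patient can rate the same short symptom questionnaire several times a day
for a few weeks, yielding a T × I multivariate time series (T assessments,
I Likert-type items) for that one person.

`idioplan` turns such a series into a ranked list of per-symptom
**treatment-priority scores**, and provides the process-monitoring
statistics used to follow the therapy once it starts. It is a library
first (see `examples/`), with a thin `idioplan` CLI on top.

## The algorithm

Given a cleaned series, the planning pipeline runs five gated steps:

1. **Exploratory P-technique factor analysis.** Maximum-likelihood factoring
   of the patient's standardized item series, with direct-oblimin rotation
   (latent symptom dimensions are expected to correlate). Candidates with
   k = 2, 3, 4 factors are fitted; a candidate passes when TLI ≥ .95 and
   RMS ≤ .08, and the smallest passing k wins.
2. **Confirmatory factor analysis.** Items with exploratory pattern loadings
   |λ| > .30 define the confirmatory measurement model
   Σ = ΛΦΛ′ + Θ (factor variances fixed at 1, correlations free), fitted by
   ML and gated on TLI ≥ .95 and SRMR ≤ .08.
3. **Vector autoregression.** Factor scores f_t = Z_t W (standardized items ×
   weighting matrix, default W = Λ̂) are modelled per equation as
   f_t = c + τ·t + A₁f_{t−1} + … + A_p f_{t−p} + ε_t, with the lag order
   p ∈ 1..5 chosen by AIC on a common estimation sample.
4. **Factor scores.** Each factor's *within-time* variance share
   (Σ_i λ_ij² / k²) is multiplied by its *between-time* share (ΔR² of the
   lag block over the intercept+trend model), and the products are
   normalized so the dominant factor scores exactly 1.
5. **Symptom scores.** Item means (raw scale), normalized by the largest
   mean, are weighted by Σ_j λ_ij · factorscore_j and rescaled so the top
   item scores exactly 100. High scorers are severe, belong to dominant
   factors, and sit upstream in the lagged dynamics.

If any gate fails the result is an explicit `no_model` with diagnostics —
an honest outcome, not an error.

Monitoring statistics: moving-window **dynamic complexity** C = F·D
(fluctuation intensity × value-distribution evenness, both in [0, 1]),
unthresholded **recurrence matrices** of Euclidean distances, **LOESS**
trend curves with pointwise 95% bands, and weekly percent-change outcome
scores.

A fully parameterized **synthetic-patient generator** (latent VAR(p) with
oblique innovations → loadings → observation noise → Likert rounding →
missingness) with retained ground truth makes every stage testable without
patient data; presets `two-factor-dominant`, `pure-noise`, and
`three-factor` cover the main study conditions.

## Worked example

```bash
python examples/plan_synthetic_patient.py
```

prints (seed 7; a dominant factor behind items 1–5, a secondary factor
behind items 6–9, 10% missingness):

```
simulated series: 120 assessments x 10 items, 9.8% missing

Treatment planning report
=========================

Symptom priorities (descending):
  100.00  item4
   94.79  item1
   93.07  item2
   92.79  item3
   86.65  item5
   40.75  item6
   38.69  item7
   32.36  item9
   23.83  item8
   14.11  item10

Factor model: k=2, exploratory TLI=0.981, RMS=0.050; confirmatory TLI=0.980, SRMR=0.060
  Factor 1: within=61.86%, between=9.07%, score=1.000
  Factor 2: within=52.42%, between=7.94%, score=0.742

VAR: p=1, per-equation R2=0.091, 0.116
```

The five generating dominant-factor items head the table (priority 87–100):
they are rated most severely and load on the factor whose past values carry
the most information about the system's future, so treating them first
promises the largest spillover onto the remaining symptoms. The same
pipeline is available from the shell:

```bash
idioplan simulate --preset two-factor-dominant --T 120 --seed 7 --out series.csv --truth truth.json
idioplan plan --input series.csv --config patient.json --out report.json
idioplan monitor --input series.csv --config patient.json --item item1
```

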