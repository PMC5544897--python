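# Methods

This note documents the statistical model behind `idioplan`, the numerical
choices made where the procedure was genuinely open, what the synthetic
generator does and does not emulate, and the package's known limitations.

## Data model and cleaning

The raw input is one patient's T × I matrix of Likert-type symptom ratings
with strictly increasing timestamps and declared scale bounds. All
downstream fitting treats the ratings as continuous and the observations as
equally spaced in index order; a warning is emitted when timestamp gaps
deviate more than 50% from the modal gap, but the index-order convention is
kept (daily-life sampling is rarely perfectly regular, and the VAR stage
needs a single lag unit).

Missing responses are handled by a deliberately conservative two-step rule:
internal per-item gaps of length ≤ `max_gap` (default 1) are linearly
interpolated, and any row still incomplete afterwards is dropped. Every
action is tallied in a `CleaningReport` so the preprocessing is auditable.
Interpolation keeps the time axis usable for the VAR; the default of a
single step means at most one assessment in a row is ever fabricated per
item. Assessment schedules split the patient's waking window into equal
parts, wake and sleep inclusive (a single daily assessment sits at the
window midpoint).

## Exploratory stage

Maximum-likelihood factor analysis of the item correlation matrix, fitted
through the likelihood concentrated over the uniquenesses ψ: for fixed ψ
the optimal loadings follow from the eigenstructure of ψ^{−1/2} S ψ^{−1/2},
so only the I-dimensional ψ is optimized (L-BFGS-B on log ψ, two starts —
flat 0.5 and squared-multiple-correlation-based — with ψ floored at 0.005;
hitting the floor is flagged as a Heywood case). Oblique rotation uses the
gradient-projection algorithm with the quartimin criterion (direct oblimin,
γ = 0); factors are sign-aligned so each factor's largest-magnitude loading
is positive.

Fit: χ² = (T − 1 − (2I+5)/6 − 2k/3)·F with F the ML discrepancy (Bartlett's
correction, mirroring the R factor-analysis convention), df =
[(I−k)² − (I+k)]/2, TLI against the independence model (whose discrepancy
is −log|S|), RMS as the root mean square of off-diagonal residuals of
S − Σ̂. Candidates k = 2, 3, 4 are fitted and gated jointly on TLI ≥ .95
and RMS ≤ .08 (the canonical joint cutoffs; both configurable); the
smallest passing k is selected. The cap at four factors matches the
reference procedure and is configurable.

Two behaviours of this stage on degenerate data are worth knowing. On
near-noise data the independence model itself fits, making TLI numerically
unstable (a ratio of two near-zero quantities) — the gate can then pass
vacuously; the pipeline is protected by the later pattern gate, which
requires at least two loadings > .30 per factor. And ML factoring of noise
readily produces single-item Heywood factors; these are flagged, floored,
and typically eliminated by the same pattern gate.

## Confirmatory stage

The exploratory pattern is hardened by the strict rule |λ| > .30: items
under the threshold on every factor are excluded, items above it on several
factors keep all those cross-loadings. The resulting model
Σ(θ) = ΛΦΛ′ + Θ is estimated by ML on the standardized included items
(L-BFGS-B over free loadings, the k(k−1)/2 factor correlations, and
residual variances bounded below at 0.005; factor variances fixed at 1 for
identification; non-positive-definite Φ proposals rejected inside the
objective). χ² = (T−1)·F without Bartlett correction — the confirmatory
convention of the SEM tooling this stage mirrors. SRMR uses all unique
elements of the standardized residual matrix, diagonal included. The gate
is TLI ≥ .95 and SRMR ≤ .08.

Factor scores are the standardized included items times a weighting
matrix. The default weighting is the estimated loading matrix itself
(matching the worked procedure's description); regression (Thurstone)
weights Σ̂^{−1}ΛΦ are available as an option. Loading-matrix weights are
simpler and rank-preserving but do not correct for item overlap; the
option exists precisely because the two conventions disagree in general.

## VAR stage

Per-equation OLS of each factor score on an intercept, a linear trend in
the observation index (1-based), and lags 1..p of all factors. The lag
order p ∈ 1..5 minimizes AIC = T_eff·log|Σ̂_res| + 2·(estimated
coefficients) on a common estimation sample: the first `max_lag` rows are
held out for every candidate so the criteria are comparable; ties break
toward the smaller order. Coefficient inference uses ordinary OLS t tests;
reports flag edges with two-sided p < .05. Synchronous association between
factors is reported as the residual correlation.

The *between-time* variance share of a factor is ΔR²: the R² of its full
equation minus the R² of the intercept+trend-only equation on the same
rows, clipped to [0, 1]. This operationalizes "variance explained by the
auto- and cross-regressive parameters, net of trend" as a bounded,
well-defined quantity; a sum-of-squared-coefficients reading was rejected
as unbounded. The trend regressor deliberately absorbs slow drift so the
lagged terms are not credited with it.

## Scoring algebra

Within-time share of factor j: Σ_i λ_ij² / k². The divisor k² (rather than
the verbally more obvious k) is the reading that reproduces the reference
worked example's printed percentages from its printed loading matrix; the
literal /k variant is available behind `literal_within_divisor`. Factor
scores are the products within × between normalized by their maximum (the
dominant factor scores exactly 1). Symptom scores: raw item means (on the
original rating scale, computed after cleaning) normalized by the largest
mean, times Σ_j λ_ij·factorscore_j over the factors the pattern assigns
the item to, rescaled to a maximum of exactly 100 and sorted descending.
Excluded items are listed but unscored. Ties in the normalizing maxima are
broken by first index; scores are unaffected.

The pipeline is deterministic given the input and options, and the
priority scores are invariant to a positive rescaling of all ratings
(means normalize out; standardization absorbs scale).

## Monitoring statistics

Dynamic complexity per moving window of width m (default 7, the 5–7 range
being conventional) on a scale of range R:

* F = [Σ |Δy|/Δsteps over successive points of return] / [R·(m−1)], where
  points of return are the window's first point, last point, and interior
  direction reversals (a plateau's reversal is attributed to its start).
  Full-range alternation at every step gives F = 1; a monotone uniform
  full-range ramp gives F = 1/(m−1)²; a flat window gives 0.
* D = max(0, 1 − Σ|g_i − R/(m−1)|/R) over the m−1 gaps g_i of the sorted
  window values: evenly spread values covering the scale give 1, constant
  windows give 0.
* C = F·D ∈ [0, 1], assigned to the window's last index (causal alignment,
  usable in real time).

These concrete formulas are this package's documented definition of the
concept; the literature states the idea (fluctuation × distribution in a
moving window) without a canonical printed formula, so exact numerical
agreement with other implementations is not claimed, and both components
are exposed so alternative definitions can be swapped in.

Recurrence matrices are unthresholded Euclidean distance matrices
(absolute differences in the univariate case). LOESS is degree-1 with the
tricube kernel and span 0.75 by default; the 95% band uses the global
residual variance estimate RSS/(n − 2tr(L) + tr(L′L)) and the norm of each
local weight vector, assuming locally Gaussian residuals. Weekly outcome
change is the plain percent change against the previous week and is
undefined at a zero previous score.

## Synthetic patients

The generator draws a k-variate VAR(p) with innovation correlation Φ,
discards a 50-step burn-in, rescales the latents to unit stationary
standard deviation (computed exactly from the discrete Lyapunov equation
on the companion form, so loadings stay interpretable on the correlation
scale), adds an optional linear trend, maps to items via Λ, adds
independent N(0, σ²) observation noise, shifts by the item baseline means,
rounds to the Likert grid and clamps to the scale bounds. Missingness is
injected cell-wise (or row-wise, emulating skipped assessments) at a
configurable rate; the ~10% default used in examples matches reported
daily-assessment compliance in the literature this pipeline targets.

Presets: `two-factor-dominant` (loadings .70–.85 on items 1–5 vs .65–.75 on
items 6–9, a weak tenth item below the pattern threshold, Φ₁₂ = .3,
autoregression .55 on the dominant factor with a .30 cross-lag onto the
secondary one, item means ≈6 vs ≈3 on the 0–8 scale, noise SD 0.6);
`pure-noise` (zero loadings — the pipeline should refuse a model); and
`three-factor` (three clean triplets, for factor-count selection). These
values were fixed once as a realistic strong-structure regime for a 10-item
EMA scale assessed three times daily over several weeks.

What the generator does *not* emulate: ordinal thresholding of a latent
normal (items are rounded, not probit-discretized), time-varying loadings,
diurnal cycles, autocorrelated measurement error, and informative
(state-dependent) missingness. Passing recovery tests therefore show the
pipeline is correct under its own assumptions — not that real EMA data
satisfy those assumptions.

## Problem sizes used in the test suite

Recovery properties use T = 500 (50 seeds for confirmatory-loading RMSE,
10 for exploratory congruence), VAR coefficient bias uses T = 1000 over 50
seeds, and the end-to-end ranking property uses 100 synthetic patients of
T = 120 — sizes at which the asymptotic tolerances quoted in the tests are
comfortably attained while the whole suite stays quick on one core.

## Known limitations

* The ML χ² statistics assume independent observations; P-technique data
  are serially dependent, so the fit gates are heuristic screens, not
  calibrated tests. This mirrors the procedure being reimplemented.
* TLI is unstable when the independence model fits (near-noise data); see
  the exploratory-stage notes.
* With loading-matrix weights, factor scores contain measurement error,
  which attenuates VAR coefficients and hence between-time shares — the
  occasional dominance flip between closely matched factors at T ≈ 120 is
  the visible consequence.
* Likert responses are treated as continuous throughout; no polychoric or
  robust (categorical) estimators are provided.
* The between-time ΔR² definition is one defensible reading of
  "variance explained by the lagged parameters"; other decompositions
  (e.g. generalized variance shares) would give different absolute values,
  though typically the same dominance ordering.
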