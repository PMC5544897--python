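"""Ground-truth recovery: the generator and the fitting stages agree.

Simulates a patient from a known 2-factor structure and shows that the
exploratory stage recovers the generating loadings, the confirmatory stage
reproduces the factor correlation, and the VAR stage finds the lagged
structure — the property chain every pipeline stage is tested on.
"""

import numpy as np

from idioplan import (
    build_pattern,
    clean_timeseries,
    factor_score_series,
    fit_cfa,
    fit_var,
    preset,
    select_lag,
    select_model,
    simulate_patient,
)

truth = preset("two-factor-dominant")
ts, truth = simulate_patient(truth, T=500, seed=11)
cleaned, report = clean_timeseries(ts)
print(f"simulated T={cleaned.n_obs}, true k={truth.k_true}, "
      f"true VAR lag p={truth.p}")

efa = select_model(cleaned)
print(f"\nexploratory stage selected k={efa.k} "
      f"(TLI={efa.fit.tli:.3f}, RMS={efa.fit.rms:.3f})")
print("largest loading per item (true nonzero pattern is items 1-5 / 6-9):")
print(np.round(np.abs(efa.loadings).max(axis=1), 2))

pattern = build_pattern(efa)
cfa = fit_cfa(cleaned, pattern)
print(f"\nconfirmatory factor correlation phi12 = {cfa.phi[0, 1]:.3f} "
      f"(generator innovation correlation {truth.phi[0, 1]:.2f})")

fs = factor_score_series(cleaned, cfa)
p = select_lag(fs)
var = fit_var(fs, p)
print(f"\nVAR: selected lag p={p}, per-equation R2 = {np.round(var.r2, 3)}")
print("significant lagged edges (source -> target, lag, coefficient):")
for edge in var.significant_edges():
    print("  ", edge)
print("\nThe dominant factor's strong autoregression and its cross-lagged "
      "push on the second factor mirror the generating coefficients.")
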