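"""Vector autoregression on the factor-score series.

Stage 3 of the planning pipeline.  Each factor's score series is regressed
on an intercept, a linear trend in the observation index, and lags 1..p of
all factors (per-equation OLS, the classical VAR estimator).  The lag order
is chosen by AIC over p = 1..5 on a common estimation sample, so the
criteria are comparable across candidates.  Per-equation R², coefficient
t tests, the residual correlation (the factors' synchronous association),
and the trend-adjusted lagged-variance share ΔR² feed the scoring stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .errors import CollinearityError, SampleSizeError

__all__ = [
    "FactorScoreSeries",
    "VarModel",
    "select_lag",
    "fit_var",
    "lagged_block_r2",
]


@dataclass
class FactorScoreSeries:
    """T x k matrix of per-assessment factor scores."""

    scores: np.ndarray
    factor_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.scores = np.atleast_2d(np.asarray(self.scores, dtype=float))
        if np.isnan(self.scores).any():
            raise ValueError("factor scores must not contain missing values")
        if not self.factor_labels:
            self.factor_labels = [
                f"Factor {j + 1}" for j in range(self.scores.shape[1])
            ]

    @property
    def n_obs(self) -> int:
        return self.scores.shape[0]

    @property
    def k(self) -> int:
        return self.scores.shape[1]


@dataclass
class VarModel:
    """Estimated VAR(p) with trend; coefficient layout follows the design
    matrix: A[j, i, l] maps factor i at t-(l+1) to factor j at t."""

    p: int
    A: np.ndarray  # k x k x p lag coefficients
    intercept: np.ndarray  # k
    trend: np.ndarray | None  # k slopes per index step, None if no trend
    se: np.ndarray  # k x n_regressors OLS standard errors
    tstat: np.ndarray
    pval: np.ndarray
    r2: np.ndarray  # k per-equation R²
    aic: float
    resid_cov: np.ndarray  # k x k
    resid_corr: np.ndarray  # synchronous associations
    factor_labels: list[str]
    n_obs_used: int

    def significant_edges(self, alpha: float = 0.05) -> list[tuple[str, str, int, float]]:
        """(source, target, lag, coefficient) for lag terms with p < alpha."""
        k = self.A.shape[0]
        offset = 1 + (1 if self.trend is not None else 0)
        out = []
        for j in range(k):
            for l in range(self.p):
                for i in range(k):
                    col = offset + l * k + i
                    if self.pval[j, col] < alpha:
                        out.append(
                            (
                                self.factor_labels[i],
                                self.factor_labels[j],
                                l + 1,
                                float(self.A[j, i, l]),
                            )
                        )
        return out


def _design(
    y: np.ndarray, p: int, trend: bool, start: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Stack regressors [1, t, y_{t-1}, ..., y_{t-p}] for rows start..T-1."""
    t_total, k = y.shape
    s = p if start is None else start
    rows = np.arange(s, t_total)
    cols = [np.ones(len(rows))]
    if trend:
        cols.append(rows.astype(float) + 1.0)  # 1-based observation index
    for lag in range(1, p + 1):
        cols.append(y[rows - lag])
    X = np.column_stack([c if c.ndim > 1 else c[:, None] for c in cols])
    return X, y[rows], rows


def fit_var(
    fs: FactorScoreSeries, p: int, trend: bool = True, start: int | None = None
) -> VarModel:
    """Per-equation OLS estimation of a VAR(p) with optional linear trend.

    ``start`` fixes the first estimated row (used during lag selection to
    hold the estimation sample constant across candidates).
    """
    y = fs.scores
    t_total, k = y.shape
    s = p if start is None else start
    n_coef_eq = 1 + int(trend) + k * p
    if t_total - s < n_coef_eq + 1:
        raise SampleSizeError(
            f"T={t_total} too small for VAR({p}) with {n_coef_eq} regressors"
        )
    X, Y, _ = _design(y, p, trend, start=s)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise CollinearityError("singular regressor matrix in VAR fit")
    t_eff = X.shape[0]
    A = np.zeros((k, k, p))
    intercept = np.zeros(k)
    tr = np.zeros(k) if trend else None
    se = np.zeros((k, X.shape[1]))
    tstat = np.zeros_like(se)
    pval = np.zeros_like(se)
    r2 = np.zeros(k)
    resid = np.zeros((t_eff, k))
    offset = 1 + int(trend)
    for j in range(k):
        fit = sm.OLS(Y[:, j], X).fit()
        beta = fit.params
        intercept[j] = beta[0]
        if trend:
            tr[j] = beta[1]  # type: ignore[index]
        for l in range(p):
            A[j, :, l] = beta[offset + l * k : offset + (l + 1) * k]
        se[j] = fit.bse
        tstat[j] = fit.tvalues
        pval[j] = fit.pvalues
        r2[j] = fit.rsquared
        resid[:, j] = fit.resid
    resid_cov = (resid.T @ resid) / t_eff
    d = np.sqrt(np.diag(resid_cov))
    d = np.where(d == 0, 1.0, d)
    resid_corr = resid_cov / np.outer(d, d)
    sign, logdet = np.linalg.slogdet(resid_cov)
    aic = t_eff * (logdet if sign > 0 else -np.inf) + 2 * k * n_coef_eq
    return VarModel(
        p=p,
        A=A,
        intercept=intercept,
        trend=tr,
        se=se,
        tstat=tstat,
        pval=pval,
        r2=r2,
        aic=float(aic),
        resid_cov=resid_cov,
        resid_corr=resid_corr,
        factor_labels=list(fs.factor_labels),
        n_obs_used=t_eff,
    )


def select_lag(
    fs: FactorScoreSeries, max_lag: int = 5, trend: bool = True
) -> int:
    """Smallest-AIC lag order over 1..max_lag on a common estimation sample.

    The first ``max_lag`` rows are held out as pre-sample for every
    candidate; ties break toward the smaller order.
    """
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    aics = []
    for p in range(1, max_lag + 1):
        model = fit_var(fs, p, trend=trend, start=max_lag)
        aics.append(model.aic)
    return int(np.argmin(aics)) + 1


def lagged_block_r2(fs: FactorScoreSeries, model: VarModel) -> np.ndarray:
    """Trend-adjusted lagged variance share per equation.

    ΔR² = R²(intercept + trend + lags) − R²(intercept + trend only), both on
    the model's own estimation sample; clipped to [0, 1].  This isolates the
    variance genuinely carried by the auto- and cross-regressive terms.
    """
    y = fs.scores
    t_total, k = y.shape
    start = t_total - model.n_obs_used
    trend = model.trend is not None
    X_full, Y, rows = _design(y, model.p, trend, start=start)
    base_cols = 1 + int(trend)
    X_base = X_full[:, :base_cols]
    delta = np.zeros(k)
    for j in range(k):
        full = sm.OLS(Y[:, j], X_full).fit()
        base = sm.OLS(Y[:, j], X_base).fit()
        delta[j] = full.rsquared - base.rsquared
    return np.clip(delta, 0.0, 1.0)
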