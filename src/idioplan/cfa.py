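"""Confirmatory P-factor analysis.

Stage 2 of the planning pipeline.  The exploratory solution is hardened
into a confirmatory model: an item is kept on a factor only when its
exploratory pattern loading exceeds a threshold (default .30, strict), the
resulting measurement model Sigma = Lambda Phi Lambda' + Theta is estimated
by maximum likelihood on the standardized included items (factor variances
fixed at 1, factor correlations free), and the fit is gated on TLI and
SRMR.  The estimated loading matrix doubles as the factor-score weighting
matrix; regression (Thurstone) weights are available as an option.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .efa import (
    FactorModel,
    FitIndices,
    ml_discrepancy,
    standardize,
    _srmr,
    _tucker_lewis,
)
from .errors import ConvergenceError, UnidentifiedModelError, ValidationError
from .timeseries import SymptomTimeSeries
from .var import FactorScoreSeries

__all__ = [
    "CfaPattern",
    "CfaModel",
    "build_pattern",
    "fit_cfa",
    "cfa_passes",
    "factor_score_series",
]

THETA_FLOOR = 0.005


@dataclass
class CfaPattern:
    """Which item measures which factor, per the loading-threshold rule."""

    k: int
    included: list[list[str]]  # per factor, item ids
    excluded_items: list[str]

    @property
    def included_items(self) -> list[str]:
        """All modelled items, in first-appearance order."""
        seen: list[str] = []
        for items in self.included:
            for i in items:
                if i not in seen:
                    seen.append(i)
        return seen

    def as_terms(self) -> list[str]:
        """Render the pattern in 'Factor j = Item a + Item b' report syntax."""
        return [
            f"Factor {j + 1} = " + " + ".join(items)
            for j, items in enumerate(self.included)
        ]


@dataclass
class CfaModel:
    """Estimated confirmatory measurement model on standardized items."""

    pattern: CfaPattern
    loadings: np.ndarray  # I' x k, zero where the pattern excludes the pair
    phi: np.ndarray  # k x k factor correlations, unit diagonal
    theta: np.ndarray  # I' residual variances
    item_ids: list[str]  # included items, row order of `loadings`
    fit: FitIndices
    weights: np.ndarray  # I' x k factor-score weighting matrix
    heywood: bool = False
    item_means: np.ndarray | None = None  # raw-scale means, for scoring
    item_sds: np.ndarray | None = None

    def implied_correlation(self) -> np.ndarray:
        s = self.loadings @ self.phi @ self.loadings.T
        out = s.copy()
        np.fill_diagonal(out, np.diag(s) + self.theta)
        return out


def build_pattern(
    efa: FactorModel, threshold: float = 0.30
) -> CfaPattern:
    """Assign item i to factor j iff |Lambda_ij| > threshold (strict).

    Items that reach no factor are excluded.  A factor left with fewer than
    two indicators makes the confirmatory model under-identified.
    """
    lam = np.abs(efa.loadings)
    included: list[list[str]] = []
    for j in range(efa.k):
        items = [efa.item_ids[i] for i in np.flatnonzero(lam[:, j] > threshold)]
        included.append(items)
    assigned = {i for items in included for i in items}
    excluded = [i for i in efa.item_ids if i not in assigned]
    for j, items in enumerate(included):
        if len(items) < 2:
            raise UnidentifiedModelError(
                f"factor {j + 1} has {len(items)} indicator(s); need >= 2"
            )
    return CfaPattern(k=efa.k, included=included, excluded_items=excluded)


def _free_loading_mask(pattern: CfaPattern, item_ids: list[str]) -> np.ndarray:
    mask = np.zeros((len(item_ids), pattern.k), dtype=bool)
    for j, items in enumerate(pattern.included):
        for i in items:
            mask[item_ids.index(i), j] = True
    return mask


def fit_cfa(
    ts: SymptomTimeSeries | np.ndarray,
    pattern: CfaPattern,
    weighting: str = "loadings",
    max_iter: int = 2000,
) -> CfaModel:
    """ML estimation of the confirmatory model on standardized data.

    ``weighting`` selects the factor-score weighting matrix: ``"loadings"``
    (the estimated pattern loadings, the default) or ``"regression"``
    (Thurstone weights Sigma^-1 Lambda Phi).
    """
    if isinstance(ts, SymptomTimeSeries):
        if ts.mask.any():
            raise ValidationError("series must be cleaned (no missing values)")
        frame = ts.to_frame()
        all_ids = list(ts.item_ids)
        x_full = frame.to_numpy()
    else:
        x_full = np.asarray(ts, dtype=float)
        all_ids = [f"item{i + 1}" for i in range(x_full.shape[1])]
    item_ids = [i for i in all_ids if i in set(pattern.included_items)]
    missing = [i for i in pattern.included_items if i not in all_ids]
    if missing:
        raise ValidationError(f"series lacks items required by pattern: {missing}")
    cols = [all_ids.index(i) for i in item_ids]
    x = x_full[:, cols]
    t, p = x.shape
    k = pattern.k
    mask = _free_loading_mask(pattern, item_ids)
    n_lam = int(mask.sum())
    n_phi = k * (k - 1) // 2
    n_free = n_lam + n_phi + p
    df = p * (p + 1) // 2 - n_free
    if df < 0:
        raise UnidentifiedModelError("more free parameters than moments")
    if t <= n_free:
        raise ValidationError("need more observations than free parameters")
    z = standardize(x)
    S = np.corrcoef(z, rowvar=False)
    tri = np.tril_indices(k, -1)

    def unpack(theta_vec: np.ndarray):
        lam = np.zeros((p, k))
        lam[mask] = theta_vec[:n_lam]
        phi = np.eye(k)
        phi[tri] = theta_vec[n_lam : n_lam + n_phi]
        phi.T[tri] = phi[tri]
        resid = theta_vec[n_lam + n_phi :]
        return lam, phi, resid

    def objective(theta_vec: np.ndarray) -> float:
        lam, phi, resid = unpack(theta_vec)
        if k > 1 and np.linalg.eigvalsh(phi)[0] <= 1e-8:
            return 1e6
        sigma = lam @ phi @ lam.T + np.diag(resid)
        return ml_discrepancy(S, sigma)

    x0 = np.concatenate(
        [np.full(n_lam, 0.6), np.full(n_phi, 0.2), np.full(p, 0.5)]
    )
    bounds = (
        [(-2.0, 2.0)] * n_lam
        + [(-0.995, 0.995)] * n_phi
        + [(THETA_FLOOR, 10.0)] * p
    )
    res = optimize.minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": max_iter, "ftol": 1e-14, "gtol": 1e-10},
    )
    if not np.isfinite(res.fun):
        raise ConvergenceError("CFA optimization failed")
    if res.nit >= max_iter:
        raise ConvergenceError(f"CFA did not converge in {max_iter} iterations")
    lam, phi, resid = unpack(res.x)
    heywood = bool(np.any(resid <= THETA_FLOOR * (1 + 1e-6)))
    if heywood:
        warnings.warn("Heywood case: residual variance at floor", stacklevel=2)
    # sign-align each factor (largest-|loading| positive)
    for j in range(k):
        idx = np.argmax(np.abs(lam[:, j]))
        if lam[idx, j] < 0:
            lam[:, j] *= -1.0
            phi[j, :] *= -1.0
            phi[:, j] *= -1.0
            np.fill_diagonal(phi, 1.0)
    sigma = lam @ phi @ lam.T + np.diag(resid)
    F = ml_discrepancy(S, sigma)
    chi2 = (t - 1) * F
    _, logdet_s = np.linalg.slogdet(S)
    chi2_null = (t - 1) * float(-logdet_s)
    df_null = p * (p - 1) // 2
    fit = FitIndices(
        chi2=float(chi2),
        df=df,
        chi2_null=float(chi2_null),
        df_null=df_null,
        tli=_tucker_lewis(chi2, df, chi2_null, df_null),
        rms=float(
            np.sqrt(np.mean((S - sigma)[~np.eye(p, dtype=bool)] ** 2))
        ),
        srmr=_srmr(S, sigma),
    )
    if weighting == "loadings":
        weights = lam.copy()
    elif weighting == "regression":
        weights = np.linalg.solve(sigma, lam @ phi)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=1)
    return CfaModel(
        pattern=pattern,
        loadings=lam,
        phi=phi,
        theta=resid,
        item_ids=item_ids,
        fit=fit,
        weights=weights,
        heywood=heywood,
        item_means=means,
        item_sds=sds,
    )


def cfa_passes(
    model: CfaModel, tli_min: float = 0.95, srmr_max: float = 0.08
) -> bool:
    """Joint Hu–Bentler gate on the confirmatory fit."""
    fit = model.fit
    return bool(np.isfinite(fit.tli) and fit.tli >= tli_min and fit.srmr <= srmr_max)


def factor_score_series(
    ts: SymptomTimeSeries | np.ndarray, model: CfaModel
) -> FactorScoreSeries:
    """Per-assessment factor scores: standardized included items x weights."""
    if isinstance(ts, SymptomTimeSeries):
        if ts.mask.any():
            raise ValidationError("series must be cleaned before scoring")
        all_ids = list(ts.item_ids)
        x_full = ts.values
    else:
        x_full = np.asarray(ts, dtype=float)
        all_ids = [f"item{i + 1}" for i in range(x_full.shape[1])]
    try:
        cols = [all_ids.index(i) for i in model.item_ids]
    except ValueError as exc:
        raise ValidationError(f"series lacks a modelled item: {exc}") from exc
    z = standardize(x_full[:, cols])
    scores = z @ model.weights
    labels = [f"Factor {j + 1}" for j in range(model.pattern.k)]
    return FactorScoreSeries(scores=scores, factor_labels=labels)
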