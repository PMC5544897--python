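"""Exploratory P-technique factor analysis with maximum likelihood.

Stage 1 of the planning pipeline.  The patient's standardized item series is
factored by maximum likelihood (the "P-technique": variables x occasions for
a single person), candidate models with 2, 3 and 4 factors are fitted, an
oblique (oblimin) rotation is applied because latent symptom dimensions are
expected to correlate, and each candidate is gated on joint Hu–Bentler
criteria (TLI and the root mean squared residual of the correlation
matrix).  The passing model with the fewest factors wins.

The ML fit uses the concentrated likelihood over uniquenesses: for fixed
uniqueness vector psi the optimal loadings follow from the eigenstructure of
psi^{-1/2} S psi^{-1/2}, so only the I-dimensional psi is optimized
numerically (the same strategy as R's ``factanal``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from ._rotation import oblimin_rotate
from .errors import ConvergenceError, UnidentifiedModelError, ValidationError
from .timeseries import SymptomTimeSeries

__all__ = [
    "FitIndices",
    "FactorModel",
    "NoModel",
    "fit_efa",
    "efa_fit_indices",
    "select_model",
    "standardize",
    "ml_discrepancy",
]

PSI_FLOOR = 0.005  # Heywood-case floor on uniquenesses


@dataclass
class FitIndices:
    """Likelihood-ratio fit summary of a factor model."""

    chi2: float
    df: int
    chi2_null: float
    df_null: int
    tli: float
    rms: float
    srmr: float


@dataclass
class FactorModel:
    """Rotated exploratory factor solution on standardized items."""

    k: int
    loadings: np.ndarray  # I x k rotated pattern matrix
    phi: np.ndarray  # k x k factor correlations
    uniquenesses: np.ndarray  # I
    item_ids: list[str]
    fit: FitIndices | None = None
    heywood: bool = False
    dropped_items: list[str] = field(default_factory=list)

    @property
    def communalities(self) -> np.ndarray:
        return 1.0 - self.uniquenesses

    def implied_correlation(self) -> np.ndarray:
        """Model-implied correlation matrix Lambda Phi Lambda' + Theta."""
        s = self.loadings @ self.phi @ self.loadings.T
        out = s.copy()
        np.fill_diagonal(out, np.diag(s) + self.uniquenesses)
        return out


@dataclass
class NoModel:
    """Sentinel returned when no candidate factor model passes the gate."""

    diagnostics: dict[int, str] = field(default_factory=dict)

    def __bool__(self) -> bool:  # allows `if model:` gating
        return False


def standardize(x: np.ndarray) -> np.ndarray:
    """Z-score columns (ddof=1), the scale on which all factoring happens."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd


def ml_discrepancy(S: np.ndarray, sigma: np.ndarray) -> float:
    """ML discrepancy F = log|Sigma| + tr(S Sigma^-1) - log|S| - I."""
    p = S.shape[0]
    sign, logdet_sig = np.linalg.slogdet(sigma)
    if sign <= 0:
        return np.inf
    _, logdet_s = np.linalg.slogdet(S)
    return float(logdet_sig + np.trace(S @ np.linalg.inv(sigma)) - logdet_s - p)


def _efa_degrees_of_freedom(p: int, k: int) -> int:
    return ((p - k) ** 2 - (p + k)) // 2


def _concentrated_objective(log_psi: np.ndarray, S: np.ndarray, k: int) -> float:
    """Profile ML criterion: sum over trailing eigenvalues of (lam - log lam - 1)."""
    psi = np.exp(log_psi)
    d = 1.0 / np.sqrt(psi)
    Sstar = S * np.outer(d, d)
    lam = np.linalg.eigvalsh(Sstar)[::-1]
    tail = lam[k:]
    tail = np.clip(tail, 1e-12, None)
    return float(np.sum(tail - np.log(tail) - 1.0))


def _loadings_from_psi(psi: np.ndarray, S: np.ndarray, k: int) -> np.ndarray:
    d = 1.0 / np.sqrt(psi)
    Sstar = S * np.outer(d, d)
    lam, vec = np.linalg.eigh(Sstar)
    order = np.argsort(lam)[::-1][:k]
    lam_k = np.clip(lam[order] - 1.0, 0.0, None)
    A = vec[:, order] * np.sqrt(lam_k)
    return A * np.sqrt(psi)[:, None]


def fit_efa(
    ts: SymptomTimeSeries | np.ndarray,
    k: int,
    rotate: bool = True,
    max_iter: int = 1000,
) -> FactorModel:
    """Maximum-likelihood exploratory factor analysis with oblimin rotation.

    Zero-variance items are dropped with a warning; Heywood cases are
    flagged and floored at ``PSI_FLOOR``.  Loadings are sign-aligned so each
    factor's largest-magnitude loading is positive.
    """
    if isinstance(ts, SymptomTimeSeries):
        if ts.mask.any():
            raise ValidationError("series must be cleaned (no missing values)")
        x = ts.values
        item_ids = list(ts.item_ids)
    else:
        x = np.asarray(ts, dtype=float)
        item_ids = [f"item{i + 1}" for i in range(x.shape[1])]
    t, p0 = x.shape
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    dropped = [item_ids[j] for j in np.flatnonzero(~keep)]
    if dropped:
        warnings.warn(f"dropping zero-variance items: {dropped}", stacklevel=2)
        x = x[:, keep]
        item_ids = [i for i, ok in zip(item_ids, keep) if ok]
    p = x.shape[1]
    if _efa_degrees_of_freedom(p, k) < 0:
        raise UnidentifiedModelError(
            f"{k}-factor model on {p} items has negative degrees of freedom"
        )
    if t <= p:
        raise ValidationError("need more observations than items (T > I)")
    z = standardize(x)
    S = np.corrcoef(z, rowvar=False)
    S = np.atleast_2d(S)

    # multi-start on the uniquenesses; keep the best converged solution
    starts = [np.full(p, 0.5), np.clip(1.0 - _smc(S), 0.05, 0.95)]
    best = None
    for psi0 in starts:
        res = optimize.minimize(
            _concentrated_objective,
            np.log(psi0),
            args=(S, k),
            method="L-BFGS-B",
            bounds=[(np.log(PSI_FLOOR), np.log(1.0))] * p,
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("EFA optimization failed")
    if best.nit >= max_iter:
        raise ConvergenceError(f"EFA did not converge in {max_iter} iterations")
    psi = np.exp(best.x)
    heywood = bool(np.any(psi <= PSI_FLOOR * (1 + 1e-6)))
    if heywood:
        warnings.warn(
            "Heywood case: uniqueness at floor for at least one item", stacklevel=2
        )
    psi = np.maximum(psi, PSI_FLOOR)
    A = _loadings_from_psi(psi, S, k)

    if rotate and k > 1:
        lam, phi, _ = oblimin_rotate(A)
    else:
        lam, phi = A.copy(), np.eye(k)
    # sign-align: largest-|loading| entry of each factor positive
    for j in range(k):
        idx = np.argmax(np.abs(lam[:, j]))
        if lam[idx, j] < 0:
            lam[:, j] *= -1.0
            phi[j, :] *= -1.0
            phi[:, j] *= -1.0
    model = FactorModel(
        k=k,
        loadings=lam,
        phi=phi,
        uniquenesses=psi,
        item_ids=item_ids,
        heywood=heywood,
        dropped_items=dropped,
    )
    model.fit = efa_fit_indices(model, S, t)
    return model


def _smc(S: np.ndarray) -> np.ndarray:
    """Squared multiple correlations, the classical communality start."""
    try:
        inv = np.linalg.inv(S)
        return 1.0 - 1.0 / np.diag(inv)
    except np.linalg.LinAlgError:
        return np.full(S.shape[0], 0.5)


def efa_fit_indices(model: FactorModel, S: np.ndarray, T: int) -> FitIndices:
    """Bartlett-corrected chi-square, TLI against the independence model,
    RMS of off-diagonal residuals, and SRMR over all unique elements."""
    p = S.shape[0]
    k = model.k
    df = _efa_degrees_of_freedom(p, k)
    if df <= 0:
        raise UnidentifiedModelError("model has non-positive degrees of freedom")
    sigma = model.implied_correlation()
    F = ml_discrepancy(S, sigma)
    chi2 = max((T - 1 - (2 * p + 5) / 6.0 - 2 * k / 3.0), 1.0) * F
    _, logdet_s = np.linalg.slogdet(S)
    F_null = float(-logdet_s)
    df_null = p * (p - 1) // 2
    chi2_null = max((T - 1 - (2 * p + 5) / 6.0), 1.0) * F_null
    tli = _tucker_lewis(chi2, df, chi2_null, df_null)
    resid = S - sigma
    off = resid[~np.eye(p, dtype=bool)]
    rms = float(np.sqrt(np.mean(off**2)))
    srmr = _srmr(S, sigma)
    return FitIndices(
        chi2=float(chi2),
        df=df,
        chi2_null=float(chi2_null),
        df_null=df_null,
        tli=tli,
        rms=rms,
        srmr=srmr,
    )


def _tucker_lewis(chi2: float, df: int, chi2_null: float, df_null: int) -> float:
    c_null = chi2_null / df_null
    c_model = chi2 / df
    denom = c_null - 1.0
    if denom == 0:
        return float("nan")
    return float((c_null - c_model) / denom)


def _srmr(S: np.ndarray, sigma: np.ndarray) -> float:
    """SRMR over all unique elements of the standardized residual matrix,
    diagonal included."""
    d = np.sqrt(np.diag(S))
    resid = (S - sigma) / np.outer(d, d)
    iu = np.triu_indices_from(resid)
    return float(np.sqrt(np.mean(resid[iu] ** 2)))


def select_model(
    ts: SymptomTimeSeries | np.ndarray,
    candidates: tuple[int, ...] = (2, 3, 4),
    tli_min: float = 0.95,
    rms_max: float = 0.08,
) -> FactorModel | NoModel:
    """Fit candidate factor counts and return the smallest passing model.

    A candidate passes when TLI >= ``tli_min`` and RMS <= ``rms_max``; a
    candidate whose fit raises is treated as non-passing.  Returns
    :class:`NoModel` (falsy) with per-candidate diagnostics when nothing
    passes.
    """
    diagnostics: dict[int, str] = {}
    for k in sorted(candidates):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = fit_efa(ts, k)
        except (ConvergenceError, UnidentifiedModelError, ValidationError) as exc:
            diagnostics[k] = f"fit failed: {exc}"
            continue
        fit = model.fit
        assert fit is not None
        if np.isfinite(fit.tli) and fit.tli >= tli_min and fit.rms <= rms_max:
            return model
        diagnostics[k] = f"TLI={fit.tli:.3f}, RMS={fit.rms:.3f}"
    return NoModel(diagnostics=diagnostics)
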