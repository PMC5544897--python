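"""Treatment-priority scoring and pipeline orchestration.

Stages 4–5 of the planning pipeline, plus the end-to-end driver.

Step 4 condenses each latent factor into a single relevance score: the
within-time variance share (how much item variance the factor explains
synchronously, from the confirmatory loadings) is multiplied by the
between-time variance share (how much variance its auto- and
cross-regressive VAR terms explain beyond intercept and trend, ΔR²), and
the products are normalized by their maximum so the dominant factor scores
exactly 1.

Step 5 turns factor relevance into per-symptom priorities: each item's raw
mean rating is normalized by the largest item mean, multiplied by the sum
over the factors it measures of (loading × factor score), and the results
are rescaled so the top item scores exactly 100.  High-priority items are
severe, belong to dominant factors, and sit upstream in the lagged
dynamics — treating them first promises the largest spillover.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cfa as cfa_mod
from . import efa as efa_mod
from . import var as var_mod
from .errors import (
    ConvergenceError,
    DegenerateScoresError,
    IdioplanError,
    InsufficientDataError,
    SampleSizeError,
    UnidentifiedModelError,
)
from .timeseries import CleaningReport, PatientConfig, SymptomTimeSeries, clean_timeseries

__all__ = [
    "PlanningOptions",
    "PlanningScores",
    "PriorityTable",
    "PlanningResult",
    "within_time_variance",
    "factor_scores",
    "symptom_scores",
    "run_planning",
    "render_report",
]


@dataclass
class PlanningOptions:
    """Tunable thresholds of the pipeline; defaults follow the published
    procedure (Hu–Bentler joint cutoffs, .30 pattern threshold, lags 1–5)."""

    min_measurements: int = 40
    max_gap: int = 1
    loading_threshold: float = 0.30
    tli_min: float = 0.95
    rms_max: float = 0.08
    srmr_max: float = 0.08
    max_lag: int = 5
    trend: bool = True
    candidates: tuple[int, ...] = (2, 3, 4)
    literal_within_divisor: bool = False
    weighting: str = "loadings"


@dataclass
class PlanningScores:
    """Per-factor variance shares and normalized relevance scores."""

    within: np.ndarray  # fraction of item variance, per factor
    between: np.ndarray  # trend-adjusted lagged ΔR², per factor
    raw_factor: np.ndarray  # within * between
    factor_score: np.ndarray  # raw / max(raw), max exactly 1


@dataclass
class PriorityTable:
    """Ranked symptom priorities; ``table`` is sorted descending by score."""

    table: pd.DataFrame  # item_id, item_text, mean, norm_mean, contribution, symptom_score
    excluded_items: list[str] = field(default_factory=list)


@dataclass
class PlanningResult:
    status: str  # "found" | "no_model"
    diagnostics: list[str]
    efa: efa_mod.FactorModel | None = None
    cfa: cfa_mod.CfaModel | None = None
    var: var_mod.VarModel | None = None
    scores: PlanningScores | None = None
    priorities: PriorityTable | None = None
    cleaning: CleaningReport | None = None


def within_time_variance(
    model: cfa_mod.CfaModel, literal_divisor: bool = False
) -> np.ndarray:
    """Within-time variance share per factor from the confirmatory loadings.

    share_j = sum_i Lambda_ij^2 / k^2.  The k^2 divisor reproduces the
    published worked example; ``literal_divisor=True`` selects the plain /k
    variant instead.
    """
    k = model.pattern.k
    div = k if literal_divisor else k * k
    return np.sum(model.loadings**2, axis=0) / div


def factor_scores(within: np.ndarray, between: np.ndarray) -> PlanningScores:
    """Multiply the two variance shares and normalize by the maximum."""
    within = np.asarray(within, dtype=float)
    between = np.asarray(between, dtype=float)
    if np.any(within < 0) or np.any(between < 0):
        raise ValueError("variance shares must be non-negative")
    raw = within * between
    top = raw.max()
    if top <= 0:
        raise DegenerateScoresError("all factor products are zero")
    return PlanningScores(
        within=within, between=between, raw_factor=raw, factor_score=raw / top
    )


def symptom_scores(
    ts: SymptomTimeSeries,
    model: cfa_mod.CfaModel,
    fscores: PlanningScores,
) -> PriorityTable:
    """Per-item priority scores on a 0–100 scale.

    Item means are taken on the raw (unstandardized) ratings of the cleaned
    series; an item's contribution sums loading × factor score over every
    factor the pattern assigns it to.  Items the pattern excluded get no
    score and are listed separately.
    """
    frame = ts.to_frame()
    texts = dict(zip(ts.item_ids, ts.item_texts))
    included = model.item_ids
    means = frame[included].mean(axis=0).to_numpy()
    top_mean = means.max()
    if top_mean <= 0:
        raise DegenerateScoresError("all item means are zero")
    norm_means = means / top_mean
    mask = cfa_mod._free_loading_mask(model.pattern, included)
    contrib = (model.loadings * mask) @ fscores.factor_score
    q = norm_means * contrib
    top_q = np.max(q)
    if top_q <= 0:
        raise DegenerateScoresError("all raw item scores are zero")
    scores = 100.0 * q / top_q
    table = pd.DataFrame(
        {
            "item_id": included,
            "item_text": [texts.get(i, i) for i in included],
            "mean": means,
            "norm_mean": norm_means,
            "contribution": contrib,
            "symptom_score": scores,
        }
    ).sort_values("symptom_score", ascending=False, kind="stable")
    table = table.reset_index(drop=True)
    excluded = [i for i in ts.item_ids if i not in set(included)]
    return PriorityTable(table=table, excluded_items=excluded)


def run_planning(
    ts: SymptomTimeSeries,
    config: PatientConfig | None = None,
    options: PlanningOptions | None = None,
) -> PlanningResult:
    """Run the full planning pipeline with its three fit gates.

    Returns ``status="found"`` with all stage results when every gate
    passes, or ``status="no_model"`` with diagnostics naming the failed
    gate.  A series shorter than ``min_measurements`` raises
    :class:`InsufficientDataError` instead — that is a data-collection
    problem, not a modelling outcome.
    """
    opt = options or PlanningOptions()
    diag: list[str] = []
    cleaned, report = clean_timeseries(ts, max_gap=opt.max_gap)
    diag.append(
        f"cleaning: {report.n_rows_in} rows in, {report.n_rows_out} out, "
        f"{report.interpolated_cells} cells interpolated"
    )
    if cleaned.n_obs < opt.min_measurements:
        raise InsufficientDataError(
            f"{cleaned.n_obs} measurements after cleaning; "
            f"minimum is {opt.min_measurements}"
        )

    efa = efa_mod.select_model(
        cleaned, candidates=opt.candidates, tli_min=opt.tli_min, rms_max=opt.rms_max
    )
    if isinstance(efa, efa_mod.NoModel):
        for k, msg in efa.diagnostics.items():
            diag.append(f"exploratory gate failed for k={k}: {msg}")
        return PlanningResult(status="no_model", diagnostics=diag, cleaning=report)
    diag.append(
        f"exploratory gate passed: k={efa.k}, TLI={efa.fit.tli:.3f}, "
        f"RMS={efa.fit.rms:.3f}"
    )

    try:
        pattern = cfa_mod.build_pattern(efa, threshold=opt.loading_threshold)
    except UnidentifiedModelError as exc:
        diag.append(f"confirmatory gate failed: pattern under-identified ({exc})")
        return PlanningResult(
            status="no_model", diagnostics=diag, efa=efa, cleaning=report
        )
    try:
        cfa = cfa_mod.fit_cfa(cleaned, pattern, weighting=opt.weighting)
    except (ConvergenceError, UnidentifiedModelError, IdioplanError) as exc:
        diag.append(f"confirmatory gate failed: {exc}")
        return PlanningResult(
            status="no_model", diagnostics=diag, efa=efa, cleaning=report
        )
    if not cfa_mod.cfa_passes(cfa, tli_min=opt.tli_min, srmr_max=opt.srmr_max):
        diag.append(
            f"confirmatory gate failed: TLI={cfa.fit.tli:.3f}, "
            f"SRMR={cfa.fit.srmr:.3f}"
        )
        return PlanningResult(
            status="no_model", diagnostics=diag, efa=efa, cfa=cfa, cleaning=report
        )
    diag.append(
        f"confirmatory gate passed: TLI={cfa.fit.tli:.3f}, SRMR={cfa.fit.srmr:.3f}"
    )

    fs = cfa_mod.factor_score_series(cleaned, cfa)
    try:
        p = var_mod.select_lag(fs, max_lag=opt.max_lag, trend=opt.trend)
        var = var_mod.fit_var(fs, p, trend=opt.trend)
    except (SampleSizeError, IdioplanError) as exc:
        diag.append(f"VAR stage failed: {exc}")
        return PlanningResult(
            status="no_model", diagnostics=diag, efa=efa, cfa=cfa, cleaning=report
        )
    diag.append(f"VAR fitted: p={p}, R2=" + np.array2string(var.r2, precision=3))

    between = var_mod.lagged_block_r2(fs, var)
    within = within_time_variance(cfa, literal_divisor=opt.literal_within_divisor)
    try:
        scores = factor_scores(within, between)
        priorities = symptom_scores(cleaned, cfa, scores)
    except DegenerateScoresError as exc:
        diag.append(f"scoring failed: {exc}")
        return PlanningResult(
            status="no_model",
            diagnostics=diag,
            efa=efa,
            cfa=cfa,
            var=var,
            cleaning=report,
        )
    diag.append("scoring complete")
    return PlanningResult(
        status="found",
        diagnostics=diag,
        efa=efa,
        cfa=cfa,
        var=var,
        scores=scores,
        priorities=priorities,
        cleaning=report,
    )


def _round_list(arr, nd=6):
    return [round(float(v), nd) for v in np.asarray(arr).ravel()]


def result_to_dict(result: PlanningResult) -> dict:
    """Lossless-enough JSON view of a planning result (floats rounded to 6
    decimals for bitwise-stable reports)."""
    out: dict = {"status": result.status, "diagnostics": result.diagnostics}
    if result.cleaning is not None:
        out["cleaning"] = {
            "n_rows_in": result.cleaning.n_rows_in,
            "n_rows_out": result.cleaning.n_rows_out,
            "missing_rate": round(result.cleaning.missing_rate, 6),
            "interpolated_cells": result.cleaning.interpolated_cells,
            "dropped_rows": result.cleaning.dropped_rows,
        }
    if result.efa is not None:
        out["exploratory"] = {
            "k": result.efa.k,
            "tli": round(result.efa.fit.tli, 6),
            "rms": round(result.efa.fit.rms, 6),
        }
    if result.cfa is not None:
        out["confirmatory"] = {
            "terms": result.cfa.pattern.as_terms(),
            "excluded_items": result.cfa.pattern.excluded_items,
            "loadings": [_round_list(row) for row in result.cfa.loadings],
            "phi": [_round_list(row) for row in result.cfa.phi],
            "tli": round(result.cfa.fit.tli, 6),
            "srmr": round(result.cfa.fit.srmr, 6),
        }
    if result.var is not None:
        out["var"] = {
            "p": result.var.p,
            "r2": _round_list(result.var.r2),
            "aic": round(result.var.aic, 6),
            "significant_edges": [
                [src, dst, lag, round(coef, 6)]
                for src, dst, lag, coef in result.var.significant_edges()
            ],
        }
    if result.scores is not None:
        out["factor_scores"] = {
            "within": _round_list(result.scores.within),
            "between": _round_list(result.scores.between),
            "score": _round_list(result.scores.factor_score),
        }
    if result.priorities is not None:
        out["priorities"] = [
            {
                "item_id": row.item_id,
                "item_text": row.item_text,
                "symptom_score": round(float(row.symptom_score), 6),
            }
            for row in result.priorities.table.itertuples()
        ]
        out["unscored_items"] = result.priorities.excluded_items
    return out


def render_report(result: PlanningResult) -> tuple[str, str]:
    """Render a planning result as (plain text, JSON string).

    The JSON is a deterministic serialization of :func:`result_to_dict`;
    the text report shows the priority table, factor summary, and VAR
    summary a practitioner would read.
    """
    data = result_to_dict(result)
    lines: list[str] = ["Treatment planning report", "=" * 25]
    if result.status == "found":
        assert result.priorities is not None and result.scores is not None
        lines.append("")
        lines.append("Symptom priorities (descending):")
        for row in result.priorities.table.itertuples():
            lines.append(f"  {row.symptom_score:6.2f}  {row.item_text}")
        if result.priorities.excluded_items:
            lines.append(
                "  (unscored items: "
                + ", ".join(result.priorities.excluded_items)
                + ")"
            )
        lines.append("")
        lines.append(
            f"Factor model: k={result.efa.k}, exploratory TLI="
            f"{result.efa.fit.tli:.3f}, RMS={result.efa.fit.rms:.3f}; "
            f"confirmatory TLI={result.cfa.fit.tli:.3f}, "
            f"SRMR={result.cfa.fit.srmr:.3f}"
        )
        for j, s in enumerate(result.scores.factor_score):
            lines.append(
                f"  Factor {j + 1}: within={100 * result.scores.within[j]:.2f}%, "
                f"between={100 * result.scores.between[j]:.2f}%, score={s:.3f}"
            )
        lines.append("")
        lines.append(
            f"VAR: p={result.var.p}, per-equation R2="
            + ", ".join(f"{v:.3f}" for v in result.var.r2)
        )
    else:
        lines.append("")
        lines.append("No satisfactory model was found.")
        for d in result.diagnostics:
            lines.append(f"  {d}")
    text = "\n".join(lines) + "\n"
    return text, json.dumps(data, sort_keys=True)
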