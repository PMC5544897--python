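"""Patient symptom time series: containers, CSV I/O, cleaning, schedules.

A patient answers the same short Likert-type symptom questionnaire several
times a day for a few weeks.  The resulting T x I table (T assessments,
I items) is the sole raw input of the treatment-planning pipeline.  This
module reads and validates such tables, linearly interpolates short internal
gaps, drops rows that remain incomplete, and generates equally spaced
assessment schedules from a patient's waking window.
"""

from __future__ import annotations

import datetime as dt
import io
import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    InvalidWindowError,
    UnrecoverableSeriesError,
    ValidationError,
)

__all__ = [
    "SymptomTimeSeries",
    "PatientConfig",
    "CleaningReport",
    "read_timeseries",
    "write_timeseries",
    "clean_timeseries",
    "make_schedule",
]


@dataclass
class PatientConfig:
    """Assessment-side configuration for a single patient.

    ``items`` maps item ids to the questionnaire text shown to the patient;
    ``schedule`` holds the daily assessment times (strictly increasing,
    within one day).
    """

    patient_code: str
    items: list[tuple[str, str]]
    scale_min: float
    scale_max: float
    schedule: list[dt.time] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.patient_code:
            raise ValidationError("patient_code must be non-empty")
        if not self.items:
            raise ValidationError("items must be non-empty")
        if not self.scale_max > self.scale_min:
            raise ValidationError("scale_max must exceed scale_min")
        if self.schedule:
            for a, b in zip(self.schedule, self.schedule[1:]):
                if b <= a:
                    raise ValidationError("schedule times must be strictly increasing")

    @property
    def item_ids(self) -> list[str]:
        return [i for i, _ in self.items]

    @property
    def assessments_per_day(self) -> int:
        return len(self.schedule)

    @classmethod
    def from_file(cls, path: str | Path) -> "PatientConfig":
        """Read a key-value config file (JSON)."""
        with open(path) as fh:
            raw = json.load(fh)
        items = [(str(i), str(t)) for i, t in raw["items"]]
        schedule = [dt.time.fromisoformat(s) for s in raw.get("schedule", [])]
        return cls(
            patient_code=raw["patient_code"],
            items=items,
            scale_min=float(raw["scale_min"]),
            scale_max=float(raw["scale_max"]),
            schedule=schedule,
        )

    def to_file(self, path: str | Path) -> None:
        raw = {
            "patient_code": self.patient_code,
            "items": [list(p) for p in self.items],
            "scale_min": self.scale_min,
            "scale_max": self.scale_max,
            "schedule": [t.isoformat() for t in self.schedule],
        }
        Path(path).write_text(json.dumps(raw, indent=2))


@dataclass
class SymptomTimeSeries:
    """T x I matrix of Likert responses with timestamps and scale bounds.

    ``values`` holds floats with NaN in masked (missing) cells; ``mask`` is
    True where the response is missing.
    """

    values: np.ndarray
    timestamps: pd.DatetimeIndex
    item_ids: list[str]
    item_texts: list[str]
    scale_min: float
    scale_max: float
    mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValidationError("values must be a T x I matrix")
        if self.mask is None:
            self.mask = np.isnan(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        t, i = self.values.shape
        if t < 1 or i < 1:
            raise ValidationError("need T >= 1 and I >= 1")
        if len(self.timestamps) != t:
            raise ValidationError("timestamps length must equal T")
        if len(self.item_ids) != i:
            raise ValidationError("item_ids length must equal I")
        if not self.item_texts:
            self.item_texts = list(self.item_ids)
        if len(self.item_texts) != i:
            raise ValidationError("item_texts length must equal I")
        if not self.scale_max > self.scale_min:
            raise ValidationError("scale_max must exceed scale_min")
        ts = np.asarray(self.timestamps.view("int64"))
        if t > 1 and not np.all(np.diff(ts) > 0):
            raise ValidationError("timestamps must be strictly increasing")
        obs = self.values[~self.mask]
        bad = (obs < self.scale_min) | (obs > self.scale_max)
        if np.any(bad):
            r, c = np.argwhere(~self.mask)[np.flatnonzero(bad)[0]]
            raise ValidationError(
                f"value {self.values[r, c]} out of scale "
                f"[{self.scale_min}, {self.scale_max}] at row {r}, item "
                f"{self.item_ids[c]!r}"
            )

    @property
    def n_obs(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    @property
    def missing_rate(self) -> float:
        return float(self.mask.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.timestamps, columns=self.item_ids)

    def check_gap_regularity(self, tol: float = 0.5) -> None:
        """Warn when timestamp gaps deviate more than ``tol`` from the modal gap.

        The pipeline models observations as equally spaced in index order;
        strongly irregular sampling weakens that reading.
        """
        if self.n_obs < 3:
            return
        gaps = np.diff(np.asarray(self.timestamps.view("int64"), dtype=float))
        vals, counts = np.unique(gaps, return_counts=True)
        modal = vals[np.argmax(counts)]
        if modal > 0 and np.any(np.abs(gaps - modal) / modal > tol):
            warnings.warn(
                "timestamp gaps deviate >50% from the modal gap; the pipeline "
                "treats observations as equally spaced in index order",
                stacklevel=2,
            )


@dataclass
class CleaningReport:
    """Audit trail of what :func:`clean_timeseries` did."""

    n_rows_in: int
    n_rows_out: int
    missing_rate: float
    interpolated_cells: int
    dropped_rows: int

    def to_json(self) -> str:
        return json.dumps(asdict(self))


_MISSING_TOKENS = {"", "na", "nan", "n/a", "none", "null"}


def read_timeseries(
    source: str | Path | io.TextIOBase, config: PatientConfig
) -> SymptomTimeSeries:
    """Read a symptom time series from CSV.

    The CSV must have a ``timestamp`` column (ISO-8601) and one column per
    configured item id; empty cells and "NA" mark missing responses.
    Column order in the result follows the config's item order.
    """
    try:
        df = pd.read_csv(source, dtype=str, skipinitialspace=True)
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise FormatError(f"could not parse CSV: {exc}") from exc
    df.columns = [str(c).strip() for c in df.columns]
    if "timestamp" not in df.columns:
        raise FormatError("CSV must have a 'timestamp' column")
    missing_cols = [i for i in config.item_ids if i not in df.columns]
    if missing_cols:
        raise FormatError(f"missing item columns: {missing_cols}")
    extra = [c for c in df.columns if c != "timestamp" and c not in config.item_ids]
    if extra:
        raise FormatError(f"unknown item columns: {extra}")
    try:
        timestamps = pd.DatetimeIndex(
            [pd.Timestamp(t) for t in df["timestamp"].astype(str)]
        )
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-parsable timestamp: {exc}") from exc

    t, i = len(df), len(config.item_ids)
    values = np.full((t, i), np.nan)
    for j, item in enumerate(config.item_ids):
        col = df[item]
        for r, cell in enumerate(col):
            s = "" if cell is None or (isinstance(cell, float) and np.isnan(cell)) else str(cell).strip()
            if s.lower() in _MISSING_TOKENS:
                continue
            try:
                values[r, j] = float(s)
            except ValueError as exc:
                raise FormatError(
                    f"non-numeric value {s!r} at row {r}, item {item!r}"
                ) from exc
    return SymptomTimeSeries(
        values=values,
        timestamps=timestamps,
        item_ids=list(config.item_ids),
        item_texts=[t for _, t in config.items],
        scale_min=config.scale_min,
        scale_max=config.scale_max,
    )


def write_timeseries(ts: SymptomTimeSeries, dest: str | Path | io.TextIOBase) -> None:
    """Write a series in the same CSV dialect ``read_timeseries`` accepts."""
    df = ts.to_frame().copy()
    out = df.astype(object)
    out[ts.mask] = ""
    out.insert(0, "timestamp", [t.isoformat() for t in ts.timestamps])
    out.to_csv(dest, index=False)


def clean_timeseries(
    ts: SymptomTimeSeries, max_gap: int = 1
) -> tuple[SymptomTimeSeries, CleaningReport]:
    """Interpolate short internal gaps, drop rows that stay incomplete.

    Internal missing runs of length <= ``max_gap`` per item are linearly
    interpolated in index order; any row still containing a missing value
    afterwards is dropped.  The output contains no missing values, and the
    report tallies every action taken.
    """
    values = ts.values.copy()
    mask = ts.mask.copy()
    t, n_items = values.shape
    rate_in = float(mask.mean())
    interpolated = 0
    for j in range(n_items):
        col = values[:, j]
        obs_idx = np.flatnonzero(~mask[:, j])
        if len(obs_idx) < 2:
            raise UnrecoverableSeriesError(
                f"item {ts.item_ids[j]!r} has fewer than 2 observed points"
            )
        miss_idx = np.flatnonzero(mask[:, j])
        for run in _runs(miss_idx):
            lo, hi = run[0] - 1, run[-1] + 1
            internal = lo >= 0 and hi < t and not mask[lo, j] and not mask[hi, j]
            if internal and len(run) <= max_gap:
                col[run] = np.interp(run, [lo, hi], [col[lo], col[hi]])
                mask[run, j] = False
                interpolated += len(run)
    keep = ~mask.any(axis=1)
    dropped = int((~keep).sum())
    if keep.sum() < 1:
        raise UnrecoverableSeriesError("no complete rows remain after cleaning")
    cleaned = SymptomTimeSeries(
        values=values[keep],
        timestamps=ts.timestamps[keep],
        item_ids=list(ts.item_ids),
        item_texts=list(ts.item_texts),
        scale_min=ts.scale_min,
        scale_max=ts.scale_max,
    )
    report = CleaningReport(
        n_rows_in=t,
        n_rows_out=int(keep.sum()),
        missing_rate=rate_in,
        interpolated_cells=interpolated,
        dropped_rows=dropped,
    )
    return cleaned, report


def _runs(idx: np.ndarray) -> list[np.ndarray]:
    """Split sorted integer indices into consecutive runs."""
    if len(idx) == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1) + 1
    return np.split(idx, breaks)


def make_schedule(wake: dt.time, sleep: dt.time, n: int) -> list[dt.time]:
    """Split the waking window into ``n`` equally spaced assessment times.

    Wake and sleep are the first and last assessments; a single daily
    assessment lands at the window midpoint.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    w = _seconds(wake)
    s = _seconds(sleep)
    if s <= w:
        raise InvalidWindowError("sleep time must be later than wake time")
    if n == 1:
        secs = [(w + s) / 2.0]
    else:
        step = (s - w) / (n - 1)
        secs = [w + k * step for k in range(n)]
    return [_from_seconds(x) for x in secs]


def _seconds(t: dt.time) -> float:
    return t.hour * 3600 + t.minute * 60 + t.second + t.microsecond / 1e6


def _from_seconds(x: float) -> dt.time:
    x = int(round(x))
    h, rem = divmod(x, 3600)
    m, s = divmod(rem, 60)
    return dt.time(h % 24, m, s)
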