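"""Patient vital-sign series, resampling, MAP approximation and AHE detection.

The substrate for everything downstream is a minute-indexed time series of a
single vital per patient.  An Acute Hypotensive Episode (AHE) is a 30-minute
window in which at least 27 of the 30 minute-sampled Mean Arterial Pressure
(MAP) values are no greater than 60 mmHg.  Missing minutes are represented
explicitly and never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

VITAL_NAMES = ("MAP", "HR", "PUL", "RR", "OSAT")

#: AHE definition defaults: 27 of 30 minute samples at or below 60 mmHg.
AHE_WINDOW_MINUTES = 30
AHE_LOW_THRESHOLD = 60.0
AHE_MIN_LOW_COUNT = 27


class EmptyInputError(ValueError):
    """Raised when an operation receives no samples."""


@dataclass(frozen=True)
class AheEvent:
    """First qualifying hypotensive window of a MAP record."""

    start_minute: int
    n_low: int


@dataclass
class VitalSeries:
    """One patient's measurements of one vital on an integer minute grid.

    ``times`` are strictly increasing minute offsets from record start;
    ``values`` are the matching finite measurements.  Minutes absent from
    ``times`` are missing (gaps are preserved, never interpolated).
    """

    patient_id: str
    vital: str
    times: np.ndarray
    values: np.ndarray
    _dense_cache: Optional[tuple] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.vital not in VITAL_NAMES:
            raise ValueError(f"unknown vital {self.vital!r}; expected one of {VITAL_NAMES}")
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be 1-D and of equal length")
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times.size and self.times[0] < 0:
            raise ValueError("times must be non-negative minute offsets")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite")

    def __len__(self) -> int:
        return int(self.times.size)

    @property
    def extent(self) -> int:
        """One past the last observed minute (0 for an empty series)."""
        return int(self.times[-1]) + 1 if self.times.size else 0

    def _dense(self) -> tuple:
        """Cached dense view: (values-with-NaN, csum of values, csum of mask)."""
        if self._dense_cache is None:
            n = self.extent
            dense = np.full(n, np.nan)
            dense[self.times] = self.values
            mask = ~np.isnan(dense)
            csum_v = np.concatenate(([0.0], np.cumsum(np.where(mask, dense, 0.0))))
            csum_m = np.concatenate(([0], np.cumsum(mask.astype(np.int64))))
            object.__setattr__(self, "_dense_cache", (dense, csum_v, csum_m))
        return self._dense_cache

    def dense_values(self) -> np.ndarray:
        """Minute-indexed array over [0, extent) with NaN at missing minutes."""
        return self._dense()[0]

    def window_stats(self, start: int, end: int) -> tuple[float, int]:
        """(sum of present values, count of present values) over [start, end)."""
        if start < 0 or end < start:
            raise ValueError("require 0 <= start <= end")
        _, csum_v, csum_m = self._dense()
        start = min(start, self.extent)
        end = min(end, self.extent)
        return float(csum_v[end] - csum_v[start]), int(csum_m[end] - csum_m[start])

    def restrict_before(self, minute: int) -> "VitalSeries":
        """Copy containing only samples strictly before ``minute``."""
        keep = self.times < minute
        return VitalSeries(self.patient_id, self.vital, self.times[keep], self.values[keep])


@dataclass
class PatientRecord:
    """All vitals for one patient plus the onset of the first AHE, if any."""

    patient_id: str
    series: Mapping[str, VitalSeries]
    ahe_onset: Optional[int] = None

    def __post_init__(self) -> None:
        for s in self.series.values():
            if s.patient_id != self.patient_id:
                raise ValueError("member series must share patient_id")

    @property
    def map_series(self) -> VitalSeries:
        try:
            return self.series["MAP"]
        except KeyError:
            raise KeyError(f"record {self.patient_id} has no MAP series") from None

    @property
    def label(self) -> str:
        """'A' if the record contains an AHE, else 'NA'."""
        return "A" if self.ahe_onset is not None else "NA"


def resample_to_minutes(
    raw_times: Iterable[float],
    raw_values: Iterable[float],
    patient_id: str = "",
    vital: str = "MAP",
) -> VitalSeries:
    """Aggregate per-second samples into minute means.

    Each minute bucket ``m`` collects raw samples whose timestamp (seconds)
    falls in ``[m*60, (m+1)*60)`` and takes their arithmetic mean.  Minutes
    with no samples are left missing.
    """
    t = np.asarray(list(raw_times) if not isinstance(raw_times, np.ndarray) else raw_times, dtype=np.float64)
    v = np.asarray(list(raw_values) if not isinstance(raw_values, np.ndarray) else raw_values, dtype=np.float64)
    if t.size == 0:
        raise EmptyInputError("no samples to resample")
    if t.shape != v.shape:
        raise ValueError("raw_times and raw_values must have equal length")
    if np.any(np.diff(t) < 0):
        raise ValueError("raw_times must be non-decreasing")
    buckets = np.floor_divide(t, 60.0).astype(np.int64)
    agg = pd.Series(v).groupby(buckets).mean()
    return VitalSeries(patient_id, vital, agg.index.to_numpy(), agg.to_numpy())


def approximate_map(
    systolic: float, diastolic: float, convention: str = "standard"
) -> float:
    """Approximate mean arterial pressure from systolic/diastolic readings.

    ``standard`` uses the conventional (X + 2Y)/3 weighting (diastole lasts
    about twice as long as systole in the cardiac cycle).  ``paper_literal``
    evaluates (2/3)X − (1/3)Y instead, kept only for comparison: it fails the
    sanity check MAP = X when X = Y.
    """
    x = np.asarray(systolic, dtype=np.float64)
    y = np.asarray(diastolic, dtype=np.float64)
    if np.any(y <= 0) or np.any(x < y):
        raise ValueError("require systolic >= diastolic > 0")
    if convention == "standard":
        out = (x + 2.0 * y) / 3.0
    elif convention == "paper_literal":
        out = (2.0 / 3.0) * x - (1.0 / 3.0) * y
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return float(out) if out.ndim == 0 else out


def detect_ahe(
    series: VitalSeries,
    window_minutes: int = AHE_WINDOW_MINUTES,
    low_threshold: float = AHE_LOW_THRESHOLD,
    min_low_count: int = AHE_MIN_LOW_COUNT,
) -> Optional[AheEvent]:
    """Find the earliest acute hypotensive episode in a minute-sampled MAP series.

    Scans every window of ``window_minutes`` consecutive minutes left to right
    (stride 1).  A window qualifies only if all its minutes are present and at
    least ``min_low_count`` of its values are <= ``low_threshold``.  Returns
    the earliest qualifying window, or None.
    """
    dense = series.dense_values()
    n = dense.size
    if n < window_minutes:
        return None
    present = ~np.isnan(dense)
    low = present & (dense <= low_threshold)
    # sliding counts over every window via cumulative sums
    cp = np.concatenate(([0], np.cumsum(present)))
    cl = np.concatenate(([0], np.cumsum(low)))
    w = window_minutes
    present_counts = cp[w:] - cp[:-w]
    low_counts = cl[w:] - cl[:-w]
    ok = (present_counts == w) & (low_counts >= min_low_count)
    hits = np.flatnonzero(ok)
    if hits.size == 0:
        return None
    start = int(hits[0])
    return AheEvent(start_minute=start, n_low=int(low_counts[start]))


def truncate_at_first_ahe(record: PatientRecord, **detect_kwargs) -> PatientRecord:
    """Cut every vital strictly before the first AHE onset.

    Records without an AHE are returned unchanged with ``ahe_onset`` unset.
    """
    event = detect_ahe(record.map_series, **detect_kwargs)
    if event is None:
        return replace(record, ahe_onset=None)
    onset = event.start_minute
    trimmed = {v: s.restrict_before(onset) for v, s in record.series.items()}
    return PatientRecord(record.patient_id, trimmed, ahe_onset=onset)


# ---------------------------------------------------------------------------
# tabular I/O — one row per (patient, vital, minute-or-second, value)

def records_from_frame(frame: pd.DataFrame) -> dict[str, PatientRecord]:
    """Build PatientRecords from a long-format vitals table.

    Accepts the minute dialect (columns patient_id, vital, minute, value) or
    the per-second dialect (patient_id, vital, second, value), which is
    resampled to minute means.
    """
    if "minute" in frame.columns:
        time_col, per_second = "minute", False
    elif "second" in frame.columns:
        time_col, per_second = "second", True
    else:
        raise ValueError("vitals table needs a 'minute' or 'second' column")
    records: dict[str, PatientRecord] = {}
    for pid, patient_rows in frame.groupby("patient_id", sort=True):
        series = {}
        for vital, rows in patient_rows.groupby("vital"):
            rows = rows.sort_values(time_col)
            if per_second:
                series[vital] = resample_to_minutes(
                    rows[time_col].to_numpy(), rows["value"].to_numpy(), str(pid), str(vital)
                )
            else:
                series[vital] = VitalSeries(
                    str(pid), str(vital), rows[time_col].to_numpy(), rows["value"].to_numpy()
                )
        records[str(pid)] = PatientRecord(str(pid), series)
    return records


def read_vitals_csv(path) -> dict[str, PatientRecord]:
    """Read the vitals CSV dialect (minute or per-second)."""
    return records_from_frame(pd.read_csv(path))


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Long-format minute-dialect table for a set of records."""
    parts = []
    for rec in records:
        for vital, s in rec.series.items():
            parts.append(
                pd.DataFrame(
                    {"patient_id": rec.patient_id, "vital": vital, "minute": s.times, "value": s.values}
                )
            )
    if not parts:
        return pd.DataFrame(columns=["patient_id", "vital", "minute", "value"])
    return pd.concat(parts, ignore_index=True)


def ahe_report(records: Iterable[PatientRecord], **detect_kwargs) -> pd.DataFrame:
    """Per-patient AHE detection table: patient_id, ahe_onset_minute, n_low."""
    rows = []
    for rec in records:
        event = detect_ahe(rec.map_series, **detect_kwargs)
        rows.append(
            {
                "patient_id": rec.patient_id,
                "ahe_onset_minute": event.start_minute if event else pd.NA,
                "n_low": event.n_low if event else pd.NA,
            }
        )
    return pd.DataFrame(rows, columns=["patient_id", "ahe_onset_minute", "n_low"])
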