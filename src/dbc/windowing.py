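"""Observation / prediction / test window placement and cohort filtering.

The prediction protocol is parameterised by an [O, P, T] triple of window
lengths in minutes.  Relative to a per-patient anchor minute (the AHE onset
for positive patients), the prediction window is the last P minutes before
the anchor; the observation window (length O, used for training) and the
test window (length T, whose mean is classified) both end where the
prediction window begins.  All intervals are half-open, 0-based minutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .vitals import PatientRecord

#: Evaluation grids for the three window parameters (minutes).
O_GRID = (20, 40, 60, 80, 100, 120)
P_GRID = tuple(range(5, 125, 5))
T_GRID = (20, 40, 60, 80, 100, 120)

MIN_RECORD_MINUTES = 360  # six hours of MAP coverage required
MIN_ONSET_MINUTE = 300  # no AHE in the first five hours


class DegenerateClassError(ValueError):
    """A class has too few usable patients to estimate a spread."""


@dataclass(frozen=True)
class WindowConfig:
    """The [O, P, T] window-length triple, in minutes."""

    observation_minutes: int = 60
    prediction_minutes: int = 60
    test_minutes: int = 60

    def __post_init__(self) -> None:
        for name in ("observation_minutes", "prediction_minutes", "test_minutes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class WindowSummary:
    """Mean of one vital over one placed window for one patient."""

    patient_id: str
    vital: str
    anchor_minute: int
    window_kind: str  # "observation" | "test"
    start: int
    end: int
    mean_value: float
    n_samples: int
    label: str  # "A" | "NA"


def filter_cohort(records: Iterable[PatientRecord]) -> list[PatientRecord]:
    """Apply the cohort inclusion rules.

    Keeps records with at least 360 present minutes of MAP and, for
    AHE-positive records, an onset no earlier than minute 300.  Records are
    expected to be truncated at their first AHE already.
    """
    kept = []
    for rec in records:
        if "MAP" not in rec.series or len(rec.series["MAP"]) < MIN_RECORD_MINUTES:
            continue
        if rec.ahe_onset is not None and rec.ahe_onset < MIN_ONSET_MINUTE:
            continue
        kept.append(rec)
    return kept


def place_windows(
    record: PatientRecord,
    config: WindowConfig,
    anchor_policy: str = "record_end",
    rng: Optional[np.random.Generator] = None,
) -> Optional[tuple[tuple[int, int], tuple[int, int], int]]:
    """Position the observation and test windows for one patient.

    For class-A records the anchor is the AHE onset; for class-NA records it
    is set by ``anchor_policy`` ("record_end" or "seeded_random").  Returns
    ``((obs_start, obs_end), (test_start, test_end), anchor)`` or None when
    the record is too short to fit the windows before the prediction window.
    """
    o, p, t = config.observation_minutes, config.prediction_minutes, config.test_minutes
    if record.ahe_onset is not None:
        anchor = record.ahe_onset
    elif anchor_policy == "record_end":
        anchor = record.map_series.extent
    elif anchor_policy == "seeded_random":
        if rng is None:
            raise ValueError("anchor_policy='seeded_random' requires an rng")
        lo = MIN_RECORD_MINUTES
        hi = record.map_series.extent
        if hi < lo:
            return None
        anchor = int(rng.integers(lo, hi + 1))
    else:
        raise ValueError(f"unknown anchor_policy {anchor_policy!r}")
    if anchor - p - max(o, t) < 0:
        return None
    pred_start = anchor - p
    return (pred_start - o, pred_start), (pred_start - t, pred_start), anchor


def summarize_window(
    record: PatientRecord,
    interval: tuple[int, int],
    vital: str = "MAP",
    coverage_floor: float = 0.9,
    anchor_minute: int = 0,
    window_kind: str = "observation",
) -> Optional[WindowSummary]:
    """Mean of the present samples in ``interval``, or None below the coverage floor.

    A window must have at least ``coverage_floor`` of its minutes present to
    yield a usable mean; missing minutes are never imputed.
    """
    start, end = interval
    if vital not in record.series:
        return None
    total, n = record.series[vital].window_stats(start, end)
    length = end - start
    if length <= 0 or n < coverage_floor * length:
        return None
    return WindowSummary(
        patient_id=record.patient_id,
        vital=vital,
        anchor_minute=anchor_minute,
        window_kind=window_kind,
        start=start,
        end=end,
        mean_value=total / n,
        n_samples=n,
        label=record.label,
    )


def _round_interval(anchor: int, config: WindowConfig, round_index: int) -> Optional[tuple[int, int]]:
    """Observation window for a given online round.

    Round 1 is the canonical observation window ending at the prediction
    window; later rounds step back in time through earlier, non-overlapping
    windows of the same length until the record start is reached.
    """
    o, p = config.observation_minutes, config.prediction_minutes
    end = anchor - p - (round_index - 1) * o
    start = end - o
    if start < 0:
        return None
    return start, end


def build_round(
    records: Iterable[PatientRecord],
    config: WindowConfig,
    round_index: int = 1,
    vitals: tuple[str, ...] = ("MAP",),
    coverage_floor: float = 0.9,
    anchor_policy: str = "record_end",
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-vital class vectors of observation-window means for one round.

    Returns ``(y_A, y_NA)``: for each vital, the vector whose coordinates are
    the per-patient observation-window means in that round.  Patients whose
    window fails placement or the coverage floor contribute nothing; a class
    left with fewer than two coordinates for some vital raises
    DegenerateClassError (its spread would be undefined).
    """
    if round_index < 1:
        raise ValueError("round_index starts at 1")
    y: dict[str, dict[str, list[float]]] = {v: {"A": [], "NA": []} for v in vitals}
    for rec in records:
        placed = place_windows(rec, config, anchor_policy=anchor_policy, rng=rng)
        if placed is None:
            continue
        _, _, anchor = placed
        interval = _round_interval(anchor, config, round_index)
        if interval is None:
            continue
        for vital in vitals:
            summ = summarize_window(
                rec, interval, vital, coverage_floor, anchor_minute=anchor, window_kind="observation"
            )
            if summ is not None:
                y[vital][rec.label].append(summ.mean_value)
    y_a = {v: np.asarray(y[v]["A"]) for v in vitals}
    y_na = {v: np.asarray(y[v]["NA"]) for v in vitals}
    if round_index == 1:
        for v in vitals:
            if y_a[v].size < 2 or y_na[v].size < 2:
                raise DegenerateClassError(
                    f"vital {v}: need >= 2 usable patients per class "
                    f"(got A={y_a[v].size}, NA={y_na[v].size})"
                )
    return y_a, y_na


def summaries_to_frame(summaries: Iterable[WindowSummary]) -> pd.DataFrame:
    """Window-summary table: patient_id, vital, window_kind, start, end, mean, n, label."""
    rows = [
        {
            "patient_id": s.patient_id,
            "vital": s.vital,
            "window_kind": s.window_kind,
            "start": s.start,
            "end": s.end,
            "mean": s.mean_value,
            "n": s.n_samples,
            "label": s.label,
        }
        for s in summaries
    ]
    return pd.DataFrame(
        rows, columns=["patient_id", "vital", "window_kind", "start", "end", "mean", "n", "label"]
    )
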