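"""Seeded synthetic ICU cohorts for exercising the full prediction pipeline.

Each patient gets a minute-sampled MAP series built from Gaussian noise
around a personal baseline.  Episode-bound (class A) patients additionally
drift linearly down from a drift-onset minute to a hypotensive plateau, so a
sustained sub-60 mmHg stretch appears late in the record; a configurable
fraction of "fluctuators" in both classes ride a sinusoid around a lowered
baseline, dipping below 60 transiently so their window means land near the
decision boundaries without satisfying the 27-of-30 episode rule.  Auxiliary
vitals are class-uninformative noise unless an informative shift is asked
for.  Everything is reproducible from the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .vitals import PatientRecord, VitalSeries, detect_ahe

#: per-vital (baseline, noise sd) for the class-uninformative auxiliary vitals
AUX_VITALS = {"HR": (85.0, 8.0), "PUL": (85.0, 8.0), "RR": (18.0, 3.0), "OSAT": (97.0, 1.2)}


@dataclass(frozen=True)
class SynthConfig:
    """Cohort-generation settings.

    Defaults mirror the study conditions the pipeline assumes: records of at
    least six hours, roughly 28.5% of patients (1307 of 4593) developing an
    episode, drift onsets late enough that truncated positive records still
    pass the six-hour and five-hour cohort filters.
    """

    n_patients: int = 100
    ahe_fraction: float = 1307 / 4593
    record_minutes: int = 480
    baseline_map: float = 85.0
    baseline_jitter_sd: float = 2.0
    noise_sd: float = 6.0
    drift_onset_minute: int = 360
    drift_onset_jitter: int = 20
    drift_rate: float = 0.5  # mmHg per minute of decline
    plateau_map: float = 45.0
    ahe_baseline_drop: float = 10.0  # episode-bound patients run lower MAP throughout
    fluctuator_fraction: float = 0.15
    fluctuator_baseline_drop: float = 6.0
    fluctuator_amplitude: float = 21.0
    fluctuator_period: float = 50.0
    vitals: tuple[str, ...] = ("MAP",)
    informative_shift: float = 0.0  # added to class-A auxiliary-vital baselines
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ahe_fraction <= 1.0:
            raise ValueError("ahe_fraction must be in [0, 1]")
        if not 0.0 <= self.fluctuator_fraction <= 1.0:
            raise ValueError("fluctuator_fraction must be in [0, 1]")
        if self.record_minutes < 360:
            raise ValueError("record_minutes must be >= 360 (six hours)")
        if self.drift_onset_minute < 300:
            raise ValueError("drift_onset_minute must be >= 300 (five-hour filter)")
        if self.n_patients < 0:
            raise ValueError("n_patients must be non-negative")
        if "MAP" not in self.vitals:
            raise ValueError("MAP must be among the generated vitals")


def _map_trace(cfg: SynthConfig, rng: np.random.Generator, is_a: bool, fluctuates: bool) -> np.ndarray:
    t = np.arange(cfg.record_minutes, dtype=np.float64)
    base = cfg.baseline_map + rng.normal(0.0, cfg.baseline_jitter_sd)
    if is_a:
        base -= cfg.ahe_baseline_drop
    if fluctuates:
        base -= cfg.fluctuator_baseline_drop
    level = np.full_like(t, base)
    if fluctuates:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        level += cfg.fluctuator_amplitude * np.sin(2.0 * np.pi * t / cfg.fluctuator_period + phase)
    if is_a:
        onset = cfg.drift_onset_minute + int(rng.integers(0, cfg.drift_onset_jitter + 1))
        drop = cfg.drift_rate * np.clip(t - onset, 0.0, None)
        level = np.maximum(level - drop, cfg.plateau_map)
    return level + rng.normal(0.0, cfg.noise_sd, size=t.size)


def generate_cohort(config: SynthConfig) -> list[PatientRecord]:
    """Generate raw (untruncated) patient records.

    The number of intended class-A patients is ``round(n * ahe_fraction)``.
    Records are returned with ``ahe_onset`` set from the detector run on the
    generated series (the detector, not the generator's intent, defines the
    class), so the usual truncate/filter pipeline applies downstream.
    """
    master = np.random.SeedSequence(config.seed)
    n_a = round(config.n_patients * config.ahe_fraction)
    records: list[PatientRecord] = []
    for i, child in enumerate(master.spawn(config.n_patients)):
        rng = np.random.default_rng(child)
        is_a = i < n_a
        fluctuates = rng.uniform() < config.fluctuator_fraction
        pid = f"synth-{i:05d}"
        series = {}
        map_values = _map_trace(config, rng, is_a, fluctuates)
        series["MAP"] = VitalSeries(pid, "MAP", np.arange(map_values.size), map_values)
        for vital in config.vitals:
            if vital == "MAP":
                continue
            base, sd = AUX_VITALS[vital]
            if is_a:
                base += config.informative_shift
            vals = base + rng.normal(0.0, sd, size=config.record_minutes)
            series[vital] = VitalSeries(pid, vital, np.arange(vals.size), vals)
        event = detect_ahe(series["MAP"])
        records.append(
            PatientRecord(pid, series, ahe_onset=event.start_minute if event else None)
        )
    return records


def intended_labels(config: SynthConfig) -> list[str]:
    """Generator-intent labels, index-aligned with generate_cohort output."""
    n_a = round(config.n_patients * config.ahe_fraction)
    return ["A" if i < n_a else "NA" for i in range(config.n_patients)]


def cohort_manifest(records: Iterable[PatientRecord]) -> pd.DataFrame:
    """Per-record summary: id, class, length, onset, per-vital coverage."""
    rows = []
    for rec in records:
        row = {
            "patient_id": rec.patient_id,
            "class": rec.label,
            "record_minutes": rec.map_series.extent if "MAP" in rec.series else 0,
            "ahe_onset": rec.ahe_onset if rec.ahe_onset is not None else pd.NA,
        }
        for vital, s in rec.series.items():
            row[f"coverage_{vital}"] = len(s) / s.extent if s.extent else 0.0
        rows.append(row)
    cols = ["patient_id", "class", "record_minutes", "ahe_onset"]
    if rows:
        cols = cols + sorted(set().union(*(r.keys() for r in rows)) - set(cols))
    return pd.DataFrame(rows, columns=cols)
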