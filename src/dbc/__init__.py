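"""dbc — dual-boundary classification for early warning of acute hypotensive
episodes from minute-sampled ICU vital signs."""

from .vitals import (
    AheEvent,
    PatientRecord,
    VitalSeries,
    approximate_map,
    detect_ahe,
    resample_to_minutes,
    truncate_at_first_ahe,
)
from .windowing import WindowConfig, WindowSummary, build_round, filter_cohort, place_windows, summarize_window
from .classifier import (
    ClassSummary,
    DBCModel,
    DualBoundaryClassifier,
    KappaObjective,
    RegionDecision,
    classify_patient,
    classify_vital,
    fit_kappa,
    kappa_objective,
    train_offline,
    update_online,
)
from .simulate import SynthConfig, cohort_manifest, generate_cohort
from .evaluate import (
    MetricsResult,
    plan_initial_split,
    region_breakdown,
    run_grid,
    run_offline_cv,
    run_online,
    score,
)

__version__ = "0.1.0"


def prepare_cohort(records):
    """Standard preprocessing: truncate each record at its first acute
    hypotensive episode, then apply the cohort inclusion filters."""
    return filter_cohort(truncate_at_first_ahe(rec) for rec in records)
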