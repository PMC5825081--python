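"""Evaluation protocols: metrics, offline cross-validation, the online
predict-then-update stream, the [O, P, T] grid runner and the region-wise
performance breakdown.

Class A (an impending acute hypotensive episode) is the positive class
throughout: sensitivity is the fraction of true A patients predicted A,
specificity the fraction of true NA patients predicted NA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .classifier import DBCModel, UNCERTAINTY, AHE_REGION, NON_AHE_REGION
from .vitals import PatientRecord
from .windowing import O_GRID, P_GRID, T_GRID, WindowConfig, place_windows, summarize_window

REGIONS = (AHE_REGION, NON_AHE_REGION, UNCERTAINTY)


@dataclass(frozen=True)
class MetricsResult:
    """Confusion counts and the derived rates, positive = class A."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def specificity(self) -> float:
        denom = self.tn + self.fp
        return self.tn / denom if denom else float("nan")

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n if self.n else float("nan")


def score(predictions: Sequence[str], truths: Sequence[str]) -> MetricsResult:
    """Confusion counts and rates for per-patient class labels."""
    pred = np.asarray(predictions)
    true = np.asarray(truths)
    if pred.size == 0 or pred.shape != true.shape:
        raise ValueError("predictions and truths must be equal-length and non-empty")
    return MetricsResult(
        tp=int(np.count_nonzero((pred == "A") & (true == "A"))),
        fp=int(np.count_nonzero((pred == "A") & (true == "NA"))),
        tn=int(np.count_nonzero((pred == "NA") & (true == "NA"))),
        fn=int(np.count_nonzero((pred == "NA") & (true == "A"))),
    )


@dataclass(frozen=True)
class InitialSplit:
    """Composition of the online protocol's initial training set."""

    n_initial_A: int
    n_initial_NA: int
    n_predict: int

    @property
    def n_initial(self) -> int:
        return self.n_initial_A + self.n_initial_NA


def plan_initial_split(
    n_a: int,
    n_na: int,
    initial_fraction: float = 0.2,
    class_ratio: Optional[tuple[int, int]] = None,
    initial_size: Optional[int] = None,
) -> InitialSplit:
    """Size the online initial-training subset.

    The initial set holds ``initial_size`` patients (default: the nearest
    integer to ``initial_fraction`` of the cohort), split between classes at
    ``class_ratio`` (default: the cohort's own class ratio) with nearest-
    integer rounding, keeping at least 2 patients per class.
    """
    total = n_a + n_na
    n_init = int(initial_size) if initial_size is not None else round(initial_fraction * total)
    if class_ratio is not None:
        a, na = class_ratio
        share = a / (a + na)
    else:
        share = n_a / total if total else 0.0
    init_a = round(n_init * share)
    init_a = max(2, min(init_a, n_init - 2))
    init_na = n_init - init_a
    if init_a > n_a or init_na > n_na or init_a < 2 or init_na < 2:
        raise ValueError(
            f"initial split of {n_init} at ratio {share:.3f} unattainable "
            f"with cohort A={n_a}, NA={n_na}"
        )
    return InitialSplit(n_initial_A=init_a, n_initial_NA=init_na, n_predict=total - n_init)


# ---------------------------------------------------------------------------
# feature extraction: per-patient observation/test window means

@dataclass
class CohortFeatures:
    """Aligned per-patient window means for one [O, P, T] setting."""

    patient_ids: list
    labels: np.ndarray  # "A"/"NA"
    obs: dict  # vital -> (n,) array, NaN where the window was unusable
    test: dict
    n_skipped: int  # patients dropped (too short or MAP windows unusable)


def extract_features(
    records: Iterable[PatientRecord],
    config: WindowConfig,
    vitals: tuple[str, ...] = ("MAP",),
    coverage_floor: float = 0.9,
    anchor_policy: str = "record_end",
    rng: Optional[np.random.Generator] = None,
) -> CohortFeatures:
    """Observation- and test-window means per patient for one window setting.

    Patients whose windows cannot be placed, or whose MAP windows fail the
    coverage floor, are dropped (counted in ``n_skipped``); unusable windows
    of auxiliary vitals are left NaN.
    """
    ids, labels = [], []
    obs = {v: [] for v in vitals}
    test = {v: [] for v in vitals}
    skipped = 0
    for rec in records:
        placed = place_windows(rec, config, anchor_policy=anchor_policy, rng=rng)
        if placed is None:
            skipped += 1
            continue
        obs_iv, test_iv, anchor = placed
        row_obs, row_test = {}, {}
        for vital in vitals:
            so = summarize_window(rec, obs_iv, vital, coverage_floor, anchor, "observation")
            st = summarize_window(rec, test_iv, vital, coverage_floor, anchor, "test")
            row_obs[vital] = so.mean_value if so else np.nan
            row_test[vital] = st.mean_value if st else np.nan
        if np.isnan(row_obs["MAP"]) or np.isnan(row_test["MAP"]):
            skipped += 1
            continue
        ids.append(rec.patient_id)
        labels.append(rec.label)
        for vital in vitals:
            obs[vital].append(row_obs[vital])
            test[vital].append(row_test[vital])
    return CohortFeatures(
        patient_ids=ids,
        labels=np.asarray(labels),
        obs={v: np.asarray(obs[v]) for v in vitals},
        test={v: np.asarray(test[v]) for v in vitals},
        n_skipped=skipped,
    )


def _class_vectors(obs: dict, labels: np.ndarray, idx: np.ndarray) -> tuple[dict, dict]:
    """Per-vital (y_A, y_NA) vectors from the selected patients, NaNs dropped."""
    y_a, y_na = {}, {}
    for vital, col in obs.items():
        sel = col[idx]
        lab = labels[idx]
        y_a[vital] = sel[(lab == "A") & ~np.isnan(sel)]
        y_na[vital] = sel[(lab == "NA") & ~np.isnan(sel)]
    return y_a, y_na


def _fit_model(obs: dict, labels: np.ndarray, idx: np.ndarray, **est_params) -> DBCModel:
    y_a, y_na = _class_vectors(obs, labels, idx)
    usable = {
        v: (y_a[v], y_na[v]) for v in y_a if v == "MAP" or (y_a[v].size >= 2 and y_na[v].size >= 2)
    }
    return DBCModel().fit({v: p[0] for v, p in usable.items()}, {v: p[1] for v, p in usable.items()}, **est_params)


def _predict_cohort(
    model: DBCModel, feats: CohortFeatures, idx: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(labels, MAP regions) for the selected patients."""
    vitals = list(model.vitals)
    if vitals == ["MAP"]:  # vectorised fast path
        z = feats.test["MAP"][idx]
        regions, votes, _, _ = model.vitals["MAP"]._classify(z)
        return votes, regions
    preds, regions = [], []
    for i in idx:
        z_by_vital = {
            v: feats.test[v][i] for v in vitals if not np.isnan(feats.test[v][i])
        }
        label, decisions = model.predict_patient(z_by_vital)
        preds.append(label)
        regions.append(decisions["MAP"].region)
    return np.asarray(preds), np.asarray(regions)


# ---------------------------------------------------------------------------
# protocols

@dataclass
class ProtocolResult:
    """Predictions, truths and MAP regions from one evaluation protocol run."""

    metrics: MetricsResult
    predictions: np.ndarray
    truths: np.ndarray
    regions: np.ndarray  # MAP-vital region per prediction
    fold_counts: Optional[list] = None  # per-fold MetricsResult (offline CV)
    split: Optional[InitialSplit] = None  # online only
    model: Optional[DBCModel] = None  # final model (online protocol)
    n_skipped: int = 0


def run_offline_cv(
    cohort: Sequence[PatientRecord],
    config: WindowConfig,
    folds: int = 5,
    seed: int = 0,
    vitals: tuple[str, ...] = ("MAP",),
    coverage_floor: float = 0.9,
    anchor_policy: str = "record_end",
    features: Optional[CohortFeatures] = None,
    **est_params,
) -> ProtocolResult:
    """Stratified k-fold cross-validation of the offline-trained classifier.

    Each fold trains on the other folds' observation-window means and
    classifies the held-out patients' test-window means; confusion counts are
    pooled over folds.
    """
    feats = features if features is not None else extract_features(
        cohort, config, vitals, coverage_floor, anchor_policy
    )
    n = feats.labels.size
    for cls in ("A", "NA"):
        if np.count_nonzero(feats.labels == cls) < folds:
            raise ValueError(f"class {cls} has fewer usable patients than folds={folds}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    preds = np.empty(n, dtype=object)
    regions = np.empty(n, dtype=object)
    fold_counts = []
    for train_idx, test_idx in skf.split(np.zeros(n), feats.labels):
        model = _fit_model(feats.obs, feats.labels, train_idx, **est_params)
        p, r = _predict_cohort(model, feats, test_idx)
        preds[test_idx] = p
        regions[test_idx] = r
        fold_counts.append(score(p, feats.labels[test_idx]))
    return ProtocolResult(
        metrics=score(preds, feats.labels),
        predictions=preds.astype(str),
        truths=feats.labels,
        regions=regions.astype(str),
        fold_counts=fold_counts,
        n_skipped=feats.n_skipped,
    )


def run_online(
    cohort: Sequence[PatientRecord],
    config: WindowConfig,
    initial_fraction: float = 0.2,
    initial_class_ratio: Optional[tuple[int, int]] = None,
    seed: int = 0,
    batch_size: int = 1,
    vitals: tuple[str, ...] = ("MAP",),
    coverage_floor: float = 0.9,
    anchor_policy: str = "record_end",
    features: Optional[CohortFeatures] = None,
    **est_params,
) -> ProtocolResult:
    """Online protocol: seeded initial training, then predict-then-update.

    A seeded initial subset at the requested class ratio trains the model;
    the remaining patients arrive in seeded random order.  Each arrival is
    first classified from its test-window mean, then its true label is
    revealed and its observation-window mean updates the model (one online
    round per batch of arrivals, default one patient per batch).
    """
    feats = features if features is not None else extract_features(
        cohort, config, vitals, coverage_floor, anchor_policy
    )
    labels = feats.labels
    idx_a = np.flatnonzero(labels == "A")
    idx_na = np.flatnonzero(labels == "NA")
    split = plan_initial_split(idx_a.size, idx_na.size, initial_fraction, initial_class_ratio)
    rng = np.random.default_rng(seed)
    rng.shuffle(idx_a)
    rng.shuffle(idx_na)
    init_idx = np.concatenate([idx_a[: split.n_initial_A], idx_na[: split.n_initial_NA]])
    rest = np.concatenate([idx_a[split.n_initial_A :], idx_na[split.n_initial_NA :]])
    rng.shuffle(rest)
    model = _fit_model(feats.obs, labels, init_idx, **est_params)
    preds, regions = [], []
    for start in range(0, rest.size, batch_size):
        batch = rest[start : start + batch_size]
        p, r = _predict_cohort(model, feats, batch)
        preds.append(p)
        regions.append(r)
        y_a, y_na = _class_vectors(feats.obs, labels, batch)
        model.update(y_a, y_na)
    preds = np.concatenate(preds) if preds else np.asarray([], dtype=str)
    regions = np.concatenate(regions) if regions else np.asarray([], dtype=str)
    return ProtocolResult(
        metrics=score(preds, labels[rest]),
        predictions=preds,
        truths=labels[rest],
        regions=regions,
        split=split,
        model=model,
        n_skipped=feats.n_skipped,
    )


def region_breakdown(
    regions: Sequence[str], predictions: Sequence[str], truths: Sequence[str]
) -> pd.DataFrame:
    """Metrics computed separately inside each learned region.

    Region attribution follows the MAP vital (the vote tie-breaker).  Regions
    with no predictions get NaN rates; counts across regions partition the
    overall confusion counts.
    """
    regions = np.asarray(regions)
    pred = np.asarray(predictions)
    true = np.asarray(truths)
    rows = []
    for region in REGIONS:
        mask = regions == region
        if mask.any():
            m = score(pred[mask], true[mask])
            rows.append(
                {
                    "region": region,
                    "n": m.n,
                    "tp": m.tp,
                    "fp": m.fp,
                    "tn": m.tn,
                    "fn": m.fn,
                    "sensitivity": m.sensitivity,
                    "specificity": m.specificity,
                    "accuracy": m.accuracy,
                }
            )
        else:
            rows.append(
                {
                    "region": region, "n": 0, "tp": 0, "fp": 0, "tn": 0, "fn": 0,
                    "sensitivity": np.nan, "specificity": np.nan, "accuracy": np.nan,
                }
            )
    return pd.DataFrame(rows)


def run_grid(
    cohort: Sequence[PatientRecord],
    o_grid: Sequence[int] = O_GRID,
    p_grid: Sequence[int] = P_GRID,
    t_grid: Sequence[int] = T_GRID,
    mode: str = "offline",
    folds: int = 5,
    seed: int = 0,
    vitals: tuple[str, ...] = ("MAP",),
    coverage_floor: float = 0.9,
    anchor_policy: str = "record_end",
    **protocol_kwargs,
) -> pd.DataFrame:
    """Evaluate every [O, P, T] triple independently; one row per setting.

    The default grids enumerate 6 x 24 x 6 = 864 settings.  ``mode`` selects
    the offline cross-validated or the online incremental protocol.
    """
    if mode not in ("offline", "online"):
        raise ValueError("mode must be 'offline' or 'online'")
    cohort = list(cohort)
    rows = []
    for o in o_grid:
        for p in p_grid:
            for t in t_grid:
                config = WindowConfig(o, p, t)
                feats = extract_features(cohort, config, vitals, coverage_floor, anchor_policy)
                if mode == "offline":
                    res = run_offline_cv(
                        cohort, config, folds=folds, seed=seed, vitals=vitals,
                        features=feats, **protocol_kwargs,
                    )
                else:
                    res = run_online(
                        cohort, config, seed=seed, vitals=vitals,
                        features=feats, **protocol_kwargs,
                    )
                m = res.metrics
                rows.append(
                    {
                        "O": o, "P": p, "T": t, "mode": mode, "n": m.n,
                        "tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn,
                        "sensitivity": m.sensitivity,
                        "specificity": m.specificity,
                        "accuracy": m.accuracy,
                        "n_skipped": res.n_skipped,
                    }
                )
    return pd.DataFrame(rows)


def grid_summary(grid: pd.DataFrame) -> pd.DataFrame:
    """Mean and across-settings SD of each rate over the grid rows."""
    out = []
    for metric in ("sensitivity", "specificity", "accuracy"):
        out.append(
            {
                "metric": metric,
                "mean": float(grid[metric].mean()),
                "sd_across_settings": float(grid[metric].std(ddof=1)) if len(grid) > 1 else 0.0,
            }
        )
    return pd.DataFrame(out)
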