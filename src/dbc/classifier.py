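"""The Dual Boundary Classifier (DBC).

DBC is a one-dimensional, per-vital classifier with a reject region.  From
training observation-window means of the two classes (A = will have an acute
hypotensive episode, NA = will not) it learns two boundaries,

    lower = mu_A + kappa * sigma_A        upper = mu_NA - kappa * sigma_NA,

with ``kappa`` chosen on a grid to minimise the number of class-A values
above the lower boundary, class-NA values below the upper boundary, and all
values strictly inside the uncertainty interval (lower, upper).  A test mean
``z`` below the lower boundary votes A, above the upper boundary votes NA,
and inside the interval is decided by comparing aggregate squared distances
to each class's training coordinates, computed in closed form from the class
count, mean and population variance:

    d = n * ((z - mu)**2 + nu).

The classifier runs online: each round's new observation-window means update
the cumulative class count, mean and variance by single-observation
recurrences, and kappa is refit; raw patient series from earlier rounds are
never needed.  Multiple vitals each train their own model and the patient
label is a majority vote with ties broken by the MAP vote.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

__all__ = [
    "ClassSummary",
    "KappaObjective",
    "RegionDecision",
    "DualBoundaryClassifier",
    "DBCModel",
    "InfeasibleKappaError",
    "DegenerateSeparationError",
    "kappa_objective",
    "fit_kappa",
    "train_offline",
    "update_online",
    "classify_vital",
    "classify_patient",
]

KAPPA_CAP = 1e6  # stands in for an unbounded feasible range when both sigmas are 0

AHE_REGION = "ahe_region"
NON_AHE_REGION = "non_ahe_region"
UNCERTAINTY = "uncertainty"


class InfeasibleKappaError(ValueError):
    """kappa violates mu_A + kappa*sigma_A < mu_NA - kappa*sigma_NA."""


class DegenerateSeparationError(ValueError):
    """mu_A >= mu_NA: no kappa >= 0 separates the class means."""


@dataclass
class ClassSummary:
    """Running count, mean and population variance of one class's coordinates.

    Updated one coordinate at a time by the standard single-pass recurrences
    (population convention, divisor n):

        mu(n) = mu(n-1) + (x - mu(n-1)) / n
        nu(n) = ((n-1) nu(n-1) + (x - mu(n-1)) (x - mu(n))) / n
    """

    n: int = 0
    mean: float = math.nan
    variance: float = math.nan

    @property
    def stdev(self) -> float:
        return math.sqrt(self.variance) if self.n > 0 else math.nan

    def push(self, x: float) -> None:
        if self.n == 0:
            self.n, self.mean, self.variance = 1, float(x), 0.0
            return
        n = self.n + 1
        mean_old = self.mean
        mean_new = mean_old + (x - mean_old) / n
        self.variance = ((n - 1) * self.variance + (x - mean_old) * (x - mean_new)) / n
        self.mean = mean_new
        self.n = n

    def extend(self, xs: Iterable[float]) -> None:
        for x in xs:
            self.push(float(x))

    @classmethod
    def from_values(cls, xs: Iterable[float]) -> "ClassSummary":
        s = cls()
        s.extend(xs)
        return s


@dataclass(frozen=True)
class KappaObjective:
    """Misclassified / uncertain counts for one kappa value."""

    kappa: float
    n1: int  # class-A values above the upper boundary
    n2: int  # class-A values strictly inside the uncertainty interval
    n3: int  # class-NA values below the lower boundary
    n4: int  # class-NA values strictly inside the uncertainty interval

    @property
    def total(self) -> int:
        return self.n1 + self.n2 + self.n3 + self.n4


@dataclass(frozen=True)
class RegionDecision:
    """One test-window verdict: region, distances (uncertainty only), vote."""

    vital: str
    region: str
    d_A: Optional[float]
    d_NA: Optional[float]
    vote: str


def _counts(y_a: np.ndarray, y_na: np.ndarray, lower: float, upper: float) -> tuple[int, int, int, int]:
    n1 = int(np.count_nonzero(y_a > upper))
    n2 = int(np.count_nonzero((y_a > lower) & (y_a < upper)))
    n3 = int(np.count_nonzero(y_na < lower))
    n4 = int(np.count_nonzero((y_na > lower) & (y_na < upper)))
    return n1, n2, n3, n4


def kappa_objective(y_a, y_na, kappa: float) -> KappaObjective:
    """Count the four error/uncertainty terms for one kappa.

    Boundaries are built from the population mean and standard deviation of
    the supplied class vectors; kappa must satisfy the strict feasibility
    constraint mu_A + kappa*sigma_A < mu_NA - kappa*sigma_NA.
    """
    y_a = np.asarray(y_a, dtype=np.float64)
    y_na = np.asarray(y_na, dtype=np.float64)
    if y_a.size < 2 or y_na.size < 2:
        raise ValueError("need at least 2 coordinates per class")
    if kappa < 0:
        raise InfeasibleKappaError("kappa must be non-negative")
    lower = y_a.mean() + kappa * y_a.std()
    upper = y_na.mean() - kappa * y_na.std()
    if not lower < upper:
        raise InfeasibleKappaError(
            f"kappa={kappa} infeasible: lower bound {lower} !< upper bound {upper}"
        )
    n1, n2, n3, n4 = _counts(y_a, y_na, lower, upper)
    return KappaObjective(kappa=float(kappa), n1=n1, n2=n2, n3=n3, n4=n4)


def _kappa_grid(mu_a, sd_a, mu_na, sd_na, grid_size: int, cap: float = KAPPA_CAP) -> np.ndarray:
    spread = sd_a + sd_na
    kappa_max = (mu_na - mu_a) / spread if spread > 0 else cap
    return np.linspace(0.0, kappa_max, grid_size, endpoint=False)


def _candidate_kappas(
    y_all: np.ndarray, mu_a, sd_a, mu_na, sd_na, grid_size: int, cap: float
) -> np.ndarray:
    """Candidate kappa values covering every plateau of the objective.

    The objective is piecewise constant in kappa, changing only where one of
    the two boundaries crosses a data value.  Candidates are those breakpoints
    themselves, the midpoints of consecutive breakpoints (one point per open
    plateau), and ``grid_size`` equally spaced values; their minimum is the
    global minimum over the whole feasible range [0, kappa_max).
    """
    grid = _kappa_grid(mu_a, sd_a, mu_na, sd_na, grid_size, cap)
    kappa_max = (mu_na - mu_a) / (sd_a + sd_na) if sd_a + sd_na > 0 else cap
    brk = []
    if sd_a > 0:
        brk.append((y_all - mu_a) / sd_a)  # lower boundary crossings
    if sd_na > 0:
        brk.append((mu_na - y_all) / sd_na)  # upper boundary crossings
    if brk:
        b = np.concatenate(brk)
        b = np.unique(b[(b >= 0) & (b < kappa_max)])
        edges = np.concatenate(([0.0], b, [kappa_max]))
        mids = (edges[:-1] + edges[1:]) / 2.0
        cand = np.concatenate((grid, b, mids))
    else:
        cand = grid
    cand = np.unique(cand)
    # enforce strict feasibility mu_A + k sd_A < mu_NA - k sd_NA
    feasible = mu_a + cand * sd_a < mu_na - cand * sd_na
    return cand[feasible]


def _fit_kappa_from_stats(
    y_a: np.ndarray,
    y_na: np.ndarray,
    mu_a: float,
    sd_a: float,
    mu_na: float,
    sd_na: float,
    grid_size: int,
    cap: float = KAPPA_CAP,
) -> tuple[float, KappaObjective]:
    """Exact minimisation of the kappa objective.

    Boundaries come from the given class statistics; counts from the given
    coordinate vectors.  Because the objective is piecewise constant,
    evaluating it on the plateau candidate set (see _candidate_kappas) with
    sorted-array counting finds the true minimiser in O((K + n) log n); ties
    break toward the smallest kappa.
    """
    if not mu_a < mu_na:
        raise DegenerateSeparationError(f"mu_A={mu_a} >= mu_NA={mu_na}")
    cand = _candidate_kappas(np.concatenate([y_a, y_na]), mu_a, sd_a, mu_na, sd_na, grid_size, cap)
    lower = mu_a + cand * sd_a
    upper = mu_na - cand * sd_na
    a_sorted = np.sort(y_a)
    na_sorted = np.sort(y_na)
    n1 = y_a.size - np.searchsorted(a_sorted, upper, side="right")
    n2 = np.searchsorted(a_sorted, upper, side="left") - np.searchsorted(a_sorted, lower, side="right")
    n3 = np.searchsorted(na_sorted, lower, side="left")
    n4 = np.searchsorted(na_sorted, upper, side="left") - np.searchsorted(na_sorted, lower, side="right")
    totals = n1 + np.maximum(n2, 0) + n3 + np.maximum(n4, 0)
    best = int(np.argmin(totals))  # candidates ascend, so first minimum = smallest kappa
    obj = KappaObjective(
        kappa=float(cand[best]),
        n1=int(n1[best]),
        n2=int(max(n2[best], 0)),
        n3=int(n3[best]),
        n4=int(max(n4[best], 0)),
    )
    return float(cand[best]), obj


def fit_kappa(y_a, y_na, grid_size: int = 201) -> tuple[float, KappaObjective]:
    """Find the kappa* minimising n1+n2+n3+n4 over [0, kappa_max).

    kappa_max = (mu_NA - mu_A) / (sigma_A + sigma_NA) is the largest feasible
    multiplier (capped when both sigmas vanish).  The candidate set is a
    ``grid_size``-point equally spaced grid augmented with every plateau of
    the piecewise-constant objective, so the returned value is the exact
    global minimiser; ties break toward the smallest kappa.  Raises
    DegenerateSeparationError when mu_A >= mu_NA.
    """
    y_a = np.asarray(y_a, dtype=np.float64)
    y_na = np.asarray(y_na, dtype=np.float64)
    if y_a.size < 2 or y_na.size < 2:
        raise ValueError("need at least 2 coordinates per class")
    return _fit_kappa_from_stats(
        y_a, y_na, y_a.mean(), y_a.std(), y_na.mean(), y_na.std(), grid_size
    )


class DualBoundaryClassifier(ClassifierMixin, BaseEstimator):
    """Scikit-learn style estimator for the one-dimensional dual-boundary rule.

    Parameters
    ----------
    kappa_grid_size : int
        Number of equally spaced candidate kappa values on [0, kappa_max).
    distance : {"sum", "mean"}
        Uncertainty-region distance.  "sum" is the closed-form aggregate
        squared distance n*((z-mu)**2 + nu) to all stored class coordinates;
        "mean" drops the count factor (a per-coordinate mean squared
        deviation), removing the bias toward the larger class.
    pos_label, neg_label :
        Labels of the low-mean (episode) and high-mean (no-episode) classes.

    Attributes
    ----------
    summary_A_, summary_NA_ : ClassSummary
        Cumulative count / mean / population variance per class.
    values_A_, values_NA_ : ndarray
        Retained multiset of all training coordinates, needed only to refit
        kappa across online rounds (prediction uses just the summaries).
    kappa_, objective_ : fitted kappa* and its KappaObjective.
    degenerate_ : bool
        True when mu_A >= mu_NA; every prediction then takes the distance path.
    round_ : int
        Number of training rounds absorbed so far.
    """

    def __init__(
        self,
        kappa_grid_size: int = 201,
        distance: str = "sum",
        pos_label: str = "A",
        neg_label: str = "NA",
        vital: str = "MAP",
    ):
        self.kappa_grid_size = kappa_grid_size
        self.distance = distance
        self.pos_label = pos_label
        self.neg_label = neg_label
        self.vital = vital

    # -- training ----------------------------------------------------------

    def _validate_xy(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("DualBoundaryClassifier is univariate: X must have 1 feature")
            X = X[:, 0]
        if X.ndim != 1:
            raise ValueError("X must be 1-D or (n, 1)")
        if not np.all(np.isfinite(X)):
            raise ValueError("X must be finite")
        y = np.asarray(y)
        if y.shape != X.shape:
            raise ValueError("X and y length mismatch")
        known = {self.pos_label, self.neg_label}
        if not set(np.unique(y).tolist()) <= known:
            raise ValueError(f"labels must be in {known}")
        return X, y

    def fit(self, X, y):
        """Fit from scratch on coordinates X (window means) and labels y."""
        X, y = self._validate_xy(X, y)
        y_a = X[y == self.pos_label]
        y_na = X[y == self.neg_label]
        if y_a.size < 2 or y_na.size < 2:
            raise ValueError("need at least 2 training coordinates per class")
        self.classes_ = np.asarray(sorted([self.pos_label, self.neg_label]))
        self.n_features_in_ = 1
        self.summary_A_ = ClassSummary.from_values(y_a)
        self.summary_NA_ = ClassSummary.from_values(y_na)
        self.values_A_ = y_a.copy()
        self.values_NA_ = y_na.copy()
        self.round_ = 1
        self._refit_kappa()
        return self

    def partial_fit(self, X, y, classes=None):
        """Absorb one online round of new coordinates.

        Cumulative count/mean/variance are advanced by the single-observation
        recurrences; kappa* is refit against the updated boundaries using the
        retained coordinate multiset.  Either class may be absent from the
        round.  An empty round still advances ``round_``.
        """
        if not hasattr(self, "summary_A_"):
            return self.fit(X, y)
        X, y = self._validate_xy(X, y)
        new_a = X[y == self.pos_label]
        new_na = X[y == self.neg_label]
        self.summary_A_.extend(new_a)
        self.summary_NA_.extend(new_na)
        self.values_A_ = np.concatenate([self.values_A_, new_a])
        self.values_NA_ = np.concatenate([self.values_NA_, new_na])
        self.round_ += 1
        if new_a.size or new_na.size:
            self._refit_kappa()
        return self

    def _refit_kappa(self) -> None:
        a, na = self.summary_A_, self.summary_NA_
        try:
            self.kappa_, self.objective_ = _fit_kappa_from_stats(
                self.values_A_, self.values_NA_,
                a.mean, a.stdev, na.mean, na.stdev,
                self.kappa_grid_size,
            )
            self.degenerate_ = False
        except DegenerateSeparationError:
            self.kappa_, self.objective_ = math.nan, None
            self.degenerate_ = True

    # -- fitted boundaries --------------------------------------------------

    @property
    def lower_bound_(self) -> float:
        return self.summary_A_.mean + self.kappa_ * self.summary_A_.stdev

    @property
    def upper_bound_(self) -> float:
        return self.summary_NA_.mean - self.kappa_ * self.summary_NA_.stdev

    # -- prediction ---------------------------------------------------------

    def _distances(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        a, na = self.summary_A_, self.summary_NA_
        d_a = (z - a.mean) ** 2 + a.variance
        d_na = (z - na.mean) ** 2 + na.variance
        if self.distance == "sum":
            d_a = a.n * d_a
            d_na = na.n * d_na
        elif self.distance != "mean":
            raise ValueError(f"unknown distance {self.distance!r}")
        return d_a, d_na

    def _classify(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Vectorised region + vote.  Returns (regions, votes, d_A, d_NA)."""
        if not np.all(np.isfinite(z)):
            raise ValueError("test means must be finite")
        d_a, d_na = self._distances(z)
        if getattr(self, "degenerate_", False):
            uncertain = np.ones(z.shape, dtype=bool)
            regions = np.full(z.shape, UNCERTAINTY, dtype=object)
        else:
            lower, upper = self.lower_bound_, self.upper_bound_
            uncertain = ~((z < lower) | (z > upper))  # boundary values take the distance path
            regions = np.where(uncertain, UNCERTAINTY, np.where(z < lower, AHE_REGION, NON_AHE_REGION))
        votes = np.where(
            uncertain,
            np.where(d_a > d_na, self.neg_label, self.pos_label),  # ties go to A
            np.where(regions == AHE_REGION, self.pos_label, self.neg_label),
        )
        d_a = np.where(uncertain, d_a, np.nan)
        d_na = np.where(uncertain, d_na, np.nan)
        return regions, votes, d_a, d_na

    def predict(self, X) -> np.ndarray:
        """Class label for each test-window mean."""
        X = np.asarray(X, dtype=np.float64)
        z = X[:, 0] if X.ndim == 2 else np.atleast_1d(X)
        _, votes, _, _ = self._classify(z)
        return votes

    def decide(self, z: float) -> RegionDecision:
        """Full single-value verdict: region, distances, vote."""
        regions, votes, d_a, d_na = self._classify(np.asarray([float(z)]))
        in_unc = regions[0] == UNCERTAINTY
        return RegionDecision(
            vital=self.vital,
            region=str(regions[0]),
            d_A=float(d_a[0]) if in_unc else None,
            d_NA=float(d_na[0]) if in_unc else None,
            vote=str(votes[0]),
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        """JSON-ready state: the 7-tuple, variances, retained coordinates."""
        a, na = self.summary_A_, self.summary_NA_
        return {
            "vital": self.vital,
            "n_A": a.n,
            "n_NA": na.n,
            "mean_A": a.mean,
            "stdev_A": a.stdev,
            "mean_NA": na.mean,
            "stdev_NA": na.stdev,
            "kappa_star": None if self.degenerate_ else self.kappa_,
            "variance_A": a.variance,
            "variance_NA": na.variance,
            "degenerate": self.degenerate_,
            "round": self.round_,
            "kappa_grid_size": self.kappa_grid_size,
            "distance": self.distance,
            "values_A": self.values_A_.tolist(),
            "values_NA": self.values_NA_.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DualBoundaryClassifier":
        est = cls(kappa_grid_size=d["kappa_grid_size"], distance=d["distance"], vital=d["vital"])
        est.classes_ = np.asarray(sorted([est.pos_label, est.neg_label]))
        est.n_features_in_ = 1
        est.summary_A_ = ClassSummary(d["n_A"], d["mean_A"], d["variance_A"])
        est.summary_NA_ = ClassSummary(d["n_NA"], d["mean_NA"], d["variance_NA"])
        est.values_A_ = np.asarray(d["values_A"], dtype=np.float64)
        est.values_NA_ = np.asarray(d["values_NA"], dtype=np.float64)
        est.round_ = d["round"]
        est.degenerate_ = d["degenerate"]
        est.kappa_ = math.nan if d["kappa_star"] is None else float(d["kappa_star"])
        if not est.degenerate_:
            # recover the objective at the stored kappa for completeness
            lower = est.lower_bound_
            upper = est.upper_bound_
            n1, n2, n3, n4 = _counts(est.values_A_, est.values_NA_, lower, upper)
            est.objective_ = KappaObjective(est.kappa_, n1, n2, n3, n4)
        else:
            est.objective_ = None
        return est


@dataclass
class DBCModel:
    """Per-vital DualBoundaryClassifiers combined by majority vote.

    The MAP model is mandatory and breaks vote ties.
    """

    vitals: dict = field(default_factory=dict)  # vital name -> DualBoundaryClassifier
    round_index: int = 0
    vote_tiebreak_vital: str = "MAP"

    def __post_init__(self) -> None:
        if self.vitals and self.vote_tiebreak_vital not in self.vitals:
            raise ValueError(f"{self.vote_tiebreak_vital} model is mandatory")

    def fit(self, y_a: Mapping[str, np.ndarray], y_na: Mapping[str, np.ndarray], **est_params) -> "DBCModel":
        if self.vote_tiebreak_vital not in y_a:
            raise ValueError(f"{self.vote_tiebreak_vital} training vectors are mandatory")
        self.vitals = {}
        for vital in y_a:
            est = DualBoundaryClassifier(vital=vital, **est_params)
            xs = np.concatenate([y_a[vital], y_na[vital]])
            ys = np.asarray(["A"] * len(y_a[vital]) + ["NA"] * len(y_na[vital]))
            est.fit(xs, ys)
            self.vitals[vital] = est
        self.round_index = 1
        return self

    def update(self, y_a: Mapping[str, np.ndarray], y_na: Mapping[str, np.ndarray]) -> "DBCModel":
        """One online round: per-vital summary updates and kappa refits."""
        for vital, est in self.vitals.items():
            new_a = np.asarray(y_a.get(vital, ()), dtype=np.float64)
            new_na = np.asarray(y_na.get(vital, ()), dtype=np.float64)
            xs = np.concatenate([new_a, new_na])
            ys = np.asarray(["A"] * new_a.size + ["NA"] * new_na.size)
            est.partial_fit(xs, ys)
        self.round_index += 1
        return self

    def predict_patient(self, z_by_vital: Mapping[str, float]) -> tuple[str, dict[str, RegionDecision]]:
        """Majority vote over per-vital verdicts; ties broken by the MAP vote."""
        if self.vote_tiebreak_vital not in z_by_vital:
            raise ValueError(f"test mean for {self.vote_tiebreak_vital} is required")
        decisions = {
            vital: self.vitals[vital].decide(z)
            for vital, z in z_by_vital.items()
            if vital in self.vitals
        }
        votes = [d.vote for d in decisions.values()]
        n_a = votes.count("A")
        n_na = votes.count("NA")
        if n_a > n_na:
            label = "A"
        elif n_na > n_a:
            label = "NA"
        else:
            label = decisions[self.vote_tiebreak_vital].vote
        return label, decisions

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "round_index": self.round_index,
                "vote_tiebreak_vital": self.vote_tiebreak_vital,
                "vitals": {v: est.to_dict() for v, est in self.vitals.items()},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "DBCModel":
        d = json.loads(text)
        model = cls(
            vitals={v: DualBoundaryClassifier.from_dict(sub) for v, sub in d["vitals"].items()},
            round_index=d["round_index"],
            vote_tiebreak_vital=d["vote_tiebreak_vital"],
        )
        return model

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "DBCModel":
        with open(path) as fh:
            return cls.from_json(fh.read())


# -- thin functional wrappers ----------------------------------------------

def train_offline(round_vectors: tuple, **est_params) -> DBCModel:
    """Fit a DBCModel in one batch round from per-vital (y_A, y_NA) vectors."""
    y_a, y_na = round_vectors
    return DBCModel().fit(y_a, y_na, **est_params)


def update_online(model: DBCModel, round_vectors: tuple) -> DBCModel:
    """Advance a trained DBCModel by one online round."""
    y_a, y_na = round_vectors
    return model.update(y_a, y_na)


def classify_vital(model: DualBoundaryClassifier, z: float) -> RegionDecision:
    """Region + vote of a single vital's model for one test-window mean."""
    return model.decide(z)


def classify_patient(model: DBCModel, z_by_vital: Mapping[str, float]) -> tuple[str, dict]:
    """Patient-level label by majority vote over per-vital decisions."""
    return model.predict_patient(z_by_vital)
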