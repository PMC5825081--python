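"""Dual-boundary classifier: kappa objective, exact kappa fit, online
updates, the three-region rule, distances and majority voting."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from sklearn.base import clone

from dbc.classifier import (
    AHE_REGION,
    NON_AHE_REGION,
    UNCERTAINTY,
    ClassSummary,
    DBCModel,
    DualBoundaryClassifier,
    InfeasibleKappaError,
    classify_patient,
    fit_kappa,
    kappa_objective,
    train_offline,
    update_online,
)


def brute_counts(y_a, y_na, lower, upper):
    """Oracle: count the four objective terms by explicit comparison."""
    n1 = sum(1 for y in y_a if y > upper)
    n2 = sum(1 for y in y_a if lower < y < upper)
    n3 = sum(1 for y in y_na if y < lower)
    n4 = sum(1 for y in y_na if lower < y < upper)
    return n1, n2, n3, n4


def fit_dbc(y_a, y_na, **kwargs):
    y_a, y_na = np.asarray(y_a, float), np.asarray(y_na, float)
    est = DualBoundaryClassifier(**kwargs)
    return est.fit(
        np.concatenate([y_a, y_na]), np.asarray(["A"] * y_a.size + ["NA"] * y_na.size)
    )


class TestKappaObjective:
    def test_perfectly_separated_constant_classes(self):
        obj = kappa_objective([40.0, 40.0], [80.0, 80.0], kappa=1.0)
        assert (obj.n1, obj.n2, obj.n3, obj.n4) == (0, 0, 0, 0)
        assert obj.total == 0

    def test_matches_bruteforce_over_kappa_sweep(self):
        y_a = np.array([50.0, 55.0, 58.0, 62.0])
        y_na = np.array([65.0, 70.0, 72.0, 75.0])
        kappa_max = (y_na.mean() - y_a.mean()) / (y_a.std() + y_na.std())
        for kappa in np.linspace(0, kappa_max, 400, endpoint=False):
            obj = kappa_objective(y_a, y_na, kappa)
            lower = y_a.mean() + kappa * y_a.std()
            upper = y_na.mean() - kappa * y_na.std()
            assert (obj.n1, obj.n2, obj.n3, obj.n4) == brute_counts(y_a, y_na, lower, upper)

    def test_infeasible_kappa_rejected(self):
        y_a, y_na = [50.0, 55.0], [60.0, 65.0]
        with pytest.raises(InfeasibleKappaError):
            kappa_objective(y_a, y_na, kappa=5.0)


class TestFitKappa:
    def test_constant_classes_tie_break_to_zero(self):
        kappa, obj = fit_kappa([40.0, 40.0], [80.0, 80.0])
        assert kappa == 0.0 and obj.total == 0

    def test_degenerate_separation_signal(self):
        from dbc.classifier import DegenerateSeparationError

        with pytest.raises(DegenerateSeparationError):
            fit_kappa([80.0, 85.0], [60.0, 65.0])

    def test_never_worse_than_fine_grid(self, rng):
        """The plateau-exact fit matches or beats any fixed grid search."""
        for _ in range(50):
            y_a = rng.normal(70, rng.uniform(2, 5), rng.integers(10, 60))
            y_na = rng.normal(85, rng.uniform(2, 5), rng.integers(10, 60))
            if y_a.mean() >= y_na.mean():
                continue
            kappa, obj = fit_kappa(y_a, y_na)
            grid = np.linspace(
                0, (y_na.mean() - y_a.mean()) / (y_a.std() + y_na.std()), 5000, endpoint=False
            )
            totals = [kappa_objective(y_a, y_na, k).total for k in grid[::50]]
            assert obj.total <= min(totals)
            # and the reported counts are real counts at the fitted kappa
            lower = y_a.mean() + kappa * y_a.std()
            upper = y_na.mean() - kappa * y_na.std()
            assert (obj.n1, obj.n2, obj.n3, obj.n4) == brute_counts(y_a, y_na, lower, upper)


class TestClassSummary:
    def test_pushing_the_mean_shrinks_variance(self):
        s = ClassSummary.from_values([4.0, 6.0])  # mean 5, nu 1
        n, nu = s.n, s.variance
        s.push(5.0)
        assert s.mean == pytest.approx(5.0)
        assert s.variance == pytest.approx(n * nu / (n + 1))

    @given(
        values=st.lists(st.floats(min_value=40, max_value=120), min_size=2, max_size=60),
        seed=st.integers(0, 2**16),
    )
    def test_incremental_equals_batch_over_random_partitions(self, values, seed):
        rng = np.random.default_rng(seed)
        n_rounds = int(rng.integers(1, 11))
        cuts = np.sort(rng.integers(0, len(values) + 1, n_rounds - 1))
        parts = np.split(np.asarray(values), cuts)
        inc = ClassSummary()
        for part in parts:
            inc.extend(part)
        batch = np.asarray(values)
        assert inc.n == batch.size
        assert inc.mean == pytest.approx(batch.mean(), abs=1e-9)
        assert inc.variance == pytest.approx(batch.var(), abs=1e-9)


class TestOfflineOnlineEquivalence:
    def test_seven_tuple_populated(self):
        model = train_offline(({"MAP": np.array([50.0, 55.0, 60.0])}, {"MAP": np.array([80.0, 85.0])}))
        est = model.vitals["MAP"]
        assert est.summary_A_.n == 3 and est.summary_NA_.n == 2
        assert est.lower_bound_ < est.upper_bound_
        assert not est.degenerate_

    def test_constant_class_zero_variance(self):
        model = train_offline(({"MAP": np.array([50.0, 50.0, 50.0])}, {"MAP": np.array([80.0, 85.0])}))
        est = model.vitals["MAP"]
        assert est.summary_A_.mean == 50.0
        assert est.summary_A_.variance == 0.0

    def test_update_matches_batch_refit(self, rng):
        round1_a, round1_na = rng.normal(70, 3, 30), rng.normal(85, 3, 60)
        round2_a, round2_na = rng.normal(71, 3, 12), rng.normal(84, 3, 25)
        online = train_offline(({"MAP": round1_a}, {"MAP": round1_na}))
        update_online(online, ({"MAP": round2_a}, {"MAP": round2_na}))
        batch = train_offline(
            ({"MAP": np.concatenate([round1_a, round2_a])}, {"MAP": np.concatenate([round1_na, round2_na])})
        )
        for cls in ("summary_A_", "summary_NA_"):
            inc, ref = getattr(online.vitals["MAP"], cls), getattr(batch.vitals["MAP"], cls)
            assert inc.n == ref.n
            assert inc.mean == pytest.approx(ref.mean, abs=1e-9)
            assert inc.variance == pytest.approx(ref.variance, abs=1e-9)
        assert online.vitals["MAP"].kappa_ == pytest.approx(batch.vitals["MAP"].kappa_, abs=1e-9)
        assert online.round_index == 2 and batch.round_index == 1

    def test_empty_round_only_advances_counter(self, rng):
        model = train_offline(({"MAP": rng.normal(70, 3, 20)}, {"MAP": rng.normal(85, 3, 40)}))
        before = model.vitals["MAP"].to_dict()
        update_online(model, ({}, {}))
        after = model.vitals["MAP"].to_dict()
        assert model.round_index == 2
        before.pop("round"), after.pop("round")
        assert before == after

    def test_one_sided_round_updates_one_class(self, rng):
        model = train_offline(({"MAP": rng.normal(70, 3, 20)}, {"MAP": rng.normal(85, 3, 40)}))
        update_online(model, ({}, {"MAP": np.array([86.0, 87.0])}))
        est = model.vitals["MAP"]
        assert est.summary_A_.n == 20 and est.summary_NA_.n == 42


class TestRegionRule:
    def test_region_votes(self):
        est = fit_dbc([60.0, 62.0, 64.0], [80.0, 82.0, 84.0])
        low = est.lower_bound_ - 1.0
        high = est.upper_bound_ + 1.0
        assert est.decide(low).region == AHE_REGION and est.decide(low).vote == "A"
        assert est.decide(high).region == NON_AHE_REGION and est.decide(high).vote == "NA"

    def test_boundary_value_takes_distance_path(self):
        est = fit_dbc([60.0, 62.0, 64.0], [80.0, 82.0, 84.0])
        d = est.decide(est.lower_bound_)
        assert d.region == UNCERTAINTY
        assert d.d_A is not None and d.d_NA is not None

    def test_distance_tie_goes_to_class_a(self):
        # symmetric classes around z: d_A == d_NA exactly
        est = fit_dbc([60.0, 62.0], [64.0, 66.0])
        d = est.decide(63.0)
        assert d.region == UNCERTAINTY
        assert d.d_A == d.d_NA
        assert d.vote == "A"

    def test_closed_form_distance_equals_explicit_sum(self, rng):
        for _ in range(200):
            y_a = rng.normal(70, 4, rng.integers(2, 40))
            y_na = rng.normal(85, 4, rng.integers(2, 40))
            if y_a.mean() >= y_na.mean():
                continue
            est = fit_dbc(y_a, y_na)
            z = rng.uniform(60, 95)
            d_a, d_na = est._distances(np.asarray([z]))
            assert d_a[0] == pytest.approx(np.sum((z - y_a) ** 2), rel=1e-9)
            assert d_na[0] == pytest.approx(np.sum((z - y_na) ** 2), rel=1e-9)

    def test_vote_monotone_in_z(self, rng):
        est = fit_dbc(rng.normal(70, 3, 40), rng.normal(85, 3, 40))
        zs = np.linspace(40, 110, 500)
        votes = est.predict(zs)
        assert all(v == "A" for v in votes[zs < est.lower_bound_])
        assert all(v == "NA" for v in votes[zs > est.upper_bound_])

    def test_degenerate_model_routes_everything_to_distances(self):
        est = fit_dbc([80.0, 85.0, 90.0], [60.0, 65.0, 70.0])  # reversed means
        assert est.degenerate_
        d = est.decide(75.0)
        assert d.region == UNCERTAINTY and d.vote in ("A", "NA")

    def test_mean_distance_variant_removes_count_bias(self):
        y_a = [60.0, 62.0]
        y_na = [64.0, 66.0] * 50  # much larger NA class, same spread
        z = 63.0
        summed = fit_dbc(y_a, y_na, distance="sum").decide(z)
        per_point = fit_dbc(y_a, y_na, distance="mean").decide(z)
        assert summed.d_A < summed.d_NA  # count factor inflates d_NA
        assert per_point.d_A == pytest.approx(per_point.d_NA)

    def test_non_finite_test_mean_rejected(self):
        est = fit_dbc([60.0, 62.0], [80.0, 82.0])
        with pytest.raises(ValueError):
            est.decide(math.nan)


class TestMajorityVote:
    def _model(self, vitals):
        y_a = {v: np.array([60.0, 62.0, 64.0]) for v in vitals}
        y_na = {v: np.array([80.0, 82.0, 84.0]) for v in vitals}
        return DBCModel().fit(y_a, y_na)

    def test_map_breaks_ties(self):
        model = self._model(["MAP", "HR"])
        label, decisions = classify_patient(model, {"MAP": 55.0, "HR": 90.0})
        assert decisions["MAP"].vote == "A" and decisions["HR"].vote == "NA"
        assert label == "A"

    def test_unanimous(self):
        model = self._model(["MAP", "HR", "PUL", "RR", "OSAT"])
        label, _ = classify_patient(model, {v: 90.0 for v in model.vitals})
        assert label == "NA"

    def test_simple_majority(self):
        model = self._model(["MAP", "HR", "PUL", "RR", "OSAT"])
        z = {"MAP": 55.0, "HR": 55.0, "PUL": 90.0, "RR": 90.0, "OSAT": 90.0}
        label, decisions = classify_patient(model, z)
        assert [d.vote for d in decisions.values()].count("NA") == 3
        assert label == "NA"

    def test_map_mandatory(self):
        model = self._model(["MAP", "HR"])
        with pytest.raises(ValueError):
            classify_patient(model, {"HR": 90.0})


class TestEstimatorContract:
    def test_params_and_clone(self):
        est = DualBoundaryClassifier(kappa_grid_size=101, distance="mean")
        cloned = clone(est)
        assert cloned.get_params()["kappa_grid_size"] == 101
        assert cloned.get_params()["distance"] == "mean"

    def test_needs_two_per_class(self):
        est = DualBoundaryClassifier()
        with pytest.raises(ValueError):
            est.fit([60.0, 80.0, 82.0], ["A", "NA", "NA"])

    def test_two_gaussian_recovery(self, rng):
        """Well-separated two-Gaussian classes are recovered almost perfectly."""
        n = 250
        train_a, test_a = rng.normal(70, 3.5, (2, n))
        train_na, test_na = rng.normal(85, 3.5, (2, n))
        pooled = np.sqrt((train_a.var() * n + train_na.var() * n) / (2 * n))
        assert (train_na.mean() - train_a.mean()) / pooled >= 3.0
        est = fit_dbc(train_a, train_na)
        sens = np.mean(est.predict(test_a) == "A")
        spec = np.mean(est.predict(test_na) == "NA")
        assert sens >= 0.95 and spec >= 0.95

    def test_serialization_round_trip_bit_stable(self, rng):
        model = train_offline(({"MAP": rng.normal(70, 3, 25)}, {"MAP": rng.normal(85, 3, 50)}))
        update_online(model, ({"MAP": np.array([69.0])}, {"MAP": np.array([86.0])}))
        restored = DBCModel.from_json(model.to_json())
        a, b = model.vitals["MAP"], restored.vitals["MAP"]
        assert a.to_dict() == b.to_dict()
        zs = rng.uniform(60, 95, 50)
        assert list(a.predict(zs)) == list(b.predict(zs))

    def test_training_cost_scales_near_linearly(self):
        """Doubling both class sizes should not blow up fit time (near-linear fit)."""
        import time

        rng = np.random.default_rng(0)
        timings = []
        for n in (2000, 16000):
            y_a = rng.normal(70, 3, n)
            y_na = rng.normal(85, 3, n)
            best = math.inf
            for _ in range(3):
                t0 = time.perf_counter()
                fit_kappa(y_a, y_na)
                best = min(best, time.perf_counter() - t0)
            timings.append(best)
        # 8x data; allow a log factor and noise, but reject quadratic (64x)
        assert timings[1] < 32 * timings[0] + 0.05
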