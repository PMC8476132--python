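"""Performance metrics, constrained grid search, and cross-validation."""

import numpy as np
import pytest

from hybridscan import (
    GridSpec,
    ReplicateScan,
    ScenarioReplicates,
    TailCounts,
    Thresholds,
    call_outliers,
    classify_calls,
    cross_validate,
    grid_search,
    performance,
    true_window_class_size,
)


def make_tail(kappa, n_b=1000):
    kappa = np.asarray(kappa, dtype=np.int64)
    return TailCounts(kappa, n_b=n_b, tail_size=max(1, len(kappa) // 100),
                      window_size=1000, n_windows=len(kappa))


def rep_with_peaks(W, peaks, height=1000, loci=(), halo=0, halo_height=0):
    """A replicate whose kappa vector has the given peaks (plus optional
    neighbourhood halo so the kappa_d criterion can pass)."""
    k = np.zeros(W, dtype=np.int64)
    for p in peaks:
        if halo:
            lo, hi = max(0, p - halo), min(W, p + halo + 1)
            k[lo:hi] = np.maximum(k[lo:hi], halo_height)
        k[p] = height
    return ReplicateScan(make_tail(k), tuple(loci))


class TestClassification:
    def test_true_class_size_is_4d_plus_2(self):
        assert true_window_class_size((350, 650), d=9, n_windows=1000) == 38
        assert true_window_class_size((350, 650), d=9, n_windows=1000) == 4 * 9 + 2

    def test_overlapping_locus_neighbourhoods_flagged_and_merged(self):
        with pytest.warns(UserWarning):
            size = true_window_class_size((100, 110), d=9, n_windows=1000)
        assert size == 29  # union of [91,109] and [101,119]

    def test_partition_and_boundary(self):
        k = np.zeros(100, dtype=np.int64)
        calls = [
            call_outliers(make_tail(_k), Thresholds(0, 500, 0))
            for _k in ()
        ]
        tail = make_tail(np.where(np.isin(np.arange(100), [20, 30, 41]), 900, 0))
        calls = call_outliers(tail, Thresholds(d=0, thr1=500, thr2=0))
        true_calls, false_calls = classify_calls(calls, locus_windows=(20,), d=10)
        assert {c.window_index for c in true_calls} == {20, 30}
        assert {c.window_index for c in false_calls} == {41}  # distance d+1
        assert len(true_calls) + len(false_calls) == len(calls)


class TestPerformance:
    def test_no_calls_gives_all_zero_metrics(self):
        reps = [rep_with_peaks(100, [], loci=(20, 70))]
        pm = performance(reps, Thresholds(5, 900, 80))
        assert (pm.power, pm.fpr, pm.fp_in_outliers) == (0.0, 0.0, 0.0)

    def test_perfect_detection(self):
        reps = [
            rep_with_peaks(100, [20, 70], loci=(20, 70), halo=5, halo_height=500)
            for _ in range(3)
        ]
        pm = performance(reps, Thresholds(5, 900, 80))
        assert pm.power == 1.0 and pm.fpr == 0.0 and pm.fp_in_outliers == 0.0

    def test_hand_computed_mixed_case(self):
        # 3 replicate datasets, loci at 20 and 70, d=5 (true class 22 windows):
        #  rep1: calls at 20 (true) and 50 (false); rep2: call at 72 (true);
        #  rep3: no calls.
        d = 5
        reps = [
            rep_with_peaks(100, [20, 50], loci=(20, 70), halo=d, halo_height=400),
            rep_with_peaks(100, [72], loci=(20, 70), halo=d, halo_height=400),
            rep_with_peaks(100, [], loci=(20, 70)),
        ]
        pm = performance(reps, Thresholds(d, 900, 80))
        assert pm.power == pytest.approx(2 / 6)  # loci detected: 20 (r1), 70 (r2)
        assert pm.fpr == pytest.approx(1 / ((100 - 22) * 3))
        assert pm.fp_in_outliers == pytest.approx(1 / 3)

    def test_per_dataset_power_mode_requires_both_loci(self):
        d = 5
        reps = [
            rep_with_peaks(100, [20, 70], loci=(20, 70), halo=d, halo_height=400),
            rep_with_peaks(100, [20], loci=(20, 70), halo=d, halo_height=400),
        ]
        assert performance(reps, Thresholds(d, 900, 80)).power == pytest.approx(3 / 4)
        pm = performance(reps, Thresholds(d, 900, 80), power_mode="per_dataset")
        assert pm.power == pytest.approx(1 / 2)

    def test_power_non_increasing_in_thresholds_and_non_decreasing_in_d(self):
        rng = np.random.default_rng(0)
        reps = [
            ReplicateScan(make_tail(rng.integers(0, 1000, 200)), (50, 150))
            for _ in range(4)
        ]
        p0 = performance(reps, Thresholds(9, 400, 20)).power
        assert performance(reps, Thresholds(9, 700, 20)).power <= p0
        assert performance(reps, Thresholds(9, 400, 120)).power <= p0
        assert performance(reps, Thresholds(15, 400, 20)).power >= p0


class TestGridSearch:
    def test_single_feasible_cell_returned(self):
        reps = [rep_with_peaks(100, [20, 70], loci=(20, 70), halo=5, halo_height=500)]
        grid = GridSpec(thr1_values=(900,), thr2_values=(80,), d_values=(5,))
        res = grid_search(reps, metric="power", grid=grid)
        assert res.feasible and res.best == Thresholds(5, 900, 80)
        assert res.metrics.power == 1.0

    def test_empty_feasible_set_reported_explicitly(self):
        # a lone false call in every replicate, no loci -> fp_in_outliers = 1
        reps = [rep_with_peaks(100, [50], halo=9, halo_height=500, loci=(20,))]
        grid = GridSpec(thr1_values=(400,), thr2_values=(0,), d_values=(9,))
        res = grid_search(reps, metric="power", grid=grid)
        assert not res.feasible and res.best is None

    def test_tie_broken_by_smaller_d_then_larger_thr2(self):
        reps = [rep_with_peaks(100, [20, 70], loci=(20, 70), halo=4, halo_height=999)]
        grid = GridSpec(thr1_values=(400,), thr2_values=(20, 40), d_values=(5, 9))
        res = grid_search(reps, metric="power", grid=grid)
        assert res.best.d == 5          # resolution first
        assert res.best.thr2 == 40      # then larger thr2

    def test_metric_choice_flips_winner(self):
        # The locus-B call sits 8 windows from the locus: d=15 catches both
        # loci (raw power 1), d=5 only one (power 0.5), but the
        # resolution-penalized metric prefers 0.5/11 over 1.0/31.
        W = 200
        reps = [
            rep_with_peaks(W, [20, 78], loci=(20, 70), halo=1, halo_height=999)
            for _ in range(2)
        ]
        grid = GridSpec(thr1_values=(400,), thr2_values=(0,), d_values=(5, 15))
        raw = grid_search(reps, metric="power", grid=grid, enforce_constraints=False)
        penal = grid_search(reps, metric="power_over_2d1", grid=grid,
                            enforce_constraints=False)
        assert raw.best.d == 15
        assert penal.best.d == 5

    def test_grid_cell_agrees_with_direct_performance(self):
        rng = np.random.default_rng(1)
        reps = [
            ReplicateScan(make_tail(rng.integers(0, 1000, 150)), (40, 110))
            for _ in range(3)
        ]
        grid = GridSpec(thr1_values=(500, 700), thr2_values=(20, 60), d_values=(6, 9))
        res = grid_search(reps, metric="power", grid=grid, enforce_constraints=False)
        for _, row in res.table.iterrows():
            pm = performance(reps, Thresholds(int(row.d), row.thr1, row.thr2))
            assert row.power == pytest.approx(pm.power)
            assert row.fpr == pytest.approx(pm.fpr)
            assert row.fp_in_outliers == pytest.approx(pm.fp_in_outliers)


class TestCrossValidation:
    def _identical_reps(self, n=8):
        return ScenarioReplicates(
            "toy",
            [
                rep_with_peaks(100, [20, 70], loci=(20, 70), halo=5, halo_height=500)
                for _ in range(n)
            ],
        )

    def test_identical_replicates_give_unanimous_mode(self):
        grid = GridSpec(thr1_values=(400, 900), thr2_values=(0, 80), d_values=(5, 9))
        res = cross_validate(self._identical_reps(), metric="power", iters=20,
                             seed=3, grid=grid)
        assert res.counts.count_best.max() == 20
        assert res.modal_best is not None
        assert res.heldout_modal.power == 1.0

    def test_seeded_runs_reproducible(self):
        grid = GridSpec(thr1_values=(400,), thr2_values=(0, 80), d_values=(5,))
        r1 = cross_validate(self._identical_reps(), iters=10, seed=7, grid=grid)
        r2 = cross_validate(self._identical_reps(), iters=10, seed=7, grid=grid)
        assert r1.counts.equals(r2.counts)

    def test_train_and_heldout_sets_disjoint(self):
        scen = self._identical_reps(8)
        res = cross_validate(scen, iters=5, seed=1,
                             grid=GridSpec((400,), (0,), (5,)))
        for rec in res.iterations:
            if "heldout" in rec:
                # 25% of 8 -> 2 training, 6 held-out datasets
                assert rec["heldout"].n_datasets == 6

    def test_plateau_counts_superset_of_best_counts(self):
        grid = GridSpec(thr1_values=(400, 900), thr2_values=(0, 80), d_values=(5, 9))
        res = cross_validate(self._identical_reps(), metric="power", iters=10,
                             seed=5, grid=grid)
        assert (res.counts.count_top5 >= res.counts.count_best).all()
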