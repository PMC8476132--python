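"""Performance evaluation: power, false-positive rates, threshold tuning.

A "replicate dataset" is one simulation replicate at one sampling
generation, scanned into per-window tail counts with known truth (the
windows containing the two incompatibility loci).  An outlier call at
window ``i`` is a true positive when a truth window lies within its
``[i-d, i+d]`` detection region; with two well-separated loci this makes a
true-positive class of ``4d+2`` windows and a false-positive class of
``W - 4d - 2``.  Larger ``d`` mechanically inflates power, hence the
optimizing metrics ``power/(2d+1)`` and ``power/(2d+1)^2`` that penalize
coarse resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .detection import (
    OutlierCall,
    TailCounts,
    Thresholds,
    call_outliers,
    fpr_ceiling,
    smoothed_counts,
)

__all__ = [
    "ReplicateScan",
    "ScenarioReplicates",
    "PerformanceMetrics",
    "classify_calls",
    "true_window_class_size",
    "performance",
    "GridSpec",
    "GridSearchResult",
    "grid_search",
    "CrossValidationResult",
    "cross_validate",
    "METRICS",
]


@dataclass
class ReplicateScan:
    """One scanned replicate dataset: tail counts plus the truth windows."""

    tail: TailCounts
    locus_windows: tuple[int, ...] = ()


@dataclass
class ScenarioReplicates:
    """All replicate datasets of one named scenario."""

    scenario: str
    replicates: list[ReplicateScan]

    def __post_init__(self) -> None:
        if self.replicates:
            W = {r.tail.n_windows for r in self.replicates}
            if len(W) != 1:
                raise ValueError("replicates must share the window tiling")

    @property
    def n_windows(self) -> int:
        return self.replicates[0].tail.n_windows


@dataclass(frozen=True)
class PerformanceMetrics:
    """The three headline metrics for one threshold combination."""

    power: float
    fpr: float
    fp_in_outliers: float
    thresholds: Thresholds
    n_datasets: int = 0

    def metric(self, name: str) -> float:
        return METRICS[name](self)


METRICS = {
    "power": lambda pm: pm.power,
    "power_over_2d1": lambda pm: pm.power / (2 * pm.thresholds.d + 1),
    "power_over_2d1_sq": lambda pm: pm.power / (2 * pm.thresholds.d + 1) ** 2,
}


def true_window_class_size(locus_windows, d: int, n_windows: int) -> int:
    """Number of windows whose calls would count as true positives.

    The union of the ``[lw-d, lw+d]`` neighbourhoods, clipped to the genome;
    equals ``4d+2`` for two loci whose neighbourhoods neither overlap nor
    hit a chromosome end.  Overlap is flagged and the class recomputed.
    """
    covered = np.zeros(n_windows, dtype=bool)
    loci = list(locus_windows)
    for a in range(len(loci)):
        for b in range(a + 1, len(loci)):
            if abs(loci[a] - loci[b]) <= 2 * d:
                warnings.warn(
                    "locus neighbourhoods overlap; true-positive class "
                    "recomputed as their union",
                    stacklevel=2,
                )
    for lw in loci:
        covered[max(0, lw - d) : min(n_windows, lw + d + 1)] = True
    return int(covered.sum())


def classify_calls(
    calls: list[OutlierCall], locus_windows, d: int
) -> tuple[list[OutlierCall], list[OutlierCall]]:
    """Partition calls into true and false positives.

    A call at window ``i`` is true iff some truth window lies within
    ``[i-d, i+d]``; with no truth windows every call is false.
    """
    loci = np.asarray(list(locus_windows), dtype=np.int64)
    true_calls, false_calls = [], []
    for call in calls:
        i = call.window_index
        if loci.size and np.any(np.abs(loci - i) <= d):
            true_calls.append(call)
        else:
            false_calls.append(call)
    return true_calls, false_calls


def _iter_replicates(reps) -> tuple[list[ReplicateScan], int]:
    if isinstance(reps, ScenarioReplicates):
        reps = reps.replicates
    reps = list(reps)
    if not reps:
        raise ValueError("need at least one replicate dataset")
    W = reps[0].tail.n_windows
    return reps, W


def performance(
    reps,
    thr: Thresholds,
    power_mode: str = "per_locus",
    _kd_cache: dict | None = None,
) -> PerformanceMetrics:
    """Power, false-positive rate and proportion of false positives in calls.

    ``power_mode="per_locus"`` (default) counts each incompatibility locus
    in each replicate dataset as one detection opportunity; a locus is
    detected when at least one true call covers it.  ``"per_dataset"``
    instead requires both loci of a dataset to be covered.  The
    false-positive rate divides false calls by the number of
    false-positive-class windows summed over datasets.
    """
    if power_mode not in ("per_locus", "per_dataset"):
        raise ValueError("power_mode must be 'per_locus' or 'per_dataset'")
    reps, W = _iter_replicates(reps)
    d = thr.d
    n_true_calls = n_false_calls = 0
    detected = 0
    opportunities = 0
    false_class_total = 0
    for rep in reps:
        if _kd_cache is not None:
            key = (id(rep), d)
            kd = _kd_cache.get(key)
            if kd is None:
                kd = _kd_cache[key] = smoothed_counts(rep.tail, d)
        else:
            kd = smoothed_counts(rep.tail, d)
        cand = np.flatnonzero(rep.tail.kappa > thr.thr1)
        call_windows = cand[kd[cand] > thr.thr2]
        loci = np.asarray(rep.locus_windows, dtype=np.int64)
        if loci.size:
            is_true = np.any(
                np.abs(loci[None, :] - call_windows[:, None]) <= d, axis=1
            ) if call_windows.size else np.zeros(0, bool)
        else:
            is_true = np.zeros(call_windows.size, bool)
        n_true_calls += int(is_true.sum())
        n_false_calls += int(call_windows.size - is_true.sum())
        hits = [
            bool(call_windows.size)
            and bool(np.any(np.abs(call_windows - lw) <= d))
            for lw in loci
        ]
        if power_mode == "per_locus":
            detected += sum(hits)
            opportunities += loci.size
        else:
            detected += int(bool(loci.size) and all(hits))
            opportunities += int(bool(loci.size))
        false_class_total += W - true_window_class_size(loci, d, W)

    n_calls = n_true_calls + n_false_calls
    return PerformanceMetrics(
        power=detected / opportunities if opportunities else 0.0,
        fpr=n_false_calls / false_class_total if false_class_total else 0.0,
        fp_in_outliers=n_false_calls / n_calls if n_calls else 0.0,
        thresholds=thr,
        n_datasets=len(reps),
    )


@dataclass(frozen=True)
class GridSpec:
    """The threshold grid explored when tuning ``{d, thr1, thr2}``."""

    thr1_values: tuple = tuple(range(400, 1001, 50))
    thr2_values: tuple = tuple(range(0, 301, 20))
    d_values: tuple = tuple(range(5, 20))

    def combos(self):
        for d in self.d_values:
            for thr1 in self.thr1_values:
                for thr2 in self.thr2_values:
                    yield Thresholds(d=d, thr1=thr1, thr2=thr2)


@dataclass
class GridSearchResult:
    feasible: bool
    best: Thresholds | None
    metrics: PerformanceMetrics | None
    metric_name: str
    metric_value: float | None
    table: pd.DataFrame

    def plateau(self, within: float = 0.05) -> pd.DataFrame:
        """Feasible combinations with metric within ``within`` of the best."""
        if not self.feasible:
            return self.table.iloc[0:0]
        ok = self.table[self.table.feasible]
        return ok[ok.metric_value >= (1.0 - within) * self.metric_value]


def _scenario_list(reps) -> list[ScenarioReplicates]:
    if isinstance(reps, ScenarioReplicates):
        return [reps]
    reps = list(reps)
    if reps and isinstance(reps[0], ReplicateScan):
        return [ScenarioReplicates("", reps)]
    return reps


def grid_search(
    reps,
    metric: str = "power_over_2d1",
    grid: GridSpec | None = None,
    enforce_constraints: bool = True,
    power_mode: str = "per_locus",
) -> GridSearchResult:
    """Constrained search for the best ``{d, thr1, thr2}`` combination.

    Accepts one scenario (or a bare replicate list) or several scenarios;
    with several, the optimizing metric is averaged over scenarios and the
    constraints must hold in each.  A combination is feasible when its
    false-positive rate is below the Bonferroni ceiling ``5*thr1/10,000 %``
    and its proportion of false positives among outliers is below 5%
    (in every scenario).  Ties are broken by smaller ``d``, then smaller
    ``fp_in_outliers``, then larger ``thr2``.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {sorted(METRICS)}")
    scenarios = _scenario_list(reps)
    if not scenarios:
        raise ValueError("no replicate data supplied")
    grid = grid or GridSpec()
    kd_cache: dict = {}

    rows = []
    for thr in grid.combos():
        per_scen = [
            performance(s, thr, power_mode=power_mode, _kd_cache=kd_cache)
            for s in scenarios
        ]
        feasible = (not enforce_constraints) or all(
            pm.fpr < fpr_ceiling(thr.thr1) and pm.fp_in_outliers < 0.05
            for pm in per_scen
        )
        mval = float(np.mean([pm.metric(metric) for pm in per_scen]))
        rows.append(
            {
                "d": thr.d,
                "thr1": thr.thr1,
                "thr2": thr.thr2,
                "power": float(np.mean([pm.power for pm in per_scen])),
                "fpr": float(np.mean([pm.fpr for pm in per_scen])),
                "fp_in_outliers": float(np.mean([pm.fp_in_outliers for pm in per_scen])),
                "metric_value": mval,
                "feasible": feasible,
            }
        )
    table = pd.DataFrame(rows)

    ok = table[table.feasible]
    if ok.empty:
        return GridSearchResult(False, None, None, metric, None, table)
    ranked = ok.sort_values(
        by=["metric_value", "d", "fp_in_outliers", "thr2"],
        ascending=[False, True, True, False],
        kind="mergesort",
    )
    top = ranked.iloc[0]
    best = Thresholds(d=int(top.d), thr1=float(top.thr1), thr2=float(top.thr2))
    best_pm = PerformanceMetrics(
        power=float(top.power),
        fpr=float(top.fpr),
        fp_in_outliers=float(top.fp_in_outliers),
        thresholds=best,
        n_datasets=sum(len(s.replicates) for s in scenarios),
    )
    return GridSearchResult(True, best, best_pm, metric, float(top.metric_value), table)


@dataclass
class CrossValidationResult:
    counts: pd.DataFrame  # one row per combo: count_best, count_top5
    modal_best: Thresholds | None
    modal_top5: Thresholds | None
    heldout_modal: PerformanceMetrics | None
    iterations: list[dict]


def cross_validate(
    reps,
    metric: str = "power_over_2d1",
    train_frac: float = 0.25,
    iters: int = 100,
    plateau: float = 0.05,
    seed: int | None = None,
    grid: GridSpec | None = None,
    power_mode: str = "per_locus",
) -> CrossValidationResult:
    """Repeated subset cross-validation of the threshold grid search.

    Each iteration trains the grid search on a random ``train_frac`` subset
    of the replicate datasets (stratified by scenario when several are
    pooled, drawn without replacement), records the single best combination
    *and* every combination within ``plateau`` of its metric, then measures
    performance of the best combination on the held-out datasets.  The mode
    of the best-combination distribution is the recommended setting; the
    mode of the plateau distribution is its more robust variant.
    """
    scenarios = _scenario_list(reps)
    if sum(len(s.replicates) for s in scenarios) < 2:
        raise ValueError("cross-validation needs at least two replicate datasets")
    rng = np.random.default_rng(seed)
    grid = grid or GridSpec()

    best_counts: dict[tuple, int] = {}
    top5_counts: dict[tuple, int] = {}
    iterations = []
    for it in range(iters):
        train_scen, test_scen = [], []
        for s in scenarios:
            n = len(s.replicates)
            n_train = max(1, min(n - 1, round(train_frac * n))) if n > 1 else 1
            pick = rng.choice(n, size=n_train, replace=False)
            mask = np.zeros(n, dtype=bool)
            mask[pick] = True
            train_scen.append(
                ScenarioReplicates(s.scenario, [r for r, m in zip(s.replicates, mask) if m])
            )
            held = [r for r, m in zip(s.replicates, mask) if not m]
            if held:
                test_scen.append(ScenarioReplicates(s.scenario, held))

        res = grid_search(train_scen, metric=metric, grid=grid, power_mode=power_mode)
        record = {"iteration": it, "feasible": res.feasible}
        if res.feasible:
            key = (res.best.d, res.best.thr1, res.best.thr2)
            best_counts[key] = best_counts.get(key, 0) + 1
            for _, row in res.plateau(plateau).iterrows():
                k5 = (int(row.d), float(row.thr1), float(row.thr2))
                top5_counts[k5] = top5_counts.get(k5, 0) + 1
            if test_scen:
                pms = [
                    performance(s, res.best, power_mode=power_mode) for s in test_scen
                ]
                record["heldout"] = PerformanceMetrics(
                    power=float(np.mean([p.power for p in pms])),
                    fpr=float(np.mean([p.fpr for p in pms])),
                    fp_in_outliers=float(np.mean([p.fp_in_outliers for p in pms])),
                    thresholds=res.best,
                    n_datasets=sum(p.n_datasets for p in pms),
                )
            record["best"] = res.best
        iterations.append(record)

    keys = sorted(set(best_counts) | set(top5_counts))
    counts = pd.DataFrame(
        {
            "d": [k[0] for k in keys],
            "thr1": [k[1] for k in keys],
            "thr2": [k[2] for k in keys],
            "count_best": [best_counts.get(k, 0) for k in keys],
            "count_top5": [top5_counts.get(k, 0) for k in keys],
        }
    ).sort_values(["count_best", "count_top5"], ascending=False, kind="mergesort")

    def _modal(column: str) -> Thresholds | None:
        if counts.empty or counts[column].max() == 0:
            return None
        row = counts.sort_values(column, ascending=False, kind="mergesort").iloc[0]
        return Thresholds(d=int(row.d), thr1=float(row.thr1), thr2=float(row.thr2))

    modal_best = _modal("count_best")
    modal_top5 = _modal("count_top5")
    heldout_modal = None
    if modal_best is not None:
        key = (modal_best.d, modal_best.thr1, modal_best.thr2)
        pms = [
            rec["heldout"]
            for rec in iterations
            if rec.get("best") is not None
            and (rec["best"].d, rec["best"].thr1, rec["best"].thr2) == key
            and "heldout" in rec
        ]
        if pms:
            heldout_modal = PerformanceMetrics(
                power=float(np.mean([p.power for p in pms])),
                fpr=float(np.mean([p.fpr for p in pms])),
                fp_in_outliers=float(np.mean([p.fp_in_outliers for p in pms])),
                thresholds=modal_best,
                n_datasets=int(np.mean([p.n_datasets for p in pms])),
            )
    return CrossValidationResult(counts, modal_best, modal_top5, heldout_modal, iterations)
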