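"""Bootstrap calibration of window probabilities and two-threshold outlier calls.

Raw multinomial probabilities are astronomically small and depend strongly
on the per-window SNP count, so windows are ranked, not tested: the sample
of ``2n`` haplotypes is resampled with replacement ``n_b`` times, the
windows falling in the lowest 1% of per-window probabilities are recorded
in each replicate, and ``kappa[i]`` counts how often window ``i`` lands in
that tail.  A window is called an outlier when it is itself consistently in
the tail (``kappa > thr1``) *and* its ``[i-d, i+d]`` neighbourhood is, on
average, consistently in the tail (``kappa_d > thr2``) — epistatic
selection distorts the SFS over a broad region, whereas chance outliers are
isolated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .sample import HaplotypeSample
from .spectra import n_windows_for

__all__ = [
    "Thresholds",
    "TailCounts",
    "OutlierCall",
    "bootstrap_tail_counts",
    "smoothed_counts",
    "call_outliers",
    "candidate_bound",
    "fpr_ceiling",
]


@dataclass(frozen=True)
class Thresholds:
    """Outlier-calling thresholds: neighbourhood half-width and the two cuts."""

    d: int
    thr1: float
    thr2: float

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError("neighbourhood half-width d must be >= 0")
        if self.thr1 < 0 or self.thr2 < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass
class TailCounts:
    """Per-window 1%-tail occurrence counts from the bootstrap."""

    kappa: np.ndarray
    n_b: int
    tail_size: int
    window_size: int
    n_windows: int

    def __post_init__(self) -> None:
        self.kappa = np.asarray(self.kappa, dtype=np.int64)
        if self.kappa.shape != (self.n_windows,):
            raise ValueError("kappa must have one entry per window")
        if self.kappa.min(initial=0) < 0 or self.kappa.max(initial=0) > self.n_b:
            raise ValueError("each kappa must lie in [0, n_b]")

    def smoothed(self, d: int) -> np.ndarray:
        return smoothed_counts(self, d)


@dataclass(frozen=True)
class OutlierCall:
    """One outlier window with its detection region ``[i-d, i+d]``."""

    window_index: int
    kappa: int
    kappa_d: float
    region: tuple[int, int]  # inclusive window interval, clipped to the genome


def _tail_size(n_windows: int) -> int:
    return max(1, n_windows // 100)


def bootstrap_tail_counts(
    sample: HaplotypeSample,
    window_size: int = 500_000,
    n_b: int = 1_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TailCounts:
    """Count, per window, how often it falls in the bootstrap 1% tail.

    Each replicate resamples the ``2n`` haplotypes with replacement,
    recomputes every local SFS *and* the genome-wide SFS, scores each window
    by its multinomial log-probability, and marks the ``max(1, W//100)``
    lowest-probability windows (ties broken by window index; empty windows
    have probability one and never enter the tail).
    """
    if n_b < 1:
        raise ValueError("n_b must be >= 1")
    if sample.n_hap < 2:
        raise ValueError("need at least two haplotypes to bootstrap")
    W = n_windows_for(sample.sequence_length, window_size)
    if W < 1:
        raise ValueError("the genome tiles into zero windows")
    tail = _tail_size(W)
    nh = sample.n_hap
    S = sample.n_sites
    if S == 0:
        raise ValueError("cannot scan a sample with no segregating sites")
    n_nonempty = np.unique(sample.positions // window_size).size
    if n_nonempty < tail:
        raise ValueError(
            "fewer non-empty windows than bootstrap tail slots; "
            "use a larger window size"
        )

    if rng is None:
        rng = np.random.default_rng(seed)
    # One batched draw: replicate b resamples haplotypes IDX[b, :].
    IDX = rng.integers(0, nh, size=(n_b, nh))
    weights = np.empty((n_b, nh), dtype=np.float32)
    for b in range(n_b):
        weights[b] = np.bincount(IDX[b], minlength=nh)

    G = sample.genotypes.astype(np.float32)  # (S, nh); counts stay exact
    D = G @ weights.T  # (S, n_b) resampled derived counts
    win = (sample.positions // window_size).astype(np.int64)

    # GL[c] = log(c!) for every count that can occur in a replicate.
    GL = gammaln(np.arange(S + 2, dtype=np.float64) + 1.0)
    kappa = np.zeros(W, dtype=np.int64)
    n_bins = nh - 1
    for b in range(n_b):
        d = np.rint(D[:, b]).astype(np.int64)
        poly = (d > 0) & (d < nh)
        flat = np.bincount(win[poly] * (nh + 1) + d[poly], minlength=W * (nh + 1))
        hist = flat.reshape(W, nh + 1)[:, 1:nh]
        k = hist.sum(axis=1)
        g = hist.sum(axis=0)
        tot = g.sum()
        logp_bins = np.where(g > 0, np.log(np.maximum(g, 1) / tot), 0.0)
        logp = GL[k] - GL[hist].sum(axis=1) + hist @ logp_bins
        logp = np.where(k > 0, logp, np.inf)  # exclude empty windows
        order = np.argsort(logp, kind="stable")
        kappa[order[:tail]] += 1

    return TailCounts(kappa, n_b=n_b, tail_size=tail, window_size=window_size,
                      n_windows=W)


def smoothed_counts(kappa, d: int) -> np.ndarray:
    """Neighbourhood mean ``kappa_d(i)``: mean of kappa over ``[i-d, i+d]``.

    The focal window is included; at the chromosome edges the mean is taken
    over the truncated neighbourhood (the divisor is the actual window
    count).
    """
    if d < 0:
        raise ValueError("d must be >= 0")
    k = np.asarray(kappa.kappa if isinstance(kappa, TailCounts) else kappa, float)
    W = k.shape[0]
    cs = np.concatenate(([0.0], np.cumsum(k)))
    i = np.arange(W)
    lo = np.maximum(0, i - d)
    hi = np.minimum(W - 1, i + d)
    return (cs[hi + 1] - cs[lo]) / (hi - lo + 1)


def call_outliers(tail: TailCounts, thr: Thresholds) -> list[OutlierCall]:
    """Two-threshold outlier classification.

    Windows with ``kappa > thr1`` become candidates; a candidate is called
    an outlier when the neighbourhood mean satisfies ``kappa_d > thr2``.
    Overlapping detection regions are reported separately (not merged).
    """
    kd = smoothed_counts(tail, thr.d)
    W = tail.n_windows
    calls = []
    for i in np.flatnonzero(tail.kappa > thr.thr1):
        if kd[i] > thr.thr2:
            calls.append(
                OutlierCall(
                    window_index=int(i),
                    kappa=int(tail.kappa[i]),
                    kappa_d=float(kd[i]),
                    region=(max(0, int(i) - thr.d), min(W - 1, int(i) + thr.d)),
                )
            )
    return calls


def candidate_bound(thr1: float, n_b: int = 1_000, tail_size: int = 10) -> int:
    """Maximum possible number of candidate outliers for a given ``thr1``.

    The bootstrap distributes exactly ``n_b * tail_size`` tail slots, so at
    most ``floor(n_b * tail_size / thr1)`` windows can each collect more
    than ``thr1`` of them; this bound is what enters the Bonferroni
    correction for multiple testing.
    """
    if thr1 <= 0:
        raise ValueError("thr1 must be positive")
    return int(n_b * tail_size // thr1)


def fpr_ceiling(thr1: float) -> float:
    """Bonferroni-corrected false-positive-rate ceiling, as a fraction.

    A 5% family-wise level divided by the candidate bound gives
    ``5 * thr1 / 10,000`` percent, i.e. ``thr1 * 5e-6`` as a fraction
    (e.g. 4.5e-3 at ``thr1 = 900``).
    """
    if thr1 <= 0:
        raise ValueError("thr1 must be positive")
    return 5.0 * thr1 / 10_000 / 100.0
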