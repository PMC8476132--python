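"""Windowed unfolded site-frequency spectra and their multinomial scoring.

The genome is tiled with non-overlapping windows (500 kb at full scale,
giving 1,000 windows).  Each window's unfolded SFS — counts of SNPs by
derived-allele count 1..2n-1 — is scored by the log-probability of drawing
that spectrum from a multinomial whose category probabilities come from the
genome-wide SFS.  The genome-wide spectrum thereby acts as the null model,
absorbing the (possibly complicated) demography of the hybrid zone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import binom

from .sample import HaplotypeSample

__all__ = [
    "SFS",
    "WindowedSFS",
    "window_sfs",
    "sfs_log_probability",
    "sfs_from_sample",
    "predict_initial_hybrid_sfs",
    "window_score_table",
]


@dataclass
class SFS:
    """Unfolded SFS over derived-allele counts ``1..n_hap-1``.

    Monomorphic and sample-fixed bins are excluded by construction; counts
    may be floats for *expected* spectra.
    """

    counts: np.ndarray
    n_hap: int

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1 or self.counts.shape[0] != self.n_hap - 1:
            raise ValueError("counts must have length n_hap - 1 (bins 1..n_hap-1)")
        if np.any(self.counts < 0):
            raise ValueError("SFS counts must be non-negative")

    @property
    def n_snps(self):
        return self.counts.sum()

    def proportions(self) -> np.ndarray:
        tot = self.counts.sum()
        return self.counts / tot if tot > 0 else np.zeros_like(self.counts, float)


@dataclass
class WindowedSFS:
    """Per-window spectra tiling ``[0, L)`` plus their genome-wide sum."""

    window_size: int
    counts: np.ndarray  # (n_windows, n_hap - 1)
    n_hap: int
    sequence_length: int

    @property
    def n_windows(self) -> int:
        return int(self.counts.shape[0])

    @property
    def global_sfs(self) -> SFS:
        return SFS(self.counts.sum(axis=0), self.n_hap)

    def window(self, i: int) -> SFS:
        return SFS(self.counts[i], self.n_hap)

    def window_bounds(self, i: int) -> tuple[int, int]:
        lo = i * self.window_size
        return lo, min(lo + self.window_size, self.sequence_length)

    def snps_per_window(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def n_windows_for(L: int, window_size: int) -> int:
    return -(-int(L) // int(window_size))  # ceil division


def window_sfs(sample: HaplotypeSample, window_size: int = 500_000) -> WindowedSFS:
    """Tabulate the unfolded SFS in non-overlapping windows.

    SNPs fall in window ``pos // window_size`` (0-based half-open windows);
    a final partial window is kept when ``L`` is not a multiple of the
    window size.  The genome-wide spectrum is the bin-wise sum over windows.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    nh = sample.n_hap
    W = n_windows_for(sample.sequence_length, window_size)
    n_bins = nh - 1
    if sample.n_sites == 0:
        return WindowedSFS(window_size, np.zeros((W, n_bins), np.int64), nh,
                           sample.sequence_length)
    win = sample.positions // window_size
    dc = sample.derived_counts()
    flat = np.bincount(win * (nh + 1) + dc, minlength=W * (nh + 1))
    counts = flat.reshape(W, nh + 1)[:, 1:nh].astype(np.int64)
    return WindowedSFS(window_size, counts, nh, sample.sequence_length)


def sfs_from_sample(sample: HaplotypeSample) -> SFS:
    """Genome-wide unfolded SFS of a sample."""
    nh = sample.n_hap
    counts = np.bincount(sample.derived_counts(), minlength=nh + 1)[1:nh]
    return SFS(counts.astype(np.int64), nh)


def _as_counts(x) -> np.ndarray:
    return np.asarray(x.counts if isinstance(x, SFS) else x, dtype=float)


def sfs_log_probability(local, global_) -> float:
    """Log multinomial probability of a local SFS given the genome-wide one.

    With ``k`` the window's SNP count and ``p_i`` the genome-wide bin
    proportions, returns ``log[k!/prod(c_i!) * prod p_i^{c_i}]``, computed
    entirely through log-gamma.  An empty window has probability one.
    """
    c = _as_counts(local)
    g = _as_counts(global_)
    if c.shape != g.shape:
        raise ValueError("local and global SFS must share their binning")
    if isinstance(local, SFS) and isinstance(global_, SFS) and local.n_hap != global_.n_hap:
        raise ValueError("local and global SFS must share n_hap")
    k = c.sum()
    if k == 0:
        return 0.0
    tot = g.sum()
    occupied = c > 0
    if np.any(occupied & (g == 0)):
        raise ValueError("local SFS occupies a bin with zero genome-wide probability")
    logp = np.zeros_like(g)
    pos = g > 0
    logp[pos] = np.log(g[pos] / tot)
    return float(gammaln(k + 1) - gammaln(c + 1).sum() + (c * logp).sum())


def predict_initial_hybrid_sfs(parent1: SFS, parent2: SFS, n_fixed_diff: int) -> SFS:
    """Expected sample SFS of the hybrid population at founding (generation 0).

    Each source is half of the founding gene pool, so a site at frequency
    ``f`` in one source segregates at expected frequency ``f/2`` in the new
    hybrid population; a sample of the same ``2n`` haplotypes then draws a
    ``Binomial(2n, f/2)`` derived count.  The ``n_fixed_diff`` differences
    fixed between the sources each sit at frequency exactly 0.5, producing
    the diagnostic mass of SNPs at intermediate frequency.  Bins 0 and 2n
    (monomorphic in the sample) are dropped, matching the polymorphism rule.
    """
    if parent1.n_hap != parent2.n_hap:
        raise ValueError("parental spectra must share n_hap")
    nh = parent1.n_hap
    bins = np.arange(1, nh)
    # Row j-1: binomial pmf of the hybrid sample count for a parental site
    # with derived count j (hybrid frequency j / (2 * nh)).
    freqs = bins / (2.0 * nh)
    pmf = binom.pmf(bins[None, :], nh, freqs[:, None])
    expected = parent1.counts @ pmf + parent2.counts @ pmf
    expected = expected + n_fixed_diff * binom.pmf(bins, nh, 0.5)
    return SFS(expected, nh)


def window_score_table(sample: HaplotypeSample, window_size: int = 500_000) -> pd.DataFrame:
    """Per-window summary: bounds, SNP count, and multinomial log-probability."""
    wsfs = window_sfs(sample, window_size)
    g = wsfs.global_sfs
    rows = []
    for i in range(wsfs.n_windows):
        lo, hi = wsfs.window_bounds(i)
        rows.append(
            {
                "window": i,
                "start": lo,
                "end": hi,
                "n_snps": int(wsfs.counts[i].sum()),
                "log_probability": sfs_log_probability(wsfs.window(i), g),
            }
        )
    return pd.DataFrame(rows)
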