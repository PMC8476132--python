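"""The polarized haplotype sample: the common currency of the package.

A :class:`HaplotypeSample` holds the derived-allele states of ``2n``
phased haplotypes at every site that is biallelic and polymorphic *within
the sample*, with strictly increasing positions.  It is produced by the
simulator, read from a polarized VCF, and consumed by the SFS machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["HaplotypeSample"]


@dataclass
class HaplotypeSample:
    """Derived-allele matrix of a phased sample.

    Parameters
    ----------
    positions
        0-based site coordinates, strictly increasing, in ``[0, sequence_length)``.
    genotypes
        ``(n_sites, n_hap)`` array of 0/1 derived-allele states.
    sequence_length
        Chromosome length in bp.
    generation
        Generations since founding of the hybrid population (if known).
    scenario_tag
        Free-text provenance label.
    """

    positions: np.ndarray
    genotypes: np.ndarray
    sequence_length: int
    generation: int | None = None
    scenario_tag: str = ""

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.genotypes = np.asarray(self.genotypes, dtype=np.uint8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be a (n_sites, n_hap) matrix")
        if self.positions.shape[0] != self.genotypes.shape[0]:
            raise ValueError("positions and genotypes disagree on the site count")
        if self.positions.size:
            if np.any(np.diff(self.positions) <= 0):
                raise ValueError("positions must be strictly increasing")
            if self.positions[0] < 0 or self.positions[-1] >= self.sequence_length:
                raise ValueError("positions must lie in [0, sequence_length)")
            counts = self.derived_counts()
            if counts.min() < 1 or counts.max() > self.n_hap - 1:
                raise ValueError("every site must be polymorphic in the sample")

    @property
    def n_sites(self) -> int:
        return int(self.genotypes.shape[0])

    @property
    def n_hap(self) -> int:
        return int(self.genotypes.shape[1])

    def derived_counts(self) -> np.ndarray:
        """Per-site derived-allele counts (each in ``1..n_hap-1``)."""
        return self.genotypes.sum(axis=1, dtype=np.int64)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypeSample):
            return NotImplemented
        return (
            self.sequence_length == other.sequence_length
            and np.array_equal(self.positions, other.positions)
            and np.array_equal(self.genotypes, other.genotypes)
        )
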