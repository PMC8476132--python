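"""Deterministic two-locus gamete-frequency dynamics for the hybrid sink.

An infinite-population recursion on the four gamete frequencies
(AB, Ab, aB, ab) under the same life cycle as the individual-based
simulator: random union of gametes, viability selection against the
incompatibility, meiosis with recombination fraction ``c`` between the two
loci, then replacement of a fraction ``m`` of the gamete pool by each
source (source 1 contributes only ``Ab`` gametes, source 2 only ``aB``).

This serves as an independent check on the stochastic simulator: at large
population size the simulated allele-frequency trajectory should track this
recursion to within Monte-Carlo error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import SimParams
from .sim import epistatic_fitness

__all__ = ["GameteState", "recursion_step", "iterate_recursion", "equilibrium_frequency"]

# Gamete order: index -> (derived-A, derived-B)
_GAMETES = ((1, 1), (1, 0), (0, 1), (0, 0))  # AB, Ab, aB, ab
_IDX_AB, _IDX_Ab, _IDX_aB, _IDX_ab = 0, 1, 2, 3


@dataclass(frozen=True)
class GameteState:
    """Frequencies of the four gametes (AB, Ab, aB, ab)."""

    x: np.ndarray

    @property
    def freq_A(self) -> float:
        return float(self.x[_IDX_AB] + self.x[_IDX_Ab])

    @property
    def freq_B(self) -> float:
        return float(self.x[_IDX_AB] + self.x[_IDX_aB])


def _fitness_matrix(params: SimParams) -> np.ndarray:
    w = np.empty((4, 4))
    for i, (ai, bi) in enumerate(_GAMETES):
        for j, (aj, bj) in enumerate(_GAMETES):
            w[i, j] = epistatic_fitness(ai + aj, bi + bj, params)
    return w


def recursion_step(x: np.ndarray, params: SimParams, c: float = 0.5) -> np.ndarray:
    """Advance the gamete frequencies by one generation."""
    x = np.asarray(x, dtype=float)
    W = _fitness_matrix(params)
    F = np.outer(x, x) * W
    wbar = F.sum()
    if wbar <= 0:
        raise RuntimeError("mean fitness is zero; the population is inviable")
    F /= wbar

    y = np.zeros(4)
    for i, (ai, bi) in enumerate(_GAMETES):
        for j, (aj, bj) in enumerate(_GAMETES):
            f = F[i, j]
            if f == 0.0:
                continue
            # Parental gametes with probability 1-c, recombinants with c.
            y[i] += f * (1 - c) / 2
            y[j] += f * (1 - c) / 2
            r1 = _GAMETES.index((ai, bj))
            r2 = _GAMETES.index((aj, bi))
            y[r1] += f * c / 2
            y[r2] += f * c / 2

    m = params.m
    y = (1 - 2 * m) * y
    y[_IDX_Ab] += m  # source 1 is fixed for derived A, ancestral b
    y[_IDX_aB] += m  # source 2 is fixed for ancestral a, derived B
    return y


def iterate_recursion(
    params: SimParams,
    c: float = 0.5,
    x0: np.ndarray | None = None,
    max_iter: int = 100_000,
    tol: float = 1e-12,
    record: bool = False,
) -> tuple[GameteState, int, np.ndarray | None]:
    """Iterate from the 50:50 founding composition to stationarity.

    Returns the stationary state, the number of generations used, and (if
    ``record``) the trajectory of the derived-A frequency.
    """
    x = np.array([0.0, 0.5, 0.5, 0.0]) if x0 is None else np.asarray(x0, float)
    traj = [x[_IDX_AB] + x[_IDX_Ab]] if record else None
    for it in range(1, max_iter + 1):
        x_new = recursion_step(x, params, c=c)
        if record:
            traj.append(x_new[_IDX_AB] + x_new[_IDX_Ab])
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            break
        x = x_new
    return GameteState(x), it, (np.asarray(traj) if record else None)


def equilibrium_frequency(
    eps: float = -0.5,
    m: float = 0.05,
    s_a: float = 0.0,
    s_b: float = 0.0,
    dominance: str = "codominant",
    c: float = 0.5,
) -> float:
    """Stationary frequency of the derived incompatible A allele in the sink.

    Convenience wrapper around :func:`iterate_recursion` with free
    recombination between the loci and symmetric per-source migration.
    """
    params = SimParams(m=m, eps=eps, s_a=s_a, s_b=s_b, dominance=dominance)
    state, _, _ = iterate_recursion(params, c=c)
    return state.freq_A
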