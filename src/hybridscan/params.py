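"""Simulation parameters and the named hybrid-zone scenarios.

The model is a two-source / one-sink hybrid zone: two parental populations
of ``Np`` diploids diverge in allopatry for ``n_burnin`` generations, after
which a hybrid population of ``N`` diploids is founded as a 50:50 mixture
and thereafter receives migrants from each source at rate ``m`` per
generation.  Two incompatibility loci (derived allele *A* fixed in source 1,
derived allele *B* fixed in source 2) interact epistatically with
coefficient ``eps`` <= 0; the ancestral alleles may additionally carry
single-locus disadvantages ``s_a`` and ``s_b``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

__all__ = ["SimParams", "SCENARIOS", "scenario_params"]


@dataclass(frozen=True)
class SimParams:
    """All demographic, genomic and selective parameters of one run.

    Rates ``mu`` and ``r`` are per base pair per generation *before* the
    ``rescale`` speed-up factor; the effective rates used by the simulator
    are ``mu * rescale`` and ``r * rescale`` (a larger chromosome is
    represented by fewer, more mutable base pairs, keeping ``L*mu`` and
    ``L*r`` constant).
    """

    Np: int = 5_000
    N: int = 10_000
    n_burnin: int = 50_000
    mu: float = 1e-9
    r: float = 5e-9
    m: float = 0.005
    L: int = 500_000_000
    pos_A: int = 175_000_000
    pos_B: int = 325_000_000
    eps: float = -0.1
    s_a: float = 0.0
    s_b: float = 0.0
    dominance: str = "codominant"
    rescale: int = 10
    seed: int | None = None
    sample_size: int = 50
    sample_generations: tuple[int, ...] = (100, 1_000, 5_000, 10_000)

    def __post_init__(self) -> None:
        if min(self.Np, self.N, self.n_burnin, self.L) <= 0:
            raise ValueError("Np, N, n_burnin and L must be positive")
        if not 0.0 <= self.m <= 0.5:
            raise ValueError("migration rate m must lie in [0, 0.5] per source")
        if not -1.0 <= self.eps <= 0.0:
            raise ValueError("epistasis coefficient eps must lie in [-1, 0]")
        for s in (self.s_a, self.s_b):
            if not -1.0 <= s <= 0.0:
                raise ValueError("single-locus coefficients must lie in [-1, 0]")
        if not 0 <= self.pos_A < self.pos_B < self.L:
            raise ValueError("need 0 <= pos_A < pos_B < L")
        if self.mu < 0 or self.r < 0:
            raise ValueError("mutation and recombination rates must be >= 0")
        if self.dominance not in ("recessive", "codominant"):
            raise ValueError("dominance must be 'recessive' or 'codominant'")
        if self.rescale < 1:
            raise ValueError("rescale factor must be >= 1")
        if self.sample_size <= 0:
            raise ValueError("sample_size must be positive")

    # Effective per-bp rates after the chromosome-compression speed-up.
    @property
    def mu_eff(self) -> float:
        return self.mu * self.rescale

    @property
    def r_eff(self) -> float:
        return self.r * self.rescale

    @property
    def selection_coefficients(self) -> tuple[float, float, float]:
        return (self.s_a, self.s_b, self.eps)

    def scaled(self, lam: int, genome_shrink: int = 1) -> "SimParams":
        """Desk-scale preset: shrink sizes and times by ``lam``, speed rates up.

        Population sizes, burn-in length and sampling times are divided by
        ``lam`` while per-bp rates (and the magnitudes of the selection
        coefficients) are multiplied by ``lam``, preserving N*mu, N*r, N*m
        and N*|eps|; coefficients are clipped to their valid ranges
        (m <= 0.5, eps >= -1, s >= -1).  ``genome_shrink`` additionally
        divides the chromosome length and the locus positions, leaving the
        per-bp rates untouched (so the genome simply carries fewer sites).
        """
        if lam < 1 or genome_shrink < 1:
            raise ValueError("lam and genome_shrink must be >= 1")

        def clip_neg(x: float) -> float:
            return max(-1.0, x * lam)

        return replace(
            self,
            Np=max(2, self.Np // lam),
            N=max(2, self.N // lam),
            n_burnin=max(1, self.n_burnin // lam),
            mu=self.mu * lam,
            r=self.r * lam,
            m=min(0.5, self.m * lam),
            eps=clip_neg(self.eps),
            s_a=clip_neg(self.s_a),
            s_b=clip_neg(self.s_b),
            L=max(2, self.L // genome_shrink),
            pos_A=self.pos_A // genome_shrink,
            pos_B=self.pos_B // genome_shrink,
            sample_generations=tuple(max(1, g // lam) for g in self.sample_generations),
        )


def _scenario(eps: float, s: float, m: float, dominance: str = "codominant") -> dict:
    return {"eps": eps, "s_a": s, "s_b": s, "m": m, "dominance": dominance}


#: Named scenarios: combinations of epistasis strength, single-locus
#: selection against the ancestral alleles, and migration rate.  The
#: ``... rec.`` variants make the double-heterozygote fitness cost fully
#: recessive.  Note the combined single-locus + epistasis scenario uses the
#: default migration rate.
SCENARIOS: dict[str, dict] = {
    "Default": _scenario(-0.1, 0.0, 0.005),
    "Default rec.": _scenario(-0.1, 0.0, 0.005, "recessive"),
    "Low ep.": _scenario(-0.02, 0.0, 0.005),
    "Low ep. rec.": _scenario(-0.02, 0.0, 0.005, "recessive"),
    "High ep.": _scenario(-0.5, 0.0, 0.005),
    "High ep. rec.": _scenario(-0.5, 0.0, 0.005, "recessive"),
    "Low mig.": _scenario(-0.1, 0.0, 0.0005),
    "Low mig. rec.": _scenario(-0.1, 0.0, 0.0005, "recessive"),
    "High mig.": _scenario(-0.1, 0.0, 0.05),
    "High mig. rec.": _scenario(-0.1, 0.0, 0.05, "recessive"),
    "High mig. high ep.": _scenario(-0.5, 0.0, 0.05),
    "High mig. high ep. rec.": _scenario(-0.5, 0.0, 0.05, "recessive"),
    "Neu.": _scenario(0.0, 0.0, 0.005),
    "SL-sel.": _scenario(0.0, -0.02, 0.005),
    "High SL-sel.": _scenario(0.0, -0.1, 0.005),
    "SL-sel. and ep.": _scenario(-0.1, -0.02, 0.005),
    "SL-sel. and ep. rec.": _scenario(-0.1, -0.02, 0.005, "recessive"),
}


def scenario_params(name: str, seed: int | None = None, **overrides) -> SimParams:
    """Build a :class:`SimParams` for a named scenario.

    Extra keyword arguments override any field (handy for desk-scale runs).
    """
    if name not in SCENARIOS:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(SCENARIOS))}"
        )
    kwargs = dict(SCENARIOS[name])
    kwargs.update(overrides)
    return SimParams(seed=seed, **kwargs)
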