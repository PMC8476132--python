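"""Individual-based forward simulation of a two-source / hybrid-sink system.

Two parental populations of ``Np`` diploids accumulate neutral variation
(and fixed differences) during an allopatric burn-in; a hybrid population
of ``N`` diploids is then founded as a 50:50 mixture and evolves under
migration from both sources, uniform recombination, neutral mutation, and
viability selection against the two-locus incompatibility.

All populations share one :class:`SiteRegistry` of segregating neutral
sites; haplotypes are stored as packed 64-bit words (one bit per site), so
a meiosis is a handful of word-range copy/xor operations per crossover
segment rather than a per-site loop.  Between prunes, newly arisen
mutations live in a small unsorted tail of the registry and are handled
site by site; every prune compacts, re-sorts the registry by position and
restores the fully packed fast path.  Mutation follows the infinite-sites
approximation (unique integer positions, no recurrence), recombination is
a Poisson number of crossovers placed uniformly, and viability selection
is implemented by rejection sampling of offspring so the census size never
changes.  The allele copied at position q comes from parental strand
``(start + #{breakpoints <= q}) mod 2``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .params import SimParams
from .sample import HaplotypeSample

__all__ = [
    "epistatic_fitness",
    "Haplotype",
    "Population",
    "SiteRegistry",
    "ParentalState",
    "CoalescentAncestry",
    "Simulation",
    "run_burn_in",
    "simulate_scenario",
]

_H1 = {"recessive": 0.0, "codominant": 1.0}

# Registry housekeeping: compact, drop dead columns and re-sort by position
# this often.  Most new mutations are lost within a few generations, so
# regular pruning keeps every per-generation pass close to the
# standing-variation size.
_PRUNE_INTERVAL = 10

_WORD = 64
_ALL_ONES = (1 << _WORD) - 1


def _mask(lo_bit: int, hi_bit: int) -> np.uint64:
    """Word mask selecting bits [lo_bit, hi_bit) of a 64-bit word."""
    return np.uint64(((1 << hi_bit) - (1 << lo_bit)) & _ALL_ONES)


# lookup tables: _LOW[b] keeps bits [0, b), _HIGH[b] keeps bits [b, 64)
_LOW = np.array([int(_mask(0, b)) for b in range(_WORD + 1)], dtype=np.uint64)
_HIGH = np.array([int(_mask(b, _WORD)) for b in range(_WORD + 1)], dtype=np.uint64)

try:  # compiled kernels; the numpy paths below are the tested reference
    from numba import njit as _njit

    @_njit(cache=True)
    def _meiosis_kernel(W, out, parents, starts, nwu, n_sorted, cuts_flat,
                        bp_flat, bp_offs, het_col, het_offs, tail_pos,
                        low, high):  # pragma: no cover - compiled
        one = np.uint64(1)
        for g in range(out.shape[0]):
            par = parents[g]
            h0 = 2 * par + starts[g]
            out[g, :nwu] = W[h0, :nwu]
            b0, b1 = bp_offs[g], bp_offs[g + 1]
            if b0 == b1:
                continue
            h1 = 2 * par + 1 - starts[g]
            k = b1 - b0
            for j in range(1, k + 1, 2):
                a = cuts_flat[b0 + j - 1]
                b = cuts_flat[b0 + j] if j < k else n_sorted
                if a >= b:
                    continue
                wa = a >> 6
                ba = a & 63
                wb = b >> 6
                bb = b & 63
                if wa == wb:
                    m = high[ba] & low[bb]
                    out[g, wa] ^= (W[h0, wa] ^ W[h1, wa]) & m
                else:
                    out[g, wa] ^= (W[h0, wa] ^ W[h1, wa]) & high[ba]
                    for w in range(wa + 1, wb):
                        out[g, w] ^= W[h0, w] ^ W[h1, w]
                    if bb:
                        out[g, wb] ^= (W[h0, wb] ^ W[h1, wb]) & low[bb]
            # unsorted-tail sites: per-site strand parity
            for e in range(het_offs[par], het_offs[par + 1]):
                t = het_col[e]
                q = tail_pos[t]
                lo, hi = b0, b1
                while lo < hi:  # count breakpoints <= q
                    mid = (lo + hi) // 2
                    if bp_flat[mid] <= q:
                        lo = mid + 1
                    else:
                        hi = mid
                if (lo - b0) & 1:
                    col = n_sorted + t
                    out[g, col >> 6] ^= one << np.uint64(col & 63)

    @_njit(cache=True)
    def _gather_pack_kernel(W, col_idx, out):  # pragma: no cover - compiled
        one = np.uint64(1)
        out[:] = 0
        for r in range(W.shape[0]):
            for j in range(col_idx.shape[0]):
                c = col_idx[j]
                if (W[r, c >> 6] >> np.uint64(c & 63)) & one:
                    out[r, j >> 6] |= one << np.uint64(j & 63)

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def epistatic_fitness(XA, XB, params: SimParams):
    """Viability of a genotype carrying ``XA`` and ``XB`` derived alleles.

    w = (1+s_a)^(2-XA) * (1+s_b)^(2-XB) * (1 + h_{XA*XB} * eps)^(XA*XB)

    where the dominance coefficient of the epistatic interaction is
    ``h_1 = 0`` (recessive) or ``1`` (codominant) for the double
    heterozygote and ``h_k = 1`` otherwise.  Accepts scalars or arrays.
    """
    scalar = np.isscalar(XA) and np.isscalar(XB)
    XA = np.asarray(XA)
    XB = np.asarray(XB)
    if np.any((XA < 0) | (XA > 2)) or np.any((XB < 0) | (XB > 2)):
        raise ValueError("XA and XB must be diploid allele counts in {0, 1, 2}")
    k = XA * XB
    h = np.where(k == 1, _H1[params.dominance], 1.0)
    w = (
        (1.0 + params.s_a) ** (2 - XA)
        * (1.0 + params.s_b) ** (2 - XB)
        * (1.0 + h * params.eps) ** k
    )
    return float(w) if scalar else w


@dataclass(frozen=True)
class Haplotype:
    """Sparse view of one haplotype: derived neutral positions + selected loci."""

    derived_sites: np.ndarray
    allele_A: int
    allele_B: int


class SiteRegistry:
    """Shared registry of neutral segregating sites across all populations.

    Column ``j`` of every attached population refers to ``positions[j]``.
    Columns ``[0, n_sorted)`` are sorted by position (the packed fast path);
    columns ``[n_sorted, n)`` are the unsorted tail of recent mutations.
    Positions are unique (infinite sites) and exclude the two selected
    loci, which are tracked separately.
    """

    def __init__(self, L: int, reserved: tuple[int, ...] = ()):
        self.L = int(L)
        self.positions = np.empty(1024, dtype=np.int64)
        self.n = 0
        self.n_sorted = 0
        self.reserved = frozenset(int(p) for p in reserved)
        self.active: set[int] = set(self.reserved)
        self._pops: list["Population"] = []

    @property
    def capacity(self) -> int:
        return self.positions.shape[0]

    @property
    def n_words(self) -> int:
        return self.capacity // _WORD

    def attach(self, pop: "Population") -> None:
        self._pops.append(pop)

    def _grow(self, need: int) -> None:
        newcap = self.capacity
        while newcap < need:
            newcap *= 2
        if newcap == self.capacity:
            return
        pos = np.empty(newcap, dtype=np.int64)
        pos[: self.n] = self.positions[: self.n]
        self.positions = pos
        for pop in self._pops:
            pop._grow(newcap // _WORD)

    def draw_new_positions(self, count: int, rng: np.random.Generator) -> np.ndarray:
        """Sample ``count`` fresh unique positions not currently in use."""
        out = np.empty(count, dtype=np.int64)
        filled = 0
        while filled < count:
            cand = rng.integers(0, self.L, size=count - filled)
            for p in cand:
                p = int(p)
                if p not in self.active:
                    self.active.add(p)
                    out[filled] = p
                    filled += 1
        return out[:count]

    def add_sites(self, new_positions: np.ndarray) -> np.ndarray:
        """Register new positions (in the unsorted tail); return column indices."""
        k = len(new_positions)
        self._grow(self.n + k)
        cols = np.arange(self.n, self.n + k)
        self.positions[self.n : self.n + k] = new_positions
        # fresh columns must start derived-free: clear any stale buffer bits
        a, b = self.n, self.n + k
        wa, ba = a >> 6, a & 63
        wb, bb = b >> 6, b & 63
        for pop in self._pops:
            W = pop.W
            if wa == wb:
                W[:, wa] &= np.uint64(_ALL_ONES ^ int(_mask(ba, bb)))
            else:
                W[:, wa] &= np.uint64(_ALL_ONES ^ int(_mask(ba, _WORD)))
                W[:, wa + 1 : wb] = 0
                if bb:
                    W[:, wb] &= np.uint64(_ALL_ONES ^ int(_mask(0, bb)))
        self.n += k
        return cols

    def prune(self) -> None:
        """Drop dead columns, re-sort by position, repack every population.

        Columns lost everywhere (no bit set in any population) or fixed
        everywhere (set in every haplotype of every population) are found
        with word-level or/and reductions, so no per-column counting is
        needed.
        """
        n = self.n
        if n == 0:
            self.n_sorted = 0
            return
        nw = -(-n // _WORD)
        any_bits = np.zeros(nw, dtype=np.uint64)
        all_bits = np.full(nw, np.uint64(_ALL_ONES))
        for pop in self._pops:
            any_bits |= np.bitwise_or.reduce(pop.W[:, :nw], axis=0)
            all_bits &= np.bitwise_and.reduce(pop.W[:, :nw], axis=0)
        keep_bits = any_bits & ~all_bits
        keep = np.unpackbits(
            keep_bits.view(np.uint8), bitorder="little"
        )[:n].astype(bool)
        for p in self.positions[:n][~keep]:
            self.active.discard(int(p))
        kept_pos = self.positions[:n][keep]
        order = np.argsort(kept_pos, kind="stable")
        m_new = kept_pos.size
        self.positions[:m_new] = kept_pos[order]
        self.n = self.n_sorted = m_new
        col_idx = np.flatnonzero(keep)[order]
        for pop in self._pops:
            if _HAVE_NUMBA:
                _gather_pack_kernel(pop.W, col_idx, pop._buf)
                pop.W, pop._buf = pop._buf, pop.W
            else:
                pop._repack(pop._unpacked(ncols=n)[:, col_idx])


class Population:
    """A diploid population of ``K`` individuals (``2K`` haplotypes).

    Neutral genomes live in ``W``, a ``(2K, n_words)`` array of packed
    64-bit words (bit ``j & 63`` of word ``j >> 6`` is registry column
    ``j``, little-endian within bytes); the two selected loci are the
    boolean arrays ``A`` and ``B``.  The ``G`` property exposes the
    unpacked boolean matrix for inspection (it materializes a copy).
    """

    def __init__(self, label: str, K: int, registry: SiteRegistry):
        self.label = label
        self.K = int(K)
        self.registry = registry
        self.W = np.zeros((2 * self.K, registry.n_words), dtype=np.uint64)
        self._buf = np.zeros_like(self.W)
        self.A = np.zeros(2 * self.K, dtype=bool)
        self.B = np.zeros(2 * self.K, dtype=bool)
        registry.attach(self)

    # -- packed-storage helpers

    def _grow(self, new_words: int) -> None:
        W = np.zeros((2 * self.K, new_words), dtype=np.uint64)
        W[:, : self.W.shape[1]] = self.W
        self.W = W
        self._buf = np.zeros_like(W)

    def _unpacked(self, rows: np.ndarray | slice = slice(None),
                  ncols: int | None = None) -> np.ndarray:
        """Unpack (a copy of) the requested rows to a 0/1 uint8 matrix."""
        if ncols is None:
            ncols = self.registry.capacity
        nw = -(-ncols // _WORD) if ncols else 0
        bytes_view = np.ascontiguousarray(self.W[rows, :nw]).view(np.uint8)
        bits = np.unpackbits(bytes_view, axis=1, bitorder="little")
        return bits[:, :ncols]

    def _repack(self, matrix: np.ndarray) -> None:
        """Replace the genomes with a freshly packed boolean matrix."""
        self.W[:] = 0
        if matrix.shape[1]:
            packed = np.packbits(matrix, axis=1, bitorder="little")
            words = -(-matrix.shape[1] // _WORD)
            padded = np.zeros((matrix.shape[0], words * 8), dtype=np.uint8)
            padded[:, : packed.shape[1]] = packed
            self.W[:, :words] = padded.view(np.uint64)

    def set_bits(self, rows: np.ndarray, cols: np.ndarray) -> None:
        words = cols >> 6
        bits = (np.uint64(1) << (cols & 63).astype(np.uint64))
        np.bitwise_or.at(self.W, (rows, words), bits)

    def copy_members_from(self, other: "Population", src: np.ndarray,
                          dst: np.ndarray) -> None:
        """Copy whole individuals (both strands + selected loci)."""
        for off in (0, 1):
            self.W[2 * dst + off] = other.W[2 * src + off]
            self.A[2 * dst + off] = other.A[2 * src + off]
            self.B[2 * dst + off] = other.B[2 * src + off]

    # -- inspection

    @property
    def G(self) -> np.ndarray:
        """Unpacked boolean genotype matrix (haplotypes x registry columns)."""
        return self._unpacked().astype(bool)

    def derived_counts(self) -> np.ndarray:
        n = self.registry.n
        return self._unpacked(ncols=n).sum(axis=0, dtype=np.int64)

    def haplotype(self, i: int) -> Haplotype:
        """Sparse view of haplotype ``i`` (positions sorted)."""
        n = self.registry.n
        row = self._unpacked(rows=np.array([i]), ncols=n)[0].astype(bool)
        pos = self.registry.positions[:n][row]
        return Haplotype(np.sort(pos), int(self.A[i]), int(self.B[i]))

    def allele_frequency_A(self) -> float:
        return float(self.A.mean())

    def allele_frequency_B(self) -> float:
        return float(self.B.mean())


@dataclass
class ParentalState:
    """Snapshot of the two parental populations after burn-in (reusable)."""

    registry: SiteRegistry
    p1: Population
    p2: Population
    generations_done: int

    def copy(self) -> "ParentalState":
        return copy.deepcopy(self)

    def fixed_difference_count(self) -> int:
        """Sites fixed for the derived allele in one source and absent in the other."""
        n = self.registry.n
        c1 = self.p1._unpacked(ncols=n).sum(axis=0, dtype=np.int64)
        c2 = self.p2._unpacked(ncols=n).sum(axis=0, dtype=np.int64)
        h1, h2 = 2 * self.p1.K, 2 * self.p2.K
        return int(np.sum(((c1 == h1) & (c2 == 0)) | ((c1 == 0) & (c2 == h2))))


class CoalescentAncestry:
    """Coalescent stand-in for the allopatric burn-in, reusable across runs.

    Simulates (once) the recombination genealogy of the two sources — two
    populations of ``Np`` diploids splitting ``n_burnin`` generations ago —
    and lets callers draw parental states with independent neutral mutation
    overlays restricted to ages younger than the split, so the sources
    start from identical genomes exactly as in the forward model.  This is
    an approximation (a continuous-time genealogy in place of discrete
    Wright-Fisher reproduction).  Drawing several states from one ancestry
    shares the genealogy but not the mutations: a variance/compute
    trade-off for desk-scale replicate studies, where fully independent
    ancestries are preferable when affordable.
    """

    def __init__(self, params: SimParams, seed: int | None = None):
        import msprime

        self.params = params
        dem = msprime.Demography()
        dem.add_population(name="p1", initial_size=params.Np)
        dem.add_population(name="p2", initial_size=params.Np)
        dem.add_population(name="anc", initial_size=params.Np)
        dem.add_population_split(
            time=params.n_burnin, derived=["p1", "p2"], ancestral="anc"
        )
        self.ts = msprime.sim_ancestry(
            samples={"p1": params.Np, "p2": params.Np},
            demography=dem,
            sequence_length=params.L,
            recombination_rate=params.r_eff,
            ploidy=2,
            random_seed=seed,
        )

    def draw_state(self, mutation_seed: int) -> ParentalState:
        """Overlay a fresh neutral mutation history and build the sources."""
        import msprime

        p = self.params
        mts = msprime.sim_mutations(
            self.ts,
            rate=p.mu_eff,
            end_time=p.n_burnin,  # no variation predates the allopatric split
            model=msprime.BinaryMutationModel(),
            random_seed=mutation_seed,
        )
        # Enforce the infinite-sites contract: exactly one mutation per kept
        # site, and keep clear of the selected-locus coordinates.
        muts_per_site = np.bincount(
            mts.mutations_site.astype(np.int64), minlength=mts.num_sites
        )
        site_pos = mts.sites_position.astype(np.int64)
        keep = (muts_per_site == 1) & (site_pos != p.pos_A) & (site_pos != p.pos_B)
        gm = mts.genotype_matrix()[keep].astype(bool)
        positions = site_pos[keep]

        reg = SiteRegistry(p.L, reserved=(p.pos_A, p.pos_B))
        p1 = Population("parent1", p.Np, reg)
        p2 = Population("parent2", p.Np, reg)
        reg.add_sites(positions)
        reg.active.update(int(x) for x in positions)
        n1 = 2 * p.Np
        p1._repack(gm[:, :n1].T)
        p2._repack(gm[:, n1 : 2 * n1].T)
        p1.A[:] = True
        p2.B[:] = True
        reg.prune()
        return ParentalState(reg, p1, p2, p.n_burnin)


class Simulation:
    """One hybrid-zone run: burn-in, founding, generation stepping, sampling.

    All randomness flows through a single seeded generator, so identical
    parameters and seed give bit-identical samples.
    """

    def __init__(self, params: SimParams, rng: np.random.Generator | None = None):
        self.params = params
        self.rng = rng if rng is not None else np.random.default_rng(params.seed)
        self.registry: SiteRegistry | None = None
        self.p1: Population | None = None
        self.p2: Population | None = None
        self.hybrid: Population | None = None
        self.generation: int | None = None  # counts from hybrid founding

    # ------------------------------------------------------------------ burn-in

    def run_burn_in(self, method: str = "forward") -> ParentalState:
        """Diverge the two parental populations in allopatry.

        ``method="forward"`` runs the full individual-based burn-in from
        identical, variation-free genomes (the reference behaviour).
        ``method="coalescent"`` draws an equivalent parental sample from a
        coalescent model with mutations restricted to the last ``n_burnin``
        generations — an approximation (continuous-time genealogy in place
        of discrete Wright-Fisher reproduction) that is orders of magnitude
        faster and is intended for desk-scale work.
        """
        p = self.params
        if method == "forward":
            reg = SiteRegistry(p.L, reserved=(p.pos_A, p.pos_B))
            self.p1 = Population("parent1", p.Np, reg)
            self.p2 = Population("parent2", p.Np, reg)
            self.registry = reg
            # Reciprocal fixed differences at the two selected loci.
            self.p1.A[:] = True
            self.p2.B[:] = True
            for g in range(p.n_burnin):
                self._reproduce(self.p1, select=False)
                self._reproduce(self.p2, select=False)
                if (g + 1) % _PRUNE_INTERVAL == 0:
                    reg.prune()
            reg.prune()
        elif method == "coalescent":
            self._coalescent_burn_in()
        else:
            raise ValueError("burn-in method must be 'forward' or 'coalescent'")
        return ParentalState(self.registry, self.p1, self.p2, p.n_burnin)

    def _coalescent_burn_in(self) -> None:
        s1, s2 = self.rng.integers(1, 2**31 - 1, size=2)
        ancestry = CoalescentAncestry(self.params, seed=int(s1))
        state = ancestry.draw_state(int(s2))
        self.registry = state.registry
        self.p1 = state.p1
        self.p2 = state.p2

    def set_parental_state(self, state: ParentalState) -> None:
        """Adopt (a private copy of) a cached burn-in result."""
        state = state.copy()
        self.registry = state.registry
        self.p1 = state.p1
        self.p2 = state.p2

    # ------------------------------------------------------------------ founding

    def found_hybrid(self) -> Population:
        """Found the hybrid sink as a 50:50 draw from the two sources.

        Each founder is copied (not removed) from parent 1 with probability
        0.5, else from parent 2; the generation counter starts at 0.
        """
        if self.p1 is None or self.p2 is None:
            raise RuntimeError("run (or set) the burn-in before founding the hybrid")
        p = self.params
        hyb = Population("hybrid", p.N, self.registry)
        from_p1 = self.rng.random(p.N) < 0.5
        donor_idx = self.rng.integers(0, p.Np, size=p.N)
        for src_pop, mask in ((self.p1, from_p1), (self.p2, ~from_p1)):
            tgt = np.flatnonzero(mask)
            hyb.copy_members_from(src_pop, donor_idx[tgt], tgt)
        self.hybrid = hyb
        self.generation = 0
        return hyb

    # ------------------------------------------------------------------ stepping

    def advance_generation(self) -> None:
        """One life cycle for all three populations.

        The sources evolve neutrally (and keep accumulating divergence);
        hybrid offspring are formed by random mating with recombination and
        mutation and survive with probability equal to their viability
        (rejected juveniles are redrawn, keeping N constant); finally a
        binomial number of hybrids (mean ``m*N`` per source) is replaced by
        copies of randomly chosen parental individuals.  Migrants face
        selection at the next reproduction, not on arrival.
        """
        if self.hybrid is None:
            raise RuntimeError("found the hybrid population before stepping")
        self._reproduce(self.p1, select=False)
        self._reproduce(self.p2, select=False)
        self._reproduce(self.hybrid, select=True)
        self._migrate()
        self.generation += 1
        if self.generation % _PRUNE_INTERVAL == 0:
            self.registry.prune()

    def _migrate(self) -> None:
        p = self.params
        if p.m == 0.0:
            return
        n1 = int(self.rng.binomial(p.N, p.m))
        n2 = int(self.rng.binomial(p.N, p.m))
        ntot = min(n1 + n2, p.N)
        if ntot == 0:
            return
        targets = self.rng.choice(p.N, size=ntot, replace=False)
        donors = self.rng.integers(0, p.Np, size=ntot)
        cut = min(n1, ntot)
        for src_pop, sl in ((self.p1, slice(0, cut)), (self.p2, slice(cut, ntot))):
            if targets[sl].size:
                self.hybrid.copy_members_from(src_pop, donors[sl], targets[sl])

    # ------------------------------------------------------------------ meiosis

    def _reproduce(self, pop: Population, select: bool) -> None:
        p = self.params
        rng = self.rng
        K = pop.K
        r_genome = p.r_eff * p.L

        parents = np.empty(2 * K, dtype=np.int64)  # per-gamete parent individual
        newA = np.empty(2 * K, dtype=bool)
        newB = np.empty(2 * K, dtype=bool)
        bps_all: list[np.ndarray] = [None] * (2 * K)
        start_all = np.empty(2 * K, dtype=np.int64)

        filled = 0
        rounds = 0
        while filled < K:
            rounds += 1
            if rounds > 200:
                raise RuntimeError(
                    "viability selection rejected every proposed offspring; "
                    "all genotypes appear inviable"
                )
            chunk = K - filled
            c_mom = rng.integers(0, K, size=chunk)
            c_dad = rng.integers(0, K, size=chunk)
            nx = rng.poisson(r_genome, size=2 * chunk)
            starts = rng.integers(0, 2, size=2 * chunk)
            flat = rng.integers(0, p.L, size=int(nx.sum()))
            offs = np.concatenate(([0], np.cumsum(nx)))

            # Parity of the copied strand at the two selected loci: the
            # start strand switched once per breakpoint left of the locus.
            par_g = np.empty(2 * chunk, dtype=np.int64)
            par_g[0::2] = c_mom
            par_g[1::2] = c_dad
            cntA = np.concatenate(([0], np.cumsum(flat <= p.pos_A)))
            cntB = np.concatenate(([0], np.cumsum(flat <= p.pos_B)))
            pa = (starts + (cntA[offs[1:]] - cntA[offs[:-1]])) & 1
            pb = (starts + (cntB[offs[1:]] - cntB[offs[:-1]])) & 1
            gamA = pop.A[2 * par_g + pa]
            gamB = pop.B[2 * par_g + pb]

            XA = gamA[0::2].astype(np.int64) + gamA[1::2]
            XB = gamB[0::2].astype(np.int64) + gamB[1::2]
            if select:
                w = epistatic_fitness(XA, XB, p)
                acc = rng.random(chunk) < w
            else:
                acc = np.ones(chunk, dtype=bool)
            for j in np.flatnonzero(acc):
                c = filled
                for g in (0, 1):
                    parents[2 * c + g] = par_g[2 * j + g]
                    bps_all[2 * c + g] = np.sort(
                        flat[offs[2 * j + g] : offs[2 * j + g + 1]]
                    )
                    start_all[2 * c + g] = starts[2 * j + g]
                    newA[2 * c + g] = gamA[2 * j + g]
                    newB[2 * c + g] = gamB[2 * j + g]
                filled += 1
                if filled == K:
                    break

        self._build_offspring_genomes(pop, parents, start_all, bps_all)
        pop.A = newA
        pop.B = newB

        # New neutral mutations in the offspring gametes (infinite sites).
        mu_genome = p.mu_eff * p.L
        if mu_genome > 0:
            counts = rng.poisson(mu_genome, size=2 * K)
            total = int(counts.sum())
            if total:
                reg = pop.registry
                newpos = reg.draw_new_positions(total, rng)
                cols = reg.add_sites(newpos)
                rows = np.repeat(np.arange(2 * K), counts)
                pop.set_bits(rows, cols)

    def _build_offspring_genomes(self, pop, parents, start_all, bps_all) -> None:
        """Word-level meiosis: copy the start strand, xor in the other
        strand's differences over odd-parity crossover segments."""
        reg = pop.registry
        n, n_sorted = reg.n, reg.n_sorted
        sorted_pos = reg.positions[:n_sorted]
        tail_pos = reg.positions[n_sorted:n]
        W = pop.W
        out_all = pop._buf
        n_words_used = -(-n // _WORD) if n else 0

        # Heterozygous tail sites (recent mutations, unsorted region) per
        # individual, precomputed once: the per-site fix-up path below only
        # walks these short lists.
        if n > n_sorted:
            w_lo = n_sorted >> 6
            tail_bits = np.unpackbits(
                np.ascontiguousarray(W[:, w_lo:n_words_used]).view(np.uint8),
                axis=1, bitorder="little",
            )
            tail_bits = tail_bits[:, n_sorted - w_lo * _WORD : n - w_lo * _WORD]
            het_ind, het_col = np.nonzero(tail_bits[0::2] != tail_bits[1::2])
            het_col = het_col.astype(np.int64)
            het_offs = np.zeros(pop.K + 1, dtype=np.int64)
            het_offs[1:] = np.cumsum(np.bincount(het_ind, minlength=pop.K))
        else:
            tail_bits = None
            het_col = np.zeros(0, dtype=np.int64)
            het_offs = np.zeros(pop.K + 1, dtype=np.int64)

        if _HAVE_NUMBA:
            bp_offs = np.zeros(2 * pop.K + 1, dtype=np.int64)
            bp_offs[1:] = np.cumsum([b.size for b in bps_all])
            bp_flat = (
                np.concatenate(bps_all) if bp_offs[-1] else np.zeros(0, np.int64)
            )
            cuts_flat = np.searchsorted(sorted_pos, bp_flat, side="left")
            _meiosis_kernel(
                W, out_all, parents, start_all, n_words_used, n_sorted,
                cuts_flat.astype(np.int64), bp_flat, bp_offs, het_col,
                het_offs, np.ascontiguousarray(tail_pos), _LOW, _HIGH,
            )
            pop._buf = pop.W
            pop.W = out_all
            return

        for g in range(2 * pop.K):
            par = int(parents[g])
            st = int(start_all[g])
            h0 = 2 * par + st
            out = out_all[g]
            out[:n_words_used] = W[h0, :n_words_used]
            bps = bps_all[g]
            if not bps.size:
                continue
            h1 = 2 * par + 1 - st
            x = W[h0, :n_words_used] ^ W[h1, :n_words_used]
            # crossover breakpoints -> sorted-column boundaries; segment j
            # (columns [c_j, c_{j+1})) uses the other strand when j is odd
            cuts = np.searchsorted(sorted_pos, bps, side="left")
            k = cuts.size
            for j in range(1, k + 1, 2):
                a = int(cuts[j - 1])
                b = int(cuts[j]) if j < k else n_sorted
                if a >= b:
                    continue
                wa, ba = a >> 6, a & 63
                wb, bb = b >> 6, b & 63
                if wa == wb:
                    out[wa] ^= x[wa] & (_HIGH[ba] & _LOW[bb])
                else:
                    out[wa] ^= x[wa] & _HIGH[ba]
                    out[wa + 1 : wb] ^= x[wa + 1 : wb]
                    if bb:
                        out[wb] ^= x[wb] & _LOW[bb]
            # unsorted tail: per-site parity for heterozygous tail sites
            if tail_bits is not None and het_offs[par] < het_offs[par + 1]:
                idx = het_col[het_offs[par] : het_offs[par + 1]]
                odd = (np.searchsorted(bps, tail_pos[idx], side="right") & 1) == 1
                for t in idx[odd]:
                    col = n_sorted + int(t)
                    out[col >> 6] ^= np.uint64(1) << np.uint64(col & 63)

        pop._buf = pop.W
        pop.W = out_all

    # ------------------------------------------------------------------ sampling

    def sample_haplotypes(self, tag: str = "") -> HaplotypeSample:
        """Sample ``sample_size`` diploids without replacement from the hybrid.

        Only sites biallelic and polymorphic within the sample are retained;
        the selected loci enter as ordinary biallelic sites when they are
        polymorphic in the sample.  Sampled individuals stay in the
        population.
        """
        p = self.params
        if self.hybrid is None:
            raise RuntimeError("no hybrid population to sample")
        if p.sample_size > p.N:
            raise ValueError("sample_size exceeds the hybrid population size")
        idx = self.rng.choice(p.N, size=p.sample_size, replace=False)
        rows = np.empty(2 * p.sample_size, dtype=np.int64)
        rows[0::2] = 2 * idx
        rows[1::2] = 2 * idx + 1
        n = self.registry.n
        sub = self.hybrid._unpacked(rows=rows, ncols=n)
        counts = sub.sum(axis=0, dtype=np.int64)
        nh = 2 * p.sample_size
        poly = (counts > 0) & (counts < nh)
        positions = self.registry.positions[:n][poly]
        mat = sub[:, poly]

        extra_pos = []
        extra_cols = []
        for locus_pos, alleles in ((p.pos_A, self.hybrid.A), (p.pos_B, self.hybrid.B)):
            col = alleles[rows]
            c = int(col.sum())
            if 0 < c < nh:
                extra_pos.append(locus_pos)
                extra_cols.append(col)
        if extra_pos:
            positions = np.concatenate([positions, np.asarray(extra_pos)])
            mat = np.concatenate([mat, np.stack(extra_cols, axis=1)], axis=1)

        order = np.argsort(positions, kind="stable")
        return HaplotypeSample(
            positions=positions[order],
            genotypes=mat[:, order].T.astype(np.uint8),
            sequence_length=p.L,
            generation=self.generation,
            scenario_tag=tag,
        )


# ---------------------------------------------------------------------- helpers


def run_burn_in(
    params: SimParams,
    method: str = "forward",
    rng: np.random.Generator | None = None,
) -> ParentalState:
    """Run (once) the allopatric burn-in; the result is reusable across
    replicates that share the same genomic architecture."""
    sim = Simulation(params, rng=rng)
    return sim.run_burn_in(method=method)


def simulate_scenario(
    params: SimParams,
    parental_state: ParentalState | None = None,
    burn_in: str = "forward",
    sample_generations: tuple[int, ...] | None = None,
    tag: str = "",
    rng: np.random.Generator | None = None,
) -> dict[int, HaplotypeSample]:
    """End-to-end run: burn-in (or cached state), founding, sampling schedule.

    Returns a mapping from sampling generation to the haplotype sample.
    """
    gens = tuple(sorted(sample_generations or params.sample_generations))
    sim = Simulation(params, rng=rng)
    if parental_state is not None:
        sim.set_parental_state(parental_state)
    else:
        sim.run_burn_in(method=burn_in)
    sim.found_hybrid()
    out: dict[int, HaplotypeSample] = {}
    if 0 in gens:
        out[0] = sim.sample_haplotypes(tag=tag)
    for target in gens:
        if target == 0:
            continue
        while sim.generation < target:
            sim.advance_generation()
        out[target] = sim.sample_haplotypes(tag=tag)
    return out
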