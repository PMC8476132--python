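"""Scaled-down recovery study shared by the acceptance test.

Runs desk-scale versions of the main simulation scenarios, scans every
replicate, grid-searches the calling thresholds on the focal
(incompatibility) scenario and measures recovery of the true locus windows
plus the cross-scenario detectability ordering.

Desk-scale configuration (shrink factor 20, see the package's methods
note): Np=250, N=500, burn-in 2,500 generations, a 5 Mb chromosome with
the loci at 1.75 / 3.25 Mb, scanned in 1,000 windows of 5 kb (the
full-scale window count, so the bootstrap tail keeps 10 slots) with
n_b = 1,000 bootstrap replicates.  Selection and migration coefficients
are compounded over the 20 merged generations; the neutral mutation and
recombination rates are raised 4x above the strictly product-preserving
values to keep the scan in its operating regime (enough SNPs per window,
distortion within the detection-region grid).  Burn-ins use the
coalescent shortcut: a few independent recombination genealogies, each
replicate drawing its own mutation overlay.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from hybridscan import (
    CoalescentAncestry,
    ReplicateScan,
    SimParams,
    Simulation,
    Thresholds,
    bootstrap_tail_counts,
    call_outliers,
    grid_search,
    performance,
)

WINDOW_SIZE = 5_000
N_BOOT = 1_000
N_ANCESTRIES = 3

BASE = SimParams(
    Np=250, N=500, n_burnin=2_500, mu=8e-8, r=4e-7, rescale=10,
    L=5_000_000, pos_A=1_750_000, pos_B=3_250_000,
    eps=0.0, m=0.0954, seed=0, sample_size=50,
)

LOCUS_WINDOWS = (BASE.pos_A // WINDOW_SIZE, BASE.pos_B // WINDOW_SIZE)


def compounded(rate_per_gen: float, lam: int = 20) -> float:
    """Probability-like rate compounded over ``lam`` merged generations."""
    return 1.0 - (1.0 - rate_per_gen) ** lam


#: Desk-scale scenario coefficients (full-scale values compounded over the
#: 20 merged generations; migration clipped to the valid per-source range).
SCENARIOS = {
    "Default": dict(eps=-compounded(0.1), m=compounded(0.005)),
    "Low ep.": dict(eps=-compounded(0.02), m=compounded(0.005)),
    "High mig.": dict(eps=-compounded(0.1), m=min(0.5, compounded(0.05))),
    "Neu.": dict(eps=0.0, m=compounded(0.005)),
}


@dataclass
class ScenarioResult:
    name: str
    datasets: list[ReplicateScan]          # one per replicate x sampled generation
    per_replicate: list[list[ReplicateScan]]


def run_scenario(
    name: str,
    ancestries: list[CoalescentAncestry],
    n_reps: int,
    sample_gens: tuple[int, ...],
    seed0: int,
) -> ScenarioResult:
    over = SCENARIOS[name]
    has_loci = over["eps"] != 0.0
    datasets, per_rep = [], []
    for i in range(n_reps):
        seed = seed0 + i
        params = dataclasses.replace(BASE, seed=seed, **over)
        state = ancestries[i % len(ancestries)].draw_state(mutation_seed=seed)
        sim = Simulation(params)
        sim.set_parental_state(state)
        sim.found_hybrid()
        mine, last = [], 0
        for gen in sorted(sample_gens):
            for _ in range(gen - last):
                sim.advance_generation()
            last = gen
            sample = sim.sample_haplotypes(tag=name)
            tail = bootstrap_tail_counts(
                sample, window_size=WINDOW_SIZE, n_b=N_BOOT, seed=seed * 100 + gen
            )
            rep = ReplicateScan(tail, LOCUS_WINDOWS if has_loci else ())
            datasets.append(rep)
            mine.append(rep)
        per_rep.append(mine)
    return ScenarioResult(name, datasets, per_rep)


def replicate_union_coverage(result: ScenarioResult, thr: Thresholds) -> list[int]:
    """Per replicate: how many of the two truth windows its calls cover,
    pooling the calls from all of the replicate's sampled generations."""
    out = []
    for reps in result.per_replicate:
        covered = set()
        for rep in reps:
            for call in call_outliers(rep.tail, thr):
                for lw in rep.locus_windows:
                    if abs(call.window_index - lw) <= thr.d:
                        covered.add(lw)
        out.append(len(covered))
    return out


def run_study(base_seed: int = 20_210_607):
    """The full desk-scale study; returns everything the assertions need."""
    rng = np.random.default_rng(base_seed)
    anc_seeds = [int(s) for s in rng.integers(1, 2**31 - 1, size=N_ANCESTRIES)]
    ancestries = [CoalescentAncestry(BASE, seed=s) for s in anc_seeds]

    default = run_scenario("Default", ancestries, n_reps=20,
                           sample_gens=(25, 50), seed0=base_seed + 1_000)
    low_ep = run_scenario("Low ep.", ancestries, n_reps=5,
                          sample_gens=(50,), seed0=base_seed + 2_000)
    high_mig = run_scenario("High mig.", ancestries, n_reps=3,
                            sample_gens=(50,), seed0=base_seed + 3_000)
    neutral = run_scenario("Neu.", ancestries, n_reps=4,
                           sample_gens=(50,), seed0=base_seed + 4_000)

    search = grid_search(default.datasets, metric="power")
    out = {
        "default": default,
        "low_ep": low_ep,
        "high_mig": high_mig,
        "neutral": neutral,
        "search": search,
    }
    if search.feasible:
        thr = search.best
        out["thresholds"] = thr
        out["coverage"] = replicate_union_coverage(default, thr)
        # same-footing comparison across scenarios: generation-50 datasets
        gen50 = [reps[-1] for reps in default.per_replicate]
        out["power_default_g50"] = performance(gen50, thr).power
        out["power_low_ep"] = performance(low_ep.datasets, thr).power
        out["power_high_mig"] = performance(high_mig.datasets, thr).power
        out["neutral_calls"] = [
            len(call_outliers(rep.tail, thr)) for rep in neutral.datasets
        ]
    return out
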