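"""Migration-selection balance of an incompatibility in the hybrid sink.

Iterates the deterministic two-locus gamete-frequency recursion (random
union, viability selection, free recombination, then migrant replacement)
from the 50:50 founding composition and prints the stationary frequency of
each incompatible allele for several selection strengths.
"""

from hybridscan import SimParams
from hybridscan.dynamics import iterate_recursion

print("per-source migration m = 0.05, codominant epistasis:\n")
print("  eps    stationary freq of A (and B)   generations to converge")
for eps in (-0.1, -0.3, -0.5, -0.9):
    params = SimParams(eps=eps, m=0.05)
    state, n_iter, _ = iterate_recursion(params, c=0.5)
    print(f"  {eps:+.1f}        {state.freq_A:.3f}                      {n_iter}")

print(
    "\nStrong selection cannot purge the incompatible alleles: migration"
    "\nre-imports them every generation, so both settle at an intermediate"
    "\nfrequency (about 0.27 at eps=-0.5) instead of being lost."
)
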