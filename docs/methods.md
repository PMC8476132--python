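# Methods

`hybridscan` implements, end to end, a strategy for locating the loci of
Bateson–Dobzhansky–Muller (BDM) incompatibilities from genome sequences of a
hybrid-zone population: a forward simulator of a two-source / hybrid-sink
system with two-locus epistatic viability selection, a windowed
site-frequency-spectrum (SFS) genome scan scored by multinomial
probabilities under the genome-wide SFS, bootstrap calibration with a
two-threshold outlier rule, and a power/false-positive evaluation harness
with constrained grid search and cross-validation over the calling
thresholds.  This note records the model, the numerical choices, and what
the desk-scale studies do and do not demonstrate.

## The model

Two parental populations of `Np` diploids start from identical,
variation-free genomes apart from reciprocal fixed differences at two loci
(derived allele *A* fixed in source 1, derived *B* in source 2) and diverge
in allopatry for `n_burnin` generations under neutral mutation (rate `mu`
per bp) and uniform recombination (`r` per bp) on a single chromosome of
`L` bp.  A hybrid population of `N` diploids is then founded in one
generation as a 50:50 mixture (each founder copied from a random source
with probability 1/2, sources not depleted) and thereafter receives
migrants at rate `m` per source per generation, with no back-migration: the
hybrid is a sink, and its generation counter starts at 0 at founding.

Viability of a genotype with `XA`, `XB` ∈ {0,1,2} derived alleles is

    w = (1+s_a)^(2−XA) · (1+s_b)^(2−XB) · (1 + h_{XA·XB}·ε)^(XA·XB)

with ε ≤ 0 the epistasis coefficient, `s_a`, `s_b` ≤ 0 optional
disadvantages of the *ancestral* alleles, and the dominance coefficient of
the interaction `h_1` = 0 (recessive) or 1 (codominant) for the double
heterozygote and `h_k` = 1 otherwise.  Survival to adulthood has
probability `w`; survivors contribute equally to the next generation.

Life cycle per generation: the sources reproduce neutrally (and keep
accumulating divergence); hybrid offspring are formed by random mating
(selfing admitted, as in a standard Wright–Fisher population) with
Poisson(`r·L`) crossovers placed uniformly and Poisson(`mu·L`) new neutral
mutations per gamete at unique integer positions (infinite-sites:
recurrent mutation disallowed); viability selection is applied by rejection
sampling of proposed offspring so the census size never changes; finally a
Binomial(`N`, `m`) number of hybrids per source is replaced by copies of
randomly chosen (current-generation) source individuals.  Migrants face
selection at their first reproduction, not on arrival.  Samples of
`sample_size` diploids (default 50) are drawn without replacement and
retain only sites biallelic and polymorphic within the sample; the selected
loci enter as ordinary biallelic sites when sample-polymorphic.

Defaults mirror the full-scale study conditions: `Np`=5,000, `N`=10,000,
`n_burnin`=50,000, `mu`=1e-9, `r`=5e-9, `m`=0.005/source, `L`=500 Mb, loci
at 175 and 325 Mb, ε=−0.1, samples at generations 100/1,000/5,000/10,000,
plus a ×10 rescaling of `mu` and `r` (a long chromosome represented by
fewer, more mutable base pairs; `L·mu` and `L·r` preserved).  The named
scenarios (`Default`, `Low ep.`, `High ep.`, `Low mig.`, `High mig.`,
`High mig. high ep.`, `Neu.`, `SL-sel.`, `High SL-sel.`,
`SL-sel. and ep.`, with recessive variants) vary ε ∈ {0,−0.02,−0.1,−0.5},
s ∈ {0,−0.02,−0.1} and m ∈ {0.0005, 0.005, 0.05}.  The combined
single-locus + epistasis scenario uses the default migration rate, which is
the only reading consistent with its reported behaviour relative to the
default scenario.

## The scan

The unfolded SFS (derived-allele counts 1..2n−1; ancestral alleles known)
is tabulated in non-overlapping windows — 500 kb at full scale, i.e. 1,000
windows — and summed into the genome-wide SFS.  Each window is scored by
the log multinomial probability of its spectrum given bin probabilities
estimated from the genome-wide spectrum (including the focal window, which
guarantees every occupied bin has positive probability).  Probabilities are
computed purely in log-gamma form; an empty window has probability one.
These probabilities are astronomically small and fall with the window's SNP
count, so they are *ranked*, not tested: `n_b`=1,000 bootstrap replicates
resample the 2n haplotypes with replacement, local and global spectra are
recomputed, and the `max(1, ⌊0.01·W⌋)` lowest-probability windows per
replicate are marked (ties broken by window index; the slot count is exact,
so Σκ = n_b · tail_size always).  κ_i counts how often window i lands in
that tail.  A window is called an outlier when κ > thr1 *and* the mean of κ
over `[i−d, i+d]` (truncated at chromosome ends, focal window included)
exceeds thr2 — selection distorts the SFS over a broad region, whereas
windows extreme by genealogical chance are isolated.  Since at most
`n_b·tail_size/thr1` windows can collect more than thr1 slots, that bound
enters the Bonferroni correction: the false-positive-rate ceiling used
throughout is 5·thr1/10,000 percent.

## Evaluation

A replicate dataset is one simulation replicate at one sampling generation.
A call at window i is a true positive when a locus window lies in
`[i−d, i+d]`; with two well-separated loci the true class has 4d+2 windows.
Power (default) counts each locus per dataset as one detection opportunity;
a per-dataset mode (both loci required) is available.  The false-positive
rate divides false calls by false-class windows summed over datasets, and
the proportion of false positives among outliers is 0 when there are no
calls.  The grid search sweeps thr1 ∈ {400,450,…,1000}, thr2 ∈ {0,20,…,300},
d ∈ {5,…,19}, discards combinations violating the FPR ceiling or a 5%
proportion of false positives among outliers, and maximizes one of power,
power/(2d+1), or power/(2d+1)²; ties fall to smaller d, then smaller
fp-in-outliers, then larger thr2.  Cross-validation retrains the grid
search on random 25% subsets (stratified by scenario, drawn without
replacement) over 100 iterations, also recording every combination within
5% of each iteration's best (the "plateau" variant), and reports the modal
combination with held-out performance.  With several scenarios pooled, the
optimizing metric is averaged across scenarios and the constraints must
hold in each.

## Desk-scale configuration

Full-scale runs are cluster-sized, so tests and examples use a rescaled
system.  A shrink factor λ divides `Np`, `N`, `n_burnin` and the sampling
times and multiplies `mu`, `r`, `m` and the selection coefficients,
preserving N·mu, N·r, N·m and N·|ε|; coefficients are clipped to their
valid ranges.  Because a rescaled generation stands for λ real ones,
probability-like rates compose multiplicatively rather than linearly: the
desk-scale studies therefore use the compounded values
ε_λ = −(1−(1+ε)^λ) and m_λ = 1−(1−m)^λ where the difference matters
(λ=20 maps ε=−0.1 to −0.878 and m=0.005 to 0.095; the linear rule would
clip ε at −1, making the double heterozygote lethal and qualitatively
changing the dynamics).  The chromosome is shrunk 100-fold to `L`=5 Mb with
loci at 1.75/3.25 Mb.

The scan geometry at desk scale keeps the full-scale window count — 1,000
windows of 5 kb, so the bootstrap tail keeps its ten slots per replicate —
with the neutral mutation and recombination rates both raised four-fold
above the strictly product-preserving values.  The choices keep the scan
in its operating regime.  At product-preserving μ a 1,000-window desk
tiling leaves ~11 SNPs per window and the bootstrap tail is dominated by
sparsely populated, genealogically idiosyncratic windows; 4x μ restores
~50 SNPs per window.  Fewer, wider windows were tried instead and
rejected: with only 2-5 tail slots per bootstrap replicate the two locus
regions compete with each other (and with any chance window) for slots,
capping each locus's κ well below the candidacy grid.  Compression also
makes selection per rescaled generation strong, which both broadens the
local distortion and displaces its peak: at product-preserving
recombination the tail mass lands 20-30 windows from the loci — outside
the d ≤ 19 detection grid, so genuinely selection-driven calls are scored
as false positives and the constrained threshold search collapses (the
same failure the full-scale study reports when selection is too strong).
The distortion length scales inversely with recombination, and the 4x
rate pulls the peaks to within a few windows of the loci while also
quadrupling within-window genealogical averaging.

Desk-scale validation replicates draw their burn-ins from a small set of
independent coalescent ancestries (four in the recovery study), each
replicate overlaying its own neutral mutation history
(:class:`CoalescentAncestry`).  A single burn-in shared by all replicates
— the appropriate economy at full scale — makes the same genealogically
odd windows recur in every replicate as systematic false positives at
small scale, while a fully independent burn-in per replicate is the
costliest part of a replicate; sharing the recombination genealogy within
a small group but never the mutations is the middle ground.

The recovery study itself runs 20 replicates of the shrunk default
scenario (sampled at generations 5, 25 and 50 — the compressed analogues
of the early full-scale sampling times), plus smaller sets of the weak-
epistasis, high-migration and neutral scenarios at generation 50, scans
everything at n_b = 1,000, grid-searches the thresholds on the default
scenario under the published constraints, and then checks that the calls
localize to the truth windows, that the neutral scenario stays near-null,
and that the detectability ordering (default above weak epistasis, high
migration undetectable) reproduces.  Desk-scale recovery should be read as
a qualitative reproduction — localization and orderings — not as a
reproduction of full-scale power values.

## Numerical and implementation choices

- Coordinates are 0-based half-open; windows `[k·w, (k+1)·w)` with a final
  partial window kept; VCF conversion to 1-based happens only in the I/O
  layer (ALT = derived, AA INFO = ancestral).
- The allele copied at position q during meiosis comes from strand
  `(start + #{breakpoints ≤ q}) mod 2`; breakpoint positions are uniform
  integers, crossover counts Poisson, no interference.
- Populations share one registry of segregating sites with dense boolean
  haplotype matrices; columns lost everywhere or fixed in every population
  are pruned every 5 generations.  A compiled (numba) meiosis kernel is
  used when available; a pure-numpy reference path produces bit-identical
  results and is exercised in the tests.
- One seeded generator (`numpy` PCG64) drives an entire run; identical
  parameters and seed give bit-identical samples.  The bootstrap resamples
  via rows of one batched integer draw, which is the documented contract an
  independent oracle can reproduce.
- `run_burn_in(method="coalescent")` replaces the forward burn-in with an
  msprime draw: two populations splitting `n_burnin` generations ago, with
  mutations restricted to ages younger than the split (so the sources start
  identical, exactly as in the forward model) and sites carrying more than
  one mutation dropped to honour infinite sites.  This is an approximation
  — a continuous-time genealogy stands in for discrete Wright–Fisher
  reproduction — and is validated against the forward burn-in's
  segregating-site distribution in the tests.
- The deterministic two-locus recursion iterates random union → selection →
  recombination (fraction c) → migrant replacement on the four gamete
  frequencies from the 50:50 founding state; it is the independent oracle
  for the simulator's allele-frequency dynamics (agreement within
  Monte-Carlo error at large N) and yields the stationary incompatible
  allele frequency ≈0.27 under ε=−0.5, m=0.05, c=0.5.
- Ties at the bootstrap tail boundary break by window index; empty windows
  never enter the tail; an error is raised if fewer non-empty windows exist
  than tail slots.
- Overlapping outlier regions are reported separately, not merged; if two
  locus neighbourhoods overlap (loci closer than 2d+1 windows) the
  true-positive class is recomputed as their union and a warning issued.

## What the synthetic data do not show

The generator emulates the study system faithfully at reduced scale, but
real hybrid-zone data differ in ways outside this model: polymorphic (not
fixed) incompatibility alleles in the sources, more than two interacting
loci, spatial structure and asymmetric migration, non-equilibrium
demography in the sources, genotyping and polarization error, and
non-uniform recombination and mutation landscapes.  Passing the desk-scale
studies shows the pipeline is internally correct and that the scan detects
epistatic distortion under the modelled conditions; it does not quantify
performance on real data, and the method cannot by itself distinguish
epistatic from single-locus selection at a detected locus.
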