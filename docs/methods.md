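# Methods

`mtphylogeo` implements the inference chain used in mtDNA haplogroup
phylogeography: from rCRS-relative haplotype notation to haplogroup
assignment, median-joining network phylogenies, rho/sigma coalescence
dating, geographic centers of dispersal, regional population statistics,
and a Poisson serial-founder model of colonization. This note records the
models, the numerical choices, and what the synthetic test bed does and
does not establish.

## Haplotype notation and the reference

Haplotypes are sets of mutations numbered 1-based on the 16,569-bp revised
Cambridge Reference Sequence (rCRS), with the historical placeholder at
np 3107 retained as `N` so that printed positions match the literature.
The token grammar covers transitions (`16343`), transversions (`6515G`),
deletions (`15944dT`, `523dCA`), insertions (`523.1CA`), back-mutations
(`@16223`), and the hypervariable-segment shorthand in which `343` means
np 16343. Transitions carry no explicit derived base (the rCRS partner is
implied); a repeated plain token on an already-mutated background is
rejected rather than silently toggled — a reversion must be written with
`@`. Default analysis windows are HVSI 16024–16383 and HVSII 57–372, both
configurable.

The packaged reference (`data/synthetic_rcrs.fasta`) is a deterministic
**synthetic** stand-in of rCRS length with `N` at np 3107. Every coordinate
convention, window, and round-trip behaves identically against the real
rCRS, which users should supply as a FASTA for work on real sequences; no
scientific claim in this package depends on the actual rCRS base content.

Haplogroup assignment walks a user-supplied definition forest (name,
parent, diagnostic motif per clade), accumulates root-to-clade motifs
(a child's `@x` cancels an ancestral gain), and returns the deepest clade
whose cumulative motif is matched at a configurable fraction of its sites
(default 1.0; lower it for HVS-only data where coding-region sites are
unobserved). Ties break on fewest private mutations, then name. The
fraction default is a package choice: published assignments of this kind
were made by hand with unstated tolerance for missing motif sites.

## Median-joining networks

Distinct mutations are binary-expanded into presence/absence characters
(multi-state sites split per derived state; indels anchored at their np),
and distances are weighted Hamming distances with per-site weights
(default 1.0; an optional table down-weights notoriously unstable sites
such as 16182/16183/16519 and the 523-524 indel region to 0.2 — they are
never dropped from the data, only down-weighted). The construction
iterates:

1. a minimum spanning network (all links lying in some minimum spanning
   tree; links within `epsilon` of the minimax connection level when the
   tolerance is positive),
2. candidate median generation — the majority consensus of every linked
   pair combined with each third node,
3. admission of cost-reducing medians (those within `epsilon` of the round's
   best triple connection cost), and
4. pruning of obsolete median vectors.

Two regimes are deliberately distinguished. For instances with at most 12
distinct sampled haplotypes the construction runs to full median closure
and prunes medians *exactly*: a Dreyfus–Wagner dynamic program computes the
minimum Steiner length within the candidate node set, and every median
whose removal leaves that optimum unchanged is discarded (deterministic
order), so the retained medians are exactly the Steiner points of one
optimal tree and the network's spanning length equals the minimal
(maximum-parsimony) length. For larger data the greedy
epsilon-gated admission and a steepest-descent prune are used — the
standard heuristic behavior, which may exceed the optimum slightly.
`exact_steiner_length` exposes the independent full-hypercube
Dreyfus–Wagner solver (up to 16 sites) used as the reference in tests.
A node budget (default 50,000) guards combinatorial blow-up and raises an
error rather than truncating silently.

Reduced-median preprocessing resolves each incompatible character pair
(all four gametes present) by hypothesizing homoplasy at the
faster-mutating (lower-weight) site in the minority gamete class and
appending the toggled intermediate as an unsampled seed; compatible data
pass through unchanged, and the network length never increases.

Reticulations are resolved into a rooted clade tree by deleting, in each
cycle, the link whose labelling mutation has the highest relative site
rate (the inverse of its weight), with ties broken by higher np, then
token, then content-based node keys, so the result is invariant under
input reordering. The tree is rooted at a user-supplied root haplotype
(inserted and linked to its nearest node if not already present); branch
labels orient gains and losses (`@x`) relative to the parent, and branch
lengths are mutation counts. Homoplasy counting tallies, per mutation, the
branches carrying it or its reversion.

## Coalescence dating

The rho statistic at a focal node is the mean number of mutations from the
node to each sampled descendant (tip multiplicities weighted); its
standard error sigma follows the branch-sum estimator
sigma^2 = sum over branches of (n_b/n)^2 l_b. Ages use a linear clock of
one substitution per 3624 years over the whole molecule — the package does
not implement time-dependent (purifying-selection-corrected) calibration,
which users should apply externally if needed. Confidence intervals are
the normal approximation rho ± z·sigma (z = 1.96 by default), floored at
zero years; the symmetric form matches how such intervals are printed in
practice. Founder ages compute rho as the mean symmetric-difference
distance from a designated founder haplotype over a regional subset, with
sigma from the star-tree formula; back-mutations count one step, matching
parsimony branch lengths. Age contrasts treat estimates as independent
normals (z-test); per-tip mutation-count contrasts use Welch's two-sample
t-test.

## Phylogeography

Geographic centers are arithmetic means of decimal-degree coordinates with
per-axis sample standard deviations — demonstrably the convention behind
the reference worked values — with a great-circle (unit-vector) centroid
behind a flag; longitude spans of 180° or more raise an error unless an
explicit unwrap is requested. The dispersal focus of an ancestral clade is
the same mean applied to its daughter-clade centers. Native-region
assignment follows the 90%/10% rule: a clade is native to the region
holding at least `major` (default 0.90) of its occurrences when every
other region holds at most `minor` (default 0.10); clades present in every
region (or satisfying the native rule everywhere, as happens at degenerate
thresholds) are `widespread`; everything else is `unassigned`. Exclusion
lists for regions of known recent colonization are configuration, not
hardcoded.

## Population statistics

Haplotype diversity is 1 − Σp² with the n/(n−1) small-sample correction by
default; richness is 100·(distinct/n) and exclusivity the share of a
region's distinct haplotypes found nowhere else — both definitions are
consistent with the printed regional summaries they emulate. Nei's
standard identity I = Σpq / sqrt(Σp²·Σq²) and D = −ln I operate on matched
frequency profiles (disjoint profiles give infinite distance).

AMOVA is distance-based with two reported components (among regions
vs. within): under presence/absence site coding the pairwise
mutation-difference counts *are* squared Euclidean distances, so they
enter the sums of squares directly. Variance components follow the
standard unequal-n moment estimators; Phi_RT is the among-region share;
the p-value permutes whole populations across regions, keeping sample
membership intact, with p = (1 + #{Phi* ≥ Phi})/(1 + permutations).
The Mantel test correlates upper-triangle entries under simultaneous
row/column permutation with a two-tailed count of |r*| ≥ |r|. Both take an
explicit seed and report it; results are bit-identical across runs.
PCA is centered covariance PCA (correlation scaling behind a flag), with
explained-variance percentages over all components summing to 100.
Two-proportion comparisons default to Fisher's exact test (small counts
are common in regional tables), with a pooled z-approximation as an
option. Geographic distance matrices use the haversine great-circle
distance in kilometres from region representative points.

## Poisson colonization model

A maternal lineage accumulates whole-molecule substitutions as a Poisson
process at rate 1/3624 per year, treated as a single channel exactly as
the verbal model does (per-site structure lives in the synthetic-data
generator). Over 10,000 years the pmf gives P(0) ≈ 0.063 and P(5) ≈ 0.084,
hence about six unchanged and about eight five-step carriers among one
hundred females. The serial-founder simulation hops a colonization
frontier every `step_years` (default 1000), founding each new deme with
`founders_per_step` lineages drawn uniformly without replacement from the
frontier pool, then letting every lineage in every deme accumulate
Poisson(step_years/3624) mutations per interval; distance is
migration_speed × elapsed years (1 km/year default for hunter-gatherers).
Mutation accumulation is founder-independent in expectation; the founder
subsampling alone generates multi-mutation modal divergence between
distant demes. No asymmetry between migrants and the source population is
built in, as none is mechanistically specified.

## Synthetic data

The generator emulates the statistical structure the analyses assume: a
clade radiating around 50 kya, Poisson mutation accumulation at one
substitution per 3624 years, region-structured subclade frequencies
(the packaged regional U3 profile table is the default target), and serial
founder spread. Genealogy models are `star` (each sample an independent
branch of the configured age), `kingman` (a neutral coalescent from
msprime, rescaled so the clade root sits at the configured age — used
purely to produce non-star topologies, with no demographic claim), and
`serial-founder` (regions as demes along a colonization chain). Each
sample's mutation history is an ordered event sequence; repeated hits at a
position within a lineage become back-mutations; shared ancestry is shared
prefix, so the true genealogy with branch labels is recovered exactly as a
prefix tree over event sequences. The default site pool spans the molecule
(excluding np 3107) with a small hotspot set mutating 5× faster so that
homoplasy — which reticulation resolution and homoplasy counting need —
actually occurs.

What the synthetic bed does not emulate: realistic human demography,
selection, heteroplasmy, rate variation beyond the hotspot set,
transversions/indels in generated data, or phylogenetic uncertainty in
the motif forest. Passing recovery tests therefore demonstrates the
correctness and calibration of the estimators under their own model
assumptions, not robustness to real-data violations of those assumptions.

## Problem sizes and reproducibility

The test suite and the acceptance script use desk-scale problem sizes
chosen as the smallest that make each property sharp: Steiner-equality
sweeps over all 2-3-site instances plus several hundred random instances
up to 6 haplotypes × 8 sites; 200 replicate star genealogies (n = 100,
age 50 ky) for rho/sigma recovery and interval coverage; 200-replicate
null calibrations with 199 permutations each for AMOVA and Mantel
uniformity (Kolmogorov–Smirnov at alpha 0.01); and a 180-sample,
3-region, 2-clade end-to-end run. Every stochastic procedure takes an
explicit seed, records it in its result object or report, and is
bit-reproducible given it.

## Known limitations

- The greedy (large-data) network regime is a heuristic; only the
  small-instance regime is certified against the exact Steiner length.
- The linear clock ignores time-dependence of the mtDNA substitution rate;
  ages at deep nodes inherit that bias.
- Printed uncertainty values of the "mean age ± e" form in the source
  tables mix estimation methods and samples; the package exposes
  sigma-based and across-replicate standard errors and does not claim to
  reproduce those exact ± values.
- The arithmetic-mean center is a planar approximation; it is the
  convention the reference values use, but for high-latitude or
  wide-longitude ranges the spherical option is more defensible.
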