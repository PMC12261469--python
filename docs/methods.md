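# Methods

## Model

`recombmix` treats local ancestry inference as a minimum-cost path problem
on a collapsed representation of the reference panel, in the spirit of the
Li–Stephens haplotype-copying model but with two deliberate
simplifications: mismatches cost a flat 0/1 rather than an emission
probability, and template changes *within* a population cost nothing.

Collapsing each site of the panel to its unique (allele, population) pairs
makes the panel representation independent of panel depth: a site holds at
most K·p nodes (2p bi-allelic). The free within-population switch means a
query is never asked to follow any individual haplotype — only to stay
consistent with *some* haplotype of a population at each site — so all
between-population signal is concentrated in dAIMs, sites where an allele
is present in one population's panel and absent from another's. This is an
intentional trade: allele-frequency differences below the presence/absence
threshold carry no signal here.

The path objective is

    f(P) = Σⱼ d(qⱼ, a(uⱼ)) + w · Σⱼ r(l(uⱼ), l(uⱼ₊₁)),

d ∈ {0, 1}, r(l, l) = 0, r(l, l′) = R′ⱼ,ⱼ₊₁ for l ≠ l′. Because node choice
within a population reduces to the per-population mismatch summary
m[j][l] = [query allele absent from population l's node set], the dynamic
program runs over population states only: O(n·p) time and memory, with
backpointers stored per (site, state). All queries in a batch are decoded
in one vectorized pass.

## Switch penalties

Per-interval recombination rates are (cM(posⱼ₊₁) − cM(posⱼ)) / Mb. Rates
are min-max normalized over the analyzed region's n−1 intervals and
transformed by R′ = 2/(Rnorm + 1), so R′ ∈ [1, 2]: the hottest interval
switches at cost w·1, the coldest at w·2. Numerical choices, all of them
the package's own conventions where the formulation is silent:

- cM at site positions is piecewise-linear between map entries; beyond the
  map span the flanking interval's rate is carried outward (clipped at 0).
- Negative interpolated cM differences are clipped to 0; a zero physical
  distance between adjacent sites defines a rate of 0 (fully linked).
- If all rates are numerically equal (relative spread ≤ 1e-9 — e.g. a
  uniform map, where round-off would otherwise be amplified to the full
  normalized range), Rnorm := 0 everywhere, i.e. R′ = 2: with no rate
  signal, switching is maximally and uniformly penalized and mismatch
  evidence alone drives label changes. `SwitchPenalties.degenerate` records
  this.
- Normalization is computed over the analyzed region (one chromosome per
  run), not per genome.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `w` | 1.5 | scale between mismatch and switch terms; larger w → fewer, longer tracts. w→∞ degenerates to the best single population, w=0 to per-site argmin. |
| `within_population_switch_cost` | 0 | ablation hook; > 0 restores a uniform within-population charge of cost·R′, scaled by w like every r(·) term. |
| `missing_population_cost` | 1 | charged when a population has no node at a site (all genotypes missing): absence of evidence scores like a mismatch, so it cannot beat an explicit match. |
| `prune_rare_alleles` threshold | 0 (off) | masks alleles below this within-population frequency before collapsing; helps panels with few dAIMs by removing low-frequency contaminants (≥ 0.5 rejected; note masking the witnessing allele can also *remove* a dAIM, so dAIM counts are not monotone in the threshold). |
| MAF / MAC filter | 0.005 / 50 | evaluation-time marker exclusion (≤ thresholds, computed on the query cohort). |

Tie-breaking is fixed so outputs are reproducible: among equal-cost
predecessors the DP prefers staying in the same population, then the lowest
population index; equal-cost final states take the lowest index. The
enumeration oracle applies the same preference order, so DP and oracle
agree on label paths, not just costs. Missing query alleles score 0 against
every population (uninformative) rather than 1, so query missingness cannot
induce spurious switches. Only the single best path is reported.

## Synthetic data

The generator reproduces the statistical structure LAI feeds on without
external data or a population-genetic engine:

- **Frequencies.** Balding–Nichols: per site an ancestral frequency
  q ~ Uniform(0.05, 0.95); population frequencies
  Beta(q(1−F)/F, (1−q)(1−F)/F) with F the FST-like divergence (default 0.2,
  an inter-continental magnitude).
- **Haplotypes.** Founder and reference pools are disjoint independent
  draws per site (founders feed the queries; references form the panel).
- **Admixture.** After g generations (default 15) a query haplotype carries
  Poisson(g·L) crossovers (L = map length in Morgans) placed uniformly on
  the genetic scale; each segment draws its ancestry from the admixture
  proportions (default equal) and copies a fresh uniformly chosen founder.
- **Error.** Each allele flips independently with probability 2e-4 (0.02%),
  applied to panel and queries alike.
- **Region.** 5000 sites on a 6 Mb region at 1.46 cM/Mb (the human average
  rate), i.e. ~430 sites/cM. The region length is paired with the site
  count so marker density per cM approaches, at desk scale, the regime of
  filtered sequencing data — at realistic densities every ancestry tract
  spans many discriminative sites, which is the regime the method is
  designed for. The default yields 2–3 expected tracts per query; 200 query
  haplotypes (100 diploid individuals) keep the MAC ≤ 50 filter meaningful.
- **Maps.** `uniform` spreads cM evenly; `hotspot` concentrates 80% of the
  cM into 5% of 200 intervals to exercise non-uniform penalties.

What the generator deliberately omits — and therefore what passing tests do
*not* show about real data: background LD and haplotype sharing between
founders and references (sites are independent given frequencies), rare
variants (ancestral frequencies start at 0.05), population-specific maps,
and phasing error. One measured consequence: in this generator accuracy
*decreases* mildly with reference panel size, because finite-sample allele
absences in other populations are themselves discriminative signal and
fade as panels grow, while the channels that reward large panels in real
data (rare variants carried by the query but missing from a small panel of
its own population; haplotype-level matching) are absent. On real panels
the opposite, familiar pattern — larger panels, better accuracy — is
expected.

## Evaluation

Accuracy is the mean 0/1 agreement over retained (haplotype, marker) cells.
The r² statistic follows the LAMP-LD convention: per population, true and
inferred per-individual ancestry dosages (0/1/2, haplotypes paired in file
order) are correlated and squared, then averaged over populations. The
default pools individuals × retained markers into one correlation per
population; a `per_marker` variant (correlate across individuals at each
marker, then average) is also implemented. A population with zero dosage
variance in either vector contributes r² = 1 if the vectors are identical,
else 0 (logged).

## Formats

Reference and query inputs are VCF (queries must be phased; the reference
panel may be unphased — collapsing is phase-insensitive, which the test
suite asserts end-to-end). Genetic maps are PLINK `.map` or HapMap-style
text, auto-detected. The compact panel is serialized as a VCF whose columns
are synthetic templates, one per (population, allele-slot): GT `k|k` where
the node exists, `.|.` where it does not, with population names recorded in
the header — this dialect is this package's invention, chosen so the graph
round-trips exactly and the file stays ordinary VCF. Paintings are written
as a per-site label TSV plus a segment TSV of maximal constant-label runs
in half-open bp intervals anchored at site positions.

## Problem sizes

The shipped test and acceptance workloads use the default scenario (5000
sites, 3 populations, 100–600 reference haplotypes, 200 query haplotypes)
and small randomized instances (n ≤ 10, p ≤ 3) wherever an exhaustive
oracle is the comparator; the DP itself is linear in n·p·queries and
handles chromosome-scale site counts without modification.

## Limitations

Single best path only (no posterior or uncertainty); one genetic map for
all populations; no modeling of genotyping or phasing error in the scoring
function (the flat 0/1 mismatch absorbs both); diploid queries are decoded
per haplotype, not jointly; one chromosome per run.
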