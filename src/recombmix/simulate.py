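"""Synthetic labeled panels and admixed queries with ground-truth ancestry.

The generator emulates the statistical structure local ancestry inference
feeds on, at desk scale and with no external data:

* population allele frequencies follow a Balding–Nichols model — per site,
  an ancestral frequency q ~ Uniform(0.05, 0.95) and population frequencies
  Beta(q(1-F)/F, (1-q)(1-F)/F) with F the divergence (FST) parameter;
* founder and reference haplotypes are drawn independently per site from
  those frequencies and kept disjoint;
* an admixed haplotype after g generations is a mosaic of founder
  haplotypes: crossover count ~ Poisson(g * L) with L the map length in
  Morgans, breakpoints uniform on the genetic scale, each segment's
  ancestry drawn from the admixture proportions and its alleles copied
  from a uniformly chosen founder of that ancestry;
* a small per-allele genotyping error (default 0.02%) flips alleles in
  both the panel and the queries.

Sites are independent given the frequencies — there is no background LD
beyond the mosaic itself — which preserves the signal the method uses
(population-specific allele presence plus recombination distances).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .panel_io import (
    GeneticMap,
    HaplotypePanel,
    QuerySet,
    Site,
    write_genetic_map,
    write_population_map,
    write_query_vcf,
    write_reference_panel,
    write_truth,
)

logger = logging.getLogger("recombmix")

__all__ = [
    "SimScenario",
    "SimResult",
    "draw_population_frequencies",
    "simulate_haplotype_pool",
    "simulate_admixed_haplotype",
    "add_genotyping_error",
    "build_genetic_map",
    "simulate_scenario",
    "write_fixtures",
]


@dataclass
class SimScenario:
    """Parameters of one synthetic admixture experiment.

    Sizes are in haplotypes per population; queries pair into diploid
    individuals (n_queries must be even). The defaults describe a three-way
    admixture 15 generations deep with moderately diverged source
    populations on a 6 Mb region at the human average rate of 1.46 cM/Mb.
    The region length is paired with the site count so the marker density
    (about 430 sites/cM) approaches the per-cM density of filtered
    sequencing data while the expected ancestry mosaic stays non-trivial
    (two to three tracts per query haplotype).
    """

    p: int = 3
    n_sites: int = 5000
    fst: float = 0.2
    n_ref_per_pop: int = 100
    n_founder_per_pop: int = 100
    n_queries: int = 200
    generations: int = 15
    admixture_proportions: np.ndarray | None = None
    error_rate: float = 2e-4
    chrom_length_bp: int = 6_000_000
    rate_cm_per_mb: float = 1.46
    map_style: str = "uniform"
    chrom: str = "18"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fst < 1:
            raise ValueError("fst must lie in (0, 1)")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.p < 2:
            raise ValueError("need at least 2 populations")
        if self.n_queries % 2:
            raise ValueError("n_queries must be even (queries pair into diploids)")
        if self.n_ref_per_pop % 2:
            raise ValueError(
                "n_ref_per_pop must be even (reference haplotypes pair into samples)"
            )
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must lie in [0, 1)")
        if self.map_style not in ("uniform", "hotspot"):
            raise ValueError("map_style must be 'uniform' or 'hotspot'")
        if self.admixture_proportions is None:
            self.admixture_proportions = np.full(self.p, 1.0 / self.p)
        self.admixture_proportions = np.asarray(
            self.admixture_proportions, dtype=np.float64
        )
        if self.admixture_proportions.shape != (self.p,):
            raise ValueError("admixture_proportions must have length p")
        if abs(self.admixture_proportions.sum() - 1.0) > 1e-12:
            raise ValueError("admixture_proportions must sum to 1")

    @property
    def population_names(self) -> list[str]:
        return [f"POP{i + 1}" for i in range(self.p)]


@dataclass
class SimResult:
    """Everything one scenario produces, including held-out founders and truth."""

    panel: HaplotypePanel
    queries: QuerySet
    truth: np.ndarray  # (n_queries, n_sites) population indices
    founders: np.ndarray  # (p, n_founder_per_pop, n_sites)
    gmap: GeneticMap
    breakpoints: list[np.ndarray]  # bp positions per query
    scenario: SimScenario


def draw_population_frequencies(
    p: int, n_sites: int, fst: float, seed_or_rng
) -> np.ndarray:
    """Balding–Nichols site x population allele-1 frequencies."""
    if not 0 < fst < 1:
        raise ValueError("fst must lie in (0, 1)")
    rng = np.random.default_rng(seed_or_rng)
    q = rng.uniform(0.05, 0.95, size=n_sites)
    scale = (1.0 - fst) / fst
    a = np.clip(q * scale, 1e-12, None)
    b = np.clip((1.0 - q) * scale, 1e-12, None)
    return rng.beta(a[:, None], b[:, None], size=(n_sites, p))


def simulate_haplotype_pool(
    freqs: np.ndarray, n_founder: int, n_ref: int, seed_or_rng
) -> tuple[np.ndarray, np.ndarray]:
    """Draw disjoint founder and reference haplotype pools per population.

    Returns (founders (p, n_founder, n_sites), references (p, n_ref, n_sites)).
    """
    if n_founder < 2 or n_ref < 2:
        raise ValueError("need at least 2 haplotypes per population in each pool")
    rng = np.random.default_rng(seed_or_rng)
    n_sites, p = freqs.shape
    total = n_founder + n_ref
    pool = (
        rng.random((p, total, n_sites)) < freqs.T[:, None, :]
    ).astype(np.int8)
    return pool[:, :n_founder], pool[:, n_founder:]


def simulate_admixed_haplotype(
    founders: np.ndarray,
    gmap: GeneticMap,
    g: int,
    proportions: np.ndarray,
    seed_or_rng,
    positions: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One admixed haplotype: mosaic of founders after g generations.

    Returns (haplotype, per-site truth labels, breakpoint bp positions).
    Crossovers are Poisson(g * L) with L the map length in Morgans, placed
    uniformly on the genetic scale; each segment draws an ancestry from the
    admixture proportions and copies a fresh uniformly chosen founder
    haplotype of that ancestry.
    """
    proportions = np.asarray(proportions, dtype=np.float64)
    rng = np.random.default_rng(seed_or_rng)
    L = gmap.length_morgans
    if L <= 0:
        raise ValueError("genetic map must have positive length")
    p = founders.shape[0]
    nonzero = proportions > 0
    if not nonzero.any():
        raise ValueError("admixture proportions are all zero")
    for l in np.nonzero(nonzero)[0]:
        if founders[l].shape[0] == 0:
            raise ValueError(f"population {l} has nonzero proportion but no founders")
    n_break = rng.poisson(g * L)
    cm_break = np.sort(rng.uniform(gmap.cm[0], gmap.cm[-1], size=n_break))
    bp_break = gmap.bp_at(cm_break)
    n_sites = positions.shape[0]
    hap = np.empty(n_sites, dtype=np.int8)
    truth = np.empty(n_sites, dtype=np.int64)
    bounds = np.concatenate([[0.0], bp_break, [np.inf]])
    start_idx = 0
    for seg in range(len(bounds) - 1):
        stop_idx = int(np.searchsorted(positions, bounds[seg + 1], side="left"))
        anc = int(rng.choice(p, p=proportions))
        donor = int(rng.integers(founders[anc].shape[0]))
        if stop_idx > start_idx:
            hap[start_idx:stop_idx] = founders[anc, donor, start_idx:stop_idx]
            truth[start_idx:stop_idx] = anc
        start_idx = stop_idx
    return hap, truth, bp_break


def add_genotyping_error(
    haplotypes: np.ndarray, rate: float, seed_or_rng, n_alleles: int = 2
) -> np.ndarray:
    """Independently replace each non-missing allele with a different one."""
    if not 0 <= rate < 1:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0:
        return haplotypes
    rng = np.random.default_rng(seed_or_rng)
    out = haplotypes.copy()
    flip = (rng.random(out.shape) < rate) & (out >= 0)
    if n_alleles == 2:
        out[flip] = 1 - out[flip]
    else:
        shift = rng.integers(1, n_alleles, size=int(flip.sum()))
        out[flip] = (out[flip] + shift) % n_alleles
    return out


def build_genetic_map(scenario: SimScenario, seed_or_rng=None) -> GeneticMap:
    """Genetic map over the simulated chromosome.

    "uniform" spreads cM evenly at rate_cm_per_mb; "hotspot" concentrates
    80% of the total cM into a random 5% of 200 equal physical intervals,
    exercising strongly non-uniform switch penalties.
    """
    L_bp = scenario.chrom_length_bp
    total_cm = scenario.rate_cm_per_mb * L_bp / 1e6
    if scenario.map_style == "uniform":
        pos = np.array([1, L_bp], dtype=np.int64)
        cm = np.array([0.0, total_cm])
    else:
        rng = np.random.default_rng(
            scenario.seed if seed_or_rng is None else seed_or_rng
        )
        k = 200
        pos = np.linspace(1, L_bp, k + 1).astype(np.int64)
        hot = rng.choice(k, size=max(1, k // 20), replace=False)
        weights = np.full(k, 0.2 / (k - len(hot)))
        weights[hot] = 0.8 / len(hot)
        cm = np.concatenate([[0.0], np.cumsum(weights) * total_cm])
    return GeneticMap(positions=pos, cm=cm, chrom=scenario.chrom)


def simulate_scenario(scenario: SimScenario) -> SimResult:
    """Compose the full experiment: panel, queries, truth, map — all seeded."""
    ss = np.random.SeedSequence(scenario.seed)
    (s_map, s_pos, s_freq, s_pool, s_adm, s_err) = ss.spawn(6)
    gmap = build_genetic_map(scenario, np.random.default_rng(s_map))

    rng_pos = np.random.default_rng(s_pos)
    positions = np.sort(
        rng_pos.choice(
            np.arange(1, scenario.chrom_length_bp, dtype=np.int64),
            size=scenario.n_sites,
            replace=False,
        )
    )
    sites = [
        Site(chrom=scenario.chrom, pos=int(pos), ref="A", alt=("C",), id=f"s{j}")
        for j, pos in enumerate(positions)
    ]

    freqs = draw_population_frequencies(
        scenario.p, scenario.n_sites, scenario.fst, np.random.default_rng(s_freq)
    )
    founders, refs = simulate_haplotype_pool(
        freqs,
        scenario.n_founder_per_pop,
        scenario.n_ref_per_pop,
        np.random.default_rng(s_pool),
    )

    rng_adm = np.random.default_rng(s_adm)
    haps, truths, breaks = [], [], []
    for _ in range(scenario.n_queries):
        h, t, b = simulate_admixed_haplotype(
            founders,
            gmap,
            scenario.generations,
            scenario.admixture_proportions,
            rng_adm,
            positions,
        )
        haps.append(h)
        truths.append(t)
        breaks.append(b)
    query_haps = np.stack(haps)
    truth = np.stack(truths)

    rng_err = np.random.default_rng(s_err)
    ref_alleles = refs.reshape(-1, scenario.n_sites)
    ref_alleles = add_genotyping_error(ref_alleles, scenario.error_rate, rng_err)
    query_haps = add_genotyping_error(query_haps, scenario.error_rate, rng_err)

    pop_names = scenario.population_names
    hap_population = np.repeat(np.arange(scenario.p), scenario.n_ref_per_pop)
    sample_ids = []
    for l in range(scenario.p):
        for i in range(scenario.n_ref_per_pop // 2):
            sample_ids += [f"ref_{pop_names[l]}_{i}"] * 2
    panel = HaplotypePanel(
        alleles=ref_alleles,
        sites=sites,
        hap_population=hap_population,
        population_names=pop_names,
        phased=True,
        sample_ids=sample_ids,
    )
    queries = QuerySet(
        haplotypes=query_haps,
        sites=sites,
        sample_ids=[f"adm{i // 2}" for i in range(scenario.n_queries)],
        hap_indices=np.tile([0, 1], scenario.n_queries // 2),
    )
    logger.info(
        "simulated scenario: p=%d, %d sites, %d ref haps/pop, g=%d, %d queries",
        scenario.p,
        scenario.n_sites,
        scenario.n_ref_per_pop,
        scenario.generations,
        scenario.n_queries,
    )
    return SimResult(
        panel=panel,
        queries=queries,
        truth=truth,
        founders=founders,
        gmap=gmap,
        breakpoints=breaks,
        scenario=scenario,
    )


def write_fixtures(result: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write the scenario as CLI-consumable files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference_vcf": outdir / "reference.vcf",
        "pop_map": outdir / "populations.tsv",
        "query_vcf": outdir / "queries.vcf",
        "genetic_map": outdir / "genetic.map",
        "truth": outdir / "truth.tsv",
    }
    write_reference_panel(result.panel, paths["reference_vcf"])
    samples = result.panel.sample_ids[::2]
    pops = [
        result.panel.population_names[result.panel.hap_population[2 * i]]
        for i in range(len(samples))
    ]
    write_population_map(samples, pops, paths["pop_map"])
    write_query_vcf(result.queries, paths["query_vcf"])
    write_genetic_map(result.gmap, paths["genetic_map"])
    write_truth(
        result.truth, result.queries, result.panel.population_names, paths["truth"]
    )
    return paths
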