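"""Compact population graph construction and per-interval switch penalties.

A labeled reference panel collapses, site by site, into the set of unique
(allele, population) pairs present there. Inference never needs the
original haplotypes: the only between-population signal that survives
collapsing is which alleles are present in which populations, i.e. the
dAIMs (discrete ancestry informative markers) — sites where some allele is
carried by one population's panel but absent from another's.

Template-change penalties come from the genetic map: the per-interval
recombination rate (cM/Mb) is min-max normalized to [0, 1] and passed
through R' = 2 / (Rnorm + 1), giving a penalty in [1, 2] that is largest
where recombination is rarest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .panel_io import GeneticMap, HaplotypePanel, MISSING, Site

logger = logging.getLogger("recombmix")

__all__ = [
    "CompactPopulationGraph",
    "SwitchPenalties",
    "build_compact_graph",
    "identify_daims",
    "compute_switch_penalties",
    "prune_rare_alleles",
]


@dataclass
class CompactPopulationGraph:
    """Per-site sets of (allele, population) nodes, stored as a boolean tensor.

    ``presence[j, a, l]`` is True iff some haplotype of population ``l``
    carries allele ``a`` at site ``j``. Edges are implicit (every node at
    site j connects to every node at site j+1, plus virtual source/sink
    nodes) and never materialized.
    """

    presence: np.ndarray  # (n_sites, K, p) bool
    sites: list[Site]
    population_names: list[str]

    def __post_init__(self) -> None:
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.ndim != 3:
            raise ValueError("presence must be (site, allele, population)")
        if self.presence.shape[0] != len(self.sites):
            raise ValueError("site metadata length must match presence")
        if self.presence.shape[2] != len(self.population_names):
            raise ValueError("population axis must match population_names")

    @property
    def n_sites(self) -> int:
        return self.presence.shape[0]

    @property
    def max_alleles(self) -> int:
        return self.presence.shape[1]

    @property
    def n_populations(self) -> int:
        return self.presence.shape[2]

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def node_set(self, j: int) -> frozenset[tuple[int, int]]:
        """The set S'_j of (allele, population) pairs at site j."""
        a_idx, l_idx = np.nonzero(self.presence[j])
        return frozenset(zip(a_idx.tolist(), l_idx.tolist()))

    def node_counts(self) -> np.ndarray:
        return self.presence.reshape(self.n_sites, -1).sum(axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CompactPopulationGraph):
            return NotImplemented
        return (
            self.population_names == other.population_names
            and self.sites == other.sites
            and self.presence.shape == other.presence.shape
            and bool(np.array_equal(self.presence, other.presence))
        )


@dataclass
class SwitchPenalties:
    """Normalized reciprocal recombination penalties R' for n-1 intervals."""

    values: np.ndarray  # (n-1,), each in [1, 2]
    raw_rates: np.ndarray  # (n-1,) cM/Mb
    normalization_min: float
    normalization_max: float
    degenerate: bool = False  # all rates (numerically) equal; every value = 2

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.raw_rates = np.asarray(self.raw_rates, dtype=np.float64)
        if self.values.shape != self.raw_rates.shape:
            raise ValueError("values and raw_rates must have equal length")
        if self.values.size and (
            self.values.min() < 1.0 - 1e-12 or self.values.max() > 2.0 + 1e-12
        ):
            raise ValueError("switch penalties must lie in [1, 2]")


def build_compact_graph(panel: HaplotypePanel) -> CompactPopulationGraph:
    """Collapse a panel into its compact population graph.

    A node exists at (site j, allele a, population l) iff some haplotype of
    population l carries a at j; missing alleles contribute nothing. With K
    alleles and p populations no site holds more than K*p nodes (2p in the
    bi-allelic case), which is what makes path counting on the collapsed
    graph O(n*p).
    """
    p = panel.n_populations
    if p < 2:
        raise ValueError("inference needs at least 2 populations in the panel")
    counts = np.bincount(panel.hap_population, minlength=p)
    empty = np.nonzero(counts == 0)[0]
    if empty.size:
        names = ", ".join(panel.population_names[i] for i in empty)
        raise ValueError(f"population(s) with zero haplotypes in panel: {names}")
    K = max(2, int(panel.alleles.max()) + 1 if panel.alleles.size else 2)
    presence = np.zeros((panel.n_sites, K, p), dtype=bool)
    for l in range(p):
        sub = panel.alleles[panel.hap_population == l]
        for a in range(K):
            presence[:, a, l] = (sub == a).any(axis=0)
    return CompactPopulationGraph(
        presence=presence,
        sites=list(panel.sites),
        population_names=list(panel.population_names),
    )


def identify_daims(graph: CompactPopulationGraph) -> np.ndarray:
    """Indices of sites with an allele present in one population, absent in another."""
    some = graph.presence.any(axis=2)  # (n, K): allele present in >=1 pop
    not_all = ~graph.presence.all(axis=2)  # absent from >=1 pop
    is_daim = (some & not_all).any(axis=1)
    return np.nonzero(is_daim)[0]


def compute_switch_penalties(
    sites: list[Site] | np.ndarray, gmap: GeneticMap
) -> SwitchPenalties:
    """Per-interval template-change penalties from a genetic map.

    rate_j = (cM(pos_{j+1}) - cM(pos_j)) / ((pos_{j+1} - pos_j) / 1e6);
    rates are min-max normalized over the n-1 intervals, then transformed by
    R' = 2 / (Rnorm + 1). The maximal-rate interval gets R' = 1, the minimal
    R' = 2. If all rates are equal (no signal in the map) every interval is
    assigned Rnorm = 0, i.e. R' = 2 — switching maximally penalized, leaving
    mismatch evidence to drive label changes.
    """
    if isinstance(sites, np.ndarray):
        positions = np.asarray(sites, dtype=np.int64)
    else:
        positions = np.array([s.pos for s in sites], dtype=np.int64)
    if positions.size < 2:
        raise ValueError("need at least 2 sites to compute switch penalties")
    dbp = np.diff(positions)
    if np.any(dbp < 0):
        raise ValueError("site positions must be non-decreasing")
    cm = gmap.cm_at(positions)
    dcm = np.clip(np.diff(cm), 0.0, None)
    # zero physical distance => fully linked, rate defined as 0
    rates = np.where(dbp > 0, dcm / np.where(dbp > 0, dbp, 1) * 1e6, 0.0)
    rmin, rmax = float(rates.min()), float(rates.max())
    # relative tolerance: interpolation round-off on a constant-rate map must
    # not be amplified to the full [0, 1] range by the normalization
    degenerate = rmax - rmin <= 1e-9 * max(abs(rmax), 1.0)
    if degenerate:
        logger.warning(
            "all %d inter-site recombination rates are equal (%.4g cM/Mb); "
            "degenerate normalization, every switch penalty set to 2",
            rates.size,
            rmin,
        )
        rnorm = np.zeros_like(rates)
    else:
        rnorm = (rates - rmin) / (rmax - rmin)
    values = 2.0 / (rnorm + 1.0)
    return SwitchPenalties(
        values=values,
        raw_rates=rates,
        normalization_min=rmin,
        normalization_max=rmax,
        degenerate=degenerate,
    )


def prune_rare_alleles(panel: HaplotypePanel, threshold: float) -> HaplotypePanel:
    """Mask population-rare alleles so they contribute no graph node.

    Within each population at each site, an allele carried by a fraction
    < ``threshold`` of that population's non-missing haplotypes is set to
    missing before collapsing. Dropping a wrong-population contaminant can
    turn a site into a dAIM, which is why pruning helps panels short on
    discriminative sites (though masking the witnessing allele itself can
    also remove a dAIM, so counts are not monotone in the threshold). If
    masking would leave a population with no allele at a site, its majority
    allele is kept.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if threshold >= 0.5:
        raise ValueError("threshold >= 0.5 would mask majority alleles")
    if threshold == 0:
        return panel
    alleles = panel.alleles.copy()
    K = max(2, int(alleles.max()) + 1 if alleles.size else 2)
    for l in range(panel.n_populations):
        rows = np.nonzero(panel.hap_population == l)[0]
        sub = alleles[rows]  # (m_l, n)
        counts = np.stack([(sub == a).sum(axis=0) for a in range(K)])  # (K, n)
        total = counts.sum(axis=0)  # non-missing haplotypes per site
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(total > 0, counts / np.maximum(total, 1), 0.0)
        mask = (freq > 0) & (freq < threshold)  # (K, n) alleles to drop
        # keep the majority allele where everything would be masked
        all_masked = (mask == (freq > 0)).all(axis=0) & (total > 0)
        if all_masked.any():
            keep = np.argmax(counts[:, all_masked], axis=0)
            mask[keep, np.nonzero(all_masked)[0]] = False
        for a in range(K):
            cols = np.nonzero(mask[a])[0]
            if cols.size:
                block = alleles[np.ix_(rows, cols)]
                block[block == a] = MISSING
                alleles[np.ix_(rows, cols)] = block
    return HaplotypePanel(
        alleles=alleles,
        sites=list(panel.sites),
        hap_population=panel.hap_population,
        population_names=list(panel.population_names),
        phased=panel.phased,
        sample_ids=list(panel.sample_ids),
    )
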