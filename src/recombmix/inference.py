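"""Minimum-penalty threading paths through the compact population graph.

The cost of labeling a query haplotype with populations (u_1..u_n) is

    f(P) = sum_j d(q_j, a(u_j)) + w * sum_j r(l(u_j), l(u_{j+1}))

with d a 0/1 allele mismatch, r = 0 for within-population moves and
r = R'_{j,j+1} (the normalized reciprocal recombination penalty in [1, 2])
for between-population moves, and w a scale factor balancing the two terms.
Because within-population switches are free, the best node of each
population at a site is always reachable, so the dynamic program runs over
population states only: O(n*p) time and memory. An exhaustive enumeration
oracle over all p^n label sequences verifies the DP on small instances.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .graph import CompactPopulationGraph, SwitchPenalties
from .panel_io import MISSING, QuerySet, Site

logger = logging.getLogger("recombmix")

__all__ = [
    "PenaltyParams",
    "AncestryPainting",
    "site_population_mismatch",
    "infer_path",
    "infer_queryset",
    "enumerate_paths_oracle",
]


@dataclass
class PenaltyParams:
    """Scoring parameters of the path objective.

    w scales the template-change term relative to the 0/1 mismatch term
    (default 1.5). within_population_switch_cost is 0 by definition of the
    method; setting it > 0 restores a uniform within-population r(.) =
    cost * R' for ablation runs. missing_population_cost is charged when a
    population has no node at a site (all its genotypes missing there):
    absence of evidence scores like a mismatch.
    """

    w: float = 1.5
    within_population_switch_cost: float = 0.0
    missing_population_cost: float = 1.0

    def __post_init__(self) -> None:
        if self.w < 0:
            raise ValueError("w must be non-negative")
        if self.within_population_switch_cost < 0:
            raise ValueError("within-population switch cost must be non-negative")


@dataclass
class AncestryPainting:
    """Per-site population labels for one query plus the path cost breakdown."""

    labels: np.ndarray  # (n,) population indices in [0, p)
    total_cost: float
    mismatch_cost_sum: float
    switch_cost_sum: float  # sum of r(.) terms, before scaling by w
    query_id: str = "query"
    sites: list[Site] = field(default_factory=list)


def site_population_mismatch(
    graph: CompactPopulationGraph,
    query: np.ndarray,
    params: PenaltyParams | None = None,
) -> np.ndarray:
    """Per-site, per-population mismatch costs m[j][l].

    m[j][l] = 0 if the query's allele at j is present in population l's node
    set, else 1. Free within-population switching means the best-matching
    node of each population is attainable, so only this 0/1 summary of the
    node set matters. Missing query alleles are uninformative (a zero row);
    a population with no node at a site scores missing_population_cost.
    """
    params = params or PenaltyParams()
    query = np.asarray(query)
    n, K, p = graph.presence.shape
    if query.shape[-1] != n:
        raise ValueError(
            f"query length {query.shape[-1]} does not match graph site count {n}"
        )
    squeeze = query.ndim == 1
    q = np.atleast_2d(query)  # (b, n)
    safe = np.clip(q, 0, K - 1)
    # matched[b, j, l]: query allele is a node of population l at site j
    matched = np.take_along_axis(
        graph.presence[None, :, :, :].repeat(q.shape[0], axis=0),
        safe[:, :, None, None].astype(np.int64),
        axis=2,
    )[:, :, 0, :]
    out_of_range = (q < 0) | (q >= K)
    matched = matched & ~out_of_range[:, :, None]
    m = (~matched).astype(np.float64)
    pop_absent = ~graph.presence.any(axis=1)  # (n, p)
    m = np.where(pop_absent[None, :, :], params.missing_population_cost, m)
    m = np.where((q == MISSING)[:, :, None], 0.0, m)
    return m[0] if squeeze else m


def _dp_batch(
    m: np.ndarray, penalties: SwitchPenalties, params: PenaltyParams
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Viterbi-style DP over population states for a batch.

    m is (b, n, p). Returns (labels (b, n), total costs (b,)). Tie-breaks:
    prefer staying in the current population among equal-cost predecessors,
    then the lowest population index; final states tie to the lowest index.
    """
    b, n, p = m.shape
    w = params.w
    wc = params.within_population_switch_cost
    R = penalties.values
    if R.shape[0] != n - 1:
        raise ValueError("penalty vector length must be n - 1")
    back = np.empty((n, b, p), dtype=np.int16)
    back[0] = np.arange(p)[None, :]
    C = m[:, 0, :].copy()  # (b, p)
    rows = np.arange(b)
    for j in range(1, n):
        r = float(R[j - 1])
        stay = C + w * wc * r
        best_idx = np.argmin(C, axis=1)  # lowest index on ties
        best = C[rows, best_idx]
        masked = C.copy()
        masked[rows, best_idx] = np.inf
        second_idx = np.argmin(masked, axis=1)
        second = masked[rows, second_idx]
        # cheapest predecessor != l, with its (lowest) index
        sw_val = np.where(
            np.arange(p)[None, :] == best_idx[:, None],
            second[:, None],
            best[:, None],
        ) + w * r
        sw_idx = np.where(
            np.arange(p)[None, :] == best_idx[:, None],
            second_idx[:, None],
            best_idx[:, None],
        )
        stay_wins = stay <= sw_val
        C = m[:, j, :] + np.where(stay_wins, stay, sw_val)
        back[j] = np.where(stay_wins, np.arange(p)[None, :], sw_idx)
    labels = np.empty((b, n), dtype=np.int64)
    last = np.argmin(C, axis=1)
    total = C[rows, last]
    labels[:, n - 1] = last
    for j in range(n - 1, 0, -1):
        last = back[j][rows, last]
        labels[:, j - 1] = last
    return labels, total


def _cost_breakdown(
    labels: np.ndarray,
    m: np.ndarray,
    penalties: SwitchPenalties,
    params: PenaltyParams,
) -> tuple[float, float]:
    """(mismatch sum, r-term sum) recomputed from a label sequence."""
    n = labels.shape[0]
    mism = float(m[np.arange(n), labels].sum())
    diff = labels[:-1] != labels[1:]
    r_sum = float(penalties.values[diff].sum())
    if params.within_population_switch_cost:
        r_sum += float(
            params.within_population_switch_cost * penalties.values[~diff].sum()
        )
    return mism, r_sum


def infer_path(
    graph: CompactPopulationGraph,
    penalties: SwitchPenalties,
    query: np.ndarray,
    params: PenaltyParams | None = None,
    query_id: str = "query",
) -> AncestryPainting:
    """Paint one query haplotype with the minimum-penalty population path."""
    params = params or PenaltyParams()
    if graph.n_populations < 2:
        raise ValueError("nothing to infer with fewer than 2 populations")
    m = site_population_mismatch(graph, query, params)
    if m.shape[0] == 1:  # single site: no transition term
        l = int(np.argmin(m[0]))
        return AncestryPainting(
            labels=np.array([l]),
            total_cost=float(m[0, l]),
            mismatch_cost_sum=float(m[0, l]),
            switch_cost_sum=0.0,
            query_id=query_id,
            sites=list(graph.sites),
        )
    labels, total = _dp_batch(m[None, :, :], penalties, params)
    labels, total = labels[0], float(total[0])
    mism, r_sum = _cost_breakdown(labels, m, penalties, params)
    assert abs(total - (mism + params.w * r_sum)) < 1e-6
    return AncestryPainting(
        labels=labels,
        total_cost=total,
        mismatch_cost_sum=mism,
        switch_cost_sum=r_sum,
        query_id=query_id,
        sites=list(graph.sites),
    )


def infer_queryset(
    graph: CompactPopulationGraph,
    penalties: SwitchPenalties,
    queries: QuerySet,
    params: PenaltyParams | None = None,
    marker_mask: np.ndarray | None = None,
) -> list[AncestryPainting]:
    """Paint every query haplotype (independently, in one vectorized pass).

    marker_mask, if given, marks sites whose mismatch evidence is used;
    masked-out sites are treated as uninformative (zero mismatch row) but
    still receive labels.
    """
    params = params or PenaltyParams()
    if queries.n_sites != graph.n_sites:
        raise ValueError("queries are not aligned to the graph's sites")
    m = site_population_mismatch(graph, queries.haplotypes, params)  # (q, n, p)
    if marker_mask is not None:
        marker_mask = np.asarray(marker_mask, dtype=bool)
        m = np.where(marker_mask[None, :, None], m, 0.0)
    if graph.n_sites == 1:
        paintings = []
        for i, name in enumerate(queries.hap_names):
            l = int(np.argmin(m[i, 0]))
            paintings.append(
                AncestryPainting(
                    labels=np.array([l]),
                    total_cost=float(m[i, 0, l]),
                    mismatch_cost_sum=float(m[i, 0, l]),
                    switch_cost_sum=0.0,
                    query_id=name,
                    sites=list(graph.sites),
                )
            )
        return paintings
    labels, totals = _dp_batch(m, penalties, params)
    paintings = []
    for i, name in enumerate(queries.hap_names):
        mism, r_sum = _cost_breakdown(labels[i], m[i], penalties, params)
        paintings.append(
            AncestryPainting(
                labels=labels[i],
                total_cost=float(totals[i]),
                mismatch_cost_sum=mism,
                switch_cost_sum=r_sum,
                query_id=name,
                sites=list(graph.sites),
            )
        )
        logger.debug("query %s: cost %.3f", name, float(totals[i]))
    return paintings


def enumerate_paths_oracle(
    graph: CompactPopulationGraph,
    penalties: SwitchPenalties,
    query: np.ndarray,
    params: PenaltyParams | None = None,
) -> tuple[float, np.ndarray]:
    """Exhaustive minimum of the path objective over all p^n label sequences.

    Valid because free within-population switching reduces node choice to the
    per-population mismatch summary m[j][l]. Among (numerically) tied optima
    the returned sequence follows the same preference order as the DP:
    lowest final label, then backwards prefer staying, then the lowest label.
    """
    params = params or PenaltyParams()
    n = graph.n_sites
    p = graph.n_populations
    if p**n > 1_000_000:
        raise ValueError(f"p^n = {p**n} exceeds the enumeration guard (1e6)")
    m = site_population_mismatch(graph, query, params)
    w = params.w
    wc = params.within_population_switch_cost
    R = penalties.values
    best_cost = np.inf
    candidates: list[tuple[int, ...]] = []
    for path in itertools.product(range(p), repeat=n):
        cost = 0.0
        for j in range(n):
            cost += m[j, path[j]]
        for j in range(n - 1):
            if path[j] != path[j + 1]:
                cost += w * R[j]
            elif wc:
                cost += w * wc * R[j]
        if cost < best_cost - 1e-9:
            best_cost = cost
            candidates = [path]
        elif cost <= best_cost + 1e-9:
            if cost < best_cost:
                best_cost = cost
            candidates.append(path)

    def tie_key(path: tuple[int, ...]):
        key = [path[-1]]
        for j in range(n - 2, -1, -1):
            key.append(-1 if path[j] == path[j + 1] else path[j])
        return key

    chosen = min(candidates, key=tie_key)
    return float(best_cost), np.array(chosen, dtype=np.int64)
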