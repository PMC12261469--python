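"""Scoring paintings against truth: accuracy rate and LAMP-LD-style r².

Markers are filtered before scoring: a site is excluded when its minor
allele frequency is <= 0.005 or its minor allele count is <= 50, computed
over the query haplotypes (the cohort the inference is evaluated on;
configurable to reference-panel frequencies by passing any haplotype
matrix). Accuracy is the fraction of correctly labeled (haplotype, marker)
cells among retained markers. The r² statistic pairs haplotypes into
diploid individuals, counts per-individual ancestry allele dosages
(0/1/2) for each population, and averages the squared Pearson correlation
between true and inferred dosages over populations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger("recombmix")

__all__ = [
    "EvaluationResult",
    "marker_filter_mask",
    "accuracy_rate",
    "r2_lampld",
    "evaluate_painting",
]


@dataclass
class EvaluationResult:
    accuracy: float
    r2: float
    per_population_r2: np.ndarray
    n_markers_evaluated: int
    n_markers_filtered: int


def marker_filter_mask(
    haplotypes: np.ndarray,
    maf_threshold: float = 0.005,
    mac_threshold: int = 50,
) -> np.ndarray:
    """Boolean mask of retained sites over a haplotype matrix.

    A site is excluded iff its minor allele frequency <= maf_threshold OR
    its minor allele count <= mac_threshold ("<=" taken literally, so
    monomorphic sites are always excluded). For multi-allelic sites the
    minor count is everything that is not the major allele.
    """
    haplotypes = np.asarray(haplotypes)
    if haplotypes.size == 0:
        raise ValueError("empty haplotype matrix")
    K = max(2, int(haplotypes.max()) + 1)
    counts = np.stack(
        [(haplotypes == a).sum(axis=0) for a in range(K)]
    )  # (K, n)
    total = counts.sum(axis=0)
    mac = total - counts.max(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = np.where(total > 0, mac / np.maximum(total, 1), 0.0)
    return ~((maf <= maf_threshold) | (mac <= mac_threshold))


def accuracy_rate(
    truth: np.ndarray, inferred: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Fraction of correctly labeled (haplotype, marker) cells on retained markers."""
    truth = np.atleast_2d(np.asarray(truth))
    inferred = np.atleast_2d(np.asarray(inferred))
    if truth.shape != inferred.shape:
        raise ValueError("truth and inferred label shapes differ")
    if mask is None:
        mask = np.ones(truth.shape[1], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("marker filter retained no sites")
    return float((truth[:, mask] == inferred[:, mask]).mean())


def _r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation with the degenerate-variance convention:
    a zero-variance vector gives 1.0 if the vectors are identical, else 0.0."""
    x = x.astype(np.float64).ravel()
    y = y.astype(np.float64).ravel()
    if x.std() == 0.0 or y.std() == 0.0:
        ident = bool(np.array_equal(x, y))
        logger.warning(
            "degenerate dosage variance in r2; scoring %s by convention",
            1.0 if ident else 0.0,
        )
        return 1.0 if ident else 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def r2_lampld(
    truth: np.ndarray,
    inferred: np.ndarray,
    mask: np.ndarray | None = None,
    p: int | None = None,
    mode: str = "pooled",
) -> tuple[float, np.ndarray]:
    """Mean squared correlation of true vs inferred ancestry dosages.

    Haplotype rows pair into diploid individuals as (0,1), (2,3), ...
    ``mode="pooled"`` (default) flattens individuals x retained markers into
    one correlation per population; ``mode="per_marker"`` correlates across
    individuals at each marker and averages over markers. Returns
    (mean r², per-population r²).
    """
    truth = np.atleast_2d(np.asarray(truth))
    inferred = np.atleast_2d(np.asarray(inferred))
    if truth.shape != inferred.shape:
        raise ValueError("truth and inferred label shapes differ")
    if truth.shape[0] % 2:
        raise ValueError("odd haplotype count: haplotypes must pair into diploids")
    if mask is None:
        mask = np.ones(truth.shape[1], dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("marker filter retained no sites")
    if p is None:
        p = int(max(truth.max(), inferred.max())) + 1
    t = truth[:, mask]
    f = inferred[:, mask]
    n_ind = t.shape[0] // 2
    per_pop = np.empty(p)
    for l in range(p):
        dt = (t == l).reshape(n_ind, 2, -1).sum(axis=1)  # (ind, markers)
        df = (f == l).reshape(n_ind, 2, -1).sum(axis=1)
        if mode == "pooled":
            per_pop[l] = _r2(dt, df)
        elif mode == "per_marker":
            vals = [_r2(dt[:, j], df[:, j]) for j in range(dt.shape[1])]
            per_pop[l] = float(np.mean(vals))
        else:
            raise ValueError("mode must be 'pooled' or 'per_marker'")
    return float(per_pop.mean()), per_pop


def evaluate_painting(
    truth: np.ndarray,
    inferred: np.ndarray,
    query_haplotypes: np.ndarray,
    p: int | None = None,
    maf_threshold: float = 0.005,
    mac_threshold: int = 50,
    r2_mode: str = "pooled",
) -> EvaluationResult:
    """Filter markers on the query haplotypes, then score accuracy and r²."""
    mask = marker_filter_mask(query_haplotypes, maf_threshold, mac_threshold)
    if not mask.any():
        raise ValueError(
            "marker filter retained no sites; lower --maf/--mac for small cohorts"
        )
    acc = accuracy_rate(truth, inferred, mask)
    mean_r2, per_pop = r2_lampld(truth, inferred, mask, p=p, mode=r2_mode)
    return EvaluationResult(
        accuracy=acc,
        r2=mean_r2,
        per_population_r2=per_pop,
        n_markers_evaluated=int(mask.sum()),
        n_markers_filtered=int((~mask).sum()),
    )
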