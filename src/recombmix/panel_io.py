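"""Readers and writers for the formats the tool touches.

Reference panels and query haplotypes come in as VCF (cyvcf2); compact
population graphs, simulated panels and queries go out as VCF (pysam).
Sample-to-population maps are two-column TSV, genetic maps are PLINK
``.map`` or HapMap-style text, and paintings are written as a per-site
TSV plus a run-length segment TSV.

All haplotype matrices are ``int8`` with :data:`MISSING` (-1) marking a
missing allele. Population indices are 0-based internally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF
import pysam

logger = logging.getLogger("recombmix")

MISSING: int = -1

__all__ = [
    "MISSING",
    "Site",
    "HaplotypePanel",
    "GeneticMap",
    "QuerySet",
    "read_population_map",
    "read_reference_panel",
    "read_query_haplotypes",
    "read_genetic_map",
    "write_genetic_map",
    "write_reference_panel",
    "write_query_vcf",
    "write_population_map",
    "write_compact_panel",
    "read_compact_panel",
    "write_painting",
    "write_truth",
]


@dataclass(frozen=True)
class Site:
    """One variant record: chromosome, 1-based bp position, alleles, id."""

    chrom: str
    pos: int
    ref: str
    alt: tuple[str, ...]
    id: str = "."

    @property
    def n_alleles(self) -> int:
        return 1 + len(self.alt)


@dataclass
class HaplotypePanel:
    """A labeled reference panel: m haplotypes x n sites with population tags.

    Each diploid sample contributes two rows to ``alleles``; both rows carry
    the sample's population index. ``phased`` records whether the source VCF
    was phased — graph collapsing is insensitive to phase, so an unphased
    panel is accepted.
    """

    alleles: np.ndarray  # (m, n) int8, MISSING = -1
    sites: list[Site]
    hap_population: np.ndarray  # (m,) int, values in [0, p)
    population_names: list[str]
    phased: bool = True
    sample_ids: list[str] = field(default_factory=list)  # per haplotype

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        self.hap_population = np.asarray(self.hap_population, dtype=np.int64)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D haplotype x site matrix")
        if self.alleles.shape[0] != self.hap_population.shape[0]:
            raise ValueError("hap_population length must match haplotype count")
        if self.alleles.shape[1] != len(self.sites):
            raise ValueError("site metadata length must match site count")
        if len(self.hap_population) and self.hap_population.max() >= len(
            self.population_names
        ):
            raise ValueError("population index out of range")
        pos = np.array([s.pos for s in self.sites])
        if len(pos) > 1 and not np.all(np.diff(pos) > 0):
            raise ValueError("site positions must be strictly increasing")
        chroms = {s.chrom for s in self.sites}
        if len(chroms) > 1:
            raise ValueError(
                "panel spans multiple chromosomes; run one chromosome at a time"
            )
        if not self.sample_ids:
            self.sample_ids = [f"hap{i}" for i in range(self.alleles.shape[0])]

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    @property
    def n_populations(self) -> int:
        return len(self.population_names)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.pos for s in self.sites], dtype=np.int64)

    def subset_sites(self, mask: np.ndarray) -> "HaplotypePanel":
        mask = np.asarray(mask, dtype=bool)
        return HaplotypePanel(
            alleles=self.alleles[:, mask],
            sites=[s for s, keep in zip(self.sites, mask) if keep],
            hap_population=self.hap_population,
            population_names=list(self.population_names),
            phased=self.phased,
            sample_ids=list(self.sample_ids),
        )


@dataclass
class GeneticMap:
    """Physical position to centiMorgan lookup for one chromosome.

    ``cm_at`` interpolates piecewise-linearly between entries and
    extrapolates beyond the map span with the flanking interval's rate
    (clipped at zero), so sites outside the mapped region still get a
    defined, non-decreasing genetic position.
    """

    positions: np.ndarray  # bp, strictly increasing
    cm: np.ndarray  # centiMorgan, non-decreasing
    chrom: str = "."

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        if self.positions.size == 0:
            raise ValueError("genetic map is empty")
        if self.positions.size != self.cm.size:
            raise ValueError("positions and cM arrays differ in length")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("genetic map positions must be strictly increasing")
        if np.any(np.diff(self.cm) < 0):
            raise ValueError("genetic map cM values must be non-decreasing")

    @property
    def length_morgans(self) -> float:
        return float(self.cm[-1] - self.cm[0]) / 100.0

    def cm_at(self, positions: np.ndarray) -> np.ndarray:
        positions = np.asarray(positions, dtype=np.float64)
        out = np.interp(positions, self.positions, self.cm)
        if self.positions.size >= 2:
            left_rate = max(
                0.0,
                (self.cm[1] - self.cm[0]) / (self.positions[1] - self.positions[0]),
            )
            right_rate = max(
                0.0,
                (self.cm[-1] - self.cm[-2])
                / (self.positions[-1] - self.positions[-2]),
            )
            lo = positions < self.positions[0]
            hi = positions > self.positions[-1]
            out[lo] = self.cm[0] - (self.positions[0] - positions[lo]) * left_rate
            out[hi] = self.cm[-1] + (positions[hi] - self.positions[-1]) * right_rate
        return out

    def bp_at(self, cm_values: np.ndarray) -> np.ndarray:
        """Inverse lookup (used by the simulator to place crossovers)."""
        cm_values = np.asarray(cm_values, dtype=np.float64)
        return np.interp(cm_values, self.cm, self.positions.astype(np.float64))


@dataclass
class QuerySet:
    """Phased query haplotypes aligned site-for-site to a reference panel."""

    haplotypes: np.ndarray  # (q, n) int8
    sites: list[Site]
    sample_ids: list[str]  # per haplotype
    hap_indices: np.ndarray  # (q,) 0/1 within the sample
    panel_mask: np.ndarray | None = None  # set when --intersect subsets the panel

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.hap_indices = np.asarray(self.hap_indices, dtype=np.int64)
        if self.haplotypes.shape[1] != len(self.sites):
            raise ValueError("site metadata length must match site count")
        if self.haplotypes.shape[0] != len(self.sample_ids):
            raise ValueError("sample_ids length must match haplotype count")

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def hap_names(self) -> list[str]:
        return [
            f"{s}_{h}" for s, h in zip(self.sample_ids, self.hap_indices)
        ]


# ---------------------------------------------------------------------------
# reading


def read_population_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample_id, population_name); '#' lines are comments."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#", dtype=str, names=["sample", "pop"]
    )
    if df.shape[1] < 2 or df["pop"].isna().any():
        raise ValueError(f"population map {path} must have two tab-separated columns")
    return dict(zip(df["sample"], df["pop"]))


def _gt_pair(gt: list) -> tuple[int, int, bool]:
    """Normalize a cyvcf2 genotype entry to (a0, a1, phased)."""
    if len(gt) == 2:  # haploid
        a = gt[0]
        return (a if a is not None and a >= 0 else MISSING, MISSING, True)
    a0, a1, phased = gt[0], gt[1], bool(gt[-1])
    a0 = a0 if a0 is not None and a0 >= 0 else MISSING
    a1 = a1 if a1 is not None and a1 >= 0 else MISSING
    return a0, a1, phased


def _read_vcf_haplotypes(
    vcf_path: str | Path,
    samples: Sequence[str] | None = None,
    multiallelic: bool = False,
    require_phased: bool = False,
):
    """Shared VCF -> (haplotype matrix, sites, sample order, phased flag)."""
    vcf = VCF(str(vcf_path))
    vcf_samples = list(vcf.samples)
    if samples is not None:
        missing = [s for s in samples if s not in vcf_samples]
        if missing:
            raise ValueError(
                f"sample(s) in population map absent from VCF {vcf_path}: "
                + ", ".join(missing)
            )
        vcf.set_samples(list(samples))
        used = list(vcf.samples)
    else:
        used = vcf_samples
    if not used:
        raise ValueError(f"VCF {vcf_path} has no usable samples")

    sites: list[Site] = []
    columns: list[np.ndarray] = []
    phased_all = True
    for v in vcf:
        if len(v.ALT) != 1 and not multiallelic:
            raise ValueError(
                f"multi-allelic record at {v.CHROM}:{v.POS} "
                "(pass multiallelic=True / --multiallelic to accept)"
            )
        sites.append(
            Site(
                chrom=str(v.CHROM),
                pos=int(v.POS),
                ref=str(v.REF),
                alt=tuple(str(a) for a in v.ALT),
                id=str(v.ID) if v.ID else ".",
            )
        )
        col = np.empty(2 * len(used), dtype=np.int8)
        for i, gt in enumerate(v.genotypes):
            a0, a1, phased = _gt_pair(gt)
            if not phased and (a0 != MISSING or a1 != MISSING):
                if require_phased:
                    raise ValueError(
                        f"unphased genotype for sample {used[i]} at "
                        f"{v.CHROM}:{v.POS}; queries must be phased haplotypes"
                    )
                phased_all = False
            col[2 * i] = a0
            col[2 * i + 1] = a1
        columns.append(col)
    if not sites:
        raise ValueError(f"VCF {vcf_path} contains no variant records")
    alleles = np.stack(columns, axis=1)  # (2*samples, n_sites)
    return alleles, sites, used, phased_all


def read_reference_panel(
    vcf_path: str | Path,
    pop_map_path: str | Path,
    multiallelic: bool = False,
) -> HaplotypePanel:
    """Load a labeled reference panel from VCF plus a sample->population TSV.

    Each mapped diploid sample contributes two haplotype rows tagged with its
    population. Unphased genotypes are accepted (collapsing is
    phase-insensitive); missing genotypes become the missing sentinel.
    Population order follows first appearance in the map file.
    """
    pop_map = read_population_map(pop_map_path)
    samples = list(pop_map)
    alleles, sites, used, phased = _read_vcf_haplotypes(
        vcf_path, samples=samples, multiallelic=multiallelic
    )
    population_names: list[str] = []
    for s in samples:
        if pop_map[s] not in population_names:
            population_names.append(pop_map[s])
    pop_index = {name: i for i, name in enumerate(population_names)}
    hap_population = np.repeat([pop_index[pop_map[s]] for s in used], 2)
    sample_ids = [s for s in used for _ in range(2)]
    panel = HaplotypePanel(
        alleles=alleles,
        sites=sites,
        hap_population=hap_population,
        population_names=population_names,
        phased=phased,
        sample_ids=sample_ids,
    )
    logger.info(
        "reference panel: %d haplotypes, %d sites, %d populations (%s)",
        panel.n_haplotypes,
        panel.n_sites,
        panel.n_populations,
        ",".join(population_names),
    )
    return panel


def read_query_haplotypes(
    vcf_path: str | Path,
    panel: HaplotypePanel,
    intersect: bool = False,
) -> QuerySet:
    """Load phased query haplotypes and align them to the panel's sites.

    In strict mode (default) the query VCF must carry exactly the panel's
    sites; with ``intersect=True`` both are subset to the shared sites and
    the returned QuerySet carries ``panel_mask`` for subsetting the panel.
    """
    alleles, sites, used, _ = _read_vcf_haplotypes(vcf_path, require_phased=True)
    key = lambda s: (s.chrom, s.pos, s.ref, s.alt)
    panel_keys = [key(s) for s in panel.sites]
    query_keys = [key(s) for s in sites]
    if query_keys == panel_keys:
        qmask = np.ones(len(sites), dtype=bool)
        pmask = None
    else:
        if not intersect:
            extra = set(query_keys) - set(panel_keys)
            miss = set(panel_keys) - set(query_keys)
            raise ValueError(
                "query sites do not match panel sites "
                f"({len(extra)} query-only, {len(miss)} panel-only); "
                "rerun with intersect=True / --intersect to subset to shared sites"
            )
        shared = set(panel_keys) & set(query_keys)
        if not shared:
            raise ValueError("query and panel share no sites")
        qmask = np.array([k in shared for k in query_keys])
        pmask = np.array([k in shared for k in panel_keys])
        logger.info(
            "intersecting query and panel: %d shared sites "
            "(%d query-only and %d panel-only dropped)",
            len(shared),
            int((~qmask).sum()),
            int((~pmask).sum()),
        )
    sample_ids = [s for s in used for _ in range(2)]
    hap_indices = np.tile([0, 1], len(used))
    return QuerySet(
        haplotypes=alleles[:, qmask],
        sites=[s for s, k in zip(sites, qmask) if k],
        sample_ids=sample_ids,
        hap_indices=hap_indices,
        panel_mask=pmask,
    )


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_genetic_map(path: str | Path) -> GeneticMap:
    """Read a genetic map in PLINK ``.map`` or HapMap-style layout.

    HapMap style is (chrom, bp, rate, cM), usually with a header line; PLINK
    style is (chrom, id, cM, bp) with no header. The dialect is auto-detected
    from the header and column types. Entries are sorted by bp with duplicate
    positions collapsed (first kept); a cM value that decreases along the
    chromosome is an error.
    """
    rows: list[list[str]] = []
    with open(path) as fh:
        for line in fh:
            toks = line.split()
            if toks:
                rows.append(toks)
    if not rows:
        raise ValueError(f"genetic map {path} is empty")
    if len(rows[0]) < 4:
        raise ValueError(f"genetic map {path}: expected 4 columns")
    # a header row is non-numeric where both dialects carry numbers
    header = not (_is_number(rows[0][2]) and _is_number(rows[0][3]))
    if header:
        body, dialect = rows[1:], "hapmap"
    else:
        body = rows
        if len(rows[0]) < 4:
            raise ValueError(f"genetic map {path}: expected 4 columns")
        if not _is_number(rows[0][1]):
            dialect = "plink"
        else:
            # both layouts numeric: bp is the strictly-increasing integer column
            col1 = [float(r[1]) for r in rows]
            col3 = [float(r[3]) for r in rows]
            inc1 = all(b > a for a, b in zip(col1, col1[1:]))
            inc3 = all(b > a for a, b in zip(col3, col3[1:]))
            dialect = "hapmap" if inc1 or not inc3 else "plink"
    if not body:
        raise ValueError(f"genetic map {path} has a header but no entries")
    chrom = body[0][0]
    if dialect == "hapmap":
        pos = [int(float(r[1])) for r in body]
        cm = [float(r[3])
              for r in body]
    else:
        pos = [int(float(r[3])) for r in body]
        cm = [float(r[2]) for r in body]
    order = np.argsort(pos, kind="stable")
    pos_a = np.array(pos)[order]
    cm_a = np.array(cm)[order]
    keep = np.concatenate([[True], np.diff(pos_a) > 0])
    pos_a, cm_a = pos_a[keep], cm_a[keep]
    bad = np.nonzero(np.diff(cm_a) < 0)[0]
    if bad.size:
        raise ValueError(
            f"genetic map {path}: cM decreases at row {int(bad[0]) + 2} "
            f"(position {int(pos_a[bad[0] + 1])})"
        )
    return GeneticMap(positions=pos_a, cm=cm_a, chrom=chrom)


def write_genetic_map(gmap: GeneticMap, path: str | Path) -> None:
    """Write HapMap-style (chrom, bp, rate cM/Mb, cM) with a header line."""
    with open(path, "w") as fh:
        fh.write("Chromosome\tPosition(bp)\tRate(cM/Mb)\tMap(cM)\n")
        rates = np.zeros_like(gmap.cm)
        if gmap.positions.size > 1:
            rates[:-1] = np.diff(gmap.cm) / (np.diff(gmap.positions) / 1e6)
        for p, r, c in zip(gmap.positions, rates, gmap.cm):
            fh.write(f"{gmap.chrom}\t{int(p)}\t{r:.8g}\t{c:.8g}\n")


# ---------------------------------------------------------------------------
# writing VCF


def _vcf_header(sites: list[Site], sample_names: Sequence[str], extra: Sequence[str] = ()):
    header = pysam.VariantHeader()
    for line in extra:
        header.add_line(line)
    header.add_line(f"##contig=<ID={sites[0].chrom}>")
    header.add_line(
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'
    )
    for s in sample_names:
        header.add_sample(s)
    return header


def _write_diploid_vcf(
    path: str | Path,
    sites: list[Site],
    alleles: np.ndarray,
    sample_names: Sequence[str],
    extra_header: Sequence[str] = (),
) -> None:
    """Write pairs of haplotype rows as phased diploid GT columns."""
    if alleles.shape[0] != 2 * len(sample_names):
        raise ValueError("haplotype count must be twice the sample count")
    header = _vcf_header(sites, sample_names, extra_header)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, site in enumerate(sites):
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                stop=site.pos - 1 + len(site.ref),
                alleles=(site.ref, *site.alt),
                id=None if site.id == "." else site.id,
            )
            for i, name in enumerate(sample_names):
                a0 = int(alleles[2 * i, j])
                a1 = int(alleles[2 * i + 1, j])
                rec.samples[name]["GT"] = (
                    None if a0 == MISSING else a0,
                    None if a1 == MISSING else a1,
                )
                rec.samples[name].phased = True
            out.write(rec)


def write_reference_panel(panel: HaplotypePanel, path: str | Path) -> None:
    """Serialize a panel as a phased VCF (consecutive haplotype pairs = samples)."""
    if panel.n_haplotypes % 2:
        raise ValueError("panel must contain an even number of haplotypes")
    names = panel.sample_ids[::2]
    if len(set(names)) != len(names):
        raise ValueError("duplicate sample ids in panel")
    _write_diploid_vcf(path, panel.sites, panel.alleles, names)


def write_query_vcf(queries: QuerySet, path: str | Path) -> None:
    _write_diploid_vcf(
        path, queries.sites, queries.haplotypes, queries.sample_ids[::2]
    )


def write_population_map(
    sample_ids: Sequence[str], populations: Sequence[str], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for s, p in zip(sample_ids, populations):
            fh.write(f"{s}\t{p}\n")


# ---------------------------------------------------------------------------
# compact-panel VCF

_COMPACT_TAG = "##recombmix_compact_panel=1"


def write_compact_panel(graph, path: str | Path) -> None:
    """Serialize a compact population graph as a VCF of template columns.

    The encoding is this package's own dialect: one synthetic haploid
    template per (population, allele-slot) pair, written as a diploid column
    ``{pop}~A{k}`` whose GT at site j is ``k|k`` when the (k, pop) node
    exists there and ``.|.`` otherwise. A header line records the population
    names in order, so the graph round-trips exactly.
    """
    if graph.n_sites == 0:
        raise ValueError("cannot serialize an empty compact graph (0 sites)")
    from . import __version__

    K = graph.max_alleles
    names = [
        f"{pop}~A{k}" for pop in graph.population_names for k in range(K)
    ]
    extra = [
        _COMPACT_TAG,
        f"##recombmix_version={__version__}",
        "##recombmix_populations=" + ",".join(graph.population_names),
        f"##recombmix_max_alleles={K}",
    ]
    header = _vcf_header(graph.sites, names, extra)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j, site in enumerate(graph.sites):
            rec = out.new_record(
                contig=site.chrom,
                start=site.pos - 1,
                stop=site.pos - 1 + len(site.ref),
                alleles=(site.ref, *site.alt),
                id=None if site.id == "." else site.id,
            )
            for l, pop in enumerate(graph.population_names):
                for k in range(K):
                    name = f"{pop}~A{k}"
                    if k < site.n_alleles and graph.presence[j, k, l]:
                        rec.samples[name]["GT"] = (k, k)
                    else:
                        rec.samples[name]["GT"] = (None, None)
                    rec.samples[name].phased = True
            out.write(rec)


def read_compact_panel(path: str | Path):
    """Inverse of :func:`write_compact_panel`."""
    from .graph import CompactPopulationGraph

    vcf = VCF(str(path))
    raw = vcf.raw_header
    if _COMPACT_TAG.lstrip("#") not in raw:
        raise ValueError(f"{path} is not a recombmix compact-panel VCF")
    pops: list[str] | None = None
    K = None
    for line in raw.splitlines():
        if line.startswith("##recombmix_populations="):
            pops = line.split("=", 1)[1].split(",")
        elif line.startswith("##recombmix_max_alleles="):
            K = int(line.split("=", 1)[1])
    if pops is None or K is None:
        raise ValueError(f"{path}: compact-panel header metadata missing")
    col_of = {f"{pop}~A{k}": (k, l) for l, pop in enumerate(pops) for k in range(K)}
    samples = list(vcf.samples)
    if set(samples) != set(col_of):
        raise ValueError(f"{path}: template columns do not match header metadata")
    sites: list[Site] = []
    presence_rows: list[np.ndarray] = []
    for v in vcf:
        sites.append(
            Site(
                chrom=str(v.CHROM),
                pos=int(v.POS),
                ref=str(v.REF),
                alt=tuple(str(a) for a in v.ALT),
                id=str(v.ID) if v.ID else ".",
            )
        )
        row = np.zeros((K, len(pops)), dtype=bool)
        for i, gt in enumerate(v.genotypes):
            a0, _, _ = _gt_pair(gt)
            if a0 != MISSING:
                k, l = col_of[samples[i]]
                row[k, l] = True
        presence_rows.append(row)
    return CompactPopulationGraph(
        presence=np.stack(presence_rows, axis=0),
        sites=sites,
        population_names=pops,
    )


# ---------------------------------------------------------------------------
# painting output


def write_painting(
    paintings: Sequence,
    population_names: Sequence[str],
    persite_path: str | Path,
    segments_path: str | Path | None = None,
) -> None:
    """Write per-site population labels and maximal constant-label segments.

    The per-site TSV has a ``#chrom  pos`` prefix and one label column per
    query haplotype. The segment TSV lists maximal runs as half-open bp
    intervals ``[start, end)`` anchored at site positions: a run ending at
    the last site closes at ``last_pos + 1``, otherwise at the next run's
    first position.
    """
    if not paintings:
        raise ValueError("no paintings to write")
    sites = paintings[0].sites
    for p in paintings:
        if [s.pos for s in p.sites] != [s.pos for s in sites] or [
            s.chrom for s in p.sites
        ] != [s.chrom for s in sites]:
            raise ValueError("paintings have mismatched site lists")
    names = [p.query_id for p in paintings]
    with open(persite_path, "w") as fh:
        fh.write("#chrom\tpos\t" + "\t".join(names) + "\n")
        for j, site in enumerate(sites):
            labels = [population_names[p.labels[j]] for p in paintings]
            fh.write(f"{site.chrom}\t{site.pos}\t" + "\t".join(labels) + "\n")
    if segments_path is None:
        return
    pos = [s.pos for s in sites]
    with open(segments_path, "w") as fh:
        fh.write("#chrom\tstart_pos\tend_pos\thap\tpopulation\n")
        for p in paintings:
            lab = np.asarray(p.labels)
            change = np.nonzero(np.diff(lab))[0]
            starts = np.concatenate([[0], change + 1])
            ends = np.concatenate([change, [len(lab) - 1]])
            for a, b in zip(starts, ends):
                end_bp = pos[b + 1] if b + 1 < len(pos) else pos[b] + 1
                fh.write(
                    f"{sites[0].chrom}\t{pos[a]}\t{end_bp}\t{p.query_id}\t"
                    f"{population_names[lab[a]]}\n"
                )


def write_truth(
    truth: np.ndarray,
    queries: QuerySet,
    population_names: Sequence[str],
    path: str | Path,
) -> None:
    """Write ground-truth labels in the per-site painting layout."""
    with open(path, "w") as fh:
        fh.write("#chrom\tpos\t" + "\t".join(queries.hap_names) + "\n")
        for j, site in enumerate(queries.sites):
            labels = [population_names[truth[i, j]] for i in range(truth.shape[0])]
            fh.write(f"{site.chrom}\t{site.pos}\t" + "\t".join(labels) + "\n")


def read_labels_tsv(path: str | Path) -> tuple[pd.DataFrame, list[str]]:
    """Read a per-site label TSV (painting or truth); returns (frame, hap columns)."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    hap_cols = [c for c in df.columns if c not in ("chrom", "pos")]
    if not hap_cols:
        raise ValueError(f"{path} has no haplotype label columns")
    return df, hap_cols
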