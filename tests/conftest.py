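import numpy as np
import pytest

from recombmix import (
    CompactPopulationGraph,
    HaplotypePanel,
    Site,
    SwitchPenalties,
)


def make_sites(n, chrom="1", start=100, step=100):
    return [
        Site(chrom=chrom, pos=start + j * step, ref="A", alt=("C",), id=f"s{j}")
        for j in range(n)
    ]


def make_panel(alleles, hap_population, population_names=None, **kw):
    alleles = np.asarray(alleles, dtype=np.int8)
    hap_population = np.asarray(hap_population)
    if population_names is None:
        population_names = [
            f"P{i}" for i in range(int(hap_population.max()) + 1)
        ]
    return HaplotypePanel(
        alleles=alleles,
        sites=make_sites(alleles.shape[1]),
        hap_population=hap_population,
        population_names=population_names,
        **kw,
    )


def random_panel(rng, n_sites=None, p=None, m_per_pop=None):
    """Small random bi-allelic panel for property checks."""
    n = n_sites or int(rng.integers(2, 9))
    p = p or int(rng.integers(2, 4))
    m = m_per_pop or int(rng.integers(1, 5))
    alleles = rng.integers(0, 2, size=(p * m, n)).astype(np.int8)
    return make_panel(alleles, np.repeat(np.arange(p), m))


def random_graph(rng, n=None, p=None):
    """Random compact graph where every population has a node at every site."""
    n = n or int(rng.integers(2, 9))
    p = p or int(rng.integers(2, 4))
    presence = rng.random((n, 2, p)) < 0.6
    none = ~presence.any(axis=1)
    a_fill = rng.integers(0, 2, size=presence.shape[::2])
    for j, l in zip(*np.nonzero(none)):
        presence[j, a_fill[j, l], l] = True
    return CompactPopulationGraph(
        presence=presence,
        sites=make_sites(n),
        population_names=[f"P{i}" for i in range(p)],
    )


def uniform_penalties(n, value=2.0):
    return SwitchPenalties(
        values=np.full(n - 1, value),
        raw_rates=np.zeros(n - 1),
        normalization_min=0.0,
        normalization_max=0.0,
    )


def random_penalties(rng, n):
    return SwitchPenalties(
        values=rng.uniform(1.0, 2.0, n - 1),
        raw_rates=rng.uniform(0.0, 3.0, n - 1),
        normalization_min=0.0,
        normalization_max=3.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def two_pop_panel():
    """Pop A all-zero haplotypes, pop B all-one haplotypes, 8 sites."""
    alleles = np.array([[0] * 8] * 3 + [[1] * 8] * 3, dtype=np.int8)
    return make_panel(alleles, [0, 0, 0, 1, 1, 1], ["A", "B"])


def write_vcf_text(path, records, samples, phased=True, chrom="1"):
    """Tiny literal VCF writer for read-path fixtures only (not the package's)."""
    sep = "|" if phased else "/"
    lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom}>",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    for pos, ref, alt, gts in records:
        gt_strs = []
        for g in gts:
            if isinstance(g, str):
                gt_strs.append(g)
            else:
                gt_strs.append(sep.join("." if a is None else str(a) for a in g))
        lines.append(
            f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gt_strs)
        )
    path.write_text("\n".join(lines) + "\n")
    return path
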