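import numpy as np
import pytest

from divscan.genotype_io import MISSING, GenotypeMatrix, VariantSite


def make_gm(calls, positions=None, chrom="chr1", pops=None, quals=None, infos=None):
    """Build a GenotypeMatrix from a dosage array (rows = samples)."""
    calls = np.asarray(calls, dtype=np.int8)
    n_samples, n_sites = calls.shape
    if positions is None:
        positions = list(range(1, n_sites + 1))
    samples = [f"s{i}" for i in range(n_samples)]
    if pops is None:
        pop_of = {s: "P1" for s in samples}
    elif isinstance(pops, dict):
        pop_of = pops
    else:
        pop_of = {s: p for s, p in zip(samples, pops)}
    sites = [
        VariantSite(
            chrom=chrom,
            pos=int(p),
            ref="A",
            alts=("T",),
            qual=100.0 if quals is None else quals[i],
            info=dict(infos[i]) if infos is not None else {},
        )
        for i, p in enumerate(positions)
    ]
    return GenotypeMatrix(samples=samples, pop_of=pop_of, sites=sites, calls=calls)


@pytest.fixture
def toy_two_pop_gm():
    """5 + 5 diploids, 6 sites over positions 1..60."""
    rng = np.random.default_rng(7)
    calls = rng.integers(0, 3, size=(10, 6)).astype(np.int8)
    calls[0, 0] = MISSING
    return make_gm(
        calls,
        positions=[5, 12, 20, 33, 41, 58],
        pops=["A"] * 5 + ["B"] * 5,
    )


@pytest.fixture
def toy_vcf(tmp_path):
    text = """##fileformat=VCFv4.2
##contig=<ID=chr1,length=1000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2
chr1\t10\t.\tA\tT\t50\tPASS\tQD=3.0;MQ=55\tGT\t0/0\t0/1
chr1\t20\t.\tC\tG\t50\tPASS\t.\tGT\t./.\t1|1
"""
    path = tmp_path / "toy.vcf"
    path.write_text(text)
    return str(path)


@pytest.fixture
def toy_pop_table(tmp_path):
    path = tmp_path / "pops.tsv"
    path.write_text("S1\tPOP1\nS2\tPOP2\n")
    return str(path)
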