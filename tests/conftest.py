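import pytest

from musmosaic.genome import ChromKind, Chromosome, GenomeLayout, Interval
from musmosaic.simulate import default_panel
from musmosaic.variants import VariantSite


@pytest.fixture
def tiny_layout() -> GenomeLayout:
    """Two 100-kb autosomes, a 100-kb X, and a mitochondrion; chr1 carries a
    Robertsonian fusion; centromere-proximal = first 10 kb."""
    chroms = [
        Chromosome("chr1", 100_000, ChromKind.AUTOSOME),
        Chromosome("chr2", 100_000, ChromKind.AUTOSOME),
        Chromosome("chrX", 100_000, ChromKind.X),
        Chromosome("chrM", 16_299, ChromKind.MITOCHONDRIAL),
    ]
    return GenomeLayout(chroms, {}, {"chr1"}).with_default_centromeres(10_000)


@pytest.fixture
def panel():
    return default_panel()


def make_site(
    chrom="chr1",
    position=1000,
    ref="A",
    alts=("G",),
    dp=50,
    mq=40.0,
    alt_support=20,
    genotypes=None,
    **extra_gts,
):
    """Site factory: every panel sample defaults to hom-alt focals, hom-ref
    everyone else; override per sample via keyword (e.g. outgroup=(0, 1))."""
    p = default_panel()
    gts = {name: (0, 0) for name in p.all_samples}
    gts["focalA"] = (1, 1)
    gts["focalB"] = (1, 1)
    if genotypes:
        gts.update(genotypes)
    gts.update(extra_gts)
    return VariantSite(
        chrom=chrom,
        position=position,
        ref=ref,
        alts=list(alts),
        site_depth=dp,
        mapping_quality=mq,
        alt_support=alt_support,
        genotypes=gts,
    )


@pytest.fixture
def site_factory():
    return make_site


@pytest.fixture
def one_interval():
    return Interval("chr1", 0, 25_000)
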