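import numpy as np
import pytest

from introscan.model import GenomeCallSet, Role, VariantKind, VariantSite
from introscan import simulate as sim


def snp(pos: int, alt: str = "A", chrom: str = "chr", **kw) -> VariantSite:
    return VariantSite(chrom, pos, VariantKind.SNP, alt, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)


@pytest.fixture(scope="session")
def small_landscape():
    """A 50 kb circular landscape with the default donor panel."""
    root = np.random.default_rng(7)
    landscape = sim.make_marker_landscape(50_000, markers_per_kb=8.0, rng=root)
    donors = sim.default_donors(landscape)
    return landscape, donors


@pytest.fixture
def mixed_callset():
    """A call set exercising every variant kind, including a large deletion."""
    sites = [
        snp(100, "G", gene="acs", syn="nonsynonymous"),
        VariantSite("chr", 500, VariantKind.SMALL_INDEL, "+AG"),
        VariantSite("chr", 900, VariantKind.SMALL_INDEL, "-3"),
        VariantSite("chr", 2000, VariantKind.IS_INSERTION, "IS150"),
        VariantSite("chr", 5000, VariantKind.LARGE_DELETION, "1200", gene="rbsD"),
    ]
    return GenomeCallSet.from_sites("sampleX", Role.RECOMBINANT, sites)
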