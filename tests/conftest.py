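import numpy as np
import pytest
from hypothesis import settings

from dnmt3b_targets.genome_model import Gene, GeneModel, GenomicInterval

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_locus_model():
    """Three hand-built genes exercising every feature category.

    G1 (+): body [10000,20000), 3 exons, UTRs at both ends; promoter
    [5000,10000) with the default 5 kb window, downstream [20000,21000).
    G2 (+): body [4000,9000) with a single exon, so G1's promoter overlaps
    G2's intron. G3 (-): body [30000,40000), promoter genomically right of
    the body, downstream genomically left.
    """
    g1 = Gene(
        "G1",
        "ALPHA",
        GenomicInterval("chr1", 10_000, 20_000, "+"),
        exons=(
            GenomicInterval("chr1", 10_000, 11_000, "+"),
            GenomicInterval("chr1", 15_000, 16_000, "+"),
            GenomicInterval("chr1", 19_000, 20_000, "+"),
        ),
        utr5=(GenomicInterval("chr1", 10_000, 10_200, "+"),),
        utr3=(GenomicInterval("chr1", 19_800, 20_000, "+"),),
    )
    g2 = Gene(
        "G2",
        "BETA",
        GenomicInterval("chr1", 4_000, 9_000, "+"),
        exons=(GenomicInterval("chr1", 4_000, 4_500, "+"),),
    )
    g3 = Gene(
        "G3",
        "GAMMA",
        GenomicInterval("chr1", 30_000, 40_000, "-"),
        exons=(
            GenomicInterval("chr1", 30_000, 31_000, "-"),
            GenomicInterval("chr1", 39_000, 40_000, "-"),
        ),
    )
    return GeneModel([g1, g2, g3])
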