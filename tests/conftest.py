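import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def simple_models():
    """Two hand-built genes: one with a 5'UTR intron, one with two CDS introns."""
    from isoretain.counting import CDS, FIVE_PRIME_UTR, GeneModel

    g1 = GeneModel(
        gene_id="g1",
        chrom="chrI",
        strand="+",
        cds=(300, 800),
        introns=((100, 200, FIVE_PRIME_UTR),),
    )
    g2 = GeneModel(
        gene_id="g2",
        chrom="chrI",
        strand="-",
        cds=(1000, 1700),
        introns=((1100, 1150, CDS), (1300, 1450, CDS)),
        labels=frozenset({"RP"}),
    )
    return [g1, g2]
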