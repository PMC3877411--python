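import numpy as np
import pytest
from hypothesis import settings

from hwmi import GenotypeCounts, GenotypeVector, Panel

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def gt_counts() -> GenotypeCounts:
    """The worked-example G/T SNP: 146 individuals, 48 no-calls."""
    return GenotypeCounts(46, 32, 20, 48)


@pytest.fixture
def gt_vector() -> GenotypeVector:
    calls = np.array([0] * 46 + [1] * 32 + [2] * 20 + [-1] * 48, dtype=np.int8)
    return GenotypeVector("gt_snp", ("G", "T"), calls)


@pytest.fixture
def small_panel() -> Panel:
    """3 individuals x 2 markers, with one missing call."""
    return Panel(
        individuals=["s1", "s2", "s3"],
        markers=[
            GenotypeVector("m1", ("A", "G"), [0, 1, 2], chrom="1", pos=100),
            GenotypeVector("m2", ("C", "T"), [-1, 1, 0], chrom="1", pos=200),
        ],
    )
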