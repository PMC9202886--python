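import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from deltacc import BinnedDeltaTrack, GenomicInterval, Viewpoint
from deltacc.normalization import DeltaTrack

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def iv(start: int, end: int, chrom: str = "chr1") -> GenomicInterval:
    return GenomicInterval(chrom, start, end)


@pytest.fixture
def viewpoint_at_origin() -> Viewpoint:
    """Viewpoint whose midpoint (0) sits on the first bin boundary."""
    return Viewpoint(name="vp", interval=GenomicInterval("chr1", 0, 1))


def make_binned(values, bin_size=1000, origin=0, chrom="chr1", vp_index=None):
    return BinnedDeltaTrack(
        chrom=chrom,
        origin=origin,
        bin_size=bin_size,
        values=np.asarray(values, dtype=float),
        viewpoint_bin_index=vp_index,
    )


def make_delta(fragments, values, pair=("a", "b")):
    return DeltaTrack(fragments=list(fragments), delta=np.asarray(values, float),
                      condition_pair=pair)
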