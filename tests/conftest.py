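import pytest

from tfhot.intervals import GenomicInterval, PeakRecord, PeakSet
from tfhot.synthetic import LandscapeConfig, TierSpec


def make_peak(chrom, start, end, summit=None):
    return PeakRecord(GenomicInterval(chrom, start, end), summit)


def make_set(factor, cell_type, spans, chrom="chr1"):
    return PeakSet(
        factor, cell_type, [make_peak(chrom, s, e) for s, e in spans]
    )


@pytest.fixture
def small_config():
    """One cell type, 8 factors, 50/30/20 planted tiers, zero jitter."""
    return LandscapeConfig(
        seed=11,
        chrom_length=2_000_000,
        cell_types={"ES": 8},
        tiers=[
            TierSpec("singleton", 50, (1, 1), mean_height=10.0),
            TierSpec("combinatorial", 30, (2, 5), mean_height=30.0),
            TierSpec("hotspot", 20, (6, 8), mean_height=80.0,
                     profile="bimodal", signal_amplitude=4.0),
        ],
    )
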