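import numpy as np
import pytest

from cenloop.core import BinnedTrack, GenomeAnnotation, GenomicInterval


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Two chromosomes (300 kb, 500 kb) with centromeres at 150 kb / 100 kb."""
    return GenomeAnnotation(
        chromosomes={"chrI": 300_000, "chrII": 500_000},
        centromeres={"chrI": 150_000, "chrII": 100_000},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_track(values_by_chrom: dict, bin_size: int = 100,
               mask=None, semantics: str = "nFE") -> BinnedTrack:
    values = {c: np.asarray(v, dtype=float) for c, v in values_by_chrom.items()}
    m = None
    if mask is not None:
        m = {c: np.asarray(v, dtype=bool) for c, v in mask.items()}
    return BinnedTrack(bin_size=bin_size, values=values, mask=m, semantics=semantics)


def interval(chrom: str, start: int, end: int, strand: str = ".", name=None):
    return GenomicInterval(chrom, start, end, strand=strand, name=name)
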