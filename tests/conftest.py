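import numpy as np
import pytest

from tadfuse.fourc import FourCProfile, Viewpoint
from tadfuse.fragmap import digest_genome, valid_fragments


def make_profile(raw, ends=None, frag_len=100, viewpoint_pos=0,
                 mask=None) -> FourCProfile:
    """Hand-built profile: one end per `frag_len` fragment, raw as given."""
    raw = np.asarray(raw, dtype=float)
    n = raw.size
    if ends is None:
        ends = np.arange(n) * frag_len
    ends = np.asarray(ends, dtype=np.int64)
    bounds = np.stack([ends, ends + frag_len], axis=1)
    prof = FourCProfile(
        viewpoint=Viewpoint("vp", "chrT", viewpoint_pos),
        ends=ends,
        frag_index=np.arange(n),
        frag_bounds=bounds,
        raw=raw,
        mask=np.zeros(n, dtype=bool) if mask is None else np.asarray(mask),
    )
    return prof


@pytest.fixture
def toy_genome():
    # GATC cuts at 0(start),3,19; GTAC inside the middle fragment at 11
    return {"chrT": "AAAGATCCCCCGTACCCCCGATCAAA"}


@pytest.fixture
def toy_fragmap(toy_genome):
    return digest_genome(toy_genome, "GATC", "GTAC", min_len=4)


@pytest.fixture
def simple_valid_map():
    """Two chromosomes with clean valid fragments of length 50."""
    frag = "GATC" + "A" * 20 + "GTAC" + "C" * 22  # length 50, non-blind
    genome = {"chr1": frag * 8, "chr2": frag * 6}
    return valid_fragments(digest_genome(genome, "GATC", "GTAC", min_len=40))
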