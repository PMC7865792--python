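import numpy as np
import pytest

from chromoblock.annotation import BeadAnnotation


@pytest.fixture
def simple_beads():
    """A 10-bead single chain, F half then P half, boundaries at 0, 4, 9."""
    classes = list("FFFFFPPPPP")
    boundary = {0, 4, 9}
    return [
        BeadAnnotation(chain_id=0, bin_index=i, domain_class=c,
                       is_lad=(c == "P" and i >= 7),
                       is_tad_boundary=i in boundary,
                       source_bp_start=i * 100_000)
        for i, c in enumerate(classes)
    ]


def make_chain(classes, boundaries=(), lads=(), chain_id=0, start_bin=0):
    return [
        BeadAnnotation(chain_id=chain_id, bin_index=start_bin + i,
                       domain_class=c, is_lad=i in lads,
                       is_tad_boundary=i in boundaries,
                       source_bp_start=(start_bin + i) * 100_000)
        for i, c in enumerate(classes)
    ]
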