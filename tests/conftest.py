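from __future__ import annotations

import numpy as np
import pytest

from anchorkit._seq import random_seq


def diverge(seq: str, p: float, rng: np.random.Generator) -> str:
    """Substitute each base with probability p (never to itself)."""
    out = list(seq)
    for i in np.nonzero(rng.random(len(seq)) < p)[0]:
        out[i] = "ACGT"[("ACGT".index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)


def identity_at(contig, template: str) -> float:
    """Identity of an assembled contig against its template at its offset."""
    seg = template[contig.ref_start : contig.ref_start + len(contig.sequence)]
    if not seg:
        return 0.0
    return sum(a == b for a, b in zip(contig.sequence, seg)) / len(seg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def random_template(rng):
    return random_seq(1000, rng)
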