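"""Small shared sequence helpers."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_seq(length: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def kmer_set(seq: str, k: int) -> set[str]:
    """Distinct k-mers over ACGT only; windows containing other symbols are skipped."""
    seq = seq.upper()
    out = set()
    for i in range(len(seq) - k + 1):
        w = seq[i : i + k]
        if all(c in "ACGT" for c in w):
            out.add(w)
    return out
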