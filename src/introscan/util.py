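"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

DNA_ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) start positions of ``needle`` in ``haystack``."""
    if not needle:
        raise ValueError("empty search pattern")
    hits = []
    i = haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA sequence of the given length."""
    if length <= 0:
        raise ValueError("length must be positive")
    idx = rng.integers(0, 4, size=length)
    return "".join(DNA_ALPHABET[i] for i in idx)
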