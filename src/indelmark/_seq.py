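"""Small shared sequence helpers."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random ACGT string."""
    return _BASES[rng.integers(0, 4, length, dtype=np.uint8)].tobytes().decode()


def random_base_not(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(0, 3))]


def count_occurrences(haystack: str, needle: str) -> int:
    """Count (possibly overlapping) exact occurrences of needle."""
    n = 0
    i = haystack.find(needle)
    while i != -1:
        n += 1
        i = haystack.find(needle, i + 1)
    return n


def find_occurrences(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) start positions of needle."""
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out
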