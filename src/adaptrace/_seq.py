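"""Low-level DNA string helpers shared across modules.

All coordinates in the package are 0-based half-open; strand "+" means the
replicon sequence as written.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

DNA_ALPHABET = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


def is_dna(seq: str) -> bool:
    return set(seq) <= DNA_ALPHABET


def hamming(a: str, b: str, limit: int | None = None) -> int:
    """Hamming distance between equal-length strings.

    With ``limit`` set, returns early with ``limit + 1`` as soon as the
    distance exceeds it — the common case in mismatch-budgeted scans.
    """
    if len(a) != len(b):
        raise ValueError("hamming: length mismatch")
    if a == b:
        return 0
    d = 0
    if limit is None:
        for x, y in zip(a, b):
            if x != y:
                d += 1
        return d
    for x, y in zip(a, b):
        if x != y:
            d += 1
            if d > limit:
                return d
    return d


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    """Random DNA with the given expected GC fraction."""
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)
    return bases.tobytes().decode("ascii")


def gc_fraction(seq: str) -> float:
    if not seq:
        return float("nan")
    return (seq.count("G") + seq.count("C")) / len(seq)


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Apply i.i.d. substitution errors at the given per-base rate."""
    if rate <= 0.0 or not seq:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size == 0:
        return seq
    acgt = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hit:
        # draw a base different from the current one
        choices = acgt[acgt != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")
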