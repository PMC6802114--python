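"""Small DNA-string utilities shared across the pipeline."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings.

    N is not given special treatment: any character inequality counts,
    so N-vs-A is a mismatch and N-vs-N is a match only literally.
    """
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def is_dna(seq: str, allow_n: bool = True) -> bool:
    allowed = set("ACGTN" if allow_n else "ACGT")
    return bool(seq) and set(seq) <= allowed


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA of the given length."""
    return "".join(np.array(list(DNA_ALPHABET))[rng.integers(0, 4, size=length)])


def encode(seq: str) -> np.ndarray:
    """Encode DNA into a uint8 array (byte values) for vectorised comparisons."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def encode_matrix(seqs: list[str]) -> np.ndarray:
    """Stack equal-length sequences into an (n, L) uint8 matrix."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must have equal length")
    return np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
        len(seqs), length
    )


def mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    """Apply uniform per-base substitution errors; never substitutes to self."""
    if error_rate <= 0.0:
        return seq
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < error_rate
    if not hit.any():
        return seq
    for i in np.flatnonzero(hit):
        choices = [b for b in DNA_ALPHABET if b != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return "".join(arr)
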