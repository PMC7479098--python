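"""Low-level sequence utilities shared across the pipeline.

Sequences are plain ``str`` over {A,C,G,T} at the API surface; heavy numeric
kernels encode them as uint8 ASCII arrays so that mismatch counting is a
vectorized numpy comparison.
"""

from __future__ import annotations

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_VALID = frozenset(b"ACGT")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 ASCII array."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()


def decode(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def encode_block(seqs: list[str]) -> np.ndarray:
    """Stack equal-length sequences into an (n, L) uint8 matrix."""
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ValueError("encode_block requires equal-length sequences")
    return np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(len(seqs), L).copy()


def is_acgt(seq: str) -> bool:
    return bool(seq) and set(seq.encode("ascii")) <= _VALID


def hamming_identity(a: np.ndarray, b: np.ndarray) -> float:
    """Gapless identity of two equal-length encoded sequences."""
    if a.shape != b.shape:
        raise ValueError("hamming_identity requires equal lengths")
    return float(np.mean(a == b))


def mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site independently with probability ``rate``.

    A substituted site receives one of the three other bases uniformly.
    Returns a new array; the input is untouched.
    """
    out = arr.copy()
    n = arr.size
    k = rng.binomial(n, rate)
    if k == 0:
        return out
    pos = rng.choice(n, size=k, replace=False)
    # shift by 1..3 within the base alphabet => always a different base
    idx = np.searchsorted(BASES, out[pos])
    out[pos] = BASES[(idx + rng.integers(1, 4, size=k)) % 4]
    return out


def random_seq(length: int, rng: np.random.Generator) -> np.ndarray:
    return BASES[rng.integers(0, 4, size=length)]
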