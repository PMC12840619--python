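"""Internal helpers: byte-level DNA encoding shared by the simulator and the
k-mer seeding machinery.  Codes: A=0, C=1, G=2, T=3, N=4.  N never matches
anything downstream (k-mers containing N are excluded from indexing)."""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[b + 32] = i  # lowercase

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

A, C, G, T, N = 0, 1, 2, 3, 4


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 code array (unknown characters -> N)."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def jc_substitution_probability(mu_t: float) -> float:
    """Expected fraction of sites substituted after time t at rate mu under
    Jukes-Cantor: p = 3/4 * (1 - exp(-4*mu*t/3))."""
    return 0.75 * (1.0 - np.exp(-4.0 * mu_t / 3.0))


def mutate(arr: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Return a copy of ``arr`` with each site substituted with probability
    ``p`` to one of the three other bases (uniform). N sites are left alone."""
    out = arr.copy()
    if p <= 0 or len(arr) == 0:
        return out
    hit = (rng.random(len(arr)) < p) & (out < 4)
    n_hit = int(hit.sum())
    if n_hit:
        out[hit] = (out[hit] + rng.integers(1, 4, n_hit, dtype=np.uint8)) % 4
    return out


def p_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Proportion of differing sites over positions where both are A/C/G/T."""
    n = min(len(a), len(b))
    a, b = a[:n], b[:n]
    ok = (a < 4) & (b < 4)
    if not ok.any():
        return 0.0
    return float((a[ok] != b[ok]).mean())


def kmer_codes(arr: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All k-mers of a code array as uint64 keys.

    Returns (keys, valid) where ``valid`` marks k-mers free of N.  Key of the
    k-mer at offset i packs bases big-endian, 2 bits each.
    """
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64), np.empty(0, dtype=bool)
    a = arr.astype(np.uint64)
    keys = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        window = a[j : j + n]
        keys = (keys << np.uint64(2)) | (window & np.uint64(3))
        valid &= window < 4
    return keys, valid
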