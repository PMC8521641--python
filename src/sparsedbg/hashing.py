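"""Orientation-canonical k-mer hashing.

Two hash functions with distinct jobs:

* a 64-bit strand-symmetric *rolling* hash (ntHash-style cyclic polynomial)
  that orders k-mers inside winnowing windows — O(1) per position after O(k)
  setup, here computed for all positions at once with prefix-xor tricks;
* a 128-bit *identity* hash (BLAKE2b, fixed parameters, no per-process salt)
  of the canonical orientation of a k-mer, which names graph nodes.  With
  128 bits, two distinct k-mers collide with probability ~2^-128; collisions
  are treated as impossible and neither detected nor resolved, which is what
  lets arbitrarily long k-mers be stored in constant space.

Canonical orientation is the lexicographically smaller of a k-mer and its
reverse complement, so node identity never depends on the strand a k-mer was
observed on.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from .dna import encode, reverse_complement

# Fixed per-base seeds (the ntHash constants); fixed so that graphs are
# reproducible across runs and platforms.
_SEED_TAB = np.array(
    [
        0x3C8BFBB395C60474,  # A
        0x3193C18562A02B4C,  # C
        0x20323ED082572324,  # G
        0x295549F54BE24456,  # T
    ],
    dtype=np.uint64,
)

_U64 = np.uint64
_SIXTYFOUR = _U64(64)


@dataclass(frozen=True)
class KmerIdentity:
    """128-bit canonical identity of a k-mer occurrence.

    ``canonical_is_forward`` records whether the k-mer as observed matched the
    canonical orientation (True) or its reverse complement did (False).
    """

    hash128: int
    canonical_is_forward: bool


def _rol(x: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Bitwise rotate-left of uint64 values; ``r`` taken mod 64 (r=0 safe)."""
    r = np.asarray(r, dtype=np.uint64) % _SIXTYFOUR
    return (x << r) | (x >> ((_SIXTYFOUR - r) % _SIXTYFOUR))


def _finalize(x: np.ndarray) -> np.ndarray:
    """splitmix64 finalizer (bijective xorshift-multiply scramble).

    The raw cyclic-polynomial values of overlapping windows are linearly
    related (rotations and shared XOR terms), which measurably biases
    minimizer selection below the 2/(w+1) expectation; scrambling each value
    through a nonlinear mix restores effectively independent orderings while
    keeping the whole computation rolling and strand-symmetric.
    """
    x = x.copy()
    x ^= x >> np.uint64(30)
    x *= np.uint64(0xBF58476D1CE4E5B9)
    x ^= x >> np.uint64(27)
    x *= np.uint64(0x94D049BB133111EB)
    x ^= x >> np.uint64(31)
    return x


def canonical_form(kmer: str) -> tuple[str, bool]:
    """Return the lexicographically smaller of ``kmer`` and its reverse
    complement, plus a flag: True if ``kmer`` itself won (palindromes count
    as forward)."""
    rc = reverse_complement(kmer)
    if kmer <= rc:
        return kmer, True
    return rc, False


def rolling_hashes(seq: str, k: int) -> np.ndarray:
    """Strand-symmetric 64-bit window hashes for every k-mer start of ``seq``.

    Returns an array of length ``len(seq) - k + 1`` (empty if the sequence is
    shorter than k).  The value at position i depends only on ``seq[i:i+k]``
    and equals the value of the reverse-complement k-mer, so scanning the
    reverse complement of ``seq`` yields the mirrored value sequence.
    """
    n = len(seq)
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        return np.empty(0, dtype=np.uint64)
    codes = encode(seq)
    pos = np.arange(n, dtype=np.int64)
    fw_seed = _SEED_TAB[codes]
    rc_seed = _SEED_TAB[3 - codes]  # seed of the complement base

    # forward hash of window i: XOR_j rol(seed[s[i+j]], k-1-j)
    contrib = _rol(fw_seed, (-pos) % 64)
    pref = np.zeros(n + 1, dtype=np.uint64)
    pref[1:] = np.bitwise_xor.accumulate(contrib)
    window = pref[k:] ^ pref[: n - k + 1]
    m = window.size
    fwd = _rol(window, (k - 1 + np.arange(m, dtype=np.int64)) % 64)

    # reverse-complement hash of window i: XOR_m rol(seed[comp(s[i+m])], m)
    contrib_rc = _rol(rc_seed, pos % 64)
    pref[1:] = np.bitwise_xor.accumulate(contrib_rc)
    window_rc = pref[k:] ^ pref[: n - k + 1]
    rcv = _rol(window_rc, (-np.arange(m, dtype=np.int64)) % 64)

    return _finalize(np.minimum(fwd, rcv))


def identity_hash(kmer: str) -> KmerIdentity:
    """128-bit canonical identity hash of a k-mer.

    Equal for a k-mer and its reverse complement; stable across processes
    and platforms (keyless BLAKE2b with a 16-byte digest).
    """
    canon, forward = canonical_form(kmer)
    digest = hashlib.blake2b(canon.encode("ascii"), digest_size=16).digest()
    return KmerIdentity(
        hash128=int.from_bytes(digest, "little"),
        canonical_is_forward=forward,
    )


def hash128_of_canonical(canonical_kmer: str) -> int:
    """Identity hash of a k-mer already known to be in canonical orientation."""
    digest = hashlib.blake2b(canonical_kmer.encode("ascii"), digest_size=16)
    return int.from_bytes(digest.digest(), "little")
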