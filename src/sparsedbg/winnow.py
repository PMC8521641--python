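"""Minimizer winnowing: select a sparse, window-guaranteed subset of k-mers.

A position is selected iff its 64-bit window hash is the minimum within at
least one window of w consecutive k-mer start positions (ties broken by the
leftmost position).  Every window therefore contains at least one selected
position, and consecutive selections are at most w apart, so with w <= k-1
consecutive selected k-mers always overlap by at least k-w >= 1 characters.
w=1 selects every k-mer (the dense de Bruijn graph case); larger w gives
sparser graphs.  On random sequence the expected selected fraction is
2/(w+1).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .hashing import KmerIdentity, identity_hash, rolling_hashes
from .hpc import HpcSequence


@dataclass
class MinimizerChain:
    """Selected minimizer positions of one read, in sequence order."""

    positions: list[int]
    identities: list[KmerIdentity]
    origin: str = ""

    def __len__(self) -> int:
        return len(self.positions)


def validate_params(k: int, w: int) -> None:
    """Enforce k >= 2 and 1 <= w <= k-1 (edge-overlap guarantee)."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if not 1 <= w <= k - 1:
        raise ValueError(f"w must satisfy 1 <= w <= k-1, got w={w} for k={k}")


def select_positions(hashes: np.ndarray, w: int) -> list[int]:
    """Winnow an array of per-position hash values with window size ``w``.

    Returns the sorted, deduplicated selected positions.  If fewer than ``w``
    positions exist the whole range counts as a single window.  Implemented
    with a monotone deque (O(n)); leftmost tie-break falls out of keeping the
    earliest index among equal values at the deque front.
    """
    n = len(hashes)
    if n == 0:
        return []
    if w < 1:
        raise ValueError("w must be >= 1")
    if w == 1:
        return list(range(n))
    if n <= w:
        return [int(np.argmin(hashes))]
    selected: list[int] = []
    dq: deque[int] = deque()
    for i in range(n):
        hi = hashes[i]
        while dq and hashes[dq[-1]] > hi:
            dq.pop()
        dq.append(i)
        if dq[0] <= i - w:
            dq.popleft()
        if i >= w - 1 and (not selected or selected[-1] != dq[0]):
            selected.append(dq[0])
    return selected


def select_minimizers(hpc: HpcSequence, k: int, w: int) -> MinimizerChain:
    """Minimizer chain of a homopolymer-compressed read.

    Reads shorter than k (in HPC space) contribute an empty chain.
    """
    validate_params(k, w)
    hashes = rolling_hashes(hpc.chars, k)
    if hashes.size == 0:
        return MinimizerChain(positions=[], identities=[], origin=hpc.origin)
    positions = select_positions(hashes, w)
    identities = [identity_hash(hpc.chars[p : p + k]) for p in positions]
    return MinimizerChain(positions=positions, identities=identities, origin=hpc.origin)


def expected_density(w: int) -> float:
    """Expected fraction of positions selected on random sequence: 2/(w+1)."""
    if w < 1:
        raise ValueError("w must be >= 1")
    return 2.0 / (w + 1)
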