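"""Shared fixtures and independent oracles for the test suite.

The oracle functions here deliberately re-derive results with naive
algorithms (per-window recomputation, quadratic scans, exhaustive k-mer
enumeration) so that the fast implementations are checked against code that
shares none of their machinery.
"""

from __future__ import annotations

import numpy as np
import pytest

from sparsedbg.dna import BASES, reverse_complement
from sparsedbg.graph import SparseGraph, edge_key
from sparsedbg.hashing import canonical_form, hash128_of_canonical
from sparsedbg.hpc import compress

# fixed ntHash per-base seeds, restated independently of the implementation
ORACLE_SEEDS = {
    "A": 0x3C8BFBB395C60474,
    "C": 0x3193C18562A02B4C,
    "G": 0x20323ED082572324,
    "T": 0x295549F54BE24456,
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
_MASK = (1 << 64) - 1


def rol64(x: int, r: int) -> int:
    r %= 64
    return ((x << r) | (x >> (64 - r))) & _MASK


def window_hash_oracle(kmer: str) -> int:
    """Direct (non-rolling) strand-symmetric hash of one k-mer, including the
    splitmix64 finalizer (restated here with plain Python ints)."""
    k = len(kmer)
    fwd = 0
    rcv = 0
    for j, base in enumerate(kmer):
        fwd ^= rol64(ORACLE_SEEDS[base], k - 1 - j)
        rcv ^= rol64(ORACLE_SEEDS[_COMP[base]], j)
    x = min(fwd, rcv)
    x = (x ^ (x >> 30)) * 0xBF58476D1CE4E5B9 & _MASK
    x = (x ^ (x >> 27)) * 0x94D049BB133111EB & _MASK
    return x ^ (x >> 31)


def winnow_oracle(hashes, w: int) -> list[int]:
    """Quadratic winnowing: take the leftmost arg-min of every window."""
    n = len(hashes)
    if n == 0:
        return []
    if n <= w:
        return [int(np.argmin(hashes))]
    selected = set()
    for j in range(n - w + 1):
        window = hashes[j : j + w]
        selected.add(j + int(np.argmin(window)))
    return sorted(selected)


def dense_graph_oracle(read_seqs: list[str], k: int):
    """Brute-force dense (w=1) graph content from raw reads.

    Returns (set of canonical HPC k-mer strings, multiset of canonical
    (from, to, overlap=k-1) adjacency keys built from string identities).
    """
    nodes: set[str] = set()
    edges: dict = {}
    for seq in read_seqs:
        chars = compress(seq).chars
        if len(chars) < k:
            continue
        prev = None
        for p in range(len(chars) - k + 1):
            kmer = chars[p : p + k]
            canon, fwd = canonical_form(kmer)
            nodes.add(canon)
            cur = (hash128_of_canonical(canon), fwd)
            if prev is not None:
                key = edge_key(prev, cur, k - 1)
                edges[key] = edges.get(key, 0) + 1
            prev = cur
    return nodes, edges


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def random_hpc_text(rng: np.random.Generator, length: int) -> str:
    """Random sequence with no two adjacent equal characters (HPC space)."""
    out = [BASES[int(rng.integers(0, 4))]]
    for _ in range(length - 1):
        choices = [b for b in BASES if b != out[-1]]
        out.append(choices[int(rng.integers(0, 3))])
    return "".join(out)


def build_toy_graph(kmer_walks: list[list[str]], k: int, w: int) -> SparseGraph:
    """Construct a graph directly from explicit k-mer walks.

    Each walk is a list of k-mer strings with overlap k-1 between
    consecutive entries (their junctions must spell consistently).  Run
    observations are all ones.  Used to hand-build branching topologies.
    """
    g = SparseGraph(k=k, w=w)
    for walk in kmer_walks:
        prev = None
        for kmer in walk:
            assert len(kmer) == k
            canon, fwd = canonical_form(kmer)
            h = hash128_of_canonical(canon)
            node = g.nodes.get(h)
            if node is None:
                from sparsedbg.graph import KmerNode

                node = KmerNode(id=h, k=k, hpc_chars=canon)
                g.nodes[h] = node
            node.coverage += 1
            node.run_obs.append(np.ones(k, dtype=np.uint8))
            cur = (h, fwd)
            if prev is not None:
                g.add_edge(prev, cur, k - 1)
            prev = cur
    return g


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
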