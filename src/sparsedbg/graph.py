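"""The bidirected sparse de Bruijn graph over minimizer k-mers.

Nodes are canonical k-mers named by their 128-bit identity hash; each node
also stores its HPC text (recorded at first observation, so sequence can be
restored at output time without a second pass over the reads) and the
run-length observations at each of its k offsets.  Edges connect *oriented*
nodes: an edge is added whenever two selected minimizers are adjacent in a
read, with HPC-space overlap k - (distance between their start positions).
An edge and its mirror (reverse the orientation of both endpoints and swap
them) are the same bidirected object, stored once under a canonical key.
Two distinct overlaps between the same oriented pair are distinct edges,
since the overlap is part of the graph's spelling semantics.

Sequencing errors that make a read miss one minimizer create an edge that
bypasses a two-node path; :meth:`SparseGraph.clean_transitive_edges` removes
such edges when a higher-coverage detour exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .dna import reverse_complement
from .hpc import RUN_CAP, HpcSequence
from .winnow import MinimizerChain

#: An oriented node: (128-bit node hash, True for canonical/forward).
OrientedNode = tuple[int, bool]

#: Canonical storage key of a bidirected edge: (from, to, HPC overlap).
EdgeKey = tuple[OrientedNode, OrientedNode, int]


def flip(node: OrientedNode) -> OrientedNode:
    """The same node in the opposite orientation."""
    return (node[0], not node[1])


def edge_key(u: OrientedNode, v: OrientedNode, overlap: int) -> EdgeKey:
    """Canonical key under which an edge and its mirror coincide."""
    forward: EdgeKey = (u, v, overlap)
    mirror: EdgeKey = (flip(v), flip(u), overlap)
    return forward if forward <= mirror else mirror


@dataclass
class KmerNode:
    """A canonical k-mer node with coverage and run-length observations."""

    id: int
    k: int
    hpc_chars: str  # canonical orientation, length k
    coverage: int = 0
    # one uint8 array of length k per observation, canonical orientation
    run_obs: list[np.ndarray] = field(default_factory=list)

    def oriented_chars(self, forward: bool) -> str:
        return self.hpc_chars if forward else reverse_complement(self.hpc_chars)

    def run_count_matrix(self) -> np.ndarray:
        """(k, max_run+1) matrix of run-length observation counts per offset."""
        stacked = np.stack(self.run_obs)
        maxr = int(stacked.max())
        counts = np.zeros((self.k, maxr + 1), dtype=np.int64)
        np.add.at(
            counts,
            (np.broadcast_to(np.arange(self.k), stacked.shape), stacked),
            1,
        )
        return counts


class SparseGraph:
    """Node/edge store for the minimizer graph, with read-threading state."""

    def __init__(self, k: int, w: int):
        self.k = k
        self.w = w
        self.nodes: dict[int, KmerNode] = {}
        self.edges: dict[EdgeKey, int] = {}  # canonical key -> coverage
        self._out: dict[OrientedNode, list[tuple[OrientedNode, int]]] | None = None

    # -- construction ------------------------------------------------------

    def thread_chain(self, chain: MinimizerChain, hpc: HpcSequence) -> None:
        """Insert one read's minimizer chain: nodes, tallies and edges."""
        if not chain.positions:
            return
        k = self.k
        runs = np.minimum(hpc.run_lengths, RUN_CAP).astype(np.uint8)
        prev: OrientedNode | None = None
        prev_pos = 0
        for pos, ident in zip(chain.positions, chain.identities):
            node = self.nodes.get(ident.hash128)
            if node is None:
                kmer = hpc.chars[pos : pos + k]
                canon = kmer if ident.canonical_is_forward else reverse_complement(kmer)
                node = KmerNode(id=ident.hash128, k=k, hpc_chars=canon)
                self.nodes[ident.hash128] = node
            obs = runs[pos : pos + k]
            if not ident.canonical_is_forward:
                obs = obs[::-1]
            node.run_obs.append(obs.copy())
            node.coverage += 1
            oriented: OrientedNode = (ident.hash128, ident.canonical_is_forward)
            if prev is not None:
                gap = pos - prev_pos
                overlap = k - gap
                if overlap < 1:
                    raise AssertionError(
                        "non-overlapping adjacent minimizers (w > k-1?)"
                    )
                self.add_edge(prev, oriented, overlap)
            prev = oriented
            prev_pos = pos

    def add_edge(self, u: OrientedNode, v: OrientedNode, overlap: int, count: int = 1) -> None:
        key = edge_key(u, v, overlap)
        self.edges[key] = self.edges.get(key, 0) + count
        self._out = None

    # -- adjacency ---------------------------------------------------------

    @property
    def out(self) -> dict[OrientedNode, list[tuple[OrientedNode, int]]]:
        """Outgoing adjacency: oriented node -> [(successor, overlap), ...]."""
        if self._out is None:
            out: dict[OrientedNode, list[tuple[OrientedNode, int]]] = {}
            for (u, v, o) in self.edges:
                out.setdefault(u, []).append((v, o))
                mu, mv = flip(v), flip(u)
                if (mu, mv, o) != (u, v, o):  # self-mirror edge lists once
                    out.setdefault(mu, []).append((mv, o))
            self._out = out
        return self._out

    def out_edges(self, u: OrientedNode) -> list[tuple[OrientedNode, int]]:
        return self.out.get(u, [])

    def edge_coverage(self, u: OrientedNode, v: OrientedNode, overlap: int) -> int:
        return self.edges.get(edge_key(u, v, overlap), 0)

    # -- cleaning ----------------------------------------------------------

    def clean_transitive_edges(self, t: float = 0.25) -> int:
        """Remove error-induced edges bypassed by a higher-coverage 2-path.

        An edge e = (u -> v) is removed iff some oriented 2-path u -> m -> v
        (not reusing e itself) has both edges at coverage >= coverage(e), and
        coverage(e) <= max(1, floor(t * min of the two detour coverages)) for
        the detour maximizing that minimum.  All removals are decided against
        the pre-cleaning graph in one simultaneous pass (no cascade).
        Returns the number of edges removed.
        """
        doomed: list[EdgeKey] = []
        for key, cov_e in self.edges.items():
            u, v, _ = key
            best = 0
            for (m, o1) in self.out_edges(u):
                c1 = self.edge_coverage(u, m, o1)
                if c1 < cov_e or edge_key(u, m, o1) == key:
                    continue
                for (v2, o2) in self.out_edges(m):
                    if v2 != v or edge_key(m, v2, o2) == key:
                        continue
                    c2 = self.edge_coverage(m, v2, o2)
                    if c2 >= cov_e:
                        best = max(best, min(c1, c2))
            if best and cov_e <= max(1, int(t * best)):
                doomed.append(key)
        for key in doomed:
            del self.edges[key]
        if doomed:
            self._out = None
        return len(doomed)

    def drop_low_coverage(self, min_node_cov: int = 1, min_edge_cov: int = 1) -> None:
        """Optional abundance pre-filter; the defaults of 1 keep everything."""
        if min_node_cov < 1 or min_edge_cov < 1:
            raise ValueError("coverage thresholds must be >= 1")
        if min_node_cov > 1:
            gone = {nid for nid, n in self.nodes.items() if n.coverage < min_node_cov}
            for nid in gone:
                del self.nodes[nid]
            if gone:
                self.edges = {
                    key: cov
                    for key, cov in self.edges.items()
                    if key[0][0] not in gone and key[1][0] not in gone
                }
                self._out = None
        if min_edge_cov > 1:
            before = len(self.edges)
            self.edges = {k: c for k, c in self.edges.items() if c >= min_edge_cov}
            if len(self.edges) != before:
                self._out = None

    # -- integrity ---------------------------------------------------------

    def iter_oriented_edges(self) -> Iterator[tuple[OrientedNode, OrientedNode, int, int]]:
        """Each stored edge once, in its canonical direction, with coverage."""
        for (u, v, o), cov in self.edges.items():
            yield u, v, o, cov

    def validate(self) -> None:
        """Check structural invariants (tests and debugging; not on hot path).

        Every edge endpoint must exist; every overlap must lie in
        [max(1, k-w), k-1]; and the spelled junction must match: the last
        ``overlap`` characters of the from-node equal the first ``overlap``
        characters of the to-node, in their respective orientations.
        """
        lo = max(1, self.k - self.w)
        for (u, v, o), cov in self.edges.items():
            if u[0] not in self.nodes or v[0] not in self.nodes:
                raise AssertionError("edge endpoint missing from node store")
            if not lo <= o <= self.k - 1:
                raise AssertionError(f"overlap {o} outside [{lo}, {self.k - 1}]")
            if cov < 1:
                raise AssertionError("edge with coverage < 1")
            su = self.nodes[u[0]].oriented_chars(u[1])
            sv = self.nodes[v[0]].oriented_chars(v[1])
            if su[-o:] != sv[:o]:
                raise AssertionError("junction spelling mismatch across edge")
        for node in self.nodes.values():
            if node.coverage < 1 or len(node.hpc_chars) != self.k:
                raise AssertionError("malformed node")
            if len(node.run_obs) != node.coverage:
                raise AssertionError("run observations out of step with coverage")
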