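"""Unitig condensation, HPC spelling, run-length pooling and expansion.

A unitig is a maximal non-branching oriented path: extension continues
through a junction iff the current oriented node has exactly one outgoing
edge and its successor exactly one incoming edge (in the bidirected sense).
A cycle in which every junction is non-branching becomes one circular
unitig, broken at the constituent node with the smallest hash (oriented
forward) so output is deterministic.  Linear unitigs are canonicalized to
the lexicographically smaller of their two spellings.

Spelling walks the path: the first node contributes its k HPC characters,
each subsequent node its last k - overlap characters.  Run-length tallies
are pooled per spelled position from every node offset that maps there —
positions inside an overlap receive observations from both adjacent nodes —
and the per-position consensus (modal run length, ties toward the smallest)
turns the HPC spelling back into base space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import OrientedNode, SparseGraph, edge_key, flip
from .hpc import consensus_from_counts, expand, tally_from_counts_row


@dataclass
class Unitig:
    """A condensed non-branching path with spelled and expanded sequence.

    ``overlaps[i]`` is the HPC overlap between ``path[i]`` and
    ``path[(i+1) % len(path)]``; for circular unitigs the last entry closes
    the cycle (so ``len(overlaps) == len(path)``), for linear unitigs
    ``len(overlaps) == len(path) - 1``.
    """

    id: int
    path: list[OrientedNode]
    overlaps: list[int]
    circular: bool
    hpc_seq: str = ""
    consensus_runs: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    run_counts: np.ndarray = field(default_factory=lambda: np.empty((0, 2), np.int64))
    seq: str = ""  # expanded (base-space) sequence
    avg_coverage: float = 0.0

    @property
    def name(self) -> str:
        return f"utg{self.id:07d}"

    @property
    def run_tallies(self) -> list[dict[int, int]]:
        """Per-HPC-position run-length tallies as plain dicts."""
        return [tally_from_counts_row(row) for row in self.run_counts]

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True, order=True)
class LinkRecord:
    """A bidirected link between unitig ends (GFA L-line payload)."""

    from_name: str
    from_orient: str  # '+' or '-'
    to_name: str
    to_orient: str
    overlap_hpc: int
    overlap_bp: int  # expanded length of the shared overlap


@dataclass(frozen=True)
class AssemblyStats:
    contig_count: int
    total_length: int  # expanded bp
    n50: int  # expanded bp


def _single_out(graph: SparseGraph, x: OrientedNode):
    outs = graph.out_edges(x)
    return outs[0] if len(outs) == 1 else None


def _walk_from(graph: SparseGraph, start: int, visited: set[int]):
    """Maximal non-branching path through ``start``; marks nodes visited."""
    path: list[OrientedNode] = [(start, True)]
    overlaps: list[int] = []
    visited.add(start)
    circular = False

    # forward
    while True:
        step = _single_out(graph, path[-1])
        if step is None:
            break
        nxt, o = step
        if _single_out(graph, flip(nxt)) is None:  # in-degree of nxt != 1
            break
        if nxt == path[0]:
            circular = True
            overlaps.append(o)  # cycle-closing overlap
            break
        if nxt[0] in visited:
            break  # hairpin back into the path: stop at the branch
        visited.add(nxt[0])
        path.append(nxt)
        overlaps.append(o)

    if not circular:
        # backward: step from flip(path[0]); prepending flip(nxt) keeps the
        # path in forward sense.  (A cycle always closes during the forward
        # sweep, so no closure check is needed here.)
        while True:
            step = _single_out(graph, flip(path[0]))
            if step is None:
                break
            nxt, o = step
            if _single_out(graph, flip(nxt)) is None:
                break
            if nxt[0] in visited:
                break
            visited.add(nxt[0])
            path.insert(0, flip(nxt))
            overlaps.insert(0, o)

    if circular:
        # canonical break point: smallest node hash first, oriented forward
        n = len(path)
        anchor = min(range(n), key=lambda i: path[i][0])
        if not path[anchor][1]:
            path = [flip(x) for x in reversed(path)]
            overlaps = list(reversed(overlaps[:-1])) + [overlaps[-1]]
            anchor = n - 1 - anchor
        path = path[anchor:] + path[:anchor]
        overlaps = overlaps[anchor:] + overlaps[:anchor]
    return path, overlaps, circular


def _spell(graph: SparseGraph, path: list[OrientedNode], overlaps: list[int],
           circular: bool) -> str:
    """HPC spelling of a path; validates suffix/prefix agreement at joins."""
    k = graph.k
    spelled = graph.nodes[path[0][0]].oriented_chars(path[0][1])
    for node, o in zip(path[1:], overlaps):
        chars = graph.nodes[node[0]].oriented_chars(node[1])
        if spelled[-o:] != chars[:o]:
            raise AssertionError("suffix/prefix mismatch while spelling unitig")
        spelled += chars[o:]
    if circular:
        length = sum(k - o for o in overlaps)
        if length >= k:
            o = overlaps[-1]
            if spelled[-o:] != spelled[:o]:
                raise AssertionError("cycle-closing suffix/prefix mismatch")
            spelled = spelled[:length]
        else:
            # cycle shorter than one k-mer (tandem-repeat loop): wrap
            buf = bytearray(length)
            offset = 0
            for node, o in zip(path, overlaps):
                chars = graph.nodes[node[0]].oriented_chars(node[1])
                for t, ch in enumerate(chars):
                    buf[(offset + t) % length] = ord(ch)
                offset += k - o
            spelled = buf.decode("ascii")
    return spelled


def _pool_counts(graph: SparseGraph, path: list[OrientedNode], overlaps: list[int],
                 circular: bool, length: int) -> np.ndarray:
    """Pooled per-position run-length observation counts for a spelled path."""
    k = graph.k
    mats = []
    maxr = 1
    for node in path:
        mat = graph.nodes[node[0]].run_count_matrix()
        if not node[1]:
            mat = mat[::-1]  # mirror offsets for reverse orientation
        mats.append(mat)
        maxr = max(maxr, mat.shape[1] - 1)
    counts = np.zeros((length, maxr + 1), dtype=np.int64)
    cols = np.arange(k)
    offset = 0
    for i, mat in enumerate(mats):
        positions = offset + cols
        if circular:
            positions = positions % length
            # positions may repeat when k > cycle length: accumulate safely
            np.add.at(counts, (positions[:, None], np.arange(mat.shape[1])[None, :]), mat)
        else:
            counts[positions, : mat.shape[1]] += mat
        if i < len(overlaps):
            offset += k - overlaps[i]
    return counts


def condense(graph: SparseGraph) -> list[Unitig]:
    """Condense the cleaned graph into unitigs with expanded sequences.

    Every node ends up in exactly one unitig.  Unitigs are sorted by their
    smallest constituent node hash and numbered from 1, which together with
    the orientation canonicalization makes output independent of read input
    order and strand.
    """
    visited: set[int] = set()
    unitigs: list[Unitig] = []
    for nid in sorted(graph.nodes):
        if nid in visited:
            continue
        path, overlaps, circular = _walk_from(graph, nid, visited)
        spelled = _spell(graph, path, overlaps, circular)
        if not circular:
            rev_path = [flip(x) for x in reversed(path)]
            rev_overlaps = list(reversed(overlaps))
            rev_spelled = _spell(graph, rev_path, rev_overlaps, False)
            if rev_spelled < spelled:
                path, overlaps, spelled = rev_path, rev_overlaps, rev_spelled
        counts = _pool_counts(graph, path, overlaps, circular, len(spelled))
        runs = consensus_from_counts(counts)
        seq = expand(spelled, runs)
        cov = float(np.mean([graph.nodes[x[0]].coverage for x in path]))
        unitigs.append(
            Unitig(id=0, path=path, overlaps=overlaps, circular=circular,
                   hpc_seq=spelled, consensus_runs=runs, run_counts=counts,
                   seq=seq, avg_coverage=cov)
        )
    unitigs.sort(key=lambda u: min(x[0] for x in u.path))
    for i, u in enumerate(unitigs, start=1):
        u.id = i
    return unitigs


def _end_of(u: Unitig, oriented: OrientedNode) -> str | None:
    """Which end of ``u`` an outgoing oriented node is: '+' = out of the
    tail, '-' = out of the head (leaving the unitig reversed)."""
    if oriented == u.path[-1]:
        return "+"
    if oriented == flip(u.path[0]):
        return "-"
    return None


def _entry_of(u: Unitig, oriented: OrientedNode) -> str | None:
    """Orientation with which an edge *enters* unitig ``u``."""
    if oriented == u.path[0]:
        return "+"
    if oriented == flip(u.path[-1]):
        return "-"
    return None


def compute_links(graph: SparseGraph, unitigs: list[Unitig]) -> list[LinkRecord]:
    """Derive GFA links from graph edges between unitig-terminal nodes.

    The expanded overlap length is the sum of the consensus run lengths over
    the shared HPC positions, read from the source segment.  Each bidirected
    link is emitted once (mirror suppressed), sorted for byte-stable output.
    A circular unitig's cycle-closing edge becomes its self-link.
    """
    by_node: dict[int, Unitig] = {}
    internal: set = set()
    for u in unitigs:
        for x in u.path:
            by_node[x[0]] = u
        for i, o in enumerate(u.overlaps):
            internal.add(edge_key(u.path[i], u.path[(i + 1) % len(u.path)], o))

    def oriented_runs(u: Unitig, orient: str) -> np.ndarray:
        return u.consensus_runs if orient == "+" else u.consensus_runs[::-1]

    links: set[LinkRecord] = set()
    for (a, b, o) in graph.edges:
        key = edge_key(a, b, o)
        ua, ub = by_node[a[0]], by_node[b[0]]
        if key in internal:
            if ua.circular:
                # the segment stores the cycle non-redundantly (the closing
                # overlap is not duplicated), so the self-link abuts: 0M
                links.add(LinkRecord(ua.name, "+", ua.name, "+", 0, 0))
            continue
        oa = _end_of(ua, a)
        ob = _entry_of(ub, b)
        if oa is None or ob is None:
            raise AssertionError("non-internal edge not at a unitig end")
        # emit the lexicographically smaller of the link and its mirror,
        # with the expanded overlap read from the emitted source segment
        if (ua.name, oa, ub.name, ob) <= (ub.name, "+" if ob == "-" else "-",
                                          ua.name, "+" if oa == "-" else "-"):
            exp = int(oriented_runs(ua, oa)[-o:].sum())
            links.add(LinkRecord(ua.name, oa, ub.name, ob, o, exp))
        else:
            so = "+" if ob == "-" else "-"
            to = "+" if oa == "-" else "-"
            exp = int(oriented_runs(ub, so)[-o:].sum())
            links.add(LinkRecord(ub.name, so, ua.name, to, o, exp))
    return sorted(links)


def assembly_stats(unitigs: list[Unitig]) -> AssemblyStats:
    """Contig count, total expanded length, and N50 (expanded space).

    N50 is the length at which the running sum of descending-sorted contig
    lengths first reaches at least half the total.
    """
    if not unitigs:
        raise ValueError("assembly statistics require at least one unitig")
    lengths = sorted((len(u) for u in unitigs), reverse=True)
    total = sum(lengths)
    acc = 0
    for length in lengths:
        acc += length
        if 2 * acc >= total:
            return AssemblyStats(contig_count=len(lengths), total_length=total, n50=length)
    raise AssertionError("unreachable")
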