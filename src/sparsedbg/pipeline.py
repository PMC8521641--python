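"""End-to-end assembly pipeline: reads -> sparse DBG -> unitigs -> stats.

Stage order: homopolymer-compress each read, winnow its minimizers, thread
the chain into the bidirected graph; then optional coverage filtering,
transitive-edge cleaning, unitig condensation, run-length consensus
expansion, and link derivation.  Single-threaded and deterministic:
identical inputs and configuration give identical results regardless of
read order or strand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .graph import SparseGraph
from .hpc import compress
from .io_seq import ReadRecord
from .unitig import AssemblyStats, LinkRecord, Unitig, assembly_stats, compute_links, condense
from .winnow import select_minimizers, validate_params


@dataclass
class AssemblyResult:
    graph: SparseGraph
    unitigs: list[Unitig]
    links: list[LinkRecord]
    stats: AssemblyStats | None
    counters: dict[str, int | float] = field(default_factory=dict)


def assemble(
    reads: Iterable[ReadRecord | tuple[str, str]],
    k: int,
    w: int,
    *,
    min_node_cov: int = 1,
    min_edge_cov: int = 1,
    clean: bool = True,
    clean_t: float = 0.25,
) -> AssemblyResult:
    """Run the full pipeline over an iterable of reads.

    ``reads`` may yield :class:`ReadRecord` objects or plain
    ``(read_id, sequence)`` pairs over the {A,C,G,T} alphabet.
    """
    validate_params(k, w)
    graph = SparseGraph(k=k, w=w)
    n_reads = 0
    hpc_bases = 0
    minimizers = 0
    for rec in reads:
        if isinstance(rec, ReadRecord):
            read_id, seq = rec.read_id, rec.sequence
        else:
            read_id, seq = rec
        if not seq:
            continue
        n_reads += 1
        hpc = compress(seq, origin=read_id)
        hpc_bases += len(hpc)
        chain = select_minimizers(hpc, k, w)
        minimizers += len(chain)
        graph.thread_chain(chain, hpc)
    graph.drop_low_coverage(min_node_cov, min_edge_cov)
    removed = graph.clean_transitive_edges(clean_t) if clean else 0
    unitigs = condense(graph)
    links = compute_links(graph, unitigs) if unitigs else []
    stats = assembly_stats(unitigs) if unitigs else None
    counters: dict[str, int | float] = {
        "reads": n_reads,
        "hpc_bases": hpc_bases,
        "minimizers": minimizers,
        "nodes": len(graph.nodes),
        "edges": len(graph.edges),
        "edges_removed": removed,
        "unitigs": len(unitigs),
        "total_length": stats.total_length if stats else 0,
        "n50": stats.n50 if stats else 0,
    }
    return AssemblyResult(graph=graph, unitigs=unitigs, links=links,
                          stats=stats, counters=counters)
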