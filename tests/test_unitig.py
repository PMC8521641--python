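"""Unitig condensation, spelling, run-length pooling and statistics."""

import numpy as np
import pytest

from conftest import build_toy_graph
from sparsedbg.dna import reverse_complement
from sparsedbg.graph import flip
from sparsedbg.hpc import compress
from sparsedbg.pipeline import assemble
from sparsedbg.simulate import SimConfig, random_genome, sample_reads
from sparsedbg.unitig import Unitig, assembly_stats, compute_links, condense


def _partition(unitigs):
    return {frozenset(x[0] for x in u.path) for u in unitigs}


def test_unbranched_chain_condenses_to_one_unitig():
    g = build_toy_graph([["AACGT", "ACGTC", "CGTCC"]], k=5, w=2)
    unitigs = condense(g)
    assert len(unitigs) == 1
    u = unitigs[0]
    assert len(u.path) == 3 and not u.circular
    assert len(u.hpc_seq) == 5 + 2 * (5 - 4)  # k + sum(k - overlap)
    assert u.hpc_seq in ("AACGTCC", reverse_complement("AACGTCC"))


def test_branching_center_stays_separate():
    # two walks share the center k-mer CGTCC: branch on the outgoing side
    g = build_toy_graph(
        [["AACGT", "ACGTC", "CGTCC", "GTCCA"],
         ["AACGT", "ACGTC", "CGTCC", "GTCCG"]],
        k=5, w=2,
    )
    unitigs = condense(g)
    # chain AACGT-ACGTC-CGTCC is unbranched; the two tips split off
    assert len(unitigs) == 3
    sizes = sorted(len(u.path) for u in unitigs)
    assert sizes == [1, 1, 3]


def test_single_node_unitig_spells_its_kmer():
    g = build_toy_graph([["AACGT"]], k=5, w=2)
    (u,) = condense(g)
    assert u.hpc_seq in ("AACGT", reverse_complement("AACGT"))
    assert u.consensus_runs.tolist() == [1] * 5
    assert u.seq == u.hpc_seq  # all-ones tallies: expansion is the identity


def test_condensation_matches_bruteforce_partition(rng):
    """Node partition equals an independent forced-join component search on
    simulated graphs of up to ~200 nodes."""
    import networkx as nx

    for seed in (101, 102, 103):
        genome = random_genome(1200, seed=seed)
        cfg = SimConfig(genome_length=1200, read_length_mean=400,
                        read_length_sd=40, coverage=8, seed=seed + 50)
        reads, _ = sample_reads(genome, cfg)
        res = assemble(reads, 21, 10, clean=False)
        g = res.graph
        assert len(g.nodes) <= 250
        # oracle: join u--v (undirected, on node ids) wherever the oriented
        # junction is forced: exactly one out-edge and one in-edge
        joins = nx.Graph()
        joins.add_nodes_from(g.nodes)
        for nid in g.nodes:
            for orient in (True, False):
                x = (nid, orient)
                outs = g.out_edges(x)
                if len(outs) != 1:
                    continue
                (y, _o), = outs
                if len(g.out_edges(flip(y))) == 1:
                    joins.add_edge(nid, y[0])
        oracle = {frozenset(c) for c in nx.connected_components(joins)}
        assert _partition(res.unitigs) == oracle


def test_error_free_circular_genome_recovered_exactly(rng):
    genome = random_genome(6000, seed=31)
    cfg = SimConfig(genome_length=6000, read_length_mean=900, read_length_sd=90,
                    coverage=15, seed=32)
    reads, _ = sample_reads(genome, cfg)
    res = assemble(reads, 31, 15)
    assert len(res.unitigs) == 1
    u = res.unitigs[0]
    assert u.circular
    # HPC spelling is rotation/RC-equivalent to the genome's HPC form
    gh = compress(genome).chars
    assert u.hpc_seq in gh + gh or reverse_complement(u.hpc_seq) in gh + gh
    # expansion with error-free tallies reproduces the genome itself
    assert u.seq in genome + genome or reverse_complement(u.seq) in genome + genome


def test_boundary_overlap_tallies_are_consistent(rng):
    """At a branch, the expanded tail of one unitig matches the expanded head
    of its neighbour over the link overlap."""
    common = random_genome(3000, seed=41, circular=False)
    lead_a = random_genome(2000, seed=42, circular=False)
    lead_b = random_genome(2000, seed=43, circular=False)
    reads = []
    for tag, genome in (("a", lead_a + common), ("b", lead_b + common)):
        cfg = SimConfig(genome_length=len(genome), circular=False,
                        read_length_mean=700, read_length_sd=50,
                        coverage=12, seed=44 if tag == "a" else 45)
        rds, _ = sample_reads(genome, cfg)
        reads.extend((f"{tag}{rid}", s) for rid, s in rds)
    res = assemble(reads, 31, 15)
    assert len(res.unitigs) >= 2 and res.links
    by_name = {u.name: u for u in res.unitigs}
    for link in res.links:
        if link.overlap_bp == 0:
            continue
        src = by_name[link.from_name].seq
        dst = by_name[link.to_name].seq
        if link.from_orient == "-":
            src = reverse_complement(src)
        if link.to_orient == "-":
            dst = reverse_complement(dst)
        assert src[-link.overlap_bp:] == dst[: link.overlap_bp]


def test_run_tallies_expose_pooled_observations():
    g = build_toy_graph([["AACGT", "ACGTC"]], k=5, w=2)
    (u,) = condense(g)
    tallies = u.run_tallies
    assert len(tallies) == len(u.hpc_seq)
    # overlap positions pool observations from both nodes
    assert any(sum(t.values()) == 2 for t in tallies)
    assert all(set(t) == {1} for t in tallies)


@pytest.mark.parametrize(
    "lengths, n50",
    [([100], 100), ([50, 30, 20], 50), ([40, 30, 30], 30)],
)
def test_assembly_stats_n50(lengths, n50):
    unitigs = [
        Unitig(id=i + 1, path=[(i, True)], overlaps=[], circular=False, seq="A" * n)
        for i, n in enumerate(lengths)
    ]
    stats = assembly_stats(unitigs)
    assert stats.contig_count == len(lengths)
    assert stats.total_length == sum(lengths)
    assert stats.n50 == n50


def test_assembly_stats_requires_unitigs():
    with pytest.raises(ValueError):
        assembly_stats([])
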