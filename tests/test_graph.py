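"""Bidirected graph construction, invariance, and transitive-edge cleaning."""

import random

import numpy as np
import pytest

from conftest import build_toy_graph, dense_graph_oracle, random_dna
from sparsedbg.dna import reverse_complement
from sparsedbg.graph import SparseGraph, edge_key, flip
from sparsedbg.hpc import compress
from sparsedbg.pipeline import assemble
from sparsedbg.simulate import SimConfig, random_genome, sample_reads
from sparsedbg.winnow import select_minimizers


def _build(reads, k, w, clean=False):
    return assemble(reads, k, w, clean=clean)


def _graph_content(g: SparseGraph):
    nodes = {nid: n.coverage for nid, n in g.nodes.items()}
    return nodes, dict(g.edges)


def test_dense_graph_equals_bruteforce_enumeration(rng):
    """At w=1 the graph is the dense HPC de Bruijn graph: node set equals the
    distinct canonical k-mers, edge multiset equals observed adjacencies."""
    k = 11
    genome = random_genome(3000, seed=5, circular=False)
    cfg = SimConfig(genome_length=3000, circular=False, read_length_mean=400,
                    read_length_sd=40, coverage=5, seed=6)
    reads, _ = sample_reads(genome, cfg)
    result = _build(reads, k, 1)
    oracle_nodes, oracle_edges = dense_graph_oracle([s for _, s in reads], k)
    assert {n.hpc_chars for n in result.graph.nodes.values()} == oracle_nodes
    assert dict(result.graph.edges) == oracle_edges
    result.graph.validate()


def test_duplicated_read_doubles_coverage(rng):
    seq = random_dna(rng, 500)
    once = _build([("r", seq)], 21, 10)
    twice = _build([("r1", seq), ("r2", seq)], 21, 10)
    n1, e1 = _graph_content(once.graph)
    n2, e2 = _graph_content(twice.graph)
    assert n2 == {k: 2 * v for k, v in n1.items()}
    assert e2 == {k: 2 * v for k, v in e1.items()}


def test_read_and_its_reverse_complement_build_identical_graphs(rng):
    seq = random_dna(rng, 800)
    fwd = _build([("r", seq)], 21, 10)
    rev = _build([("r", reverse_complement(seq))], 21, 10)
    assert _graph_content(fwd.graph) == _graph_content(rev.graph)


def test_graph_invariant_under_read_order_and_global_rc(rng):
    genome = random_genome(5000, seed=9)
    cfg = SimConfig(genome_length=5000, read_length_mean=900, read_length_sd=90,
                    coverage=8, seed=10)
    reads, _ = sample_reads(genome, cfg)
    base = _graph_content(_build(reads, 31, 15).graph)
    shuffled = reads[:]
    random.Random(3).shuffle(shuffled)
    assert _graph_content(_build(shuffled, 31, 15).graph) == base
    rc_reads = [(rid, reverse_complement(s)) for rid, s in reads]
    assert _graph_content(_build(rc_reads, 31, 15).graph) == base


def test_coverage_conservation_and_overlap_bounds(rng):
    genome = random_genome(4000, seed=13)
    cfg = SimConfig(genome_length=4000, read_length_mean=700, read_length_sd=70,
                    coverage=6, seed=14)
    reads, _ = sample_reads(genome, cfg)
    k, w = 31, 15
    total_selected = sum(
        len(select_minimizers(compress(s), k, w)) for _, s in reads
    )
    result = _build(reads, k, w)
    assert sum(n.coverage for n in result.graph.nodes.values()) == total_selected
    result.graph.validate()  # checks overlap in [k-w, k-1] + junction spelling


# -- transitive-edge cleaning -------------------------------------------------

def _triangle(cov_detour1, cov_detour2, cov_direct, k=5):
    """u -> m -> v detour plus direct u -> v edge, with given coverages."""
    from sparsedbg.hashing import canonical_form, hash128_of_canonical

    walk = ["AACGT", "ACGTC", "CGTCC"]  # u, m, v with k-1 overlaps
    g = build_toy_graph([walk], k=k, w=2)
    # rebuild edges with explicit coverages
    g.edges.clear()
    g._out = None
    ids = {}
    for kmer in walk:
        canon, fwd = canonical_form(kmer)
        ids[kmer] = (hash128_of_canonical(canon), fwd)
    g.add_edge(ids["AACGT"], ids["ACGTC"], 4, count=cov_detour1)
    g.add_edge(ids["ACGTC"], ids["CGTCC"], 4, count=cov_detour2)
    g.add_edge(ids["AACGT"], ids["CGTCC"], 3, count=cov_direct)
    return g, ids


def test_low_coverage_bypass_edge_removed():
    g, ids = _triangle(10, 10, 1)
    removed = g.clean_transitive_edges(t=0.25)
    assert removed == 1
    assert edge_key(ids["AACGT"], ids["CGTCC"], 3) not in g.edges
    assert len(g.edges) == 2


def test_balanced_triangle_kept_as_genuine_repeat():
    g, _ = _triangle(10, 10, 10)
    assert g.clean_transitive_edges(t=0.25) == 0
    assert len(g.edges) == 3


def test_bypass_above_relative_threshold_kept():
    # floor(0.25 * 10) = 2; coverage 3 exceeds it -> kept
    g, _ = _triangle(10, 10, 3)
    assert g.clean_transitive_edges(t=0.25) == 0
    # but coverage 2 is removable
    g2, _ = _triangle(10, 10, 2)
    assert g2.clean_transitive_edges(t=0.25) == 1


def test_cleaning_is_single_pass_without_cascade():
    """Removals are decided simultaneously against the pre-cleaning state: a
    detour edge that is itself removable does not rescue the edge it
    bypasses from comparison against the original coverages, and a second
    pass finds nothing new."""
    g, ids = _triangle(10, 10, 1)
    first = g.clean_transitive_edges(t=0.25)
    assert first == 1
    assert g.clean_transitive_edges(t=0.25) == 0


def test_missing_minimizer_occurrence_creates_cleanable_bypass(rng):
    """Drop one interior minimizer occurrence from one read (the footprint
    of an error destroying that occurrence): the graph gains exactly one
    low-coverage bypass edge, and cleaning restores the error-free graph."""
    genome = random_genome(4000, seed=21)
    cfg = SimConfig(genome_length=4000, read_length_mean=800, read_length_sd=80,
                    coverage=20, seed=22)
    reads, _ = sample_reads(genome, cfg)
    k, w = 31, 15

    def build_with_drop(drop_read=None):
        g = SparseGraph(k=k, w=w)
        for rid, seq in reads:
            hpc = compress(seq, origin=rid)
            chain = select_minimizers(hpc, k, w)
            if rid == drop_read and len(chain) > 4:
                mid = len(chain) // 2
                chain.positions.pop(mid)
                chain.identities.pop(mid)
            g.thread_chain(chain, hpc)
        return g

    baseline = build_with_drop(None)
    injected = build_with_drop(reads[0][0])
    extra = set(injected.edges) - set(baseline.edges)
    assert len(extra) == 1
    assert injected.edges[next(iter(extra))] == 1
    assert set(injected.nodes) == set(baseline.nodes)
    injected.clean_transitive_edges(t=0.25)
    assert set(injected.edges) == set(baseline.edges)


# -- coverage filtering -------------------------------------------------------

def test_drop_low_coverage_defaults_are_noop(rng):
    result = _build([("r", random_dna(rng, 400))], 21, 10)
    before = _graph_content(result.graph)
    result.graph.drop_low_coverage(1, 1)
    assert _graph_content(result.graph) == before


def test_drop_low_coverage_removes_nodes_and_incident_edges(rng):
    seq = random_dna(rng, 400)
    g = _build([("a", seq), ("b", seq), ("c", random_dna(rng, 200))], 21, 10).graph
    singletons = {nid for nid, n in g.nodes.items() if n.coverage < 2}
    g.drop_low_coverage(min_node_cov=2, min_edge_cov=1)
    assert singletons.isdisjoint(g.nodes)
    for (u, v, _o) in g.edges:
        assert u[0] in g.nodes and v[0] in g.nodes
    # recount oracle: all remaining nodes meet the threshold
    assert all(n.coverage >= 2 for n in g.nodes.values())
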