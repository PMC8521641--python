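# Methods

This note documents the model behind `sparsedbg`, the parameters that
matter, the numerical conventions, and what the bundled simulator does and
does not emulate.

## Pipeline model

The input is a set of low-error long reads over {A,C,G,T} (N-containing
reads are split into N-free segments at input). Stages, in order:

1. **Homopolymer compression.** Each maximal run of an identical base
   collapses to one character; the run length (≥ 1) is kept per compressed
   position. All k-mer work happens in this HPC space. Rationale: the
   dominant error mode of HiFi-class reads perturbs run *lengths*, which
   HPC removes entirely as long as a run does not vanish (the simulator's
   ±1-with-floor channel guarantees this; real data can rarely delete a
   length-1 run, which then behaves like a substitution).
2. **Rolling window hash.** Every k-mer start gets a 64-bit
   strand-symmetric value: an ntHash-style cyclic polynomial (fixed
   per-base seed constants, rotate–XOR recurrence) is computed for the
   forward and reverse-complement orientation, the minimum of the two is
   taken, and the result is passed through the splitmix64 finalizer. The
   finalizer matters: raw cyclic-polynomial values of overlapping windows
   are linearly related, and we measured the resulting minimizer density ~3 %
   below the 2/(w+1) expectation; after the nonlinear scramble the density
   matches 2/(w+1) within sampling error. The whole computation is
   vectorized (prefix-XOR over rotated seed contributions), O(1) work per
   position.
3. **Winnowing.** A position is selected iff its value is minimal in at
   least one window of `w` consecutive start positions; ties break to the
   leftmost position; a read shorter than one window forms a single window.
   This gives the window guarantee (gap between selections ≤ w) and, with
   the enforced `w ≤ k−1`, a minimum overlap of `k−w ≥ 1` between adjacent
   selections. `w = 1` reproduces the dense de Bruijn graph. No extra
   terminal selection is forced at read ends; the consequence is only that
   up to `w−1` positions at each read end may go unrepresented, slightly
   shortening terminal unitigs. A useful structural fact (we rely on it and
   test it end to end): because every read window is also a window of the
   underlying genome, a read's selection is a contiguous slice of the
   genome's selection — error-free reads can never skip an interior
   minimizer, so error-free graphs contain no spurious branches.
4. **Graph.** Nodes are canonical k-mers (lexicographically smaller of
   k-mer and reverse complement) named by a 128-bit keyless BLAKE2b hash;
   collisions are treated as impossible and not checked (at 2⁻¹²⁸,
   verification would cost more than it buys). Each node stores its HPC
   text, recorded at first observation, so sequence restoration needs no
   second pass over the reads, plus one run-length observation vector per
   occurrence (values capped at 255). Edges are bidirected, keyed by
   (oriented pair, overlap) with the mirror folded in; parallel edges with
   different overlaps and self-loops are legal and flow through unchanged.
5. **Transitive-edge cleaning.** The error signature targeted is a read
   missing one minimizer occurrence, which threads a direct edge bypassing
   a two-node path. An edge `e = u→v` is removed iff some oriented 2-path
   `u→m→v` (not reusing `e`) has both coverages ≥ cov(e) and
   cov(e) ≤ max(1, ⌊t·min(detour coverages)⌋), taking the detour that
   maximizes that minimum; `t` defaults to 0.25 and is exposed as
   configuration. Decisions are made in one simultaneous pass against the
   pre-cleaning state (no cascade), so removal order cannot matter. The
   relative threshold keeps genuine repeat triangles, whose direct edge
   carries real coverage.
6. **Unitigs.** Maximal non-branching oriented paths (extension through a
   junction requires out-degree 1 and successor in-degree 1, bidirected).
   Fully non-branching cycles become one circular unitig, broken at the
   smallest constituent node hash oriented forward; linear unitigs take the
   lexicographically smaller of their two spellings. Together with sorting
   unitigs by smallest node hash, this makes output byte-identical across
   read orders and global strand flips.
7. **Run-length consensus and expansion.** Per spelled HPC position, all
   observations from every node offset mapping there (overlap positions
   pool both adjacent nodes) are tallied; the consensus is the modal run
   length with ties broken toward the smaller length — run lengths are
   small integers under a roughly symmetric ±1 channel, so the mode is
   robust and the tie rule deterministic. Expansion repeats each character
   by its consensus length.
8. **GFA 1.0 output.** One `S` record per unitig with the expanded sequence
   and a `dp:f:` tag carrying mean node coverage (two decimals); one `L`
   record per bidirected link with the expanded overlap as a single-match
   CIGAR, each link emitted once, records sorted. Before writing, every
   link's overlap spelling (suffix of source = prefix of target) is
   verified. A circular unitig's sequence is stored non-redundantly (the
   cycle-closing overlap is not duplicated), so its self-link is `0M`;
   links between distinct unitigs carry the real shared overlap.

## Parameters

| parameter | units | default | notes |
|---|---|---|---|
| `k` | HPC bp | 2001 | node k-mer size; large k resolves repeats, needs reads ≫ k |
| `w` | start positions | 1000 | sparsity; density ≈ 2/(w+1); must satisfy 1 ≤ w ≤ k−1 |
| `--clean-t` | fraction | 0.25 | relative coverage threshold of transitive cleaning |
| `--min-node-cov`, `--min-edge-cov` | count | 1 | optional abundance filter; defaults keep everything |

The CLI defaults target real HiFi-scale data; tests and the acceptance
script run at desk scale (genomes of 10–100 kb, k of 31–501) purely as the
package's own choice of reproducible problem sizes.

## The simulator

`sparsedbg.simulate` generates a random genome whose homopolymer runs are
geometrically extended (default extension probability 0.25, capped at 6),
and reads with uniform starts (wrapping on circular genomes), uniform
strands, normal lengths, a per-run ±1 length perturbation (floored at 1) as
the dominant error mode, and rare substitutions placed to differ from both
neighbours. Defaults (100 kb circular genome, 8 kb ± 0.8 kb reads, 20×,
run-error 0.1 when errors are wanted) emulate a bacterial-scale HiFi
experiment shrunk to desk size.

What it does **not** emulate: HPC-visible errors (full run deletions,
insertions creating new runs — i.e. the simulator's error channel never
changes the compressed sequence), chimeric reads, coverage bias, quality
scores, and long genomic repeats. Passing tests therefore demonstrate the
machinery (selection, graph, consensus, determinism) under the stated error
model; they do not demonstrate robustness to HPC-visible error bubbles,
against which the only defence here is transitive-edge cleaning plus the
optional coverage filter.

## Numerical and degenerate-input conventions

* Reads shorter than k (in HPC space) contribute nothing; an assembly with
  zero usable reads is reported as empty input (CLI exit 1).
* Run-length observations are stored as uint8 (cap 255); only the reported
  consensus of biologically absurd >255 runs would be affected.
* Tie-breaks are everywhere deterministic: leftmost position in winnowing,
  smallest length in consensus, lexicographic spelling for unitig
  orientation, smallest hash for cycle break points.
* Winnowing strand symmetry (and hence byte-identical output under global
  reverse complement) assumes no two equal 64-bit window hashes co-occur in
  one window; a tie requires an exact k-mer repeat within w positions,
  absent in random genomes and vanishing for the k in normal use.
* Unitig-boundary consensus: the overlap region of two linked unitigs is
  tallied independently from the two terminal nodes, whose occurrence sets
  can differ slightly (a read may end inside one of them). At working
  coverage both consensus calls agree; the GFA writer verifies the overlap
  spelling and fails loudly rather than emit an inconsistent file.
* 128-bit hash collisions are assumed away rather than detected; this is a
  deliberate trade, not an oversight.

## Known limitations

No tip clipping, bubble popping or other error correction beyond
transitive-edge cleaning; no read-to-graph alignment; no GFA input or
GFA 2.0; single-threaded (determinism is the contract any future
parallelism must keep). Memory holds the whole graph and per-node
observation vectors; disk-backed construction is out of scope.
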