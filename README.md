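# sparsedbg

Minimizer-based **sparse de Bruijn graph** construction and unitig assembly
for HiFi-like long reads.

HiFi reads combine multi-kilobase lengths with error rates low enough that
de Bruijn graphs become practical for long-read data — but classical dense
DBG builders must store every k-mer and stop scaling long before the k-mer
sizes (hundreds to thousands of bp) at which long reads resolve repeats
best. `sparsedbg` addresses this with three ideas working together:

1. **Homopolymer compression (HPC).** The dominant HiFi error mode is a
   wrong homopolymer run length. Collapsing each maximal run `B^n → B`
   removes most errors before any k-mer is formed; per-position run lengths
   are kept so the compression can be reversed at output.
2. **Minimizer winnowing.** In every window of `w` consecutive k-mer start
   positions, the k-mer with the smallest strand-symmetric 64-bit hash is
   selected. Only selected k-mers become graph nodes, so the graph size
   scales as ~`2/(w+1)` of the dense graph, while the *window guarantee*
   bounds the gap between selections by `w` (with `w ≤ k−1`, consecutive
   selections always overlap).
3. **Constant-size node identities.** Each selected k-mer is named by a
   128-bit hash of its canonical orientation. Collisions (~2⁻¹²⁸) are
   treated as impossible, so a 5000 bp k-mer costs the same to store as a
   31 bp one — this is what lets `k` scale arbitrarily high.

Edges connect oriented nodes whenever two selected minimizers are adjacent
in a read, with HPC-space overlap `k − distance`. Edges created by a read
missing one minimizer (an error signature) are removed by transitive-edge
cleaning; maximal non-branching paths are condensed to unitigs; homopolymer
run lengths are restored by a per-position modal consensus over all read
observations; and the graph is written as GFA 1.0 (plus optional contig
FASTA).

## Worked example

Simulate a 100 kb circular genome with 20× HiFi-like reads whose only
frequent errors are ±1 homopolymer run-length perturbations, then assemble:

```bash
sparsedbg simulate --length 100000 --coverage 20 --run-error 0.1 \
    --seed 11 --out-prefix sim
sparsedbg build -i sim.reads.fasta -o sim.gfa -f sim.contigs.fa -k 501 -w 250
```

The build prints a machine-readable summary (this is real output):

```
reads=250
hpc_bases=1506227
minimizers=11131
nodes=620
edges=620
edges_removed=0
unitigs=1
total_length=100000
n50=100000
```

Reading it: 250 reads compressed to ~1.5 M HPC bases; winnowing at
`w=250` kept 11 131 k-mer occurrences (≈ the expected `2/(w+1)` density);
they collapse to 620 distinct nodes forming a single cycle, which condenses
to **one circular unitig of exactly 100 000 bp** — the genome, recovered to
the base up to rotation/strand, because the run-length consensus at 20×
overwhelms the 10 % per-run noise. `sim.gfa` holds one `S` record (with a
`dp:f:` mean-coverage tag) and one self-link `L utg0000001 + utg0000001 + 0M`
marking circularity.

The same pipeline is available as a library:

```python
from sparsedbg import assemble, random_genome, sample_reads, SimConfig

genome = random_genome(100_000, seed=11)
reads, truth = sample_reads(genome, SimConfig(seed=12, coverage=20))
result = assemble(reads, k=501, w=250)
print(result.counters["unitigs"], result.stats.n50)
```

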