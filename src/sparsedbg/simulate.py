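"""Synthetic genomes and HiFi-like reads with ground truth.

The read simulator emulates the error profile that motivates homopolymer
compression: the dominant error mode perturbs the *length* of a homopolymer
run (+-1 with equal probability, floored at 1, so a run never vanishes and
the compressed sequence is unchanged), plus rare substitutions.  Substituted
bases are chosen to differ from both neighbours, so a substitution changes
exactly one compressed position and never merges runs.

Genomes are drawn base by base with run lengths extended geometrically
(capped) so that homopolymer compression is non-trivial; circular genomes
avoid equal first/last bases so the wrap never merges runs.  Everything is
deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .dna import BASES, reverse_complement
from .hpc import compress, expand


@dataclass
class SimConfig:
    """Study conditions for one simulated read set.

    Defaults model a desk-scale HiFi experiment: a 100 kb circular genome at
    20x coverage with ~8 kb reads and homopolymer run-length perturbations as
    the only frequent error mode.
    """

    genome_length: int = 100_000
    circular: bool = True
    read_length_mean: float = 8_000.0
    read_length_sd: float = 800.0
    min_read_length: int = 50
    coverage: float = 20.0
    run_length_error_rate: float = 0.0  # per homopolymer run
    substitution_rate: float = 0.0  # per base
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.run_length_error_rate < 1):
            raise ValueError("run_length_error_rate must be in [0, 1)")
        if not (0 <= self.substitution_rate < 1):
            raise ValueError("substitution_rate must be in [0, 1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.genome_length < self.read_length_mean:
            raise ValueError("genome_length must be >= mean read length")


@dataclass(frozen=True)
class TruthRecord:
    """Origin of one simulated read: 0-based half-open genome interval.

    For circular genomes ``end`` may exceed the genome length, meaning the
    read wraps past the origin.  ``strand`` is '+' or '-'.
    """

    read_id: str
    start: int
    end: int
    strand: str


def random_genome(length: int, seed: int, circular: bool = True,
                  max_homopolymer: int = 6, extension_prob: float = 0.25) -> str:
    """Random genome with geometrically extended homopolymer runs.

    Each new run picks a base different from the previous one and a length
    1 + Geometric(extension_prob) truncated at ``max_homopolymer``.  With
    ``max_homopolymer=1`` the genome equals its own HPC form.
    """
    if length < 1:
        raise ValueError("genome length must be >= 1")
    rng = np.random.default_rng(seed)
    chunks: list[str] = []
    total = 0
    prev = None
    while total < length:
        choices = [b for b in BASES if b != prev]
        base = choices[rng.integers(len(choices))]
        run = 1
        while run < max_homopolymer and rng.random() < extension_prob:
            run += 1
        chunks.append(base * run)
        total += run
        prev = base
    genome = "".join(chunks)[:length]
    if circular and length > 1 and genome[0] == genome[-1]:
        # avoid run merging across the origin
        tail_choices = [b for b in BASES if b not in (genome[0], genome[-2])]
        genome = genome[:-1] + tail_choices[int(rng.integers(len(tail_choices)))]
    return genome


def _perturb_runs(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Apply +-1 run-length errors (floored at 1) to each homopolymer run."""
    h = compress(seq)
    runs = h.run_lengths.copy()
    hit = rng.random(runs.size) < rate
    delta = rng.choice((-1, 1), size=runs.size)
    runs[hit] = np.maximum(1, runs[hit] + delta[hit])
    return expand(h.chars, runs)


def _apply_substitutions(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute bases at ``rate``, avoiding both neighbours so the HPC
    structure changes at exactly one compressed position per event."""
    positions = np.flatnonzero(rng.random(len(seq)) < rate)
    if positions.size == 0:
        return seq
    out = list(seq)
    for p in positions:
        left = out[p - 1] if p > 0 else None
        right = out[p + 1] if p + 1 < len(out) else None
        choices = [b for b in BASES if b != out[p] and b != left and b != right]
        if not choices:  # cannot happen with 4 bases, kept for safety
            choices = [b for b in BASES if b != out[p]]
        out[p] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def sample_reads(genome: str, config: SimConfig):
    """Sample HiFi-like reads; returns (list of (read_id, sequence), truth).

    Read starts are uniform (wrapping on circular genomes), strands uniform,
    lengths normal (clipped); expected total read bases ~ coverage x genome
    length.  With zero error rates every read is an exact genomic substring
    (or its reverse complement).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = len(genome)
    n_reads = max(1, round(config.coverage * L / config.read_length_mean))
    doubled = genome + genome  # for wrap-around extraction
    reads: list[tuple[str, str]] = []
    truth: list[TruthRecord] = []
    for i in range(n_reads):
        length = int(np.clip(rng.normal(config.read_length_mean, config.read_length_sd),
                             config.min_read_length, L))
        if config.circular:
            start = int(rng.integers(0, L))
        else:
            start = int(rng.integers(0, L - length + 1))
        sub = doubled[start : start + length]
        strand = "+" if rng.random() < 0.5 else "-"
        obs = sub if strand == "+" else reverse_complement(sub)
        if config.run_length_error_rate > 0:
            obs = _perturb_runs(obs, config.run_length_error_rate, rng)
        if config.substitution_rate > 0:
            obs = _apply_substitutions(obs, config.substitution_rate, rng)
        read_id = f"read{i:06d}"
        reads.append((read_id, obs))
        truth.append(TruthRecord(read_id, start, start + length, strand))
    return reads, truth


def write_reads_fasta(reads: list[tuple[str, str]], path: str | Path,
                      width: int = 80) -> None:
    with open(path, "w") as fh:
        for read_id, seq in reads:
            fh.write(f">{read_id}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth(truth: list[TruthRecord], path: str | Path) -> None:
    """BED-like truth table: read_id, start, end (0-based half-open), strand."""
    with open(path, "w") as fh:
        for rec in truth:
            fh.write(f"{rec.read_id}\t{rec.start}\t{rec.end}\t{rec.strand}\n")


def homopolymer_position_fraction(max_homopolymer: int, extension_prob: float) -> float:
    """Closed-form fraction of genome positions inside runs of length >= 2.

    Run lengths follow 1 + Geometric(q) truncated at m: P(L=l) = (1-q) q^(l-1)
    for l < m and P(L=m) = q^(m-1).  The fraction of *positions* in runs of
    length >= 2 is E[L; L>=2] / E[L].
    """
    q = extension_prob
    m = max_homopolymer
    probs = np.array([(1 - q) * q ** (l - 1) for l in range(1, m)] + [q ** (m - 1)])
    lengths = np.arange(1, m + 1)
    e_total = float((probs * lengths).sum())
    e_ge2 = float((probs[1:] * lengths[1:]).sum())
    return e_ge2 / e_total
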