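"""Homopolymer compression, expansion and run-length consensus.

HiFi-like reads are dominated by homopolymer run-length errors: a run of the
same base is read with the wrong multiplicity far more often than a base is
miscalled.  Collapsing every maximal run to a single character ("homopolymer
compression", HPC) therefore removes most errors while preserving the
sequence's structure.  The per-position run lengths are retained so the
compression can be reversed; at output time the run length written for each
position is a *consensus* over all observations collected from the reads.

The consensus statistic is the mode of the observed run lengths, with ties
broken toward the smallest length.  Run lengths are small integers and the
error channel is roughly symmetric (+-1), so the mode is robust to the rare
large deviation; the tie rule makes the result deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .dna import encode, decode

#: Run lengths recorded into node tallies are capped at this value; biological
#: homopolymers beyond it are vanishingly rare and the cap only affects the
#: reported consensus for such runs.
RUN_CAP = 255

#: A tally of observed run lengths: {run length: observation count}.
RunLengthTally = Mapping[int, int]


@dataclass
class HpcSequence:
    """A homopolymer-compressed sequence plus per-position run lengths.

    Invariants: ``len(run_lengths) == len(chars)``; every run length >= 1;
    no two adjacent characters of ``chars`` are equal.
    """

    chars: str
    run_lengths: np.ndarray  # positive ints, one per HPC position
    origin: str = ""

    def __len__(self) -> int:
        return len(self.chars)

    def expand(self) -> str:
        """Reverse the compression using this sequence's own run lengths."""
        return expand(self.chars, self.run_lengths)


def compress(sequence: str, origin: str = "") -> HpcSequence:
    """Collapse maximal homopolymer runs of ``sequence`` to single characters.

    ``expand(compress(s))`` reproduces ``s`` exactly.
    """
    if not sequence:
        raise ValueError("cannot homopolymer-compress an empty sequence")
    raw = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    encode(sequence)  # alphabet check
    starts = np.flatnonzero(np.concatenate(([True], raw[1:] != raw[:-1])))
    run_lengths = np.diff(np.append(starts, raw.size)).astype(np.int64)
    chars = raw[starts].tobytes().decode("ascii")
    return HpcSequence(chars=chars, run_lengths=run_lengths, origin=origin)


def expand(chars: str, run_lengths) -> str:
    """Expand HPC text: position ``i`` contributes ``chars[i]`` repeated
    ``run_lengths[i]`` times."""
    run_lengths = np.asarray(run_lengths)
    if len(chars) != run_lengths.size:
        raise ValueError(
            f"HPC length {len(chars)} != run-length count {run_lengths.size}"
        )
    if run_lengths.size == 0:
        return ""
    if run_lengths.min() < 1:
        raise ValueError("run lengths must be >= 1")
    codes = encode(chars)
    return decode(np.repeat(codes, run_lengths))


def consensus_run(tally: RunLengthTally) -> int:
    """Modal run length of a tally; ties broken toward the smallest length."""
    if not tally:
        raise ValueError("consensus requested on an empty run-length tally")
    # max count wins; among equal counts the smallest length wins
    return min(tally, key=lambda length: (-tally[length], length))


def consensus_from_counts(counts: np.ndarray) -> np.ndarray:
    """Vectorized consensus over a per-position count matrix.

    ``counts[i, l]`` is the number of observations of run length ``l`` at HPC
    position ``i`` (column 0 unused).  Returns one consensus length per row.
    Equivalent, row by row, to :func:`consensus_run`.
    """
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("counts must be a (positions, max_run+1) matrix")
    totals = counts[:, 1:].sum(axis=1)
    if counts.shape[0] and totals.min() == 0:
        raise ValueError("position with no run-length observations")
    # argmax returns the first (= smallest length) among tied maxima
    return np.argmax(counts[:, 1:], axis=1).astype(np.int64) + 1


def tally_from_counts_row(row: np.ndarray) -> dict[int, int]:
    """One row of a count matrix as a plain {length: count} tally."""
    lengths = np.flatnonzero(row)
    return {int(l): int(row[l]) for l in lengths if l > 0}
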