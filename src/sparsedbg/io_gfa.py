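"""GFA 1.0 and FASTA serialization of the condensed unitig graph.

Segments carry the expanded (base-space) sequence and the mean read coverage
of their constituent nodes as a ``dp:f:`` tag (two decimal places).  Links
carry the expanded overlap as a single-match CIGAR ``<n>M``.  Records are
sorted (segments by name, links lexicographically) and every bidirected link
appears exactly once, so output is byte-identical across runs and input
orderings.  Before writing, every link is checked: the suffix of the source
segment must equal the prefix of the target segment over the stated overlap.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

from .dna import reverse_complement
from .unitig import LinkRecord, Unitig

GFA_HEADER = "H\tVN:Z:1.0"


class GfaError(RuntimeError):
    """Inconsistent graph handed to the GFA writer."""


def _oriented_seq(seq: str, orient: str) -> str:
    return seq if orient == "+" else reverse_complement(seq)


def validate_links(unitigs: list[Unitig], links: Iterable[LinkRecord]) -> None:
    """Check the overlap spelling of every link against the segment sequences."""
    by_name = {u.name: u for u in unitigs}
    for link in links:
        if link.from_name not in by_name or link.to_name not in by_name:
            raise GfaError(f"link references unknown segment: {link}")
        if link.overlap_bp == 0:
            continue
        src = _oriented_seq(by_name[link.from_name].seq, link.from_orient)
        dst = _oriented_seq(by_name[link.to_name].seq, link.to_orient)
        if src[-link.overlap_bp :] != dst[: link.overlap_bp]:
            raise GfaError(
                f"overlap mismatch on link {link.from_name}{link.from_orient} -> "
                f"{link.to_name}{link.to_orient} ({link.overlap_bp} bp)"
            )


def write_gfa(unitigs: list[Unitig], links: list[LinkRecord], path: str | Path) -> None:
    """Write the unitig graph as GFA 1.0 (H, S and L records)."""
    validate_links(unitigs, links)
    lines = [GFA_HEADER]
    for u in sorted(unitigs, key=lambda u: u.name):
        lines.append(f"S\t{u.name}\t{u.seq}\tdp:f:{u.avg_coverage:.2f}")
    for link in sorted(links):
        lines.append(
            f"L\t{link.from_name}\t{link.from_orient}\t{link.to_name}"
            f"\t{link.to_orient}\t{link.overlap_bp}M"
        )
    try:
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    except OSError as exc:
        raise GfaError(f"cannot write GFA to {path}: {exc}") from exc


def write_fasta_contigs(unitigs: list[Unitig], path: str | Path, width: int = 80) -> None:
    """Write expanded unitig sequences as FASTA, named like the GFA segments."""
    try:
        with open(path, "w") as fh:
            for u in sorted(unitigs, key=lambda u: u.name):
                fh.write(f">{u.name}\n")
                for i in range(0, len(u.seq), width):
                    fh.write(u.seq[i : i + width] + "\n")
    except OSError as exc:
        raise GfaError(f"cannot write FASTA to {path}: {exc}") from exc
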