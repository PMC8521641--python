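"""Streaming FASTA/FASTQ input with normalization.

Format is auto-detected from the first non-whitespace character ('>' FASTA,
'@' FASTQ) and gzip from the magic bytes.  Sequences are uppercased
(soft-masking carries no meaning here), IUPAC ambiguity codes other than N
are mapped to N, and each read is split at N runs so that downstream k-mer
hashing only ever sees the {A,C,G,T} alphabet.  FASTQ qualities are
discarded — the method never uses them.  Records are yielded one at a time;
memory use is bounded by a single record, not by file size.
"""

from __future__ import annotations

import gzip
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

_ACGT_SEGMENT = re.compile(r"[ACGT]+")
_NON_ACGTN = re.compile(r"[^ACGTN]")


class SequenceInputError(RuntimeError):
    """Unreadable or malformed sequence input."""


@dataclass(frozen=True)
class ReadRecord:
    """One N-free, normalized read segment."""

    read_id: str
    sequence: str
    source_index: int


def _open_text(path: str | Path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _detect_format(handle) -> str:
    while True:
        ch = handle.read(1)
        if ch == "":
            raise SequenceInputError("empty input")
        if not ch.isspace():
            break
    handle.seek(0)
    if ch == ">":
        return "fasta"
    if ch == "@":
        return "fastq"
    raise SequenceInputError(
        f"cannot detect format: first character {ch!r} is neither '>' nor '@'"
    )


def _normalize(seq: str) -> str:
    return _NON_ACGTN.sub("N", seq.upper())


def stream_reads(paths: Iterable[str | Path]) -> Iterator[ReadRecord]:
    """Stream normalized, N-split read segments from FASTA/FASTQ files.

    Files are consumed in the given order, records in file order.  A read
    containing N splits into one record per maximal N-free segment, with
    ``/1``, ``/2``, ... appended to the read id; reads whose id duplicates an
    earlier one are disambiguated by appending their ordinal.  Each emitted
    record carries a sequential 0-based ``source_index``.
    """
    index = 0
    seen_ids: set[str] = set()
    for path in paths:
        path = Path(path)
        try:
            handle = _open_text(path)
        except OSError as exc:
            raise SequenceInputError(f"cannot read {path}: {exc}") from exc
        with handle:
            try:
                fmt = _detect_format(handle)
            except SequenceInputError as exc:
                raise SequenceInputError(f"{path}: {exc}") from exc
            parser = SeqIO.parse(handle, fmt)
            while True:
                try:
                    rec = next(parser)
                except StopIteration:
                    break
                except ValueError as exc:
                    raise SequenceInputError(
                        f"{path}: malformed {fmt} record: {exc}"
                    ) from exc
                base_id = rec.id or f"read{index}"
                if base_id in seen_ids:
                    base_id = f"{base_id}_{index}"
                seen_ids.add(base_id)
                segments = _ACGT_SEGMENT.findall(_normalize(str(rec.seq)))
                if len(segments) == 1:
                    yield ReadRecord(base_id, segments[0], index)
                    index += 1
                else:
                    for i, seg in enumerate(segments, start=1):
                        yield ReadRecord(f"{base_id}/{i}", seg, index)
                        index += 1
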