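"""Read hygiene: FASTQ I/O, exact-match adapter trimming, length filtering.

The analysis keeps reads of 18–30 nt (inclusive): the lower bound guarantees
each in-area read spans at least one diagnostic mismatch, the upper bound
admits a 23-nt siRNA core plus up to three non-templated 3' nucleotides plus
small Dicer-length jitter. Quality scores are carried but never used.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .references import normalize_seq

__all__ = ["ReadRecord", "read_fastq", "write_fastq", "trim_adapter", "length_filter"]


@dataclass(frozen=True)
class ReadRecord:
    """One small-RNA read, sequence U->T normalized."""

    id: str
    seq: str
    label: str | None = None  # optional ground-truth category (simulations)

    @property
    def length(self) -> int:
        return len(self.seq)


def read_fastq(path: str | Path) -> Iterator[ReadRecord]:
    for rec in SeqIO.parse(str(path), "fastq"):
        yield ReadRecord(id=rec.id, seq=normalize_seq(str(rec.seq), rec.id))


def write_fastq(reads: Iterable[ReadRecord], path: str | Path, qual_char: str = "I") -> int:
    """Write 4-line FASTQ records with constant Phred+33 quality."""
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual_char * len(r.seq)}\n")
            n += 1
    return n


def trim_adapter(read: ReadRecord, adapter: str) -> ReadRecord:
    """Cut the read at the leftmost exact occurrence of the full adapter.

    Empty adapter is a no-op; adapters shorter than 5 nt are rejected (too
    likely to occur by chance in an exact-match scheme).
    """
    if not adapter:
        return read
    adapter = normalize_seq(adapter, "adapter")
    if len(adapter) < 5:
        raise ValueError(f"adapter must be empty or >= 5 nt, got {len(adapter)} nt")
    idx = read.seq.find(adapter)
    if idx < 0:
        return read
    return replace(read, seq=read.seq[:idx])


def length_filter(
    reads: Iterable[ReadRecord], min_len: int = 18, max_len: int = 30
) -> tuple[list[ReadRecord], Counter]:
    """Keep reads with min_len <= length <= max_len (both inclusive).

    Returns (retained reads, tally of discarded reads keyed by length).
    """
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    kept: list[ReadRecord] = []
    discarded: Counter = Counter()
    for r in reads:
        if min_len <= r.length <= max_len:
            kept.append(r)
        else:
            discarded[r.length] += 1
    return kept, discarded
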