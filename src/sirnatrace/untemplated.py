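"""Iterative 3' trim-and-remap search for non-templated nucleotides, with
per-stratum sequence logos and tail-composition summaries.

A read that fails to map exactly may carry 3'-terminal bases absent from its
template (in this system, poly-U tails that mark sense-oriented siRNAs for
degradation). The search removes one base from the 3' end at a time and
re-attempts exact mapping, up to four mapping iterations in total, so tails of
up to three nucleotides are detectable; reads still unmapped after the fourth
iteration are unclassified. The first successful iteration wins, which makes
the reported tail the shortest suffix whose removal restores an exact match.

Mapping policy is identical to the primary mapper: no mismatches, and a call
requires a unique placement — or a concordant flank double-hit, which is
orientation-informative and receives a tail call like any other read. Trimmed
cores shorter than 15 nt (the 18-nt filter floor minus three trims) are never
attempted, preserving the read-length window arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable

import numpy as np
import pandas as pd

from .mapping import MappingHit, MappingResult, find_hits
from .preprocess import ReadRecord
from .references import HeteroduplexModel

__all__ = [
    "TailCall",
    "PositionLogo",
    "iterative_search",
    "build_logos",
    "tail_composition",
    "write_logos",
]

_ACCEPTED_VERDICTS = ("unique", "flank_ambiguous")
_RNA_ROWS = ("A", "C", "G", "U")


@dataclass(frozen=True)
class TailCall:
    """Outcome of the trim-and-remap search for one read."""

    read_id: str
    n_untemplated: int  # 0..max_tail
    tail_seq: str  # RNA alphabet (U, not T), length == n_untemplated
    result: MappingResult  # mapping of the templated core
    original_length: int

    @property
    def core_hit(self) -> MappingHit:
        return self.result.hits[0]

    @property
    def core_length(self) -> int:
        return self.original_length - self.n_untemplated

    @property
    def orientation(self) -> str:
        return self.core_hit.orientation


def iterative_search(
    read: ReadRecord,
    model: HeteroduplexModel,
    max_tail: int = 3,
    min_core: int = 15,
    mapper: Callable[[ReadRecord, HeteroduplexModel], MappingResult] = find_hits,
) -> TailCall | None:
    """Trim 0..max_tail bases from the 3' end, remapping after each trim.

    Returns the TailCall of the first iteration whose trimmed core maps with
    an accepted verdict, or None after max_tail + 1 failed attempts. A trim
    that produces a multimapping core yields no call at that iteration but
    iteration continues. `mapper` selects the reference set (heteroduplex
    strands by default; pass map_to_target for target-gene reads).
    """
    for k in range(0, max_tail + 1):
        core_len = read.length - k
        if core_len < min_core:
            break
        core = ReadRecord(id=read.id, seq=read.seq[:core_len])
        mr = mapper(core, model)
        if mr.verdict in _ACCEPTED_VERDICTS:
            return TailCall(
                read_id=read.id,
                n_untemplated=k,
                tail_seq=read.seq[core_len:].replace("T", "U"),
                result=mr,
                original_length=read.length,
            )
    return None


@dataclass
class PositionLogo:
    """Base counts and information content per position for one read stratum.

    Columns cover the full original read 5'->3' as sequenced; positions at
    index >= core length (`templated_length`) are the non-templated tail.
    IC per column is 2 + sum_b p_b log2 p_b (0 log 0 := 0), without
    small-sample correction.
    """

    read_length: int
    orientation: str
    n_untemplated: int
    counts: pd.DataFrame  # rows A/C/G/U, one column per position
    information_content: np.ndarray
    n_reads: int

    @property
    def templated_length(self) -> int:
        return self.read_length - self.n_untemplated


def _column_ic(counts: np.ndarray) -> np.ndarray:
    totals = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, counts / np.maximum(totals, 1), 0.0)
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return np.where(totals > 0, 2.0 + plogp.sum(axis=0), 0.0)


def build_logos(
    calls: Iterable[TailCall],
    reads_by_id: dict[str, ReadRecord],
    min_len: int = 18,
    max_len: int = 30,
) -> list[PositionLogo]:
    """Stratify tail-called reads by (orientation, read length, tail count)
    and compute a position frequency matrix plus per-column information
    content for each stratum. Strata without reads are skipped."""
    strata: dict[tuple[str, int, int], np.ndarray] = {}
    tallies: dict[tuple[str, int, int], int] = {}
    row_index = {b: i for i, b in enumerate(_RNA_ROWS)}
    for call in calls:
        L = call.original_length
        if not (min_len <= L <= max_len):
            continue
        key = (call.orientation, L, call.n_untemplated)
        mat = strata.setdefault(key, np.zeros((4, L), dtype=np.int64))
        seq = reads_by_id[call.read_id].seq.replace("T", "U")
        for j, b in enumerate(seq):
            if b in row_index:
                mat[row_index[b], j] += 1
        tallies[key] = tallies.get(key, 0) + 1

    logos = []
    for (orientation, L, k), mat in sorted(strata.items()):
        logos.append(
            PositionLogo(
                read_length=L,
                orientation=orientation,
                n_untemplated=k,
                counts=pd.DataFrame(mat, index=list(_RNA_ROWS),
                                    columns=list(range(1, L + 1))),
                information_content=_column_ic(mat),
                n_reads=tallies[(orientation, L, k)],
            )
        )
    return logos


def write_logos(logos: list[PositionLogo], out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for lg in logos:
        p = out / f"logo_{lg.orientation}_len{lg.read_length}_tail{lg.n_untemplated}.tsv"
        df = lg.counts.copy()
        df.loc["IC_bits"] = np.round(lg.information_content, 6)
        df.to_csv(p, sep="\t")
        paths.append(p)
    return paths


def tail_composition(calls: Iterable[TailCall]) -> pd.DataFrame:
    """Fraction of tails that are all-U, by orientation and tail length.

    Only reads with >= 1 non-templated nucleotide contribute. Returns columns
    orientation, tail_len, n, n_all_u, frac_all_u; empty strata simply do not
    appear (no NaN ratios are emitted).
    """
    rows: dict[tuple[str, int], list[int]] = {}
    for call in calls:
        if call.n_untemplated < 1:
            continue
        key = (call.orientation, call.n_untemplated)
        entry = rows.setdefault(key, [0, 0])
        entry[0] += 1
        entry[1] += int(set(call.tail_seq) == {"U"})
    return pd.DataFrame(
        [
            {
                "orientation": o,
                "tail_len": k,
                "n": n,
                "n_all_u": n_u,
                "frac_all_u": n_u / n,
            }
            for (o, k), (n, n_u) in sorted(rows.items())
        ],
        columns=["orientation", "tail_len", "n", "n_all_u", "frac_all_u"],
    )
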