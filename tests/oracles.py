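"""Independent mapping oracles, deliberately distinct from the implementation.

The implementation searches with str.find; these oracles check every start
position explicitly — one by pure slice comparison (tiny inputs), one
vectorized over a sliding byte-window view (larger sweeps). Both enumerate
hits and apply the verdict rules from first principles.
"""

from __future__ import annotations

import numpy as np

from sirnatrace.mapping import MappingHit, MappingResult
from sirnatrace.references import reverse_complement


def slice_occurrences(needle: str, haystack: str) -> list[int]:
    return [
        i
        for i in range(len(haystack) - len(needle) + 1)
        if haystack[i : i + len(needle)] == needle
    ]


def windowed_occurrences(needle: str, haystack: str) -> list[int]:
    """Check all positions at once on a sliding byte-window view."""
    n, m = len(haystack), len(needle)
    if m == 0 or m > n:
        return []
    hay = np.frombuffer(haystack.encode(), dtype=np.uint8)
    nee = np.frombuffer(needle.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(hay, m)
    return [int(i) for i in np.flatnonzero((windows == nee).all(axis=1))]


def oracle_find_hits(read, model, occurrences=slice_occurrences) -> MappingResult:
    refs = {
        "senseHD": model.sense_strand,
        "antisenseHD": model.antisense_strand_senseproj,
    }
    rc = reverse_complement(read.seq)
    hits = sorted(
        MappingHit(name, orient, start, len(read.seq))
        for name, ref in refs.items()
        for orient, query in (("sense", read.seq), ("antisense", rc))
        for start in occurrences(query, ref)
    )
    if not hits:
        verdict = "unmapped"
    elif len(hits) == 1:
        verdict = "unique"
    elif (
        len(hits) == 2
        and hits[0].reference != hits[1].reference
        and hits[0].start == hits[1].start
        and hits[0].orientation == hits[1].orientation
        and model.sense_strand[hits[0].start : hits[0].end]
        == model.antisense_strand_senseproj[hits[1].start : hits[1].end]
    ):
        verdict = "flank_ambiguous"
    else:
        verdict = "multimapped"
    return MappingResult(read.id, tuple(hits), verdict)
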