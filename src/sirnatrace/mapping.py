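"""Exact, strand-aware read placement with a no-mismatch / no-multimap policy.

Reads are matched, with zero mismatches, against the two heteroduplex strands
(both stored in mRNA-sense orientation) in both orientations. A read maps
`sense` where its sequence occurs verbatim in a reference and `antisense`
where its reverse complement does. Uniqueness is required for a strand call,
with one deliberate exception: a read from the mismatch-free flanks occurs at
the same position on both strands in the same orientation — such concordant
double hits are retained as `flank_ambiguous` (orientation is still
informative; strand of origin is not). Any other multi-hit configuration is
discarded as `multimapped`. Sequencing errors surface as `unmapped` because no
mismatch tolerance exists anywhere.

References are at most a few kb, so hit search is a full overlapping scan; it
must agree exactly with a naive position-by-position oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

from .preprocess import ReadRecord
from .references import HeteroduplexModel, reverse_complement

__all__ = ["MappingHit", "MappingResult", "find_hits", "map_to_target", "find_occurrences"]

HD_REFERENCES = ("senseHD", "antisenseHD")


@dataclass(frozen=True, order=True)
class MappingHit:
    reference: str  # senseHD | antisenseHD | target
    orientation: str  # sense | antisense
    start: int  # 0-based on the sense-orientation reference
    length: int

    @property
    def end(self) -> int:
        """Half-open end coordinate."""
        return self.start + self.length

    @property
    def five_prime(self) -> int:
        """Reference coordinate of the read's 5' end."""
        return self.start if self.orientation == "sense" else self.end - 1


@dataclass(frozen=True)
class MappingResult:
    read_id: str
    hits: tuple[MappingHit, ...]
    verdict: str  # unique | flank_ambiguous | multimapped | unmapped

    @property
    def primary_hit(self) -> MappingHit | None:
        """The single informative hit (first of the concordant pair for flanks)."""
        return self.hits[0] if self.hits else None


def find_occurrences(needle: str, haystack: str) -> list[int]:
    """All start positions of overlapping exact occurrences."""
    if not needle:
        return []
    out = []
    i = haystack.find(needle)
    while i >= 0:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _scan(seq: str, references: dict[str, str]) -> list[MappingHit]:
    rc = reverse_complement(seq)
    hits = []
    for name, ref in references.items():
        for start in find_occurrences(seq, ref):
            hits.append(MappingHit(name, "sense", start, len(seq)))
        for start in find_occurrences(rc, ref):
            hits.append(MappingHit(name, "antisense", start, len(seq)))
    return sorted(hits)


def _verdict(hits: list[MappingHit], flank_aware: bool) -> str:
    if not hits:
        return "unmapped"
    if len(hits) == 1:
        return "unique"
    if (
        flank_aware
        and len(hits) == 2
        and {h.reference for h in hits} == set(HD_REFERENCES)
        and hits[0].start == hits[1].start
        and hits[0].orientation == hits[1].orientation
    ):
        # exact matching of the same read at the same locus on both strands
        # implies the underlying subsequences are identical
        return "flank_ambiguous"
    return "multimapped"


def find_hits(read: ReadRecord, model: HeteroduplexModel) -> MappingResult:
    """Map a read against both heteroduplex strands simultaneously."""
    hits = _scan(
        read.seq,
        {
            "senseHD": model.sense_strand,
            "antisenseHD": model.antisense_strand_senseproj,
        },
    )
    return MappingResult(read.id, tuple(hits), _verdict(hits, flank_aware=True))


def map_to_target(read: ReadRecord, model: HeteroduplexModel) -> MappingResult:
    """Map a read against the endogenous target gene (no flank concept)."""
    hits = _scan(read.seq, {"target": model.target_gene})
    return MappingResult(read.id, tuple(hits), _verdict(hits, flank_aware=False))
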