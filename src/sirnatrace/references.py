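"""Heteroduplex/target sequence model and mismatch-design validation.

A heteroduplex dsRNA is a designed double-stranded trigger whose two strands
carry deliberate mismatches against each other (and against the target mRNA)
inside a central *mismatch area*, flanked by regions identical on both strands
and to the mRNA. Sequenced siRNAs that cover at least one diagnostic mismatch
betray which applied strand templated them; combined with read orientation this
separates exogenously applied RNA from RDR (RNA-dependent RNA polymerase)
transcription products.

Both strands are stored projected into mRNA-sense orientation, so "sense" /
"antisense" always means orientation relative to the endogenous mRNA, and the
downstream four-way provenance classification is a pure (reference,
orientation) pair. Coordinates are 0-based half-open internally; human-readable
reports use 1-based closed intervals. U is normalized to T at every input
boundary (sequencers emit T; tails are rendered back as U where RNA is meant).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "HeteroduplexModel",
    "DesignReport",
    "normalize_seq",
    "reverse_complement",
    "build_model",
    "load_model",
    "write_model_fasta",
    "validate_design",
    "toy_model",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


def normalize_seq(seq: str, context: str = "sequence") -> str:
    """Uppercase, map U->T, and reject non-nucleotide characters.

    Raises ValueError naming the offending 0-based position.
    """
    s = str(seq).strip().upper().replace("U", "T")
    for i, c in enumerate(s):
        if c not in _VALID:
            raise ValueError(
                f"non-nucleotide character {c!r} at position {i} in {context}"
            )
    return s


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; U accepted on input."""
    return normalize_seq(seq).translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class HeteroduplexModel:
    """The two applied strands (sense projection), the target gene, and the
    diagnostic mismatch bookkeeping derived from them.

    feeding_fragment is the half-open interval of target_gene covered by the
    applied duplex; mismatch_area is half-open on the heteroduplex coordinate
    system (position 0 = feeding_fragment start).
    """

    sense_strand: str
    antisense_strand_senseproj: str
    target_gene: str
    feeding_fragment: tuple[int, int]
    mismatch_area: tuple[int, int]
    interstrand_mismatches: tuple[int, ...]
    target_mismatches_sense: tuple[int, ...]
    target_mismatches_antisense: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.sense_strand)

    @property
    def antisense_strand_applied(self) -> str:
        """The physically applied antisense ssRNA (DNA alphabet)."""
        return reverse_complement(self.antisense_strand_senseproj)

    def reference(self, name: str) -> str:
        """Mapping reference sequence by name: senseHD | antisenseHD | target."""
        if name == "senseHD":
            return self.sense_strand
        if name == "antisenseHD":
            return self.antisense_strand_senseproj
        if name == "target":
            return self.target_gene
        raise KeyError(f"unknown reference {name!r}")

    def flank_intervals(self) -> list[tuple[int, int]]:
        """Half-open heteroduplex intervals outside the mismatch area."""
        a0, a1 = self.mismatch_area
        out = []
        if a0 > 0:
            out.append((0, a0))
        if a1 < len(self):
            out.append((a1, len(self)))
        return out


def _diff_positions(a: str, b: str) -> tuple[int, ...]:
    return tuple(int(i) for i in np.flatnonzero(
        np.frombuffer(a.encode(), dtype=np.uint8)
        != np.frombuffer(b.encode(), dtype=np.uint8)
    ))


def build_model(
    sense_strand: str,
    antisense_strand_applied: str,
    target_gene: str,
    feeding_fragment: tuple[int, int],
    mismatch_area: tuple[int, int],
) -> HeteroduplexModel:
    """Build and validate a HeteroduplexModel.

    `antisense_strand_applied` is the physically applied antisense ssRNA; it is
    projected into mRNA-sense orientation via reverse complement before any
    comparison. Validation fails if the strands differ in length, the feeding
    fragment does not match the duplex length, or any inter-strand mismatch
    lies outside the declared mismatch area (the flanks must be clean, or the
    flank analysis is meaningless).
    """
    sense = normalize_seq(sense_strand, "sense strand")
    anti_proj = reverse_complement(antisense_strand_applied)
    target = normalize_seq(target_gene, "target gene")

    if len(sense) != len(anti_proj):
        raise ValueError(
            f"strand length mismatch: sense {len(sense)} nt vs antisense "
            f"projection {len(anti_proj)} nt"
        )
    f0, f1 = int(feeding_fragment[0]), int(feeding_fragment[1])
    if not (0 <= f0 < f1 <= len(target)):
        raise ValueError(f"feeding_fragment {feeding_fragment} outside target")
    if f1 - f0 != len(sense):
        raise ValueError(
            f"feeding_fragment length {f1 - f0} != heteroduplex length {len(sense)}"
        )
    a0, a1 = int(mismatch_area[0]), int(mismatch_area[1])
    if not (0 <= a0 <= a1 <= len(sense)):
        raise ValueError(f"mismatch_area {mismatch_area} outside heteroduplex")

    inter = _diff_positions(sense, anti_proj)
    outside = [p for p in inter if not (a0 <= p < a1)]
    if outside:
        raise ValueError(
            "inter-strand mismatch outside declared mismatch_area at "
            f"positions {outside} (1-based: {[p + 1 for p in outside]})"
        )
    frag = target[f0:f1]
    return HeteroduplexModel(
        sense_strand=sense,
        antisense_strand_senseproj=anti_proj,
        target_gene=target,
        feeding_fragment=(f0, f1),
        mismatch_area=(a0, a1),
        interstrand_mismatches=inter,
        target_mismatches_sense=_diff_positions(sense, frag),
        target_mismatches_antisense=_diff_positions(anti_proj, frag),
    )


def _read_fasta_record(path: str | Path, record_id: str | None = None) -> str:
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if record_id is None:
        return str(records[0].seq)
    for rec in records:
        if rec.id == record_id:
            return str(rec.seq)
    raise KeyError(f"record {record_id!r} not found in {path}")


def load_model(
    sense_fasta: str | Path,
    antisense_fasta: str | Path,
    target_fasta: str | Path,
    feeding_fragment: tuple[int, int],
    mismatch_area: tuple[int, int],
    sense_id: str | None = None,
    antisense_id: str | None = None,
    target_id: str | None = None,
) -> HeteroduplexModel:
    """Build a model from FASTA files (antisense given as the applied ssRNA)."""
    return build_model(
        _read_fasta_record(sense_fasta, sense_id),
        _read_fasta_record(antisense_fasta, antisense_id),
        _read_fasta_record(target_fasta, target_id),
        feeding_fragment,
        mismatch_area,
    )


def write_model_fasta(model: HeteroduplexModel, out_dir: str | Path) -> dict[str, Path]:
    """Serialize the model to three FASTA files (antisense as applied strand).

    Re-loading via load_model with the model's intervals reproduces identical
    mismatch lists.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, seq in (
        ("sense", model.sense_strand),
        ("antisense", model.antisense_strand_applied),
        ("target", model.target_gene),
    ):
        p = out / f"{name}.fasta"
        SeqIO.write([SeqRecord(Seq(seq), id=name, description="")], str(p), "fasta")
        paths[name] = p
    return paths


@dataclass(frozen=True)
class DesignReport:
    """Outcome of the diagnostic-coverage check of a heteroduplex design."""

    passed: bool
    min_read_len: int
    n_diagnostic: int
    violating_windows: tuple[tuple[int, int], ...]  # half-open, HD coords
    max_gap: int

    def to_dict(self) -> dict:
        return {
            "passed": self.passed,
            "min_read_len": self.min_read_len,
            "n_diagnostic_positions": self.n_diagnostic,
            "n_violating_windows": len(self.violating_windows),
            # 1-based closed intervals for the human-readable report
            "violating_windows_1based": [
                [s + 1, e] for s, e in self.violating_windows
            ],
            "max_gap_between_diagnostics": self.max_gap,
        }


def validate_design(model: HeteroduplexModel, min_read_len: int = 18) -> DesignReport:
    """Check that every read-sized window inside the mismatch area carries at
    least one inter-strand mismatch.

    The length filter keeps reads >= min_read_len precisely so each retained
    in-area read covers a diagnostic position; a design passes iff every window
    of min_read_len fully contained in the mismatch area contains >= 1
    inter-strand mismatch (equivalently, the maximum gap between consecutive
    diagnostic positions, including the area boundaries, is < min_read_len).
    """
    if min_read_len < 1:
        raise ValueError("min_read_len must be >= 1")
    a0, a1 = model.mismatch_area
    positions = [p for p in model.interstrand_mismatches if a0 <= p < a1]

    # prefix counts of diagnostics over the area
    mask = np.zeros(len(model) + 1, dtype=np.int64)
    for p in positions:
        mask[p + 1] = 1
    csum = np.cumsum(mask)

    violating = []
    for start in range(a0, a1 - min_read_len + 1):
        if csum[start + min_read_len] - csum[start] == 0:
            violating.append((start, start + min_read_len))

    # largest diagnostic-free stretch, boundaries included
    bounds = [a0 - 1] + positions + [a1]
    max_gap = max((b - a - 1 for a, b in zip(bounds, bounds[1:])), default=a1 - a0)
    return DesignReport(
        passed=not violating,
        min_read_len=min_read_len,
        n_diagnostic=len(positions),
        violating_windows=tuple(violating),
        max_gap=int(max_gap),
    )


_ROT = {"A": "C", "C": "G", "G": "T", "T": "A"}


def toy_model(
    seed: int = 20240901,
    target_len: int = 1200,
    feeding_fragment: tuple[int, int] = (300, 800),
    mismatch_area: tuple[int, int] = (100, 400),
    spacing: int = 12,
) -> HeteroduplexModel:
    """A documented, representative heteroduplex design on a random target.

    Synthetic stand-in for a real design (whose exact mismatch coordinates are
    not part of this package): diagnostic inter-strand mismatches are placed
    every `spacing` nt across the mismatch area — the sense strand base is
    rotated one step and the antisense-projection base two steps, so both
    strands also differ from the mRNA there — and every fourth diagnostic
    position additionally carries a sense-strand-only edit relative to the
    mRNA. With spacing 12 < 18 the design passes validate_design(18).
    """
    rng = np.random.default_rng(seed)
    target = "".join(rng.choice(list("ACGT"), size=target_len))
    f0, f1 = feeding_fragment
    frag = target[f0:f1]
    a0, a1 = mismatch_area

    sense = list(frag)
    anti = list(frag)
    first = a0 + spacing // 2
    for k, p in enumerate(range(first, a1 - 2, spacing)):
        base = frag[p]
        sense[p] = _ROT[base]
        anti[p] = _ROT[_ROT[base]]
        if k % 4 == 0 and p + 3 < a1 - 2:
            # sense-only edit vs mRNA (antisense projection keeps the mRNA base)
            q = p + 3
            sense[q] = _ROT[frag[q]]
    sense_s = "".join(sense)
    anti_proj = "".join(anti)
    return build_model(
        sense_s,
        reverse_complement(anti_proj),  # applied antisense ssRNA
        target,
        feeding_fragment,
        mismatch_area,
    )
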