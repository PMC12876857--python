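"""Provenance classification and signature summary tables.

The four-way strand dissection is a pure lookup on (reference, orientation)
of a unique heteroduplex hit: a read in the native orientation of the strand
whose mismatch signature it carries (senseHD_sense, antisenseHD_antisense)
derives from the exogenously applied dsRNA, while a read carrying one strand's
signature in the opposite orientation (senseHD_antisense, antisenseHD_sense)
must be an RDR transcription product. Concordant flank double-hits keep their
orientation only; unique target-gene hits clear of the feeding fragment are
secondary siRNAs; everything else is unassigned.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mapping import HD_REFERENCES, MappingResult
from .preprocess import ReadRecord
from .references import HeteroduplexModel
from .simdata import CATEGORIES, FLANK_CATEGORIES, HD_CATEGORIES

__all__ = ["ProvenanceCall", "SignatureTables", "classify_read", "summarize"]

EXOGENOUS_CATEGORIES = ("senseHD_sense", "antisenseHD_antisense")
RDR_CATEGORIES = ("senseHD_antisense", "antisenseHD_sense")
PRIMARY_CATEGORIES = HD_CATEGORIES + FLANK_CATEGORIES
CALL_CATEGORIES = PRIMARY_CATEGORIES + ("secondary_mRNA", "unassigned")


@dataclass(frozen=True)
class ProvenanceCall:
    read_id: str
    category: str
    core_length: int | None = None
    start: int | None = None
    reference: str | None = None
    orientation: str | None = None
    n_untemplated: int = 0
    tail_seq: str = ""


def classify_read(mr: MappingResult, model: HeteroduplexModel,
                  n_untemplated: int = 0, tail_seq: str = "") -> ProvenanceCall:
    """Turn one mapping result into a provenance call.

    `mr` is the result of find_hits, or of map_to_target for reads that found
    no unique heteroduplex placement (pipeline order). Tail annotation, when
    the read went through the untemplated-nucleotide search, is carried along.
    """
    if mr.verdict == "unique":
        hit = mr.hits[0]
        if hit.reference in HD_REFERENCES:
            category = f"{hit.reference}_{hit.orientation}"
        elif hit.reference == "target":
            f0, f1 = model.feeding_fragment
            outside = hit.end <= f0 or hit.start >= f1
            category = "secondary_mRNA" if outside else "unassigned"
        else:  # pragma: no cover - references are fixed upstream
            category = "unassigned"
    elif mr.verdict == "flank_ambiguous":
        category = f"flank_{mr.hits[0].orientation}"
    else:
        category = "unassigned"

    hit = mr.primary_hit if category != "unassigned" else None
    return ProvenanceCall(
        read_id=mr.read_id,
        category=category,
        core_length=hit.length if hit else None,
        start=hit.start if hit else None,
        reference=hit.reference if hit else None,
        orientation=hit.orientation if hit else None,
        n_untemplated=n_untemplated,
        tail_seq=tail_seq,
    )


@dataclass
class SignatureTables:
    """Per-category length distributions, coverage, and headline ratios.

    category_ratios: each heteroduplex category's share of all 23-nt-core
    heteroduplex-mapped reads. ratio_23nt_vs_total: 23-nt-core heteroduplex
    reads over all input reads. secondary_primary_ratio: secondary over
    primary 23-nt-core read counts, where primary = the four strand
    categories plus the two flank categories; the siRNA class is exactly
    core length 23 after tail removal, which keeps degradation fragments
    that happen to map out of the ratio. Denominators are recorded in
    metadata; a None ratio flags an empty denominator.
    """

    length_distribution: pd.DataFrame  # columns: category, length, count
    coverage: pd.DataFrame  # columns: reference, position, category, orientation, count
    category_ratios: dict[str, float | None]
    ratio_23nt_vs_total: float | None
    secondary_primary_ratio: float | None
    category_counts: dict[str, int]
    metadata: dict = field(default_factory=dict)

    def summary_dict(self) -> dict:
        return {
            "category_counts": self.category_counts,
            "category_ratios": self.category_ratios,
            "ratio_23nt_vs_total": self.ratio_23nt_vs_total,
            "secondary_primary_ratio": self.secondary_primary_ratio,
            "metadata": self.metadata,
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.length_distribution.to_csv(out / "length_distribution.tsv", sep="\t", index=False)
        cov = self.coverage.copy()
        cov["position"] = cov["position"] + 1  # 1-based in exports
        cov.to_csv(out / "coverage.tsv", sep="\t", index=False)
        ratios = pd.DataFrame(
            [{"category": c, "ratio": r} for c, r in self.category_ratios.items()]
        )
        ratios.to_csv(out / "category_ratios.tsv", sep="\t", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def summarize(
    calls: list[ProvenanceCall],
    reads: list[ReadRecord],
    n_total_reads: int | None = None,
) -> SignatureTables:
    """Aggregate provenance calls into the signature tables.

    `reads` are the length-filtered reads the calls were made on (original
    lengths, tails included); `n_total_reads` is the denominator for the
    23-nt-vs-total ratio and defaults to len(reads). Empty inputs yield
    zero-filled tables with None-flagged ratios.
    """
    if n_total_reads is None:
        n_total_reads = len(reads)
    lengths = {r.id: r.length for r in reads}

    counts: dict[str, int] = {c: 0 for c in CALL_CATEGORIES}
    len_rows: dict[tuple[str, int], int] = {}
    cov_rows: dict[tuple[str, int, str, str], int] = {}
    n_hd_23 = 0
    n_secondary_23 = 0
    hd23_by_cat: dict[str, int] = {c: 0 for c in HD_CATEGORIES}

    for call in calls:
        if call.category == "secondary_mRNA" and call.core_length == 23:
            n_secondary_23 += 1
        counts[call.category] += 1
        read_len = lengths.get(call.read_id)
        if read_len is not None:
            key = (call.category, read_len)
            len_rows[key] = len_rows.get(key, 0) + 1
        if call.category in PRIMARY_CATEGORIES and call.core_length == 23:
            n_hd_23 += 1
            if call.category in HD_CATEGORIES:
                hd23_by_cat[call.category] += 1
        if call.start is not None and call.reference is not None:
            ref = "senseHD" if call.reference == "both" else call.reference
            for pos in range(call.start, call.start + call.core_length):
                k = (ref, pos, call.category, call.orientation)
                cov_rows[k] = cov_rows.get(k, 0) + 1

    length_distribution = pd.DataFrame(
        [{"category": c, "length": l, "count": n} for (c, l), n in sorted(len_rows.items())],
        columns=["category", "length", "count"],
    )
    coverage = pd.DataFrame(
        [
            {"reference": r, "position": p, "category": c, "orientation": o, "count": n}
            for (r, p, c, o), n in sorted(cov_rows.items())
        ],
        columns=["reference", "position", "category", "orientation", "count"],
    )

    n_hd4_23 = sum(hd23_by_cat.values())
    category_ratios = {
        c: (hd23_by_cat[c] / n_hd4_23 if n_hd4_23 else None) for c in HD_CATEGORIES
    }
    n_primary = sum(counts[c] for c in PRIMARY_CATEGORIES)
    n_secondary = counts["secondary_mRNA"]
    return SignatureTables(
        length_distribution=length_distribution,
        coverage=coverage,
        category_ratios=category_ratios,
        ratio_23nt_vs_total=(n_hd_23 / n_total_reads if n_total_reads else None),
        secondary_primary_ratio=(n_secondary_23 / n_hd_23 if n_hd_23 else None),
        category_counts=counts,
        metadata={
            "n_total_reads": n_total_reads,
            "n_classified_reads": len(calls),
            "n_primary": n_primary,
            "n_secondary": n_secondary,
            "n_primary_core23": n_hd_23,
            "n_secondary_core23": n_secondary_23,
            "n_heteroduplex_core23": n_hd_23,
            "n_strand_categories_core23": n_hd4_23,
            "denominators": {
                "category_ratios": "23-nt-core reads in the four strand categories",
                "ratio_23nt_vs_total": "all reads entering classification "
                                       "(post-trim, pre-length-filter)",
                "secondary_primary_ratio": "23-nt-core reads only; primary = "
                                           "four strand categories + flanks",
            },
        },
    )
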