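"""Synthetic small-RNA library generator with ground truth.

Emulates the statistical structure of heteroduplex-feeding sRNA-seq libraries:
a 23-nt-dominant siRNA population drawn from the four strand/orientation
provenance categories with an antisense bias, mismatch-free flank reads,
poly-U 3' tails on sense-oriented reads versus random-base tails on
antisense-oriented reads, degradation fragments spanning the length filter's
boundaries, and a low-abundance secondary-siRNA class antisense to the target
mRNA outside the feeding fragment. Mutant presets remove the
RDR/Dicer-dependent classes and leave only degradation products.

Ground truth travels in a side table keyed by read id — never in the FASTQ
headers — so the pipeline under test cannot cheat. All randomness flows from
one numpy Generator; the per-read draw order is fixed (category, then core
length, then placement, then tail length, then tail bases) so a seed pins the
output byte-for-byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import ReadRecord
from .references import HeteroduplexModel, reverse_complement

__all__ = [
    "CATEGORIES",
    "HD_CATEGORIES",
    "FLANK_CATEGORIES",
    "SimulationConfig",
    "preset",
    "simulate_library",
    "write_truth",
    "read_truth",
]

HD_CATEGORIES = (
    "senseHD_sense",
    "senseHD_antisense",
    "antisenseHD_sense",
    "antisenseHD_antisense",
)
FLANK_CATEGORIES = ("flank_sense", "flank_antisense")
CATEGORIES = HD_CATEGORIES + FLANK_CATEGORIES + ("secondary_mRNA", "degradation")

# Dicer-length jitter around the dominant 23-nt product
_DEFAULT_CORE_LENGTHS = {21: 0.05, 22: 0.15, 23: 0.60, 24: 0.15, 25: 0.05}
# tail lengths 0..3; the trim-and-remap search cannot see beyond 3
_DEFAULT_TAIL_PROBS = {0: 0.55, 1: 0.20, 2: 0.18, 3: 0.07}

MUTANT_PRESETS = ("wildtype", "rdr1_null", "rdr2_truncation", "rdr2_hypomorph")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_reads: int = 10_000
    category_weights: dict[str, float] = field(default_factory=dict)
    core_length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_CORE_LENGTHS)
    )
    tail_len_probs: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_TAIL_PROBS)
    )
    secondary_ratio: float = 0.03
    mutant_preset: str = "wildtype"

    def validate(self) -> None:
        if set(self.category_weights) - set(CATEGORIES):
            raise ValueError(
                f"unknown categories: {sorted(set(self.category_weights) - set(CATEGORIES))}"
            )
        total = sum(self.category_weights.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"category_weights sum to {total}, not 1")
        if any(w < 0 for w in self.category_weights.values()):
            raise ValueError("category_weights must be non-negative")
        if any(k > 3 or k < 0 for k in self.tail_len_probs):
            raise ValueError("tail lengths are limited to 0..3")
        if not np.isclose(sum(self.tail_len_probs.values()), 1.0, atol=1e-9):
            raise ValueError("tail_len_probs must sum to 1")
        if not np.isclose(sum(self.core_length_distribution.values()), 1.0, atol=1e-9):
            raise ValueError("core_length_distribution must sum to 1")


def _normalized(weights: dict[str, float]) -> dict[str, float]:
    total = sum(weights.values())
    return {c: weights.get(c, 0.0) / total for c in CATEGORIES}


def preset(name: str, seed: int = 0, n_reads: int = 10_000, **overrides) -> SimulationConfig:
    """Named library compositions.

    wildtype: all eight categories present, antisense-oriented siRNA classes
    ~2.5x their sense-oriented counterparts, secondary/primary read ratio 0.03.
    rdr1_null / rdr2_truncation: no 23-nt siRNA classes at all — only
    degradation products. rdr2_hypomorph: siRNA classes reduced (15% of
    wild-type share) but detectable.
    """
    if name not in MUTANT_PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {MUTANT_PRESETS}")

    secondary_ratio = overrides.pop("secondary_ratio", 0.03)
    base = {
        "senseHD_sense": 0.08,
        "senseHD_antisense": 0.20,  # RDR copy of the sense strand, antisense-oriented
        "antisenseHD_sense": 0.08,  # RDR copy of the antisense strand
        "antisenseHD_antisense": 0.20,
        "flank_sense": 0.03,
        "flank_antisense": 0.075,
    }
    if name in ("rdr1_null", "rdr2_truncation"):
        base = {c: 0.0 for c in base}
        secondary_ratio = 0.0
    elif name == "rdr2_hypomorph":
        base = {c: 0.15 * w for c, w in base.items()}

    primary = sum(base.values())
    base["secondary_mRNA"] = secondary_ratio * primary
    # degradation absorbs the remaining mass (>= 0.315 even for wildtype)
    base["degradation"] = 1.0 - sum(base.values())
    weights = _normalized(base)
    cfg = SimulationConfig(
        seed=seed,
        n_reads=n_reads,
        category_weights=weights,
        secondary_ratio=secondary_ratio,
        mutant_preset=name,
        **overrides,
    )
    cfg.validate()
    return cfg


def _window_start(rng, intervals: list[tuple[int, int]], length: int) -> int | None:
    """Uniform start of a length-`length` window fully inside one interval."""
    spans = [(lo, hi - lo - length + 1) for lo, hi in intervals if hi - lo >= length]
    total = sum(n for _, n in spans)
    if total == 0:
        return None
    k = int(rng.integers(0, total))
    for lo, n in spans:
        if k < n:
            return lo + k
        k -= n
    raise AssertionError("unreachable")


def simulate_library(
    model: HeteroduplexModel,
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Draw a library and its truth table.

    Reads are emitted 5'->3' as sequenced: antisense-oriented reads are
    reverse-complemented reference substrings, and any 3' tail is appended to
    the sequenced read after orientation is applied. Heteroduplex-category
    cores are placed fully inside the mismatch area (so each is strand-
    diagnostic); flank cores fully outside it; secondary cores on the target
    outside the feeding fragment, always antisense; degradation fragments are
    unmodified substrings of either strand in either orientation with lengths
    15–35 that deliberately straddle the length filter.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)

    cats = list(CATEGORIES)
    weights = np.array([cfg.category_weights.get(c, 0.0) for c in cats])
    if weights.sum() == 0:
        raise ValueError("all category weights are zero")
    weights = weights / weights.sum()

    core_lens = np.array(sorted(cfg.core_length_distribution))
    core_p = np.array([cfg.core_length_distribution[k] for k in core_lens], dtype=float)
    core_p /= core_p.sum()
    tail_lens = np.array(sorted(cfg.tail_len_probs))
    tail_p = np.array([cfg.tail_len_probs[k] for k in tail_lens], dtype=float)
    tail_p /= tail_p.sum()

    a0, a1 = model.mismatch_area
    f0, f1 = model.feeding_fragment
    flanks = model.flank_intervals()
    target_outside = [(0, f0), (f1, len(model.target_gene))]
    bases = np.array(list("ACGT"))

    reads: list[ReadRecord] = []
    rows: list[dict] = []
    for i in range(cfg.n_reads):
        read_id = f"simread_{i:07d}"
        cat = cats[int(rng.choice(len(cats), p=weights))]

        if cat == "degradation":
            length = int(rng.integers(15, 36))
            reference = ("senseHD", "antisenseHD")[int(rng.integers(0, 2))]
            orientation = ("sense", "antisense")[int(rng.integers(0, 2))]
            start = _window_start(rng, [(0, len(model))], length)
            tail = ""
        elif cat == "secondary_mRNA":
            length = int(core_lens[int(rng.choice(len(core_lens), p=core_p))])
            reference, orientation = "target", "antisense"
            start = _window_start(rng, target_outside, length)
            tail = ""
        else:
            length = int(core_lens[int(rng.choice(len(core_lens), p=core_p))])
            orientation = cat.rsplit("_", 1)[1]
            if cat in FLANK_CATEGORIES:
                reference = "both"
                start = _window_start(rng, flanks, length)
            else:
                reference = cat.rsplit("_", 1)[0]
                start = _window_start(rng, [(a0, a1)], length)
            k = int(tail_lens[int(rng.choice(len(tail_lens), p=tail_p))])
            if orientation == "sense":
                tail = "T" * k
            else:
                tail = "".join(bases[rng.integers(0, 4, size=k)]) if k else ""
        if start is None:
            raise ValueError(f"no room for a {length}-nt {cat} read in the model")

        ref_seq = model.sense_strand if reference in ("senseHD", "both") else (
            model.antisense_strand_senseproj if reference == "antisenseHD"
            else model.target_gene
        )
        core = ref_seq[start : start + length]
        seq = (core if orientation == "sense" else reverse_complement(core)) + tail
        reads.append(ReadRecord(id=read_id, seq=seq))
        rows.append(
            {
                "read_id": read_id,
                "category": cat,
                "reference": reference,
                "orientation": orientation,
                "core_start": start,
                "core_len": length,
                "tail": tail.replace("T", "U"),
            }
        )

    truth = pd.DataFrame(
        rows,
        columns=["read_id", "category", "reference", "orientation",
                 "core_start", "core_len", "tail"],
    )
    return reads, truth


def write_truth(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"tail": str})
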