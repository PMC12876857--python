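"""End-to-end orchestration: config handling, staged execution, run manifest,
and report rendering.

One structured YAML config drives a run; all randomness flows from a single
`seed` key. Stages: (optional) simulate -> preprocess -> mapping + tail search
-> classify -> summarize -> overlap -> report. Outputs land in a run directory
under fixed filenames; plots are optional and rendering failures degrade to
warnings (the TSV/JSON outputs are the contract).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import (
    PRIMARY_CATEGORIES,
    ProvenanceCall,
    SignatureTables,
    classify_read,
    summarize,
)
from .mapping import MappingHit, MappingResult, map_to_target
from .overlap import OverlapHistogram, overlap_signature
from .preprocess import ReadRecord, length_filter, read_fastq, trim_adapter, write_fastq
from .references import HeteroduplexModel, load_model, toy_model, validate_design
from .simdata import preset, simulate_library, write_truth
from .untemplated import TailCall, build_logos, iterative_search, tail_composition, write_logos

__all__ = [
    "ConfigError",
    "DesignError",
    "load_config",
    "model_from_config",
    "call_read",
    "run_pipeline",
    "render_report",
    "aggregate_replicates",
]

log = logging.getLogger("sirnatrace")


class ConfigError(ValueError):
    """Malformed or incomplete run configuration."""


class DesignError(RuntimeError):
    """Heteroduplex design failed validation; carries the report."""

    def __init__(self, report):
        self.report = report
        super().__init__(
            f"heteroduplex design failed validation: {len(report.violating_windows)} "
            f"window(s) without a diagnostic mismatch (max gap {report.max_gap} nt)"
        )


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ConfigError("config root must be a mapping")
    return cfg


def _require(block: dict, key: str, where: str):
    if key not in block:
        raise ConfigError(f"missing config key {where}.{key}")
    return block[key]


def model_from_config(cfg: dict, seed: int = 0) -> HeteroduplexModel:
    """Build the HeteroduplexModel from the `references:` block."""
    if "references" not in cfg:
        raise ConfigError("missing config key references")
    refs = cfg["references"]
    if refs.get("builtin") == "toy":
        return toy_model(seed=int(refs.get("toy_seed", 20240901)))
    ff = tuple(_require(refs, "feeding_fragment", "references"))
    area = tuple(_require(refs, "mismatch_area", "references"))
    return load_model(
        _require(refs, "sense_fasta", "references"),
        _require(refs, "antisense_fasta", "references"),
        _require(refs, "target_fasta", "references"),
        ff,
        area,
        sense_id=refs.get("sense_id"),
        antisense_id=refs.get("antisense_id"),
        target_id=refs.get("target_id"),
    )


def call_read(
    read: ReadRecord, model: HeteroduplexModel, max_tail: int = 3
) -> tuple[TailCall | None, ProvenanceCall]:
    """Full per-read pipeline: heteroduplex tail search first, target-gene
    tail search for reads without a heteroduplex placement, then the
    provenance call."""
    tc = iterative_search(read, model, max_tail=max_tail)
    if tc is None:
        tc = iterative_search(read, model, max_tail=max_tail, mapper=map_to_target)
    if tc is None:
        return None, classify_read(MappingResult(read.id, (), "unmapped"), model)
    return tc, classify_read(
        tc.result, model, n_untemplated=tc.n_untemplated, tail_seq=tc.tail_seq
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _calls_frame(pairs: list[tuple[TailCall | None, ProvenanceCall]]) -> pd.DataFrame:
    rows = []
    for tc, call in pairs:
        rows.append(
            {
                "read_id": call.read_id,
                "category": call.category,
                "reference": call.reference or "",
                "orientation": call.orientation or "",
                "core_start": "" if call.start is None else call.start,
                "core_len": "" if call.core_length is None else call.core_length,
                "n_untemplated": tc.n_untemplated if tc else "",
                "tail": tc.tail_seq if tc else "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=["read_id", "category", "reference", "orientation",
                 "core_start", "core_len", "n_untemplated", "tail"],
    )


def _overlap_hits(pairs) -> list[MappingHit]:
    """Core hits of primary-category reads; flank reads contribute once, on
    the sense-strand coordinate system (identical on both strands)."""
    hits = []
    for tc, call in pairs:
        if tc is None or call.category not in PRIMARY_CATEGORIES:
            continue
        ref = "senseHD" if call.reference == "both" else call.reference
        hits.append(MappingHit(ref, call.orientation, call.start, call.core_length))
    return hits


def run_pipeline(config: dict | str | Path, output_dir: str | Path | None = None) -> Path:
    """Execute the configured run; returns the output directory.

    Aborts with DesignError (writing the design report first) if the
    heteroduplex design fails validation, and with ConfigError for missing
    keys. Re-running with an identical config and seed reproduces summary.json
    byte-for-byte.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    seed = int(config.get("seed", 0))
    out = Path(output_dir or config.get("output_dir", "sirnatrace_run"))
    out.mkdir(parents=True, exist_ok=True)

    pre_cfg = config.get("preprocess", {})
    min_len = int(pre_cfg.get("min_len", 18))
    max_len = int(pre_cfg.get("max_len", 30))
    adapter = pre_cfg.get("adapter", "") or ""
    max_tail = int(config.get("untemplated", {}).get("max_tail", 3))
    max_overlap = int(config.get("overlap", {}).get("max_overlap", 30))

    log.info("building references")
    model = model_from_config(config, seed)
    report = validate_design(model, min_read_len=min_len)
    with open(out / "design_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    if not report.passed:
        raise DesignError(report)

    checksums = {}
    if "simulate" in config:
        log.info("simulating library")
        sim = config["simulate"]
        sim_cfg = preset(
            sim.get("preset", "wildtype"),
            seed=seed,
            n_reads=int(sim.get("n_reads", 10_000)),
            **{
                k: sim[k]
                for k in ("secondary_ratio", "core_length_distribution", "tail_len_probs")
                if k in sim
            },
        )
        reads, truth = simulate_library(model, sim_cfg)
        write_fastq(reads, out / "reads.fastq")
        write_truth(truth, out / "truth.tsv")
    elif "reads_fastq" in config:
        fq = Path(config["reads_fastq"])
        if not fq.exists():
            raise ConfigError(f"reads_fastq not found: {fq}")
        checksums[str(fq)] = _sha256(fq)
        reads = list(read_fastq(fq))
    else:
        raise ConfigError("missing config key simulate (or reads_fastq)")

    n_input = len(reads)
    log.info("preprocessing %d reads", n_input)
    trimmed = [trim_adapter(r, adapter) for r in reads]
    retained, discarded = length_filter(trimmed, min_len, max_len)
    pd.DataFrame(
        sorted(discarded.items()), columns=["length", "n_discarded"]
    ).to_csv(out / "discard_tally.tsv", sep="\t", index=False)

    log.info("mapping, tail search and classification on %d reads", len(retained))
    pairs = [call_read(r, model, max_tail=max_tail) for r in retained]
    calls_df = _calls_frame(pairs)
    calls_df.to_csv(out / "calls.tsv", sep="\t", index=False)

    tables = summarize([c for _, c in pairs], retained, n_total_reads=len(trimmed))
    tail_calls = [tc for tc, _ in pairs if tc is not None]
    comp = tail_composition(tail_calls)
    comp.to_csv(out / "tail_composition.tsv", sep="\t", index=False)
    logos = build_logos(tail_calls, {r.id: r for r in retained}, min_len, max_len)
    write_logos(logos, out / "logos")

    log.info("overlap signature")
    hist = overlap_signature(_overlap_hits(pairs), max_overlap=max_overlap)
    hist.write(out / "overlap.tsv")

    manifest = {
        "tool": "sirnatrace",
        "version": __version__,
        "seed": seed,
        "config": config,
        "input_checksums": checksums,
        "read_counts": {
            "input": n_input,
            "after_trim": len(trimmed),
            "length_filtered": len(retained),
            "discarded_by_length": int(sum(discarded.values())),
            "classified": len(pairs),
            "tail_called": len(tail_calls),
            "unassigned": tables.category_counts["unassigned"],
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")

    render_report(
        tables, comp, hist, out,
        plots=bool(config.get("report", {}).get("plots", False)),
        model=model,
    )
    log.info("run complete: %s", out)
    return out


def render_report(
    tables: SignatureTables,
    tail_comp: pd.DataFrame,
    hist: OverlapHistogram,
    out_dir: str | Path,
    plots: bool = False,
    model: HeteroduplexModel | None = None,
) -> Path:
    """Write the machine-readable summary (and optional plots) for one run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables.write(out)
    summary = tables.summary_dict()
    summary["tail_composition"] = tail_comp.to_dict(orient="records")
    summary["overlap"] = {
        "peak_overlap": hist.peak_overlap,
        "n_pairs": hist.n_pairs,
        "max_overlap": hist.max_overlap,
    }
    path = out / "summary.json"
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    if plots:
        try:
            _render_plots(tables, hist, out, model)
        except Exception as exc:  # plotting is best-effort
            warnings.warn(f"plot rendering failed: {exc}", stacklevel=2)
    return path


def _render_plots(tables, hist, out: Path, model) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ld = tables.length_distribution
    if len(ld):
        fig, ax = plt.subplots(figsize=(7, 4))
        for cat, sub in ld.groupby("category"):
            ax.plot(sub["length"], sub["count"], marker="o", label=cat)
        ax.set_xlabel("read length (nt)")
        ax.set_ylabel("reads")
        ax.legend(fontsize=7)
        fig.savefig(out / "length_distribution.png", dpi=120, bbox_inches="tight")
        plt.close(fig)

    ratios = {c: v for c, v in tables.category_ratios.items() if v is not None}
    if ratios:
        fig, ax = plt.subplots(figsize=(5, 3.5))
        ax.bar(list(ratios), list(ratios.values()))
        ax.set_ylabel("share of 23-nt heteroduplex reads")
        ax.tick_params(axis="x", labelrotation=30, labelsize=7)
        fig.savefig(out / "category_ratios.png", dpi=120, bbox_inches="tight")
        plt.close(fig)

    df = hist.to_frame()
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(df["overlap_len"], df["probability"])
    ax.set_xlabel("5'-5' overlap (nt)")
    ax.set_ylabel("probability")
    fig.savefig(out / "overlap.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    cov = tables.coverage
    if len(cov) and model is not None:
        fig, ax = plt.subplots(figsize=(7, 3.5))
        for (ref, orient), sub in cov.groupby(["reference", "orientation"]):
            prof = sub.groupby("position")["count"].sum()
            ax.plot(prof.index, prof.values, label=f"{ref} {orient}", lw=0.8)
        a0, a1 = model.mismatch_area
        ax.axvspan(a0, a1, alpha=0.15, color="red", label="mismatch area")
        ax.set_xlabel("position (nt)")
        ax.set_ylabel("coverage")
        ax.set_yscale("symlog")
        ax.legend(fontsize=7)
        fig.savefig(out / "coverage.png", dpi=120, bbox_inches="tight")
        plt.close(fig)


def aggregate_replicates(summaries: list[dict]) -> dict:
    """Mean and SD across replicate run summaries (SD null for one sample)."""
    import numpy as np

    def stats(values):
        vals = [v for v in values if v is not None]
        if not vals:
            return {"mean": None, "sd": None, "n": 0}
        return {
            "mean": float(np.mean(vals)),
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else None,
            "n": len(vals),
        }

    out = {"n_replicates": len(summaries)}
    for key in ("ratio_23nt_vs_total", "secondary_primary_ratio"):
        out[key] = stats([s.get(key) for s in summaries])
    cats = sorted({c for s in summaries for c in s.get("category_ratios", {})})
    out["category_ratios"] = {
        c: stats([s.get("category_ratios", {}).get(c) for s in summaries]) for c in cats
    }
    return out
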