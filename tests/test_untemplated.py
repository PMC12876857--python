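"""Iterative 3' trim-and-remap tail search, logos, tail composition."""

import numpy as np
import pytest

from sirnatrace.mapping import find_hits
from sirnatrace.pipeline import call_read
from sirnatrace.preprocess import ReadRecord
from sirnatrace.simdata import preset, simulate_library
from sirnatrace.untemplated import (
    TailCall,
    build_logos,
    iterative_search,
    tail_composition,
)


def _rr(seq, rid="r"):
    return ReadRecord(id=rid, seq=seq)


def untemplated_sense_cores(model, core_len=23, tail="TT"):
    """Starts of in-area sense cores for which `tail` is genuinely
    non-templated: no tail base coincides with the template continuation, so
    every partial trim still fails to map at this locus."""
    a0, a1 = model.mismatch_area
    ref = model.sense_strand
    return [
        s
        for s in range(a0, a1 - core_len + 1)
        if all(
            s + core_len + k < len(ref) and ref[s + core_len + k] != tail[k]
            for k in range(len(tail))
        )
    ]


def test_two_uridine_tail_called_at_iteration_two(model):
    """A 23-nt siRNA elongated with two uridines: core 23, tail 'UU'."""
    start = untemplated_sense_cores(model)[0]
    read = _rr(model.sense_strand[start : start + 23] + "TT")
    tc = iterative_search(read, model)
    assert tc is not None
    assert tc.n_untemplated == 2
    assert tc.tail_seq == "UU"
    assert tc.core_length == 23
    assert tc.core_hit.start == start


def test_exact_read_is_iteration_zero(model):
    a0, _ = model.mismatch_area
    read = _rr(model.sense_strand[a0 : a0 + 23])
    tc = iterative_search(read, model)
    assert tc.n_untemplated == 0 and tc.tail_seq == ""


def _nonmatching_suffix(model, start, core_len, length):
    """A suffix no prefix-trim of which restores a template match."""
    ref = model.sense_strand
    core = ref[start : start + core_len]
    rng = np.random.default_rng(0)
    while True:
        suffix = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])
        read = _rr(core + suffix)
        if all(
            find_hits(_rr(read.seq[: len(read.seq) - k]), model).verdict
            not in ("unique", "flank_ambiguous")
            for k in range(0, length)
        ):
            return read


def test_four_appended_bases_exceed_the_detection_ceiling(model):
    """Four mapping iterations see at most three non-templated bases."""
    start = untemplated_sense_cores(model)[2]
    read = _nonmatching_suffix(model, start, 23, 4)
    assert iterative_search(read, model) is None


def test_first_success_rule_reports_shortest_consistent_tail(model):
    """A tail base matching the template extends the mapped core instead."""
    a0, a1 = model.mismatch_area
    ref = model.sense_strand
    start = next(
        s for s in range(a0, a1 - 23) if ref[s + 23] == "T"
    )
    read = _rr(ref[start : start + 23] + "TT")  # first T is templated
    tc = iterative_search(read, model)
    assert tc.n_untemplated < 2
    assert tc.core_length + tc.n_untemplated == read.length


def test_trimmed_core_never_below_15nt(model):
    """An 18-nt read may trim down to a 15-nt core; a 17-nt read would need a
    14-nt core for its 3-base tail and is never attempted below the floor."""
    a0, _ = model.mismatch_area
    ok = _nonmatching_suffix(model, a0, 15, 3)  # 18 nt, core 15
    tc = iterative_search(ok, model)
    assert tc is not None and tc.core_length == 15
    short = _nonmatching_suffix(model, a0, 14, 3)  # 17 nt, core would be 14
    assert iterative_search(short, model) is None


def test_tail_recovery_verbatim_on_simulation(model):
    """Where the generated tail is genuinely non-templated, the call matches
    the truth verbatim; otherwise the call reports the shortest consistent
    tail (a strict suffix of the generated one)."""
    cfg = preset("wildtype", seed=31, n_reads=3000)
    reads, truth = simulate_library(model, cfg)
    tru = truth.set_index("read_id")
    n_checked = 0
    for r in reads:
        row = tru.loc[r.id]
        if row["category"] in ("degradation", "secondary_mRNA"):
            continue
        tc, call = call_read(r, model)
        assert tc is not None
        true_tail = str(row["tail"])
        assert call.category == row["category"]
        if tc.tail_seq == true_tail:
            n_checked += 1
        else:  # shortest-consistent-tail: reported tail is a strict suffix
            assert true_tail.endswith(tc.tail_seq) and len(tc.tail_seq) < len(true_tail)
    assert n_checked > 1000


def _toy_calls(model, seqs, tail_len):
    """TailCalls for constructed reads (must genuinely map)."""
    out = []
    for i, seq in enumerate(seqs):
        tc = iterative_search(_rr(seq, rid=f"c{i}"), model)
        assert tc is not None and tc.n_untemplated == tail_len
        out.append(tc)
    return out


def test_logo_degenerate_uu_columns_have_two_bits(model):
    starts = untemplated_sense_cores(model)[:8]
    seqs = [model.sense_strand[s : s + 23] + "TT" for s in starts]
    calls = _toy_calls(model, seqs, 2)
    reads = {f"c{i}": _rr(s, rid=f"c{i}") for i, s in enumerate(seqs)}
    logos = build_logos(calls, reads)
    assert len(logos) == 1
    lg = logos[0]
    assert (lg.orientation, lg.read_length, lg.n_untemplated) == ("sense", 25, 2)
    # final two columns: 100% U, information content 2 bits
    assert lg.counts.loc["U"].iloc[-2:].tolist() == [len(seqs)] * 2
    assert lg.information_content[-2:] == pytest.approx([2.0, 2.0])
    # column sums conserve reads
    assert (lg.counts.sum(axis=0) == len(seqs)).all()


def test_logo_uniform_columns_have_zero_bits():
    from sirnatrace.untemplated import _column_ic

    counts = np.full((4, 5), 7)
    assert _column_ic(counts) == pytest.approx(np.zeros(5))


def test_logos_conserve_classified_reads(model):
    cfg = preset("wildtype", seed=32, n_reads=1500)
    reads, _ = simulate_library(model, cfg)
    pairs = [call_read(r, model) for r in reads]
    calls = [tc for tc, _ in pairs if tc is not None]
    logos = build_logos(calls, {r.id: r for r in reads})
    in_window = [c for c in calls if 18 <= c.original_length <= 30]
    assert sum(lg.counts.iloc[:, 0].sum() for lg in logos) == len(in_window)


def test_sense_tail_columns_more_informative_than_antisense(model):
    """Poly-U sense tails vs random antisense tails: mean tail-column IC is
    higher for sense strata."""
    cfg = preset("wildtype", seed=33, n_reads=6000)
    reads, _ = simulate_library(model, cfg)
    calls = [tc for tc, _ in (call_read(r, model) for r in reads) if tc]
    logos = build_logos(calls, {r.id: r for r in reads})

    def mean_tail_ic(orientation):
        vals = [
            lg.information_content[lg.templated_length :].mean()
            for lg in logos
            if lg.orientation == orientation and lg.n_untemplated > 0 and lg.n_reads >= 20
        ]
        return np.mean(vals)

    assert mean_tail_ic("sense") > mean_tail_ic("antisense") + 0.5


def test_tail_composition_counts():
    def fake(rid, orient, tail):
        from sirnatrace.mapping import MappingHit, MappingResult

        mr = MappingResult(rid, (MappingHit("senseHD", orient, 0, 23),), "unique")
        return TailCall(rid, len(tail), tail, mr, 23 + len(tail))

    calls = [
        fake("a", "sense", "UU"),
        fake("b", "sense", "UU"),
        fake("c", "sense", "UA"),
        fake("d", "sense", "UU"),
        fake("e", "sense", ""),  # tailless reads do not contribute
    ]
    df = tail_composition(calls)
    assert len(df) == 1
    row = df.iloc[0]
    assert (row["orientation"], row["tail_len"], row["n"]) == ("sense", 2, 4)
    assert row["frac_all_u"] == pytest.approx(0.75)


def test_tail_composition_empty_is_empty_frame():
    df = tail_composition([])
    assert len(df) == 0
    assert list(df.columns) == ["orientation", "tail_len", "n", "n_all_u", "frac_all_u"]


def test_random_antisense_tails_are_all_u_at_quarter_rate(model):
    """Uniform random tail bases: all-U fraction ~= 0.25^k for length k."""
    cfg = preset("wildtype", seed=34, n_reads=12_000)
    reads, _ = simulate_library(model, cfg)
    calls = [tc for tc, _ in (call_read(r, model) for r in reads) if tc]
    df = tail_composition(calls).set_index(["orientation", "tail_len"])
    for k in (1, 2):
        row = df.loc[("antisense", k)]
        expect = 0.25**k
        se = np.sqrt(expect * (1 - expect) / row["n"])
        # shortest-consistent-tail truncation biases slightly; allow 4 SE
        assert abs(row["frac_all_u"] - expect) <= 4 * se + 0.02
    sense = df.loc[("sense", 2)]
    assert sense["frac_all_u"] == 1.0
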