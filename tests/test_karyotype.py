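"""Breakpoint-window calling and karyotype combination rules."""

import numpy as np
import pytest

from niptsr.families import Breakpoint, Rearrangement
from niptsr.hmm import CrossoverInterval, PosteriorTrack
from niptsr.karyotype import (
    BreakpointWindow,
    WindowCall,
    breakpoint_windows,
    call_breakpoint_window,
    call_karyotype,
)


def make_track(lor, chrom="chr1", start=0, spacing=100_000, crossovers=(),
               labels=("Hap0", "Hap1")):
    lor = np.asarray(lor, dtype=float)
    n = len(lor)
    lp0 = -np.logaddexp(0.0, -lor)
    lp1 = -np.logaddexp(0.0, lor)
    track = PosteriorTrack(
        parent="mother",
        chrom=chrom,
        positions=start + np.arange(n) * spacing,
        lor=lor,
        log_post=np.column_stack([lp0, lp1]),
        viterbi_path=(lor < 0).astype(np.int64),
        state_labels=labels,
    )
    track.crossovers = list(crossovers)
    return track


WINDOW = BreakpointWindow("bp1", "chr1", 0, 2_000_000)


class TestCallBreakpointWindow:
    def test_negative_lor_calls_hap1(self):
        track = make_track([-8.0] * 20)
        call = call_breakpoint_window(track, WINDOW, min_snps=8)
        assert call.call == "Hap1"
        assert call.n_informative_snps == 20

    def test_positive_lor_calls_hap0(self):
        track = make_track([+8.0] * 20)
        assert call_breakpoint_window(track, WINDOW, min_snps=8).call == "Hap0"

    def test_too_few_snps_no_call(self):
        track = make_track([-8.0, -8.0])
        call = call_breakpoint_window(track, WINDOW, min_snps=10)
        assert call.call == "no_call"
        assert "fewer than" in call.reason

    def test_crossover_in_window_no_call(self):
        co = CrossoverInterval("chr1", 500_000, 600_000, "Hap0", "Hap1")
        track = make_track([8.0] * 20, crossovers=[co])
        call = call_breakpoint_window(track, WINDOW, min_snps=8)
        assert call.call == "no_call"
        assert call.crossover_in_window

    def test_crossover_outside_window_ignored(self):
        co = CrossoverInterval("chr1", 5_000_000, 5_100_000, "Hap0", "Hap1")
        track = make_track([8.0] * 20, crossovers=[co])
        assert call_breakpoint_window(track, WINDOW, min_snps=8).call == "Hap0"

    def test_weak_mean_lor_no_call(self):
        track = make_track([0.5] * 20)
        call = call_breakpoint_window(track, WINDOW, min_snps=8,
                                      lor_threshold=np.log(100))
        assert call.call == "no_call"
        assert "threshold" in call.reason

    def test_uncovered_window_no_call(self):
        track = make_track([8.0] * 20, start=50_000_000)
        call = call_breakpoint_window(track, WINDOW, min_snps=8)
        assert call.call == "no_call"
        assert "coverage" in call.reason

    def test_unlabelled_track_rejected(self):
        track = make_track([8.0] * 20, labels=("RefHap", "AltHap"))
        with pytest.raises(ValueError):
            call_breakpoint_window(track, WINDOW)


def wc(call, bp="bp1", chrom="chr1", lor=10.0):
    return WindowCall(bp, chrom, (0, 1), 20, lor if call == "Hap0" else -lor, call)


@pytest.fixture
def translocation():
    return Rearrangement(
        kind="reciprocal_translocation",
        breakpoints=(Breakpoint("bp1", "chr1", 60_000_000, 60_010_000),
                     Breakpoint("bp2", "chr2", 30_000_000, 30_010_000)),
        carrier_parent="mother",
    )


class TestCallKaryotype:
    def test_both_hap1_is_normal(self, translocation):
        pred = call_karyotype([wc("Hap1"), wc("Hap1", "bp2", "chr2")], translocation)
        assert pred.call == "normal"

    def test_both_hap0_is_balanced_carrier(self, translocation):
        pred = call_karyotype([wc("Hap0"), wc("Hap0", "bp2", "chr2")], translocation)
        assert pred.call == "balanced_carrier"

    def test_mixed_is_possible_unbalanced(self, translocation):
        pred = call_karyotype([wc("Hap0"), wc("Hap1", "bp2", "chr2")], translocation)
        assert pred.call == "possible_unbalanced"

    def test_any_window_no_call_propagates(self, translocation):
        calls = [wc("Hap0"), WindowCall("bp2", "chr2", (0, 1), 2, np.nan, "no_call")]
        assert call_karyotype(calls, translocation).call == "no_call"

    def test_wrong_window_count_rejected(self, translocation):
        with pytest.raises(ValueError):
            call_karyotype([wc("Hap0")], translocation)

    def test_relabel_symmetry_flips_outcomes(self, translocation):
        # exchanging Hap0/Hap1 everywhere flips normal <-> balanced_carrier
        # and leaves no_call unchanged
        grids = [
            (["Hap1", "Hap1"], "normal", "balanced_carrier"),
            (["Hap0", "Hap0"], "balanced_carrier", "normal"),
            (["Hap0", "Hap1"], "possible_unbalanced", "possible_unbalanced"),
            (["Hap0", "no_call"], "no_call", "no_call"),
        ]
        for calls, expect, expect_flipped in grids:
            wcs = [wc(c, f"bp{i+1}", ["chr1", "chr2"][i]) for i, c in enumerate(calls)]
            assert call_karyotype(wcs, translocation).call == expect
            flipped = [w.flipped() for w in wcs]
            assert call_karyotype(flipped, translocation).call == expect_flipped


class TestBreakpointWindows:
    def test_symmetric_flanks_for_translocation(self, translocation):
        wins = breakpoint_windows(translocation, flank_bp=1_000_000)
        assert (wins[0].start, wins[0].end) == (59_000_000, 61_010_000)

    def test_robertsonian_uses_q_side_only(self):
        rob = Rearrangement(
            kind="robertsonian",
            breakpoints=(Breakpoint("bp1", "chr13", 1_500_000, 1_600_000),
                         Breakpoint("bp2", "chr14", 1_500_000, 1_600_000)),
            carrier_parent="father",
        )
        wins = breakpoint_windows(rob, flank_bp=1_000_000)
        assert (wins[0].start, wins[0].end) == (1_500_000, 2_600_000)

    def test_robertsonian_requires_acrocentrics(self):
        with pytest.raises(ValueError):
            Rearrangement(
                kind="robertsonian",
                breakpoints=(Breakpoint("bp1", "chr1", 1, 2),
                             Breakpoint("bp2", "chr14", 1, 2)),
                carrier_parent="father",
            )

    def test_inversion_breakpoints_share_chromosome(self):
        with pytest.raises(ValueError):
            Rearrangement(
                kind="inversion",
                breakpoints=(Breakpoint("bp1", "chr1", 1, 2),
                             Breakpoint("bp2", "chr2", 1, 2)),
                carrier_parent="mother",
            )
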