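"""TSN/pause calling: oracle equivalence, conventions, strand symmetry."""

import numpy as np
import pytest

from conftest import make_track
from proipseq.genes import GeneModel
from proipseq.tracks import FIVE_PRIME, THREE_PRIME
from proipseq.tsn_pause import (
    call_pause, call_tsn, detect_clear_pause, pause_fraction, tss_offset_stats,
)


def gene_with_track(counts_by_offset, strand="+", tss=30_000, end_kind=FIVE_PRIME):
    """A gene plus a track holding counts at TSS-relative offsets."""
    if strand == "+":
        gene = GeneModel("g", "c1", "+", tss, tss + 20_000)
    else:
        gene = GeneModel("g", "c1", "-", tss - 20_000 + 1, tss + 1)
    assert gene.tss == tss
    entries = {}
    for off, c in counts_by_offset.items():
        pos = gene.offset_to_pos(gene.tss, off)
        entries[pos] = c
    track = make_track({("c1", strand): entries}, end_kind=end_kind)
    return gene, track


class TestCallTsn:
    def test_argmax_in_window(self):
        gene, track = gene_with_track({10: 3.0, 55: 9.0, 300: 4.0})
        call = call_tsn(track, gene)
        assert call.called and call.offset == 55
        assert call.count == 9.0

    def test_tie_breaks_upstream(self):
        gene, track = gene_with_track({20: 5.0, 40: 5.0})
        assert call_tsn(track, gene).offset == 20

    def test_zero_signal_not_called(self):
        gene, track = gene_with_track({})
        assert not call_tsn(track, gene).called

    def test_signal_outside_window_ignored(self):
        gene, track = gene_with_track({-150: 9.0, 450: 9.0, 30: 1.0})
        assert call_tsn(track, gene).offset == 30

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_oracle_equivalence_random_windows(self, strand):
        # exhaustive per-position scan vs the caller, 500 windows per strand
        rng = np.random.default_rng(17 if strand == "+" else 23)
        for _ in range(500):
            n_pos = int(rng.integers(1, 15))
            offsets = rng.choice(np.arange(-100, 401), size=n_pos, replace=False)
            counts = rng.integers(1, 50, size=n_pos).astype(float)
            gene, track = gene_with_track(dict(zip(offsets.tolist(), counts.tolist())), strand=strand)
            call = call_tsn(track, gene)
            best = min(
                (off for off, c in zip(offsets, counts) if c == counts.max()),
            )
            assert call.called and call.offset == best

    def test_strand_mirror_symmetry(self):
        counts = {12: 4.0, 55: 7.0, 201: 2.0}
        gp, tp = gene_with_track(counts, strand="+")
        gm, tm = gene_with_track(counts, strand="-")
        assert call_tsn(tp, gp).offset == call_tsn(tm, gm).offset == 55


class TestCallPause:
    def make_pair(self, three_offsets, strand="+", tsn_offset=10):
        gene, five = gene_with_track({tsn_offset: 50.0}, strand=strand)
        _, three = gene_with_track(three_offsets, strand=strand, end_kind=THREE_PRIME)
        tsn = call_tsn(five, gene)
        return gene, three, tsn

    def test_early_pause_one_based_distance(self):
        # 3'-mode 24 nt downstream of the TSN -> +25 in 1-based convention
        gene, three, tsn = self.make_pair({10 + 24: 9.0, 10 + 44: 3.0})
        call = call_pause(three, tsn, gene)
        assert call.distance == 25 and call.pause_class == "early"

    def test_late_pause_window(self):
        gene, three, tsn = self.make_pair({10 + 44: 9.0})
        call = call_pause(three, tsn, gene)
        assert call.distance == 45 and call.pause_class == "late"

    def test_outside_window(self):
        gene, three, tsn = self.make_pair({10 + 90: 9.0})
        assert call_pause(three, tsn, gene).pause_class == "outside"

    def test_upstream_of_tsn_negative_distance(self):
        gene, three, tsn = self.make_pair({10 - 5: 9.0})
        call = call_pause(three, tsn, gene)
        assert call.distance == -5 and call.pause_class == "outside"

    def test_zero_signal_gives_none(self):
        gene, three, tsn = self.make_pair({})
        call = call_pause(three, tsn, gene)
        assert not call.called and call.pause_class == "none"

    def test_uncalled_tsn_rejected(self):
        gene, three, tsn = self.make_pair({})
        gene2, empty_five = gene_with_track({})
        uncalled = call_tsn(empty_five, gene2)
        with pytest.raises(ValueError, match="TSN"):
            call_pause(three, uncalled, gene)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_oracle_equivalence_random_windows(self, strand):
        rng = np.random.default_rng(31 if strand == "+" else 37)
        for _ in range(500):
            n_pos = int(rng.integers(1, 15))
            offsets = rng.choice(np.arange(-100, 401), size=n_pos, replace=False)
            counts = rng.integers(1, 50, size=n_pos).astype(float)
            gene, three, tsn = self.make_pair(
                dict(zip(offsets.tolist(), counts.tolist())), strand=strand
            )
            call = call_pause(three, tsn, gene)
            best = min(off for off, c in zip(offsets, counts) if c == counts.max())
            d0 = best - 10  # TSN sits at offset 10
            assert call.called
            assert call.distance == (d0 + 1 if d0 >= 0 else d0)


class TestPauseFraction:
    def test_window_sums(self):
        gene, five = gene_with_track({0: 10.0})
        tsn = call_tsn(five, gene)
        # 30 counts early (+10), 10 counts late (+45)
        _, three = gene_with_track({9: 30.0, 44: 10.0}, end_kind=THREE_PRIME)
        assert pause_fraction(three, tsn, gene) == (0.75, 0.25)

    def test_all_late(self):
        gene, five = gene_with_track({0: 10.0})
        tsn = call_tsn(five, gene)
        _, three = gene_with_track({44: 5.0}, end_kind=THREE_PRIME)
        assert pause_fraction(three, tsn, gene) == (0.0, 1.0)

    def test_empty_region(self):
        gene, five = gene_with_track({0: 10.0})
        tsn = call_tsn(five, gene)
        _, three = gene_with_track({}, end_kind=THREE_PRIME)
        assert pause_fraction(three, tsn, gene) == (0.0, 0.0)

    def test_fractions_sum_to_one_when_signal_in_region(self):
        rng = np.random.default_rng(3)
        gene, five = gene_with_track({0: 10.0})
        tsn = call_tsn(five, gene)
        counts = {int(o): float(c) for o, c in zip(rng.choice(60, 20, replace=False), rng.integers(1, 9, 20))}
        _, three = gene_with_track(counts, end_kind=THREE_PRIME)
        fe, fl = pause_fraction(three, tsn, gene)
        assert fe + fl == pytest.approx(1.0)


class TestClearPause:
    def make(self, peak, background):
        gene, five = gene_with_track({0: 10.0})
        tsn = call_tsn(five, gene)
        counts = {25: peak}
        counts.update({200 + i: background for i in range(200)})
        _, three = gene_with_track(counts, end_kind=THREE_PRIME)
        return three, tsn, gene

    def test_strong_peak_detected(self):
        three, tsn, gene = self.make(20.0, 1.0)
        assert detect_clear_pause(three, tsn, gene)

    def test_low_peak_rejected(self):
        three, tsn, gene = self.make(3.0, 0.0)
        assert not detect_clear_pause(three, tsn, gene)

    def test_high_background_rejected(self):
        three, tsn, gene = self.make(20.0, 10.0)
        assert not detect_clear_pause(three, tsn, gene)


class TestOffsetStats:
    def test_mean_median(self):
        genes_tracks = [gene_with_track({o: 5.0}) for o in (10, 20, 60)]
        calls = [call_tsn(t, g) for g, t in genes_tracks]
        mean, median, hist = tss_offset_stats(calls)
        assert (mean, median) == (30.0, 20.0)
        assert hist.loc[20] == 1 and hist.sum() == 3

    def test_single_call(self):
        gene, track = gene_with_track({55: 2.0})
        mean, median, _ = tss_offset_stats([call_tsn(track, gene)])
        assert mean == median == 55.0

    def test_no_calls_rejected(self):
        gene, track = gene_with_track({})
        with pytest.raises(ValueError, match="no called"):
            tss_offset_stats([call_tsn(track, gene)])

    def test_matches_direct_oracle_on_many_offsets(self):
        rng = np.random.default_rng(13)
        offsets = rng.integers(-100, 401, size=500)
        calls = []
        for i, o in enumerate(offsets.tolist()):
            gene, track = gene_with_track({o: 2.0}, tss=5_000)
            calls.append(call_tsn(track, gene))
        mean, median, hist = tss_offset_stats(calls)
        assert mean == pytest.approx(float(np.mean(offsets)))
        assert median == pytest.approx(float(np.median(offsets)))
        assert hist.sum() == 500
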