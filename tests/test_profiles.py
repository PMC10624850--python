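"""Ratio tracks, composite profiles, gbRPK and response classification."""

import numpy as np
import pytest

from conftest import make_track
from proipseq.genes import GeneModel
from proipseq.profiles import (
    classify_hs_response, composite_profile, crossing_point, gbRPK,
    group_by_activity, log2_ratio_track, sum_antibody_activity,
)

import pandas as pd


def track_from_dense(values, chrom="c1", strand="+", start=0, **kw):
    entries = {int(start + i): float(v) for i, v in enumerate(values) if v != 0}
    return make_track({(chrom, strand): entries}, **kw)


class TestLog2Ratio:
    def test_equal_tracks_center_at_zero(self):
        t = make_track({("c1", "+"): {5: 4.0, 9: 1.0}, ("c1", "-"): {2: 3.0}})
        ratio = log2_ratio_track(t, t)
        for key in ratio.data:
            assert np.allclose(ratio.data[key][1], 0.0)

    def test_plain_log2_without_pseudocount(self):
        num = make_track({("c1", "+"): {5: 8.0}})
        den = make_track({("c1", "+"): {5: 2.0}})
        ratio = log2_ratio_track(num, den, pseudocount=0.0)
        assert ratio.data[("c1", "+")][1].tolist() == [2.0]

    def test_pseudocount_symmetric_at_double_zero(self):
        num = make_track({("c1", "+"): {5: 0.0}})
        den = make_track({("c1", "+"): {5: 0.0}})
        ratio = log2_ratio_track(num, den, pseudocount=0.5)
        assert ratio.data[("c1", "+")][1].tolist() == [0.0]

    def test_disjoint_coverage_uses_pseudocount(self):
        num = make_track({("c1", "+"): {5: 3.5}})
        den = make_track({("c1", "+"): {9: 1.5}})
        ratio = log2_ratio_track(num, den, pseudocount=0.5)
        pos, val = ratio.data[("c1", "+")]
        assert pos.tolist() == [5, 9]
        assert val[0] == pytest.approx(np.log2(4.0 / 0.5))
        assert val[1] == pytest.approx(np.log2(0.5 / 2.0))

    def test_mismatched_end_kind_rejected(self):
        from proipseq.tracks import FIVE_PRIME, THREE_PRIME
        a = make_track({}, end_kind=FIVE_PRIME)
        b = make_track({}, end_kind=THREE_PRIME)
        with pytest.raises(ValueError, match="end kind"):
            log2_ratio_track(a, b)


def make_gene(gene_id="g", strand="+", start=10_000, length=5_000, tsn_off=0):
    gene = GeneModel(gene_id, "c1", strand, start, start + length)
    return gene.with_tsn(gene.offset_to_pos(gene.tss, tsn_off))


class TestCompositeProfile:
    def test_constant_signal_collapses_band(self):
        gene = make_gene()
        track = track_from_dense([2.0] * 5_000, start=10_000)
        prof = composite_profile(track, [gene], anchor="body")
        assert np.allclose(prof.mean, 2.0)
        assert np.allclose(prof.q_lo, 2.0) and np.allclose(prof.q_hi, 2.0)

    def test_two_genes_average(self):
        g1, g2 = make_gene("a", start=10_000), make_gene("b", start=40_000)
        dense = np.zeros(60_000)
        dense[10_000:15_000] = 1.0
        dense[40_000:45_000] = 3.0
        track = track_from_dense(dense)
        prof = composite_profile(track, [g1, g2], anchor="body")
        assert np.allclose(prof.mean, 2.0)

    def test_gene_body_mass_conserved(self):
        rng = np.random.default_rng(21)
        genes, entries = [], {}
        start = 1_000
        for i in range(8):
            length = int(rng.integers(73, 4_001))
            strand = "+" if i % 2 == 0 else "-"
            g = GeneModel(f"g{i}", "c1", strand, start, start + length)
            g = g.with_tsn(g.tss)
            genes.append(g)
            for p in range(start, start + length):
                if rng.random() < 0.3:
                    entries[(("c1", strand), p)] = float(rng.integers(1, 9))
            start += length + 500
        data = {}
        for (key, p), v in entries.items():
            data.setdefault(key, {})[p] = v
        track = make_track(data)
        prof = composite_profile(track, genes, anchor="body")
        for i, g in enumerate(genes):
            expected = sum(
                v for (key, p), v in entries.items()
                if key == ("c1", g.strand) and g.start <= p < g.end
            )
            assert prof.gene_mass(i) == pytest.approx(expected, rel=1e-9)

    def test_gene_order_invariance(self):
        g1, g2, g3 = (make_gene(n, start=s) for n, s in (("a", 5_000), ("b", 20_000), ("c", 40_000)))
        rng = np.random.default_rng(2)
        dense = np.zeros(50_000)
        dense[rng.choice(50_000, 2_000, replace=False)] = 1.0
        track = track_from_dense(dense)
        p1 = composite_profile(track, [g1, g2, g3], anchor="body")
        p2 = composite_profile(track, [g3, g1, g2], anchor="body")
        assert np.allclose(p1.mean, p2.mean)
        assert np.allclose(p1.q_lo, p2.q_lo) and np.allclose(p1.q_hi, p2.q_hi)

    def test_strand_mirror_symmetry(self):
        # same offset pattern on opposite strands gives identical profiles
        pattern = {3: 2.0, 100: 5.0, 999: 1.0}
        gp = make_gene("p", strand="+", start=10_000, length=2_000)
        gm_model = GeneModel("m", "c1", "-", 30_000, 32_000).with_tsn(31_999)
        entries_p = {gp.offset_to_pos(gp.tsn, o): v for o, v in pattern.items()}
        entries_m = {gm_model.offset_to_pos(gm_model.tsn, o): v for o, v in pattern.items()}
        track = make_track({("c1", "+"): entries_p, ("c1", "-"): entries_m})
        prof_p = composite_profile(track, [gp], anchor="tsn", window=(0, 1000), bin_width=1)
        prof_m = composite_profile(track, [gm_model], anchor="tsn", window=(0, 1000), bin_width=1)
        assert np.array_equal(prof_p.matrix, prof_m.matrix)

    def test_short_gene_excluded_with_warning(self):
        short = GeneModel("tiny", "c1", "+", 100, 140).with_tsn(100)
        track = make_track({})
        with pytest.warns(UserWarning, match="excluded"):
            prof = composite_profile(track, [short], anchor="body")
        assert prof.n == 0

    def test_window_must_fit_bins(self):
        gene = make_gene()
        with pytest.raises(ValueError, match="bin_width"):
            composite_profile(make_track({}), [gene], anchor="tsn", window=(0, 10), bin_width=3)

    def test_promoter_bins_match_dense_oracle(self):
        gene = make_gene(tsn_off=37)
        rng = np.random.default_rng(8)
        dense = np.zeros(30_000)
        dense[rng.choice(30_000, 1_500, replace=False)] = rng.integers(1, 6, 1_500)
        track = track_from_dense(dense)
        prof = composite_profile(track, [gene], anchor="tsn", window=(-1000, 1000), bin_width=5)
        anchor = gene.tsn
        window = dense[anchor - 1000 : anchor + 1000]
        assert np.allclose(prof.matrix[0], window.reshape(-1, 5).mean(axis=1))


class TestCrossingPoint:
    def test_constant_dominance_returns_range_start(self):
        a, b = np.ones(50), np.zeros(50)
        assert crossing_point(a, b, search_range=(10, 50)) == 10

    def test_never_crossing_returns_none(self):
        assert crossing_point(np.zeros(50), np.ones(50)) is None

    def test_sigmoid_crossing_located(self):
        x = np.arange(300)
        a = np.tanh((x - 139.5) / 5.0)  # first positive bin is 140
        b = np.zeros(300)
        assert crossing_point(a, b) == 140

    def test_transient_blip_skipped(self):
        d = np.zeros(60)
        d[10] = 1.0  # single-bin excursion
        d[30:] = 1.0  # sustained crossing
        assert crossing_point(d, np.zeros(60), k=5) == 30


class TestGbRPK:
    def test_arithmetic(self):
        gene = make_gene(length=11_000)
        # 500 counts uniformly in the body (offsets 500..10499 => 10,000 nt)
        entries = {gene.tsn + 500 + i * 20: 1.0 for i in range(500)}
        track = make_track({("c1", "+"): entries})
        assert gbRPK(track, gene) == pytest.approx(500 / 10_500 * 1000)

    def test_explicit_body_definition(self):
        gene = make_gene(length=11_000)
        entries = {gene.tsn + 600: 7.0}
        track = make_track({("c1", "+"): entries})
        assert gbRPK(track, gene, body=(500, 10_499)) == pytest.approx(7.0 / 10_000 * 1000)

    def test_empty_body_is_zero(self):
        gene = make_gene()
        assert gbRPK(make_track({}), gene) == 0.0

    def test_linear_in_track(self):
        gene = make_gene()
        t = make_track({("c1", "+"): {gene.tsn + 1_000: 4.0}})
        assert gbRPK(t.scaled(2.0), gene) == pytest.approx(2 * gbRPK(t, gene))

    def test_zero_length_body_rejected(self):
        gene = make_gene(length=400)
        with pytest.raises(ValueError, match="body"):
            gbRPK(make_track({}), gene, body_start_offset=500)


class TestActivity:
    def test_sum_requires_all_antibodies(self):
        assert sum_antibody_activity(
            {"unPh": 1, "Ser2Ph": 2, "Ser5Ph": 3, "Ser7Ph": 4}
        ) == 10
        with pytest.raises(ValueError, match="Ser7Ph"):
            sum_antibody_activity({"unPh": 1, "Ser2Ph": 2, "Ser5Ph": 3})

    def test_equal_split_into_groups(self):
        df = pd.DataFrame({"gene": list("abcdefgh"), "sum_gbRPK": range(8)})
        out = group_by_activity(df)
        assert out["activity_group"].value_counts().tolist() == [2, 2, 2, 2]

    def test_ties_split_deterministically_by_id(self):
        df = pd.DataFrame({"gene": list("dacb"), "sum_gbRPK": [1.0] * 4})
        out = group_by_activity(df, n_groups=2)
        assert dict(zip(out["gene"], out["activity_group"])) == {"a": 1, "b": 1, "c": 2, "d": 2}

    def test_too_few_genes_rejected(self):
        df = pd.DataFrame({"gene": ["a"], "sum_gbRPK": [1.0]})
        with pytest.raises(ValueError, match="groups"):
            group_by_activity(df, n_groups=4)

    def test_boundaries_match_sort_oracle(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"gene": [f"g{i}" for i in range(37)], "sum_gbRPK": rng.random(37)})
        out = group_by_activity(df)
        ranked = df.sort_values(["sum_gbRPK", "gene"]).reset_index(drop=True)
        sizes = [len(c) for c in np.array_split(np.arange(37), 4)]
        expected = np.repeat([1, 2, 3, 4], sizes)
        lookup = dict(zip(ranked["gene"], expected))
        assert all(lookup[g] == grp for g, grp in zip(out["gene"], out["activity_group"]))


class TestHsResponse:
    @pytest.mark.parametrize(
        "ref, treated, expected",
        [(10, 40, "activated"), (40, 10, "repressed"), (10, 12, "unchanged"),
         (0, 5, "activated"), (0, 0.2, "unchanged")],
    )
    def test_rule_application(self, ref, treated, expected):
        assert classify_hs_response(ref, treated) == expected

    def test_antisymmetric_for_symmetric_thresholds(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            r, t = rng.random(2) * 50 + 1.0
            fwd = classify_hs_response(r, t, up_fc=2.0, down_fc=0.5, min_activity=1.0)
            rev = classify_hs_response(t, r, up_fc=2.0, down_fc=0.5, min_activity=1.0)
            swap = {"activated": "repressed", "repressed": "activated", "unchanged": "unchanged"}
            assert rev == swap[fwd]

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError, match="thresholds"):
            classify_hs_response(1, 2, up_fc=0.9)
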