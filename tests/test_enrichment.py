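"""ROI enrichment: the 2x2 probability formula against an exact
big-integer oracle, window assignment geometry, DMROI calling on
planted and null cohorts, and gene-set enrichment."""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from methscreen.dmr import GroupDesign, call_dmrs
from methscreen.enrichment import (
    ROI,
    assign_windows,
    call_dmrois,
    geneset_enrichment,
    roi_point_probability,
    roi_tail_probability,
    rois_from_frame,
)
from methscreen.synthetic import SimulationConfig, array_rois, simulate_array_cohort


def oracle_point(a, b, c, d):
    n = a + b + c + d
    return Fraction(comb(a + b, a) * comb(c + d, c), comb(n, a + c))


def oracle_tail(a, b, c, d):
    total = Fraction(0)
    ap = a
    while ap <= min(a + b, a + c):
        total += oracle_point(ap, a + b - ap, a + c - ap, d - a + ap)
        ap += 1
    return total


def all_tables(n_max):
    for n in range(1, n_max + 1):
        for a in range(n + 1):
            for b in range(n + 1 - a):
                for c in range(n + 1 - a - b):
                    yield a, b, c, n - a - b - c


class TestPointProbability:
    def test_single_possible_table(self):
        assert roi_point_probability(2, 0, 0, 0) == pytest.approx(1.0)

    def test_hand_computed_half(self):
        # C(1,1)*C(1,0)/C(2,1) = 1/2
        assert roi_point_probability(1, 0, 0, 1) == pytest.approx(0.5)

    def test_exact_mode_returns_fraction(self):
        assert roi_point_probability(1, 0, 0, 1, exact=True) == Fraction(1, 2)

    def test_matches_big_integer_oracle_all_tables_n12(self):
        for a, b, c, d in all_tables(12):
            got = roi_point_probability(a, b, c, d)
            want = float(oracle_point(a, b, c, d))
            assert got == pytest.approx(want, rel=1e-12, abs=1e-300)

    def test_point_masses_sum_to_one_over_fixed_margins(self):
        for a, b, c, d in [(3, 5, 2, 7), (0, 4, 4, 0), (6, 0, 0, 6), (2, 2, 2, 2)]:
            total = 0.0
            row1, col1 = a + b, a + c
            for ap in range(max(0, col1 - (c + d)), min(row1, col1) + 1):
                total += roi_point_probability(
                    ap, row1 - ap, col1 - ap, (c + d) - (col1 - ap)
                )
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            roi_point_probability(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            roi_tail_probability(0, 0, 0, 0)

    def test_large_counts_no_overflow(self):
        p = roi_point_probability(40, 400, 160, 24_000)
        assert 0.0 < p < 1.0


class TestTailProbability:
    def test_margin_maximal_a_tail_equals_point(self):
        assert roi_tail_probability(3, 0, 2, 4) == pytest.approx(
            roi_point_probability(3, 0, 2, 4)
        )

    def test_hand_enumerated_half(self):
        assert roi_tail_probability(1, 0, 0, 1) == pytest.approx(0.5)

    def test_matches_enumeration_oracle_all_tables_n12(self):
        for a, b, c, d in all_tables(12):
            got = roi_tail_probability(a, b, c, d)
            want = float(oracle_tail(a, b, c, d))
            assert got == pytest.approx(want, rel=1e-12, abs=1e-300)

    def test_tail_at_least_point(self):
        for a, b, c, d in all_tables(8):
            assert roi_tail_probability(a, b, c, d) >= roi_point_probability(
                a, b, c, d
            ) - 1e-12

    def test_tail_monotone_decreasing_in_a_at_fixed_margins(self):
        # margins: sig total 6, in-ROI 5, n = 20
        row1, col1, n = 6, 5, 20
        tails = []
        for a in range(max(0, col1 - (n - row1)), min(row1, col1) + 1):
            b, c = row1 - a, col1 - a
            d = n - a - b - c
            tails.append(roi_tail_probability(a, b, c, d))
        assert all(t1 >= t2 - 1e-12 for t1, t2 in zip(tails, tails[1:]))


class TestAssignWindows:
    def _windows(self):
        return pd.DataFrame(
            {
                "chrom": ["chr1"] * 3 + ["chr2"],
                "start": [100, 950, 2000, 100],
                "end": [200, 1050, 2100, 200],
            }
        )

    def test_unique_overlap(self):
        rois = [ROI("gA", "chr1", 0, 500, "+", tss=400)]
        got = assign_windows(self._windows(), rois)
        assert got.tolist() == ["gA", None, None, None]

    def test_tie_broken_by_nearest_tss(self):
        rois = [
            ROI("gA", "chr1", 0, 1000, "+", tss=200),
            ROI("gB", "chr1", 900, 1800, "+", tss=1100),
        ]
        got = assign_windows(self._windows(), rois)
        # window [950,1050) overlaps both; midpoint 1000 is nearer gB's TSS
        assert got.iloc[1] == "gB"

    def test_chromosome_without_rois_unassigned(self):
        rois = [ROI("gA", "chr1", 0, 5000, "+")]
        assert assign_windows(self._windows(), rois).iloc[3] is None

    def test_total_name_mismatch_hard_error(self):
        rois = [ROI("gA", "1", 0, 5000, "+")]  # ensembl-style names
        with pytest.raises(ValueError, match="no shared chromosome names"):
            assign_windows(self._windows(), rois)

    def test_roi_validation(self):
        with pytest.raises(ValueError):
            ROI("g", "chr1", 100, 100, "+")
        with pytest.raises(ValueError):
            ROI("g", "chr1", 0, 100, "x")


class TestCallDmrois:
    def _screen(self, cfg):
        co = simulate_array_cohort(cfg)
        design = GroupDesign.from_labels(co.group_labels)
        tab = call_dmrs(co.methylation, design, regions=co.regions)
        rois = rois_from_frame(array_rois(co))
        return co, design, tab, rois

    def test_planted_roi_top_ranked_and_called(self):
        cfg = SimulationConfig(
            n_regions=600, n_true_dmrs=12, cluster_dmrs=True, windows_per_roi=20,
            seed=41,
        )
        co, design, tab, rois = self._screen(cfg)
        out = call_dmrois(tab, rois, co.methylation, design)
        top = out.iloc[0]
        assert top.gene_id == "GENE0000"  # the fully planted promoter
        assert top.is_dmroi
        assert top.n_dmrs_in_roi >= 1

    def test_null_cohort_dmroi_rate_below_one_percent(self):
        cfg = SimulationConfig(
            n_regions=4000, n_true_dmrs=0, windows_per_roi=20, seed=43
        )
        co, design, tab, rois = self._screen(cfg)
        out = call_dmrois(tab, rois, co.methylation, design)
        assert out.is_dmroi.mean() <= 0.01

    def test_counts_partition_the_informative_windows(self):
        cfg = SimulationConfig(n_regions=400, n_true_dmrs=5, windows_per_roi=20, seed=44)
        co, design, tab, rois = self._screen(cfg)
        out = call_dmrois(tab, rois, co.methylation, design)
        assert (out.n == out.a + out.b + out.c + out.d).all()
        assert (out.n == int(tab.informative.sum())).all()

    def test_significant_windows_without_composite_dmr_not_dmroi(self):
        # windows all trend-significant but abs_diff < 0.20 -> no DMR call
        rng = np.random.default_rng(45)
        n_win, n_s = 40, 24
        labels = np.repeat([1, 2, 3, 4], 6)
        design = GroupDesign(
            tuple(f"s{i}" for i in range(n_s)),
            {f"s{i}": int(g) for i, g in enumerate(labels)},
        )
        base = 0.4 + 0.03 * (labels - 2.5)  # strong trend, small range
        Y = base[None, :] + rng.normal(0, 0.005, (n_win, n_s))
        meth = pd.DataFrame(Y, columns=design.sample_ids)
        regions = pd.DataFrame(
            {"chrom": "chr1", "start": 100 * np.arange(n_win),
             "end": 100 * np.arange(n_win) + 100}
        )
        tab = call_dmrs(meth, design, regions=regions)
        assert (tab.p_robust < 0.01).all() and not tab.is_dmr.any()
        rois = [ROI("gA", "chr1", 0, 2000, "+"), ROI("gB", "chr1", 2000, 4000, "+")]
        out = call_dmrois(tab, rois, meth, design)
        assert not out.is_dmroi.any()


class TestGeneSetEnrichment:
    def test_forced_total_overlap_p_one(self):
        genes = ["g1", "g2", "g3"]
        out = geneset_enrichment(genes, {"all": genes}, genes)
        assert out.p_hyper.iloc[0] == pytest.approx(1.0)

    def test_zero_overlap_tail_is_one(self):
        out = geneset_enrichment(
            ["g1"], {"s": ["g9", "g8"]}, [f"g{i}" for i in range(1, 11)]
        )
        assert out.p_hyper.iloc[0] == pytest.approx(1.0)

    def test_matches_independent_tail_sum_oracle(self):
        # background 25,000; set 71; 41 DMROI genes; k >= 4
        N, K, n_draw, k = 25_000, 71, 41, 4
        background = [f"g{i}" for i in range(N)]
        members = background[:K]
        hits = background[: k] + background[K : K + (n_draw - k)]
        out = geneset_enrichment(hits, {"path": members}, background)
        want = float(
            sum(
                Fraction(comb(K, j) * comb(N - K, n_draw - j), comb(N, n_draw))
                for j in range(k, min(K, n_draw) + 1)
            )
        )
        assert out.p_hyper.iloc[0] == pytest.approx(want, rel=1e-10)

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            geneset_enrichment([], {"s": ["g"]}, [])

    def test_stray_genes_rejected(self):
        with pytest.raises(ValueError):
            geneset_enrichment(["gX"], {"s": ["g1"]}, ["g1", "g2"])

    def test_bh_adjustment_monotone(self):
        background = [f"g{i}" for i in range(100)]
        sets = {f"s{i}": background[i : i + 20] for i in range(5)}
        out = geneset_enrichment(background[:10], sets, background)
        assert (out.p_bh.to_numpy() >= out.p_hyper.to_numpy() - 1e-12).all()
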