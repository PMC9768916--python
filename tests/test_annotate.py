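"""Anchor annotation, loop categories, in-loop fractions, shared loops."""

import numpy as np
import pytest

from conftest import brute_force_anchor_label, make_scene, make_tss
import loopscape as L
from loopscape.annotate import (
    all_categories,
    annotate_anchor,
    canonical_category,
    categorize_loops,
    element_loop_flags,
    expression_by_category,
    in_loop_fraction,
    shared_loops,
    window_for_resolution,
)
from loopscape.elements import RegElement
from loopscape.genomic_io import GenomicInterval, LoopRecord


def element(label, start, end, chrom="chr1", source="x"):
    return RegElement(
        interval=GenomicInterval(chrom, start, end),
        label=label,
        source_id=source,
        center=(start + end) // 2,
    )


def loop(s1, s2, res=5_000, chrom="chr1", **kw):
    return LoopRecord.make(
        GenomicInterval(chrom, s1, s1 + res),
        GenomicInterval(chrom, s2, s2 + res),
        res,
        **kw,
    )


class TestCategorySpace:
    def test_exactly_28_canonical_categories(self):
        cats = all_categories()
        assert len(cats) == 28
        assert len(set(cats)) == 28

    def test_canonicalization_orders_by_priority(self):
        assert canonical_category("insulator", "promoter") == ("promoter", "insulator")
        assert canonical_category("none", "enhancer") == ("enhancer", "none")

    def test_resolution_keyed_windows(self):
        assert window_for_resolution(1_000) == 2_000
        assert window_for_resolution(5_000) == 10_000


class TestAnnotateAnchor:
    def test_promoter_wins_over_insulator(self):
        els = [
            element("insulator", 100_000, 100_500, source="i"),
            element("promoter", 100_200, 104_200, source="p"),
        ]
        al = annotate_anchor(GenomicInterval("chr1", 100_000, 105_000), els, 2_000)
        assert al.label == "promoter" and al.element_id == "p"

    def test_no_overlap_is_none(self):
        els = [element("enhancer", 500_000, 501_000)]
        al = annotate_anchor(GenomicInterval("chr1", 0, 5_000), els, 2_000)
        assert al.label == "none" and al.element_id is None

    def test_abutting_expanded_anchor_does_not_match(self):
        # expanded anchor ends exactly where the element starts (half-open)
        els = [element("enhancer", 7_000, 8_000)]
        al = annotate_anchor(GenomicInterval("chr1", 0, 5_000), els, 2_000)
        assert al.label == "none"

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_priority_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = list(L.elements.PRIORITY)
        els = [
            element(
                labels[int(rng.integers(len(labels)))],
                int(s),
                int(s + rng.integers(200, 3_000)),
                source=f"e{k}",
            )
            for k, s in enumerate(rng.integers(0, 400_000, size=60))
        ]
        for _ in range(40):
            s = int(rng.integers(0, 400_000))
            anchor = GenomicInterval("chr1", s, s + 5_000)
            got = annotate_anchor(anchor, els, 2_000)
            want_label, want_id = brute_force_anchor_label(anchor, els, 2_000)
            assert (got.label, got.element_id) == (want_label, want_id)

    def test_element_order_invariance(self):
        rng = np.random.default_rng(3)
        els = [
            element("enhancer", 10_000, 11_000, source="a"),
            element("enhancer", 10_200, 12_500, source="b"),
            element("insulator", 10_400, 10_800, source="c"),
        ]
        anchor = GenomicInterval("chr1", 9_000, 13_000)
        ref = annotate_anchor(anchor, els, 2_000)
        for _ in range(5):
            rng.shuffle(els)
            assert annotate_anchor(anchor, els, 2_000) == ref


class TestCategorizeLoops:
    def test_all_insulator_anchors_single_category(self):
        els = [element("insulator", p, p + 400, source=f"i{p}")
               for p in (100_000, 500_000, 900_000)]
        loops = [loop(100_000, 500_000), loop(500_000, 900_000)]
        cat = categorize_loops(loops, els, window=2_000)
        assert set(cat.by_category) == {("insulator", "insulator")}
        assert int(cat.table["count"].sum()) == 2

    def test_empty_loop_list_gives_empty_table(self):
        cat = categorize_loops([], [element("promoter", 0, 4_000)], window=2_000)
        assert len(cat.table) == 0 and cat.by_category == {}

    def test_planted_ranking_recovered(self):
        cfg, _, _, _, els = make_scene(
            91, chrom_size=20_000_000, n_tss=400, n_peaks=250
        )
        tl = L.plant_loops(els, cfg, n_loops=1_500)
        recs = [LoopRecord.make(t.anchor1, t.anchor2, 1_000) for t in tl]
        cat = categorize_loops(recs, els, window=2_000)
        planted = sorted(
            cfg.loop_category_weights.items(), key=lambda kv: -kv[1]
        )
        top3_planted = [f"{a}-{b}" for (a, b), _ in planted[:3]]
        assert list(cat.table["category"][:3]) == top3_planted


class TestInLoopFraction:
    def _els(self):
        return [
            element("promoter", p, p + 4_000, source=f"p{p}")
            for p in (100_000, 300_000, 500_000, 700_000)
        ]

    def test_loops_covering_everything_give_fraction_one(self):
        els = self._els()
        loops = [loop(100_000, 300_000), loop(500_000, 700_000)]
        df = in_loop_fraction(els, {"d": loops}, window=2_000)
        assert df.loc["promoter", "d"] == 1.0
        assert df.loc["promoter", "union"] == 1.0

    def test_two_disjoint_half_covers_union_to_one(self):
        els = self._els()
        a = [loop(100_000, 300_000)]
        b = [loop(500_000, 700_000)]
        df = in_loop_fraction(els, {"a": a, "b": b}, window=2_000)
        assert df.loc["promoter", "a"] == 0.5
        assert df.loc["promoter", "b"] == 0.5
        assert df.loc["promoter", "union"] == 1.0

    def test_empty_loop_set_gives_zero(self):
        df = in_loop_fraction(self._els(), {"none": []}, window=2_000)
        assert df.loc["promoter", "none"] == 0.0

    def test_union_dominates_each_dataset(self):
        cfg, _, _, _, els = make_scene(92)
        tl = L.plant_loops(els, cfg, n_loops=25)
        recs = [LoopRecord.make(t.anchor1, t.anchor2, 5_000) for t in tl]
        df = in_loop_fraction(els, {"a": recs[:12], "b": recs[12:]})
        for col in ("a", "b"):
            assert (df["union"] + 1e-12 >= df[col]).all()


class TestSharedLoops:
    def test_identical_lists_fully_shared(self):
        loops = [loop(100_000, 400_000), loop(600_000, 900_000)]
        fa, fb = shared_loops(loops, list(loops), window=10_000)
        assert fa.all() and fb.all()

    def test_far_shifted_list_shares_nothing(self):
        a = [loop(100_000, 400_000)]
        b = [loop(130_000, 430_000)]  # shifted by 30 kb > 2*10 kb window
        fa, fb = shared_loops(a, b, window=10_000)
        assert not fa.any() and not fb.any()

    def test_one_to_many_matching_is_asymmetric(self):
        a = [loop(100_000, 400_000)]
        b = [loop(104_000, 404_000), loop(96_000, 396_000)]
        fa, fb = shared_loops(a, b, window=10_000)
        assert fa.sum() == 1 and fb.sum() == 2

    def test_window_shrink_never_increases_sharing(self):
        rng = np.random.default_rng(8)
        a = [loop(int(s), int(s) + int(d))
             for s, d in zip(rng.integers(0, 5_000_000, 40),
                             rng.integers(100_000, 900_000, 40))]
        b = [loop(int(s), int(s) + int(d))
             for s, d in zip(rng.integers(0, 5_000_000, 40),
                             rng.integers(100_000, 900_000, 40))]
        prev = None
        for w in (50_000, 20_000, 5_000, 0):
            fa, _ = shared_loops(a, b, window=w)
            if prev is not None:
                assert fa.sum() <= prev
            prev = fa.sum()


class TestExpressionByCategory:
    def _setup(self, delta):
        """Two promoter categories; the P-heterochromatin promoters weaker."""
        rng = np.random.default_rng(10)
        tss, els, loops = [], [], []
        pos = 100_000
        for k in range(120):
            hot = k % 2 == 0
            fpkm = 5.0 + rng.normal(0, 0.5) if hot else 5.0 - delta + rng.normal(0, 0.5)
            fpkm = max(fpkm, 0.01)
            t = make_tss(pos=pos, gene=f"g{k}", fpkm=(fpkm,))
            tss.append(t)
            prom = element("promoter", pos - 2_000, pos + 2_000, source=f"g{k}")
            partner_label = "enhancer" if hot else "heterochromatin"
            partner = element(partner_label, pos + 300_000, pos + 301_000,
                              source=f"x{k}")
            els.extend([prom, partner])
            loops.append(loop(pos - 2_000, pos + 300_000, res=1_000))
            pos += 700_000
        cat = categorize_loops(loops, els, window=2_000)
        return cat, tss

    def test_planted_expression_difference_detected(self):
        cat, tss = self._setup(delta=2.0)
        arrays, pmat = expression_by_category(cat, tss)
        key_hi = "promoter-enhancer"
        key_lo = "promoter-heterochromatin"
        assert pmat.loc[key_hi, key_lo] < 0.01
        assert arrays[("promoter", "enhancer")].mean() > arrays[
            ("promoter", "heterochromatin")
        ].mean()

    def test_small_category_skipped_with_warning(self):
        els = [
            element("promoter", 98_000, 102_000, source="g0"),
            element("enhancer", 400_000, 401_000, source="e0"),
        ]
        tss = [make_tss(pos=100_000, gene="g0", fpkm=(3.0,))]
        cat = categorize_loops([loop(98_000, 400_000, res=1_000)], els, window=2_000)
        with pytest.warns(UserWarning, match="skipped"):
            arrays, _ = expression_by_category(cat, tss)
        assert arrays == {}
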