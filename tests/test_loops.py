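"""Loop calling: Poisson oracle, FDR behavior, capture restriction, distance bins."""

import numpy as np
import pytest
from scipy.stats import poisson

import loopscape as L
from loopscape.contacts import ContactMap
from loopscape.genomic_io import GenomicInterval, LoopRecord
from loopscape.loops import (
    DISTANCE_CATEGORIES,
    LoopCallParams,
    call_loops,
    capture_score,
    distance_category,
    distance_distribution,
)


def flat_background_map(n=200, mean=20, seed=0, binsize=10_000, hot=None, fold=10):
    """Poisson map around a flat expectation, optionally one enriched pixel."""
    rng = np.random.default_rng(seed)
    expect = np.full((n, n), float(mean))
    if hot is not None:
        i, j = hot
        expect[i, j] = expect[j, i] = mean * fold
    counts = rng.poisson(np.triu(expect))
    return ContactMap.from_dense_upper("chrS", binsize, counts)


class TestCallLoops:
    def test_params_invariants(self):
        with pytest.raises(ValueError):
            LoopCallParams(peak_width=3, donut_width=3)
        with pytest.raises(ValueError):
            LoopCallParams(resolution=10_000, min_distance=15_000)

    def test_hot_pixel_called_and_matches_poisson_tail_oracle(self):
        hot = (60, 110)
        m = flat_background_map(hot=hot, fold=10)
        params = LoopCallParams(resolution=10_000, min_distance=50_000,
                                max_distance=1_900_000)
        calls = call_loops(m, params)
        found = [
            c for c in calls
            if c.anchor1.start == hot[0] * 10_000 and c.anchor2.start == hot[1] * 10_000
        ]
        assert len(found) == 1
        assert found[0].qvalue < 0.20
        # independent oracle: upper Poisson tail of the observed count at the
        # flat background rate is astronomically small for a 10x pixel
        obs = m.dense()[hot]
        p_oracle = poisson.sf(obs - 1, 20.0)
        assert p_oracle < 1e-12
        # caller's own p (local background ~ the flat rate) is equally extreme
        assert 10 ** (-found[0].score) < 1e-8

    def test_null_map_produces_almost_no_calls(self):
        params = LoopCallParams(resolution=10_000)
        n_calls = [
            len(call_loops(flat_background_map(seed=s), params)) for s in range(5)
        ]
        assert np.median(n_calls) == 0

    def test_qvalues_monotone_in_pvalues(self):
        cfg = L.SynthConfig(
            seed=2,
            chrom_sizes={"chrS": 4_000_000},
            n_tss=100,
            depth=2_500_000,
            loop_category_weights={
                ("promoter", "promoter"): 0.3,
                ("promoter", "insulator"): 0.4,
                ("insulator", "insulator"): 0.3,
            },
        )
        sizes, tss = L.generate_genome(cfg)
        proms = L.active_promoters(tss, chrom_sizes=sizes)
        ctcf = L.generate_peaks(sizes, "CTCF", cfg, tss, n_peaks=60)
        els = L.classify_elements(proms, [], ctcf, [], [], [], tss)
        tl = L.plant_loops(els, cfg, n_loops=20)
        m = L.simulate_contact_map("chrS", 10_000, [], tl, cfg)
        calls = call_loops(m, LoopCallParams(resolution=10_000))
        assert len(calls) >= 10
        by_p = sorted(calls, key=lambda c: -c.score)  # ascending p
        qs = [c.qvalue for c in by_p]
        assert all(q1 <= q2 + 1e-12 for q1, q2 in zip(qs, qs[1:]))

    def test_merged_cluster_reports_single_interior_centroid(self):
        # a 2x2 block of enriched pixels must merge to one call inside it
        rng = np.random.default_rng(5)
        expect = np.full((150, 150), 20.0)
        for i, j in [(40, 90), (40, 91), (41, 90), (41, 91)]:
            expect[i, j] = expect[j, i] = 200.0
        m = ContactMap.from_dense_upper(
            "chrS", 10_000, rng.poisson(np.triu(expect))
        )
        calls = call_loops(m, LoopCallParams(resolution=10_000))
        in_block = [
            c
            for c in calls
            if c.anchor1.start // 10_000 in (40, 41)
            and c.anchor2.start // 10_000 in (90, 91)
        ]
        assert len(in_block) == 1  # the 4 significant pixels merge to one call

    def test_resolution_mismatch_rejected(self):
        m = flat_background_map(binsize=5_000)
        with pytest.raises(ValueError):
            call_loops(m, LoopCallParams(resolution=10_000))


class TestCaptureScore:
    def test_empty_bait_list_rejected(self):
        m = flat_background_map()
        with pytest.raises(ValueError):
            capture_score(m, [], LoopCallParams(resolution=10_000))

    def test_calls_always_touch_a_bait(self):
        hot_on = (30, 80)   # anchor bin 30 overlaps the bait
        hot_off = (120, 170)
        rng = np.random.default_rng(9)
        expect = np.full((200, 200), 20.0)
        for (i, j) in (hot_on, hot_off):
            expect[i, j] = expect[j, i] = 300.0
        m = ContactMap.from_dense_upper("chrS", 10_000, rng.poisson(np.triu(expect)))
        bait = [GenomicInterval("chrS", 300_000, 310_000)]  # bin 30 only
        calls = capture_score(m, bait, LoopCallParams(resolution=10_000))
        assert calls, "the bait-anchored enrichment must be reported"
        for c in calls:
            assert c.bait_id is not None
            touches = (
                c.anchor1.overlaps(bait[0]) or c.anchor2.overlaps(bait[0])
            )
            assert touches
        assert not any(
            c.anchor1.start == 1_200_000 and c.anchor2.start == 1_700_000
            for c in calls
        )


class TestDistanceCategories:
    @pytest.mark.parametrize(
        "dist,expected",
        [
            (100_000, "<200 kb"),
            (200_000, "200-400 kb"),
            (400_000, "400-600 kb"),  # left-closed boundary
            (999_999, "800 kb-1 Mb"),
            (1_000_000, ">1 Mb"),
            (1_500_000, ">1 Mb"),
        ],
    )
    def test_bin_edges_left_closed(self, dist, expected):
        lp = LoopRecord.make(
            GenomicInterval("c", 0, 10_000),
            GenomicInterval("c", dist, dist + 10_000),
            10_000,
        )
        assert distance_category(lp) == expected

    def test_empty_distribution_all_zero(self):
        counts, fracs = distance_distribution([])
        assert all(v == 0 for v in counts.values())
        assert all(v == 0.0 for v in fracs.values())

    def test_single_category_gets_fraction_one(self):
        loops = [
            LoopRecord.make(
                GenomicInterval("c", s, s + 10_000),
                GenomicInterval("c", s + 100_000, s + 110_000),
                10_000,
            )
            for s in range(0, 300_000, 20_000)
        ]
        counts, fracs = distance_distribution(loops)
        assert fracs["<200 kb"] == 1.0
        assert sum(counts.values()) == len(loops)

    def test_uniform_distances_match_analytic_bin_widths(self):
        rng = np.random.default_rng(123)
        n = 4_000
        dists = rng.integers(20_000, 1_200_000, size=n)
        loops = [
            LoopRecord.make(
                GenomicInterval("c", 0, 1_000),
                GenomicInterval("c", int(d), int(d) + 1_000),
                1_000,
            )
            for d in dists
        ]
        _, fracs = distance_distribution(loops)
        span = 1_200_000 - 20_000
        expected = {
            "<200 kb": 180_000 / span,
            "200-400 kb": 200_000 / span,
            "400-600 kb": 200_000 / span,
            "600-800 kb": 200_000 / span,
            "800 kb-1 Mb": 200_000 / span,
            ">1 Mb": 200_000 / span,
        }
        for cat in DISTANCE_CATEGORIES:
            se = np.sqrt(expected[cat] * (1 - expected[cat]) / n)
            assert abs(fracs[cat] - expected[cat]) < 4 * se
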