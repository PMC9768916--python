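"""Synthetic generator: determinism, degenerate laws, planted structure."""

import numpy as np
import pytest

import loopscape as L
from loopscape.loops import distance_category
from loopscape.genomic_io import LoopRecord

from conftest import make_scene


class TestGenerateGenome:
    def test_zero_tss_gives_empty_list(self):
        cfg = L.SynthConfig(seed=0, n_tss=0)
        _, tss = L.generate_genome(cfg)
        assert tss == []

    def test_fixed_seed_is_deterministic(self):
        a = L.generate_genome(L.SynthConfig(seed=7))
        b = L.generate_genome(L.SynthConfig(seed=7))
        assert a == b

    def test_constant_fpkm_one_makes_every_tss_an_active_promoter(self):
        # log-normal with sigma 0 and mu 0 is the constant 1.0 > 0.5
        cfg = L.SynthConfig(seed=3, n_tss=100, fpkm_law=(0.0, 0.0))
        sizes, tss = L.generate_genome(cfg)
        proms = L.active_promoters(tss, chrom_sizes=sizes)
        assert len(proms) == 100

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError):
            L.SynthConfig(chrom_sizes={"bad": 0})


class TestGeneratePeaks:
    def test_zero_count_gives_empty_set(self):
        cfg = L.SynthConfig(seed=0)
        sizes, tss = L.generate_genome(cfg)
        assert L.generate_peaks(sizes, "H3K27ac", cfg, tss, n_peaks=0) == []

    def test_unknown_mark_rejected(self):
        cfg = L.SynthConfig(seed=0)
        sizes, tss = L.generate_genome(cfg)
        with pytest.raises(ValueError):
            L.generate_peaks(sizes, "H3K4me1", cfg, tss)

    def test_degenerate_width_law_gives_exact_widths(self):
        cfg = L.SynthConfig(seed=1)
        cfg.peak_width_law["H3K27ac"] = (1500.0, 0.0)
        sizes, tss = L.generate_genome(cfg)
        peaks = L.generate_peaks(sizes, "H3K27ac", cfg, tss, n_peaks=40)
        assert all(p.width == 1500 for p in peaks)

    def test_all_tss_free_peaks_become_enhancers(self):
        cfg = L.SynthConfig(seed=2, n_tss=150)
        sizes, tss = L.generate_genome(cfg)
        peaks = L.generate_peaks(
            sizes, "H3K27ac", cfg, tss, n_peaks=60, tss_free_frac=1.0
        )
        proms = L.active_promoters(tss, chrom_sizes=sizes)
        els = L.classify_elements(proms, peaks, [], [], [], [], tss)
        enh = [e for e in els if e.label == "enhancer"]
        assert len(enh) == 60

    def test_peaks_stay_inside_chromosome(self):
        cfg = L.SynthConfig(seed=4, chrom_sizes={"c": 300_000}, n_tss=20)
        sizes, tss = L.generate_genome(cfg)
        for p in L.generate_peaks(sizes, "NDR", cfg, tss, n_peaks=50):
            assert 0 <= p.start < p.end <= 300_000


class TestPlantLoops:
    def test_degenerate_weights_give_single_category(self):
        cfg, sizes, tss, peaks, els = make_scene(31)
        cfg.loop_category_weights = {("insulator", "insulator"): 1.0}
        tl = L.plant_loops(els, cfg, n_loops=50)
        assert len(tl) == 50
        assert all(t.category == ("insulator", "insulator") for t in tl)

    def test_zero_loops_empty(self):
        cfg, _, _, _, els = make_scene(32)
        assert len(L.plant_loops(els, cfg, n_loops=0)) == 0

    def test_missing_category_pool_rejected(self):
        cfg, sizes, tss, peaks, _ = make_scene(33)
        proms = L.active_promoters(tss, chrom_sizes=sizes)
        only_proms = L.classify_elements(proms, [], [], [], [], [], tss)
        cfg.loop_category_weights = {("enhancer", "enhancer"): 1.0}
        with pytest.raises(ValueError, match="no eligible pair"):
            L.plant_loops(only_proms, cfg, n_loops=5)

    def test_fixed_distance_law_lands_in_200_400kb_bin(self):
        cfg, _, _, _, els = make_scene(34)
        cfg.loop_distance_law = (np.log(300_000.0), 0.0)
        tl = L.plant_loops(els, cfg, n_loops=40)
        for t in tl:
            lp = LoopRecord.make(t.anchor1, t.anchor2, 10_000)
            assert distance_category(lp) == "200-400 kb"

    def test_anchor_order_and_fold_invariants(self):
        cfg, _, _, _, els = make_scene(35)
        for t in L.plant_loops(els, cfg, n_loops=30):
            assert t.anchor1.chrom == t.anchor2.chrom
            assert t.anchor1.start <= t.anchor2.start
            assert t.fold >= 1.0


class TestSimulateContactMap:
    def test_symmetric_nonnegative_integer_counts(self):
        cfg, _, _, _, els = make_scene(41, depth=500_000)
        tl = L.plant_loops(els, cfg, n_loops=10)
        m = L.simulate_contact_map("chrS", 10_000, [], tl, cfg)
        d = m.dense()
        assert np.array_equal(d, d.T)
        assert d.min() >= 0
        assert np.array_equal(d, np.round(d))

    def test_zero_decay_gives_equal_expectation_across_distances(self):
        cfg = L.SynthConfig(
            seed=8,
            chrom_sizes={"chrS": 1_000_000},
            n_tss=0,
            depth=4_000_000,
            decay_exponent=0.0,
            loop_category_weights={},
        )
        m = L.simulate_contact_map("chrS", 10_000, [], L.TrueLoopSet([]), cfg)
        prof = L.expected_by_distance(m).values
        mean_c = m.total() / (m.n_bins * (m.n_bins + 1) / 2)
        for d in (0, 25, 50, 75, 99):
            se = np.sqrt(mean_c / (m.n_bins - d))
            assert abs(prof[d] - mean_c) < 4 * se

    def test_doubling_depth_doubles_mean_count(self):
        # Monte-Carlo over 20 replicate draws of the same structure
        base = L.SynthConfig(
            seed=0,
            chrom_sizes={"chrS": 1_000_000},
            n_tss=0,
            depth=200_000,
            loop_category_weights={},
        )
        totals1, totals2 = [], []
        for rep in range(20):
            rng1 = np.random.default_rng([rep, 1])
            rng2 = np.random.default_rng([rep, 2])
            m1 = L.simulate_contact_map(
                "chrS", 10_000, [], L.TrueLoopSet([]), base, depth=200_000, rng=rng1
            )
            m2 = L.simulate_contact_map(
                "chrS", 10_000, [], L.TrueLoopSet([]), base, depth=400_000, rng=rng2
            )
            totals1.append(m1.total())
            totals2.append(m2.total())
        r = np.mean(totals2) / np.mean(totals1)
        assert abs(r - 2.0) < 4 * np.sqrt(1 / np.sum(totals1) + 1 / np.sum(totals2)) * 2

    def test_negative_depth_rejected(self):
        cfg = L.SynthConfig(seed=0, n_tss=0, loop_category_weights={})
        with pytest.raises(ValueError):
            L.simulate_contact_map("chrS", 10_000, [], L.TrueLoopSet([]), cfg, depth=-1)


class TestDownsample:
    def _map(self, seed=0, depth=400_000):
        cfg = L.SynthConfig(
            seed=seed,
            chrom_sizes={"chrS": 2_000_000},
            n_tss=0,
            depth=depth,
            loop_category_weights={},
        )
        return L.simulate_contact_map("chrS", 10_000, [], L.TrueLoopSet([]), cfg)

    def test_fraction_one_is_identity(self):
        m = self._map()
        assert L.downsample_contacts(m, 1.0) == m

    def test_fraction_zero_is_empty(self):
        assert L.downsample_contacts(self._map(), 0.0, seed=1).total() == 0

    def test_half_fraction_within_binomial_bound(self):
        m = self._map()
        n = m.total()
        sub = L.downsample_contacts(m, 0.5, seed=2)
        assert abs(sub.total() - n / 2) < 4 * np.sqrt(n / 4)

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(ValueError):
            L.downsample_contacts(self._map(), 1.5)


class TestSignalTracks:
    def test_flags_must_align(self):
        cfg, _, _, _, els = make_scene(51, chrom_size=1_000_000, n_tss=30, n_peaks=10)
        with pytest.raises(ValueError):
            L.simulate_signal_tracks(els, [True], cfg)

    def test_fixed_seed_byte_identical(self):
        cfg, _, _, _, els = make_scene(52, chrom_size=1_000_000, n_tss=30, n_peaks=10)
        flags = [True, False] * (len(els) // 2) + [True] * (len(els) % 2)
        t1 = L.simulate_signal_tracks(els, flags, cfg)
        t2 = L.simulate_signal_tracks(els, flags, cfg)
        for name in t1:
            a, b = t1[name]["chrS"].values, t2[name]["chrS"].values
            assert np.array_equal(a, b, equal_nan=True)

    def test_zero_phasing_amplitude_kills_flank_oscillation(self):
        from dataclasses import replace
        from loopscape.profiles import phasing_score, profile

        scores = {"zero": [], "strong": []}
        for seed in range(6):
            for key, amp in (("zero", 0.0), ("strong", 0.4)):
                sig = replace(
                    L.synth.SignalParams(),
                    phasing_amp_in=amp,
                    phasing_amp_out=amp,
                )
                cfg, _, _, _, els = make_scene(
                    60 + seed, chrom_size=1_500_000, n_tss=40, n_peaks=15, signal=sig
                )
                flags = [True] * len(els)
                tracks = L.simulate_signal_tracks(els, flags, cfg)
                pm = profile(
                    tracks["mnase"], [(e.chrom, e.center) for e in els]
                )
                curve = np.nanmean(pm.values, axis=0)
                scores[key].append(phasing_score(curve, pm.offsets))
        # zero-amplitude scores hover near 0; strong phasing clearly above
        assert np.mean(scores["strong"]) > 10 * abs(np.mean(scores["zero"]))
        assert abs(np.mean(scores["zero"])) < 3 * np.std(scores["zero"]) + 1e-4
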