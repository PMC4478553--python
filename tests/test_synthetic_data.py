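"""Ground-truth simulators: determinism, exact zero-noise limits, calibration."""

import math

import numpy as np
import pytest
from scipy import stats

from cghcnv.core import GenomeSpec
from cghcnv.synthetic_data import (NoiseSpec, QpcrTarget, default_genome,
                                   expected_log2, simulate_probe_map,
                                   simulate_qpcr, simulate_ratio_track,
                                   simulate_sex_mismatch, simulate_truth)
from cghcnv.validation import ddct_copy_ratio

NO_NOISE = NoiseSpec(probe_sd=0.0, qc_fail_fraction=0.0, seed=5)


class TestProbeMap:
    def test_probe_count_tracks_mean_spacing(self):
        genome = GenomeSpec((("1", 1_000_000),))
        pm = simulate_probe_map(genome, mean_spacing=2632, seed=3)
        expected = 1_000_000 / 2632
        assert expected * 0.8 <= len(pm) <= expected * 1.2

    def test_probe_length_and_sorting(self, probe_map):
        df = probe_map.probes
        assert ((df["end"] - df["start"]) == 60).all()
        for chrom in probe_map.chroms:
            sub = df[df["chrom"] == chrom]
            assert sub["start"].is_monotonic_increasing

    def test_same_seed_identical_map(self, small_genome):
        a = simulate_probe_map(small_genome, seed=7)
        b = simulate_probe_map(small_genome, seed=7)
        assert a.probes.equals(b.probes)
        c = simulate_probe_map(small_genome, seed=8)
        assert not a.probes.equals(c.probes)

    def test_tiny_chromosome_gets_no_probes(self):
        genome = GenomeSpec((("1", 1_000_000), ("scrap", 500)))
        with pytest.warns(UserWarning, match="scrap"):
            pm = simulate_probe_map(genome, mean_spacing=2632, seed=0)
        assert "scrap" not in set(pm.probes["chrom"])


class TestTruth:
    def test_expected_log2_values(self):
        assert expected_log2(4) == 1.0
        assert expected_log2(1) == -1.0
        assert expected_log2(3) == pytest.approx(0.585, abs=1e-3)
        assert expected_log2(0) == -4.0  # saturation floor, not -inf

    def test_segments_non_overlapping_and_in_bounds(self, small_genome):
        segs = simulate_truth(small_genome, 40, size_range=(5_000, 100_000),
                              seed=9)
        assert len(segs) == 40
        lengths = small_genome.lengths
        by_chrom = {}
        for s in segs:
            assert 0 <= s.start < s.end <= lengths[s.chrom]
            assert s.copy_state != small_genome.ploidy_baseline
            by_chrom.setdefault(s.chrom, []).append((s.start, s.end))
        for ivs in by_chrom.values():
            ivs.sort()
            for (s1, e1), (s2, _) in zip(ivs, ivs[1:]):
                assert e1 <= s2

    def test_state_frequencies_within_binomial_bounds(self, small_genome):
        segs = simulate_truth(small_genome, 100, size_range=(5_000, 20_000),
                              state_weights={1: 0.5, 3: 0.5}, seed=10)
        n_loss = sum(1 for s in segs if s.copy_state == 1)
        lo, hi = stats.binom.interval(0.99, 100, 0.5)
        assert lo <= n_loss <= hi

    def test_impossible_placement_names_chromosome(self):
        genome = GenomeSpec((("1", 50_000),))
        with pytest.raises(RuntimeError, match="chromosome 1"):
            simulate_truth(genome, 30, size_range=(20_000, 40_000), seed=1)


class TestRatioTrack:
    def test_zero_noise_reproduces_truth_exactly(self, probe_map, small_genome):
        segs = simulate_truth(small_genome, 3, size_range=(50_000, 200_000),
                              state_weights={4: 1.0}, seed=12, sample_id="Z")
        track = simulate_ratio_track(probe_map, segs, NO_NOISE)
        mid = (probe_map.starts + probe_map.ends) // 2
        chroms = probe_map.probes["chrom"].to_numpy()
        covered = np.zeros(len(probe_map), dtype=bool)
        for s in segs:
            covered |= (chroms == s.chrom) & (mid >= s.start) & (mid < s.end)
        assert np.all(track.log2[covered] == 1.0)
        assert np.all(track.log2[~covered] == 0.0)

    def test_pure_noise_sd_consistent(self):
        genome = GenomeSpec((("1", 10_000_000),))
        pm = simulate_probe_map(genome, mean_spacing=1000, seed=1)
        assert len(pm) > 8000
        track = simulate_ratio_track(pm, [], NoiseSpec(probe_sd=0.15, seed=2,
                                                       qc_fail_fraction=0.0))
        assert 0.15 * 0.9 <= track.log2.std() <= 0.15 * 1.1

    def test_wave_recoverable_by_sinusoid_fit(self):
        genome = GenomeSpec((("1", 30_000_000),))
        pm = simulate_probe_map(genome, mean_spacing=3000, seed=4)
        period = 10e6
        track = simulate_ratio_track(
            pm, [], NoiseSpec(probe_sd=0.05, wave_amplitude=0.2,
                              wave_period=period, qc_fail_fraction=0.0, seed=6))
        pos = pm.starts.astype(float)
        design = np.column_stack([np.sin(2 * np.pi * pos / period),
                                  np.cos(2 * np.pi * pos / period),
                                  np.ones_like(pos)])
        coef, *_ = np.linalg.lstsq(design, track.log2, rcond=None)
        amp = math.hypot(coef[0], coef[1])
        assert amp == pytest.approx(0.2, rel=0.1)

    def test_qc_failures_injected(self, probe_map):
        track = simulate_ratio_track(probe_map, [],
                                     NoiseSpec(probe_sd=0.1, seed=3,
                                               qc_fail_fraction=0.05))
        d = track.data
        bad = ((d["intensity_test"] <= 50) | (d["intensity_ref"] <= 50)
               | (d["snr_test"] <= 25) | (d["snr_ref"] <= 25))
        assert bad.sum() == pytest.approx(0.05 * len(probe_map), rel=0.2)

    def test_same_seed_identical_track(self, probe_map):
        spec = NoiseSpec(probe_sd=0.2, seed=42)
        a = simulate_ratio_track(probe_map, [], spec)
        b = simulate_ratio_track(probe_map, [], spec)
        assert a.data.equals(b.data)


class TestSexMismatch:
    def test_zero_noise_construction(self, probe_map):
        track = simulate_sex_mismatch(probe_map, NO_NOISE)
        chroms = probe_map.probes["chrom"].to_numpy()
        assert np.all(track.log2[chroms == "X"] == -1.0)
        assert np.all(track.log2[chroms == "1"] == 0.0)

    def test_chry_probes_are_gains_at_zero_noise(self):
        genome = default_genome(n_autosomes=1, autosome_mb=5, with_x=True,
                                x_mb=3, with_y=True, y_mb=2)
        pm = simulate_probe_map(genome, seed=2)
        track = simulate_sex_mismatch(pm, NO_NOISE)
        chroms = pm.probes["chrom"].to_numpy()
        assert np.all(track.log2[chroms == "Y"] > 0)

    def test_requires_x_chromosome(self):
        genome = GenomeSpec((("1", 2_000_000),))
        pm = simulate_probe_map(genome, seed=0)
        with pytest.raises(ValueError, match="X"):
            simulate_sex_mismatch(pm, NO_NOISE)

    def test_noisy_chrx_rarely_positive(self):
        genome = default_genome(n_autosomes=0, with_x=True, x_mb=20)
        pm = simulate_probe_map(genome, mean_spacing=2000, seed=5)
        track = simulate_sex_mismatch(pm, NoiseSpec(probe_sd=0.15, seed=6,
                                                    qc_fail_fraction=0.0))
        frac_pos = float((track.log2 > 0).mean())
        assert frac_pos < 1e-3  # Phi(-1/0.15) is ~1e-11


class TestQpcr:
    def test_noiseless_ddct_is_exact(self):
        from cghcnv.core import TruthSegment
        truth = [TruthSegment("P1", "1", 0, 100_000, 4, 1.0),
                 TruthSegment("P1", "1", 200_000, 300_000, 1, -1.0)]
        t_gain = QpcrTarget("tg", "1", 40_000, 40_200)
        t_loss = QpcrTarget("tl", "1", 240_000, 240_200)
        ct = simulate_qpcr(truth, [(t_gain, "P1"), (t_loss, "P1")],
                           efficiency=2.0, ct_sd=0.0, seed=1)
        assert ddct_copy_ratio(ct, "tg", "P1") == pytest.approx(2.0, abs=1e-12)
        assert ddct_copy_ratio(ct, "tl", "P1") == pytest.approx(0.5, abs=1e-12)
        # region with no truth info is treated as baseline
        t_base = QpcrTarget("tb", "1", 500_000, 500_200)
        ct2 = simulate_qpcr(truth, [(t_base, "P1")], ct_sd=0.0, seed=1)
        assert ddct_copy_ratio(ct2, "tb", "P1") == pytest.approx(1.0, abs=1e-12)

    def test_duplicate_wells_present(self):
        from cghcnv.core import TruthSegment
        truth = [TruthSegment("P1", "1", 0, 100_000, 3, 0.585)]
        t = QpcrTarget("t1", "1", 50_000, 50_200)
        ct = simulate_qpcr(truth, [(t, "P1")], ct_sd=0.1, seed=2)
        counts = ct.records.groupby(["sample_id", "target_id"]).size()
        assert (counts == 2).all()

    def test_baseline_ct_differences_center_on_zero(self):
        from cghcnv.core import TruthSegment
        truth = [TruthSegment("P1", "1", 0, 10_000, 3, 0.585)]
        targets = [(QpcrTarget(f"b{i}", "1", 1_000_000 + 10_000 * i,
                               1_000_000 + 10_000 * i + 200), "P1")
                   for i in range(200)]
        ct_sd = 0.1
        ct = simulate_qpcr(truth, targets, ct_sd=ct_sd, seed=3)
        diffs = []
        for i in range(200):
            diffs.append(ct.mean_ct("P1", f"b{i}") - ct.mean_ct("REF", f"b{i}"))
        diffs = np.array(diffs)
        assert abs(diffs.mean()) < 3 * ct_sd / np.sqrt(len(diffs))

    def test_efficiency_bounds_enforced(self):
        with pytest.raises(ValueError):
            simulate_qpcr([], [], efficiency=1.5, seed=0)
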