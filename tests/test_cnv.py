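"""Smoothing, purity/ploidy grid search and chromosome calling."""

import numpy as np
import pandas as pd
import pytest

from sptumor.core import (
    AUTOSOMES,
    ChromosomeCall,
    MarkerProfile,
    PurityPloidyEstimate,
)
from sptumor.cnv import (
    call_chromosomes,
    estimate_purity_ploidy,
    exon_ratio_screen,
    moving_average_ratio,
    singleton_profile,
)
from sptumor.simulate import SimulationConfig, simulate_marker_profile


def make_profile(segments, het=False, alt_fraction=0.5):
    """Manual marker profile from (chrom, n, tumor_depth, normal_depth) blocks."""
    frames = []
    offsets: dict[str, int] = {}
    for chrom, n, t, nd in segments:
        start = offsets.get(chrom, 0)
        offsets[chrom] = start + n
        t_depth = np.full(n, t, dtype=float)
        alt = t_depth * alt_fraction if het else np.zeros(n)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": np.arange(start + 1, start + n + 1),
                    "tumor_depth": t_depth,
                    "normal_depth": float(nd),
                    "tumor_alt": alt,
                    "tumor_ref": t_depth - alt,
                    "het": het,
                }
            )
        )
    return MarkerProfile(pd.concat(frames, ignore_index=True))


class TestMovingAverage:
    def test_constant_input_is_fixed_point(self):
        profile = make_profile([("chr1", 200, 30, 30)])
        out = moving_average_ratio(profile, window=25)
        assert np.allclose(out, 1.0)

    def test_window_one_is_identity(self):
        rng = np.random.default_rng(5)
        depths = rng.integers(10, 90, size=100)
        profile = make_profile([("chr1", 1, int(d), 30) for d in depths])
        out = moving_average_ratio(profile, window=1)
        assert np.allclose(out, profile.df["ratio"])

    def test_matches_brute_force_centered_mean(self):
        rng = np.random.default_rng(7)
        ratios = rng.uniform(0.5, 2.5, size=40)
        profile = make_profile([("chr1", 40, 30, 30)])
        profile.df["ratio"] = ratios
        window = 5
        out = moving_average_ratio(profile, window=window).to_numpy()
        for i in range(40):
            lo, hi = max(0, i - window // 2), min(40, i + window // 2 + 1)
            assert out[i] == pytest.approx(ratios[lo:hi].mean())

    def test_windows_never_cross_chromosomes(self):
        profile = make_profile([("chr1", 50, 30, 30), ("chr2", 50, 60, 30)])
        out = moving_average_ratio(profile, window=40)
        assert np.allclose(out[:50], 1.0)
        assert np.allclose(out[50:], 2.0)

    def test_unsorted_positions_rejected(self):
        profile = make_profile([("chr1", 10, 30, 30)])
        profile.df.loc[3, "pos"] = 10_000
        with pytest.raises(ValueError, match="sorted"):
            moving_average_ratio(profile, window=3)

    def test_window_below_one_rejected(self):
        profile = make_profile([("chr1", 10, 30, 30)])
        with pytest.raises(ValueError):
            moving_average_ratio(profile, window=0)


def _autosome_calls(calls):
    return {c.chrom: c for c in calls if c.chrom in AUTOSOMES}


class TestPurityPloidyRecovery:
    def test_noise_free_pure_tumor_recovered_exactly(self, table1):
        cfg = SimulationConfig(seed=11, ploidy_profile=table1, purity=1.0,
                               depth_noise=False)
        profile = simulate_marker_profile(table1, cfg, tumor_id="SpT1")
        est = estimate_purity_ploidy(profile)
        assert est.purity == 1.0
        assert not est.low_confidence
        calls = _autosome_calls(call_chromosomes(profile, est))
        for chrom in AUTOSOMES:
            row = table1.df.query("tumor_id == 'SpT1' and chrom == @chrom").iloc[0]
            assert calls[chrom].copy_number == row["copy_number"], chrom
            assert calls[chrom].minor == row["minor"], chrom
        # chr13 is a 3:0 state: copy-neutral-like loss of heterozygosity flag
        assert calls["chr13"].major == 3 and calls["chr13"].loh_flag

    def test_noise_free_contaminated_tumor_recovered_exactly(self, table1):
        cfg = SimulationConfig(seed=12, ploidy_profile=table1, purity=0.8,
                               depth_noise=False)
        profile = simulate_marker_profile(table1, cfg, tumor_id="SpT1")
        est = estimate_purity_ploidy(profile)
        assert est.purity == pytest.approx(0.8, abs=1e-9)
        calls = _autosome_calls(call_chromosomes(profile, est))
        for chrom in AUTOSOMES:
            expected = table1.copies("SpT1", chrom)
            assert calls[chrom].copy_number == expected, chrom

    def test_noisy_contaminated_tumor_within_tolerance(self, table1):
        cfg = SimulationConfig(seed=13, ploidy_profile=table1, purity=0.825)
        profile = simulate_marker_profile(table1, cfg, tumor_id="SpT1")
        est = estimate_purity_ploidy(profile)
        assert est.purity == pytest.approx(0.825, abs=0.03)
        calls = _autosome_calls(call_chromosomes(profile, est))
        for chrom in AUTOSOMES:
            assert calls[chrom].copy_number == table1.copies("SpT1", chrom), chrom

    def test_half_admixed_tumor_not_mistaken_for_pure(self, table1):
        # rho = 0.5 with copies c is mean-identical to rho = 1 with copies
        # c + 2; BAF and the nullisomy penalty must break the alias
        cfg = SimulationConfig(seed=14, ploidy_profile=table1, purity=0.5)
        profile = simulate_marker_profile(table1, cfg, tumor_id="SpT1")
        est = estimate_purity_ploidy(profile)
        assert est.purity == pytest.approx(0.5, abs=0.05)

    def test_flat_genome_flagged_low_confidence(self):
        rows = [("T1", c, 2, 1, 1) for c in AUTOSOMES]
        rows += [("T1", "chrX", 2, 1, 1), ("T1", "chrY", 2, 1, 1)]
        from sptumor.core import KaryotypeTable

        table = KaryotypeTable(
            pd.DataFrame(rows, columns=["tumor_id", "chrom", "copy_number", "major", "minor"])
        )
        cfg = SimulationConfig(seed=15, ploidy_profile=table, depth_noise=False)
        profile = simulate_marker_profile(table, cfg, tumor_id="T1")
        est = estimate_purity_ploidy(profile)
        assert est.low_confidence
        # purity is unidentifiable here; ties resolve to the purest model
        assert est.purity == 1.0


class TestChromosomeCalls:
    def test_sparse_chromosome_suppressed(self, table1):
        cfg = SimulationConfig(seed=16, ploidy_profile=table1, depth_noise=False)
        profile = simulate_marker_profile(table1, cfg, tumor_id="SpT1")
        est = estimate_purity_ploidy(profile)
        calls = {c.chrom: c for c in call_chromosomes(profile, est)}
        # chrY carries ~1100 markers at the default density, under the floor
        assert calls["chrY"].n_markers <= 1500
        assert calls["chrY"].suppressed
        assert not calls["chr1"].suppressed

    def test_arm_level_run_reported_as_event(self):
        # chr1 is 2 copies except a 2,000-marker interior run at 4 copies
        t = np.full(6000, 26.0)
        t[2000:4000] = 52.0
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(1, 6001),
                "tumor_depth": t,
                "normal_depth": 26.0,
                "tumor_alt": 0.0,
                "tumor_ref": t,
                "het": False,
            }
        )
        other = pd.DataFrame(
            {
                "chrom": "chr2",
                "pos": np.arange(1, 6001),
                "tumor_depth": 39.0,
                "normal_depth": 26.0,
                "tumor_alt": 0.0,
                "tumor_ref": 39.0,
                "het": False,
            }
        )
        profile = MarkerProfile(pd.concat([df, other], ignore_index=True))
        est = PurityPloidyEstimate(purity=1.0, haploid_coverage=13.0)
        calls = {c.chrom: c for c in call_chromosomes(profile, est, window=1)}
        assert calls["chr1"].copy_number == 2
        assert len(calls["chr1"].arm_events) == 1
        start, end, copy = calls["chr1"].arm_events[0]
        assert copy == 4
        assert start == 2001 and end == 4000
        assert calls["chr2"].copy_number == 3
        assert calls["chr2"].arm_events == []

    def test_short_deviant_run_ignored(self):
        t = np.full(6000, 26.0)
        t[3000:3400] = 52.0  # 400 markers: below the evidence floor
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(1, 6001),
                "tumor_depth": t,
                "normal_depth": 26.0,
                "tumor_alt": 0.0,
                "tumor_ref": t,
                "het": False,
            }
        )
        profile = MarkerProfile(df)
        est = PurityPloidyEstimate(purity=1.0, haploid_coverage=13.0)
        calls = {c.chrom: c for c in call_chromosomes(profile, est, window=1)}
        assert calls["chr1"].arm_events == []


class TestSingletonProfile:
    def test_ratio_against_modal_coverage_baseline(self):
        t = np.full(4000, 40.0)
        t[1000:2000] = 80.0  # a gained block
        t[5] = 0.0  # zero-coverage marker must be masked
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": np.arange(1, 4001),
                "tumor_depth": t,
                "normal_depth": 0.0,
                "tumor_alt": 0.0,
                "tumor_ref": t,
                "het": False,
            }
        )
        profile = MarkerProfile(df, tumor_id="solo")
        smoothed = singleton_profile(profile, window=1)
        assert smoothed.iloc[0] == pytest.approx(1.0)
        assert smoothed.iloc[1500] == pytest.approx(2.0)
        assert np.isnan(smoothed.iloc[5])

    def test_explicit_baseline_and_validation(self):
        df = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": [1, 2, 3],
                "tumor_depth": [30.0, 30.0, 30.0],
                "normal_depth": 0.0,
                "tumor_alt": 0.0,
                "tumor_ref": 30.0,
                "het": False,
            }
        )
        profile = MarkerProfile(df)
        out = singleton_profile(profile, expected_diploid_coverage=60.0, window=1)
        assert np.allclose(out, 0.5)
        with pytest.raises(ValueError):
            singleton_profile(profile, expected_diploid_coverage=0.0)


class TestExonScreen:
    @staticmethod
    def _setup():
        est = PurityPloidyEstimate(purity=1.0, haploid_coverage=13.0)
        calls = [
            ChromosomeCall("chr1", 2, 1, 1, 5000),
            ChromosomeCall("chr2", 3, 2, 1, 5000),
        ]
        return est, calls

    def test_flags_only_strictly_deviant_exons(self):
        est, calls = self._setup()
        exons = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr1"],
                "start": [100, 500, 900],
                "end": [200, 600, 1000],
                # implied copies (x2 of the ratio at h = 0.5): 2.0, 3.0, 3.1
                "tumor_mean": [26.0, 39.0, 40.3],
                "normal_mean": [26.0, 26.0, 26.0],
            }
        )
        out = exon_ratio_screen(exons, est, calls, median_normal_depth=26.0)
        # deviation of exactly 1.0 copy is not strictly greater than 1.0
        assert list(out["start"]) == [900]
        assert out["deviation"].iloc[0] == pytest.approx(1.1)

    def test_suppressed_chromosomes_and_zero_normal_skipped(self):
        est, calls = self._setup()
        calls.append(ChromosomeCall("chr3", 0, 0, 0, 100, suppressed=True))
        exons = pd.DataFrame(
            {
                "chrom": ["chr3", "chr1"],
                "start": [10, 20],
                "end": [90, 80],
                "tumor_mean": [120.0, 80.0],
                "normal_mean": [26.0, 0.0],
            }
        )
        out = exon_ratio_screen(exons, est, calls, median_normal_depth=26.0)
        assert out.empty
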