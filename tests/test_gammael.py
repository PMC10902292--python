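"""Gamma-patch detection, element characterization, table filters, statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from _patch_oracle import oracle_patches
from gammaens import gammael
from gammaens.thetacycles import ThetaCycle

CYCLE = ThetaCycle(start_peak=0, desc_flank=25, trough=50, asc_flank=75,
                   end_peak=100, amplitude=1.5, duration_ms=100.0,
                   frequency=10.0, asymmetry=1.0)


def blob_snippet(blobs):
    """38x36 snippet with rectangular blobs: (row, col, height) triples."""
    s = np.zeros((38, 36))
    for r, c, h in blobs:
        s[r:r + 2, c:c + 2] = h
    return s


class TestDetectPatches:
    def test_six_disjoint_blobs_capped_at_four_strongest(self):
        snip = blob_snippet([(5, 3, 10), (10, 8, 9), (15, 13, 8),
                             (20, 18, 7), (25, 23, 6), (30, 28, 5)])
        patches = gammael.detect_patches(snip, min_freq_hz=0)
        assert len(patches) == 4
        assert sorted(p.mean_amp for p in patches) == [7, 8, 9, 10]

    def test_single_blob_single_patch(self):
        snip = blob_snippet([(12, 10, 5)])
        patches = gammael.detect_patches(snip)
        assert len(patches) == 1
        assert len(patches[0].rows) == 4

    def test_saddle_connection_does_not_fuse_patches(self):
        snip = np.zeros((38, 36))
        snip[10, 10], snip[10, 11], snip[10, 12] = 10.0, 4.0, 9.0
        patches = gammael.detect_patches(snip, min_freq_hz=0)
        assert len(patches) == 2
        extents = sorted(sorted(zip(p.rows, p.cols)) for p in patches)
        assert extents == [[(10, 10)], [(10, 12)]]

    def test_all_zero_snippet_gives_no_patches(self):
        assert gammael.detect_patches(np.zeros((38, 36))) == []

    def test_sub_gamma_rows_do_not_seed_patches(self):
        snip = np.zeros((38, 36))
        snip[0:2, 5] = 9.0  # 15-20 Hz rows, below the gamma composite band
        assert gammael.detect_patches(snip) == []
        assert len(gammael.detect_patches(snip, min_freq_hz=0)) == 1

    @pytest.mark.parametrize("ties", [False, True])
    def test_matches_bruteforce_threshold_sweep(self, ties):
        rng = np.random.default_rng(11)
        for _ in range(40):
            if ties:
                amp = rng.integers(0, 8, size=(10, 10)).astype(float)
            else:
                amp = np.abs(rng.normal(size=(10, 10)))
            mine = gammael.detect_patches(amp, max_count=100, min_freq_hz=0)
            got = sorted((frozenset(zip(p.rows.tolist(), p.cols.tolist()))
                          for p in mine), key=sorted)
            ref = sorted(oracle_patches(amp, max_count=100), key=sorted)
            assert got == ref

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_element_count_never_exceeds_four(self, seed):
        amp = np.abs(np.random.default_rng(seed).normal(size=(38, 36)))
        assert len(gammael.detect_patches(amp)) <= 4


class TestBoundaryHandling:
    def test_straddling_patch_assigned_to_stronger_cycle_only(self):
        a = np.zeros((38, 36))
        b = np.zeros((38, 36))
        a[10, 34:36] = 5.0   # stronger share in cycle A
        b[10, 0] = 4.0       # continuation into cycle B
        got_a = gammael.detect_patches(a, neighbors=(None, b), min_freq_hz=0)
        got_b = gammael.detect_patches(b, neighbors=(a, None), min_freq_hz=0)
        assert len(got_a) == 1 and len(got_b) == 0
        # full cross-boundary extent is recovered
        assert len(got_a[0].rows) == 3

    def test_interior_patch_unaffected_by_neighbors(self):
        a = blob_snippet([(12, 15, 6)])
        plain = gammael.detect_patches(a)
        with_n = gammael.detect_patches(a, neighbors=(np.zeros((38, 36)),) * 2)
        assert len(plain) == len(with_n) == 1
        assert sorted(zip(plain[0].rows, plain[0].cols)) == \
            sorted(zip(with_n[0].rows, with_n[0].cols - with_n[0].col_offset))


class TestCharacterize:
    def test_single_cell_element(self):
        snip = np.zeros((38, 36))
        snip[13, 17] = 5.0  # 80 Hz row, 175 deg bin center
        el = gammael.characterize_element(
            gammael.detect_patches(snip)[0], CYCLE)
        assert el.gamma_amplitude == 5.0
        assert el.gamma_frequency == 80.0
        assert el.gamma_phase == 175.0
        assert el.theta_amplitude == CYCLE.amplitude
        assert el.theta_frequency == CYCLE.frequency

    def test_power_weighted_frequency(self):
        # cells at 70 Hz (weight 1) and 90 Hz (weight 3) -> 85 Hz
        p = gammael.GammaPatch(rows=np.array([11, 15]), cols=np.array([5, 5]),
                               amps=np.array([1.0, 3.0]), birth_threshold=1.0)
        assert p.frequency() == pytest.approx(85.0)

    def test_circular_phase_mean_across_wrap(self):
        # bin centers 355 and 5 deg, equal weight -> 0 deg
        p = gammael.GammaPatch(rows=np.array([10, 10]), cols=np.array([35, 0]),
                               amps=np.array([1.0, 1.0]), birth_threshold=1.0)
        assert p.phase_deg() == pytest.approx(0.0, abs=1e-9)


class TestElementTable:
    def _elements(self, n, amps=None, speeds=None, rng_seed=0):
        rng = np.random.default_rng(rng_seed)
        amps = rng.uniform(1, 2, n) if amps is None else amps
        speeds = np.full(n, 20.0) if speeds is None else speeds
        return [gammael.GammaElement(
            gamma_amplitude=float(a), gamma_frequency=80.0, gamma_phase=100.0,
            theta_amplitude=1.0, theta_frequency=10.0, theta_asymmetry=1.0,
            channel=3, layer="rad", trial=0, cycle_id=i, section="other",
            speed=float(s)) for i, (a, s) in enumerate(zip(amps, speeds))]

    def test_uniform_amplitudes_survive_one_percent_trims(self):
        table = gammael.compile_element_table(self._elements(1000))
        assert 980 <= len(table) < 1000

    def test_high_speed_cycles_excluded(self):
        els = self._elements(200)
        els[7].speed = 120.0
        table = gammael.compile_element_table(els)
        assert 7 not in set(table["cycle_id"])

    def test_empty_input_gives_empty_table_with_header(self):
        table = gammael.compile_element_table([])
        assert len(table) == 0
        assert "gamma_frequency" in table.columns

    def test_amplitudes_strictly_inside_percentile_band(self):
        els = self._elements(500)
        original = np.array([e.gamma_amplitude for e in els])
        table = gammael.compile_element_table(els)
        assert table["gamma_amplitude"].min() > np.percentile(original, 1)
        assert table["gamma_amplitude"].max() < np.percentile(original, 99)
        assert len(table) < 500


class TestBandRatio:
    grid = np.arange(15.0, 200.1, 5.0)

    def _pdf(self, center):
        p = np.exp(-((self.grid - center) ** 2) / 20.0)
        return p / p.sum()

    def test_all_slow_mass_gives_minus_one(self):
        assert gammael.gamma_band_ratio(self._pdf(40.0), self.grid) == -1.0

    def test_all_medium_mass_gives_plus_one(self):
        assert gammael.gamma_band_ratio(self._pdf(80.0), self.grid) == 1.0

    def test_equal_modes_balance_to_zero(self):
        pdf = self._pdf(40.0) + self._pdf(80.0)
        ratio = gammael.gamma_band_ratio(pdf / pdf.sum(), self.grid)
        assert abs(ratio) < 0.05

    def test_no_mode_in_either_band_rejected(self):
        with pytest.raises(ValueError):
            gammael.gamma_band_ratio(self._pdf(180.0), self.grid)


class TestKLBootstrap:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(60, 10, 2000)
        b = rng.normal(60, 10, 2000)
        out = gammael.compare_distributions_kl(a, b, reps=150, subsample=500,
                                               seed=1)
        assert not out["significant"]

    def test_separated_distributions_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(40, 5, 3000)
        b = rng.normal(90, 5, 3000)
        out = gammael.compare_distributions_kl(a, b, reps=150, subsample=500,
                                               seed=1)
        assert out["significant"]
        assert out["divergence"] > out["null_upper_95"]

    def test_identical_samples_have_near_zero_divergence(self):
        a = np.random.default_rng(2).normal(60, 10, 2000)
        out = gammael.compare_distributions_kl(a, a.copy(), reps=60,
                                               subsample=800, seed=1)
        # only histogram sampling noise remains at this subsample size
        assert out["divergence"] < 0.05
        assert not out["significant"]
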