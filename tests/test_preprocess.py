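"""Signal conditioning: band-pass, alignment, biopsy masking, gating, ROIs."""

import numpy as np
import pytest

from thzburn.containers import SiteLabel, WaveformTrace
from thzburn.errors import ConfigurationError, GatingError
from thzburn.preprocess import (
    GateSpec,
    align_cube,
    bandpass,
    detect_invalid_pixels,
    extract_roi_observations,
    gate_tissue_reflection,
)
from thzburn.synthdata import demo_config, generate_dataset, generate_site_cube


def _healthy(site="s0"):
    return SiteLabel(site, "healthy", 0.0, 100.0)


def _tone(freq_thz, n=2048, dt=0.05):
    # snap to the nearest DFT bin so circular filtering probes the
    # transfer function without spectral-leakage edge artifacts
    f = round(freq_thz * n * dt) / (n * dt)
    t = np.arange(n) * dt
    return WaveformTrace(0.0, dt, np.sin(2 * np.pi * f * t))


class TestBandpass:
    def test_in_band_tone_preserved(self):
        x = _tone(0.5)
        y = bandpass(x, 0.1, 1.0)
        assert np.max(np.abs(y.samples)) == pytest.approx(1.0, rel=0.01)

    def test_out_of_band_tone_suppressed(self):
        x = _tone(2.0)
        y = bandpass(x, 0.1, 1.0)
        assert np.max(np.abs(y.samples)) <= 0.01

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            bandpass(_tone(0.5, dt=0.2), 0.1, 3.0)

    def test_zero_phase_no_peak_shift(self):
        cfg = demo_config(snr_db=None, drift_max=0, nx=1, ny=1)
        cube = generate_site_cube(cfg, _healthy())
        trace = cube.trace(0, 0)
        filtered = bandpass(trace, 0.1, 1.0)
        assert abs(int(np.argmax(np.abs(filtered.samples))) - int(np.argmax(np.abs(trace.samples)))) <= 1


class TestAlignment:
    def _cube_and_air(self, seed=7, snr=30.0):
        cfg = demo_config(snr_db=snr, drift_max=0, nx=6, ny=6, seed=seed)
        cubes, air = generate_dataset(cfg, {"H": 1}, seed=seed)
        return cfg, cubes[0], air

    def test_planted_global_shift_recovered(self):
        """+7-sample global shift recovered as -7 against the air template."""
        cfg, cube, air = self._cube_and_air()
        original = cube.data.copy()
        cube.data = np.roll(cube.data, 7, axis=2)
        gate = (cfg.tau1 - 4, cfg.tau1 + 4)
        aligned, shifts = align_cube(cube, gate, template=air)
        assert np.all(shifts == -7)
        np.testing.assert_array_equal(aligned.data, original)

    def test_already_aligned_cube_gets_zero_shifts(self):
        cfg, cube, air = self._cube_and_air()
        _, shifts = align_cube(cube, (cfg.tau1 - 4, cfg.tau1 + 4), template=air)
        assert np.all(shifts == 0)

    def test_per_pixel_shift_against_site_median(self):
        """One deviant pixel realigns to the site-median template."""
        cfg, cube, _ = self._cube_and_air(snr=None)
        cube.data[2, 3] = np.roll(cube.data[2, 3], 5)
        _, shifts = align_cube(cube, (cfg.tau1 - 4, cfg.tau1 + 4))
        assert shifts[2, 3] == -5
        shifts[2, 3] = 0
        assert np.all(shifts == 0)

    def test_generator_drift_within_bound(self):
        cfg = demo_config(snr_db=30.0, drift_max=6, nx=6, ny=6, seed=20)
        cubes, air = generate_dataset(cfg, {"H": 4}, seed=20)
        for cube in cubes:
            _, shifts = align_cube(cube, (cfg.tau1 - 4, cfg.tau1 + 4), template=air)
            assert np.all(np.abs(shifts) <= cfg.drift_max)
            assert np.all(shifts == -cube.meta["drift_samples"])

    def test_flat_gate_pixel_marked_invalid(self):
        cfg, cube, air = self._cube_and_air(snr=None)
        cube.data[1, 1] = 0.0
        aligned, _ = align_cube(cube, (cfg.tau1 - 4, cfg.tau1 + 4), template=air)
        assert not aligned.valid_mask[1, 1]

    def test_gate_outside_trace_rejected(self):
        cfg, cube, air = self._cube_and_air()
        with pytest.raises(ConfigurationError):
            align_cube(cube, (-10.0, -1.0), template=air)


class TestBiopsyDetection:
    def test_planted_biopsy_block_recovered_exactly(self):
        """A 4x4 planted block at 30-dB SNR is flagged exactly (plus corners)."""
        cfg = demo_config(snr_db=30.0, nx=25, ny=25, seed=13)
        cube = generate_site_cube(cfg, _healthy(), biopsy_region=(10, 8, 4, 4))
        echo = cfg.tau2 + cfg.fp_delay
        mask = detect_invalid_pixels(cube, (echo - 2.5, echo + 3.5), k_mad=5.0)
        expected = np.ones((25, 25), bool)
        expected[10:14, 8:12] = False
        for iy in (0, 24):
            for ix in (0, 24):
                expected[iy, ix] = False
        assert np.array_equal(mask, expected)

    def test_clean_cube_keeps_all_but_corners(self):
        cfg = demo_config(snr_db=None, drift_max=0, nx=10, ny=10)
        cube = generate_site_cube(cfg, _healthy())
        echo = cfg.tau2 + cfg.fp_delay
        mask = detect_invalid_pixels(cube, (echo - 2.5, echo + 3.5), k_mad=5.0)
        assert mask.sum() == 100 - 4

    def test_flagging_stable_in_echo_amplitude(self):
        """Once above threshold, a stronger echo flags the same set."""
        flagged = []
        for fp_amp in (0.3, 0.6, 0.9):
            cfg = demo_config(snr_db=30.0, nx=12, ny=12, seed=4, fp_amp=fp_amp)
            cube = generate_site_cube(cfg, _healthy(), biopsy_region=(4, 4, 4, 4))
            echo = cfg.tau2 + cfg.fp_delay
            mask = detect_invalid_pixels(cube, (echo - 2.5, echo + 3.5), k_mad=5.0)
            flagged.append(frozenset(map(tuple, np.argwhere(~mask))))
        assert flagged[0] == flagged[1] == flagged[2]

    def test_gate_outside_trace_rejected(self):
        cfg = demo_config(nx=6, ny=6)
        cube = generate_site_cube(cfg, _healthy())
        with pytest.raises(ConfigurationError):
            detect_invalid_pixels(cube, (100.0, 200.0))


class TestGating:
    def _trace(self, tau2=20.0):
        cfg = demo_config(snr_db=None, drift_max=0, nx=1, ny=1, tau2=tau2)
        return cfg, generate_site_cube(cfg, _healthy()).trace(0, 0)

    def test_gate_length_is_width_over_dt(self):
        cfg, trace = self._trace()
        out = gate_tissue_reflection(trace, GateSpec(width=12.8), (14.0, 30.0))
        assert out.n_samples == 256
        # the conventional 25-ps gate at 0.01-ps sampling holds 2500 samples
        assert GateSpec(width=25.0).n_samples(0.01) == 2500

    def test_window_weighting_is_pointwise(self):
        from scipy.signal.windows import blackman

        cfg, trace = self._trace()
        spec = GateSpec(width=12.8)
        out = gate_tissue_reflection(trace, spec, (14.0, 30.0))
        m = out.n_samples
        start = int(round((out.t0 - trace.t0) / trace.dt))
        np.testing.assert_allclose(
            out.samples, trace.samples[start : start + m] * blackman(m), atol=1e-15
        )

    def test_translation_invariance_of_peak_centred_gate(self):
        """Identical pulses at different arrival times gate identically
        (arrivals far enough from the first reflection's tail)."""
        _, a = self._trace(tau2=22.0)
        _, b = self._trace(tau2=30.0)
        spec = GateSpec(width=12.8)
        ga = gate_tissue_reflection(a, spec, (16.0, 28.0))
        gb = gate_tissue_reflection(b, spec, (24.0, 36.0))
        np.testing.assert_allclose(ga.samples, gb.samples, atol=1e-8)

    def test_truncated_window_rejected(self):
        cfg, trace = self._trace()
        with pytest.raises(GatingError):
            gate_tissue_reflection(trace, GateSpec(width=45.0), (14.0, 30.0))

    def test_gating_is_idempotent(self):
        cfg, trace = self._trace()
        spec = GateSpec(width=12.8)
        once = gate_tissue_reflection(trace, spec, (14.0, 30.0))
        twice = gate_tissue_reflection(once, spec, (14.0, 30.0))
        np.testing.assert_array_equal(once.samples, twice.samples)


class TestROIExtraction:
    def _valid_cube(self, nx=25, ny=25):
        cfg = demo_config(snr_db=30.0, nx=nx, ny=ny, seed=6)
        cube = generate_site_cube(cfg, _healthy())
        cube.valid_mask[:] = True
        return cube

    def test_fully_valid_grid_tiles_completely(self):
        assert len(extract_roi_observations(self._valid_cube(), 5)) == 25

    def test_blocks_touching_invalid_pixels_dropped(self):
        cube = self._valid_cube()
        cube.valid_mask[7, 7] = False  # inside tile (1, 1)
        obs = extract_roi_observations(cube, 5)
        assert len(obs) == 24
        assert all(o.roi_id != f"{cube.label.site_id}:r1c1" for o in obs)

    def test_mean_of_identical_traces_is_identity(self):
        cfg = demo_config(snr_db=None, drift_max=0, nx=5, ny=5)
        cube = generate_site_cube(cfg, _healthy())
        cube.valid_mask[:] = True
        obs = extract_roi_observations(cube, 5)
        assert len(obs) == 1
        np.testing.assert_allclose(obs[0].mean_trace.samples, cube.data[0, 0], atol=1e-12)

    def test_observation_count_bounded_by_tiling(self):
        cube = self._valid_cube(nx=27, ny=27)
        assert len(extract_roi_observations(cube, 5)) <= (27 // 5) ** 2

    def test_roi_larger_than_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            extract_roi_observations(self._valid_cube(nx=4, ny=4), 5)
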