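"""Spectral-processing contracts: apodization, FT, phasing, baseline,
referencing, binning, exclusion, alignment and normalization."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nmrmetab as nm
from nmrmetab.nmrproc import bin_edge_grid

CFG = nm.ProcessingConfig()


def lorentzian(ppm, center, height, hw_ppm):
    g = hw_ppm / 2.0
    return height * g**2 / ((ppm - center) ** 2 + g**2)


def make_axis(step=0.001, lo=0.2, hi=9.7):
    n = int(round((hi - lo) / step)) + 1
    return np.linspace(hi, lo, n)


# ---------------------------------------------------------------------------
# FID-domain


class TestApodize:
    def test_zero_lb_is_identity(self, rng):
        fid = nm.Fid(rng.normal(size=256) + 1j * rng.normal(size=256), 1e-3)
        out = nm.apodize(fid, 0.0)
        assert np.array_equal(out.points, fid.points)

    def test_first_point_unchanged_and_closed_form(self):
        fid = nm.Fid(np.ones(2048, dtype=complex), dwell_time=1e-3)
        out = nm.apodize(fid, 1.0)
        assert out.points[0] == 1.0
        # point k=1000 at lb=1 Hz, dwell=1 ms: exp(-pi * 1 * 1000 * 1e-3)
        assert out.points[1000].real == pytest.approx(np.exp(-np.pi), rel=1e-12)

    def test_negative_lb_rejected(self):
        fid = nm.Fid(np.ones(4, dtype=complex), 1e-3)
        with pytest.raises(nm.ProcessingError):
            nm.apodize(fid, -1.0)


class TestZeroFill:
    def test_identity_padding_and_energy(self, rng):
        pts = rng.normal(size=1024) + 1j * rng.normal(size=1024)
        fid = nm.Fid(pts, 1e-3)
        assert np.array_equal(nm.zero_fill(fid, 1024).points, pts)
        out = nm.zero_fill(fid, 4096)
        assert out.points.size == 4096
        assert np.all(out.points[1024:] == 0)
        assert np.abs(out.points).sum() == pytest.approx(np.abs(pts).sum())

    def test_shrinking_rejected(self):
        with pytest.raises(nm.ProcessingError):
            nm.zero_fill(nm.Fid(np.ones(16, dtype=complex), 1e-3), 8)


class TestFourierTransform:
    def test_damped_exponential_gives_lorentzian_at_offset(self):
        n, dwell, f = 8192, 1e-4, 300.0
        t = np.arange(n) * dwell
        fid = nm.Fid(np.exp(2j * np.pi * f * t - t / 0.5), dwell,
                     spectrometer_freq=599.35, carrier_ppm=4.7)
        spec = nm.fourier_transform(fid)
        expected_ppm = 4.7 + f / 599.35
        peak_ppm = spec.ppm[np.argmax(spec.intensity)]
        grid_step = abs(np.median(np.diff(spec.ppm)))
        assert abs(peak_ppm - expected_ppm) <= grid_step

    def test_zero_fid_and_parseval(self, rng):
        zero = nm.fourier_transform(nm.Fid(np.zeros(64, dtype=complex), 1e-3))
        assert np.all(zero.intensity == 0)
        pts = rng.normal(size=512) + 1j * rng.normal(size=512)
        spec = nm.fourier_transform(nm.Fid(pts, 1e-3))
        lhs = (np.abs(spec.complex_intensity) ** 2).sum()
        rhs = 512 * (np.abs(pts) ** 2).sum()
        assert lhs == pytest.approx(rhs, rel=1e-9)


class TestPhaseCorrect:
    def _lorentz_spectrum(self):
        ppm = make_axis()
        real = lorentzian(ppm, 5.0, 1.0, 0.01)
        g = 0.005
        imag = -1.0 * g * (ppm - 5.0) / ((ppm - 5.0) ** 2 + g**2) * g
        return nm.Spectrum(ppm, real, complex_intensity=real + 1j * imag)

    def test_explicit_zero_is_identity(self):
        spec = self._lorentz_spectrum()
        out = nm.phase_correct(spec, 0.0)
        assert np.allclose(out.intensity, spec.intensity)

    def test_group_property(self):
        spec = self._lorentz_spectrum()
        out = nm.phase_correct(nm.phase_correct(spec, 90.0), -90.0)
        assert np.allclose(out.intensity, spec.intensity, atol=1e-12)

    def test_auto_recovers_known_rotation(self):
        spec = self._lorentz_spectrum()
        rotated = nm.phase_correct(spec, 33.0)
        fixed = nm.phase_correct(rotated, "auto")
        assert np.allclose(
            fixed.intensity, spec.intensity, atol=2e-3 * spec.intensity.max()
        )


class TestBaseline:
    def test_constant_offset_removed(self):
        ppm = make_axis()
        signal = lorentzian(ppm, 3.0, 1.0, 0.004) + lorentzian(ppm, 7.0, 0.5, 0.004)
        c = 0.3
        out = nm.baseline_correct(nm.Spectrum(ppm, signal + c))
        removed = (signal + c) - out.intensity
        # offset recovered within 5% of c in signal-free territory
        free = (ppm > 4.0) & (ppm < 6.0)
        assert np.abs(removed[free] - c).max() < 0.05 * c

    def test_removed_component_is_smooth(self):
        ppm = make_axis()
        signal = lorentzian(ppm, 5.0, 2.0, 0.004) + 0.1
        out = nm.baseline_correct(nm.Spectrum(ppm, signal))
        removed = signal - out.intensity
        # second difference of the baseline stays tiny vs the peak height
        assert np.abs(np.diff(removed, 2)).max() < 1e-4 * signal.max()

    def test_zero_baseline_nearly_untouched(self):
        ppm = make_axis()
        signal = lorentzian(ppm, 5.0, 1.0, 0.004)
        out = nm.baseline_correct(nm.Spectrum(ppm, signal))
        assert np.abs(out.intensity - signal).max() < 0.02


class TestReferencing:
    def _spec_with_peak(self, center):
        ppm = make_axis()
        return nm.Spectrum(ppm, lorentzian(ppm, center, 1.0, 0.004))

    def test_known_shift(self):
        out = nm.reference_to_glucose(self._spec_with_peak(5.240), CFG)
        assert np.allclose(out.ppm - self._spec_with_peak(5.240).ppm, -0.004)
        peak = out.ppm[np.argmax(out.intensity)]
        assert peak == pytest.approx(5.236, abs=1e-9)

    def test_already_referenced_is_identity(self):
        spec = self._spec_with_peak(5.236)
        out = nm.reference_to_glucose(spec, CFG)
        assert np.array_equal(out.ppm, spec.ppm)

    def test_idempotent(self):
        once = nm.reference_to_glucose(self._spec_with_peak(5.241), CFG)
        twice = nm.reference_to_glucose(once, CFG)
        assert np.array_equal(once.ppm, twice.ppm)

    def test_flat_spectrum_raises(self):
        ppm = make_axis()
        with pytest.raises(nm.ReferencingError):
            nm.reference_to_glucose(nm.Spectrum(ppm, np.zeros_like(ppm)), CFG)


class TestBinning:
    def test_bin_count_is_2125(self):
        assert bin_edge_grid(CFG).shape[0] == 2125

    def test_constant_intensity(self):
        ppm = make_axis()
        row = nm.bin_spectrum(nm.Spectrum(ppm, np.ones_like(ppm)), CFG)
        assert np.allclose(row, 0.004, rtol=1e-9)

    def test_additivity(self, rng):
        # axis whose endpoints are exactly the bin-range edges
        ppm = np.linspace(9.0, 0.5, 8501)
        inten = rng.random(ppm.size)
        row = nm.bin_spectrum(nm.Spectrum(ppm, inten), CFG)
        full = np.trapezoid(inten[::-1], ppm[::-1])
        assert row.sum() == pytest.approx(full, rel=1e-9)

    def test_narrow_spectrum_rejected(self):
        ppm = np.linspace(6.0, 2.0, 1000)
        with pytest.raises(nm.ProcessingError):
            nm.bin_spectrum(nm.Spectrum(ppm, np.ones_like(ppm)), CFG)


class TestExclusion:
    def _matrix(self, rng, n=3):
        edges = bin_edge_grid(CFG)
        return nm.BinnedMatrix(
            rng.random((n, edges.shape[0])), edges, [f"s{i}" for i in range(n)]
        )

    def test_empty_is_identity(self, rng):
        m = self._matrix(rng)
        out = nm.exclude_regions(m, [])
        assert np.array_equal(out.values, m.values)

    def test_water_region_removes_238_bins(self, rng):
        m = self._matrix(rng)
        out = nm.exclude_regions(m, [CFG.water_region])
        assert m.n_bins - out.n_bins == 238

    def test_no_survivor_intersects(self, rng):
        m = self._matrix(rng)
        out = nm.exclude_regions(m, [(4.23, 5.18), (7.0, 7.2)])
        for lo, hi in out.excluded_regions:
            assert out.bins_in_region((lo, hi)).size == 0


class TestAlignment:
    def test_zero_jitter_gives_zero_shifts(self):
        design = nm.CohortDesign(
            groups=(("a", 5),), shift_jitter_sd=0.0, residual_jitter_sd=0.0,
            noise_sd=0.001, seed=2,
        )
        cohort = nm.simulate_cohort(design)
        m = nm.preprocess_spectra(
            list(cohort.spectra), list(cohort.sample_ids), normalize=False
        )
        for shifts in m.alignment_shifts.values():
            assert np.all(shifts == 0)

    def test_synthetic_displacement_recovered(self, small_matrix):
        m = small_matrix
        region = (1.43, 1.50)
        idx = m.bins_in_region(region)
        values = m.values.copy()
        seg = values[0, idx].copy()
        displaced = np.empty_like(seg)
        displaced[2:] = seg[:-2]  # push +2 bins, edge-pad the start
        displaced[:2] = seg[0]
        values[0, idx] = displaced
        shifted = dataclasses.replace(m, values=values, alignment_shifts=None,
                                      aligned_regions=())
        out = nm.align_segments(shifted, [region])
        assert out.alignment_shifts[region][0] == -2

    def test_segment_is_permutation_with_padding(self, small_matrix):
        m = small_matrix
        for region, shifts in m.alignment_shifts.items():
            idx = m.bins_in_region(region)
            assert np.all(np.abs(shifts) <= idx.size // 2)


class TestNormalization:
    def test_rows_sum_to_one_and_scale_invariance(self, rng):
        edges = bin_edge_grid(CFG)
        vals = rng.random((4, edges.shape[0])) + 0.1
        m = nm.BinnedMatrix(vals, edges, [f"s{i}" for i in range(4)])
        out = nm.total_sum_normalize(m)
        assert np.allclose(out.values.sum(axis=1), 1.0, atol=1e-9)
        scaled = nm.total_sum_normalize(
            dataclasses.replace(m, values=vals * np.array([[7.0], [1], [1], [1]]))
        )
        assert np.allclose(scaled.values[0], out.values[0], atol=1e-12)

    def test_zero_row_rejected(self):
        edges = bin_edge_grid(CFG)
        vals = np.ones((2, edges.shape[0]))
        vals[1] = 0.0
        m = nm.BinnedMatrix(vals, edges, ["a", "b"])
        with pytest.raises(nm.ProcessingError):
            nm.total_sum_normalize(m)


class TestPipelineInvariants:
    @settings(max_examples=5, deadline=None)
    @given(st.floats(min_value=0.1, max_value=100.0))
    def test_end_to_end_scale_invariance(self, c):
        """Multiplying a raw spectrum by c>0 cannot change its normalized row."""
        design = nm.CohortDesign(groups=(("a", 3),), seed=7)
        cohort = nm.simulate_cohort(design)
        spectra = list(cohort.spectra)
        ids = list(cohort.sample_ids)
        base = nm.preprocess_spectra(spectra, ids)
        scaled_first = nm.Spectrum(spectra[0].ppm, spectra[0].intensity * c)
        out = nm.preprocess_spectra([scaled_first] + spectra[1:], ids)
        assert np.allclose(out.values[0], base.values[0], atol=1e-9)

    def test_fid_chain_recovers_simulated_spectrum_peaks(self):
        """apodize -> zero-fill -> FT -> phase -> baseline -> reference
        round-trips a synthetic FID back to a spectrum whose glucose
        reference lands on 5.236 ppm."""
        design = nm.CohortDesign(
            groups=(("a", 1),), noise_sd=0.0, shift_jitter_sd=0.0,
            residual_jitter_sd=0.0, baseline_amplitude=0.0, seed=3,
        )
        spec = nm.simulate_cohort(design).spectra[0]
        fid = nm.spectrum_to_fid(spec, spectral_width_hz=8370.0, n_points=16384)
        cfg = dataclasses.replace(CFG, lb_hz=0.0, zero_fill_to=16384)
        out = nm.process_fid(fid, cfg)
        win = np.abs(out.ppm - 5.236) < 0.02
        peak = out.ppm[np.where(win)[0][np.argmax(out.intensity[win])]]
        assert peak == pytest.approx(5.236, abs=1e-9)
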