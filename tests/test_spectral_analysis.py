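import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from thzdyn import (
    CorrelationSeries,
    HarmonicSpec,
    Spectrum,
    Trajectory,
    absorbance_from_transmittance,
    autocorrelation,
    classify_peak_trend,
    find_peaks,
    make_harmonic_trajectory,
    rotational_acf,
    spectrum_from_acf,
    vacf,
)
from thzdyn.spectral_analysis import SPEED_OF_LIGHT_CM_PER_PS

from conftest import make_atoms


def brute_force_acf(x: np.ndarray, n_lags: int, bias: str) -> np.ndarray:
    """Double-loop oracle for the 1-D autocorrelation."""
    n = len(x)
    out = np.zeros(n_lags)
    for tau in range(n_lags):
        s = sum(x[t] * x[t + tau] for t in range(n - tau))
        out[tau] = s / (n if bias == "biased" else n - tau)
    return out


class TestAutocorrelation:
    def test_constant_series_is_unity(self):
        acf = autocorrelation(np.full(200, 3.0), max_lag=0.5, dt=0.01,
                              detrend=False, bias="unbiased")
        assert np.allclose(acf.values, 1.0)
        # biased estimator tapers deterministically by (n - tau) / n
        biased = autocorrelation(np.full(200, 3.0), max_lag=0.5, dt=0.01,
                                 detrend=False, bias="biased")
        assert np.allclose(biased.values, (200 - np.arange(51)) / 200)

    def test_cosine_acf_closed_form(self):
        dt, f = 0.01, 2.0  # ps, ps^-1
        t = np.arange(20_000) * dt
        acf = autocorrelation(np.cos(2 * np.pi * f * t), max_lag=1.0, dt=dt,
                              bias="unbiased")
        assert np.abs(acf.values - np.cos(2 * np.pi * f * acf.lags)).max() < 1e-3

    def test_white_noise_decorrelates(self):
        rng = np.random.default_rng(0)
        n = 50_000
        acf = autocorrelation(rng.normal(size=n), max_lag=0.2, dt=0.01)
        assert np.abs(acf.values[1:]).max() <= 4 / np.sqrt(n)

    @given(st.integers(0, 2**32 - 1), st.sampled_from(["biased", "unbiased"]))
    @settings(max_examples=20, deadline=None)
    def test_matches_brute_force_oracle(self, seed, bias):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(32, 512))
        x = rng.normal(size=n)
        acf = autocorrelation(x, max_lag=0.15, dt=0.01, normalize=False,
                              detrend=False, bias=bias)
        expect = brute_force_acf(x, len(acf.values), bias)
        assert np.abs(acf.values - expect).max() < 1e-10

    def test_max_lag_must_fit(self):
        with pytest.raises(ValueError, match="max_lag"):
            autocorrelation(np.ones(10), max_lag=1.0, dt=0.01)


class TestVacf:
    def test_single_harmonic_mode_is_cosine(self):
        spec = HarmonicSpec(modes=((60.0, 0.25, 0.0),), dt=0.01, n_frames=8192,
                            n_atoms=6, seed=3)
        traj = make_harmonic_trajectory(spec)
        acf = vacf(traj, np.arange(6), max_lag=5.0, bias="unbiased")
        omega = 2 * np.pi * 60.0 * SPEED_OF_LIGHT_CM_PER_PS
        assert np.abs(acf.values - np.cos(omega * acf.lags)).max() < 1e-3

    def test_static_atoms_excluded_with_warning(self):
        spec = HarmonicSpec(modes=((60.0, 0.25, 0.0),), dt=0.01, n_frames=256,
                            n_atoms=3, seed=3)
        traj = make_harmonic_trajectory(spec)
        traj.velocities[:, 1, :] = 0.0
        with pytest.warns(UserWarning, match="static"):
            acf = vacf(traj, np.arange(3), max_lag=0.5)
        assert acf.meta["n_atoms"] == 2
        with pytest.raises(ValueError, match="zero velocity variance"):
            traj.velocities[:] = 0.0
            vacf(traj, np.arange(3), max_lag=0.5)

    def test_derives_velocities_when_missing(self):
        spec = HarmonicSpec(modes=((40.0, 0.3, 0.0),), dt=0.01, n_frames=2048,
                            n_atoms=4, seed=5)
        traj = make_harmonic_trajectory(spec)
        positions_only = Trajectory(atoms=traj.atoms, coords=traj.coords, dt=traj.dt)
        acf = vacf(positions_only, np.arange(4), max_lag=2.0, bias="unbiased")
        omega = 2 * np.pi * 40.0 * SPEED_OF_LIGHT_CM_PER_PS
        assert acf.meta["velocities_derived"]
        assert np.abs(acf.values - np.cos(omega * acf.lags)).max() < 5e-3
        with pytest.raises(ValueError, match="derivation is disabled"):
            vacf(positions_only, np.arange(4), max_lag=2.0, derive_if_missing=False)


class TestRotationalAcf:
    @staticmethod
    def _two_atom(coords):
        atoms = make_atoms([("CA", "C", 1, "ALA", "protein"),
                            ("CA", "C", 2, "ALA", "protein")])
        return Trajectory(atoms=atoms, coords=coords, dt=0.01)

    def test_fixed_vector_is_unity(self):
        coords = np.zeros((100, 2, 3))
        coords[:, 1] = [1.0, 2.0, 3.0]
        acf = rotational_acf(self._two_atom(coords), 0, 1, max_lag=0.5)
        assert np.allclose(acf.values, 1.0)

    @pytest.mark.parametrize("order", [1, 2])
    def test_uniform_rotation_closed_form(self, order):
        omega = 2 * np.pi * 0.5
        t = np.arange(4000) * 0.01
        coords = np.zeros((4000, 2, 3))
        coords[:, 1, 0] = np.cos(omega * t)
        coords[:, 1, 1] = np.sin(omega * t)
        acf = rotational_acf(self._two_atom(coords), 0, 1, max_lag=3.0, order=order)
        c = np.cos(omega * acf.lags)
        expect = c if order == 1 else 0.5 * (3 * c**2 - 1)
        assert np.abs(acf.values - expect).max() < 1e-10

    def test_coincident_atoms_name_frame(self):
        coords = np.zeros((10, 2, 3))
        coords[:, 1, 0] = 1.0
        coords[4, 1] = 0.0
        with pytest.raises(ValueError, match="frame 4"):
            rotational_acf(self._two_atom(coords), 0, 1, max_lag=0.05)


class TestSpectrum:
    def test_cosine_acf_peak_at_converted_wavenumber(self):
        dt, f = 0.01, 1.0  # 1 ps^-1 -> 33.356 cm^-1
        lags = np.arange(2000) * dt
        acf = CorrelationSeries(lags=lags, values=np.cos(2 * np.pi * f * lags))
        spec = spectrum_from_acf(acf)
        peak = spec.wavenumbers[np.argmax(spec.amplitude)]
        assert abs(peak - 33.356) <= spec.bin_width

    def test_constant_acf_power_in_zero_bin(self):
        lags = np.arange(256) * 0.01
        spec = spectrum_from_acf(
            CorrelationSeries(lags=lags, values=np.ones(256)), window="none",
            zero_pad_factor=1,
        )
        assert np.argmax(spec.amplitude) == 0
        assert spec.amplitude[1:].max() < 1e-6 * spec.amplitude[0]

    def test_parseval_identity_no_window_no_pad(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=512)
        values[0] = 1.0
        lags = np.arange(512) * 0.01
        acf = CorrelationSeries(lags=lags, values=values, normalized=False)
        spec = spectrum_from_acf(acf, window="none", zero_pad_factor=1)
        # rfft Parseval: double all bins except DC (and Nyquist for even n)
        total = spec.amplitude[0] + spec.amplitude[-1] + 2 * spec.amplitude[1:-1].sum()
        assert total / 512 == pytest.approx((values**2).sum(), rel=1e-8)

    def test_exponential_acf_is_low_pass(self):
        tau0 = 0.5
        lags = np.arange(4000) * 0.01
        acf = CorrelationSeries(lags=lags, values=np.exp(-lags / tau0))
        spec = spectrum_from_acf(acf, window="none", kind="amplitude")
        assert np.argmax(spec.amplitude) == 0
        half = spec.amplitude <= spec.amplitude[0] / 2
        nu_half = spec.wavenumbers[np.argmax(half)]
        # Lorentzian amplitude half point: sqrt(3)/(2 pi tau0), in cm^-1
        expect = np.sqrt(3) / (2 * np.pi * tau0) / SPEED_OF_LIGHT_CM_PER_PS
        assert nu_half == pytest.approx(expect, rel=0.05)

    def test_nonuniform_lag_grid_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            CorrelationSeries(lags=np.array([0.0, 0.1, 0.3]), values=np.ones(3))


class TestFindPeaks:
    def test_single_mode_single_peak(self, two_mode_traj):
        acf = vacf(two_mode_traj, np.arange(8), max_lag=10.0)
        spec = spectrum_from_acf(acf)
        ps = find_peaks(spec, min_prominence=0.05, band=(10.0, 60.0))
        assert len(ps) == 1
        assert abs(ps.peaks[0].position - 40.0) <= spec.bin_width

    def test_two_modes_two_peaks(self, two_mode_traj):
        acf = vacf(two_mode_traj, np.arange(8), max_lag=10.0)
        spec = spectrum_from_acf(acf)
        ps = find_peaks(spec, min_prominence=0.05, band=(10.0, 200.0))
        assert len(ps) == 2
        assert np.allclose(sorted(ps.positions), [40.0, 90.0], atol=spec.bin_width)

    def test_flat_spectrum_empty(self):
        spec = Spectrum(wavenumbers=np.arange(100.0), amplitude=np.ones(100))
        assert len(find_peaks(spec)) == 0

    def test_band_outside_support_rejected(self):
        spec = Spectrum(wavenumbers=np.arange(100.0), amplitude=np.ones(100))
        with pytest.raises(ValueError, match="band"):
            find_peaks(spec, band=(500.0, 600.0))


def test_random_harmonic_specs_recover_every_mode():
    """Pipeline trajectory -> VACF -> spectrum -> peaks finds each planted
    wavenumber within one bin, for 20 random mode sets."""
    rng = np.random.default_rng(2024)
    for k in range(20):
        n_modes = int(rng.integers(1, 4))
        wns = np.sort(rng.uniform(20.0, 220.0, size=n_modes))
        while np.any(np.diff(wns) < 15.0):  # keep modes resolvable
            wns = np.sort(rng.uniform(20.0, 220.0, size=n_modes))
        # amplitude ~ 1/wavenumber keeps per-mode velocity power (A*omega)^2
        # comparable, so every mode clears the prominence threshold
        spec = HarmonicSpec(
            modes=tuple((float(w), float(rng.uniform(8.0, 20.0) / w), float(rng.uniform(0, 6)))
                        for w in wns),
            dt=0.01, n_frames=4096, n_atoms=6, seed=int(rng.integers(2**31)),
        )
        traj = make_harmonic_trajectory(spec)
        acf = vacf(traj, np.arange(6), max_lag=10.0)
        sp = spectrum_from_acf(acf)
        ps = find_peaks(sp, min_prominence=0.02, band=(10.0, 240.0))
        for w in wns:
            assert np.min(np.abs(ps.positions - w)) <= sp.bin_width, (k, w, ps.positions)


class TestClassifyPeakTrend:
    def test_constant_positions_harmonic(self):
        pts = [(93.0, 225.0), (200.0, 225.0), (303.0, 225.0)]
        assert classify_peak_trend(pts, shift_tolerance=2.0) == "harmonic-like"

    def test_clear_red_shift_anharmonic(self):
        pts = [(200.0, 185.0), (303.0, 180.0)]
        assert classify_peak_trend(pts, shift_tolerance=2.0) == "anharmonic-like"

    def test_shift_within_tolerance_harmonic(self):
        pts = [(200.0, 185.0), (303.0, 184.0)]
        assert classify_peak_trend(pts, shift_tolerance=2.0) == "harmonic-like"

    def test_invariant_to_input_ordering(self):
        pts = [(303.0, 180.0), (93.0, 188.0), (200.0, 185.0)]
        assert classify_peak_trend(pts) == classify_peak_trend(pts[::-1])

    def test_duplicate_temperatures_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            classify_peak_trend([(200.0, 185.0), (200.0, 180.0)])


class TestAbsorbance:
    def test_reference_values(self):
        ab = absorbance_from_transmittance(np.array([100.0, 10.0]))
        assert ab.absorbance[0] == pytest.approx(0.0, abs=1e-12)
        assert ab.absorbance[1] == pytest.approx(1.0, abs=1e-12)

    def test_from_intensities(self):
        ab = absorbance_from_transmittance(intensity=np.array([25.0]),
                                           background=np.array([50.0]))
        assert ab.percent_transmittance[0] == pytest.approx(50.0)
        assert ab.absorbance[0] == pytest.approx(0.30103, abs=1e-5)

    def test_nonpositive_transmittance_rejected(self):
        with pytest.raises(ValueError):
            absorbance_from_transmittance(np.array([50.0, 0.0]))

    def test_over_100_warns_and_goes_negative(self):
        with pytest.warns(UserWarning, match="above 100"):
            ab = absorbance_from_transmittance(np.array([101.0]))
        assert ab.absorbance[0] < 0
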