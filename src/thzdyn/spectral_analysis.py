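"""Autocorrelation functions, wavenumber spectra, peaks and absorbance.

The velocity autocorrelation function (VACF) of a set of atoms,

    C_v(tau) = < v_i(t + tau) . v_i(t) > / < |v_i|^2 >,

averaged over time origins and atoms, is the workhorse here: its Fourier
transform approximates a vibrational density of states, so peaks in the
transformed spectrum locate the frequencies of collective motion.  The
same correlation engine serves hydrogen-bond occupancy series and the
rotational ACF of an inter-atom vector.

Frequency axes are expressed in wavenumber (cm^-1) using the exact
conversion 1 ps^-1 = 1 / (2.99792458e-2 cm/ps) = 33.356... cm^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal as _signal

from .trajectory_io import Trajectory, finite_difference_velocities

__all__ = [
    "SPEED_OF_LIGHT_CM_PER_PS",
    "CorrelationSeries",
    "Spectrum",
    "Peak",
    "PeakSet",
    "AbsorbanceSpectrum",
    "autocorrelation",
    "vacf",
    "rotational_acf",
    "spectrum_from_acf",
    "find_peaks",
    "classify_peak_trend",
    "absorbance_from_transmittance",
]

#: c in cm/ps; divides a frequency in ps^-1 to give wavenumber in cm^-1.
SPEED_OF_LIGHT_CM_PER_PS = 2.99792458e-2


# ---------------------------------------------------------------------------
# Containers


@dataclass
class CorrelationSeries:
    """Autocorrelation values on a uniform lag grid starting at 0 ps."""

    lags: np.ndarray
    values: np.ndarray
    normalized: bool = True
    n_samples_per_lag: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.lags.shape != self.values.shape:
            raise ValueError("lags and values must have identical shape")
        if self.lags[0] != 0:
            raise ValueError("lag grid must start at 0")
        steps = np.diff(self.lags)
        if len(steps) and not np.allclose(steps, steps[0]):
            raise ValueError("lag grid must be uniform")
        if self.normalized and abs(self.values[0] - 1.0) > 1e-12:
            raise ValueError(f"normalized ACF must have C(0)=1, got {self.values[0]}")

    @property
    def dt(self) -> float:
        return float(self.lags[1] - self.lags[0])

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for k, v in self.meta.items():
                fh.write(f"# {k}: {v}\n")
            fh.write("# lag_ps\tvalue\n")
            for lag, val in zip(self.lags, self.values):
                fh.write(f"{lag:.10g}\t{val:.10g}\n")
        return path


@dataclass
class Spectrum:
    """Amplitude on an ascending, uniformly spaced wavenumber grid (cm^-1)."""

    wavenumbers: np.ndarray
    amplitude: np.ndarray
    kind: str = "power"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        if self.wavenumbers.shape != self.amplitude.shape:
            raise ValueError("wavenumbers and amplitude must have identical shape")
        steps = np.diff(self.wavenumbers)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0]):
            raise ValueError("wavenumber grid must be ascending and uniform")
        if self.kind == "power" and np.any(self.amplitude < 0):
            raise ValueError("power spectrum must be non-negative")

    @property
    def bin_width(self) -> float:
        return float(self.wavenumbers[1] - self.wavenumbers[0])

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            for k, v in self.meta.items():
                fh.write(f"# {k}: {v}\n")
            fh.write("# wavenumber_cm-1\tamplitude\n")
            for w, a in zip(self.wavenumbers, self.amplitude):
                fh.write(f"{w:.10g}\t{a:.10g}\n")
        return path


@dataclass(frozen=True)
class Peak:
    position: float  # cm^-1
    height: float
    prominence: float


@dataclass
class PeakSet:
    """Local maxima of a spectrum, ascending in wavenumber."""

    peaks: list[Peak]
    min_prominence: float
    band: tuple[float, float]

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.peaks])


@dataclass
class AbsorbanceSpectrum:
    """Percent transmittance and the absorbance A = -log10(%T/100)."""

    wavenumbers: np.ndarray | None
    percent_transmittance: np.ndarray
    absorbance: np.ndarray
    intensity: np.ndarray | None = None
    background: np.ndarray | None = None


# ---------------------------------------------------------------------------
# Correlation engine


def _acf_1d_fft(x: np.ndarray, n_lags: int, bias: str) -> np.ndarray:
    """Raw (unnormalised) ACF of each row of ``x`` via FFT.

    ``bias="biased"`` divides every lag by n (guarantees a positive
    semidefinite ACF and hence a non-negative power spectrum);
    ``"unbiased"`` divides lag tau by (n - tau), the plain mean over
    valid time origins.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = x.shape[1]
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    fx = np.fft.rfft(x, nfft, axis=1)
    corr = np.fft.irfft(fx * np.conj(fx), nfft, axis=1)[:, :n_lags]
    if bias == "biased":
        corr /= n
    elif bias == "unbiased":
        corr /= (n - np.arange(n_lags))[None, :]
    else:
        raise ValueError(f"bias must be 'biased' or 'unbiased', got {bias!r}")
    return corr


def autocorrelation(
    series: np.ndarray,
    max_lag: float,
    dt: float,
    normalize: bool = True,
    detrend: bool = True,
    bias: str = "biased",
) -> CorrelationSeries:
    """Time-origin-averaged autocorrelation of a (frames,) or (frames,
    channels) series.

    Channels are correlated independently and averaged afterwards.  When
    ``normalize`` is set the result is divided by the lag-0 value so
    C(0) = 1.  ``detrend`` removes the per-channel time mean first
    (drift protection for generic observables; disable for velocities,
    whose mean is already ~0).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError("series must be 1-D or (frames, channels)")
    n = x.shape[0]
    n_lags = int(round(max_lag / dt)) + 1
    if n_lags >= n:
        raise ValueError(f"max_lag {max_lag} ps >= series duration {(n - 1) * dt} ps")
    if detrend:
        x = x - x.mean(axis=0, keepdims=True)
    corr = _acf_1d_fft(x.T, n_lags, bias).mean(axis=0)
    c0 = corr[0]
    if normalize:
        if c0 <= 0:
            raise ValueError("zero-variance series cannot be normalized")
        corr = corr / c0
    return CorrelationSeries(
        lags=np.arange(n_lags) * dt,
        values=corr,
        normalized=normalize,
        n_samples_per_lag=n - np.arange(n_lags),
        meta={"bias": bias, "detrended": detrend},
    )


def vacf(
    traj: Trajectory,
    selection: Sequence[int],
    max_lag: float,
    derive_if_missing: bool = True,
    bias: str = "biased",
) -> CorrelationSeries:
    """Velocity autocorrelation function averaged over selected atoms.

    Per atom the 3 Cartesian components are correlated and summed (a
    dot-product correlation), normalised by that atom's mean squared
    speed; the per-atom curves are then averaged.  Atoms with zero
    velocity variance are excluded with a warning.
    """
    selection = np.asarray(selection, dtype=int)
    if selection.size == 0:
        raise ValueError("empty atom selection")
    if traj.velocities is None:
        if not derive_if_missing:
            raise ValueError("trajectory has no velocities and derivation is disabled")
        traj = finite_difference_velocities(traj)
    v = traj.velocities[:, selection, :]  # (F, A, 3)
    n = v.shape[0]
    n_lags = int(round(max_lag / traj.dt)) + 1
    if n_lags >= n:
        raise ValueError(f"max_lag {max_lag} ps >= trajectory duration")
    flat = v.transpose(1, 2, 0).reshape(-1, n)  # (A*3, F)
    corr = _acf_1d_fft(flat, n_lags, bias).reshape(len(selection), 3, n_lags).sum(axis=1)
    c0 = corr[:, 0]
    live = c0 > 1e-300
    if not np.any(live):
        raise ValueError("all selected atoms have zero velocity variance")
    if not np.all(live):
        warnings.warn(f"{int((~live).sum())} static atom(s) excluded from VACF")
    values = (corr[live] / c0[live, None]).mean(axis=0)
    return CorrelationSeries(
        lags=np.arange(n_lags) * traj.dt,
        values=values,
        normalized=True,
        n_samples_per_lag=n - np.arange(n_lags),
        meta={"bias": bias, "n_atoms": int(live.sum()),
              "velocities_derived": traj.velocities_derived},
    )


def rotational_acf(
    traj: Trajectory,
    atom_a: int,
    atom_b: int,
    max_lag: float,
    order: int = 1,
) -> CorrelationSeries:
    """Rotational ACF of the unit vector from ``atom_a`` to ``atom_b``.

    Order 1 is ``< u(t+tau) . u(t) >``; order 2 applies the second
    Legendre polynomial P2(x) = (3 x^2 - 1) / 2 to the dot product.
    Averages run over all valid time origins.
    """
    if atom_a == atom_b:
        raise ValueError("atoms must be distinct")
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    d = traj.coords[:, atom_b, :] - traj.coords[:, atom_a, :]
    d = traj.displacements_min_image(d)
    norms = np.linalg.norm(d, axis=1)
    bad = np.nonzero(norms < 1e-10)[0]
    if bad.size:
        raise ValueError(f"atoms coincide at frame {bad[0]}")
    u = d / norms[:, None]
    n = u.shape[0]
    n_lags = int(round(max_lag / traj.dt)) + 1
    if n_lags >= n:
        raise ValueError("max_lag exceeds trajectory duration")
    values = np.empty(n_lags)
    for k in range(n_lags):
        dots = (u[k:] * u[: n - k]).sum(axis=1)
        if order == 2:
            dots = 0.5 * (3.0 * dots**2 - 1.0)
        values[k] = dots.mean()
    return CorrelationSeries(
        lags=np.arange(n_lags) * traj.dt,
        values=values / values[0],
        normalized=True,
        n_samples_per_lag=n - np.arange(n_lags),
        meta={"order": order, "atom_a": atom_a, "atom_b": atom_b},
    )


# ---------------------------------------------------------------------------
# Spectra


def spectrum_from_acf(
    acf: CorrelationSeries,
    window: str = "hann",
    zero_pad_factor: int = 4,
    kind: str = "power",
) -> Spectrum:
    """Fourier-transform a one-sided ACF onto a wavenumber grid.

    The ACF is tapered by the decaying half of a Hann window (value 1 at
    lag 0, 0 at the last lag), zero-padded by ``zero_pad_factor`` and
    transformed with a real FFT.  ``kind="power"`` stores the squared
    magnitude, ``"amplitude"`` the magnitude.  The frequency axis f
    (ps^-1) is converted to wavenumber via nu = f / c with
    c = 2.99792458e-2 cm/ps.
    """
    if window not in ("hann", "none"):
        raise ValueError(f"window must be 'hann' or 'none', got {window!r}")
    if kind not in ("power", "amplitude"):
        raise ValueError(f"kind must be 'power' or 'amplitude', got {kind!r}")
    if zero_pad_factor < 1:
        raise ValueError("zero_pad_factor must be >= 1")
    y = acf.values.copy()
    n = y.size
    if window == "hann":
        y *= np.hanning(2 * n - 1)[n - 1 :]
    nfft = n * int(zero_pad_factor)
    spec = np.abs(np.fft.rfft(y, nfft))
    if kind == "power":
        spec = spec**2
    freqs = np.fft.rfftfreq(nfft, d=acf.dt)  # ps^-1
    return Spectrum(
        wavenumbers=freqs / SPEED_OF_LIGHT_CM_PER_PS,
        amplitude=spec,
        kind=kind,
        meta={"window": window, "zero_pad_factor": int(zero_pad_factor),
              "n_lags": n, "source": acf.meta},
    )


def find_peaks(
    spec: Spectrum,
    min_prominence: float = 0.05,
    band: tuple[float, float] | None = None,
) -> PeakSet:
    """Locate local maxima above a prominence threshold.

    ``min_prominence`` is a fraction of the maximum amplitude inside
    ``band`` (default: the whole support).  Peak positions are refined
    by 3-point parabolic interpolation, so a well-resolved line is
    located to a fraction of a bin.
    """
    w, a = spec.wavenumbers, spec.amplitude
    if band is None:
        band = (float(w[0]), float(w[-1]))
    lo, hi = band
    mask = (w >= lo) & (w <= hi)
    if not np.any(mask):
        raise ValueError(f"band {band} outside spectrum support [{w[0]}, {w[-1]}]")
    idx = np.nonzero(mask)[0]
    sub = a[idx]
    if sub.max() <= 0:
        return PeakSet(peaks=[], min_prominence=min_prominence, band=band)
    locs, props = _signal.find_peaks(sub, prominence=min_prominence * sub.max())
    peaks: list[Peak] = []
    for loc, prom in zip(locs, props["prominences"]):
        i = idx[loc]
        pos, height = float(w[i]), float(a[i])
        if 0 < i < len(w) - 1:
            ym, y0, yp = a[i - 1], a[i], a[i + 1]
            denom = ym - 2 * y0 + yp
            if denom < 0:
                delta = 0.5 * (ym - yp) / denom
                pos += delta * spec.bin_width
                height = y0 - 0.25 * (ym - yp) * delta
        peaks.append(Peak(position=pos, height=height, prominence=float(prom)))
    peaks.sort(key=lambda p: p.position)
    return PeakSet(peaks=peaks, min_prominence=min_prominence, band=band)


def classify_peak_trend(
    peak_positions_by_temperature: Sequence[tuple[float, float]],
    shift_tolerance: float = 2.0,
) -> str:
    """Classify a peak's temperature trend as harmonic- or anharmonic-like.

    A red-shift of the peak position with temperature signals anharmonic
    motion; a position that stays put signals a harmonic vibration.  The
    test is on the least-squares slope of position vs temperature:
    anharmonic-like iff slope < -shift_tolerance / (T_max - T_min),
    i.e. the fitted total shift across the measured range exceeds the
    tolerance towards lower wavenumber.
    """
    pts = sorted((float(t), float(p)) for t, p in peak_positions_by_temperature)
    if len(pts) < 2:
        raise ValueError("need at least two temperatures")
    temps = np.array([t for t, _ in pts])
    if np.any(np.diff(temps) == 0):
        raise ValueError("duplicate temperatures")
    pos = np.array([p for _, p in pts])
    slope = np.polyfit(temps, pos, 1)[0]
    span = temps[-1] - temps[0]
    return "anharmonic-like" if slope < -shift_tolerance / span else "harmonic-like"


# ---------------------------------------------------------------------------
# Absorbance


def absorbance_from_transmittance(
    percent_transmittance: np.ndarray | None = None,
    intensity: np.ndarray | None = None,
    background: np.ndarray | None = None,
    wavenumbers: np.ndarray | None = None,
) -> AbsorbanceSpectrum:
    """Convert percent transmittance (or raw intensities) to absorbance.

    Either ``percent_transmittance`` or the pair (``intensity``,
    ``background``) must be given; in the latter case
    %T = 100 * I / I0.  Absorbance is A = -log10(%T / 100) pointwise.
    Values above 100 %T (possible with experimental noise) are kept and
    yield a small negative A, with a warning; %T <= 0 is an error.
    """
    if percent_transmittance is None:
        if intensity is None or background is None:
            raise ValueError("give percent_transmittance or both intensity and background")
        intensity = np.asarray(intensity, dtype=float)
        background = np.asarray(background, dtype=float)
        if np.any(intensity <= 0) or np.any(background <= 0):
            raise ValueError("intensities must be strictly positive")
        percent_transmittance = 100.0 * intensity / background
    pct = np.asarray(percent_transmittance, dtype=float)
    if np.any(pct <= 0):
        raise ValueError("percent transmittance must be > 0")
    if np.any(pct > 100):
        warnings.warn(
            "percent transmittance above 100 (noise); absorbance will be negative there"
        )
    A = -np.log10(pct / 100.0)
    return AbsorbanceSpectrum(
        wavenumbers=None if wavenumbers is None else np.asarray(wavenumbers, dtype=float),
        percent_transmittance=pct,
        absorbance=A,
        intensity=intensity,
        background=background,
    )
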