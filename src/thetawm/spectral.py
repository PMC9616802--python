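"""Frequency-domain estimation.

Implements the spectral stages of the pipeline:

* time-resolved power via a sliding Hanning-tapered Fourier transform with a
  variable number of cycles per frequency (2 cycles below 4 Hz up to 5 cycles
  from 6 Hz), resolved in 50 ms steps;
* whole-epoch Hanning spectra on a fine (0.2 Hz) zero-padded grid for the
  per-trial theta peak statistic;
* IRASA (irregular-resampling auto-spectral analysis) separation of the
  aperiodic 1/f component from narrowband oscillatory peaks;
* spectral smoothing and prominence-based peak detection with per-condition
  averaging.

Power is amplitude-normalised: a unit-amplitude sinusoid at an analysed
frequency yields power ~ 1 at its bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import h5py
import numpy as np
import pandas as pd
from scipy import signal

from .containers import EpochSet

#: cycles per frequency for the sliding-window decomposition
DEFAULT_CYCLES = ((4.0, 2), (5.0, 3), (6.0, 4), (np.inf, 5))

DEFAULT_TF_FREQS = np.arange(2.0, 10.0 + 1e-9, 0.5)
THETA_BAND = (4.0, 8.0)


def cycles_for(freq: float, cycles_map=DEFAULT_CYCLES) -> int:
    """Number of taper cycles used at ``freq``."""
    for upper, cyc in cycles_map:
        if freq < upper:
            return cyc
    return cycles_map[-1][1]


@dataclass
class SpectralEstimate:
    """Power (and optionally complex coefficients) over trials x channels x
    freqs (x times).

    ``power`` is non-negative for direct estimates; IRASA oscillatory
    residuals may dip below zero off-peak and are carried in the same
    container.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray | None = None
    coefficients: np.ndarray | None = None
    ch_names: list[str] | None = None
    method: dict = field(default_factory=dict)

    def channel_mean(self, labels=None) -> np.ndarray:
        """Average power over channels (all, or a named subset)."""
        if labels is None:
            return self.power.mean(axis=1)
        idx = [self.ch_names.index(str(l)) for l in labels]
        return self.power[:, idx].mean(axis=1)

    def save(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("power", data=self.power)
            f.create_dataset("freqs", data=self.freqs)
            if self.times is not None:
                f.create_dataset("times", data=self.times)
            if self.coefficients is not None:
                f.create_dataset("coefficients", data=self.coefficients)
            if self.ch_names is not None:
                f.create_dataset("channels", data=np.array(
                    self.ch_names, dtype=h5py.string_dtype()))
            for k, v in self.method.items():
                f["power"].attrs[k] = str(v)

    @classmethod
    def load(cls, path) -> "SpectralEstimate":
        with h5py.File(path, "r") as f:
            kw = dict(power=f["power"][()], freqs=f["freqs"][()])
            if "times" in f:
                kw["times"] = f["times"][()]
            if "coefficients" in f:
                kw["coefficients"] = f["coefficients"][()]
            if "channels" in f:
                kw["ch_names"] = [c.decode() if isinstance(c, bytes) else str(c)
                                  for c in f["channels"][()]]
            kw["method"] = dict(f["power"].attrs)
        return cls(**kw)


# ---------------------------------------------------------------------------
# time-resolved power
# ---------------------------------------------------------------------------

def tf_power(epochs: EpochSet, freqs=None, step: float = 0.05,
             cycles_map=DEFAULT_CYCLES,
             keep_coefficients: bool = False) -> SpectralEstimate:
    """Sliding-window Hanning-tapered Fourier power.

    At each frequency ``f`` the window spans ``cycles(f) / f`` seconds; the
    window centre advances in ``step``-second increments over the epoch.
    Time points where the window would exceed the epoch are NaN.
    """
    if freqs is None:
        freqs = DEFAULT_TF_FREQS
    freqs = np.asarray(freqs, dtype=float)
    rate = epochs.rate
    n = epochs.n_samples
    t = epochs.times
    centers = np.arange(t[0], t[-1] + 0.5 / rate, step)
    n_t, n_c = epochs.n_trials, epochs.n_channels
    power = np.full((n_t, n_c, freqs.size, centers.size), np.nan)
    coeffs = (np.full((n_t, n_c, freqs.size, centers.size), np.nan,
                      dtype=complex) if keep_coefficients else None)
    longest = 0.0
    for fi, f in enumerate(freqs):
        cyc = cycles_for(f, cycles_map)
        wlen = int(round(cyc / f * rate))
        longest = max(longest, wlen / rate)
        if wlen > n:
            raise ValueError(
                f"epoch too short for {cyc} cycles at {f} Hz "
                f"({wlen / rate:.2f} s window, {n / rate:.2f} s epoch)")
        taper = np.hanning(wlen)
        tau = (np.arange(wlen) - (wlen - 1) / 2.0) / rate
        kernel = taper * np.exp(-2j * np.pi * f * tau) * (2.0 / taper.sum())
        # centre sample of each candidate window
        c_idx = np.round((centers - t[0]) * rate).astype(int)
        start = c_idx - wlen // 2
        valid = (start >= 0) & (start + wlen <= n)
        if not valid.any():
            continue
        views = np.lib.stride_tricks.sliding_window_view(epochs.data, wlen,
                                                         axis=-1)
        c = views[:, :, start[valid], :] @ kernel.conj()
        power[:, :, fi, valid] = np.abs(c) ** 2
        if keep_coefficients:
            coeffs[:, :, fi, valid] = c
    return SpectralEstimate(
        power=power, freqs=freqs, times=centers, coefficients=coeffs,
        ch_names=list(epochs.ch_names),
        method=dict(taper="hanning", step=step,
                    cycles_map=tuple(cycles_map), kind="sliding"))


# ---------------------------------------------------------------------------
# whole-epoch spectra
# ---------------------------------------------------------------------------

def _band_power(data: np.ndarray, rate: float, band, grid_step: float):
    """Hanning-tapered zero-padded rFFT power of ``data`` restricted to
    ``band``; returns (power, freqs).  ``data``: (..., samples)."""
    n = data.shape[-1]
    n_fft = rate / grid_step
    if abs(n_fft - round(n_fft)) > 1e-6:
        raise ValueError("rate / grid_step must be an integer FFT length")
    n_fft = int(round(n_fft))
    if n_fft < n:
        # keep the requested grid density by padding to a multiple
        n_fft *= int(np.ceil(n / n_fft))
    taper = np.hanning(n)
    spec = np.fft.rfft(data * taper, n=n_fft, axis=-1)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / rate)
    sel = (freqs >= band[0] - 1e-9) & (freqs <= band[1] + 1e-9)
    # keep only the requested grid even when padding overshot its density
    steps = freqs / grid_step
    sel &= np.abs(steps - np.round(steps)) < 1e-6
    coef = 2.0 * spec[..., sel] / taper.sum()
    return np.abs(coef) ** 2, freqs[sel]


def epoch_spectrum(epochs: EpochSet, band=THETA_BAND, grid_step: float = 0.2,
                   window: tuple[float, float] | None = None) -> SpectralEstimate:
    """Single Hanning-tapered spectrum over the whole epoch (or ``window``).

    The signal is zero-padded so the frequency grid has ``grid_step``
    spacing (default 0.2 Hz, i.e. padding to a 5 s equivalent for integer
    sampling rates), which places the requested band grid on exact bins.
    """
    if window is None:
        window = (0.0, epochs.times[-1] + 1.0 / epochs.rate)
    mask = epochs.time_mask(*window)
    data = epochs.data[:, :, mask]
    if data.shape[-1] < epochs.rate:
        raise ValueError("epoch (window) must span at least 1 s")
    power, freqs = _band_power(data, epochs.rate, band, grid_step)
    return SpectralEstimate(power=power, freqs=freqs, times=None,
                            ch_names=list(epochs.ch_names),
                            method=dict(taper="hanning", grid_step=grid_step,
                                        kind="whole-epoch"))


# ---------------------------------------------------------------------------
# IRASA
# ---------------------------------------------------------------------------

DEFAULT_IRASA_FACTORS = tuple(
    float(h) for h in np.round(np.arange(1.1, 1.9 + 1e-9, 0.05), 2))


@lru_cache(maxsize=None)
def _irasa_median_bias(n_factors: int) -> float:
    """Small-sample bias of the median-of-geometric-means fractal estimate.

    A single-taper power estimate is exponentially distributed about the true
    PSD (chi-squared, 2 dof).  The geometric mean of the independent up/down
    estimates is then ``PSD * sqrt(E1 * E2)`` with ``E ~ Exp(1)``, whose
    density is ``4 x K0(2x)``.  The fractal component (median over the factor
    set) therefore underestimates the PSD by the expected sample median of
    that variable, computed here by order-statistic quadrature and divided
    out by :func:`irasa`.
    """
    from math import lgamma

    from scipy import integrate
    from scipy.special import k0, k1

    m = n_factors

    def F(x):
        return 1.0 - 2.0 * x * k1(2.0 * x)

    def f(x):
        return 4.0 * x * k0(2.0 * x)

    def order_mean(j):  # E[X_(j)] of m iid draws, 1-based
        lognorm = (lgamma(m + 1) - lgamma(j) - lgamma(m - j + 1))

        def integrand(x):
            Fx = F(x)
            return x * np.exp(lognorm + (j - 1) * np.log(max(Fx, 1e-300))
                              + (m - j) * np.log(max(1.0 - Fx, 1e-300))) * f(x)

        return integrate.quad(integrand, 0.0, 20.0, limit=200)[0]

    if m == 1:
        return order_mean(1)
    if m % 2:
        return order_mean((m + 1) // 2)
    return 0.5 * (order_mean(m // 2) + order_mean(m // 2 + 1))


def irasa(epochs: EpochSet, factors=DEFAULT_IRASA_FACTORS, band=THETA_BAND,
          grid_step: float = 0.2,
          window: tuple[float, float] | None = None):
    """Separate the aperiodic (fractal) spectrum from oscillatory peaks.

    For each resampling factor ``h`` the signal is resampled up by ``h`` and
    down by ``1/h``; narrowband peaks move to ``f/h`` and ``f*h`` while the
    scale-free 1/f component is invariant under the geometric mean of the two
    spectra.  The fractal component is the median of those geometric means
    across factors; the oscillatory residual is the original spectrum minus
    the fractal component (it may be negative off-peak).

    Returns ``(fractal, oscillatory)`` as :class:`SpectralEstimate` objects
    on the same frequency grid as :func:`epoch_spectrum`.
    """
    factors = tuple(float(h) for h in factors)
    if len(factors) == 0:
        raise ValueError("factor set must not be empty")
    if any(h <= 1.0 for h in factors):
        raise ValueError("resampling factors must exceed 1")
    base = epoch_spectrum(epochs, band=band, grid_step=grid_step,
                          window=window)
    if window is None:
        window = (0.0, epochs.times[-1] + 1.0 / epochs.rate)
    mask = epochs.time_mask(*window)
    data = epochs.data[:, :, mask]
    n = data.shape[-1]
    per_factor = np.empty((len(factors),) + base.power.shape)
    for hi, h in enumerate(factors):
        spectra = []
        for n_new in (int(round(n * h)), int(round(n / h))):
            # the resampled array is read out at the *original* rate, which
            # stretches/compresses time and shifts a tone at f to f/h (up)
            # or f*h (down) while leaving the scale-free 1/f magnitude
            # invariant under the geometric mean of the pair
            resampled = signal.resample(data, n_new, axis=-1)
            p, _ = _band_power(resampled, epochs.rate, band, grid_step)
            spectra.append(p)
        per_factor[hi] = np.sqrt(spectra[0] * spectra[1])
    fractal_power = np.median(per_factor, axis=0) / _irasa_median_bias(len(factors))
    meta = dict(base.method, kind="irasa-fractal", factors=factors)
    fractal = SpectralEstimate(power=fractal_power, freqs=base.freqs,
                               ch_names=base.ch_names, method=meta)
    residual = SpectralEstimate(power=base.power - fractal_power,
                                freqs=base.freqs, ch_names=base.ch_names,
                                method=dict(meta, kind="irasa-oscillatory"))
    return fractal, residual


# ---------------------------------------------------------------------------
# smoothing and peak detection
# ---------------------------------------------------------------------------

def smooth_spectrum(power: np.ndarray, window_elements: int,
                    axis: int = -1) -> np.ndarray:
    """Sliding mean along the frequency axis, truncated at the band edges."""
    power = np.asarray(power, dtype=float)
    n = power.shape[axis]
    if window_elements > n:
        raise ValueError("smoothing window exceeds number of grid points")
    if window_elements < 1:
        raise ValueError("window must be >= 1 element")
    w = int(window_elements)
    x = np.moveaxis(power, axis, -1)
    csum = np.concatenate([np.zeros(x.shape[:-1] + (1,)),
                           np.cumsum(x, axis=-1)], axis=-1)
    # even windows cover the current and preceding elements
    lo = np.clip(np.arange(n) - w // 2, 0, n)
    hi = np.clip(np.arange(n) - w // 2 + w, 0, n)
    out = (csum[..., hi] - csum[..., lo]) / (hi - lo)
    return np.moveaxis(out, -1, axis)


def detect_peak(spectrum: np.ndarray, freqs: np.ndarray):
    """Most-prominent-peak frequency of a single spectrum.

    Local maxima are strict interior maxima; the prominence of each is its
    height above the higher of its two flanking bases (band edges act as
    bases).  Returns ``(peak_freq, prominence, discarded)``; a spectrum with
    no interior local maximum (e.g. a monotone 1/f slope) is flagged
    discarded.  Ties in prominence resolve to the lower frequency.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    peaks, _ = signal.find_peaks(spectrum)
    if peaks.size == 0:
        return np.nan, np.nan, True
    prominences = signal.peak_prominences(spectrum, peaks)[0]
    best = int(np.argmax(prominences))  # first max -> lower frequency on ties
    return float(freqs[peaks[best]]), float(prominences[best]), False


def peak_table(spectra: np.ndarray, freqs: np.ndarray,
               metadata: pd.DataFrame | None = None,
               smoothing: int | None = None) -> pd.DataFrame:
    """Per-trial most-prominent-peak table from channel-mean spectra.

    ``spectra``: (trials, freqs).  Optional sliding-mean smoothing (in grid
    elements) is applied before detection.
    """
    spectra = np.asarray(spectra, dtype=float)
    if smoothing is not None and smoothing > 1:
        spectra = smooth_spectrum(spectra, smoothing, axis=-1)
    rows = [detect_peak(s, freqs) for s in spectra]
    table = pd.DataFrame(rows, columns=["peak_hz", "prominence", "discarded"])
    if metadata is not None:
        table = pd.concat([metadata.reset_index(drop=True), table], axis=1)
    return table


def condition_peak_means(table: pd.DataFrame,
                         participant_col: str = "participant",
                         condition_col: str = "task") -> pd.DataFrame:
    """Mean peak frequency per participant and condition.

    Discarded trials (no detected peak) are excluded from the mean; the
    discarded fraction is reported per cell.  A cell whose trials were all
    discarded yields a missing mean and a warning.
    """
    records = []
    for (p, c), g in table.groupby([participant_col, condition_col]):
        kept = g.loc[~g["discarded"]]
        frac = 1.0 - len(kept) / len(g)
        if len(kept) == 0:
            warnings.warn(f"all trials discarded for {p}/{c}")
            mean = np.nan
        else:
            mean = float(kept["peak_hz"].mean())
        records.append({participant_col: p, condition_col: c,
                        "mean_peak_hz": mean, "n_trials": len(g),
                        "discarded_fraction": frac})
    return pd.DataFrame(records)


def trial_peak_frequencies(epochs: EpochSet, channels, band=THETA_BAND,
                           grid_step: float = 0.2,
                           smoothing: int | None = None,
                           use_irasa: bool = False,
                           irasa_factors=DEFAULT_IRASA_FACTORS,
                           window: tuple[float, float] | None = None
                           ) -> pd.DataFrame:
    """Full per-trial peak pipeline: spectra -> channel mean -> peak.

    Spectra from the given (fronto-medial) channel set are averaged per
    trial before peak detection.  With ``use_irasa`` the detection runs on
    the oscillatory residual after removal of the 1/f component.
    """
    if use_irasa:
        _, est = irasa(epochs, factors=irasa_factors, band=band,
                       grid_step=grid_step, window=window)
    else:
        est = epoch_spectrum(epochs, band=band, grid_step=grid_step,
                             window=window)
    spectra = est.channel_mean(channels)
    return peak_table(spectra, est.freqs, metadata=epochs.metadata,
                      smoothing=smoothing)
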