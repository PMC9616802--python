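"""Deterministic signal conditioning applied before the analysis stages.

All operations preserve trial count, channel set and metadata; they act only
on the voltage array (and, for resampling, the time axis).
"""

from __future__ import annotations

import numpy as np
from fractions import Fraction

from scipy import ndimage, signal

from .containers import ChannelLayout, EpochSet


def rereference(epochs: EpochSet, reference_channels) -> EpochSet:
    """Subtract the mean of the reference channels from every channel.

    Mirrors offline re-referencing to the average of two mastoid channels.
    """
    idx = epochs.channel_indices(reference_channels)
    ref = epochs.data[:, idx, :].mean(axis=1, keepdims=True)
    return epochs.copy(data=epochs.data - ref)


def highpass(epochs: EpochSet, cutoff: float, order: int = 4) -> EpochSet:
    """Zero-phase Butterworth high-pass filter."""
    if not 0 < cutoff < epochs.rate / 2:
        raise ValueError("cutoff must lie in (0, Nyquist)")
    sos = signal.butter(order, cutoff, btype="highpass", fs=epochs.rate,
                        output="sos")
    data = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return epochs.copy(data=data)


def resample(epochs: EpochSet, new_rate: float) -> EpochSet:
    """Anti-aliased downsampling (polyphase); regenerates the time axis."""
    if new_rate >= epochs.rate:
        raise ValueError("only downsampling is supported")
    frac = Fraction(new_rate / epochs.rate).limit_denominator(1000)
    data = signal.resample_poly(epochs.data, frac.numerator, frac.denominator,
                                axis=-1)
    return epochs.copy(data=data, rate=new_rate, tmin=epochs.tmin)


def sliding_average(epochs: EpochSet, window: float) -> EpochSet:
    """Centered moving mean over ``window`` seconds, truncated at the edges.

    Output length is unchanged; near the edges the mean runs over the part of
    the window that falls inside the epoch.
    """
    w = int(round(window * epochs.rate))
    if w < 2:
        raise ValueError("window must cover at least 2 samples")
    n = epochs.n_samples
    if w > n:
        raise ValueError("window longer than epoch")
    kernel = np.ones(w)
    # running sum and per-sample effective window length; truncation at the
    # edges falls out of the zero-padded convolution divided by the count
    sums = ndimage.convolve1d(epochs.data, kernel, axis=-1, mode="constant",
                              cval=0.0)
    counts = ndimage.convolve1d(np.ones(n), kernel, mode="constant", cval=0.0)
    return epochs.copy(data=sums / counts)


def baseline_correct(epochs: EpochSet,
                     baseline_window: tuple[float, float]) -> EpochSet:
    """Subtract the per-trial, per-channel mean over ``baseline_window``.

    The window is half-open ``[start, end)`` in seconds relative to epoch
    onset; with the stored 200 ms pre-onset padding the conventional baseline
    is ``(-0.2, 0.0)``.
    """
    mask = epochs.time_mask(*baseline_window)
    if not mask.any():
        raise ValueError("baseline window lies outside the epoch")
    base = epochs.data[:, :, mask].mean(axis=-1, keepdims=True)
    return epochs.copy(data=epochs.data - base)


def neighbours(layout: ChannelLayout, radius: float) -> dict[str, set[str]]:
    """Channel adjacency at a Euclidean distance threshold.

    Symmetric and irreflexive.  The radius is in layout units (unit head
    radius); :meth:`ChannelLayout.calibrate_radius` picks a radius yielding a
    target mean neighbour count (about 5.7 for the searchlight graph).
    """
    return layout.neighbours(radius)
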