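"""Seed-based spectral coherence.

Cross-spectral densities come from the same sliding Hanning-tapered
decomposition as the time-frequency power estimates.  Magnitude-squared
coherence between a frontal seed (Fz by default) and every other channel is
trial-averaged per frequency and time, then averaged over a time window of
interest.  Condition contrasts with unequal trial counts are equalised by
averaging over repeated random subsamples of the larger condition.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import EpochSet
from .spectral import SpectralEstimate, tf_power
from .stats import ClusterTestResult, cluster_permutation_test

THETA_GRID = np.arange(4.0, 8.0 + 1e-9, 0.5)


@dataclass
class CrossSpectra:
    """Seed-to-all cross-spectral densities plus auto-spectra."""

    csd: np.ndarray            # trials x channels x freqs x times, complex
    power: np.ndarray          # trials x channels x freqs x times (auto)
    seed: str
    seed_index: int
    freqs: np.ndarray
    times: np.ndarray
    ch_names: list[str]


@dataclass
class CoherenceMap:
    seed: str
    coherence: np.ndarray      # channels x freqs, in [0, 1]
    freqs: np.ndarray
    ch_names: list[str]
    n_trials: int
    band: tuple
    window: tuple | None = None
    subsamples: int = 1
    meta: dict = field(default_factory=dict)

    def band_mean(self, channels=None) -> np.ndarray:
        coh = self.coherence
        if channels is not None:
            idx = [self.ch_names.index(str(c)) for c in channels]
            coh = coh[idx]
        return coh.mean(axis=-1)

    def to_frame(self) -> pd.DataFrame:
        rows = [(ch, f, self.coherence[i, j])
                for i, ch in enumerate(self.ch_names)
                for j, f in enumerate(self.freqs)]
        return pd.DataFrame(rows, columns=["channel", "freq", "coherence"])


def cross_spectra(epochs: EpochSet, seed_channel: str = "Fz",
                  freqs=THETA_GRID, step: float = 0.05,
                  cycles_map=None) -> CrossSpectra:
    """CSD(seed, ch, f, t) = F_seed * conj(F_ch) from tapered coefficients."""
    if seed_channel not in epochs.ch_names:
        raise KeyError(f"seed channel {seed_channel!r} not present")
    kwargs = dict(freqs=freqs, step=step, keep_coefficients=True)
    if cycles_map is not None:
        kwargs["cycles_map"] = cycles_map
    est: SpectralEstimate = tf_power(epochs, **kwargs)
    si = epochs.ch_names.index(seed_channel)
    coef = est.coefficients
    csd = coef[:, si:si + 1, :, :] * np.conj(coef)
    return CrossSpectra(csd=csd, power=est.power, seed=seed_channel,
                        seed_index=si, freqs=est.freqs, times=est.times,
                        ch_names=list(epochs.ch_names))


def coherence_from_csd(cs: CrossSpectra, band=(4.0, 8.0),
                       window: tuple[float, float] | None = None,
                       trial_subset=None) -> CoherenceMap:
    """Magnitude-squared coherence map from a CSD stack.

    ``|<CSD>_trials|^2 / (<P_seed> <P_ch>)`` per channel, frequency and time,
    then averaged over the time bins inside ``window`` per frequency.
    """
    sel = slice(None) if trial_subset is None else np.asarray(trial_subset)
    csd = cs.csd[sel]
    power = cs.power[sel]
    n_trials = csd.shape[0]
    if n_trials < 2:
        raise ValueError("coherence needs at least 2 trials")
    num = np.abs(csd.mean(axis=0)) ** 2
    den = power.mean(axis=0)[cs.seed_index][None] * power.mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        msc = num / den
    fmask = (cs.freqs >= band[0] - 1e-9) & (cs.freqs <= band[1] + 1e-9)
    msc = msc[:, fmask]
    if window is not None:
        tmask = (cs.times >= window[0] - 1e-12) & (cs.times < window[1] - 1e-12)
        msc = msc[:, :, tmask]
    with warnings.catch_warnings():
        # silent channels yield all-NaN slices; propagate NaN quietly
        warnings.simplefilter("ignore", RuntimeWarning)
        coh = np.nanmean(msc, axis=-1)
    return CoherenceMap(seed=cs.seed, coherence=coh,
                        freqs=cs.freqs[fmask], ch_names=cs.ch_names,
                        n_trials=n_trials, band=tuple(band),
                        window=window)


def coherence_map(epochs: EpochSet, seed_channel: str = "Fz",
                  band=(4.0, 8.0), window=None, freqs=THETA_GRID,
                  step: float = 0.05) -> CoherenceMap:
    cs = cross_spectra(epochs, seed_channel=seed_channel, freqs=freqs,
                       step=step)
    return coherence_from_csd(cs, band=band, window=window)


def subsample_coherence(epochs: EpochSet, target_n_trials: int,
                        seed_channel: str = "Fz", k: int = 10,
                        band=(4.0, 8.0), window=None, freqs=THETA_GRID,
                        step: float = 0.05,
                        seed: int | None = None) -> CoherenceMap:
    """Trial-count-matched coherence: mean of ``k`` without-replacement draws.

    Used to compare a condition with many trials against one with few, since
    magnitude-squared coherence is biased upward at low trial counts.
    """
    if target_n_trials > epochs.n_trials:
        raise ValueError("target_n_trials exceeds available trials")
    cs = cross_spectra(epochs, seed_channel=seed_channel, freqs=freqs,
                       step=step)
    rng = np.random.default_rng(seed)
    maps = []
    for _ in range(k):
        subset = rng.choice(epochs.n_trials, size=target_n_trials,
                            replace=False)
        maps.append(coherence_from_csd(cs, band=band, window=window,
                                       trial_subset=subset))
    mean_coh = np.mean([m.coherence for m in maps], axis=0)
    out = maps[0]
    return CoherenceMap(seed=out.seed, coherence=mean_coh, freqs=out.freqs,
                        ch_names=out.ch_names, n_trials=target_n_trials,
                        band=out.band, window=window, subsamples=k)


def coherence_contrast(maps_a: list[CoherenceMap], maps_b: list[CoherenceMap],
                       adjacency: np.ndarray, n_perm: int = 500,
                       alpha: float = 0.05, min_channel_extent: int = 3,
                       seed: int | None = None,
                       searchlight_channels=None):
    """Paired cluster contrast of per-participant coherence maps.

    Clusters jointly over channels x frequencies.  If a set of
    searchlight-significant channel labels is supplied, the channel overlap
    between the significant coherence cluster(s) and that set is reported.

    Returns ``(ClusterTestResult, overlap_report)``.
    """
    if len(maps_a) != len(maps_b):
        raise ValueError("conditions must have the same participants")
    a = np.stack([m.coherence for m in maps_a])
    b = np.stack([m.coherence for m in maps_b])
    result = cluster_permutation_test(a, b, adjacency, n_perm=n_perm,
                                      alpha=alpha,
                                      min_channel_extent=min_channel_extent,
                                      seed=seed)
    ch_names = maps_a[0].ch_names
    sig = set(result.significant_channels(ch_names))
    report = {"significant_channels": sorted(sig)}
    if searchlight_channels is not None:
        sl = set(map(str, searchlight_channels))
        inter = sig & sl
        report.update(
            searchlight_channels=sorted(sl),
            overlap_channels=sorted(inter),
            overlap_fraction=(len(inter) / len(sig) if sig else np.nan))
    return result, report
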