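"""Orchestration of the four headline analyses.

Each ``run_*`` function consumes per-participant epoch sets (synthetic or
imported), applies the appropriate module chain with seeds derived from the
config's master seed, and returns a plain dict of results that the analysis
scripts serialise to tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import connectivity, decoding, preprocessing, spectral, stats
from .containers import EpochSet


@dataclass
class AnalysisConfig:
    """All stated analysis parameters in one serialisable place."""

    theta_band: tuple = (4.0, 8.0)
    tf_freq_start: float = 2.0
    tf_freq_stop: float = 10.0
    tf_freq_step: float = 0.5
    tf_time_step: float = 0.05
    decode_rate: float = 200.0
    smooth_window_s: float = 0.1
    baseline_window: tuple = (-0.2, 0.0)
    folds: int = 5
    repeats: int = 5
    n_perm: int = 500
    alpha: float = 0.05
    min_channel_extent: int = 3
    coherence_seed: str = "Fz"
    subsample_k: int = 10
    peak_grid_step: float = 0.2
    irasa_factors: tuple = spectral.DEFAULT_IRASA_FACTORS
    smoothing_windows: tuple = (2, 3, 4, 5)
    master_seed: int = 0

    @property
    def tf_freqs(self) -> np.ndarray:
        return np.arange(self.tf_freq_start, self.tf_freq_stop + 1e-9,
                         self.tf_freq_step)

    def derived_seeds(self, n: int, salt: int = 0) -> list[int]:
        ss = np.random.SeedSequence([self.master_seed, salt])
        return [int(s) for s in ss.generate_state(n) % (2 ** 31)]

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump({k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in asdict(self).items()})
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "AnalysisConfig":
        if hasattr(source, "read") or "\n" in str(source):
            payload = yaml.safe_load(source if isinstance(source, str)
                                     else source.read())
        else:
            with open(source) as f:
                payload = yaml.safe_load(f)
        fields = {k: (tuple(v) if isinstance(v, list) else v)
                  for k, v in payload.items()}
        return cls(**fields)


# ---------------------------------------------------------------------------
# stage 1: spectral power contrast
# ---------------------------------------------------------------------------

def participant_power(epochs: EpochSet, config: AnalysisConfig) -> np.ndarray:
    """Delay-averaged channel x frequency power for one participant."""
    est = spectral.tf_power(epochs, freqs=config.tf_freqs,
                            step=config.tf_time_step)
    return np.nanmean(est.power, axis=(0, 3))   # mean over trials and times


def run_power_contrast(config: AnalysisConfig, epochs_a: list[EpochSet],
                       epochs_b: list[EpochSet], adjacency: np.ndarray,
                       ch_names: list[str]) -> dict:
    """Cluster contrast of delay power between two conditions.

    ``epochs_a``/``epochs_b`` hold one delay EpochSet per participant (e.g.
    1-back vs DMS, or delay vs inter-block baseline).  Returns the cluster
    result, the significant channel set, the theta-band topography of the
    contrast, and the effect size over significant channels.
    """
    if len(epochs_a) != len(epochs_b) or not epochs_a:
        raise ValueError("both conditions must be present for every participant")
    seed = config.derived_seeds(1, salt=1)[0]
    pa = np.stack([participant_power(e, config) for e in epochs_a])
    pb = np.stack([participant_power(e, config) for e in epochs_b])
    result = stats.cluster_permutation_test(
        pa, pb, adjacency, n_perm=config.n_perm, alpha=config.alpha,
        min_channel_extent=config.min_channel_extent, seed=seed)
    sig_channels = result.significant_channels(ch_names)
    freqs = config.tf_freqs
    band = (freqs >= config.theta_band[0]) & (freqs <= config.theta_band[1])
    topography = (pa - pb).mean(axis=0)[:, band].sum(axis=1)
    effect = None
    if sig_channels:
        idx = [ch_names.index(c) for c in sig_channels]
        va = pa[:, idx][:, :, band].mean(axis=(1, 2))
        vb = pb[:, idx][:, :, band].mean(axis=(1, 2))
        t, df, p, d = stats.paired_t(va, vb)
        effect = dict(t=t, df=df, p=p, cohens_d=d)
    return dict(result=result, significant_channels=sig_channels,
                theta_topography=topography, effect=effect, seed=seed)


# ---------------------------------------------------------------------------
# stage 2: decoding
# ---------------------------------------------------------------------------

def decoding_preprocess(epochs: EpochSet, config: AnalysisConfig,
                        seed: int | None = None,
                        pair: bool = True) -> EpochSet:
    """The fixed decoding chain: resample, 100 ms sliding average,
    baseline-correct to the preceding 200 ms, exemplar pair-averaging."""
    out = epochs
    if config.decode_rate < out.rate:
        out = preprocessing.resample(out, config.decode_rate)
    out = preprocessing.sliding_average(out, config.smooth_window_s)
    out = preprocessing.baseline_correct(out, config.baseline_window)
    if pair and "exemplar" in out.metadata.columns:
        out = decoding.pair_average(out, seed=seed)
    return out


def run_decoding(config: AnalysisConfig, epochs: list[EpochSet],
                 neighbours: dict | None = None,
                 generalization: bool = False) -> dict:
    """Group decoding: per-participant time courses, cluster-significant
    window, searchlight on that window, optional temporal generalization."""
    seeds = config.derived_seeds(2 * len(epochs) + 1, salt=2)
    post_onset = None
    accs = []
    processed = []
    for i, es in enumerate(epochs):
        pe = decoding_preprocess(es, config, seed=seeds[2 * i])
        pe = pe.select(np.arange(pe.n_trials))
        processed.append(pe)
        res = decoding.crossval_decode(pe, folds=config.folds,
                                       repeats=config.repeats,
                                       seed=seeds[2 * i + 1])
        accs.append(res.accuracy)
        post_onset = res.times
    accs = np.stack(accs)
    windows, cluster_res = decoding.decode_significance(
        accs, post_onset, n_perm=config.n_perm, alpha=config.alpha,
        seed=seeds[-1])
    window = max(windows, key=lambda w: w[1] - w[0]) if windows else None
    out = dict(times=post_onset, accuracies=accs, windows=windows,
               window=window, cluster=cluster_res)
    if window is not None and neighbours is not None:
        maps = []
        for i, pe in enumerate(processed):
            sl = decoding.searchlight_decode(pe, neighbours, window=window,
                                             folds=config.folds,
                                             repeats=config.repeats,
                                             seed=seeds[2 * i + 1])
            maps.append(sl.accuracy)
        out["searchlight"] = np.stack(maps)
        out["searchlight_channels"] = list(processed[0].ch_names)
    if generalization:
        tg = [decoding.temporal_generalization(pe, folds=config.folds,
                                               repeats=config.repeats,
                                               seed=seeds[2 * i + 1])
              for i, pe in enumerate(processed)]
        out["generalization"] = np.stack([g.accuracy for g in tg])
        out["train_times"] = tg[0].train_times
    return out


# ---------------------------------------------------------------------------
# stage 3: coherence
# ---------------------------------------------------------------------------

def run_coherence(config: AnalysisConfig, epochs_high: list[EpochSet],
                  epochs_low_count_reference: list[EpochSet],
                  adjacency: np.ndarray, window: tuple | None,
                  searchlight_channels=None) -> dict:
    """Seed coherence contrast between two tasks with trial-count matching.

    The condition with more trials per participant (typically DMS) is
    subsampled ``k`` times to the other condition's count before the paired
    cluster contrast.  Reports channel overlap with a searchlight
    significance map and re-decodes restricted to the coherent channels.
    """
    n = len(epochs_high)
    if n != len(epochs_low_count_reference) or n == 0:
        raise ValueError("both tasks must be present for every participant")
    seeds = config.derived_seeds(n + 1, salt=3)
    maps_ref, maps_big = [], []
    for i in range(n):
        ref = epochs_low_count_reference[i]
        big = epochs_high[i]
        maps_ref.append(connectivity.coherence_map(
            ref, seed_channel=config.coherence_seed, band=config.theta_band,
            window=window, step=config.tf_time_step))
        maps_big.append(connectivity.subsample_coherence(
            big, target_n_trials=ref.n_trials,
            seed_channel=config.coherence_seed, k=config.subsample_k,
            band=config.theta_band, window=window, step=config.tf_time_step,
            seed=seeds[i]))
    result, overlap = connectivity.coherence_contrast(
        maps_ref, maps_big, adjacency, n_perm=config.n_perm,
        alpha=config.alpha, min_channel_extent=config.min_channel_extent,
        seed=seeds[-1], searchlight_channels=searchlight_channels)
    out = dict(result=result, overlap=overlap,
               maps_a=maps_ref, maps_b=maps_big)
    sig = overlap["significant_channels"]
    if sig:
        dec_seeds = config.derived_seeds(2 * n, salt=4)
        accs = []
        for i in range(n):
            sub_idx = epochs_low_count_reference[i].channel_indices(sig)
            es = epochs_low_count_reference[i]
            sub = EpochSet(data=es.data[:, sub_idx, :], rate=es.rate,
                           tmin=es.tmin, ch_names=[str(c) for c in sig],
                           metadata=es.metadata)
            pe = decoding_preprocess(sub, config, seed=dec_seeds[2 * i])
            res = decoding.crossval_decode(pe, folds=config.folds,
                                           repeats=config.repeats,
                                           seed=dec_seeds[2 * i + 1])
            if window is not None:
                tmask = (res.times >= window[0]) & (res.times < window[1])
                accs.append(res.accuracy[tmask].mean()
                            if tmask.any() else res.accuracy.mean())
            else:
                accs.append(res.accuracy.mean())
        accs = np.asarray(accs)
        t, df, p, d = stats.paired_t(accs, np.full(n, 0.5))
        out["decode_on_coherent"] = dict(mean_accuracy=float(accs.mean()),
                                         t=t, df=df, p=p, cohens_d=d)
    return out


# ---------------------------------------------------------------------------
# stage 4: theta slowing
# ---------------------------------------------------------------------------

def peak_means_by_condition(epochs: list[EpochSet], channels,
                            config: AnalysisConfig,
                            smoothing: int | None = None,
                            use_irasa: bool = False) -> pd.DataFrame:
    """Per-participant, per-condition mean theta peak frequency."""
    tables = []
    for es in epochs:
        tables.append(spectral.trial_peak_frequencies(
            es, channels, band=config.theta_band,
            grid_step=config.peak_grid_step, smoothing=smoothing,
            use_irasa=use_irasa, irasa_factors=config.irasa_factors))
    table = pd.concat(tables, ignore_index=True)
    return spectral.condition_peak_means(table)


def _paired_from_means(means: pd.DataFrame, cond_a: str, cond_b: str):
    wide = means.pivot(index="participant", columns="task",
                       values="mean_peak_hz")
    return wide[cond_a].to_numpy(), wide[cond_b].to_numpy()


def run_slowing(config: AnalysisConfig, epochs: list[EpochSet],
                frontal_channels, cond_a: str = "1back",
                cond_b: str = "2back",
                robustness: bool = True) -> dict:
    """Theta peak slowing analysis between two load conditions.

    ``epochs`` is one EpochSet per participant carrying both conditions in
    the ``task`` metadata column.  Computes per-trial most-prominent peaks on
    the frontal channel-mean spectra, averages per condition, and tests the
    paired slowing.  Robustness variants repeat the statistic on IRASA
    residuals and on smoothed spectra; low-theta power follow-ups run
    per-frequency paired tests with Holm correction and a load x frequency
    repeated-measures ANOVA.
    """
    means = peak_means_by_condition(epochs, frontal_channels, config)
    xa, xb = _paired_from_means(means, cond_a, cond_b)
    t, df, p, d = stats.paired_t(xa, xb)
    out = dict(peak_means=means,
               grand_means={cond_a: float(np.nanmean(xa)),
                            cond_b: float(np.nanmean(xb))},
               slowing=dict(t=t, df=df, p=p, cohens_d=d))
    if robustness:
        rob = {}
        m_ir = peak_means_by_condition(epochs, frontal_channels, config,
                                       use_irasa=True)
        ia, ib = _paired_from_means(m_ir, cond_a, cond_b)
        t, df, p, d = stats.paired_t(ia, ib)
        rob["irasa"] = dict(mean_a=float(np.nanmean(ia)),
                            mean_b=float(np.nanmean(ib)), t=t, df=df, p=p,
                            cohens_d=d)
        for w in config.smoothing_windows:
            m_s = peak_means_by_condition(epochs, frontal_channels, config,
                                          smoothing=w)
            sa, sb = _paired_from_means(m_s, cond_a, cond_b)
            t, df, p, d = stats.paired_t(sa, sb)
            rob[f"smooth_{w}"] = dict(mean_a=float(np.nanmean(sa)),
                                      mean_b=float(np.nanmean(sb)), t=t,
                                      df=df, p=p, cohens_d=d)
        out["robustness"] = rob

    # low-theta power follow-up: 4-8 Hz in 0.5 Hz steps
    freq_grid = np.arange(config.theta_band[0], config.theta_band[1] + 1e-9,
                          0.5)
    per_part = []
    for es in epochs:
        est = spectral.epoch_spectrum(es, band=config.theta_band,
                                      grid_step=0.5)
        cm = est.channel_mean(frontal_channels)   # trials x freqs
        row = {}
        for cond in (cond_a, cond_b):
            sel = (es.metadata["task"] == cond).to_numpy()
            row[cond] = cm[sel].mean(axis=0)
        per_part.append(row)
    pa = np.stack([r[cond_a] for r in per_part])   # n x freqs
    pb = np.stack([r[cond_b] for r in per_part])
    per_freq = []
    for j, f in enumerate(freq_grid):
        t, df, p, d = stats.paired_t(pb[:, j], pa[:, j])
        per_freq.append(dict(freq=float(f), t=t, df=df, p=p, cohens_d=d))
    per_freq = pd.DataFrame(per_freq)
    per_freq["p_holm"] = stats.holm(per_freq["p"].to_numpy())
    anova = stats.rm_anova2(np.stack([pa, pb], axis=1))
    out["power_by_freq"] = per_freq
    out["anova"] = anova
    return out
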