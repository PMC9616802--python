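"""Synthetic EEG with known ground truth.

Generates epoched sessions that carry the statistical structure the analysis
pipeline is designed to detect:

* an aperiodic 1/f background on every channel (spectrally shaped Gaussian
  noise, power spectral density proportional to ``1/f**chi``),
* fronto-medial theta oscillators whose per-trial frequency is drawn from a
  truncated normal around a condition-specific mean (working-memory load
  shifts that mean),
* category-specific spatial patterns over posterior channels during stimulus
  and delay epochs (the decodable working-memory content),
* a band-limited signal shared between a frontal seed channel and posterior
  targets (theta coupling).

Every injected effect is logged in a ground-truth manifest so that recovery
can be scored against the generating parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import ChannelLayout, EpochSet

# idealised positions on the unit head sphere (x = right, y = anterior, z = up)
FZ_TARGET = np.array([0.0, np.sqrt(0.5), np.sqrt(0.5)])
PZ_TARGET = np.array([0.0, -np.sqrt(0.5), np.sqrt(0.5)])

#: condition presets for the frontal theta oscillator (Hz).  The two n-back
#: load levels differ by 0.08 Hz -- the small, consistent slowing the peak
#: statistic must resolve.  A separate preset pair is used for the scenario
#: in which the 1/f background is removed with IRASA before peak detection.
THETA_MEANS = {"1back": 5.85, "2back": 5.77, "dms": 6.0}
THETA_MEANS_IRASA = {"1back": 6.05, "2back": 5.99}

#: default oscillator amplitude (microvolt) against the default 10 microvolt
#: 1/f background; chosen so the delay-period band SNR of the channel-mean
#: spectrum is comfortably above 2 and per-trial peaks are recoverable.
DEFAULT_THETA_AMPLITUDE = 4.0
DEFAULT_NOISE_STD = 10.0

#: behavioural presets: P(correct) and median RT (s) per task
ACCURACY_PRESETS = {"dms": 0.96, "1back": 0.94, "2back": 0.93}
RT_MEDIANS = {"dms": 0.55, "1back": 0.60, "2back": 0.66}
RT_SIGMA = 0.35

JITTER_OPTIONS_MS = (0, 50, 100, 150)


# ---------------------------------------------------------------------------
# montage
# ---------------------------------------------------------------------------

def make_montage(n_channels: int, head_radius: float = 1.0,
                 seed: int = 0) -> ChannelLayout:
    """Quasi-uniform spherical cap layout on the upper hemisphere.

    Channels are placed on a Fibonacci lattice over the upper half of a
    sphere of radius ``head_radius``.  For eight or more channels the points
    nearest the canonical fronto-medial and parieto-medial positions are
    labelled ``Fz`` and ``Pz``; all others are ``E01``, ``E02``, ...
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    rng = np.random.default_rng(seed)
    i = np.arange(n_channels)
    z = (i + 0.5) / n_channels
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = i * golden + rng.uniform(0.0, 2.0 * np.pi)
    r = np.sqrt(1.0 - z ** 2)
    pos = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    labels = [f"E{k + 1:03d}" for k in range(n_channels)]
    if n_channels >= 8:
        i_fz = int(np.argmin(((pos - FZ_TARGET) ** 2).sum(1)))
        labels[i_fz] = "Fz"
        d_pz = ((pos - PZ_TARGET) ** 2).sum(1)
        d_pz[i_fz] = np.inf
        labels[int(np.argmin(d_pz))] = "Pz"
    return ChannelLayout(labels=labels, positions=pos * head_radius)


def channels_near(layout: ChannelLayout, point, k: int) -> list[str]:
    """Labels of the ``k`` channels nearest a reference point or label."""
    if isinstance(point, str):
        point = layout.positions[layout.index(point)]
    d = ((layout.positions - np.asarray(point, dtype=float)) ** 2).sum(1)
    order = np.argsort(d, kind="stable")[:k]
    return [layout.labels[j] for j in order]


def frontal_channels(layout: ChannelLayout, k: int = 4) -> list[str]:
    return channels_near(layout, FZ_TARGET * np.linalg.norm(layout.positions[0]), k)


def posterior_channels(layout: ChannelLayout, k: int = 6) -> list[str]:
    return channels_near(layout, PZ_TARGET * np.linalg.norm(layout.positions[0]), k)


# ---------------------------------------------------------------------------
# spectrally shaped noise
# ---------------------------------------------------------------------------

def _spectral_noise(rng: np.random.Generator, n_real: int, n_samples: int,
                    amp: np.ndarray, std: float) -> np.ndarray:
    """Real Gaussian noise with rFFT amplitude profile ``amp``.

    ``amp`` has one entry per rFFT bin; ``amp[0]`` (DC) is forced to zero.
    The output is analytically normalised so each sample has variance
    ``std**2`` in expectation.
    """
    amp = np.asarray(amp, dtype=float).copy()
    amp[0] = 0.0
    n_bins = n_samples // 2 + 1
    if amp.size != n_bins:
        raise ValueError("amplitude profile does not match rFFT length")
    g = rng.standard_normal((n_real, n_bins)) + 1j * rng.standard_normal((n_real, n_bins))
    spec = g * amp
    even = n_samples % 2 == 0
    if even:
        spec[:, -1] = spec[:, -1].real
    # variance of irfft output per sample (DC excluded)
    interior = amp[1:-1] if even else amp[1:]
    var = 4.0 * (interior ** 2).sum()
    if even:
        var += amp[-1] ** 2
    var /= n_samples ** 2
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    if var > 0 and std > 0:
        x *= std / np.sqrt(var)
    return x


def one_over_f_profile(n_samples: int, rate: float, exponent: float) -> np.ndarray:
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / rate)
    amp = np.ones_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    amp[0] = 0.0
    return amp


def generate_noise(n_trials: int, layout: ChannelLayout, duration: float,
                   rate: float, exponent: float, seed,
                   std: float = DEFAULT_NOISE_STD, tmin: float = 0.0,
                   metadata: pd.DataFrame | None = None) -> EpochSet:
    """Independent 1/f background noise per trial and channel."""
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    if exponent < 0:
        raise ValueError("exponent must be >= 0")
    n_samples = int(round(duration * rate))
    if n_samples < 2:
        raise ValueError("duration * rate must be >= 2")
    rng = np.random.default_rng(seed)
    amp = one_over_f_profile(n_samples, rate, exponent)
    x = _spectral_noise(rng, n_trials * layout.n_channels, n_samples, amp, std)
    data = x.reshape(n_trials, layout.n_channels, n_samples)
    if metadata is None:
        metadata = pd.DataFrame({"trial_index": np.arange(n_trials)})
    return EpochSet(data=data, rate=rate, tmin=tmin,
                    ch_names=list(layout.labels), metadata=metadata)


# ---------------------------------------------------------------------------
# effect injection
# ---------------------------------------------------------------------------

def _truncated_normal_freqs(rng, n, mean, sd, half_width=1.0):
    """Per-trial frequencies ~ Normal(mean, sd) truncated to mean +- half_width."""
    if sd == 0:
        return np.full(n, float(mean))
    a = -half_width / sd
    b = half_width / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def embed_oscillation(epochs: EpochSet, channels, mean_freq: float,
                      freq_sd: float, amplitude: float, seed,
                      window: tuple[float, float] | None = None):
    """Add a per-trial sinusoid on target channels; returns (epochs, manifest).

    The per-trial frequency is drawn from Normal(mean_freq, freq_sd) truncated
    symmetrically to [mean_freq - 1, mean_freq + 1] Hz; the phase is uniform.
    The sinusoid is added only within ``window`` (default: epoch onset to end).
    """
    idx = epochs.channel_indices(channels)
    out = epochs.copy()
    rng = np.random.default_rng(seed)
    n = epochs.n_trials
    freqs = _truncated_normal_freqs(rng, n, mean_freq, freq_sd)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n)
    manifest = pd.DataFrame({
        "trial_index": np.arange(n),
        "oscillator_freq": freqs,
        "oscillator_phase": phases,
        "oscillator_amplitude": amplitude,
    })
    if amplitude == 0:
        return out, manifest
    t = epochs.times
    if window is None:
        window = (0.0, t[-1] + 1.0 / epochs.rate)
    smask = epochs.time_mask(*window)
    wave = amplitude * np.cos(2.0 * np.pi * freqs[:, None] * t[None, smask]
                              + phases[:, None])
    out.data[np.ix_(np.arange(n), idx, np.flatnonzero(smask))] += wave[:, None, :]
    return out, manifest


def embed_category_pattern(epochs: EpochSet, channels, strength: float, seed,
                           label_col: str = "category",
                           window: tuple[float, float] | None = None) -> EpochSet:
    """Add a class-specific fixed spatial pattern on target channels.

    One random pattern per class is drawn once from ``seed`` and added as a
    constant offset over the target channels within ``window`` (default:
    epoch onset to end), making the classes linearly separable in channel
    space at every covered time point.
    """
    labels = epochs.metadata[label_col].astype(str).to_numpy()
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least two classes to embed a pattern")
    idx = epochs.channel_indices(channels)
    out = epochs.copy()
    if strength == 0:
        return out
    rng = np.random.default_rng(seed)
    patterns = {}
    for cls in classes:
        v = rng.standard_normal(len(idx))
        patterns[cls] = strength * v / np.linalg.norm(v)
    t = epochs.times
    if window is None:
        window = (0.0, t[-1] + 1.0 / epochs.rate)
    smask = np.flatnonzero(epochs.time_mask(*window))
    for cls in classes:
        rows = np.flatnonzero(labels == cls)
        out.data[np.ix_(rows, idx, smask)] += patterns[cls][None, :, None]
    return out


def embed_coupling(epochs: EpochSet, seed_channel: str, target_channels,
                   band: tuple[float, float], strength: float, seed,
                   amplitude: float = DEFAULT_NOISE_STD) -> EpochSet:
    """Mix a shared band-limited signal into seed and target channels.

    Each of seed and targets receives ``strength * common + (1 - strength) *
    independent`` band-limited Gaussian noise scaled to ``amplitude``
    microvolts; ``strength = 0`` leaves all channels statistically
    independent, ``strength = 1`` makes the band content identical.
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    targets = [str(c) for c in target_channels]
    if str(seed_channel) in targets:
        raise ValueError("seed channel cannot be one of the targets")
    idx = epochs.channel_indices([seed_channel] + targets)
    out = epochs.copy()
    rng = np.random.default_rng(seed)
    n_samples = epochs.n_samples
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / epochs.rate)
    amp = ((freqs >= band[0]) & (freqs <= band[1])).astype(float)
    if amp.sum() == 0:
        raise ValueError("band contains no frequency bins")
    n = epochs.n_trials
    common = _spectral_noise(rng, n, n_samples, amp, amplitude)
    indep = _spectral_noise(rng, n * len(idx), n_samples, amp, amplitude)
    indep = indep.reshape(n, len(idx), n_samples)
    mixed = strength * common[:, None, :] + (1.0 - strength) * indep
    out.data[:, idx, :] += mixed
    return out


# ---------------------------------------------------------------------------
# configuration and session assembly
# ---------------------------------------------------------------------------

@dataclass
class ThetaPreset:
    mean_freq: float
    freq_sd: float = 0.4
    amplitude: float = DEFAULT_THETA_AMPLITUDE
    target_channels: list[str] | None = None

    def __post_init__(self):
        if not 4.0 <= self.mean_freq <= 8.0:
            raise ValueError("theta preset mean frequency must lie in [4, 8] Hz")


@dataclass
class TaskPlan:
    stimulus_dur: float = 0.75
    response_dur: float = 0.75
    delay_dur: float = 2.5
    baseline_dur: float = 10.0
    pre_dur: float = 0.2           # pre-onset padding stored with every epoch
    n_back_blocks: dict = field(default_factory=lambda: {"2back": 8, "1back": 4})
    dms_runs: int = 2
    dms_exemplars: int = 15        # 5 per category x 3 categories
    dms_presentations: int = 6     # per run

    def __post_init__(self):
        if min(self.stimulus_dur, self.response_dur, self.delay_dur,
               self.baseline_dur) <= 0:
            raise ValueError("all durations must be positive")
        if self.stimulus_dur < 0.75 or self.delay_dur < 2.5:
            raise ValueError("stimulus must be >= 0.75 s and delay >= 2.5 s")


@dataclass
class CategoryEffect:
    target_channels: list[str] | None = None
    pattern_strength: float = 8.0
    pattern_seed: int | None = None


@dataclass
class CouplingSpec:
    seed_channel: str = "Fz"
    target_channels: list[str] | None = None
    band: tuple[float, float] = (4.0, 8.0)
    strength: dict = field(default_factory=lambda: {"1back": 0.6, "2back": 0.6,
                                                    "dms": 0.15})
    amplitude: float = DEFAULT_NOISE_STD

    def __post_init__(self):
        for v in self.strength.values():
            if not 0.0 <= v <= 1.0:
                raise ValueError("coupling strength must lie in [0, 1]")


@dataclass
class SimConfig:
    n_participants: int = 28
    n_channels: int = 64
    sampling_rate: float = 256.0
    task_plan: TaskPlan = field(default_factory=TaskPlan)
    noise_exponent: float = 1.0
    noise_std: float = DEFAULT_NOISE_STD
    theta_presets: dict = field(default_factory=lambda: {
        cond: ThetaPreset(mean_freq=m,
                          amplitude=(DEFAULT_THETA_AMPLITUDE
                                     if cond != "dms"
                                     else DEFAULT_THETA_AMPLITUDE / 3.0))
        for cond, m in THETA_MEANS.items()})
    category_effect: CategoryEffect = field(default_factory=CategoryEffect)
    coupling: CouplingSpec = field(default_factory=CouplingSpec)
    master_seed: int = 0


def _balanced_jitter(rng, n: int) -> np.ndarray:
    """Jitter (ms) with each option equally represented per block.

    When the block length is not a multiple of four the counts differ by at
    most one; the leftover slots are assigned by random draw without
    replacement.
    """
    reps = n // len(JITTER_OPTIONS_MS)
    vals = list(JITTER_OPTIONS_MS) * reps
    extra = n - len(vals)
    if extra:
        vals += list(rng.choice(JITTER_OPTIONS_MS, size=extra, replace=False))
    vals = np.array(vals)
    rng.shuffle(vals)
    return vals


def _behaviour(rng, task: str, n: int):
    correct = rng.random(n) < ACCURACY_PRESETS[task]
    rt = RT_MEDIANS[task] * np.exp(RT_SIGMA * rng.standard_normal(n))
    return correct, rt


def _nback_metadata(rng, task: str, n_blocks: int, participant: str) -> pd.DataFrame:
    n_per_block = 36 + int(task[0])
    rows = []
    exemplars = [f"{cat}{i}" for cat in ("object", "scene") for i in range(1, 6)]
    for b in range(n_blocks):
        seq = np.array(exemplars * (n_per_block // len(exemplars) + 1))
        rng.shuffle(seq)
        seq = seq[:n_per_block]
        jit = _balanced_jitter(rng, n_per_block)
        correct, rt = _behaviour(rng, task, n_per_block)
        for i in range(n_per_block):
            rows.append(dict(participant=participant, task=task,
                             category=seq[i][:-1], exemplar=seq[i],
                             block=b, trial_index=i, jitter_ms=int(jit[i]),
                             correct=bool(correct[i]), rt=float(rt[i])))
    return pd.DataFrame(rows)


def _dms_metadata(rng, plan: TaskPlan, participant: str) -> pd.DataFrame:
    cats = ("object", "scene", "face")
    per_cat = plan.dms_exemplars // len(cats)
    exemplars = [f"{cat}{i}" for cat in cats for i in range(1, per_cat + 1)]
    rows = []
    for run in range(plan.dms_runs):
        seq = np.array(exemplars * plan.dms_presentations)
        rng.shuffle(seq)
        n = len(seq)
        jit = _balanced_jitter(rng, n)
        correct, rt = _behaviour(rng, "dms", n)
        for i in range(n):
            cat = seq[i].rstrip("0123456789")
            rows.append(dict(participant=participant, task="dms",
                             category=cat, exemplar=seq[i],
                             block=run, trial_index=i, jitter_ms=int(jit[i]),
                             correct=bool(correct[i]), rt=float(rt[i])))
    return pd.DataFrame(rows)


def simulate_session(config: SimConfig, participant: str = "P01",
                     seed=None):
    """Simulate one participant's full session.

    Returns ``(epochs, manifest)`` where ``epochs`` maps task name to a dict
    of EpochSets keyed by epoch type (``stimulus``, ``delay``, ``response``
    and, for the n-back task, ``baseline``).  Epoch arrays are rectangular at
    the minimum epoch duration; the per-trial jitter lives in the metadata.
    """
    plan = config.task_plan
    ss = np.random.SeedSequence(config.master_seed if seed is None else seed)
    seeds = iter(ss.generate_state(64) % (2 ** 31))
    layout = make_montage(config.n_channels, seed=int(next(seeds)))
    frontal = frontal_channels(layout, k=max(2, config.n_channels // 16))
    posterior = (config.category_effect.target_channels
                 or posterior_channels(layout, k=max(3, config.n_channels // 10)))
    coup_targets = config.coupling.target_channels or posterior
    coup_targets = [c for c in coup_targets if c != config.coupling.seed_channel]
    rng_meta = np.random.default_rng(int(next(seeds)))
    pattern_seed = (config.category_effect.pattern_seed
                    if config.category_effect.pattern_seed is not None
                    else int(next(seeds)))

    tables = {"dms": _dms_metadata(rng_meta, plan, participant)}
    for task, n_blocks in plan.n_back_blocks.items():
        tables[task] = _nback_metadata(rng_meta, task, n_blocks, participant)

    epochs: dict[str, dict[str, EpochSet]] = {}
    manifest_rows = []
    for task, meta in tables.items():
        preset = config.theta_presets.get(task)
        per_task: dict[str, EpochSet] = {}
        for epoch_type, dur in (("stimulus", plan.stimulus_dur),
                                ("response", plan.response_dur),
                                ("delay", plan.delay_dur)):
            md = meta.copy()
            md["epoch"] = epoch_type
            es = generate_noise(len(md), layout, dur + plan.pre_dur,
                                config.sampling_rate, config.noise_exponent,
                                int(next(seeds)), std=config.noise_std,
                                tmin=-plan.pre_dur, metadata=md)
            osc_manifest = None
            if epoch_type == "delay" and preset is not None:
                targets = preset.target_channels or frontal
                es, osc_manifest = embed_oscillation(
                    es, targets, preset.mean_freq, preset.freq_sd,
                    preset.amplitude, int(next(seeds)))
            if epoch_type in ("stimulus", "delay"):
                es = embed_category_pattern(
                    es, posterior, config.category_effect.pattern_strength,
                    pattern_seed)
            if epoch_type == "delay":
                strength = config.coupling.strength.get(task, 0.0)
                if strength > 0:
                    es = embed_coupling(es, config.coupling.seed_channel,
                                        coup_targets, config.coupling.band,
                                        strength, int(next(seeds)),
                                        amplitude=config.coupling.amplitude)
            per_task[epoch_type] = es
            if epoch_type == "delay":
                for i, row in md.iterrows():
                    manifest_rows.append(dict(
                        participant=participant, task=task,
                        block=int(row["block"]),
                        trial_index=int(row["trial_index"]),
                        category=row["category"],
                        oscillator_freq=(float(osc_manifest["oscillator_freq"][i])
                                         if osc_manifest is not None else None),
                        theta_channels=list(preset.target_channels or frontal)
                                        if preset is not None else [],
                        pattern_channels=list(posterior),
                        coupling_channels=list(coup_targets),
                        coupling_strength=float(
                            config.coupling.strength.get(task, 0.0)),
                        master_seed=int(config.master_seed),
                    ))
        if task != "dms":
            n_blocks = plan.n_back_blocks[task]
            base_md = pd.DataFrame(dict(
                participant=participant, task=task, category="none",
                exemplar="none", block=np.repeat(np.arange(n_blocks), 2),
                trial_index=np.tile([0, 1], n_blocks), jitter_ms=0,
                correct=True, rt=np.nan))
            base_md["epoch"] = "baseline"
            per_task["baseline"] = generate_noise(
                len(base_md), layout, plan.baseline_dur, config.sampling_rate,
                config.noise_exponent, int(next(seeds)),
                std=config.noise_std, tmin=0.0, metadata=base_md)
        epochs[task] = per_task
    manifest = pd.DataFrame(manifest_rows)
    return epochs, manifest


def write_manifest(manifest: pd.DataFrame, path) -> None:
    """Ground-truth manifest as JSON lines, one record per trial."""
    with open(path, "w") as f:
        for _, row in manifest.iterrows():
            f.write(json.dumps(row.to_dict(), default=str) + "\n")


def read_manifest(path) -> pd.DataFrame:
    with open(path) as f:
        return pd.DataFrame([json.loads(line) for line in f if line.strip()])


# ---------------------------------------------------------------------------
# reduced cohorts for parameter-recovery studies
# ---------------------------------------------------------------------------

def simulate_delay_cohort(presets: dict[str, ThetaPreset],
                          n_participants: int = 28,
                          n_trials: int = 40,
                          n_channels: int = 8,
                          n_frontal: int = 4,
                          rate: float = 256.0,
                          delay_dur: float = 2.5,
                          noise_exponent: float = 1.0,
                          noise_std: float = DEFAULT_NOISE_STD,
                          master_seed: int = 0):
    """Delay-period-only cohort for the theta peak-frequency analyses.

    Each participant receives ``n_trials`` delay epochs per condition in
    ``presets``; the frontal theta oscillator of each condition is injected
    on a common frontal channel set over a 1/f background.

    Returns ``(sessions, manifest, layout, frontal)`` where ``sessions`` is a
    list of per-participant EpochSets whose metadata carries the condition in
    the ``task`` column.
    """
    ss = np.random.SeedSequence(master_seed)
    layout = make_montage(n_channels, seed=int(ss.generate_state(1)[0] % (2 ** 31)))
    frontal = frontal_channels(layout, k=n_frontal)
    child = ss.spawn(n_participants)
    sessions, manifest_rows = [], []
    for p, pseed in enumerate(child):
        seeds = iter(pseed.generate_state(4 * len(presets) + 2) % (2 ** 31))
        parts = []
        pid = f"P{p + 1:02d}"
        for cond, preset in presets.items():
            md = pd.DataFrame(dict(
                participant=pid, task=cond, epoch="delay",
                category="none", exemplar="none", block=0,
                trial_index=np.arange(n_trials), correct=True, rt=np.nan))
            es = generate_noise(n_trials, layout, delay_dur, rate,
                                noise_exponent, int(next(seeds)),
                                std=noise_std, tmin=0.0, metadata=md)
            es, osc = embed_oscillation(
                es, preset.target_channels or frontal, preset.mean_freq,
                preset.freq_sd, preset.amplitude, int(next(seeds)))
            parts.append(es)
            for _, row in osc.iterrows():
                manifest_rows.append(dict(
                    participant=pid, task=cond,
                    trial_index=int(row["trial_index"]),
                    oscillator_freq=float(row["oscillator_freq"]),
                    theta_channels=list(preset.target_channels or frontal)))
        data = np.concatenate([e.data for e in parts], axis=0)
        meta = pd.concat([e.metadata for e in parts], ignore_index=True)
        sessions.append(EpochSet(data=data, rate=rate, tmin=0.0,
                                 ch_names=list(layout.labels), metadata=meta))
    return sessions, pd.DataFrame(manifest_rows), layout, frontal
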