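"""Core data containers: epoched EEG and channel layouts.

The :class:`EpochSet` is the lingua franca of every analysis stage: a dense
``trials x channels x samples`` voltage array (microvolts) together with the
sampling rate, a time axis relative to epoch onset, channel labels and a
per-trial metadata table (task, epoch type, stimulus category, exemplar,
correctness, reaction time, block, trial index, participant).

The :class:`ChannelLayout` holds channel labels with 3-D positions on a
unit-radius head and derives the neighbour graph used for channel clustering
and searchlight decoding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

#: canonical metadata columns (extra columns are allowed and preserved)
METADATA_COLUMNS = (
    "participant",
    "task",
    "epoch",
    "category",
    "exemplar",
    "correct",
    "rt",
    "block",
    "trial_index",
)

_STRING_COLS = {"participant", "task", "epoch", "category"}


@dataclass
class EpochSet:
    """Epoched multichannel EEG.

    Parameters
    ----------
    data:
        ``(n_trials, n_channels, n_samples)`` float array, microvolts.
    rate:
        Sampling rate in Hz.
    tmin:
        Time of the first sample in seconds relative to epoch onset
        (negative when the epoch carries pre-onset padding).
    ch_names:
        Unique channel labels, one per data row.
    metadata:
        Per-trial table with one row per trial.
    """

    data: np.ndarray
    rate: float
    tmin: float
    ch_names: list[str]
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        self.ch_names = [str(c) for c in self.ch_names]
        if len(self.ch_names) != self.data.shape[1]:
            raise ValueError("channel labels do not match data")
        if len(set(self.ch_names)) != len(self.ch_names):
            raise ValueError("channel labels must be unique")
        if len(self.metadata) != self.data.shape[0]:
            raise ValueError("metadata rows must equal number of trials")
        self.metadata = self.metadata.reset_index(drop=True)

    # -- basic geometry -------------------------------------------------
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Time axis in seconds, 0 = epoch onset, spacing 1/rate."""
        return self.tmin + np.arange(self.n_samples) / self.rate

    # -- indexing helpers -----------------------------------------------
    def channel_indices(self, labels) -> np.ndarray:
        try:
            return np.array([self.ch_names.index(str(l)) for l in labels])
        except ValueError as err:
            raise KeyError(f"unknown channel label: {err}") from None

    def time_mask(self, start: float, end: float) -> np.ndarray:
        """Boolean sample mask for the half-open window [start, end)."""
        t = self.times
        return (t >= start - 1e-12) & (t < end - 1e-12)

    def copy(self, data: np.ndarray | None = None,
             metadata: pd.DataFrame | None = None,
             rate: float | None = None,
             tmin: float | None = None) -> "EpochSet":
        return EpochSet(
            data=np.array(self.data if data is None else data, copy=True),
            rate=self.rate if rate is None else rate,
            tmin=self.tmin if tmin is None else tmin,
            ch_names=list(self.ch_names),
            metadata=(self.metadata if metadata is None else metadata).copy(),
        )

    def select(self, mask) -> "EpochSet":
        """Subset trials by boolean mask or integer index array."""
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask.astype(int)
        return self.copy(data=self.data[idx], metadata=self.metadata.iloc[idx])

    def query(self, expr: str) -> "EpochSet":
        idx = self.metadata.query(expr).index.to_numpy()
        return self.copy(data=self.data[idx], metadata=self.metadata.iloc[idx])

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        """Write the lossless HDF5 container."""
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data.astype(np.float64))
            f.create_dataset("times", data=self.times)
            f.attrs["rate"] = float(self.rate)
            f.attrs["tmin"] = float(self.tmin)
            f.create_dataset("channels", data=[str(c) for c in self.ch_names],
                             dtype=h5py.string_dtype())
            meta = f.create_group("metadata")
            for col in self.metadata.columns:
                vals = self.metadata[col]
                if col in _STRING_COLS or vals.dtype == object:
                    meta.create_dataset(col,
                                        data=[str(v) for v in vals],
                                        dtype=h5py.string_dtype())
                else:
                    meta.create_dataset(col, data=vals.to_numpy())
            meta.attrs["columns"] = list(map(str, self.metadata.columns))

    @classmethod
    def load(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            rate = float(f.attrs["rate"])
            tmin = float(f.attrs["tmin"])
            ch_names = [c.decode() if isinstance(c, bytes) else str(c)
                        for c in f["channels"][()]]
            cols = list(f["metadata"].attrs["columns"])
            frame = {}
            for col in cols:
                vals = f["metadata"][col][()]
                if vals.dtype.kind in ("S", "O"):
                    vals = np.array([v.decode() if isinstance(v, bytes) else v
                                     for v in vals])
                frame[col] = vals
            metadata = pd.DataFrame(frame, columns=cols)
        return cls(data=data, rate=rate, tmin=tmin, ch_names=ch_names,
                   metadata=metadata)


@dataclass
class ChannelLayout:
    """Channel labels with 3-D positions on the unit head sphere."""

    labels: list[str]
    positions: np.ndarray  # (n, 3), unit-radius head coordinates
    positions_field: str = field(default="x,y,z", repr=False)

    def __post_init__(self) -> None:
        self.labels = [str(l) for l in self.labels]
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_labels, 3)")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("labels must be unique")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(str(label))
        except ValueError:
            raise KeyError(f"unknown channel label: {label!r}") from None

    def distance_matrix(self) -> np.ndarray:
        d = self.positions[:, None, :] - self.positions[None, :, :]
        return np.sqrt((d ** 2).sum(-1))

    def adjacency(self, radius: float) -> np.ndarray:
        """Symmetric irreflexive boolean adjacency at Euclidean ``radius``."""
        if radius <= 0:
            raise ValueError("radius must be positive")
        dist = self.distance_matrix()
        adj = dist <= radius
        np.fill_diagonal(adj, False)
        return adj

    def neighbours(self, radius: float) -> dict[str, set[str]]:
        adj = self.adjacency(radius)
        return {
            lab: {self.labels[j] for j in np.flatnonzero(adj[i])}
            for i, lab in enumerate(self.labels)
        }

    def calibrate_radius(self, target_mean_degree: float = 5.7,
                         tol: float = 0.25) -> float:
        """Radius whose neighbour graph has the requested mean degree.

        The neighbourhood radius of the searchlight/cluster graph is a
        layout-unit-dependent quantity; calibrating it against a target mean
        neighbour count makes configurations portable across montages.
        """
        dist = self.distance_matrix()
        offdiag = dist[~np.eye(self.n_channels, dtype=bool)]
        candidates = np.unique(offdiag)
        degrees = [(np.asarray(dist <= r).sum() - self.n_channels)
                   / self.n_channels for r in candidates]
        degrees = np.asarray(degrees)
        best = int(np.argmin(np.abs(degrees - target_mean_degree)))
        return float(candidates[best])

    # -- persistence -----------------------------------------------------
    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.positions, columns=["x", "y", "z"])
        df.insert(0, "label", self.labels)
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ChannelLayout":
        df = pd.read_csv(path, sep="\t")
        return cls(labels=list(df["label"].astype(str)),
                   positions=df[["x", "y", "z"]].to_numpy())
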