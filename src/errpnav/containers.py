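"""In-memory containers for continuous and epoched EEG, with on-disk formats.

Two containers flow through the pipeline:

``SubjectRecording``
    Continuous multichannel EEG (channels x time, microvolts) plus event
    markers — what an amplifier + marker stream would have produced.
``EpochSet``
    Trials x channels x time array cut around each event, with per-trial
    class labels (``error`` / ``true``).

Both round-trip through an HDF5 container and a CSV + JSON-sidecar fallback.
Optional importers for EDF+ and BrainVision recordings live in
:mod:`errpnav.io_import`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np
import h5py

from .montages import MontageSpec, get_montage

LABELS = ("error", "true")


@dataclass
class SubjectRecording:
    """Continuous EEG with event markers.

    Attributes
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal in microvolts.
    events : list of (int, str)
        (sample index of action onset, label) with label in
        ``{"error", "true"}``.
    montage : MontageSpec
    seed : int or None
        Seed the synthetic generator used, for provenance.
    """

    samples: np.ndarray
    events: list
    montage: MontageSpec
    seed: int | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError("samples must be channels x time")
        if self.samples.shape[0] != self.montage.n_channels:
            raise ValueError("channel count does not match montage")
        n_times = self.samples.shape[1]
        for idx, label in self.events:
            if not (0 <= idx < n_times):
                raise ValueError(f"event index {idx} outside recording")
            if label not in LABELS:
                raise ValueError(f"unknown event label '{label}'")

    @property
    def rate(self) -> float:
        return self.montage.sampling_rate

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    # ---- HDF5 container -------------------------------------------------
    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("samples", data=self.samples)
            idx = np.array([e[0] for e in self.events], dtype=np.int64)
            lab = np.array([e[1] for e in self.events], dtype="S8")
            f.create_dataset("event_index", data=idx)
            f.create_dataset("event_label", data=lab)
            f.attrs["rate"] = self.montage.sampling_rate
            f.attrs["montage"] = self.montage.name
            f.attrs["channel_names"] = json.dumps(self.montage.channel_names)
            f.attrs["frontocentral_weights"] = json.dumps(
                list(self.montage.frontocentral_weights))
            f.attrs["seed"] = -1 if self.seed is None else int(self.seed)

    @classmethod
    def from_hdf5(cls, path) -> "SubjectRecording":
        with h5py.File(path, "r") as f:
            samples = f["samples"][()]
            idx = f["event_index"][()]
            lab = [s.decode() for s in f["event_label"][()]]
            montage = _montage_from_attrs(dict(f.attrs))
            seed = int(f.attrs["seed"])
        return cls(samples=samples, events=list(zip(idx.tolist(), lab)),
                   montage=montage, seed=None if seed < 0 else seed)

    # ---- CSV + JSON sidecar fallback ------------------------------------
    def to_csv(self, path) -> None:
        """Write samples to ``path`` (CSV, channels as columns) and metadata
        to ``path`` with a ``.json`` suffix appended."""
        path = Path(path)
        np.savetxt(path, self.samples.T, delimiter=",",
                   header=",".join(self.montage.channel_names), comments="")
        sidecar = {
            "rate": self.montage.sampling_rate,
            "montage": self.montage.name,
            "channel_names": self.montage.channel_names,
            "frontocentral_weights": list(self.montage.frontocentral_weights),
            "events": [[int(i), l] for i, l in self.events],
            "seed": self.seed,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_csv(cls, path) -> "SubjectRecording":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        samples = np.loadtxt(path, delimiter=",", skiprows=1).T
        montage = _montage_from_meta(meta)
        return cls(samples=samples,
                   events=[(int(i), l) for i, l in meta["events"]],
                   montage=montage, seed=meta.get("seed"))


@dataclass
class EpochSet:
    """Epoched EEG: trials x channels x time, with per-trial labels.

    ``time_zero_index`` is the sample index of action onset within each
    epoch (e.g. 50 for a window starting at -0.2 s sampled at 250 Hz).
    """

    data: np.ndarray
    labels: np.ndarray
    rate: float
    channel_names: list
    time_zero_index: int

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.data.ndim != 3:
            # allow the empty sentinel (0, C, T)
            raise ValueError("data must be trials x channels x time")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length must equal trial count")
        for l in self.labels:
            if l not in LABELS:
                raise ValueError(f"unknown label '{l}'")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length must equal channel count")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    @property
    def times(self) -> np.ndarray:
        """Times in seconds relative to action onset."""
        return (np.arange(self.n_times) - self.time_zero_index) / self.rate

    def y(self) -> np.ndarray:
        """Binary label vector: 1 = error, 0 = true."""
        return np.array([1 if l == "error" else 0 for l in self.labels])

    def select_channels(self, names) -> "EpochSet":
        idx = [self.channel_names.index(n) for n in names]
        return EpochSet(self.data[:, idx, :], self.labels.copy(), self.rate,
                        list(names), self.time_zero_index)

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("labels",
                             data=np.array(self.labels.tolist(), dtype="S8"))
            f.attrs["rate"] = self.rate
            f.attrs["channel_names"] = json.dumps(list(self.channel_names))
            f.attrs["time_zero_index"] = self.time_zero_index

    @classmethod
    def from_hdf5(cls, path) -> "EpochSet":
        with h5py.File(path, "r") as f:
            data = f["data"][()]
            labels = [s.decode() for s in f["labels"][()]]
            names = json.loads(f.attrs["channel_names"])
            rate = float(f.attrs["rate"])
            tz = int(f.attrs["time_zero_index"])
        return cls(data, np.array(labels, dtype=object), rate, names, tz)


def _montage_from_meta(meta: dict) -> MontageSpec:
    name = meta["montage"]
    if name in ("gel64", "gel16", "dry20"):
        built = get_montage(name)
        if built.channel_names == list(meta["channel_names"]):
            return built
    return MontageSpec(name="custom",
                       channel_names=list(meta["channel_names"]),
                       sampling_rate=float(meta["rate"]),
                       frontocentral_weights=list(meta["frontocentral_weights"]))


def _montage_from_attrs(attrs: dict) -> MontageSpec:
    return _montage_from_meta({
        "montage": attrs["montage"],
        "channel_names": json.loads(attrs["channel_names"]),
        "rate": attrs["rate"],
        "frontocentral_weights": json.loads(attrs["frontocentral_weights"]),
    })
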