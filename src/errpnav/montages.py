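"""EEG montage definitions.

Three built-in montages mirror the recording setups the synthetic generator
emulates: a 64-channel gel cap at 250 Hz, a 16-channel frontocentral subset of
it, and a 20-channel dry headset at 500 Hz.  Each montage carries a per-channel
*frontocentral weight* in [0, 1] that scales how strongly the error-related
template projects onto that electrode (ErrPs are maximal over frontocentral
midline sites).
"""

from __future__ import annotations

from dataclasses import dataclass, field


# 64-channel gel cap layout (10-05 extension of the 10-20 system).
_GEL64_CHANNELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6",
    "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "PO9", "O1", "Oz", "O2", "PO10",
    "AF7", "AF3", "AF4", "AF8",
    "F5", "F1", "F2", "F6",
    "FT9", "FT7", "FC3", "FC4", "FT8", "FT10",
    "C5", "C1", "C2", "C6",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P5", "P1", "P2", "P6",
    "PO7", "PO3", "POz", "PO4", "PO8",
]

# 16-channel frontocentral subset.  The exact subset used with the gel cap is
# not published; this frontocentral 10-20/10-10 selection (documented
# assumption) keeps the midline and lateral central sites that carry the ErrP.
_GEL16_CHANNELS = [
    "F3", "F1", "Fz", "F2", "F4",
    "FC3", "FC1", "FC2", "FC4",
    "C3", "C1", "Cz", "C2", "C4",
    "CP1", "CP2",
]

# 20-channel dry headset (10-20 positions).
_DRY20_CHANNELS = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
]

# ErrP topography weights by electrode name; anything not listed falls back to
# a prefix heuristic in _weight_for().
_WEIGHT_BY_NAME = {
    "Fz": 1.0, "FCz": 1.0, "Cz": 0.9,
    "FC1": 0.9, "FC2": 0.9, "F1": 0.8, "F2": 0.8, "C1": 0.8, "C2": 0.8,
    "FC3": 0.7, "FC4": 0.7, "F3": 0.6, "F4": 0.6, "C3": 0.6, "C4": 0.6,
    "CPz": 0.6, "CP1": 0.5, "CP2": 0.5, "Pz": 0.4,
}

_WEIGHT_BY_PREFIX = [
    ("FC", 0.6), ("Fp", 0.15), ("AF", 0.3), ("FT", 0.2), ("TP", 0.1),
    ("CP", 0.35), ("PO", 0.1), ("F", 0.4), ("C", 0.4), ("T", 0.1),
    ("P", 0.2), ("O", 0.1),
]


def _weight_for(name: str) -> float:
    if name in _WEIGHT_BY_NAME:
        return _WEIGHT_BY_NAME[name]
    for prefix, w in _WEIGHT_BY_PREFIX:
        if name.startswith(prefix):
            return w
    return 0.1


@dataclass(frozen=True)
class MontageSpec:
    """An EEG montage: ordered channel names, rate, and ErrP topography.

    Parameters
    ----------
    name : str
        ``gel64 | gel16 | dry20 | custom``.
    channel_names : list of str
        Ordered electrode labels (10-20 / 10-05 nomenclature).
    sampling_rate : float
        Digitization rate in Hz (250 for the gel system, 500 for dry).
    frontocentral_weights : list of float
        Per-channel scalar in [0, 1]; scales the ErrP template amplitude
        at that electrode.
    """

    name: str
    channel_names: list = field(default_factory=list)
    sampling_rate: float = 250.0
    frontocentral_weights: list = field(default_factory=list)

    def __post_init__(self):
        expected = {"gel64": 64, "gel16": 16, "dry20": 20}
        if self.name in expected and len(self.channel_names) != expected[self.name]:
            raise ValueError(
                f"montage '{self.name}' requires {expected[self.name]} channels, "
                f"got {len(self.channel_names)}"
            )
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if len(self.frontocentral_weights) != len(self.channel_names):
            raise ValueError("one frontocentral weight per channel required")
        if any(not (0.0 <= w <= 1.0) for w in self.frontocentral_weights):
            raise ValueError("frontocentral weights must lie in [0, 1]")
        if self.name in expected:
            for required in ("Fz", "Cz"):
                if required not in self.channel_names:
                    raise ValueError(f"built-in montage must contain {required}")

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index_of(self, channel: str) -> int:
        try:
            return self.channel_names.index(channel)
        except ValueError:
            raise KeyError(f"channel '{channel}' not in montage '{self.name}'") from None


def _build(name: str, channels: list, rate: float) -> MontageSpec:
    return MontageSpec(
        name=name,
        channel_names=list(channels),
        sampling_rate=rate,
        frontocentral_weights=[_weight_for(c) for c in channels],
    )


def get_montage(name: str) -> MontageSpec:
    """Return a built-in montage by name (``gel64``, ``gel16``, ``dry20``)."""
    if name == "gel64":
        return _build("gel64", _GEL64_CHANNELS, 250.0)
    if name == "gel16":
        return _build("gel16", _GEL16_CHANNELS, 250.0)
    if name == "dry20":
        return _build("dry20", _DRY20_CHANNELS, 500.0)
    raise ValueError(f"unknown montage '{name}' (expected gel64, gel16 or dry20)")


BUILTIN_MONTAGES = ("gel64", "gel16", "dry20")
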