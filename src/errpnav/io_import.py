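"""Optional importers for EDF+ and BrainVision recordings.

These convert files recorded with standard acquisition software into
:class:`~errpnav.containers.SubjectRecording` so the preprocessing and
classification stages can run on real data.  They require ``mne``; the rest
of the package does not.

Event extraction: annotations/markers whose description contains ``error``
(case-insensitive) become error events, those containing ``true`` or
``correct`` become true events; anything else is ignored.
"""

from __future__ import annotations

from .containers import SubjectRecording
from .montages import MontageSpec, _weight_for


def _require_mne():
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "EDF/BrainVision import requires the optional dependency 'mne' "
            "(pip install errpnav[eeg-import])") from exc
    return mne


def _label_for(description: str) -> str | None:
    d = description.lower()
    if "error" in d:
        return "error"
    if "true" in d or "correct" in d:
        return "true"
    return None


def _from_raw(raw) -> SubjectRecording:
    data = raw.get_data() * 1e6  # volts -> microvolts
    rate = float(raw.info["sfreq"])
    names = list(raw.ch_names)
    montage = MontageSpec(name="custom", channel_names=names,
                          sampling_rate=rate,
                          frontocentral_weights=[_weight_for(n) for n in names])
    events = []
    for ann in raw.annotations:
        label = _label_for(ann["description"])
        if label is None:
            continue
        idx = int(round((ann["onset"] - raw.first_time) * rate))
        if 0 <= idx < data.shape[1]:
            events.append((idx, label))
    return SubjectRecording(samples=data, events=events, montage=montage)


def import_edf(path) -> SubjectRecording:
    """Read an EDF+ file into a SubjectRecording (microvolts)."""
    mne = _require_mne()
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    return _from_raw(raw)


def import_brainvision(vhdr_path) -> SubjectRecording:
    """Read a BrainVision triplet (.vhdr/.eeg/.vmrk) into a SubjectRecording."""
    mne = _require_mne()
    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True,
                                      verbose="error")
    return _from_raw(raw)
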