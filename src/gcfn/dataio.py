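"""Labeled motor-imagery trial collections and their on-disk formats.

The universal currency of the pipeline is the :class:`TrialSet`: a stack of
epoched multi-channel EEG trials (trials x channels x samples, microvolts)
with one class label per trial.  The four motor-imagery classes are encoded
as ``0=left hand, 1=right hand, 2=foot, 3=tongue`` throughout the package.

Two on-disk formats are supported:

* the internal container — a NumPy ``.npz`` archive whose round-trip is
  bit-exact on every field;
* GDF session files in the BioSig dialect used by the BCI Competition IV 2a
  benchmark, read through :mod:`mne` and epoched relative to the cue events.
"""

from __future__ import annotations

import dataclasses
import os
import zipfile
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CLASS_NAMES",
    "CUE_EVENT_CODES",
    "ARTIFACT_EVENT_CODE",
    "TrialSet",
    "EpochWindow",
    "load_gdf",
    "save_trialset",
    "load_trialset",
]

CLASS_NAMES = ("left hand", "right hand", "foot", "tongue")

#: GDF event codes of the four motor-imagery cues, mapped to class indices.
CUE_EVENT_CODES = {769: 0, 770: 1, 771: 2, 772: 3}

#: GDF event code marking a trial that experts flagged as artifact-bearing.
ARTIFACT_EVENT_CODE = 1023

#: 22-electrode montage of the BCI Competition IV 2a recordings
#: (10-20 system, dataset's native order).
MONTAGE_2A = (
    "Fz", "FC3", "FC1", "FCz", "FC2", "FC4",
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP3", "CP1", "CPz", "CP2", "CP4",
    "P1", "Pz", "P2", "POz",
)


class FormatError(RuntimeError):
    """Raised when an on-disk container is malformed or inconsistent."""


@dataclass(frozen=True)
class EpochWindow:
    """Half-open epoch window in seconds relative to cue onset.

    The epoch covers ``[t_start, t_end)``; its length in samples is
    ``round((t_end - t_start) * fs)``.
    """

    t_start: float = 0.5
    t_end: float = 4.0

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError(f"t_end ({self.t_end}) must exceed t_start ({self.t_start})")

    def n_samples(self, fs: float) -> int:
        n = (self.t_end - self.t_start) * fs
        if abs(n - round(n)) > 1e-9:
            raise ValueError(
                f"window ({self.t_start}, {self.t_end}) s is not an integer "
                f"number of samples at fs={fs} Hz"
            )
        return int(round(n))


@dataclass
class TrialSet:
    """Labeled collection of identically shaped multi-channel EEG epochs.

    Attributes
    ----------
    data
        Array of shape (trials, channels, samples), in microvolts.
    labels
        Integer class index per trial, each in {0, 1, 2, 3}.
    fs
        Sampling rate in Hz.
    channel_names
        Ordered electrode labels; length equals the channel axis.
    provenance
        Free-text processing tag, e.g. ``"raw"``, ``"augmented"``,
        ``"synthetic"``.
    """

    data: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str]
    provenance: str = "raw"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.data.ndim != 3:
            raise ValueError(f"data must be trials x channels x samples, got ndim={self.data.ndim}")
        if self.labels.ndim != 1 or len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"labels length {self.labels.shape} does not match "
                f"{self.data.shape[0]} trials"
            )
        if len(self.labels) and not np.isin(self.labels, [0, 1, 2, 3]).all():
            bad = sorted(set(self.labels.tolist()) - {0, 1, 2, 3})
            raise ValueError(f"labels must be in {{0,1,2,3}}; found {bad}")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[1]} channels"
            )
        self.channel_names = [str(c) for c in self.channel_names]

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def replace(self, **kwargs) -> "TrialSet":
        """Copy with selected fields replaced (data is not copied)."""
        return dataclasses.replace(self, **kwargs)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=4)


def save_trialset(ts: TrialSet, path: str | os.PathLike) -> None:
    """Write a :class:`TrialSet` to the internal ``.npz`` container.

    The round-trip ``load_trialset(save_trialset(ts))`` reproduces the data
    array bit-exactly along with labels, sampling rate, channel names and
    provenance.
    """
    np.savez(
        path,
        data=ts.data,
        labels=ts.labels,
        fs=np.float64(ts.fs),
        channel_names=np.array(ts.channel_names, dtype="U32"),
        provenance=np.array(ts.provenance, dtype="U128"),
    )


def load_trialset(path: str | os.PathLike) -> TrialSet:
    """Read a :class:`TrialSet` written by :func:`save_trialset`."""
    try:
        with np.load(path, allow_pickle=False) as npz:
            required = {"data", "labels", "fs", "channel_names", "provenance"}
            missing = required - set(npz.files)
            if missing:
                raise FormatError(f"container {path} is missing fields {sorted(missing)}")
            return TrialSet(
                data=npz["data"],
                labels=npz["labels"],
                fs=float(npz["fs"]),
                channel_names=list(npz["channel_names"]),
                provenance=str(npz["provenance"]),
            )
    except (zipfile.BadZipFile, OSError, ValueError, KeyError) as exc:
        if isinstance(exc, FormatError):
            raise
        raise FormatError(f"cannot read trial container {path}: {exc}") from exc


def load_gdf(
    path: str | os.PathLike,
    window: EpochWindow = EpochWindow(),
    *,
    exclude_artifacts: bool = False,
) -> TrialSet:
    """Epoch a GDF motor-imagery session into a :class:`TrialSet`.

    One trial is extracted per cue event (codes 769-772), covering the
    half-open window ``[cue + t_start, cue + t_end)``.  EOG channels are
    dropped; EEG channels keep the file's native order.  Trials flagged by
    the artifact marker (event 1023 within the 2 s preceding the cue) are
    kept by default; set ``exclude_artifacts=True`` to drop them.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        If the file contains no motor-imagery cue events, or the requested
        window runs past the end of the recording.
    """
    import mne

    if not os.path.exists(path):
        raise FileNotFoundError(f"GDF file not found: {path}")
    raw = mne.io.read_raw_gdf(str(path), preload=True, verbose="error")
    picks = mne.pick_types(raw.info, eeg=True, eog=False, stim=False)
    channel_names = [raw.ch_names[i] for i in picks]
    fs = float(raw.info["sfreq"])
    signal_uv = raw.get_data(picks=picks) * 1e6  # mne returns volts

    events, event_id = mne.events_from_annotations(raw, verbose="error")
    code_of = {}
    for desc, eid in event_id.items():
        try:
            code_of[eid] = int(desc)
        except ValueError:
            continue
    cue_samples, labels = [], []
    artifact_samples = []
    for sample, _, eid in events:
        code = code_of.get(eid)
        if code in CUE_EVENT_CODES:
            cue_samples.append(int(sample))
            labels.append(CUE_EVENT_CODES[code])
        elif code == ARTIFACT_EVENT_CODE:
            artifact_samples.append(int(sample))
    if not cue_samples:
        raise ValueError(f"no motor-imagery cue events (769-772) found in {path}")

    if exclude_artifacts and artifact_samples:
        artifact_samples = np.asarray(artifact_samples)
        keep = [
            i
            for i, s in enumerate(cue_samples)
            if not np.any((artifact_samples >= s - 2 * fs) & (artifact_samples <= s))
        ]
        cue_samples = [cue_samples[i] for i in keep]
        labels = [labels[i] for i in keep]

    n_samp = window.n_samples(fs)
    trials = []
    for s in cue_samples:
        start = s + int(round(window.t_start * fs))
        stop = start + n_samp
        if start < 0 or stop > signal_uv.shape[1]:
            raise ValueError(
                f"epoch window ({window.t_start}, {window.t_end}) s around cue at "
                f"sample {s} exceeds the recording ({signal_uv.shape[1]} samples)"
            )
        trials.append(signal_uv[:, start:stop])
    return TrialSet(
        data=np.stack(trials),
        labels=np.asarray(labels),
        fs=fs,
        channel_names=channel_names,
        provenance="raw",
    )
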