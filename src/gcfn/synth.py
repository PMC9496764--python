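"""Synthetic four-class motor-imagery EEG with ERD/ERS structure.

The generator emulates the physiology the decoding pipeline exploits:
during motor imagery the sensorimotor mu rhythm (8-13 Hz) and beta rhythm
(17-30 Hz) desynchronize over the contralateral hemisphere (band power
drops) and synchronize ipsilaterally (band power rises).  Each synthetic
trial is 1/f-shaped background noise plus band-limited mu and beta
oscillations on every channel; for the trial's class the oscillation
amplitude at designated channels is scaled by ``1 - erd_depth``
(contralateral, ERD) or ``1 + erd_depth`` (ipsilateral, ERS):

* left hand   — mu+beta down at C4, up at C3
* right hand  — mu+beta down at C3, up at C4
* foot        — beta down at Cz
* tongue      — mu down at Cz

These four spatial-spectral signatures are linearly separable, which makes
the generator a self-contained test bed for the whole decoding chain.  The
oscillations are stationary over the epoch (no temporal ERD ramp) and there
is no volume conduction or ocular/muscle artifact model.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .dataio import MONTAGE_2A, TrialSet

__all__ = ["MU_BAND", "BETA_BAND", "SynthConfig", "generate", "write_fixture_gdf"]

MU_BAND = (8.0, 13.0)
BETA_BAND = (17.0, 30.0)

#: Per-class oscillation modulation: class index -> list of
#: (channel label, band name, polarity) with polarity -1 for ERD
#: (amplitude x (1 - erd_depth)) and +1 for ERS (x (1 + erd_depth)).
DEFAULT_CHANNEL_MAP: dict[int, list[tuple[str, str, int]]] = {
    0: [("C4", "mu", -1), ("C4", "beta", -1), ("C3", "mu", +1), ("C3", "beta", +1)],
    1: [("C3", "mu", -1), ("C3", "beta", -1), ("C4", "mu", +1), ("C4", "beta", +1)],
    2: [("Cz", "beta", -1)],
    3: [("Cz", "mu", -1)],
}


@dataclass
class SynthConfig:
    """Generative parameters of the ERD/ERS simulator.

    Parameters
    ----------
    n_per_class
        Trials generated per class (total is four times this).
    fs
        Sampling rate, Hz; must exceed twice the beta-band upper edge.
    duration
        Epoch length in seconds (default 3.5 s = 875 samples at 250 Hz).
    erd_depth
        Fractional band-power modulation in [0, 1]; 0 disables all
        class-dependent structure.
    noise_sigma
        Standard deviation of the 1/f background noise, microvolts.
    rhythm_amp
        Standard deviation of each band-limited oscillation (mu, beta)
        before modulation, microvolts.
    seed
        RNG seed; generation is deterministic given the seed.
    channel_map
        Class -> (channel, band, polarity) modulation table; see
        :data:`DEFAULT_CHANNEL_MAP`.
    """

    n_per_class: int = 50
    fs: float = 250.0
    duration: float = 3.5
    erd_depth: float = 0.5
    noise_sigma: float = 10.0
    rhythm_amp: float = 5.0
    seed: int = 0
    channel_map: dict[int, list[tuple[str, str, int]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CHANNEL_MAP.items()}
    )

    def __post_init__(self) -> None:
        if not 0.0 <= self.erd_depth <= 1.0:
            raise ValueError(f"erd_depth must lie in [0, 1], got {self.erd_depth}")
        if self.n_per_class < 1:
            raise ValueError(f"n_per_class must be >= 1, got {self.n_per_class}")
        if not self.fs > 2 * BETA_BAND[1]:
            raise ValueError(
                f"fs={self.fs} Hz violates the Nyquist requirement for the "
                f"{BETA_BAND[1]} Hz beta-band edge"
            )
        if self.duration <= 0:
            raise ValueError(f"duration must be positive, got {self.duration}")
        for cls, mods in self.channel_map.items():
            for ch, band, pol in mods:
                if ch not in MONTAGE_2A:
                    raise ValueError(f"unknown channel {ch!r} in channel_map[{cls}]")
                if band not in ("mu", "beta"):
                    raise ValueError(f"unknown band {band!r} in channel_map[{cls}]")
                if pol not in (-1, +1):
                    raise ValueError(f"polarity must be +-1, got {pol}")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


def _band_noise(rng: np.random.Generator, n: int, fs: float, band: tuple[float, float]) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to ``band`` (Hz)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec = np.zeros(len(freqs), dtype=complex)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec[mask] = rng.standard_normal(mask.sum()) + 1j * rng.standard_normal(mask.sum())
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Unit-variance noise with a 1/f amplitude profile above 1 Hz."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = 1.0 / np.maximum(freqs, 1.0)
    amp[0] = 0.0  # no DC component
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def generate(cfg: SynthConfig) -> TrialSet:
    """Simulate a balanced four-class :class:`~gcfn.dataio.TrialSet`.

    Trials are ordered class-major (all class-0 trials first); shuffle via
    cross-validation folds, not here, so the layout stays predictable.
    """
    rng = np.random.default_rng(cfg.seed)
    n_ch = len(MONTAGE_2A)
    n_samp = cfg.n_samples
    ch_index = {ch: i for i, ch in enumerate(MONTAGE_2A)}
    bands = {"mu": MU_BAND, "beta": BETA_BAND}

    data = np.empty((4 * cfg.n_per_class, n_ch, n_samp))
    labels = np.empty(4 * cfg.n_per_class, dtype=np.int64)
    t = 0
    for cls in range(4):
        gains = np.ones((n_ch, 2))  # columns: mu, beta
        for ch, band, pol in cfg.channel_map.get(cls, []):
            gains[ch_index[ch], 0 if band == "mu" else 1] = 1.0 + pol * cfg.erd_depth
        for _ in range(cfg.n_per_class):
            for c in range(n_ch):
                x = cfg.noise_sigma * _pink_noise(rng, n_samp, cfg.fs)
                x += gains[c, 0] * cfg.rhythm_amp * _band_noise(rng, n_samp, cfg.fs, bands["mu"])
                x += gains[c, 1] * cfg.rhythm_amp * _band_noise(rng, n_samp, cfg.fs, bands["beta"])
                data[t, c] = x
            labels[t] = cls
            t += 1
    return TrialSet(
        data=data,
        labels=labels,
        fs=cfg.fs,
        channel_names=list(MONTAGE_2A),
        provenance="synthetic",
    )


# ---------------------------------------------------------------------------
# Minimal GDF 1.25 writer for self-contained reader fixtures.
# ---------------------------------------------------------------------------

_CUE_CODE_OF_CLASS = {0: 769, 1: 770, 2: 771, 3: 772}


def _pad(text: str, width: int) -> bytes:
    raw = text.encode("latin-1")[:width]
    return raw + b" " * (width - len(raw))


def write_fixture_gdf(
    cfg: SynthConfig,
    path: str | os.PathLike,
    *,
    pre_cue: float = 0.5,
    post_trial: float = 0.5,
) -> TrialSet:
    """Write a synthetic session as a minimal GDF 1.25 file.

    The generated trials (see :func:`generate`) are laid out on a continuous
    timeline with a cue event (codes 769-772) before each trial; the trial
    signal occupies ``[cue + 0.5 s, cue + 0.5 s + duration)`` so that reading
    the file back with :func:`gcfn.dataio.load_gdf` and the default epoch
    window recovers the generated trials up to float32 quantization.
    Samples are stored as float32 in microvolts with unit gain.

    Returns the generated :class:`TrialSet` (the ground truth for the file).
    """
    ts = generate(cfg)
    fs = int(round(cfg.fs))
    if abs(fs - cfg.fs) > 1e-9:
        raise ValueError("GDF fixture writer requires an integer sampling rate")
    n_ch = ts.n_channels
    n_samp = ts.n_samples
    cue_offset = int(round(0.5 * fs))  # trial data starts 0.5 s after the cue
    pre = int(round(pre_cue * fs))
    post = int(round(post_trial * fs))
    slot = pre + cue_offset + n_samp + post

    total = slot * ts.n_trials
    n_records = -(-total // fs)  # 1-second records, ceil
    total = n_records * fs
    signal = np.zeros((n_ch, total), dtype=np.float32)
    cue_samples = np.empty(ts.n_trials, dtype=np.int64)
    for i in range(ts.n_trials):
        cue = i * slot + pre
        cue_samples[i] = cue
        signal[:, cue + cue_offset : cue + cue_offset + n_samp] = ts.data[i]

    header = bytearray()
    header += _pad("GDF 1.25", 8)
    header += _pad("X X", 80)                      # patient id
    header += _pad("gcfn synthetic fixture", 80)   # recording id
    header += _pad("20220101120000" + "00", 16)    # start date/time
    header += np.int64(256 + 256 * n_ch).tobytes() # header length
    header += b"\x00" * 8 * 3                      # equipment/hospital/technician
    header += b"\x00" * 20                         # reserved
    header += np.int64(n_records).tobytes()
    header += np.array([1, 1], dtype="<u4").tobytes()  # record length 1 s
    header += np.array([n_ch], dtype="<u4").tobytes()

    for name in ts.channel_names:
        header += _pad(name, 16)
    for _ in range(n_ch):
        header += _pad("synthetic EEG", 80)
    for _ in range(n_ch):
        header += _pad("uV", 8)
    header += np.full(n_ch, -32768.0, dtype="<f8").tobytes()  # physical min
    header += np.full(n_ch, 32767.0, dtype="<f8").tobytes()   # physical max
    header += np.full(n_ch, -32768, dtype="<i8").tobytes()    # digital min
    header += np.full(n_ch, 32767, dtype="<i8").tobytes()     # digital max
    for _ in range(n_ch):
        header += _pad("HP:0.0Hz LP:100.0Hz", 80)
    header += np.full(n_ch, fs, dtype="<i4").tobytes()        # samples per record
    header += np.full(n_ch, 16, dtype="<i4").tobytes()        # GDF type 16 = float32
    header += b"\x00" * 32 * n_ch                             # reserved

    # data records: per record, channel-blocked
    records = signal.reshape(n_ch, n_records, fs).transpose(1, 0, 2)

    # mode-1 event table: positions are 1-based samples, types are cue codes
    ev = bytearray()
    ev += np.uint8(1).tobytes()
    ev += int(fs).to_bytes(3, "little")            # event sample rate
    ev += np.array([ts.n_trials], dtype="<u4").tobytes()
    ev += (cue_samples.astype("<u4") + 1).tobytes()
    ev += np.array([_CUE_CODE_OF_CLASS[int(l)] for l in ts.labels], dtype="<u2").tobytes()

    try:
        with open(path, "wb") as fh:
            fh.write(bytes(header))
            fh.write(records.astype("<f4").tobytes())
            fh.write(bytes(ev))
    except OSError as exc:
        raise OSError(f"cannot write GDF fixture to {path}: {exc}") from exc
    return ts
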