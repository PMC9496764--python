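"""Morlet continuous wavelet transform and grayscale scalogram images.

The CNN branch of the classifier consumes one 224 x 93 grayscale image per
trial.  The image is built channel by channel: each channel's signal is
analyzed with a Morlet continuous wavelet transform (CWT) on a grid of
frequencies spanning 8-30 Hz, the per-channel magnitude maps are stacked
vertically in electrode order, the stacked map is bilinearly resized to
224 x 93, min-max scaled to 8-bit gray levels (0-255), and divided by 255.

The Morlet mother wavelet is ``psi(t) = exp(i*omega*t) * exp(-t^2/2)`` with
dimensionless center parameter ``omega`` (default 6, the conventional
admissibility-respecting choice).  A dilated/translated atom at scale
``alpha`` and shift ``tau`` is ``psi((t - tau)/alpha) / sqrt(alpha)``, and
the transform is the correlation integral of the signal with the conjugate
atom.  Scales are chosen as ``alpha = omega / (2*pi*f)`` so that the
analytic center frequency of row ``f`` equals ``f`` Hz exactly.  The signal
is implicitly zero-padded where the wavelet support extends beyond the
epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from skimage.transform import resize

__all__ = ["CWTParams", "SpectrogramImage", "morlet_cwt", "build_image", "batch_images"]

IMAGE_SHAPE = (224, 93)


def _default_freqs() -> np.ndarray:
    return np.linspace(8.0, 30.0, 32)


@dataclass
class CWTParams:
    """Morlet CWT analysis grid.

    ``freqs`` are the analysis frequencies in Hz (default: 32 linearly
    spaced points in [8, 30]); ``omega`` is the dimensionless Morlet center
    parameter.  The per-frequency scale coefficients follow as
    ``omega / (2*pi*f)`` seconds.
    """

    freqs: np.ndarray = field(default_factory=_default_freqs)
    omega: float = 6.0
    image_shape: tuple[int, int] = IMAGE_SHAPE
    n_channels: int = 22

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.ndim != 1 or len(self.freqs) == 0:
            raise ValueError("freqs must be a non-empty 1-D sequence")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if self.freqs[0] < 8.0 - 1e-9 or self.freqs[-1] > 30.0 + 1e-9:
            raise ValueError(f"freqs must lie within [8, 30] Hz, got "
                             f"[{self.freqs[0]}, {self.freqs[-1]}]")
        if self.omega <= 0:
            raise ValueError(f"omega must be positive, got {self.omega}")

    def scales(self) -> np.ndarray:
        """Scale coefficient per analysis frequency, in seconds."""
        return self.omega / (2.0 * np.pi * self.freqs)


@dataclass
class SpectrogramImage:
    """A 224 x 93 grayscale scalogram, values on the 256-level grid in [0, 1]."""

    pixels: np.ndarray
    source_trial: int
    channel_order: list[str]

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")


def morlet_cwt(x: np.ndarray, params: CWTParams, fs: float) -> np.ndarray:
    """Morlet CWT magnitude of a single-channel signal.

    Returns an array of shape (len(params.freqs), len(x)); entry [f, tau]
    is the magnitude of the transform at analysis frequency ``freqs[f]`` and
    translation ``tau`` (in samples).  The correlation sum runs over the
    whole signal (full wavelet support, zero-padded edges), evaluated by FFT
    convolution; it matches a direct evaluation of the discretized
    correlation integral to floating-point accuracy.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("signal must be a non-empty 1-D array")
    return _cwt_channels(x[None, :], params, fs)[0]


def _cwt_channels(x: np.ndarray, params: CWTParams, fs: float) -> np.ndarray:
    """Morlet CWT magnitude of a (channels, samples) array, vectorized."""
    n = x.shape[1]
    dt = 1.0 / fs
    scales = params.scales()
    # Gaussian envelope support truncated at 8 standard deviations, where
    # the atom amplitude is ~1e-14 of its peak (far below any tolerance).
    half = min(n - 1, int(np.ceil(8.0 * scales.max() * fs)))
    j = np.arange(-half, half + 1)
    u = (j * dt)[None, :] / scales[:, None]
    atoms = np.exp(-1j * params.omega * u) * np.exp(-0.5 * u**2)
    kernels = atoms * (dt / np.sqrt(scales))[:, None]
    # out[m] = sum_n x[n] k[n-m]  ==  convolve(x, k reversed), centered slice
    conv = fftconvolve(x[:, None, :], kernels[None, :, ::-1], axes=2)
    return np.abs(conv[:, :, half : half + n])


def build_image(
    trial: np.ndarray, params: CWTParams, fs: float, *,
    source_trial: int = 0, channel_order: list[str] | None = None,
) -> SpectrogramImage:
    """Render one trial (channels x samples) as a grayscale scalogram.

    Per-channel CWT magnitude maps are stacked vertically in electrode
    order, bilinearly resized to the target geometry (default 224 x 93),
    min-max scaled per image to integers 0-255, and divided by 255, yielding
    pixel values on the 256-level grid in [0, 1].  The rendering is
    invariant to a positive rescaling of the input trial.
    """
    trial = np.asarray(trial, dtype=float)
    if trial.ndim != 2:
        raise ValueError("trial must be channels x samples")
    if trial.shape[0] != params.n_channels:
        raise ValueError(
            f"trial has {trial.shape[0]} channels but params expect {params.n_channels}"
        )
    maps = _cwt_channels(trial, params, fs)
    stacked = maps.reshape(-1, trial.shape[1])
    img = resize(
        stacked, params.image_shape, order=1, mode="edge",
        anti_aliasing=False, preserve_range=True,
    )
    lo, hi = img.min(), img.max()
    if hi > lo:
        img = np.rint(255.0 * (img - lo) / (hi - lo))
    else:
        img = np.zeros(params.image_shape)
    return SpectrogramImage(
        pixels=img / 255.0,
        source_trial=source_trial,
        channel_order=list(channel_order) if channel_order is not None else [],
    )


def batch_images(ts, params: CWTParams | None = None) -> list[SpectrogramImage]:
    """One scalogram image per trial of a TrialSet, order preserved."""
    if params is None:
        params = CWTParams(n_channels=ts.n_channels)
    return [
        build_image(
            ts.data[i], params, ts.fs,
            source_trial=i, channel_order=ts.channel_names,
        )
        for i in range(ts.n_trials)
    ]


def image_stack(images: list[SpectrogramImage]) -> np.ndarray:
    """Stack images into an (n, height, width) array for model input."""
    return np.stack([im.pixels for im in images])
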