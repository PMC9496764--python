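"""Bandpass filtering and per-trial standardization.

The decoding pipeline restricts the EEG to the 8-30 Hz band that carries the
mu and beta sensorimotor rhythms, using a 5th-order Butterworth bandpass.
By default the filter is applied forward-backward (zero phase), which avoids
phase distortion of the ERD time course in offline analysis; a causal
single-pass mode is available via ``zero_phase=False``.

The time-series branch of the classifier receives z-scored trials: for each
trial, the mean and population standard deviation pooled over all of its
channels and samples are removed, so every standardized trial has mean 0 and
standard deviation 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .dataio import TrialSet

__all__ = ["FilterSpec", "bandpass", "zscore", "to_gru_layout"]


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth bandpass specification (defaults: 8-30 Hz, order 5)."""

    low_hz: float = 8.0
    high_hz: float = 30.0
    order: int = 5
    zero_phase: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.low_hz < self.high_hz:
            raise ValueError(
                f"band edges must satisfy 0 < low < high, got "
                f"({self.low_hz}, {self.high_hz})"
            )
        if self.order < 1:
            raise ValueError(f"order must be >= 1, got {self.order}")


def bandpass(ts: TrialSet, spec: FilterSpec = FilterSpec()) -> TrialSet:
    """Bandpass-filter every channel of every trial independently."""
    if not spec.high_hz < ts.fs / 2:
        raise ValueError(
            f"high edge {spec.high_hz} Hz must lie below Nyquist ({ts.fs / 2} Hz)"
        )
    sos = signal.butter(
        spec.order, [spec.low_hz, spec.high_hz], btype="bandpass", fs=ts.fs, output="sos"
    )
    if spec.zero_phase:
        filtered = signal.sosfiltfilt(sos, ts.data, axis=-1)
    else:
        filtered = signal.sosfilt(sos, ts.data, axis=-1)
    return ts.replace(data=filtered, provenance=f"{ts.provenance}+bandpass")


def zscore(ts: TrialSet) -> TrialSet:
    """Standardize each trial to mean 0, standard deviation 1.

    The mean and the population standard deviation are pooled over all
    channels and samples of the trial (z_i = (x_i - mu) / sigma).

    Raises
    ------
    ValueError
        If any trial has zero variance, naming the offending trial index.
    """
    mu = ts.data.mean(axis=(1, 2), keepdims=True)
    sigma = ts.data.std(axis=(1, 2), keepdims=True)  # population (ddof=0)
    degenerate = np.flatnonzero(sigma.ravel() == 0)
    if degenerate.size:
        raise ValueError(
            f"trial {int(degenerate[0])} has zero variance; cannot z-score"
        )
    return ts.replace(data=(ts.data - mu) / sigma, provenance=f"{ts.provenance}+zscore")


def to_gru_layout(ts: TrialSet) -> np.ndarray:
    """Transpose trials to (trials, samples, channels) for the recurrent
    branch, whose time steps run along the sample axis."""
    return np.ascontiguousarray(ts.data.transpose(0, 2, 1))
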