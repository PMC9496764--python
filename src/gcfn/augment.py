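"""Time-shift / recombination data augmentation for epoched EEG.

Each trial (a channels x samples matrix) is slid along the time axis in
steps of ``S`` samples: at slide ``k`` the last ``k*S`` samples are cut off
and moved to the front, i.e. a circular shift by ``k*S``.  Sliding stops
once ``k*S >= T`` (the shifted copy would coincide with the original), so a
trial of length ``T`` yields ``ceil(T/S) - 1`` new copies.  With the
benchmark geometry ``T = 875`` and ``S = 80`` each trial produces 10 copies,
expanding a 576-trial session to 6336 trials.

Every copy is a permutation of the original samples per channel, so channel
means, variances and value multisets are preserved; only the temporal
alignment changes.  Copies inherit the source trial's class label.  The
splice discontinuity at the cut point is left as-is (no smoothing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import TrialSet

__all__ = ["AugmentConfig", "n_copies", "slide_recombine", "augment_dataset"]


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation parameters: slide step ``step`` (samples) and whether
    the untouched original trial is kept in the output."""

    step: int = 80
    include_original: bool = True

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"step must be positive, got {self.step}")


def n_copies(T: int, S: int) -> int:
    """Number of shifted copies produced per trial: ``ceil(T/S) - 1``."""
    _check_step(S, T)
    return -(-T // S) - 1


def _check_step(S: int, T: int) -> None:
    if not 0 < S < T:
        raise ValueError(f"slide step S={S} must satisfy 0 < S < T={T}")


def slide_recombine(trial: np.ndarray, S: int) -> list[np.ndarray]:
    """Return the shifted copies of one trial (originals not included).

    The k-th copy (k = 1..ceil(T/S)-1) satisfies
    ``out[c, t] = trial[c, (t - k*S) mod T]``: the last ``k*S`` samples are
    moved to the front and the remainder is appended.
    """
    trial = np.asarray(trial)
    if trial.ndim != 2:
        raise ValueError(f"trial must be channels x samples, got ndim={trial.ndim}")
    T = trial.shape[1]
    _check_step(S, T)
    return [np.roll(trial, k * S, axis=1) for k in range(1, n_copies(T, S) + 1)]


def augment_dataset(ts: TrialSet, cfg: AugmentConfig = AugmentConfig()) -> TrialSet:
    """Expand every trial of ``ts`` by its time-shifted copies.

    Output order is deterministic: source trials in their original order,
    each followed by (or, when ``include_original`` is false, replaced by)
    its copies with the shift index ascending.  All copies carry the source
    trial's label.  Provenance is set to ``"augmented"``.
    """
    T = ts.n_samples
    k_max = n_copies(T, cfg.step)
    per_trial = k_max + (1 if cfg.include_original else 0)
    out = np.empty((ts.n_trials * per_trial, ts.n_channels, T), dtype=ts.data.dtype)
    labels = np.repeat(ts.labels, per_trial)
    pos = 0
    for i in range(ts.n_trials):
        if cfg.include_original:
            out[pos] = ts.data[i]
            pos += 1
        for k in range(1, k_max + 1):
            out[pos] = np.roll(ts.data[i], k * cfg.step, axis=1)
            pos += 1
    return ts.replace(data=out, labels=labels, provenance="augmented")


def source_groups(n_source: int, cfg: AugmentConfig, T: int) -> np.ndarray:
    """Source-trial id of each augmented trial, for leakage-free splitting."""
    per_trial = n_copies(T, cfg.step) + (1 if cfg.include_original else 0)
    return np.repeat(np.arange(n_source), per_trial)
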