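"""Published benchmark accuracies used as inputs to the kappa arithmetic.

Per-subject 10-fold classification accuracies (percent) on the nine
subjects of the BCI Competition IV 2a benchmark, as printed for the
fusion model and its comparisons, plus the global accuracies of the
two ablation branches.  These are inputs — reported measurements this
package's evaluation arithmetic (mean accuracy, kappa with chance rate
0.25) can be applied to — not outputs of this package.
"""

from __future__ import annotations

__all__ = [
    "PER_SUBJECT_ACCURACY",
    "GLOBAL_ACCURACY",
    "CHANCE_RATE",
]

#: Percent accuracy per subject S1..S9.
PER_SUBJECT_ACCURACY: dict[str, tuple[float, ...]] = {
    "gcfn": (88.3, 72.8, 93.7, 76.2, 60.2, 71.1, 84.1, 96.4, 83.7),
    "csp_lda": (78.2, 74.1, 88.5, 64.3, 50.2, 57.5, 85.8, 87.5, 71.7),
}

#: Percent global (average) accuracy of each model.
GLOBAL_ACCURACY: dict[str, float] = {
    "eeg_gru": 62.9,
    "cwt_cnn": 72.7,
    "csp_lda": 73.1,
    "gcfn": 80.7,
}

#: Chance agreement rate of the balanced four-class task.
CHANCE_RATE = 0.25
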