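"""One-versus-rest CSP spatial filtering with an LDA classifier.

Common spatial patterns (CSP) finds spatial filters w maximizing the
variance of one class's filtered signal relative to the rest, by solving
the generalized eigenproblem

    Sigma_c w = lambda * Sigma_comp w

where ``Sigma_c`` is the class-average trial covariance (each trial
covariance normalized by its trace, making the filters invariant to global
amplitude) and ``Sigma_comp`` is the composite covariance, here the sum of
the four class-average covariances, so every generalized eigenvalue lies
in (0, 1).  For each class the ``m`` largest- and ``m`` smallest-eigenvalue
filters are retained; a trial's feature vector concatenates, per class
block, the log of each filtered signal's variance normalized by the block's
total variance.  Classification is multi-class linear discriminant analysis
with a shared, diagonally loaded within-class covariance; ties go to the
lower class index.

Inputs should be bandpass-filtered to the 8-30 Hz sensorimotor band first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .dataio import TrialSet

__all__ = ["CSPModel", "csp_ovr_fit", "csp_features", "lda_fit_predict", "csp_lda_crossval"]

N_CLASSES = 4


@dataclass
class CSPModel:
    """Fitted one-versus-rest CSP filters.

    ``filters[c]`` has shape (channels, 2m): the m largest- and m
    smallest-eigenvalue generalized eigenvectors of class c versus the
    composite covariance.  ``eigenvalues[c]`` holds the corresponding 2m
    eigenvalues.  The feature dimension is ``4 * 2m``.
    """

    filters: list[np.ndarray]
    eigenvalues: list[np.ndarray]
    composite_cov: np.ndarray
    m_pairs: int

    @property
    def n_features(self) -> int:
        return N_CLASSES * 2 * self.m_pairs


def _normalized_cov(trial: np.ndarray) -> np.ndarray:
    c = trial @ trial.T
    tr = np.trace(c)
    if tr <= 0:
        raise ValueError("trial with zero power; cannot form covariance")
    return c / tr


def csp_ovr_fit(ts: TrialSet, m: int = 2, loading: float = 1e-8) -> CSPModel:
    """Fit one-versus-rest CSP filters on a labeled trial set.

    Parameters
    ----------
    m
        Filter pairs kept per class (m largest + m smallest eigenvectors).
    loading
        Diagonal loading of the composite covariance, as a fraction of its
        mean diagonal (numerical conditioning).
    """
    counts = ts.class_counts()
    if (counts < 2).any():
        raise ValueError(f"need >= 2 trials per class, got counts {counts.tolist()}")
    if not 1 <= 2 * m <= ts.n_channels:
        raise ValueError(f"m={m} filter pairs infeasible for {ts.n_channels} channels")
    class_covs = []
    for c in range(N_CLASSES):
        trials = ts.data[ts.labels == c]
        class_covs.append(np.mean([_normalized_cov(t) for t in trials], axis=0))
    composite = np.sum(class_covs, axis=0)
    composite = composite + loading * np.trace(composite) / ts.n_channels * np.eye(ts.n_channels)
    filters, eigenvalues = [], []
    for c in range(N_CLASSES):
        w, v = linalg.eigh(class_covs[c], composite)  # ascending eigenvalues
        keep = np.r_[w.size - m : w.size, 0:m]        # m largest then m smallest
        filters.append(v[:, keep])
        eigenvalues.append(w[keep])
    return CSPModel(filters=filters, eigenvalues=eigenvalues,
                    composite_cov=composite, m_pairs=m)


def csp_features(model: CSPModel, ts: TrialSet) -> np.ndarray:
    """Normalized log-variance CSP features, shape (trials, 4 * 2m).

    Feature j within a class block is ``log(var_j / sum_block var)``; the
    within-block normalization removes global trial amplitude.
    """
    n_ch = model.filters[0].shape[0]
    if ts.n_channels != n_ch:
        raise ValueError(f"trial set has {ts.n_channels} channels, model expects {n_ch}")
    feats = np.empty((ts.n_trials, model.n_features))
    for i in range(ts.n_trials):
        cols = []
        for c in range(N_CLASSES):
            filtered = model.filters[c].T @ ts.data[i]
            var = filtered.var(axis=1)
            total = var.sum()
            if total <= 0 or (var <= 0).any():
                raise ValueError(f"trial {i}: zero-variance filtered signal")
            cols.append(np.log(var / total))
        feats[i] = np.concatenate(cols)
    return feats


def lda_fit_predict(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    test_features: np.ndarray,
    *,
    shrinkage: float = 1e-6,
) -> np.ndarray:
    """Multi-class LDA with shared, diagonally loaded covariance.

    Uses the least-squares solver with a small shrinkage toward the scaled
    identity as the loading.  Prediction is the argmax discriminant; exact
    ties resolve to the lower class index.
    """
    train_labels = np.asarray(train_labels)
    if len(np.unique(train_labels)) < 2:
        raise ValueError("LDA requires at least two classes in the training data")
    lda = LinearDiscriminantAnalysis(solver="lsqr", shrinkage=shrinkage)
    lda.fit(train_features, train_labels)
    scores = lda.decision_function(test_features)
    if scores.ndim == 1:  # two-class degenerate shape
        return lda.classes_[(scores > 0).astype(int)]
    return lda.classes_[np.argmax(scores, axis=1)]  # argmax ties -> lowest index


def csp_lda_crossval(ts: TrialSet, folds, m: int = 2) -> dict:
    """End-to-end CSP-LDA cross-validation, mirroring the deep model's
    evaluation output (per-fold metrics, mean accuracy, kappa)."""
    from .trainer_eval import confusion_metrics, kappa

    fold_metrics = []
    for fold in folds:
        train_ts = ts.replace(data=ts.data[fold.train_idx], labels=ts.labels[fold.train_idx])
        model = csp_ovr_fit(train_ts, m=m)
        f_train = csp_features(model, train_ts)
        val_ts = ts.replace(data=ts.data[fold.val_idx], labels=ts.labels[fold.val_idx])
        f_val = csp_features(model, val_ts)
        pred = lda_fit_predict(f_train, train_ts.labels, f_val)
        fold_metrics.append(confusion_metrics(val_ts.labels, pred))
    mean_acc = float(np.mean([mm.accuracy for mm in fold_metrics]))
    return {
        "fold_metrics": fold_metrics,
        "mean_accuracy": mean_acc,
        "kappa": kappa(mean_acc),
        "confusion": np.sum([mm.confusion for mm in fold_metrics], axis=0),
    }
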