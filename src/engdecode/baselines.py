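"""Conventional motor decoders: linear SVM and MLP on windowed features.

Each 100 ms decoding sample is summarised per channel by one value per
non-overlapping 50 ms sub-window — RMS, mean power (RMS squared) or
multi-unit spike rate — concatenated channel-major into a 112-dimensional
feature vector (2 sub-windows x 56 channels).  Features are standardised
on the training fold only; folds are shared byte-identically with the
spiking decoder.
"""

from __future__ import annotations

import numpy as np
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .folds import make_folds
from .io import LabeledSegment
from .snn import DecodeResult
from .spike_maps import detect_spikes

__all__ = [
    "feature_rms",
    "feature_power",
    "feature_spike_rate",
    "build_feature_vector",
    "build_feature_matrix",
    "train_baseline",
    "FEATURE_KINDS",
    "SUBWINDOW_S",
]

FEATURE_KINDS = ("rms", "power", "spike_rate")
SUBWINDOW_S = 0.05
MLP_HIDDEN = 236  # 210% of the 112 input features


def feature_rms(window: np.ndarray) -> float:
    """Root mean square of one sub-window."""
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise ValueError("empty window")
    return float(np.sqrt(np.mean(w**2)))


def feature_power(window: np.ndarray) -> float:
    """Mean squared magnitude; equals RMS**2 exactly."""
    w = np.asarray(window, dtype=float)
    if w.size == 0:
        raise ValueError("empty window")
    return float(np.mean(w**2))


def feature_spike_rate(window: np.ndarray, fs: float, k: float = 3.5) -> float:
    """Threshold-crossing count normalised by window length (Hz)."""
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        train = detect_spikes(window, fs, k)
    return float(len(train.times) / (len(window) / fs))


def build_feature_vector(
    sample: LabeledSegment,
    kind: str = "rms",
    k: float = 3.5,
    sample_s: float = 0.1,
) -> np.ndarray:
    """2 x 50 ms features per channel, concatenated channel-major.

    Index layout: feature ``2 * channel + subwindow`` (0-based), so a
    56-channel sample yields a 112-dim vector.
    """
    if kind not in FEATURE_KINDS:
        raise ValueError(f"kind must be one of {FEATURE_KINDS}")
    n_ch, n_samp = sample.data.shape
    if abs(n_samp / sample.fs - sample_s) > 1e-6:
        raise ValueError(
            f"expected {sample_s * 1e3:.0f} ms samples, got {n_samp / sample.fs * 1e3:.1f} ms"
        )
    n_sub = int(round(sample_s / SUBWINDOW_S))
    half = n_samp // n_sub
    out = np.empty(n_ch * n_sub)
    for c in range(n_ch):
        for w in range(n_sub):
            win = sample.data[c, w * half : (w + 1) * half]
            if kind == "rms":
                out[n_sub * c + w] = feature_rms(win)
            elif kind == "power":
                out[n_sub * c + w] = feature_power(win)
            else:
                out[n_sub * c + w] = feature_spike_rate(win, sample.fs, k)
    return out


def build_feature_matrix(samples, kind: str = "rms", k: float = 3.5) -> np.ndarray:
    return np.stack([build_feature_vector(s, kind=kind, k=k) for s in samples])


def _make_model(kind: str, seed: int, epochs: int, svm_kernel: str = "linear"):
    if kind == "svm_linear":
        return make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
    if kind == "svm_rbf":  # available but excluded from headline reports
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0))
    if kind == "mlp":
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(MLP_HIDDEN,),
                max_iter=epochs,
                early_stopping=False,
                random_state=seed,
            ),
        )
    raise ValueError(f"unknown baseline {kind!r}")


def train_baseline(
    kind: str,
    features: np.ndarray,
    labels,
    n_folds: int = 5,
    seed: int = 0,
    fold_ids: np.ndarray | None = None,
    epochs: int = 500,
) -> DecodeResult:
    """Cross-validated linear-SVM or MLP decoding on feature vectors.

    Standardisation is fitted inside each training fold (sklearn
    Pipeline), so no test-fold statistics can leak into training.  Pass
    ``fold_ids`` (from :func:`engdecode.folds.make_folds`) to evaluate on
    exactly the split used by the spiking decoder.
    """
    X = np.asarray(features, dtype=float)
    names = sorted(set(labels))
    lut = {n: i for i, n in enumerate(names)}
    y = np.array([lut[l] for l in labels])
    if fold_ids is None:
        fold_ids = make_folds(y, n_folds, seed)

    n_classes = len(names)
    fold_acc, train_acc = [], []
    confusion = np.zeros((n_classes, n_classes))
    for f in range(n_folds):
        tr = fold_ids != f
        te = ~tr
        model = _make_model(kind, seed, epochs)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # MLP convergence chatter
            model.fit(X[tr], y[tr])
        yhat = model.predict(X[te])
        fold_acc.append(float(np.mean(yhat == y[te])))
        train_acc.append(float(np.mean(model.predict(X[tr]) == y[tr])))
        for yt, yp in zip(y[te], yhat):
            confusion[yt, yp] += 1
    row = confusion.sum(axis=1, keepdims=True)
    row[row == 0] = 1
    return DecodeResult(
        fold_accuracies=np.asarray(fold_acc),
        confusion=confusion / row,
        chance=1.0 / n_classes,
        classes=names,
        train_accuracies=np.asarray(train_acc),
        model_name={"svm_linear": "linear SVM", "svm_rbf": "RBF SVM", "mlp": "MLP"}[kind],
    )
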