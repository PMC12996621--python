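"""Stratified fold assignment shared by the spiking and baseline decoders.

All decoders in a comparison must be evaluated on the *same* data split;
building folds here, from (labels, n_folds, seed) only, guarantees that
byte-identical fold index arrays are reused across models.
"""

from __future__ import annotations

import numpy as np

__all__ = ["make_folds"]


def make_folds(labels: np.ndarray, n_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Per-class round-robin fold assignment after a seeded shuffle.

    Returns an integer array of fold ids (0..n_folds-1), one per sample.
    Raises if any class has fewer samples than folds.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    fold = np.full(len(labels), -1, dtype=int)
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        if len(idx) < n_folds:
            raise ValueError(
                f"class {cls!r} has {len(idx)} samples < {n_folds} folds"
            )
        idx = rng.permutation(idx)
        fold[idx] = np.arange(len(idx)) % n_folds
    assert np.all(fold >= 0)
    return fold
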