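"""Shared fixtures: small synthetic sessions reused across test modules.

Session-scoped fixtures cache the expensive full-pipeline artifacts so the
heavy end-to-end checks (decoding recovery, electrode subsets) share one
generated dataset instead of regenerating it per test.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from engdecode.pipeline import build_event_dataset
from engdecode.preprocess import preprocess_recording
from engdecode.synthetic import generate_recording, presets


@pytest.fixture(scope="session")
def acceptance_separable_datasets():
    """Seeds 1-5 of the high-SNR preset at the reduced protocol
    (6 classes x 1 block x 10 reps), double-encoded.

    Generated lazily and cached for the whole session; used by the
    pipeline-recovery and electrode-subset checks.
    """
    out = {}

    def get(seed: int):
        if seed not in out:
            cfg = replace(presets()["high-snr-separable"], blocks=1, reps=10, seed=seed)
            rec, trials, _ = generate_recording(cfg)
            filt = preprocess_recording(rec, band="eng", notch=False)
            del rec
            out[seed] = build_event_dataset(
                filt, trials, encoding="double", preprocessed=True
            )
        return out[seed]

    return get


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
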