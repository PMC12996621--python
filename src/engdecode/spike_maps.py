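"""Multi-unit spike detection, firing-rate maps and map analytics.

The modulation metric for a channel/condition pair is the z-score

    z = (mean action rate - mean rest rate) / SD(rest rate)

computed on 100 ms firing-rate bins; a channel is called *modulated*
(responsive) for a condition when z > 0.5.  On top of the per-channel
z-scores the module derives joint/direction selectivity matrices, overlap
of motor and sensory maps, the Herdin correlation-matrix distance between
neural-activation and muscle-involvement structures, and a Friedman test
for comparing firing-rate distributions across movements.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import DIRECTIONS, JOINTS, ChannelInfo, Recording, TrialTable

__all__ = [
    "SpikeTrain",
    "detect_spikes",
    "firing_rate",
    "modulation_zscore",
    "ModulationMap",
    "compute_modulation_map",
    "selectivity_maps",
    "overlap_motor_sensory",
    "herdin_distance",
    "default_muscle_matrix",
    "muscle_similarity",
    "friedman_test",
    "REGION_OF_JOINT",
]

#: anatomical region whose evoked sensations correspond to each joint
REGION_OF_JOINT = {"knee": "knee/calf", "ankle": "ankle/heel", "toes": "foot/toes"}
SENSORY_REGIONS = ("knee/calf", "ankle/heel", "foot/toes", "none")


@dataclass
class SpikeTrain:
    """Sorted multi-unit event times (s) for one channel."""

    times: np.ndarray
    channel: ChannelInfo | None = None
    threshold: float = 0.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def count(self, t0: float, t1: float) -> int:
        return int(np.searchsorted(self.times, t1) - np.searchsorted(self.times, t0))


def detect_spikes(
    x: np.ndarray,
    fs: float,
    k: float = 3.5,
    dead_time_s: float = 0.001,
    channel: ChannelInfo | None = None,
) -> SpikeTrain:
    """Threshold-crossing multi-unit spike detection on a filtered trace.

    The channel-specific threshold is ``k`` times the SD of the whole
    trace (k = 3.5 or 4 in the study, per subject).  An event is registered
    where ``|x|`` crosses the threshold from below; subsequent crossings
    within ``dead_time_s`` are suppressed.
    """
    x = np.asarray(x, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    sd = float(np.std(x))
    if sd == 0.0:
        warnings.warn("zero-SD signal: no spikes detectable")
        return SpikeTrain(np.empty(0), channel, 0.0)
    theta = k * sd
    a = np.abs(x)
    crossings = np.flatnonzero((a[1:] >= theta) & (a[:-1] < theta)) + 1
    if a[0] >= theta:
        crossings = np.concatenate(([0], crossings))
    # greedy dead-time pruning (events are sparse)
    dead = dead_time_s * fs
    kept: list[int] = []
    last = -np.inf
    for idx in crossings:
        if idx - last >= dead:
            kept.append(int(idx))
            last = idx
    return SpikeTrain(np.asarray(kept, dtype=float) / fs, channel, theta)


def firing_rate(
    train: SpikeTrain | np.ndarray,
    t0: float,
    t1: float,
    bin_width: float = 0.1,
) -> np.ndarray:
    """Firing rate (Hz) in non-overlapping half-open bins of ``bin_width``.

    An event exactly on a bin boundary counts in the right-hand bin.
    Covers ``floor((t1 - t0)/bin_width)`` bins starting at ``t0``.
    """
    if t1 <= t0:
        raise ValueError("need t1 > t0")
    times = train.times if isinstance(train, SpikeTrain) else np.asarray(train, float)
    n_bins = int(np.floor((t1 - t0) / bin_width + 1e-9))
    edges = t0 + bin_width * np.arange(n_bins + 1)
    counts = np.diff(np.searchsorted(times, edges))
    return counts / bin_width


def modulation_zscore(action_rates, rest_rates) -> float:
    """Modulation z-score of action vs rest firing rates.

    ``(mean(action) - mean(rest)) / sd(rest)``; significant when > 0.5.
    A zero rest SD is degenerate: returns +inf if the action mean exceeds
    the rest mean, else 0, with a warning.
    """
    a = np.asarray(action_rates, dtype=float)
    r = np.asarray(rest_rates, dtype=float)
    if a.size == 0 or r.size == 0:
        raise ValueError("action and rest rate lists must be non-empty")
    sd = float(np.std(r))
    if sd == 0.0:
        warnings.warn("rest-rate SD is zero; z-score undefined (sentinel returned)")
        return float(np.inf) if a.mean() > r.mean() else 0.0
    return float((a.mean() - r.mean()) / sd)


@dataclass
class ModulationMap:
    """Per channel x condition modulation z-scores and significance flags.

    ``conditions`` are (joint, direction) pairs; ``z`` has shape
    (n_channels, n_conditions).  ``significant`` is ``z > z_threshold``.
    """

    z: np.ndarray
    conditions: list[tuple[str, str]]
    channels: list[ChannelInfo]
    mean_action_hz: np.ndarray
    mean_rest_hz: np.ndarray
    sd_rest_hz: np.ndarray
    z_threshold: float = 0.5

    @property
    def significant(self) -> np.ndarray:
        return self.z > self.z_threshold

    def condition_index(self, joint: str, direction: str) -> int:
        return self.conditions.index((joint, direction))

    def significant_channels(self, joint: str, direction: str | None = None) -> set[int]:
        """Channels significant for a joint (either direction unless given)."""
        sig = self.significant
        if direction is not None:
            return set(np.flatnonzero(sig[:, self.condition_index(joint, direction)]))
        cols = [i for i, (j, _) in enumerate(self.conditions) if j == joint]
        return set(np.flatnonzero(sig[:, cols].any(axis=1)))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ci, ch in enumerate(self.channels):
            for ki, (joint, direction) in enumerate(self.conditions):
                rows.append(
                    {
                        "channel": ch.name,
                        "joint": joint,
                        "direction": direction,
                        "z": self.z[ci, ki],
                        "significant": bool(self.significant[ci, ki]),
                        "mean_action_hz": self.mean_action_hz[ci, ki],
                        "mean_rest_hz": self.mean_rest_hz[ci, ki],
                        "sd_rest_hz": self.sd_rest_hz[ci, ki],
                    }
                )
        return pd.DataFrame(rows)


def compute_modulation_map(
    recording: Recording,
    trials: TrialTable,
    k: float = 3.5,
    bin_width: float = 0.1,
    dead_time_s: float = 0.001,
    z_threshold: float = 0.5,
    trains: list[SpikeTrain] | None = None,
) -> ModulationMap:
    """Detect spikes on every channel and z-score each (joint, direction).

    Action rates come from the direction's 1 s phase windows of every trial
    of the matching joint; rest rates from the pooled 2 s rest windows of
    all trials.  Pre-computed ``trains`` may be passed to skip detection.
    """
    if trains is None:
        trains = [
            detect_spikes(recording.data[i], recording.fs, k, dead_time_s,
                          recording.channels[i])
            for i in range(recording.n_channels)
        ]
    joints = [j for j in JOINTS if j in set(trials.df["joint"])]
    conditions = [(j, d) for j in joints for d in DIRECTIONS]
    n_ch, n_cond = len(trains), len(conditions)
    z = np.zeros((n_ch, n_cond))
    ma = np.zeros((n_ch, n_cond))
    mr = np.zeros((n_ch, n_cond))
    sr = np.zeros((n_ch, n_cond))

    rest_windows = trials.windows("rest")[["t0", "t1"]].to_numpy()
    phase_windows = {
        (j, d): trials.windows(d).query("joint == @j")[["t0", "t1"]].to_numpy()
        for (j, d) in conditions
    }
    for ci, train in enumerate(trains):
        rest = np.concatenate(
            [firing_rate(train, t0, t1, bin_width) for t0, t1 in rest_windows]
        )
        for ki, cond in enumerate(conditions):
            act = np.concatenate(
                [firing_rate(train, t0, t1, bin_width) for t0, t1 in phase_windows[cond]]
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                z[ci, ki] = modulation_zscore(act, rest)
            ma[ci, ki] = act.mean()
            mr[ci, ki] = rest.mean()
            sr[ci, ki] = rest.std()
    return ModulationMap(z, conditions, list(recording.channels), ma, mr, sr, z_threshold)


# ---------------------------------------------------------------------------
# selectivity / overlap matrices

SELECTIVITY_CATEGORIES = ("flexion_only", "extension_only", "both", "silent")


def selectivity_maps(mod: ModulationMap) -> dict:
    """Partition channels by direction selectivity per joint.

    Returns ``{"per_joint": DataFrame of percentages, "per_channel":
    DataFrame of joint-selectivity categories}``.  For every joint the four
    percentages (flexion-only / extension-only / both / silent) are over
    the full channel set and sum to 100.
    """
    joints = sorted({j for j, _ in mod.conditions}, key=JOINTS.index)
    n_ch = len(mod.channels)
    per_joint = []
    for j in joints:
        fl = mod.significant[:, mod.condition_index(j, "flexion")]
        ex = mod.significant[:, mod.condition_index(j, "extension")]
        cat_counts = {
            "flexion_only": int(np.sum(fl & ~ex)),
            "extension_only": int(np.sum(ex & ~fl)),
            "both": int(np.sum(fl & ex)),
            "silent": int(np.sum(~fl & ~ex)),
        }
        per_joint.append(
            {"joint": j, **{c: 100.0 * n / n_ch for c, n in cat_counts.items()}}
        )
    per_channel = []
    for ci, ch in enumerate(mod.channels):
        sig_joints = [j for j in joints if ci in mod.significant_channels(j)]
        category = (
            "silent" if not sig_joints
            else "single_joint" if len(sig_joints) == 1
            else "multi_joint"
        )
        per_channel.append(
            {"channel": ch.name, "joints": sig_joints, "category": category}
        )
    return {
        "per_joint": pd.DataFrame(per_joint),
        "per_channel": pd.DataFrame(per_channel),
    }


def overlap_motor_sensory(
    mod: ModulationMap,
    sensory_labels: list[str] | np.ndarray,
    region_of_joint: dict[str, str] = REGION_OF_JOINT,
) -> pd.DataFrame:
    """Motor/sensory overlap per anatomical region.

    ``sensory_labels`` gives the electrically evoked sensation region per
    channel.  For each region the channels split into motor-only,
    sensory-only, both, neither (percentages over all channels, sum 100).
    """
    labels = list(sensory_labels)
    if len(labels) != len(mod.channels):
        raise ValueError("one sensory label per channel required")
    n_ch = len(labels)
    rows = []
    for joint, region in region_of_joint.items():
        if joint not in {j for j, _ in mod.conditions}:
            continue
        motor = mod.significant_channels(joint)
        sensory = {i for i, lab in enumerate(labels) if lab == region}
        both = motor & sensory
        rows.append(
            {
                "region": region,
                "joint": joint,
                "motor_only": 100.0 * len(motor - sensory) / n_ch,
                "sensory_only": 100.0 * len(sensory - motor) / n_ch,
                "both": 100.0 * len(both) / n_ch,
                "neither": 100.0 * (n_ch - len(motor | sensory)) / n_ch,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Herdin correlation-matrix distance and muscle-involvement comparison


def herdin_distance(R1: np.ndarray, R2: np.ndarray) -> float:
    """Scale-invariant distance between two correlation matrices.

    ``d = 1 - tr(R1 R2) / (||R1||_F ||R2||_F)`` in [0, 1]: zero when the
    matrices are equal up to scaling, one when maximally different
    (trace-orthogonal).
    """
    R1 = np.asarray(R1, dtype=float)
    R2 = np.asarray(R2, dtype=float)
    if R1.shape != R2.shape or R1.ndim != 2 or R1.shape[0] != R1.shape[1]:
        raise ValueError("R1 and R2 must be square matrices of equal shape")
    n1, n2 = np.linalg.norm(R1, "fro"), np.linalg.norm(R2, "fro")
    if n1 == 0 or n2 == 0:
        raise ValueError("zero-norm matrix has no defined direction")
    d = 1.0 - np.trace(R1 @ R2) / (n1 * n2)
    return float(np.clip(d, 0.0, 1.0))


#: Below-knee muscles innervated by the sciatic nerve or its branches, with
#: binary involvement in each movement class.  Package default reference
#: table (anatomy-based; 7 flexor-side, 4 extensor-side muscles).  Users can
#: supply their own table as a muscles x movements 0/1 DataFrame.
_DEFAULT_MUSCLES = {
    #                        knee_f k_e ankle_f a_e toes_f t_e
    "gastrocnemius_medial":   (1, 0, 1, 0, 0, 0),
    "gastrocnemius_lateral":  (1, 0, 1, 0, 0, 0),
    "soleus":                 (0, 0, 1, 0, 0, 0),
    "plantaris":              (1, 0, 1, 0, 0, 0),
    "tibialis_posterior":     (0, 0, 1, 0, 0, 0),
    "flexor_digitorum_longus": (0, 0, 1, 0, 1, 0),
    "flexor_hallucis_longus": (0, 0, 1, 0, 1, 0),
    "tibialis_anterior":      (0, 0, 0, 1, 0, 0),
    "extensor_digitorum_longus": (0, 0, 0, 1, 0, 1),
    "extensor_hallucis_longus": (0, 0, 0, 1, 0, 1),
    "peroneus_tertius":       (0, 0, 0, 1, 0, 0),
}
_MOVEMENT_COLUMNS = [
    "knee_flexion", "knee_extension", "ankle_flexion",
    "ankle_extension", "toes_flexion", "toes_extension",
]
#: flexion-side movements use the 7 flexor muscles, extension-side the 4
#: extensor muscles (dorsiflexors/toe extensors).
FLEXOR_MUSCLES = [
    "gastrocnemius_medial", "gastrocnemius_lateral", "soleus", "plantaris",
    "tibialis_posterior", "flexor_digitorum_longus", "flexor_hallucis_longus",
]
EXTENSOR_MUSCLES = [
    "tibialis_anterior", "extensor_digitorum_longus",
    "extensor_hallucis_longus", "peroneus_tertius",
]


def default_muscle_matrix() -> pd.DataFrame:
    """Binary muscles x movements involvement matrix (package default)."""
    return pd.DataFrame.from_dict(
        _DEFAULT_MUSCLES, orient="index", columns=_MOVEMENT_COLUMNS
    )


def _set_overlap_matrix(sets: list[set]) -> np.ndarray:
    """Symmetric Jaccard-overlap matrix of a list of member sets."""
    n = len(sets)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            union = sets[i] | sets[j]
            M[i, j] = len(sets[i] & sets[j]) / len(union) if union else 0.0
    return M


def muscle_similarity(
    mod: ModulationMap,
    muscles: pd.DataFrame | None = None,
    direction: str = "flexion",
    joints: tuple[str, ...] = JOINTS,
) -> float:
    """Herdin distance between neural-activation and muscle-involvement maps.

    Per joint, the neural set is the channels significantly modulated in
    the given direction; the muscle set is the muscles involved in that
    joint's movement (restricted to the direction's muscle group).  Both
    set families become symmetric Jaccard-overlap matrices compared by
    :func:`herdin_distance`.
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be in {DIRECTIONS}")
    muscles = default_muscle_matrix() if muscles is None else muscles
    group = FLEXOR_MUSCLES if direction == "flexion" else EXTENSOR_MUSCLES
    group = [m for m in group if m in muscles.index]

    neural_sets, muscle_sets = [], []
    for joint in joints:
        chans = mod.significant_channels(joint, direction)
        if not chans:
            raise ValueError(f"no significantly modulated channel for joint {joint!r}")
        neural_sets.append(chans)
        col = f"{joint}_{direction}"
        if col not in muscles.columns:
            raise ValueError(f"muscle matrix lacks movement column {col!r}")
        muscle_sets.append(
            {m for m in group if muscles.loc[m, col] > 0}
        )
    return herdin_distance(
        _set_overlap_matrix(neural_sets), _set_overlap_matrix(muscle_sets)
    )


def friedman_test(samples: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square test for repeated measures.

    ``samples`` is subjects x groups (e.g. 56 channels x movement classes).
    Nonparametric alternative to repeated-measures ANOVA; within-subject
    mid-ranks.  Returns (statistic, asymptotic p-value).
    """
    X = np.asarray(samples, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a 2-D subjects x groups table, >= 2 each")
    if not np.all(np.isfinite(X)):
        raise ValueError("missing/non-finite value in repeated-measures table")
    if np.allclose(X, X[:, [0]]):
        # identical columns: no evidence against the null
        return 0.0, 1.0
    stat, p = stats.friedmanchisquare(*[X[:, j] for j in range(X.shape[1])])
    return float(stat), float(p)
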