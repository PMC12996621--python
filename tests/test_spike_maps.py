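"""Spike detection, rate maps, modulation z-scores and map analytics."""

import numpy as np
import pandas as pd
import pytest

from engdecode.spike_maps import (
    ModulationMap,
    SpikeTrain,
    default_muscle_matrix,
    detect_spikes,
    firing_rate,
    friedman_test,
    herdin_distance,
    modulation_zscore,
    muscle_similarity,
    overlap_motor_sensory,
    selectivity_maps,
    _set_overlap_matrix,
)
from engdecode.io import default_channel_layout

FS = 30000.0


class TestDetection:
    def test_zero_signal_no_events(self):
        with pytest.warns(UserWarning):
            train = detect_spikes(np.zeros(1000), FS)
        assert len(train.times) == 0

    def test_injected_transients_recovered(self, rng):
        """>= 19/20 injected 6-SD biphasic transients found within 1 ms,
        false positives near the Gaussian-tail crossing rate."""
        n = int(10 * FS)
        x = rng.standard_normal(n)
        true_t = (np.arange(20) + 0.5) * 0.5  # every 0.5 s
        tpl = np.concatenate([np.ones(9), -np.ones(21)]) * 6.0  # 1 ms biphasic
        for t in true_t:
            i = int(t * FS)
            x[i : i + 30] += tpl
        train = detect_spikes(x, FS, k=3.5)
        hits = sum(np.min(np.abs(train.times - t)) < 1e-3 for t in true_t)
        assert hits >= 19
        # Gaussian tail: P(|x|>3.5 sd) ~ 4.7e-4 per sample; with 1 ms dead
        # time the false rate is bounded well below 1000/s
        n_false = len(train.times) - hits
        from scipy.stats import norm

        tail_rate = 2 * norm.sf(3.5) * FS  # crossings/s upper bound
        assert n_false < 3 * tail_rate * 10

    def test_dead_time_enforced(self):
        x = np.zeros(3000)
        x[100:110] = 10.0
        x[115:125] = 10.0  # within 1 ms of the first
        x[200:210] = 10.0  # > 1 ms later
        train = detect_spikes(x, FS, k=3.5, dead_time_s=0.001)
        assert len(train.times) == 2

    def test_k_configurable_per_subject(self, rng):
        x = rng.standard_normal(30000)
        t35 = detect_spikes(x, FS, k=3.5)
        t40 = detect_spikes(x, FS, k=4.0)
        assert t40.threshold > t35.threshold
        assert len(t40.times) <= len(t35.times)


class TestFiringRate:
    def test_uniform_events_give_flat_rate(self):
        times = 0.05 + 0.1 * np.arange(10)
        assert np.allclose(firing_rate(times, 0.0, 1.0, 0.1), 10.0)

    def test_empty_train_zero_row(self):
        assert np.allclose(firing_rate(np.empty(0), 0.0, 1.0, 0.1), 0.0)

    def test_boundary_event_counts_right(self):
        rates = firing_rate(np.array([0.2]), 0.0, 0.4, 0.1)
        assert rates.tolist() == [0.0, 0.0, 10.0, 0.0]

    def test_count_conservation(self, rng):
        times = np.sort(rng.uniform(0, 3.0, size=200))
        train = SpikeTrain(np.unique(times))
        rates = firing_rate(train, 0.5, 2.5, 0.1)
        assert rates.sum() * 0.1 == train.count(0.5, 2.5)


class TestZScore:
    def test_equal_means_zero(self):
        z = modulation_zscore([10, 12, 8], [10, 12, 8])
        assert z == pytest.approx(0.0)

    def test_arithmetic(self):
        # mu_a=15, mu_r=10, sd_r=5 -> z=1
        rest = [5.0, 15.0]  # mean 10, population SD 5
        assert modulation_zscore([15.0, 15.0], rest) == pytest.approx(1.0)

    def test_zero_rest_sd_sentinels(self):
        with pytest.warns(UserWarning):
            assert modulation_zscore([5.0], [1.0, 1.0]) == np.inf
        with pytest.warns(UserWarning):
            assert modulation_zscore([0.0], [1.0, 1.0]) == 0.0

    def test_label_shuffle_null(self, rng):
        """Shuffling action/rest labels drives the mean z to ~0."""
        zs = []
        for _ in range(200):
            pool = rng.poisson(10, size=40).astype(float)
            rng.shuffle(pool)
            zs.append(modulation_zscore(pool[:20], pool[20:]))
        assert abs(np.mean(zs)) < 0.1

    def test_uniform_rate_increase_raises_z(self, rng):
        rest = rng.poisson(10, size=30).astype(float)
        action = rest.copy()
        z0 = modulation_zscore(action, rest)
        z1 = modulation_zscore(action + 5.0, rest)
        assert z1 > z0


def _map_from_z(z, conditions=None):
    n_ch, n_cond = z.shape
    conditions = conditions or [
        (j, d) for j in ("knee", "ankle", "toes") for d in ("flexion", "extension")
    ]
    shape = z.shape
    return ModulationMap(
        z=z,
        conditions=conditions,
        channels=default_channel_layout(n_ch),
        mean_action_hz=np.zeros(shape),
        mean_rest_hz=np.zeros(shape),
        sd_rest_hz=np.ones(shape),
    )


class TestSelectivity:
    def test_all_silent(self):
        sel = selectivity_maps(_map_from_z(np.zeros((56, 6))))
        assert (sel["per_joint"]["silent"] == 100.0).all()

    def test_quarter_flexion_only(self):
        z = np.zeros((56, 6))
        z[:14, 0] = 1.0  # 14 channels, knee flexion only
        sel = selectivity_maps(_map_from_z(z))
        knee = sel["per_joint"].set_index("joint").loc["knee"]
        assert knee["flexion_only"] == pytest.approx(25.0)
        assert knee["silent"] == pytest.approx(75.0)

    def test_random_map_matches_bruteforce(self, rng):
        z = rng.normal(0, 1, size=(56, 6))
        mod = _map_from_z(z)
        sel = selectivity_maps(mod)
        sig = z > 0.5
        for ji, joint in enumerate(("knee", "ankle", "toes")):
            fl, ex = sig[:, 2 * ji], sig[:, 2 * ji + 1]
            row = sel["per_joint"].set_index("joint").loc[joint]
            assert row["flexion_only"] == pytest.approx(100 * np.mean(fl & ~ex))
            assert row["extension_only"] == pytest.approx(100 * np.mean(~fl & ex))
            assert row["both"] == pytest.approx(100 * np.mean(fl & ex))
            # partition property
            assert row[list(("flexion_only", "extension_only", "both", "silent"))].sum() == pytest.approx(100.0)


class TestOverlap:
    def test_disjoint_sets_no_both(self):
        z = np.zeros((56, 6))
        z[:5, 0] = 1.0  # motor knee: channels 0-4
        labels = ["none"] * 56
        for i in range(5, 10):
            labels[i] = "knee/calf"
        table = overlap_motor_sensory(_map_from_z(z), labels)
        knee = table.set_index("joint").loc["knee"]
        assert knee["both"] == 0.0

    def test_identical_sets_both_fraction(self):
        z = np.zeros((56, 6))
        z[:7, 2] = 1.0  # ankle motor channels 0-6
        labels = ["ankle/heel" if i < 7 else "none" for i in range(56)]
        table = overlap_motor_sensory(_map_from_z(z), labels)
        ankle = table.set_index("joint").loc["ankle"]
        assert ankle["both"] == pytest.approx(100 * 7 / 56)
        assert ankle["motor_only"] == 0.0

    def test_rows_partition_to_100(self, rng):
        z = rng.normal(0, 1, size=(56, 6))
        labels = rng.choice(
            ["knee/calf", "ankle/heel", "foot/toes", "none"], size=56
        ).tolist()
        table = overlap_motor_sensory(_map_from_z(z), labels)
        sums = table[["motor_only", "sensory_only", "both", "neither"]].sum(axis=1)
        assert np.allclose(sums, 100.0)


class TestHerdin:
    def test_scaled_matrices_distance_zero(self, rng):
        R = rng.normal(size=(4, 4))
        R = R @ R.T
        assert herdin_distance(R, 3.0 * R) == pytest.approx(0.0, abs=1e-12)

    def test_trace_orthogonal_distance_one(self):
        assert herdin_distance(np.diag([1.0, 0.0]), np.diag([0.0, 1.0])) == 1.0

    def test_matches_direct_formula(self, rng):
        for _ in range(20):
            A = rng.normal(size=(5, 5)); A = (A + A.T) / 2
            B = rng.normal(size=(5, 5)); B = (B + B.T) / 2
            direct = 1 - np.sum(A * B.T) / (
                np.sqrt(np.sum(A * A)) * np.sqrt(np.sum(B * B))
            )
            assert herdin_distance(A, B) == pytest.approx(
                np.clip(direct, 0, 1), abs=1e-12
            )

    def test_symmetry_and_scale_invariance(self, rng):
        A = rng.normal(size=(4, 4)); A = A @ A.T
        B = rng.normal(size=(4, 4)); B = B @ B.T
        assert herdin_distance(A, B) == pytest.approx(herdin_distance(B, A))
        assert herdin_distance(2.5 * A, 0.3 * B) == pytest.approx(
            herdin_distance(A, B), abs=1e-12
        )

    def test_zero_norm_errors(self):
        with pytest.raises(ValueError):
            herdin_distance(np.zeros((3, 3)), np.eye(3))


class TestMuscleSimilarity:
    def test_identical_structures_zero(self):
        z = np.zeros((56, 6))
        # neural sets: disjoint 7/7/7 channels per joint (flexion)
        z[0:7, 0] = 1.0
        z[7:14, 2] = 1.0
        z[14:21, 4] = 1.0
        mod = _map_from_z(z)
        # muscle matrix with the same overlap structure: disjoint sets
        muscles = pd.DataFrame(
            0,
            index=[f"m{i}" for i in range(9)],
            columns=[
                "knee_flexion", "knee_extension", "ankle_flexion",
                "ankle_extension", "toes_flexion", "toes_extension",
            ],
        )
        muscles.iloc[0:3, 0] = 1
        muscles.iloc[3:6, 2] = 1
        muscles.iloc[6:9, 4] = 1
        import engdecode.spike_maps as sm

        old = sm.FLEXOR_MUSCLES
        sm.FLEXOR_MUSCLES = list(muscles.index)
        try:
            d = muscle_similarity(mod, muscles, direction="flexion")
        finally:
            sm.FLEXOR_MUSCLES = old
        # disjoint sets on both sides -> identity overlap matrices -> d = 0
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_toy_hand_computation(self):
        """3-joint example with known intersections equals the hand result."""
        sets_n = [{0, 1}, {1, 2}, {3}]
        sets_m = [{0}, {0, 1}, {2}]
        Mn = _set_overlap_matrix(sets_n)
        Mm = _set_overlap_matrix(sets_m)
        # hand-computed Jaccard matrices
        assert Mn[0, 1] == pytest.approx(1 / 3)
        assert Mm[0, 1] == pytest.approx(1 / 2)
        d_hand = 1 - np.trace(Mn @ Mm) / (
            np.linalg.norm(Mn) * np.linalg.norm(Mm)
        )
        assert herdin_distance(Mn, Mm) == pytest.approx(np.clip(d_hand, 0, 1))

    def test_direction_selects_muscle_group(self):
        m = default_muscle_matrix()
        from engdecode.spike_maps import EXTENSOR_MUSCLES, FLEXOR_MUSCLES

        assert len(FLEXOR_MUSCLES) == 7
        assert len(EXTENSOR_MUSCLES) == 4
        assert set(FLEXOR_MUSCLES) | set(EXTENSOR_MUSCLES) == set(m.index)

    def test_empty_joint_errors(self):
        mod = _map_from_z(np.zeros((56, 6)))
        with pytest.raises(ValueError, match="knee"):
            muscle_similarity(mod, direction="flexion")


class TestFriedman:
    def test_identical_columns_null(self):
        X = np.tile(np.arange(5.0)[:, None], (1, 3))
        stat, p = friedman_test(X)
        assert stat == 0.0 and p == 1.0

    def test_matches_hand_rank_computation(self):
        """Chi-square from hand-computed within-subject ranks."""
        X = np.array(
            [[1.0, 2.0, 3.0],
             [2.0, 3.0, 1.0],
             [1.0, 3.0, 2.0],
             [1.0, 2.0, 3.0],
             [2.0, 1.0, 3.0]]
        )
        n, k = X.shape
        ranks = np.array([np.argsort(np.argsort(row)) + 1 for row in X])
        Rj = ranks.sum(axis=0)
        stat_hand = 12.0 / (n * k * (k + 1)) * np.sum(Rj**2) - 3 * n * (k + 1)
        stat, p = friedman_test(X)
        assert stat == pytest.approx(stat_hand)
        assert 0 <= p <= 1

    def test_missing_value_errors(self):
        X = np.ones((4, 3))
        X[2, 1] = np.nan
        with pytest.raises(ValueError):
            friedman_test(X)

    def test_channels_as_subjects_shape(self, rng):
        # 56 channels x 3 movement-rate distributions
        X = rng.poisson(10, size=(56, 3)).astype(float) + rng.normal(0, 0.01, (56, 3))
        stat, p = friedman_test(X)
        assert np.isfinite(stat) and 0 <= p <= 1
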