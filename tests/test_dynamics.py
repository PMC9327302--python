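"""Transport-mode classification, D1 estimation and search statistics."""

import numpy as np
import pytest

from plectosearch.dynamics import (
    ModeThresholds,
    classify_frames,
    count_unique_intersegmental,
    mode_propensities,
    msd_d1,
    residence_time,
    rotation_coupling,
    scanned_fraction_by_transfer,
)
from plectosearch.walker import ProteinDNATrajectory, generate_labeled_walk


def _make_traj(R, bp, xyz=None, theta=None, z=None, n_bp=336):
    T = len(R)
    bp = np.asarray(bp, dtype=np.int64)
    return ProteinDNATrajectory(
        R=np.asarray(R, float), bp_index=bp,
        z=np.asarray(z if z is not None else bp * 3.34, float),
        theta=np.asarray(theta if theta is not None else np.zeros(T), float),
        xyz=np.asarray(xyz if xyz is not None else np.zeros((T, 3)), float),
        n_bp=n_bp)


class TestClassifier:
    def test_tight_contact_slow_advance_is_sliding(self):
        T = 200
        traj = _make_traj(np.full(T, 5.0), 1 + (np.arange(T) % 336))
        assert set(classify_frames(traj)) == {"sliding"}

    def test_every_frame_gets_exactly_one_label(self):
        w = generate_labeled_walk(
            5000, mode_rates={"hopping": 0.05, "diffusion3d": 0.02},
            d1_true=0.5, seed=0)
        labels = classify_frames(w)
        assert len(labels) == len(w)
        assert sum(mode_propensities(labels).values()) == pytest.approx(1.0)

    def test_recall_against_truth_labels(self):
        w = generate_labeled_walk(
            30_000, mode_rates={"hopping": 0.02, "diffusion3d": 0.01,
                                "intersegmental": 0.005},
            jp_positions=[(84, 252)], d1_true=0.5, seed=3)
        labels = classify_frames(w)
        for mode in ("sliding", "hopping", "diffusion3d", "intersegmental"):
            truth = w.truth_labels == mode
            assert truth.sum() > 0
            recall = float(np.mean(labels[truth] == mode))
            assert recall >= 0.9, f"{mode} recall {recall:.3f}"

    def test_programmed_jumps_detected_at_exact_frames(self):
        # hand-built trace: bound at bp 100, jumps across a 150-bp pair at
        # frames 50 and 120, spatially short
        T = 200
        bp = np.full(T, 100)
        bp[50:120] = 250
        bp[120:] = 100
        traj = _make_traj(np.full(T, 5.0), bp)
        labels = classify_frames(traj)
        assert set(np.where(labels == "intersegmental")[0]) == {50, 120}


class TestMsdD1:
    def test_ballistic_drift_flagged(self):
        T = 2000
        traj = _make_traj(np.full(T, 5.0), 1 + (np.arange(T) % 336))
        est = msd_d1(traj)
        assert est.ballistic

    def test_unbiased_walk_recovers_known_d(self):
        rng = np.random.default_rng(11)
        steps = rng.choice([-1, 1], size=20_000)
        bp = 1 + (168 + np.concatenate([[0], np.cumsum(steps)])) % 336
        traj = _make_traj(np.full(bp.size, 5.0), bp)
        est = msd_d1(traj)
        assert est.d1 == pytest.approx(0.5, rel=0.10)
        assert not est.ballistic

    def test_two_state_sliding_decomposition(self):
        # slow/fast diffusivity ratio 100, recovered per state within 15%
        w = generate_labeled_walk(60_000, d1_true=0.5,
                                  fast_slow=(0.5, 50.0, 0.005), seed=5)
        pooled = msd_d1(w, w.truth_labels)
        slow = msd_d1(w, w.truth_states, include=("slow",))
        fast = msd_d1(w, w.truth_states, include=("fast",))
        assert slow.d1 == pytest.approx(0.5, rel=0.15)
        assert fast.d1 == pytest.approx(50.0, rel=0.15)
        assert slow.d1 < pooled.d1 < fast.d1

    def test_transfer_excision_prevents_jump_inflation(self):
        # identical sliding walks, one with periodic 150-bp transfers:
        # excision keeps D1 close to the no-transfer value
        rng = np.random.default_rng(12)
        steps = rng.choice([-1, 1], size=10_000).astype(float)
        base = 100 + np.concatenate([[0], np.cumsum(steps)])
        bp_plain = 1 + (base % 336).astype(int)
        traj = _make_traj(np.full(bp_plain.size, 5.0), bp_plain)
        d_plain = msd_d1(traj).d1

        bp_jumpy = bp_plain.copy()
        offset = np.zeros_like(bp_jumpy)
        for k in range(500, bp_jumpy.size, 500):
            offset[k:] += 150
        bp_jumpy = 1 + ((bp_jumpy - 1 + offset) % 336)
        traj_j = _make_traj(np.full(bp_jumpy.size, 5.0), bp_jumpy)
        labels = classify_frames(traj_j)
        d_excised = msd_d1(traj_j, labels).d1
        assert d_excised == pytest.approx(d_plain, rel=0.15)

    def test_refuses_too_few_frames(self):
        traj = _make_traj(np.full(100, 5.0), np.full(100, 10))
        with pytest.raises(ValueError):
            msd_d1(traj)


class TestRotationCoupling:
    def test_perfect_coupling(self):
        w = generate_labeled_walk(5000, d1_true=0.5, groove_coupling=1.0,
                                  seed=6)
        assert rotation_coupling(w, w.truth_labels) >= 0.99

    def test_uncoupled_rotation_uncorrelated(self):
        w = generate_labeled_walk(20_000, d1_true=0.5, groove_coupling=0.0,
                                  theta_noise=0.3, seed=7)
        assert abs(rotation_coupling(w, w.truth_labels)) <= 0.05

    def test_partial_coupling_matches_attenuation_formula(self):
        # with coupled increment k*ds (k = 2*pi/10.5) plus Gaussian noise
        # of sd sigma_n, the Pearson correlation is
        # r = 1 / sqrt(1 + sigma_n^2 / (k^2 * sigma_ds^2))
        d1, target_r = 0.5, 0.9
        k = 2 * np.pi / 10.5
        sigma_ds = np.sqrt(2 * d1)
        sigma_n = k * sigma_ds * np.sqrt(1 / target_r ** 2 - 1)
        w = generate_labeled_walk(40_000, d1_true=d1, groove_coupling=1.0,
                                  theta_noise=sigma_n, seed=8)
        assert rotation_coupling(w, w.truth_labels) == pytest.approx(
            target_r, abs=0.03)

    def test_refuses_too_few_sliding_frames(self):
        w = generate_labeled_walk(50, d1_true=0.5, seed=9)
        with pytest.raises(ValueError):
            rotation_coupling(w, w.truth_labels)


class TestTransferBookkeeping:
    def test_no_events_counts_zero(self):
        labels = np.array(["sliding"] * 100, dtype=object)
        assert count_unique_intersegmental(labels, np.full(100, 10)) == 0

    def test_distinct_jumps_counted_once_each(self):
        T = 12
        labels = np.array(["sliding"] * T, dtype=object)
        bp = np.full(T, 10)
        pairs = [(10, 170), (30, 200), (50, 220), (70, 240), (90, 260)]
        for k, (a, b) in enumerate(pairs):
            t = 2 * k + 1
            bp[t - 1] = a
            bp[t] = b
            labels[t] = "intersegmental"
        assert count_unique_intersegmental(labels, bp) == 5

    def test_repeated_jump_counts_once(self):
        T = 100
        labels = np.array(["sliding"] * T, dtype=object)
        bp = np.full(T, 10)
        for t in range(1, T, 2):
            bp[t] = 170
            labels[t] = "intersegmental"
        assert count_unique_intersegmental(labels, bp) == 1

    def test_scanned_fraction_constructed_ledger(self):
        # 100 unique bp scanned before the jump, a fresh 100-bp run after:
        # half of all unique visits are transfer-opened
        bp = np.concatenate([np.arange(1, 101),
                             np.arange(201, 301)])
        labels = np.array(["sliding"] * 200, dtype=object)
        labels[100] = "intersegmental"
        assert scanned_fraction_by_transfer(labels, bp) == pytest.approx(0.5)

    def test_scanned_fraction_edges(self):
        labels = np.array(["sliding"] * 50, dtype=object)
        assert scanned_fraction_by_transfer(labels, np.arange(1, 51)) == 0.0
        labels_all = np.array(["intersegmental"] * 50, dtype=object)
        assert scanned_fraction_by_transfer(labels_all,
                                            np.arange(1, 51)) == 1.0


class TestResidence:
    def test_pinned_walker(self):
        traj = _make_traj(np.full(100, 5.0), np.full(100, 10))
        counts, dwell = residence_time(traj)
        assert counts[9] == 100
        assert counts.sum() == 100
        assert dwell == 100.0

    def test_uniform_scanning_is_flat_within_noise(self):
        rng = np.random.default_rng(13)
        bp = rng.integers(1, 337, size=200_000)
        traj = _make_traj(np.full(bp.size, 5.0), bp)
        counts, _ = residence_time(traj)
        expected = bp.size / 336
        assert counts.min() > 0
        # 5-sigma Poisson band over 336 bins
        assert np.abs(counts - expected).max() < 5 * np.sqrt(expected)

    def test_dwell_anti_ordered_with_diffusivity(self):
        def walk(d1, seed):
            w = generate_labeled_walk(20_000, d1_true=d1, seed=seed)
            return residence_time(w)[1]
        assert walk(1.0, 14) < walk(0.05, 15)
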