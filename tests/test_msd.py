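import numpy as np
import pytest

import memdiff as m
from conftest import brute_force_msd


def test_stationary_trajectory_has_zero_msd():
    pos = np.zeros((10, 2))
    curve = m.msd_single(pos, 0.002)
    assert np.all(curve.msd == 0)
    assert np.array_equal(curve.pair_counts, np.arange(9, 0, -1))


def test_uniform_motion_closed_form():
    pos = np.column_stack([0.1 * np.arange(10), np.zeros(10)])
    curve = m.msd_single(pos, 0.002, n_max=3)
    assert curve.msd[2] == pytest.approx(0.09, rel=1e-12)


def test_staircase_enumeration_example():
    pos = np.array([[0, 0], [1, 0], [1, 1], [2, 1], [2, 2]], dtype=float)
    curve = m.msd_single(pos, 1.0, n_max=2)
    # each 2-step displacement is (1,1): three i-terms, all equal to 2
    assert curve.msd[1] == pytest.approx(2.0, rel=1e-12)
    assert curve.pair_counts[1] == 3


def test_msd_matches_bruteforce_double_loop(rng):
    for _ in range(20):
        N = rng.integers(5, 50)
        pos = rng.normal(size=(N, 2))
        curve = m.msd_single(pos, 0.01, n_max=N - 1)
        taus, msd, counts = brute_force_msd(pos, 0.01, N - 1)
        np.testing.assert_allclose(curve.msd, msd, rtol=1e-12)
        np.testing.assert_array_equal(curve.pair_counts, counts)


def test_pooled_hand_computed_ratio():
    a = np.zeros((5, 2))  # 4 zero pairs at lag 1
    b = np.array([[0, 0], [1, 0], [2, 0]], dtype=float)  # 2 pairs of 1 µm²
    curve = m.pooled_msd([a, b], 1.0, n_max=1)
    assert curve.msd[0] == pytest.approx((0 * 4 + 1 * 2) / 6, rel=1e-12)
    assert curve.pair_counts[0] == 6


def test_pooled_single_trajectory_reduces_to_msd_single(rng):
    pos = rng.normal(size=(30, 2))
    single = m.msd_single(pos, 0.002, n_max=10)
    pooled = m.pooled_msd([pos], 0.002, n_max=10)
    np.testing.assert_allclose(single.msd, pooled.msd, rtol=1e-14)
    np.testing.assert_array_equal(single.pair_counts, pooled.pair_counts)


def test_pooled_invariant_under_duplication(rng):
    trajs = [rng.normal(size=(rng.integers(10, 30), 2)) for _ in range(5)]
    once = m.pooled_msd(trajs, 0.002, n_max=8)
    twice = m.pooled_msd(trajs + trajs, 0.002, n_max=8)
    np.testing.assert_allclose(once.msd, twice.msd, rtol=1e-14)
    np.testing.assert_array_equal(2 * once.pair_counts, twice.pair_counts)


def test_short_trajectory_truncates_with_warning():
    pos = np.zeros((5, 2))
    with pytest.warns(UserWarning, match="truncated"):
        curve = m.msd_single(pos, 1.0, n_max=10)
    assert len(curve) == 4


def test_noncontiguous_frames_fail():
    with pytest.raises(ValueError, match="contiguous"):
        m.msd_single(np.zeros((4, 2)), 1.0, frames=np.array([0, 1, 3, 4]))


def test_mixed_frame_intervals_fail(free_field):
    cfg1 = m.DiffusionSimConfig(
        d_free=0.5, frame_interval=1 / 500, n_trajectories=2, n_frames=10,
        length_dist="fixed", seed=0,
    )
    cfg2 = m.DiffusionSimConfig(
        d_free=0.5, frame_interval=1 / 30, n_trajectories=2, n_frames=10,
        length_dist="fixed", seed=0,
    )
    trajs = m.simulate_trajectories(free_field, cfg1) + m.simulate_trajectories(
        free_field, cfg2
    )
    with pytest.raises(ValueError, match="mixed frame intervals"):
        m.pooled_msd_from_trajectories(trajs, 5)


# ---------------------------------------------------------------------------
# D(tau) curves


def test_d_curve_constant_for_model_consistent_msd():
    taus = 0.002 * np.arange(1, 11)
    curve = m.MSDCurve(taus, 4 * 0.5 * taus, np.full(10, 100), 0.002)
    dcurve = m.build_d_curve(curve)
    np.testing.assert_allclose(dcurve.d_values, 0.5, rtol=1e-12)


def test_d_curve_closed_form_two_lags():
    curve = m.MSDCurve([0.1, 0.2], [0.4, 1.2], [10, 10], 0.1)
    dcurve = m.build_d_curve(curve)
    # slope = (0.1*0.4 + 0.2*1.2)/(0.01+0.04) = 5.6 -> D = 1.4
    assert dcurve.d_values[1] == pytest.approx(1.4, rel=1e-12)
    assert dcurve.d_values[0] == pytest.approx(0.4 / (4 * 0.1), rel=1e-12)


def test_d_curve_single_point_ballistic():
    dt = 0.1
    curve = m.MSDCurve([dt], [(1.0 * dt) ** 2], [5], dt)
    dcurve = m.build_d_curve(curve)
    assert dcurve.d_values[0] == pytest.approx(0.025, rel=1e-12)


def test_merge_nonoverlapping_curves_concatenates():
    fast = m.DCurve([0.002, 0.004], [0.6, 0.58], source_rate=500.0)
    slow = m.DCurve([0.033, 0.066], [0.5, 0.5], source_rate=30.0)
    merged = m.merge_d_curves(fast, slow)
    assert len(merged) == 4
    assert np.all(np.diff(merged.taus) > 0)
    np.testing.assert_array_equal(merged.rates, [500, 500, 30, 30])


def test_merge_keeps_both_points_at_identical_tau():
    fast = m.DCurve([0.01, 0.1], [0.6, 0.55], source_rate=500.0)
    slow = m.DCurve([0.1, 0.2], [0.5, 0.5], source_rate=30.0)
    merged = m.merge_d_curves(fast, slow)
    assert len(merged) == 4
    at = np.nonzero(merged.taus == 0.1)[0]
    assert list(merged.rates[at]) == [500.0, 30.0]  # faster rate first


def test_merged_free_diffusion_curves_are_flat(free_field):
    curves = []
    for rate in (500.0, 30.0):
        cfg = m.DiffusionSimConfig(
            d_free=0.5, frame_interval=1 / rate, n_trajectories=150, n_frames=80,
            length_dist="fixed", loc_noise_sigma=0.0, seed=6,
        )
        trajs = m.simulate_trajectories(free_field, cfg)
        pooled = m.pooled_msd_from_trajectories(trajs, 20, use_true=True)
        curves.append(m.build_d_curve(pooled, source_rate=rate))
    merged = m.merge_d_curves(*curves)
    assert merged.d_values.max() / merged.d_values.min() < 1.1
    np.testing.assert_allclose(merged.d_values, 0.5, rtol=0.05)
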