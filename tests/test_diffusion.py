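import numpy as np
import pytest
from scipy.stats import spearmanr

import memdiff as m


def _fit_through_origin(curve, n_lags):
    taus, msd = curve.taus[:n_lags], curve.msd[:n_lags]
    return float(np.sum(taus * msd) / (4.0 * np.sum(taus**2)))


def test_frozen_dynamics_keep_positions_constant(free_field):
    cfg = m.DiffusionSimConfig(
        d_free=0.0, frame_interval=0.002, n_trajectories=5, n_frames=20,
        length_dist="fixed", loc_noise_sigma=0.0, seed=0,
    )
    for t in m.simulate_trajectories(free_field, cfg):
        assert np.allclose(t.true_xy, t.true_xy[0])
        assert np.array_equal(t.frames, np.arange(20))


def test_free_diffusion_recovers_d_within_three_se(free_field):
    cfg = m.DiffusionSimConfig(
        d_free=0.5, frame_interval=1 / 500, n_trajectories=300, n_frames=100,
        length_dist="fixed", loc_noise_sigma=0.0, seed=2,
    )
    trajs = m.simulate_trajectories(free_field, cfg)
    pooled = m.pooled_msd_from_trajectories(trajs, 4, use_true=True)
    d_hat = _fit_through_origin(pooled, 4)
    # SE from the spread of independent per-trajectory estimates
    per_traj = np.array(
        [_fit_through_origin(m.msd_single(t.true_xy, cfg.frame_interval, 4), 4)
         for t in trajs]
    )
    se = per_traj.std(ddof=1) / np.sqrt(len(per_traj))
    assert abs(d_hat - 0.5) < 3 * se


def test_obstructed_diffusion_slows_at_long_lags(obstructed_study):
    dc = obstructed_study["dcurve"]
    short = dc.d_values[np.searchsorted(dc.taus, 0.01)]
    long = dc.d_values[np.searchsorted(dc.taus, 0.1)]
    assert long < short


def test_obstructed_d_tau_negatively_correlated_across_seeds(obstacle_field):
    """Ensemble D(τ) decreases with τ in at least 9 of 10 seeded runs."""
    hits = 0
    for seed in range(10):
        cfg = m.DiffusionSimConfig(
            d_free=0.7, frame_interval=1 / 500, n_trajectories=80, n_frames=80,
            length_dist="fixed", loc_noise_sigma=0.0, seed=seed,
        )
        trajs = m.simulate_trajectories(obstacle_field, cfg)
        dc = m.build_d_curve(m.pooled_msd_from_trajectories(trajs, 40, use_true=True))
        rho, _ = spearmanr(dc.taus, dc.d_values)
        hits += rho <= 0
    assert hits >= 9


def test_localization_noise_inflates_single_lag_msd_by_4_sigma_sq(free_field):
    sigma = 0.044
    cfg = m.DiffusionSimConfig(
        d_free=0.0, frame_interval=1 / 30, n_trajectories=200, n_frames=51,
        length_dist="fixed", loc_noise_sigma=sigma, seed=7,
    )
    trajs = m.simulate_trajectories(free_field, cfg)
    pooled = m.pooled_msd_from_trajectories(trajs, 1)
    assert pooled.pair_counts[0] >= 10_000
    assert pooled.msd[0] == pytest.approx(4 * sigma**2, rel=0.10)


def test_impermeable_obstacles_never_contain_recorded_positions(obstacle_field):
    cfg = m.DiffusionSimConfig(
        d_free=0.7, frame_interval=1 / 500, n_trajectories=20, n_frames=30,
        length_dist="fixed", loc_noise_sigma=0.0, seed=3,
    )
    for t in m.simulate_trajectories(obstacle_field, cfg):
        assert not obstacle_field.contains(t.true_xy).any()


def test_substep_resolution_keeps_rms_step_below_radius_fifth(obstacle_field):
    cfg = m.DiffusionSimConfig(
        d_free=0.7, frame_interval=1 / 500, n_trajectories=1, seed=0,
    )
    n_sub = cfg.resolve_substeps(obstacle_field)
    rms_step = np.sqrt(2 * cfg.d_free * cfg.frame_interval / n_sub)
    assert rms_step <= obstacle_field.min_radius / 5 + 1e-12


def test_geometric_lengths_respect_minimum_and_mean():
    cfg = m.DiffusionSimConfig(
        d_free=0.5, frame_interval=1 / 30, n_trajectories=400, n_frames=60,
        length_dist="geometric", min_frames=30, loc_noise_sigma=0.0, seed=1,
    )
    field = m.build_obstacle_field(5.0, 0.0, 0.101)
    lengths = np.array([len(t) for t in m.simulate_trajectories(field, cfg)])
    assert lengths.min() > 30
    assert abs(lengths.mean() - 60) < 6


def test_simulation_is_bit_reproducible(free_field):
    cfg = m.DiffusionSimConfig(
        d_free=0.5, frame_interval=1 / 500, n_trajectories=10, n_frames=30,
        length_dist="fixed", seed=123,
    )
    a = m.simulate_trajectories(free_field, cfg)
    b = m.simulate_trajectories(free_field, cfg)
    for ta, tb in zip(a, b):
        assert np.array_equal(ta.true_xy, tb.true_xy)
        assert np.array_equal(ta.observed_xy, tb.observed_xy)


def test_zero_trajectories_gives_empty_list(free_field):
    cfg = m.DiffusionSimConfig(
        d_free=0.5, frame_interval=1 / 500, n_trajectories=0, seed=0
    )
    assert m.simulate_trajectories(free_field, cfg) == []


def test_noncontiguous_frames_rejected():
    with pytest.raises(ValueError, match="contiguous"):
        m.GroundTruthTrajectory(
            0, "x", np.array([0, 2, 3]), np.zeros((3, 2)), np.zeros((3, 2)), 0.002
        )
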