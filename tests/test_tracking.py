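import numpy as np
import pandas as pd
import pytest

import memdiff as m


def _loc_table(rows):
    return pd.DataFrame(rows, columns=["movie_id", "frame", "x_um", "y_um"])


# ---------------------------------------------------------------------------
# detection


def test_flat_image_yields_no_localizations():
    assert len(m.detect_spots(np.zeros((32, 32)), psf_sigma=1.0)) == 0
    assert len(m.detect_spots(np.full((32, 32), 7.0), psf_sigma=1.0)) == 0


def test_single_noiseless_spot_localized_within_tenth_pixel():
    cam = m.CameraModel(image_shape=(32, 32), background=0.0)
    um = cam.pixel_size / 1000.0
    xy = np.array([[10.30 * um, 7.70 * um]])
    traj = m.GroundTruthTrajectory(0, "mv", np.array([0]), xy, xy.copy(), 0.002)
    movie = m.render_movie([traj], cam, apply_noise=False)
    spots = m.detect_spots(movie.frames[0], cam.psf_sigma_px)
    assert spots.shape[0] == 1
    assert np.hypot(spots[0, 0] - 10.30, spots[0, 1] - 7.70) < 0.1


def test_two_separated_spots_both_detected():
    cam = m.CameraModel(image_shape=(32, 32), background=0.0)
    um = cam.pixel_size / 1000.0
    trajs = []
    for i, (x, y) in enumerate([(8.0, 8.0), (18.0, 8.0)]):  # 10 px apart
        xy = np.array([[x * um, y * um]])
        trajs.append(m.GroundTruthTrajectory(i, "mv", np.array([0]), xy, xy.copy(), 0.002))
    movie = m.render_movie(trajs, cam, apply_noise=False)
    spots = m.detect_spots(movie.frames[0], cam.psf_sigma_px)
    assert spots.shape[0] == 2


def test_localization_precision_improves_with_photons():
    truth = (15.37, 14.81)
    rmses = []
    for photons in (200.0, 3000.0):
        cam = m.CameraModel(image_shape=(32, 32), photons_per_spot=photons)
        um = cam.pixel_size / 1000.0
        xy = np.tile([[truth[0] * um, truth[1] * um]], (60, 1))
        traj = m.GroundTruthTrajectory(0, "mv", np.arange(60), xy, xy.copy(), 0.002)
        movie = m.render_movie([traj], cam, seed=9)
        errs = []
        for frame in movie.frames:
            spots = m.detect_spots(frame, cam.psf_sigma_px)
            if len(spots) == 1:
                errs.append(np.hypot(spots[0, 0] - truth[0], spots[0, 1] - truth[1]))
        rmses.append(np.sqrt(np.mean(np.square(errs))))
    assert rmses[1] < rmses[0]


# ---------------------------------------------------------------------------
# linking


def test_single_moving_spot_links_into_one_full_trajectory():
    rows = [("mv", f, 0.1 * f, 0.05 * f) for f in range(10)]
    linked = m.link_trajectories(_loc_table(rows), m.LinkConfig(max_displacement=0.5))
    assert linked["traj_id"].nunique() == 1
    assert len(linked) == 10


def test_two_distant_spots_never_swap():
    # two spots always > 2*max_displacement apart; brute-force expectation is
    # two id-stable trajectories over all 10 frames
    rows = []
    for f in range(10):
        rows.append(("mv", f, 0.02 * f, 0.0))
        rows.append(("mv", f, 5.0 + 0.02 * f, 0.0))
    linked = m.link_trajectories(_loc_table(rows), m.LinkConfig(max_displacement=0.3))
    assert linked["traj_id"].nunique() == 2
    for tid, g in linked.groupby("traj_id"):
        assert len(g) == 10
        # x stays on one side: monotone small drift, never jumping 5 µm
        assert g["x_um"].max() - g["x_um"].min() < 1.0


def test_memory_bridges_single_missed_frame():
    rows = [("mv", 0, 1.0, 1.0), ("mv", 2, 1.05, 1.0)]  # absent on frame 1
    linked = m.link_trajectories(
        _loc_table(rows), m.LinkConfig(max_displacement=0.1, memory_frames=1)
    )
    assert linked["traj_id"].nunique() == 1
    no_mem = m.link_trajectories(
        _loc_table(rows), m.LinkConfig(max_displacement=0.1, memory_frames=0)
    )
    assert no_mem["traj_id"].nunique() == 2


def test_linking_invariant_to_row_order(rng):
    rows = []
    x = {0: 1.0, 1: 3.0, 2: 6.0}
    for f in range(8):
        for k in range(3):
            x[k] += rng.normal(0, 0.02)
            rows.append(("mv", f, x[k], 0.5 * k))
    table = _loc_table(rows)
    cfg = m.LinkConfig(max_displacement=0.5)
    a = m.link_trajectories(table, cfg)
    b = m.link_trajectories(table.sample(frac=1.0, random_state=1), cfg)
    pd.testing.assert_frame_equal(
        a.reset_index(drop=True), b.reset_index(drop=True)
    )


def test_empty_localizations_link_to_empty_output():
    out = m.link_trajectories(_loc_table([]), m.LinkConfig(max_displacement=1.0))
    assert out.empty


# ---------------------------------------------------------------------------
# filtering


def _traj_table(lengths, gap_in=None):
    rows = []
    for tid, L in enumerate(lengths):
        for f in range(L):
            if gap_in == tid and f == L // 2:
                continue
            rows.append(("mv", tid, f, 0.0, 0.0))
    return pd.DataFrame(rows, columns=["movie_id", "traj_id", "frame", "x_um", "y_um"])


def test_length_filter_at_500fps_is_inclusive_50():
    table = _traj_table([49, 50])
    kept = m.filter_trajectories(table, frame_rate=500)
    assert set(kept["traj_id"]) == {1}


def test_length_filter_at_30fps_is_inclusive_30():
    table = _traj_table([29, 30])
    kept = m.filter_trajectories(table, frame_rate=30)
    assert set(kept["traj_id"]) == {1}


def test_filter_drops_gapped_trajectories():
    table = _traj_table([60, 60], gap_in=1)
    kept = m.filter_trajectories(table, frame_rate=500)
    assert set(kept["traj_id"]) == {0}


def test_filter_empty_input_and_unknown_rate():
    empty = _traj_table([])
    assert m.filter_trajectories(empty, frame_rate=500).empty
    with pytest.raises(ValueError, match="threshold"):
        m.filter_trajectories(_traj_table([40]), frame_rate=100)
    kept = m.filter_trajectories(_traj_table([40]), frame_rate=100, min_frames=35)
    assert set(kept["traj_id"]) == {0}
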