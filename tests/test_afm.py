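import numpy as np
import pytest

import memdiff as m


def _clean_config(**kw):
    base = dict(
        domain_fraction=0.0, noise_sigma=0.0, tilt=(0.0, 0.0),
        line_offset_sigma=0.0, seed=0,
    )
    base.update(kw)
    return m.TopoSimConfig(**base)


def test_empty_clean_config_gives_constant_raster():
    topo, labels = m.generate_topography(_clean_config())
    assert np.all(topo.heights == 0)
    assert labels.n_domains == 0


def test_ground_truth_fraction_equals_pixelized_disk_area():
    cfg = _clean_config(domain_fraction=0.1, domain_diameter_sd=0.0, seed=2)
    topo, labels = m.generate_topography(cfg)
    gt_fraction = (labels.labels > 0).mean()
    # pixelization error at 5.9 nm pixels on 101 nm disks is small
    assert gt_fraction == pytest.approx(0.1, abs=0.012)
    # depressions exactly where labelled
    assert np.all(topo.heights[labels.labels > 0] < 0)
    assert np.all(topo.heights[labels.labels == 0] == 0)


def test_reference_config_reaches_target_fraction():
    topo, labels = m.generate_topography(m.TopoSimConfig(seed=3))
    gt_fraction = (labels.labels > 0).mean()
    assert gt_fraction == pytest.approx(0.24, abs=0.01)


# ---------------------------------------------------------------------------
# flattening


def test_flatten_constant_input_centres_background_at_zero():
    topo = m.Topography(np.full((64, 64), 3.7), 5.9)
    flat = m.flatten_topography(topo)
    assert np.allclose(flat.heights, 0.0, atol=0.05)


def test_flatten_removes_injected_plane():
    cfg = _clean_config(domain_fraction=0.24, noise_sigma=0.05,
                        tilt=(0.004, -0.003), seed=4)
    topo, labels = m.generate_topography(cfg)
    flat = m.flatten_topography(topo)
    bg = flat.heights[labels.labels == 0]
    assert np.sqrt(np.mean(bg**2)) < 0.06  # residual below the noise floor


def test_flatten_removes_line_offsets():
    cfg = _clean_config(domain_fraction=0.24, noise_sigma=0.05,
                        line_offset_sigma=0.3, seed=5)
    topo, labels = m.generate_topography(cfg)
    flat = m.flatten_topography(topo)
    bg_mask = labels.labels == 0
    line_medians = [
        np.median(flat.heights[i][bg_mask[i]])
        for i in range(flat.heights.shape[0])
        if bg_mask[i].any()
    ]
    assert np.max(np.abs(line_medians)) < 0.05


def test_flatten_then_segment_invariant_to_raster_artifacts():
    base = _clean_config(domain_fraction=0.24, noise_sigma=0.15, seed=6)
    warped = _clean_config(domain_fraction=0.24, noise_sigma=0.15, seed=6,
                           tilt=(0.004, -0.002), line_offset_sigma=0.2)
    seg = []
    for cfg in (base, warped):
        topo, _ = m.generate_topography(cfg)
        labels = m.segment_domains(m.flatten_topography(topo))
        seg.append(labels.labels > 0)
    agree = (seg[0] == seg[1]).mean()
    assert agree > 0.99


# ---------------------------------------------------------------------------
# segmentation and statistics


def test_constant_raster_has_no_domains():
    labels = m.segment_domains(m.Topography(np.zeros((32, 32)), 5.9))
    assert labels.n_domains == 0
    stats = m.compute_domain_stats(m.Topography(np.zeros((32, 32)), 5.9), labels)
    assert stats.n_domains == 0
    assert stats.area_fraction == 0.0
    assert np.isnan(stats.mean_depth)


def test_single_disk_segmented_to_its_area():
    px = 5.9
    n = 101
    h = np.zeros((n, n))
    rr, cc = np.mgrid[0:n, 0:n]
    radius_px = (101.0 / 2) / px
    disk = (rr - 50) ** 2 + (cc - 50) ** 2 <= radius_px**2
    h[disk] = -1.4
    topo = m.Topography(h, px)
    labels = m.segment_domains(topo)
    assert labels.n_domains == 1
    # pixel count within one edge ring of the drawn disk
    ring = 2 * np.pi * radius_px
    assert abs((labels.labels == 1).sum() - disk.sum()) <= ring
    stats = m.compute_domain_stats(topo, labels)
    assert stats.mean_equiv_diameter == pytest.approx(101.0, abs=2 * px)
    assert stats.mean_depth == pytest.approx(1.4, abs=0.01)


def test_segment_threshold_must_be_positive():
    topo = m.Topography(np.zeros((8, 8)), 5.9)
    with pytest.raises(ValueError):
        m.segment_domains(topo, depth_threshold=0.0)


def test_label_count_close_to_ground_truth_on_noisy_image():
    topo, gt = m.generate_topography(m.TopoSimConfig(seed=7))
    labels = m.segment_domains(m.flatten_topography(topo))
    assert abs(labels.n_domains - gt.n_domains) / gt.n_domains < 0.15


def test_stats_misaligned_label_map_rejected():
    topo = m.Topography(np.zeros((16, 16)), 5.9)
    labels = m.DomainLabelMap(np.zeros((8, 8), dtype=np.int32), 5.9)
    with pytest.raises(ValueError, match="align"):
        m.compute_domain_stats(topo, labels)


# ---------------------------------------------------------------------------
# free-size conventions


def test_equivalent_free_circle_hand_computation():
    # density and fraction as published: N = 1589 domains over 9 images of
    # 3x3 µm² -> 19.62 µm⁻²; φ = 0.24 -> free cell area 0.0387 µm² -> 222 nm
    stats = m.DomainStats(
        n_domains=1589, mean_depth=1.4, mean_equiv_diameter=101.0,
        area_fraction=0.24, number_density=1589 / 81.0,
    )
    est = m.domain_free_size(stats)
    assert est.convention == "equivalent_free_circle"
    assert est.l_free == pytest.approx(222.0, abs=1.0)


def test_free_circle_limit_of_vanishing_fraction():
    rho = 20.0  # µm⁻²
    stats = m.DomainStats(1, 1.4, 101.0, 1e-9, rho)
    est = m.domain_free_size(stats)
    expected = 2.0 / np.sqrt(np.pi * rho / 1e6)  # cell-circle diameter, nm
    assert est.l_free == pytest.approx(expected, rel=1e-6)


def test_lattice_gap_convention_formula():
    stats = m.DomainStats(100, 1.4, 101.0, 0.24, 19.62)
    est = m.domain_free_size(stats, convention="lattice_gap")
    expected = 2 * 101.0 * (np.sqrt(np.pi / (4 * 0.24)) - 1.0)
    assert est.l_free == pytest.approx(expected, rel=1e-12)
    # the two conventions intentionally differ
    assert est.l_free != pytest.approx(m.domain_free_size(stats).l_free, rel=0.01)


def test_free_size_error_cases():
    empty = m.DomainStats(0, float("nan"), float("nan"), 0.0, 0.0)
    with pytest.raises(ValueError):
        m.domain_free_size(empty)
    full = m.DomainStats(10, 1.4, 101.0, 1.0, 5.0)
    with pytest.raises(ValueError):
        m.domain_free_size(full)
    with pytest.raises(ValueError, match="convention"):
        m.domain_free_size(
            m.DomainStats(10, 1.4, 101.0, 0.2, 5.0), convention="banana"
        )
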