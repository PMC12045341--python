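"""Generators: determinism, closed-form limits, and statistical consistency."""

import numpy as np
import pytest

from omequant import memprofile, spt
from omequant.config import SimConfig, bleaching_config, tracking_config
from omequant.synthetic import (
    CellGeometry,
    CrossingPlan,
    boundary_foci,
    emitters_from_tracks,
    render_movie,
    simulate_bleach_trace,
    simulate_density_profile,
    simulate_ome_scenario,
    simulate_trajectories,
)


# ---------------------------------------------------------------------------
# bleach traces


def test_bleach_trace_no_fluorophores_is_flat_background():
    cfg = bleaching_config(0, noise_sd=0.0)
    trace, gt = simulate_bleach_trace(0, cfg, 50)
    assert np.allclose(trace.intensities, cfg.background_level)
    assert gt.true_bleach_times.size == 0


def test_bleach_trace_noiseless_endpoints():
    cfg = bleaching_config(3, noise_sd=0.0, bleach_rate=2.0)
    trace, _ = simulate_bleach_trace(4, cfg, 400)
    assert trace.intensities[0] == pytest.approx(
        cfg.background_level + 4 * cfg.photon_scale)
    assert trace.intensities[-1] == pytest.approx(cfg.background_level)


def test_bleach_trace_rejects_negative_arguments():
    cfg = bleaching_config(0)
    with pytest.raises(ValueError):
        simulate_bleach_trace(-1, cfg, 100)
    with pytest.raises(ValueError):
        simulate_bleach_trace(3, cfg, -5)


def test_bleach_times_match_exponential_mean():
    """Mean discretized bleach time vs the closed-form expectation.

    For exponential lifetimes at rate λ sampled on a frame grid Δt, the
    recorded frame is ceil(T/Δt), whose expectation is 1/(1 - exp(-λΔt)).
    """
    cfg = bleaching_config(11, bleach_rate=2.0, frame_interval=0.015)
    n = 10_000
    trace, gt = simulate_bleach_trace(n, cfg, 4)
    lam_dt = cfg.bleach_rate * cfg.frame_interval
    expected_frames = 1.0 / (1.0 - np.exp(-lam_dt))
    mean_t = gt.true_bleach_times.mean() * cfg.frame_interval
    se = (1.0 / cfg.bleach_rate) / np.sqrt(n)
    assert abs(mean_t - expected_frames * cfg.frame_interval) < 3 * se


def test_bleach_survivor_count_is_monotone_noiseless():
    cfg = bleaching_config(5, noise_sd=0.0)
    trace, _ = simulate_bleach_trace(8, cfg, 500)
    assert np.all(np.diff(trace.intensities) <= 0)


# ---------------------------------------------------------------------------
# trajectories


def test_zero_diffusion_tracks_are_fixed_points():
    cfg = tracking_config(0)
    tracks, _ = simulate_trajectories(0.0, 5, 10, cfg)
    for xy in tracks:
        assert np.allclose(xy, xy[0])


def test_confined_tracks_stay_inside_geometry():
    cfg = tracking_config(2)
    cell = CellGeometry(1, center=(2.0, 1.0), angle=0.3, length=4.0, width=0.7)
    tracks, gt = simulate_trajectories(0.4, 20, 60, cfg, geometry=cell)
    for xy in tracks:
        assert cell.contains(xy).all()
    for lab in gt.true_cell_of_particle:
        assert (lab == 1).all()


def test_brownian_msd_matches_closed_form():
    """Ensemble MSD of free tracks equals 4DΔt within sampling error."""
    cfg = tracking_config(4)
    true_d = 0.2
    tracks, _ = simulate_trajectories(true_d, 5000, 50, cfg)
    trajs = [spt.Trajectory(i, np.arange(len(xy)), xy) for i, xy in enumerate(tracks)]
    msd = spt.compute_msd(trajs, max_lag=12, frame_interval=cfg.frame_interval)
    for k in (1, 2, 3, 4, 8, 12):  # lags up to 1/4 of track length
        expected = 4 * true_d * k * cfg.frame_interval
        assert msd.msd[k - 1] == pytest.approx(expected, rel=0.02)


def test_trajectories_reject_negative_diffusivity():
    with pytest.raises(ValueError):
        simulate_trajectories(-0.1, 1, 5, tracking_config(0))


# ---------------------------------------------------------------------------
# rendering


def test_render_no_emitters_noiseless_is_flat():
    cfg = tracking_config(0, noise_sd=0.0)
    stack = render_movie(np.empty((0, 4)), cfg, n_frames=3)
    assert np.allclose(stack, cfg.background_level)


def test_render_static_emitter_peaks_at_its_pixel():
    cfg = tracking_config(0, noise_sd=0.0)
    x = 10 * cfg.pixel_size
    y = 7 * cfg.pixel_size
    img = render_movie(np.array([[0, x, y, cfg.photon_scale]]), cfg, n_frames=1)[0]
    assert np.unravel_index(np.argmax(img), img.shape) == (7, 10)


def test_render_conserves_integrated_intensity():
    """Noiseless total intensity above background = photon_scale x live emitters."""
    cfg = tracking_config(0, noise_sd=0.0)
    em = np.array([
        [0, 12 * 0.16, 12 * 0.16, cfg.photon_scale],
        [0, 6 * 0.16, 14 * 0.16, cfg.photon_scale],
        [1, 12 * 0.16, 12 * 0.16, cfg.photon_scale],
    ])
    stack = render_movie(em, cfg, n_frames=2)
    excess0 = (stack[0] - cfg.background_level).sum()
    excess1 = (stack[1] - cfg.background_level).sum()
    # tolerance covers pixel-sampling aliasing of the undersampled Gaussian
    assert excess0 == pytest.approx(2 * cfg.photon_scale, rel=5e-3)
    assert excess1 == pytest.approx(cfg.photon_scale, rel=5e-3)


def test_render_clips_out_of_field_positions_with_warning():
    cfg = tracking_config(0)
    em = np.array([[0, -1.0, 0.5, cfg.photon_scale]])
    with pytest.warns(UserWarning):
        render_movie(em, cfg, n_frames=1)


def test_render_localization_round_trip_subpixel():
    """A noiseless emitter at a known subpixel position is recovered to <0.1 px."""
    cfg = tracking_config(0, noise_sd=0.0)
    x = 10.37 * cfg.pixel_size
    y = 7.81 * cfg.pixel_size
    img = render_movie(np.array([[0, x, y, cfg.photon_scale]]), cfg, n_frames=1)[0]
    dets = spt.detect_particles(img, 50.0, 7, cfg.pixel_size, cfg.psf_sigma)
    assert len(dets) == 1
    assert abs(dets[0].x - x) < 0.1 * cfg.pixel_size
    assert abs(dets[0].y - y) < 0.1 * cfg.pixel_size


def test_identical_seeds_reproduce_identical_outputs():
    for make in (lambda: simulate_bleach_trace(5, bleaching_config(9), 300)[0].intensities,
                 lambda: render_movie(np.array([[0, 1.0, 1.0, 500.0]]),
                                      tracking_config(9), n_frames=2)):
        a, b = make(), make()
        assert a.tobytes() == b.tobytes()


# ---------------------------------------------------------------------------
# transfer scenarios


def _two_cells():
    g1 = CellGeometry(1, center=(3.0, 1.1), angle=0.0, length=5.5, width=0.7)
    g2 = CellGeometry(2, center=(3.0, 1.8), angle=0.0, length=5.5, width=0.7)
    return g1, g2


def test_out_and_back_plan_yields_two_crossings():
    cfg = tracking_config(5, image_shape=(20, 40))
    g1, g2 = _two_cells()
    scen = simulate_ome_scenario(cfg, [g1, g2],
                                 [CrossingPlan(cells=(1, 2, 1), n_frames=12)],
                                 rng=np.random.default_rng(5))
    assert len(scen.truth.crossings[0]) == 2
    assert [c.to_cell for c in scen.truth.crossings[0]] == [2, 1]


def test_serial_plan_crosses_three_distinct_boundaries():
    cfg = tracking_config(6, image_shape=(28, 40))
    cells = [CellGeometry(i + 1, center=(3.0, 0.9 + 0.7 * i), angle=0.0,
                          length=5.5, width=0.7) for i in range(4)]
    # a serial transit across two 0.7-μm cells takes ~100+ frames of
    # diffusion; raster-exact recovery is not enforced for such long walks
    scen = simulate_ome_scenario(cfg, cells,
                                 [CrossingPlan(cells=(1, 2, 3, 4), n_frames=300)],
                                 rng=np.random.default_rng(6),
                                 raster_check=False)
    cr = scen.truth.crossings[0]
    assert len(cr) == 3
    assert {frozenset((c.from_cell, c.to_cell)) for c in cr} == {
        frozenset((1, 2)), frozenset((2, 3)), frozenset((3, 4))}


def test_scenario_rejects_unknown_cell_and_non_adjacent_plan():
    cfg = tracking_config(7, image_shape=(20, 40))
    g1, g2 = _two_cells()
    with pytest.raises(ValueError, match="unknown cell"):
        simulate_ome_scenario(cfg, [g1, g2], [CrossingPlan(cells=(1, 9))])
    g3 = CellGeometry(3, center=(3.0, 4.5), angle=0.0, length=5.5, width=0.7)
    with pytest.raises(ValueError, match="not adjacent"):
        simulate_ome_scenario(cfg, [g1, g2, g3], [CrossingPlan(cells=(1, 3))])


def test_boundary_foci_sit_between_the_cells():
    g1, g2 = _two_cells()
    foci = boundary_foci(g1, g2, [0.3, 0.7])
    for f in foci:
        assert abs(f[1] - 1.45) < 0.05  # on the shared boundary line


# ---------------------------------------------------------------------------
# density profiles


def test_density_profile_separation_recovers_construction():
    prof, _ = simulate_density_profile([10.0, 38.8], peak_widths=3.0,
                                       amplitudes=1.0, noise_sd=0.0)
    centers = memprofile.locate_density_centers(prof, 2, polarity="peaks")
    m = memprofile.measure_separation(centers)
    assert m.separation == pytest.approx(28.8, abs=0.1)


def test_density_profile_rejects_overlapping_peaks():
    with pytest.raises(ValueError, match="overlap"):
        simulate_density_profile([10.0, 14.0], peak_widths=3.0, amplitudes=1.0)


def test_noisy_profile_separation_is_unbiased():
    rng = np.random.default_rng(21)
    seps = []
    for _ in range(30):
        prof, _ = simulate_density_profile([10.0, 38.8], peak_widths=3.0,
                                           amplitudes=1.0, noise_sd=0.1, rng=rng)
        centers = memprofile.locate_density_centers(prof, 2, polarity="peaks")
        seps.append(memprofile.measure_separation(centers).separation)
    se = np.std(seps, ddof=1) / np.sqrt(len(seps))
    assert abs(np.mean(seps) - 28.8) < 2 * max(se, 0.05)


# ---------------------------------------------------------------------------
# config


def test_simconfig_validation_and_json_round_trip():
    with pytest.raises(ValueError):
        SimConfig(pixel_size=0.0)
    with pytest.raises(ValueError):
        SimConfig(noise_sd=-1.0)
    cfg = tracking_config(3)
    assert SimConfig.from_json(cfg.to_json()) == cfg
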