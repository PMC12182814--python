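"""Strain engine: tracking, deformation-gradient strain, AHA segmentation."""

import numpy as np
import pytest

from lvmech.phantom import PhantomSpec, generate_phantom
from lvmech.strain import (AHA_SEGMENTS, SliceGeometry, Trajectories,
                           VelocityCine, build_segment_map, compute_strain,
                           segment_curves, summarize, track_displacements)
from tests.conftest import make_curves, run_strain_pipeline


def annulus_cine(n=64, r_in=20.0, r_out=28.0, n_frames=12, velocity=None,
                 slice_level="mid"):
    c = (n - 1) / 2.0
    rows, cols = np.mgrid[0:n, 0:n]
    rho = np.hypot(rows - c, cols - c)
    mask = (rho >= r_in) & (rho <= r_out)
    vel = np.zeros((n_frames, n, n, 2))
    if velocity is not None:
        vel[:] = velocity
    return VelocityCine(velocity=vel, ed_mask=mask, frame_duration_ms=50.0,
                        pixel_spacing_mm=(1.0, 1.0), slice_level=slice_level)


def test_zero_velocity_keeps_pixels_still():
    cine = annulus_cine()
    traj = track_displacements(cine)
    assert np.allclose(traj.positions_mm, traj.positions_mm[:, :1, :])
    maps = compute_strain(traj)
    assert maps.radial == pytest.approx(0.0, abs=1e-12)
    assert maps.circumferential == pytest.approx(0.0, abs=1e-12)


def test_constant_velocity_gives_linear_motion():
    cine = annulus_cine(n_frames=11, velocity=np.array([1.0, 0.0]))
    traj = track_displacements(cine)
    disp = traj.positions_mm[:, 10, :] - traj.positions_mm[:, 0, :]
    assert disp[:, 0] == pytest.approx(0.5, abs=1e-12)   # 1 mm/s * 0.5 s
    assert disp[:, 1] == pytest.approx(0.0, abs=1e-12)


def test_endocardial_radius_recovered_at_peak(fine_uniform):
    traj = fine_uniform["trajectories"]
    R0 = np.linalg.norm(traj.positions_mm[:, 0, :], axis=1)
    endo = np.abs(R0 - 20.0) < 0.3
    peak_frame = fine_uniform["spec"].n_frames // 2
    r_peak = np.linalg.norm(traj.positions_mm[endo, peak_frame, :], axis=1)
    assert r_peak.mean() == pytest.approx(15.0, rel=0.02)


def test_pure_rotation_produces_zero_strain():
    cine = annulus_cine(n_frames=12)
    geom = SliceGeometry.from_cine(cine)
    traj = track_displacements(cine, geom)
    ang = np.deg2rad(10.0)
    rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    pos = traj.positions_mm.copy()
    for k in range(1, pos.shape[1]):
        pos[:, k, :] = traj.positions_mm[:, 0, :] @ rot.T
    rotated = Trajectories(pixel_rc=traj.pixel_rc, positions_mm=pos,
                           out_of_bounds=traj.out_of_bounds,
                           frame_duration_ms=traj.frame_duration_ms,
                           pixel_spacing_mm=traj.pixel_spacing_mm, geometry=geom)
    maps = compute_strain(rotated, geom)
    assert np.abs(maps.radial[maps.valid]).max() < 1e-9
    assert np.abs(maps.circumferential[maps.valid]).max() < 1e-9


def test_midwall_strain_matches_analytic_truth(coarse_uniform):
    truth = coarse_uniform["truth"]
    curves = coarse_uniform["curves"]
    err = np.abs(curves.strain - truth.strain[0])
    assert err.max() < 0.03


def test_segment_map_partitions_and_names():
    cine = annulus_cine()
    geom = SliceGeometry.from_cine(cine)
    segmap = build_segment_map(cine, geom)
    labels = segmap.labels[cine.ed_mask]
    assert set(labels) == set(range(6))
    assert segmap.names == AHA_SEGMENTS["mid"]
    apical = annulus_cine(slice_level="apical")
    segmap_a = build_segment_map(apical, SliceGeometry.from_cine(apical))
    assert set(segmap_a.labels[apical.ed_mask]) == set(range(4))
    assert len(segmap_a.names) == 4


def test_segment_map_rotation_permutes_labels_cyclically():
    cine = annulus_cine()
    geom = SliceGeometry.from_cine(cine)
    base = build_segment_map(cine, geom)
    rot = build_segment_map(cine, SliceGeometry(
        centroid_rc=geom.centroid_rc,
        anterior_reference_angle_rad=geom.anterior_reference_angle_rad + np.pi / 3))
    # ignore pixels sitting numerically on a sector boundary
    rc = np.argwhere(cine.ed_mask)
    dy = -(rc[:, 0] - geom.centroid_rc[0])
    dx = rc[:, 1] - geom.centroid_rc[1]
    rel = np.mod(np.arctan2(dy, dx) - geom.anterior_reference_angle_rad, np.pi / 3)
    interior = (rel > 1e-9) & (rel < np.pi / 3 - 1e-9)
    b = base.labels[rc[:, 0], rc[:, 1]]
    r = rot.labels[rc[:, 0], rc[:, 1]]
    assert np.array_equal(r[interior], (b[interior] - 1) % 6)


def test_centroid_outside_cavity_rejected():
    cine = annulus_cine()
    with pytest.raises(ValueError, match="centroid"):
        build_segment_map(cine, SliceGeometry(centroid_rc=(31.5, 55.0),
                                              anterior_reference_angle_rad=0.0))


def test_segment_curves_average_and_empty_segment_error(coarse_uniform):
    maps = coarse_uniform["maps"]
    segmap = coarse_uniform["segment_map"]
    curves = coarse_uniform["curves"]
    # uniform phantom: all segment curves agree closely
    assert np.ptp(curves.strain, axis=0).max() < 5e-3
    # invalidating every pixel of one segment names it in the error
    bad = maps.__class__(pixel_rc=maps.pixel_rc, radial=maps.radial,
                         circumferential=maps.circumferential,
                         valid=maps.valid & (segmap.labels[maps.pixel_rc[:, 0],
                                                           maps.pixel_rc[:, 1]] != 2),
                         frame_duration_ms=maps.frame_duration_ms)
    with pytest.raises(ValueError, match="inferoseptal"):
        segment_curves(bad, segmap, 50.0)


def test_summarize_peak_ttp_and_tie_rule():
    curves = make_curves(np.array([[0.0, 0.1, 0.3, 0.2]]), frame_duration_ms=50.0)
    s = summarize(curves)
    assert s.peak_rs_pct[0] == pytest.approx(30.0)
    assert s.ttp_ms[0] == pytest.approx(100.0)
    tie = summarize(make_curves(np.array([[0.0, 0.3, 0.1, 0.3]])))
    assert tie.ttp_ms[0] == pytest.approx(50.0)  # earliest of the two maxima
    flat = summarize(make_curves(np.zeros((1, 12))))
    assert flat.peak_rs_pct[0] == 0.0
    assert np.isnan(flat.ttp_ms[0])


def test_global_rs_rules_agree_on_homogeneous_phantom(coarse_uniform):
    s_peak = summarize(coarse_uniform["curves"], global_rs_rule="peak_of_mean")
    s_mean = summarize(coarse_uniform["curves"], global_rs_rule="mean_of_peaks")
    assert s_peak.global_rs_pct == pytest.approx(s_peak.peak_rs_pct.mean(), abs=1.0)
    assert s_mean.global_rs_pct == pytest.approx(s_peak.global_rs_pct, abs=1.0)


def test_rotation_equivariance_of_segmental_curves(coarse_uniform):
    spec = PhantomSpec(grid_size=64, pixel_spacing_mm=1.0, n_frames=20,
                       frame_duration_ms=50.0,
                       contraction_fraction=(0.1, 0.15, 0.2, 0.25, 0.3, 0.35))
    cine, _ = generate_phantom(spec)
    geom = SliceGeometry.from_cine(cine, spec.anterior_reference_angle_rad)
    base = segment_curves(compute_strain(track_displacements(cine, geom), geom),
                          build_segment_map(cine, geom), 50.0)
    # rotate the cine 90 deg counterclockwise (y-up frame) and the reference with it
    vel = cine.velocity
    vel_rot = np.empty_like(vel)
    vel_rot[..., 0] = np.rot90(-vel[..., 1], k=1, axes=(1, 2))
    vel_rot[..., 1] = np.rot90(vel[..., 0], k=1, axes=(1, 2))
    cine_rot = VelocityCine(velocity=vel_rot, ed_mask=np.rot90(cine.ed_mask, k=1),
                            frame_duration_ms=cine.frame_duration_ms,
                            pixel_spacing_mm=cine.pixel_spacing_mm,
                            slice_level=cine.slice_level)
    geom_rot = SliceGeometry.from_cine(
        cine_rot, spec.anterior_reference_angle_rad + np.pi / 2)
    rot = segment_curves(compute_strain(track_displacements(cine_rot, geom_rot),
                                        geom_rot),
                         build_segment_map(cine_rot, geom_rot), 50.0)
    assert np.abs(rot.strain - base.strain).max() <= 0.01


def test_strain_error_shrinks_with_resolution(coarse_uniform, fine_uniform):
    def max_err(p):
        return np.abs(p["curves"].strain - p["truth"].strain[0]).max()
    assert max_err(fine_uniform) < max_err(coarse_uniform)


def test_strain_rate_integrates_back_to_strain():
    t = np.linspace(0.0, 1.0, 4097)
    curves = make_curves(np.sin(np.pi * t[None, :]) ** 2,
                         frame_duration_ms=(t[1] - t[0]) * 1000.0)
    dt_s = curves.frame_duration_ms / 1000.0
    rebuilt = np.concatenate([
        [0.0], np.cumsum((curves.strain_rate[0, 1:] + curves.strain_rate[0, :-1])
                         / 2.0 * dt_s)])
    assert np.abs(rebuilt - curves.strain[0]).max() < 1e-6


def test_noise_robustness_of_peak_strain(coarse_uniform):
    # noise at 5 % of the peak velocity magnitude
    peak_v = np.abs(coarse_uniform["cine"].velocity).max()
    noisy = run_strain_pipeline(
        PhantomSpec(grid_size=64, pixel_spacing_mm=1.0, n_frames=20,
                    frame_duration_ms=50.0, noise_sd_mm_s=0.05 * peak_v, seed=11))
    delta = np.abs(noisy["summary"].peak_rs_pct
                   - coarse_uniform["summary"].peak_rs_pct)
    assert delta.max() < 3.0


def test_cine_validation_rejects_broken_masks():
    cine = annulus_cine()
    solid = cine.ed_mask.copy()
    solid[:] = False
    solid[20:40, 20:40] = True  # no hole
    bad = VelocityCine(velocity=cine.velocity, ed_mask=solid,
                       frame_duration_ms=50.0, pixel_spacing_mm=(1.0, 1.0))
    with pytest.raises(ValueError, match="hole"):
        bad.validate()
    nan_vel = cine.velocity.copy()
    nan_vel[0, 0, 0, 0] = np.nan
    with pytest.raises(ValueError, match="finite"):
        VelocityCine(velocity=nan_vel, ed_mask=cine.ed_mask,
                     frame_duration_ms=50.0, pixel_spacing_mm=(1.0, 1.0)).validate()
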