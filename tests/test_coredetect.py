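"""Dense-core detection: each pipeline step against oracles and phantoms."""

import numpy as np
import pytest

from granulemetry.coredetect import (
    Candidate,
    DetectionParams,
    EmVolume,
    detect_cores,
    estimate_background,
    filter_candidates,
    find_core_centers,
    measure_core_grey,
    segment_core,
    subtract_and_smooth,
)
from granulemetry.synth import (
    EmPhantomSpec,
    GranulePopulationSpec,
    GreyComponent,
    generate_em_volume,
)

from _oracles import box_offsets, brute_force_flood, brute_force_opening, ellipsoid_offsets


# ---------------------------------------------------------------------------
# background estimation


def test_background_of_uniform_volume_is_the_volume(iso_geometry):
    data = np.full((8, 8, 8), 57.0)
    bg, noise = estimate_background(data, iso_geometry, radius_nm=25.0)
    assert np.array_equal(bg, data)
    assert noise == 0.0


@pytest.mark.parametrize("element", ["box", "ellipsoid"])
def test_background_matches_brute_force_opening(iso_geometry, rng, element):
    data = rng.integers(0, 255, size=(9, 9, 9)).astype(float)
    bg, _ = estimate_background(data, iso_geometry, radius_nm=22.0, element=element)
    radii = iso_geometry.radius_voxels(22.0)
    offs = box_offsets(radii) if element == "box" else ellipsoid_offsets(radii)
    assert np.allclose(bg, brute_force_opening(data, offs))


def test_background_flat_under_isolated_core(iso_geometry, make_sphere):
    data = np.full((16, 16, 16), 100.0)
    data[make_sphere((16, 16, 16), (8, 8, 8), 3)] = 200.0
    bg, noise = estimate_background(data, iso_geometry, radius_nm=45.0)
    assert np.allclose(bg, 100.0)
    assert noise == 0.0


def test_background_shift_equivariance(iso_geometry, rng):
    data = rng.normal(100, 5, size=(10, 10, 10))
    bg1, n1 = estimate_background(data, iso_geometry, radius_nm=30.0)
    bg2, n2 = estimate_background(data + 17.0, iso_geometry, radius_nm=30.0)
    assert np.allclose(bg2, bg1 + 17.0)
    assert n1 == pytest.approx(n2)


def test_background_rejects_subvoxel_radius(em_geometry):
    # 15 nm is below one z voxel (20 nm) in the anisotropic reference geometry
    with pytest.raises(ValueError):
        estimate_background(np.zeros((4, 4, 4)), em_geometry, radius_nm=15.0)


# ---------------------------------------------------------------------------
# subtraction and smoothing


def test_residual_vanishes_when_volume_equals_background(iso_geometry, rng):
    data = rng.normal(100, 5, size=(8, 8, 8))
    out = subtract_and_smooth(data, data, iso_geometry, smoothing_nm=12.0)
    assert np.allclose(out, 0.0)


def test_smoothing_conserves_mass_of_a_delta(iso_geometry):
    data = np.zeros((21, 21, 21), dtype=float)
    data[10, 10, 10] = 1000.0
    out = subtract_and_smooth(data, np.zeros_like(data), iso_geometry, smoothing_nm=20.0)
    assert out.sum() == pytest.approx(1000.0, rel=1e-4)


def test_zero_smoothing_is_identity(iso_geometry, rng):
    data = rng.normal(100, 5, size=(8, 8, 8))
    bg = np.full_like(data, 90.0)
    out = subtract_and_smooth(data, bg, iso_geometry, smoothing_nm=0.0)
    expected = np.clip(data.astype(np.float32) - np.float32(90.0), 0, None)
    assert np.array_equal(out, expected)


def test_shape_mismatch_is_an_error(iso_geometry):
    with pytest.raises(ValueError):
        subtract_and_smooth(np.zeros((4, 4, 4)), np.zeros((5, 4, 4)), iso_geometry, 5.0)


# ---------------------------------------------------------------------------
# centre finding


def test_flat_residual_gives_no_centers(iso_geometry):
    out = find_core_centers(np.zeros((8, 8, 8)), iso_geometry, DetectionParams(), 0.0)
    assert out == []


def test_two_separated_blobs_give_two_centers(iso_geometry, make_sphere):
    residual = np.zeros((24, 24, 72))
    c1, c2 = (12, 12, 10), (12, 12, 60)  # 500 nm apart at 10 nm pitch
    residual[make_sphere(residual.shape, c1, 5)] = 100.0
    residual[make_sphere(residual.shape, c2, 5)] = 100.0
    params = DetectionParams(min_separation_nm=200.0)
    cands = find_core_centers(residual, iso_geometry, params, noise=5.0)
    assert len(cands) == 2
    found = sorted(c.center_nm[2] for c in cands)
    diag = np.linalg.norm(iso_geometry.spacing_zyx)
    assert abs(found[0] - 100.0) < diag and abs(found[1] - 600.0) < diag


def test_close_blobs_are_suppressed_to_one_center(iso_geometry, make_sphere):
    residual = np.zeros((24, 24, 40))
    residual[make_sphere(residual.shape, (12, 12, 15), 5)] = 100.0
    residual[make_sphere(residual.shape, (12, 12, 25), 5)] = 90.0  # 100 nm away
    params = DetectionParams(min_separation_nm=200.0)
    cands = find_core_centers(residual, iso_geometry, params, noise=5.0)
    assert len(cands) == 1


# ---------------------------------------------------------------------------
# segmentation


def test_segmentation_recovers_binary_sphere_exactly(iso_geometry, make_sphere):
    shape = (16, 16, 16)
    sphere = make_sphere(shape, (8, 8, 8), 3.2)
    residual = np.where(sphere, 100.0, 0.0)
    cand = Candidate(np.array([80.0, 80.0, 80.0]), (8, 8, 8), 100.0)
    voxels = segment_core(residual, iso_geometry, cand, DetectionParams())
    got = {tuple(v) for v in voxels}
    assert got == {tuple(v) for v in np.argwhere(sphere)}
    # agrees with a naive BFS flood fill at the same threshold
    assert got == brute_force_flood(residual >= 50.0, (8, 8, 8))


def test_k_near_one_keeps_only_the_peak_voxel(iso_geometry):
    shape = (11, 11, 11)
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    dist = np.sqrt(sum((g - 5) ** 2 for g in grids))
    residual = np.clip(100.0 - 10.0 * dist, 0, None)  # strict single peak
    cand = Candidate(np.array([50.0, 50.0, 50.0]), (5, 5, 5), 100.0)
    voxels = segment_core(residual, iso_geometry, cand, DetectionParams(k=0.99))
    assert len(voxels) == 1 and tuple(voxels[0]) == (5, 5, 5)


def test_saddle_below_threshold_splits_touching_blobs(iso_geometry, make_sphere):
    residual = np.zeros((16, 16, 32))
    a = make_sphere(residual.shape, (8, 8, 10), 3)
    b = make_sphere(residual.shape, (8, 8, 18), 3)
    residual[a] = 100.0
    residual[b] = 100.0
    residual[8, 8, 14] = 40.0  # bridge below the k=0.5 threshold
    for center, seed in [((80.0, 80.0, 100.0), (8, 8, 10)), ((80.0, 80.0, 180.0), (8, 8, 18))]:
        cand = Candidate(np.array(center), seed, 100.0)
        voxels = segment_core(residual, iso_geometry, cand, DetectionParams())
        got = {tuple(v) for v in voxels}
        assert got == brute_force_flood(residual >= 50.0, seed)
    assert not (a & b).any()


def test_center_below_threshold_drops_candidate(iso_geometry):
    residual = np.zeros((8, 8, 8))
    residual[4, 4, 4] = 100.0
    cand = Candidate(np.array([10.0, 10.0, 10.0]), (4, 4, 4), 100.0)  # centre off-peak
    assert segment_core(residual, iso_geometry, cand, DetectionParams()) is None


# ---------------------------------------------------------------------------
# grey measurement and filters


def test_mean_core_grey():
    data = np.zeros((4, 4, 4))
    data[0, 0, 0], data[0, 0, 1], data[0, 0, 2] = 180.0, 200.0, 220.0
    voxels = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2]])
    assert measure_core_grey(data, voxels) == pytest.approx(200.0)
    with pytest.raises(ValueError):
        measure_core_grey(data, np.empty((0, 3), dtype=int))


def test_filters_reject_small_and_border_cores(iso_geometry, make_sphere):
    from granulemetry.coredetect import CoreDetection

    assert filter_candidates([], (32, 32, 32), iso_geometry, DetectionParams()) == []
    shape = (32, 32, 32)
    # 50 nm diameter core (radius 2.5 voxels at 10 nm) centred in the volume
    small = np.argwhere(make_sphere(shape, (16, 16, 16), 2.5))
    det_small = CoreDetection(np.array([160.0, 160.0, 160.0]), small, 200.0, 210.0, 100.0)
    params = DetectionParams(min_diameter_nm=150.0, max_diameter_nm=700.0)
    assert filter_candidates([det_small], shape, iso_geometry, params) == []
    # a well-sized core passes, the same core hugging a face does not
    big_mask = make_sphere(shape, (16, 16, 16), 10)
    det_big = CoreDetection(
        np.array([160.0, 160.0, 160.0]), np.argwhere(big_mask), 200.0, 210.0, 100.0
    )
    assert filter_candidates([det_big], shape, iso_geometry, params) == [det_big]
    det_edge = CoreDetection(
        np.array([160.0, 160.0, 20.0]), np.argwhere(big_mask), 200.0, 210.0, 100.0
    )
    assert filter_candidates([det_edge], shape, iso_geometry, params) == []


# ---------------------------------------------------------------------------
# full pipeline


def _small_phantom_spec(seed=3, count=6, noise_sd=5.0):
    pop = GranulePopulationSpec(
        count=count,
        diameter_mean_nm=280.0,
        diameter_sd_nm=30.0,
        diameter_bounds_nm=(230.0, 340.0),
        grey=(GreyComponent(1.0, 210.0, 8.0),),
    )
    return EmPhantomSpec(
        shape_zyx=(56, 192, 192), populations={"cell": pop}, noise_sd=noise_sd, seed=seed
    )


def test_background_only_phantom_yields_no_cores():
    spec = EmPhantomSpec(shape_zyx=(24, 48, 48), populations={}, noise_sd=0.0)
    volume, _, _ = generate_em_volume(spec)
    assert detect_cores(volume) == []


def test_detection_matches_ground_truth_on_small_phantom():
    volume, _, truths = generate_em_volume(_small_phantom_spec())
    cores = detect_cores(volume)
    assert len(cores) == len(truths)
    diag = np.linalg.norm(volume.geometry.spacing_zyx)
    true_centers = np.array([t.center_nm for t in truths])
    for core in cores:
        assert np.linalg.norm(true_centers - core.center_nm, axis=1).min() < diag


def test_detection_is_deterministic():
    volume, _, _ = generate_em_volume(_small_phantom_spec())
    first = detect_cores(volume)
    second = detect_cores(volume)
    assert len(first) == len(second)
    for a, b in zip(first, second):
        assert np.array_equal(a.voxels, b.voxels)
        assert a.mean_grey == b.mean_grey


def test_grey_shift_leaves_centers_and_segments_unchanged():
    volume, _, _ = generate_em_volume(_small_phantom_spec(noise_sd=0.0))
    shifted = EmVolume(
        data=np.clip(volume.data.astype(np.int32) + 20, 0, 255).astype(np.uint8),
        geometry=volume.geometry,
    )
    base = detect_cores(volume)
    moved = detect_cores(shifted)
    assert len(base) == len(moved)
    for a, b in zip(base, moved):
        assert np.allclose(a.center_nm, b.center_nm)
        assert np.array_equal(a.voxels, b.voxels)
        assert b.mean_grey == pytest.approx(a.mean_grey + 20.0)


def test_noise_free_grey_measurement_is_exact():
    volume, _, truths = generate_em_volume(_small_phantom_spec(noise_sd=0.0))
    cores = detect_cores(volume)
    assert len(cores) == len(truths)
    true_by_pos = {tuple(np.round(t.center_nm / 10)): t.core_grey for t in truths}
    for core in cores:
        key = tuple(np.round(core.center_nm / 10))
        grey = min(
            (abs(np.linalg.norm(t.center_nm - core.center_nm)), t.core_grey)
            for t in truths
        )[1]
        assert core.mean_grey == pytest.approx(grey)
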