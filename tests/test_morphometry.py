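"""Granule morphometry: grouping, sizing, regions, classification, summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from granulemetry.coredetect import CoreDetection
from granulemetry.morphometry import (
    AnnotationError,
    ClassificationParams,
    GranuleRecord,
    RegionAnnotation,
    assign_region,
    classify_grey,
    compare_distributions,
    equivalent_diameter,
    group_cores_into_granules,
    summarize_population,
    vesicle_density,
)

from _oracles import brute_force_ks


def _core_at(voxel, grey=200.0, n=1):
    """A one-voxel core detection at the given (z, y, x) index."""
    voxels = np.array([voxel])
    center = np.asarray(voxel, dtype=float) * 10.0  # iso 10 nm pitch
    return CoreDetection(center, voxels, grey, grey, 100.0)


class TestGrouping:
    def test_distant_cores_stay_separate(self, iso_geometry):
        cores = [_core_at((0, 0, 0)), _core_at((0, 0, 20))]  # 200 nm apart
        records = group_cores_into_granules(cores, iso_geometry, envelope_radius_nm=50.0)
        assert [r.n_cores for r in records] == [1, 1]

    def test_cores_within_combined_reach_merge(self, iso_geometry):
        cores = [_core_at((0, 0, 0)), _core_at((0, 0, 6))]  # 60 nm apart
        records = group_cores_into_granules(cores, iso_geometry, envelope_radius_nm=50.0)
        assert len(records) == 1
        assert records[0].n_cores == 2
        assert records[0].core_ids == (0, 1)

    def test_multicore_grey_is_voxel_weighted(self, iso_geometry):
        big = CoreDetection(
            np.array([0.0, 0.0, 0.0]),
            np.array([[0, 0, 0], [0, 0, 1], [0, 1, 0]]),
            210.0,
            210.0,
            100.0,
        )
        small = _core_at((0, 0, 4), grey=180.0)
        (record,) = group_cores_into_granules([big, small], iso_geometry, 50.0)
        assert record.mean_grey == pytest.approx((3 * 210 + 1 * 180) / 4)


class TestEquivalentDiameter:
    def test_single_voxel(self, em_geometry):
        d = equivalent_diameter(np.array([[0, 0, 0]]), em_geometry)
        assert d == pytest.approx(2 * np.sqrt(6.7 * 6.7 / np.pi), abs=1e-6)
        assert d == pytest.approx(7.56, abs=0.01)

    def test_uses_the_maximal_plane(self, iso_geometry):
        voxels = [[0, 0, i] for i in range(5)] + [[1, y, x] for y in range(3) for x in range(3)]
        d = equivalent_diameter(np.array(voxels), iso_geometry)
        assert d == pytest.approx(2 * np.sqrt(9 * 100.0 / np.pi))

    def test_digitized_sphere_close_to_nominal(self, iso_geometry, make_sphere):
        # sphere of diameter 45 voxels = 450 nm at 10 nm pitch
        mask = make_sphere((50, 50, 50), (25, 25, 25), 22.5)
        d = equivalent_diameter(np.argwhere(mask), iso_geometry)
        assert abs(d - 450.0) < 10.0  # within one voxel pitch

    def test_empty_set_is_an_error(self, iso_geometry):
        with pytest.raises(ValueError):
            equivalent_diameter(np.empty((0, 3), dtype=int), iso_geometry)


class TestRegions:
    @pytest.fixture
    def annotation(self):
        # 100 nm iso voxels; cell is a 26^3 box inset 2; golgi a central blob
        shape = (30, 30, 30)
        cell = np.zeros(shape, dtype=bool)
        cell[2:28, 2:28, 2:28] = True
        golgi = np.zeros(shape, dtype=bool)
        golgi[13:17, 13:17, 13:17] = True
        return RegionAnnotation(golgi_mask=golgi, cell_mask=cell, periphery_nm=1000.0)

    @pytest.fixture
    def coarse_geometry(self):
        from granulemetry.geometry import VoxelGeometry

        return VoxelGeometry(100.0, 100.0, 100.0)

    def test_near_membrane_is_periphery(self, annotation, coarse_geometry):
        # voxel (3,10,10): 200 nm from the outside -> peripheral
        label = assign_region(np.array([300.0, 1000.0, 1000.0]), annotation, coarse_geometry)
        assert label == "periphery"

    def test_deep_center_in_golgi_mask_is_golgi(self, annotation, coarse_geometry):
        label = assign_region(np.array([1500.0, 1500.0, 1500.0]), annotation, coarse_geometry)
        assert label == "golgi"

    def test_deep_center_outside_golgi_is_other(self, annotation, coarse_geometry):
        label = assign_region(np.array([1500.0, 1500.0, 1200.0]), annotation, coarse_geometry)
        assert label == "other"

    def test_center_outside_cell_is_an_error(self, annotation, coarse_geometry):
        with pytest.raises(AnnotationError):
            assign_region(np.array([0.0, 0.0, 0.0]), annotation, coarse_geometry)

    def test_golgi_mask_must_be_inside_cell(self):
        golgi = np.ones((4, 4, 4), dtype=bool)
        cell = np.zeros((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError):
            RegionAnnotation(golgi_mask=golgi, cell_mask=cell)


def _record(grey, region="golgi", diameter=300.0):
    return GranuleRecord(
        id="g", center_nm=np.zeros(3), diameter_nm=diameter, mean_grey=grey, region=region
    )


class TestClassification:
    @pytest.mark.parametrize(
        "grey,expected",
        [(189.0, "lighter"), (191.0, "denser"), (190.0, "denser")],
    )
    def test_threshold_convention(self, grey, expected):
        assert classify_grey(_record(grey)) == expected


class TestSummary:
    def test_published_wt_counts_reproduce_printed_proportions(self):
        """Golgi 179 granules (21 lighter) + periphery 517 (4 lighter)."""
        records = (
            [_record(170.0, "golgi") for _ in range(21)]
            + [_record(215.0, "golgi") for _ in range(158)]
            + [_record(170.0, "periphery") for _ in range(4)]
            + [_record(215.0, "periphery") for _ in range(513)]
        )
        summary = summarize_population(records)
        assert summary.lighter_share_pct["golgi"] == 84.0
        assert summary.per_region["periphery"]["denser_pct"] == 99.2
        assert summary.per_region["golgi"]["lighter_pct"] == 11.7
        assert summary.per_region["periphery"]["lighter_pct"] == 0.8
        assert summary.n_total == 696
        assert (
            sum(info["count"] for info in summary.per_region.values()) == summary.n_total
        )

    def test_all_denser_gives_zero_lighter_proportions(self):
        summary = summarize_population([_record(220.0, "golgi") for _ in range(5)])
        assert summary.per_region["golgi"]["lighter_pct"] == 0.0
        assert summary.n_lighter == 0

    def test_mean_sem_hand_arithmetic(self):
        records = [_record(215.0, "golgi", diameter=d) for d in (300.0, 340.0, 380.0)]
        summary = summarize_population(records)
        info = summary.per_region["golgi"]
        assert info["diameter_mean_nm"] == pytest.approx(340.0)
        assert info["diameter_sem_nm"] == pytest.approx(23.094, abs=0.001)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            summarize_population([])


class TestKolmogorovSmirnov:
    def test_identical_samples(self):
        stat, _ = compare_distributions([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert stat == pytest.approx(0.0)

    def test_disjoint_supports(self):
        stat, p = compare_distributions([1, 2, 3], [11, 12, 13])
        assert stat == pytest.approx(1.0)
        assert p < 0.2

    def test_half_overlap(self):
        stat, _ = compare_distributions([1, 2], [1, 3])
        assert stat == pytest.approx(0.5)

    @given(
        a=st.lists(st.integers(0, 4), min_size=1, max_size=8),
        b=st.lists(st.integers(0, 4), min_size=1, max_size=8),
    )
    def test_agrees_with_brute_force_ecdf_sup(self, a, b):
        stat, _ = compare_distributions(a, b)
        assert stat == pytest.approx(brute_force_ks(a, b), abs=1e-12)

    def test_empty_sample_is_an_error(self):
        with pytest.raises(ValueError):
            compare_distributions([], [1.0])


class TestVesicleDensity:
    @pytest.mark.parametrize(
        "count,volume,expected",
        [(0, 5.0, 0.0), (580, 1000.0, 0.58), (99, 100.0, 0.99)],
    )
    def test_density(self, count, volume, expected):
        assert vesicle_density(count, volume) == expected

    def test_non_positive_volume_is_an_error(self):
        with pytest.raises(ValueError):
            vesicle_density(10, 0.0)
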