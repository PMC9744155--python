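import numpy as np
import pytest
from shapely.geometry import Point, Polygon, box

from noctule.occurrences import OccurrenceRecord, OccurrenceSet
from noctule.overlap import (
    EnvPointSet,
    gap_analysis,
    overlap_matrix,
    svm_separability,
)
from noctule.overlay import ForestPolygon
from noctule.synth import ProtectedArea


def _clusters(seed=0, sep=10.0, n=30, d=3):
    rng = np.random.default_rng(seed)
    a = EnvPointSet("A", rng.normal(0.0, 1.0, (n, d)))
    b = EnvPointSet("B", rng.normal(sep, 1.0, (n, d)))
    return a, b


def _ring_and_disk(seed=0, n=40):
    rng = np.random.default_rng(seed)
    t = rng.uniform(0, 2 * np.pi, n)
    ring = EnvPointSet("ring", np.column_stack([3 * np.cos(t), 3 * np.sin(t)]))
    disk = EnvPointSet("disk", rng.normal(0, 0.4, (n, 2)))
    return ring, disk


class TestSeparability:
    def test_distant_clusters_separable_linearly(self):
        a, b = _clusters()
        out = svm_separability(a, b, "linear")
        assert out["verdict"] == "non-overlap"
        assert out["n_support_vectors"] >= 2

    def test_identical_sets_overlap_without_fit(self):
        a, _ = _clusters()
        out = svm_separability(a, EnvPointSet("A2", a.points.copy()), "linear")
        assert out["verdict"] == "overlap" and out["n_support_vectors"] == 0

    def test_ring_disk_needs_polynomial_kernel(self):
        ring, disk = _ring_and_disk()
        assert svm_separability(ring, disk, "linear")["verdict"] == "overlap"
        assert svm_separability(ring, disk, "poly2")["verdict"] == "non-overlap"
        # geometric confirmation that no hyperplane separates: the disk's
        # mean lies inside the ring's convex hull, so any halfspace holding
        # the whole ring also holds the disk center
        assert np.linalg.norm(disk.points, axis=1).max() < 3.0

    def test_interleaved_clusters_overlap(self):
        a, b = _clusters(sep=0.5)
        assert svm_separability(a, b, "linear")["verdict"] == "overlap"

    def test_monotone_under_subsetting(self):
        a, b = _clusters(seed=3)
        assert svm_separability(a, b, "linear")["verdict"] == "non-overlap"
        sub_a = EnvPointSet("A", a.points[:10])
        sub_b = EnvPointSet("B", b.points[5:20])
        assert svm_separability(sub_a, sub_b, "linear")["verdict"] == "non-overlap"

    def test_verdict_invariant_to_affine_predictor_rescaling(self):
        for seed in range(3):
            a, b = _clusters(seed=seed, sep=3.0)
            base = svm_separability(a, b, "linear")["verdict"]
            scale = np.array([100.0, 0.01, 5.0])
            shift = np.array([-7.0, 3.0, 0.0])
            a2 = EnvPointSet("A", a.points * scale + shift)
            b2 = EnvPointSet("B", b.points * scale + shift)
            assert svm_separability(a2, b2, "linear")["verdict"] == base

    def test_mismatched_columns_rejected(self):
        a, b = _clusters()
        with pytest.raises(ValueError):
            svm_separability(a, EnvPointSet("B", b.points[:, :2]), "linear")


class TestOverlapMatrix:
    def test_three_distant_clusters_all_nonoverlap(self):
        rng = np.random.default_rng(1)
        sets = [
            EnvPointSet(lbl, rng.normal(mu, 0.5, (20, 2)))
            for lbl, mu in [("A", 0.0), ("B", 10.0), ("C", -10.0)]
        ]
        mat = overlap_matrix(sets, "linear")
        for x in "ABC":
            for y in "ABC":
                expected = "overlap" if x == y else "non-overlap"
                assert mat.verdict(x, y) == expected

    def test_straddling_central_group(self):
        # West and East separable; Central spans both
        rng = np.random.default_rng(2)
        west = EnvPointSet("West", rng.normal(-5.0, 0.5, (25, 2)))
        east = EnvPointSet("East", rng.normal(5.0, 0.5, (25, 2)))
        central = EnvPointSet(
            "Central",
            np.vstack(
                [
                    rng.normal(-5.0, 0.5, (6, 2)),  # intermingled with West
                    rng.normal(0.0, 1.0, (13, 2)),
                    rng.normal(5.0, 0.5, (6, 2)),  # intermingled with East
                ]
            ),
        )
        mat = overlap_matrix([west, central, east], "linear")
        assert mat.verdict("West", "East") == "non-overlap"
        assert mat.verdict("Central", "West") == "overlap"
        assert mat.verdict("Central", "East") == "overlap"

    def test_matrix_symmetric(self):
        rng = np.random.default_rng(3)
        sets = [EnvPointSet(str(i), rng.normal(3 * i, 1.0, (15, 3))) for i in range(4)]
        mat = overlap_matrix(sets, "poly2")
        frame = mat.to_frame()
        assert (frame.to_numpy() == frame.to_numpy().T).all()

    def test_undersized_group_untested_with_warning(self):
        a, b = _clusters()
        tiny = EnvPointSet("tiny", a.points[:2])
        with pytest.warns(UserWarning, match="untested"):
            mat = overlap_matrix([a, b, tiny], "linear")
        assert mat.verdict("A", "tiny") is None
        assert mat.to_frame().loc["A", "tiny"] == "untested"


class TestGapAnalysis:
    def _forest(self, lon, lat):
        return ForestPolygon(
            center=(lon, lat),
            radius_m=1000.0,
            polygon=Point(lon, lat).buffer(0.01),
            area_ha=100.0,
            category="Old-Growth Forest",
        )

    def test_membership_categories(self):
        occ = OccurrenceSet(
            records=[
                OccurrenceRecord(0.5, 0.5),  # natura only
                OccurrenceRecord(2.5, 0.5),  # national only
                OccurrenceRecord(1.25, 0.5),  # overlap zone -> both
                OccurrenceRecord(5.0, 5.0),  # none
                OccurrenceRecord(7.0, 7.0),  # 'both'-kind polygon
            ]
        )
        protected = [
            ProtectedArea(box(0, 0, 1.5, 1), "natura2000"),
            ProtectedArea(box(1.0, 0, 3, 1), "national"),
            ProtectedArea(box(6.5, 6.5, 7.5, 7.5), "both"),
        ]
        out = gap_analysis(occ, protected, [])
        assert list(out["protection"]) == ["natura2000", "national", "both", "none", "both"]

    def test_counts_partition_total(self):
        rng = np.random.default_rng(4)
        occ = OccurrenceSet(
            records=[
                OccurrenceRecord(float(lo), float(la))
                for lo, la in zip(rng.uniform(0, 10, 40), rng.uniform(0, 10, 40))
            ]
        )
        protected = [
            ProtectedArea(box(0, 0, 4, 4), "natura2000"),
            ProtectedArea(box(2, 2, 7, 7), "national"),
        ]
        out = gap_analysis(occ, protected, [])
        counts = out["protection"].value_counts()
        assert counts.sum() == len(occ)

    def test_distance_zero_inside_forest_and_brute_force_outside(self):
        f = self._forest(5.0, 45.0)
        occ = OccurrenceSet(records=[OccurrenceRecord(5.0, 45.0), OccurrenceRecord(6.0, 45.0)])
        out = gap_analysis(occ, [], [f])
        assert out["distance_to_nearest_forest_km"].iloc[0] == 0.0
        # dense-sampling oracle for the outside point
        import shapely

        from noctule.geo import cross_haversine_km

        coords = shapely.get_coordinates(f.polygon.exterior.segmentize(0.001))
        brute = cross_haversine_km([6.0], [45.0], coords[:, 0], coords[:, 1]).min()
        assert out["distance_to_nearest_forest_km"].iloc[1] == pytest.approx(brute, abs=0.1)

    def test_invalid_polygon_repaired_with_warning(self):
        bowtie = Polygon([(0, 0), (1, 1), (1, 0), (0, 1)])  # self-intersecting
        occ = OccurrenceSet(records=[OccurrenceRecord(0.25, 0.25)])
        with pytest.warns(UserWarning, match="repaired"):
            out = gap_analysis(occ, [ProtectedArea(bowtie, "national")], [])
        assert out["protection"].iloc[0] in ("national", "none")
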