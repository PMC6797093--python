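"""Tests for centroid fusion within and across altitudes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bananacount as bc
from bananacount.detection import BoundingBox, DetectionSet
from bananacount.fusion import (
    AltitudeTransform,
    MergeSpec,
    PlantPoint,
    box_centroid,
    estimate_transform,
    fuse_altitudes,
    fuse_variants,
    load_plant_points,
    merge_within,
    save_plant_points,
    to_mosaic_coords,
    transform_points,
)
from bananacount.tiling import plan_grid

int_points = st.lists(
    st.tuples(st.integers(0, 500), st.integers(0, 500)), min_size=0, max_size=40
)


def _nx_oracle(coords, threshold):
    """Independent single-linkage oracle: all-pairs graph components."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(coords)))
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            if np.hypot(*(np.asarray(coords[i]) - coords[j])) <= threshold:
                g.add_edge(i, j)
    return sorted(
        tuple(sorted(c)) for c in nx.connected_components(g)
    )


class TestCentroids:
    @pytest.mark.parametrize(
        "box,expected",
        [(BoundingBox(10, 20, 50, 60), (30, 40)), (BoundingBox(0, 0, 600, 600), (300, 300))],
    )
    def test_box_centroid(self, box, expected):
        assert box_centroid(box) == expected
        cx, cy = box_centroid(box)
        assert box.xmin <= cx <= box.xmax and box.ymin <= cy <= box.ymax

    @pytest.mark.parametrize(
        "pt,origin,expected",
        [((30, 40), (550, 1100), (580, 1140)), ((0, 0), (0, 0), (0, 0))],
    )
    def test_to_mosaic_coords(self, pt, origin, expected):
        assert to_mosaic_coords(pt, origin) == expected


class TestMergeWithin:
    def test_pair_within_threshold(self):
        out = merge_within([(0, 0), (10, 0)], MergeSpec(30))
        assert len(out) == 1 and (out[0].x, out[0].y, out[0].members) == (5, 0, 2)

    def test_pair_beyond_threshold(self):
        out = merge_within([(0, 0), (31, 0)], MergeSpec(30))
        assert len(out) == 2

    def test_chain_merges_through_middle(self):
        out = merge_within([(0, 0), (25, 0), (50, 0)], MergeSpec(30))
        assert len(out) == 1 and (out[0].x, out[0].y, out[0].members) == (25, 0, 3)

    def test_empty_input(self):
        assert merge_within([], MergeSpec(30)) == []

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(pts=int_points)
    def test_never_increases_and_idempotent(self, pts):
        spec = MergeSpec(30)
        out = merge_within(pts, spec)
        assert len(out) <= max(len(pts), 1) if pts else out == []
        again = merge_within(out, spec)
        assert len(again) <= len(out)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(pts=int_points, shift=st.tuples(st.integers(-100, 100), st.integers(-100, 100)))
    def test_permutation_and_translation_invariance(self, pts, shift):
        spec = MergeSpec(30)
        base = merge_within(pts, spec)
        perm = merge_within(list(reversed(pts)), spec)
        assert [(p.x, p.y, p.members) for p in base] == [(p.x, p.y, p.members) for p in perm]
        dx, dy = shift
        moved = merge_within([(x + dx, y + dy) for x, y in pts], spec)
        assert [p.members for p in moved] == [p.members for p in base]
        # cluster structure is translation-invariant; means agree to rounding
        np.testing.assert_allclose(
            [(p.x - dx, p.y - dy) for p in moved],
            [(p.x, p.y) for p in base],
            atol=1e-9,
        )

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(pts=int_points)
    def test_matches_graph_component_oracle(self, pts):
        spec = MergeSpec(30)
        out = merge_within(pts, spec)
        clusters = _nx_oracle(pts, 30)
        assert len(out) == len(clusters)
        got = sorted((round(p.x, 6), round(p.y, 6)) for p in out)
        want = sorted(
            (
                round(float(np.mean([pts[i][0] for i in c])), 6),
                round(float(np.mean([pts[i][1] for i in c])), 6),
            )
            for c in clusters
        )
        assert got == want


class TestFuseVariants:
    def _set(self, variant, records):
        return DetectionSet(records, variant_tag=variant, altitude_tag="40m")

    def test_single_box_restored(self):
        grid = plan_grid(1200, 700, 600, 50)
        ds = self._set("TGI", [("tile_550_0", BoundingBox(10, 20, 50, 60))])
        out = fuse_variants([ds], grid, MergeSpec(30))
        assert len(out) == 1 and (out[0].x, out[0].y) == (580, 40)
        assert out[0].sources == frozenset({("TGI", "40m")})

    def test_same_plant_in_three_variants_merges_to_one(self):
        grid = plan_grid(1200, 700, 600, 50)
        sets = [
            self._set(v, [("tile_0_0", BoundingBox(100 + d, 100, 140 + d, 140))])
            for v, d in [("LCS", 0), ("SCT", 5), ("TGI", -5)]
        ]
        out = fuse_variants(sets, grid, MergeSpec(30))
        assert len(out) == 1 and out[0].members == 3
        assert out[0].sources == {("LCS", "40m"), ("SCT", "40m"), ("TGI", "40m")}

    def test_duplicate_in_overlapping_tiles_merges(self):
        # the same plant at mosaic (570, 100) seen from tile_0_0 and tile_550_0
        grid = plan_grid(1200, 700, 600, 50)
        ds = self._set(
            "TGI",
            [
                ("tile_0_0", BoundingBox(550, 80, 590, 120)),
                ("tile_550_0", BoundingBox(0, 80, 40, 120)),
            ],
        )
        out = fuse_variants([ds], grid, MergeSpec(30))
        assert len(out) == 1 and out[0].x == pytest.approx(570) and out[0].members == 2

    def test_mixed_altitudes_rejected(self):
        grid = plan_grid(1200, 700, 600, 50)
        a = DetectionSet([], variant_tag="LCS", altitude_tag="40m")
        b = DetectionSet([], variant_tag="LCS", altitude_tag="50m")
        with pytest.raises(ValueError):
            fuse_variants([a, b], grid, MergeSpec(30))


class TestAltitudeTransform:
    def test_identity_unchanged(self):
        pts = [(12.5, 9.75), (0, 0)]
        out = transform_points(pts, AltitudeTransform.identity())
        assert [(p.x, p.y) for p in out] == pts

    def test_50m_to_40m_parameters(self):
        t = AltitudeTransform(10032 / 7877, 7048 / 5534, -81.996, 38.003)
        (origin,) = transform_points([(0, 0)], t)
        assert (origin.x, origin.y) == (-81.996, 38.003)
        (edge,) = transform_points([(7877, 0)], t)
        assert edge.x == pytest.approx(9950.004)

    def test_scale_must_be_positive(self):
        with pytest.raises(ValueError):
            AltitudeTransform(x_scale=0.0)

    def test_estimate_transform_recovers_parameters(self):
        t = AltitudeTransform(1.2735, 1.2736, -81.996, 38.003)
        src = [(0, 0), (1000, 500), (7877, 5534), (250, 4000)]
        dst = [(p.x, p.y) for p in transform_points(src, t)]
        est = estimate_transform(src, dst)
        assert est.x_scale == pytest.approx(t.x_scale)
        assert est.y_shift == pytest.approx(t.y_shift)


class TestFuseAltitudes:
    def test_identity_duplicates_dedup(self):
        pts = [PlantPoint(100, 100), PlantPoint(300, 300)]
        fused = fuse_altitudes(
            {"40m": pts, "50m": pts},
            {"50m": AltitudeTransform.identity()},
            reference="40m",
        )
        assert len(fused) == 2

    def test_union_semantics(self):
        fused = fuse_altitudes(
            {"40m": [PlantPoint(100, 100)], "50m": [PlantPoint(500, 500)]},
            {"50m": AltitudeTransform.identity()},
            reference="40m",
        )
        assert len(fused) == 2

    def test_count_never_exceeds_sum(self):
        rng = np.random.default_rng(8)
        a = [PlantPoint(*p) for p in rng.uniform(0, 1000, (50, 2))]
        b = [PlantPoint(*p) for p in rng.uniform(0, 1000, (70, 2))]
        fused = fuse_altitudes(
            {"40m": a, "50m": b}, {"50m": AltitudeTransform.identity()}, "40m"
        )
        assert len(fused) <= 120

    def test_missing_transform_rejected(self):
        with pytest.raises(ValueError):
            fuse_altitudes({"40m": [], "50m": []}, {}, reference="40m")

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            fuse_altitudes({"50m": []}, {}, reference="40m")


def test_plant_points_csv_roundtrip(tmp_path):
    pts = [
        PlantPoint(1.5, 2.25, frozenset({("TGI", "40m"), ("LCS", "40m")}), members=3),
        PlantPoint(10, 20),
    ]
    path = tmp_path / "pts.csv"
    save_plant_points(pts, path)
    loaded = load_plant_points(path)
    assert [(p.x, p.y, p.members, p.sources) for p in loaded] == [
        (p.x, p.y, p.members, p.sources) for p in pts
    ]
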