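import itertools

import numpy as np
import pytest

from leafsurf.errors import FrameError, InputError, SchemaError
from leafsurf.patterning import (
    Leaf,
    LeafFrame,
    MetaLeaf,
    Trichome,
    base_distance,
    build_metaleaf,
    class_abundance,
    compare_genotypes,
    density,
    leaf_morphometrics,
    load_annotations,
    longitudinal_profile,
    metaleaf_histogram,
    select_leaf,
    to_frame,
    wilcoxon_ranksum,
    write_annotations,
)
from leafsurf.segmentation import LeafMask, _trace_boundary
from leafsurf.stackio import Calibration
from leafsurf.surface import SurfaceMesh

CAL = Calibration(um_per_px=1.0, um_per_slice=1.0)


def _trich(classes, positions=None):
    if positions is None:
        positions = [(10 * k, 5 * k) for k in range(len(classes))]
    return [
        Trichome(id=f"t{k}", xy_px=p, cls=c)
        for k, (p, c) in enumerate(zip(positions, classes))
    ]


def _frame(origin=(0, 0), tip=(0, 100)):
    return LeafFrame(origin_um=np.asarray(origin, float), tip_um=np.asarray(tip, float))


def _flat_mesh(side=20.0, n=10):
    g = np.linspace(0, side, n)
    X, Y = np.meshgrid(g, g)
    return SurfaceMesh.from_grid(X, Y, np.zeros_like(X))


class TestAnnotations:
    def test_json_roundtrip(self, tmp_path):
        tr = _trich([1, 2, 4])
        write_annotations(tmp_path / "a.json", "L1", "wt", tr, ((5, 6), (5, 106)))
        back, frame, genotype = load_annotations(tmp_path / "a.json", CAL)
        assert genotype == "wt" and len(back) == 3
        assert [t.cls for t in back] == [1, 2, 4]
        np.testing.assert_allclose(frame.origin_um, [5, 6])
        np.testing.assert_allclose(frame.tip_um, [5, 106])

    def test_unknown_class_rejected(self, tmp_path):
        import json

        doc = {
            "leaf_id": "L1",
            "genotype": "wt",
            "frame": {"origin_px": [0, 0], "tip_px": [0, 10]},
            "trichomes": [{"id": "t0", "x_px": 1, "y_px": 1, "class": 5}],
        }
        (tmp_path / "bad.json").write_text(json.dumps(doc))
        with pytest.raises(SchemaError, match="t0"):
            load_annotations(tmp_path / "bad.json", CAL)

    def test_missing_frame_rejected(self, tmp_path):
        import json

        doc = {"leaf_id": "L", "genotype": "wt", "frame": {}, "trichomes": []}
        (tmp_path / "bad.json").write_text(json.dumps(doc))
        with pytest.raises(SchemaError):
            load_annotations(tmp_path / "bad.json", CAL)

    def test_csv_schema(self, tmp_path):
        rows = "leaf_id,genotype,trichome_id,x_px,y_px,class,origin_x_px,origin_y_px,tip_x_px,tip_y_px\n"
        rows += "L1,wt,t0,10,20,1,0,0,0,50\nL1,wt,t1,12,30,4,0,0,0,50\n"
        (tmp_path / "a.csv").write_text(rows)
        tr, frame, genotype = load_annotations(tmp_path / "a.csv", CAL)
        assert len(tr) == 2 and tr[1].cls == 4
        assert frame.scale_um == 50.0

    def test_calibration_scales_frame(self, tmp_path):
        tr = _trich([1])
        write_annotations(tmp_path / "a.json", "L", "wt", tr, ((0, 0), (0, 10)))
        _, frame, _ = load_annotations(
            tmp_path / "a.json", Calibration(um_per_px=2.5, um_per_slice=1.0)
        )
        assert frame.scale_um == 25.0


class TestSelection:
    @pytest.mark.parametrize(
        "n_mature,accept", [(0, False), (1, True), (6, True), (7, False)]
    )
    def test_mature_count_rule(self, n_mature, accept):
        tr = _trich([1, 2] + [4] * n_mature)
        assert select_leaf(tr) is accept


class TestLeafFrame:
    def test_origin_maps_to_zero(self):
        f = _frame((10, 20), (10, 120))
        np.testing.assert_allclose(to_frame((10, 20), f), [0, 0], atol=1e-12)

    def test_tip_maps_to_unit_y(self):
        f = _frame((10, 20), (60, 80))
        np.testing.assert_allclose(to_frame((60, 80), f), [0, 1], atol=1e-12)

    def test_degenerate_frame_rejected(self):
        with pytest.raises(FrameError):
            _frame((5, 5), (5, 5))

    def test_similarity_invariance(self, rng):
        pts = rng.uniform(0, 100, size=(10, 2))
        f = _frame((20, 10), (30, 90))
        ref = np.array([to_frame(p, f) for p in pts])
        theta, s = 0.7, 2.3
        R = s * np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        t = np.array([55.0, -12.0])
        f2 = LeafFrame(origin_um=R @ f.origin_um + t, tip_um=R @ f.tip_um + t)
        moved = np.array([to_frame(R @ p + t, f2) for p in pts])
        np.testing.assert_allclose(moved, ref, atol=1e-10)

    def test_centroid_suggestion(self):
        m = np.zeros((50, 30), bool)
        m[5:45, 10:20] = True
        mask = LeafMask(mask=m, boundary=_trace_boundary(m))
        f = LeafFrame.suggest_from_mask(mask, origin_um=(14.5, 44.0))
        assert f.tip_um[1] < f.origin_um[1]  # axis points up the mask


class TestMetaLeaf:
    def _leaf(self, leaf_id="L1", genotype="wt", classes=(1, 2, 4)):
        return Leaf(
            leaf_id=leaf_id,
            genotype=genotype,
            trichomes=_trich(list(classes)),
            frame=_frame(),
            cal=CAL,
        )

    def test_pooling_counts(self):
        meta = build_metaleaf([self._leaf("L1"), self._leaf("L2")])
        assert len(meta) == 6

    def test_duplicated_leaf_duplicates_records(self):
        leaf = self._leaf()
        meta = build_metaleaf([leaf, leaf])
        r = meta.records
        assert len(r) == 2 * len(leaf.trichomes)
        for c in (1, 2, 4):
            assert (r["cls"] == c).sum() == 2

    def test_per_class_counts_preserved(self, rng):
        classes = rng.integers(1, 5, size=12).tolist()
        classes += [4] if 4 not in classes else []
        leaf = self._leaf(classes=classes)
        if not select_leaf(leaf.trichomes):
            pytest.skip("random draw produced > 6 matures")
        meta = build_metaleaf([leaf])
        for c in range(1, 5):
            assert (meta.records["cls"] == c).sum() == classes.count(c)

    def test_unselected_leaf_rejected(self):
        bad = self._leaf(classes=(1, 2, 3))  # no mature trichome
        with pytest.raises(InputError, match="L1"):
            build_metaleaf([bad])

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            build_metaleaf([])


class TestProfilesAndHistograms:
    def _meta(self, ys, classes):
        import pandas as pd

        return MetaLeaf(
            records=pd.DataFrame(
                {
                    "leaf_id": "L",
                    "genotype": "wt",
                    "cls": classes,
                    "x": 0.0,
                    "y": ys,
                }
            )
        )

    def test_single_class_profile(self):
        meta = self._meta([0.1, 0.4, 0.9], [1, 1, 1])
        prof = longitudinal_profile(meta, n_bins=3)
        occ = prof[prof["occupied"]]
        np.testing.assert_allclose(occ["p1"], 1.0)
        np.testing.assert_allclose(occ[["p2", "p3", "p4"]], 0.0)

    def test_proportions_sum_to_one(self, rng):
        meta = self._meta(rng.uniform(0, 1, 50), rng.integers(1, 5, 50))
        prof = longitudinal_profile(meta, n_bins=7)
        occ = prof[prof["occupied"]]
        np.testing.assert_allclose(occ[["p1", "p2", "p3", "p4"]].sum(axis=1), 1.0)

    def test_hand_binned_fixture(self):
        ys = [0.05, 0.15, 0.18, 0.35, 0.55, 0.58, 0.75, 0.85, 0.9, 0.95]
        cl = [1, 1, 2, 1, 3, 3, 4, 4, 4, 4]
        prof = longitudinal_profile(self._meta(ys, cl), n_bins=2)
        # bin 1 (y < 0.475): classes 1,1,2,1 -> p1 = 3/4; bin 2: 3,3,4x4
        assert prof.loc[0, "n"] == 4 and prof.loc[0, "p1"] == pytest.approx(0.75)
        assert prof.loc[1, "n"] == 6 and prof.loc[1, "p4"] == pytest.approx(4 / 6)

    def test_invalid_bins(self):
        with pytest.raises(InputError):
            longitudinal_profile(self._meta([0.5], [1]), n_bins=0)

    def test_histogram_totals(self, rng):
        n = 40
        meta = self._meta(rng.uniform(0, 1, n), rng.integers(1, 5, n))
        meta.records["x"] = rng.uniform(-0.5, 0.5, n)
        counts, _, _ = metaleaf_histogram(meta, grid=(5, 4))
        assert counts.sum() == n
        counts1, _, _ = metaleaf_histogram(meta, grid=(1, 1))
        for c in range(1, 5):
            assert counts1[c - 1].sum() == (meta.records["cls"] == c).sum()

    def test_histogram_matches_brute_force(self, rng):
        n = 30
        meta = self._meta(rng.uniform(0, 1, n), rng.integers(1, 5, n))
        meta.records["x"] = rng.uniform(-1, 1, n)
        counts, xe, ye = metaleaf_histogram(meta, grid=(4, 3))
        r = meta.records
        for c in range(1, 5):
            sel = r[r["cls"] == c]
            for iy in range(3):
                for ix in range(4):
                    expect = (
                        (sel["x"] >= xe[ix]) & (sel["x"] < xe[ix + 1])
                        & (sel["y"] >= ye[iy]) & (sel["y"] < ye[iy + 1])
                    ).sum()
                    assert counts[c - 1, iy, ix] == expect


class TestBaseDistanceAndDensity:
    def test_baseline_and_tip(self):
        f = _frame()
        tr = [
            Trichome(id="a", xy_px=(30, 0), cls=1),  # on the baseline
            Trichome(id="b", xy_px=(0, 100), cls=4),  # at the axis tip
        ]
        df = base_distance(tr, f, CAL)
        assert df.loc[0, "y_norm"] == pytest.approx(0.0, abs=1e-12)
        assert df.loc[1, "y_norm"] == pytest.approx(1.0, abs=1e-12)
        assert df.loc[1, "y_um"] == pytest.approx(100.0)

    def test_ordering_invariant_under_similarity(self, rng):
        f = _frame((5, 5), (25, 80))
        pts = rng.uniform(0, 100, size=(8, 2))
        tr = _trich([1] * 8, positions=pts)
        order = np.argsort(base_distance(tr, f, CAL)["y_norm"].to_numpy())
        R = 1.7 * np.array([[0, -1], [1, 0]])
        f2 = LeafFrame(origin_um=R @ f.origin_um + 3, tip_um=R @ f.tip_um + 3)
        tr2 = _trich([1] * 8, positions=[R @ p + 3 for p in pts])
        order2 = np.argsort(base_distance(tr2, f2, CAL)["y_norm"].to_numpy())
        np.testing.assert_array_equal(order, order2)

    def test_density_flat_mesh(self):
        mesh = _flat_mesh(side=20.0)  # 400 µm²
        tr = _trich([1, 2, 3, 4])
        d = density(tr, mesh)
        assert d["total"] == pytest.approx(0.01)
        assert sum(d[c] for c in (1, 2, 3, 4)) == pytest.approx(d["total"])

    def test_density_additivity(self, rng):
        mesh = _flat_mesh()
        classes = rng.integers(1, 5, 9).tolist()
        d = density(_trich(classes), mesh)
        assert sum(d[c] for c in (1, 2, 3, 4)) == pytest.approx(d["total"])


class TestAbundance:
    def _leaf(self, leaf_id, genotype, classes):
        return Leaf(leaf_id=leaf_id, genotype=genotype, trichomes=_trich(classes),
                    frame=_frame(), cal=CAL)

    def test_identical_leaves_zero_sd(self):
        leaves = [self._leaf(f"L{k}", "wt", [1, 2, 4, 4]) for k in range(3)]
        df = class_abundance(leaves)
        assert np.allclose(df["sd_pct"], 0.0)

    def test_proportions_sum_to_100(self):
        leaves = [self._leaf("L1", "wt", [1, 1, 2, 3, 4])]
        df = class_abundance(leaves)
        assert df["mean_pct"].sum() == pytest.approx(100.0)

    def test_three_leaf_hand_computation(self):
        leaves = [
            self._leaf("L1", "wt", [1, 4]),        # 50% class 1
            self._leaf("L2", "wt", [1, 1, 4, 4]),  # 50% class 1
            self._leaf("L3", "wt", [4, 4]),        # 0% class 1
        ]
        df = class_abundance(leaves).set_index("cls")
        assert df.loc[1, "mean_pct"] == pytest.approx(100 / 3)
        assert df.loc[4, "mean_pct"] == pytest.approx(200 / 3)
        assert df.loc[1, "sd_pct"] == pytest.approx(np.std([50, 50, 0]))


class TestMorphometrics:
    def _mask(self, rx, ry, shape=(160, 160), angle=0.0):
        h, w = shape
        yy, xx = np.mgrid[0:h, 0:w]
        xr = (xx - w / 2) * np.cos(angle) + (yy - h / 2) * np.sin(angle)
        yr = -(xx - w / 2) * np.sin(angle) + (yy - h / 2) * np.cos(angle)
        m = (xr / rx) ** 2 + (yr / ry) ** 2 <= 1
        return LeafMask(mask=m, boundary=_trace_boundary(m))

    def test_circle_index_one(self):
        mask = self._mask(50, 50)
        out = leaf_morphometrics(mask, _frame((80, 155), (80, 20)), _flat_mesh())
        assert out["leaf_index"] == pytest.approx(1.0, abs=0.02)

    def test_two_to_one_ellipse(self):
        mask = self._mask(30, 60)
        out = leaf_morphometrics(mask, _frame((80, 150), (80, 10)), _flat_mesh())
        assert out["leaf_index"] == pytest.approx(0.5, abs=0.02)

    def test_index_rotation_invariant(self):
        a = self._mask(30, 60)
        b = self._mask(30, 60, angle=np.deg2rad(35))
        f = _frame((80, 150), (80, 10))
        ia = leaf_morphometrics(a, f, _flat_mesh())["leaf_index"]
        ib = leaf_morphometrics(b, f, _flat_mesh())["leaf_index"]
        assert ia == pytest.approx(ib, abs=0.01)

    def test_length_along_frame_axis(self):
        mask = self._mask(30, 60)
        f = _frame((80, 140), (80, 20))  # axis pointing up the image
        out = leaf_morphometrics(mask, f, _flat_mesh())
        assert out["length_um"] == pytest.approx(120, abs=2)  # base at y=140, top at 20


def _enumeration_pvalue(a, b):
    """Exact two-sided rank-sum p by enumeration of all rank assignments."""
    pooled = np.concatenate([a, b])
    na, n = len(a), len(pooled)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    u_obs = ranks[:na].sum() - na * (na + 1) / 2
    mu = na * len(b) / 2
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), na):
        u = sum(ranks[list(idx)]) - na * (na + 1) / 2
        total += 1
        if abs(u - mu) >= abs(u_obs - mu) - 1e-12:
            count += 1
    return count / total


class TestWilcoxon:
    def test_separated_samples_exact_p(self):
        _, p = wilcoxon_ranksum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1)

    def test_identical_samples(self):
        _, p = wilcoxon_ranksum([1, 2, 3], [1, 2, 3])
        assert p == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(InputError):
            wilcoxon_ranksum([], [1, 2])

    def test_matches_enumeration(self, rng):
        for na in range(2, 7):
            for nb in range(2, 7):
                a = rng.normal(size=na)
                b = rng.normal(size=nb)
                _, p = wilcoxon_ranksum(a, b)
                assert p == pytest.approx(_enumeration_pvalue(a, b), abs=1e-12)

    def test_large_sample_normal_path(self, rng):
        from scipy import stats as sps

        a = rng.normal(0, 1, 40)
        b = rng.normal(0, 1, 45)
        _, p = wilcoxon_ranksum(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=0.01)


class TestCompareGenotypes:
    def test_self_comparison_all_p_one(self):
        stats = {
            ("density", 1): np.array([0.1, 0.2, 0.3]),
            ("voronoi2d", 2): np.array([5.0, 6.0, 7.0, 8.0]),
            ("leaf_index", None): np.array([0.8, 0.85]),
        }
        report = compare_genotypes(stats, stats)
        tested = report[report["tested"]]
        assert np.allclose(tested["p"], 1.0)

    def test_class4_not_tested(self):
        stats_a = {("density", 4): np.array([1.0, 2.0])}
        stats_b = {("density", 4): np.array([3.0, 4.0])}
        report = compare_genotypes(stats_a, stats_b)
        row = report.iloc[0]
        assert not row["tested"] and "mature" in row["note"]

    def test_shifted_distribution_detected(self, rng):
        areas_a = rng.normal(1000, 200, 30)
        areas_b = rng.normal(1200, 200, 30)  # 1 SD shift
        report = compare_genotypes(
            {("voronoi2d", 1): areas_a}, {("voronoi2d", 1): areas_b}
        )
        assert report.iloc[0]["p"] < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(InputError):
            compare_genotypes([], [Leaf("L", "wt", _trich([4]), _frame(), CAL)])
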