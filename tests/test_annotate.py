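"""Minimum-distance segmentation and the annotation report."""

import json

import numpy as np
import pandas as pd
import pytest

from hepatree.annotate import (SegmentMap, classify_voxels, group_voxels,
                               lobe_report, segment_attributes, write_report)
from hepatree.hierarchy import BranchDivision, Subtree
from oracles import brute_force_classify

# the published per-segment voxel counts used as worked-example input
TABLE2_NSEG = [53062, 78287, 169190, 115116, 58760, 144737, 152095, 157323]
TABLE2_RSEG = [5.71, 8.43, 18.22, 12.40, 6.33, 15.59, 16.38, 16.94]
IDENTITY_RELABEL = {i + 1: n for i, n in enumerate(
    ["SegI", "SegII", "SegIII", "SegIV", "SegV", "SegVI", "SegVII",
     "SegVIII"])}


def division_from_points(points_by_label):
    """Minimal BranchDivision whose groups are explicit voxel sets."""
    import networkx as nx
    subtrees, labels = [], []
    for lab, pts in sorted(points_by_label.items()):
        g = nx.MultiDiGraph()
        for p in pts:
            g.add_node(tuple(p), position_mm=tuple(map(float, p)))
        subtrees.append(Subtree(root=tuple(pts[0]),
                                vertices=[tuple(p) for p in pts],
                                edges=[], graph=g))
        labels.append(lab)
    return BranchDivision(subtrees=subtrees, labels=labels,
                          K=len(subtrees))


class TestClassify:
    def test_single_group_labels_everything(self):
        liver = np.zeros((8, 8, 8), bool)
        liver[1:7, 1:7, 1:7] = True
        div = division_from_points({1: [(3, 3, 3)]})
        seg = classify_voxels(liver, div, (1, 1, 1))
        assert (seg.labels[liver] == 1).all()
        assert (seg.labels[~liver] == 0).all()

    def test_nearer_group_wins(self):
        liver = np.zeros((5, 5, 9), bool)
        liver[2, 2, :] = True
        div = division_from_points({1: [(2, 2, 1)], 2: [(2, 2, 7)]})
        seg = classify_voxels(liver, div, (1, 1, 1))
        assert seg.labels[2, 2, 2] == 1   # 1 mm vs 5 mm
        assert seg.labels[2, 2, 6] == 2

    def test_equidistant_voxel_takes_lower_label(self):
        liver = np.zeros((5, 5, 9), bool)
        liver[2, 2, :] = True
        div = division_from_points({1: [(2, 2, 0)], 2: [(2, 2, 8)]})
        seg = classify_voxels(liver, div, (1, 1, 1))
        assert seg.labels[2, 2, 4] == 1

    def test_anisotropic_spacing_honored(self):
        liver = np.ones((3, 3, 5), bool)
        div = division_from_points({1: [(0, 1, 2)], 2: [(2, 1, 2)]})
        # z spacing 5 mm: voxel (1, y, x) is 5 mm from either group; the
        # x-offset voxels resolve by z-distance only
        seg = classify_voxels(liver, div, (5.0, 1.0, 1.0))
        assert seg.labels[0, 0, 0] == 1 and seg.labels[2, 0, 0] == 2

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        liver = np.zeros((24, 24, 24), bool)
        liver[3:21, 3:21, 3:21] = True
        groups = {}
        for lab in (1, 2, 3):
            pts = rng.integers(4, 20, size=(6, 3))
            groups[lab] = [tuple(p) for p in pts]
        div = division_from_points(groups)
        spacing = (1.0, 0.8, 1.2)
        seg = classify_voxels(liver, div, spacing)
        brute = brute_force_classify(
            liver, {k: np.asarray(v) for k, v in groups.items()}, spacing)
        assert (seg.labels == brute).all()

    def test_empty_liver_raises(self):
        div = division_from_points({1: [(0, 0, 0)]})
        with pytest.raises(ValueError, match="empty"):
            classify_voxels(np.zeros((3, 3, 3), bool), div, (1, 1, 1))


class TestSegmentAttributes:
    def test_published_counts_reproduce_ratios(self):
        attrs = segment_attributes(None, n_seg=TABLE2_NSEG)
        assert list(attrs["r_seg_pct"]) == TABLE2_RSEG
        assert attrs["r_seg_pct"].sum() == pytest.approx(100.0, abs=0.01)

    def test_volumes_scale_with_spacing(self):
        attrs = segment_attributes(None, n_seg=TABLE2_NSEG,
                                   spacing=(1.0, 1.0, 1.0))
        assert list(attrs["v_seg_ml"]) == [
            53.06, 78.29, 169.19, 115.12, 58.76, 144.74, 152.1, 157.32]

    def test_equal_segments(self):
        attrs = segment_attributes(None, n_seg=[1000] * 8)
        assert (attrs["r_seg_pct"] == 12.5).all()

    def test_no_tumors_zero_burden(self):
        labels = np.zeros((6, 6, 6), np.int32)
        labels[1:5, 1:5, 1:3] = 1
        labels[1:5, 1:5, 3:5] = 2
        seg = SegmentMap(labels, (1.0, 1.0, 1.0))
        attrs = segment_attributes(seg)
        assert (attrs["r_tumor_pct"] == 0).all()

    def test_tumor_burden_counts(self):
        labels = np.zeros((6, 6, 6), np.int32)
        labels[1:5, 1:5, 1:3] = 1
        labels[1:5, 1:5, 3:5] = 2
        tumors = np.zeros((6, 6, 6), bool)
        tumors[1:3, 1:3, 1:3] = True  # 8 voxels, all in segment 1
        seg = SegmentMap(labels, (1.0, 1.0, 1.0))
        attrs = segment_attributes(seg, tumors=tumors)
        assert attrs.loc[0, "r_tumor_pct"] == pytest.approx(
            100.0 * 8 / 32, abs=0.01)
        assert attrs.loc[1, "r_tumor_pct"] == 0


class TestLobeReport:
    def test_published_lobe_ratios(self):
        attrs = segment_attributes(None, n_seg=TABLE2_NSEG)
        lobes = lobe_report(attrs, IDENTITY_RELABEL).set_index("lobe")
        assert lobes.loc["caudal_lobe", "ratio_pct"] == 5.71
        assert lobes.loc["left_lateral_lobe", "ratio_pct"] == 26.65
        assert lobes.loc["left_medial_lobe", "ratio_pct"] == 12.40
        assert lobes.loc["right_anterior_lobe", "ratio_pct"] == 23.27
        assert lobes.loc["right_posterior_lobe", "ratio_pct"] == 31.97
        assert lobes.loc["left_lobe", "ratio_pct"] == 39.05
        assert lobes.loc["right_lobe", "ratio_pct"] == 55.24

    def test_uniform_split(self):
        attrs = segment_attributes(None, n_seg=[100] * 8)
        lobes = lobe_report(attrs, IDENTITY_RELABEL).set_index("lobe")
        assert lobes.loc["left_lobe", "ratio_pct"] == 37.50
        assert lobes.loc["right_lobe", "ratio_pct"] == 50.00

    def test_incomplete_relabel_raises(self):
        attrs = segment_attributes(None, n_seg=TABLE2_NSEG)
        with pytest.raises(ValueError, match="missing"):
            lobe_report(attrs, {1: "SegI"})

    def test_lobe_sums_consistent(self):
        attrs = segment_attributes(None, n_seg=TABLE2_NSEG)
        lobes = lobe_report(attrs, IDENTITY_RELABEL).set_index("lobe")
        assert (lobes.loc["left_lateral_lobe", "n_voxels"]
                + lobes.loc["left_medial_lobe", "n_voxels"]
                == lobes.loc["left_lobe", "n_voxels"])
        assert (lobes.loc["right_anterior_lobe", "n_voxels"]
                + lobes.loc["right_posterior_lobe", "n_voxels"]
                == lobes.loc["right_lobe", "n_voxels"])


class TestWriteReport:
    @pytest.fixture()
    def small_run(self):
        liver = np.zeros((12, 12, 12), bool)
        liver[2:10, 2:10, 2:10] = True
        div = division_from_points({1: [(4, 4, 4)], 2: [(8, 8, 8)]})
        seg = classify_voxels(liver, div, (1, 1, 1))
        tumors = np.zeros_like(liver)
        tumors[3:5, 3:5, 3:5] = True
        attrs = segment_attributes(seg, tumors=tumors)
        lobes = lobe_report(
            segment_attributes(None, n_seg=TABLE2_NSEG), IDENTITY_RELABEL)
        return seg, attrs, lobes, tumors

    def test_rerun_byte_identical(self, small_run, tmp_path):
        seg, attrs, lobes, tumors = small_run
        blobs = []
        for d in ("a", "b"):
            paths = write_report(seg, attrs, lobes, None,
                                 tmp_path / d, tumors=tumors,
                                 manifest={"seed": 1})
            blobs.append({k: open(p, "rb").read()
                          for k, p in paths.items() if p.endswith((
                              ".csv", ".json"))})
        assert blobs[0] == blobs[1]

    def test_tumor_membership_single_segment(self, small_run, tmp_path):
        seg, attrs, lobes, tumors = small_run
        paths = write_report(seg, attrs, lobes, None, tmp_path,
                             tumors=tumors)
        doc = json.load(open(paths["tree"]))
        assert len(doc["tumors"]) == 1
        t = doc["tumors"][0]
        assert t["segment_of_centroid"] == 1
        assert t["overlap_voxels_by_segment"] == {"1": t["n_voxels"]}

    def test_empty_tumors_empty_list(self, small_run, tmp_path):
        seg, attrs, lobes, _ = small_run
        paths = write_report(seg, attrs, lobes, None, tmp_path)
        doc = json.load(open(paths["tree"]))
        assert doc["tumors"] == []

    def test_label_volume_roundtrip(self, small_run, tmp_path):
        from hepatree.io import load_volume
        seg, attrs, lobes, _ = small_run
        paths = write_report(seg, attrs, lobes, None, tmp_path)
        data, spacing = load_volume(paths["segments"])
        assert (data == seg.labels).all()
        assert spacing == seg.spacing


class TestGroupVoxels:
    def test_path_voxels_included_by_default(self):
        import networkx as nx
        g = nx.MultiDiGraph()
        a, b = (0, 0, 0), (0, 0, 3)
        for v in (a, b):
            g.add_node(v, position_mm=tuple(map(float, v)))
        g.add_edge(a, b, key=0, path=[a, (0, 0, 1), (0, 0, 2), b])
        st = Subtree(root=a, vertices=[a, b], edges=[(a, b, 0)], graph=g)
        div = BranchDivision(subtrees=[st], labels=[1], K=1)
        assert len(group_voxels(div)[1]) == 4
        assert len(group_voxels(div, vertices_only=True)[1]) == 2
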