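import json

import numpy as np
import pytest

from gisthsi.annotation import (AnnotationSet, BACKGROUND, Box, GIST, NORMAL,
                                exclusion_mask, extract_training_set,
                                load_annotations, points_in_polygon,
                                rasterize_labels, save_annotations)
from gisthsi.preprocess import FeatureMatrix


def square(r0, c0, r1, c1):
    """Closed square polyline in (row, col) coordinates."""
    return np.array([[r0, c0], [r0, c1], [r1, c1], [r1, c0], [r0, c0]], float)


@pytest.fixture()
def seven_by_seven():
    """3x3 tumor square centered in a 7x7 specimen extent."""
    return AnnotationSet(boundary=square(1.5, 1.5, 4.5, 4.5), thickness_px=0.5,
                        extent=square(-0.5, -0.5, 6.5, 6.5))


class TestAnnotationSet:
    def test_open_polyline_rejected(self):
        verts = square(0, 0, 4, 4)[:-1]
        with pytest.raises(ValueError, match="closed"):
            AnnotationSet(boundary=verts, thickness_px=1.0)

    def test_mislabeled_normal_box_rejected(self):
        with pytest.raises(ValueError, match=r"normal box #0"):
            AnnotationSet(boundary=square(0.5, 0.5, 5.5, 5.5), thickness_px=1.0,
                          boxes=[Box("normal", 2, 2, 4, 4)])

    def test_gist_box_outside_boundary_rejected(self):
        with pytest.raises(ValueError, match=r"gist box #0"):
            AnnotationSet(boundary=square(0.5, 0.5, 3.5, 3.5), thickness_px=1.0,
                          boxes=[Box("gist", 4, 4, 6, 6)])

    def test_box_outside_extent_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            AnnotationSet(boundary=square(0.5, 0.5, 3.5, 3.5), thickness_px=1.0,
                          boxes=[Box("gist", 1, 1, 3, 3)],
                          extent=square(0.5, 0.5, 1.5, 1.5))

    def test_json_round_trip(self, tmp_path, seven_by_seven):
        ann = seven_by_seven
        ann.boxes = [Box("gist", 2, 2, 4, 4)]
        path = save_annotations(ann, tmp_path / "a.json")
        back = load_annotations(path)
        np.testing.assert_array_equal(back.boundary, ann.boundary)
        assert back.thickness_px == ann.thickness_px
        assert back.boxes == ann.boxes
        np.testing.assert_array_equal(back.extent, ann.extent)

    def test_invalid_document_names_box(self, tmp_path):
        doc = {"boundary": {"vertices": square(0.5, 0.5, 5.5, 5.5).tolist(),
                            "thickness_px": 1},
               "boxes": [{"label": "normal", "r0": 2, "c0": 2, "r1": 4, "c1": 4}]}
        p = tmp_path / "bad.json"
        p.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="normal box #0"):
            load_annotations(p)


class TestRasterizeLabels:
    def test_square_boundary_pixel_counts(self, seven_by_seven):
        # brute-force even-odd over all 49 centers gives 9 tumor, 40 normal
        img = rasterize_labels(seven_by_seven, (7, 7))
        assert int(np.sum(img.values == GIST)) == 9
        assert int(np.sum(img.values == NORMAL)) == 40
        assert int(np.sum(img.values == BACKGROUND)) == 0

    def test_boundary_equal_to_extent_leaves_no_normal(self):
        ann = AnnotationSet(boundary=square(-0.5, -0.5, 6.5, 6.5),
                            thickness_px=0.5,
                            extent=square(-0.5, -0.5, 6.5, 6.5))
        img = rasterize_labels(ann, (7, 7))
        assert int(np.sum(img.values == NORMAL)) == 0
        assert int(np.sum(img.values == GIST)) == 49

    def test_partition_of_extent(self):
        # tumor + normal pixels together exactly tile the extent
        rng = np.random.default_rng(0)
        for _ in range(5):
            cr, cc = rng.uniform(4, 6, 2)
            a, b = rng.uniform(1.5, 3.5, 2)
            t = np.linspace(0, 2 * np.pi, 33)
            boundary = np.column_stack([cr + a * np.cos(t), cc + b * np.sin(t)])
            boundary[-1] = boundary[0]
            extent = square(-0.5, -0.5, 10.5, 10.5)
            ann = AnnotationSet(boundary=boundary, thickness_px=1.0, extent=extent)
            img = rasterize_labels(ann, (11, 11))
            n_extent = int(points_in_polygon(
                np.argwhere(np.ones((11, 11), bool)).astype(float), extent).sum())
            assert (int(np.sum(img.values == GIST))
                    + int(np.sum(img.values == NORMAL))) == n_extent

    def test_degenerate_polygon_rejected(self):
        line = np.array([[1.0, 1.0], [4.0, 4.0], [1.0, 1.0]])
        ann = AnnotationSet(boundary=line, thickness_px=1.0)
        with pytest.raises(ValueError, match="degenerate"):
            rasterize_labels(ann, (6, 6))

    def test_pixel_center_on_edge_is_deterministic(self, seven_by_seven):
        a = rasterize_labels(seven_by_seven, (7, 7)).values
        b = rasterize_labels(seven_by_seven, (7, 7)).values
        np.testing.assert_array_equal(a, b)


class TestExclusionMask:
    def test_straight_segment_thickness_1_excludes_rows_3_to_7(self):
        # doubled-thickness rule: distance <= 2 from the line along row 5
        line = np.array([[5.0, 0.0], [5.0, 10.0], [5.0, 0.0]])
        ann = AnnotationSet(boundary=line, thickness_px=1.0)
        mask = exclusion_mask(ann, (11, 11))
        excluded_rows = np.nonzero(~mask.values.all(axis=1))[0]
        assert excluded_rows.tolist() == [3, 4, 5, 6, 7]

    def test_zero_thickness_excludes_only_the_line(self):
        line = np.array([[5.0, 0.0], [5.0, 10.0], [5.0, 0.0]])
        ann = AnnotationSet(boundary=line, thickness_px=0.0)
        mask = exclusion_mask(ann, (11, 11))
        assert np.array_equal(~mask.values.all(axis=1),
                              np.arange(11) == 5)

    def test_exclusion_zone_grows_with_thickness(self):
        # cross-check against a brute-force distance transform
        from scipy.spatial.distance import cdist
        t_vals = [0.5, 1.0, 2.0, 3.0]
        boundary = square(3.5, 3.5, 11.5, 11.5)
        shape = (16, 16)
        prev = -1
        dense = []
        for (r1, c1), (r2, c2) in zip(boundary[:-1], boundary[1:]):
            u = np.linspace(0, 1, 400)[:, None]
            dense.append(np.array([r1, c1]) + u * (np.array([r2, c2]) - [r1, c1]))
        dense = np.vstack(dense)
        centers = np.argwhere(np.ones(shape, bool)).astype(float)
        brute = cdist(centers, dense).min(axis=1).reshape(shape)
        for t in t_vals:
            ann = AnnotationSet(boundary=boundary, thickness_px=t)
            mask = exclusion_mask(ann, shape)
            n_excluded = int(np.sum(~mask.values))
            assert n_excluded >= prev
            prev = n_excluded
            np.testing.assert_array_equal(~mask.values, brute <= 2 * t + 1e-9)


class TestExtractTrainingSet:
    def features_on(self, shape):
        idx = np.argwhere(np.ones(shape, bool))
        rng = np.random.default_rng(1)
        X = rng.normal(size=(len(idx), 5))
        return FeatureMatrix(X, idx, np.arange(5, dtype=float))

    def test_box_pixels_become_labeled_rows(self, seven_by_seven):
        ann = seven_by_seven
        ann.boxes = [Box("gist", 2, 2, 4, 4), Box("normal", 0, 0, 1, 3)]
        ts = extract_training_set(self.features_on((7, 7)), ann, "sp1")
        assert int(np.sum(ts.y == "gist")) == 4
        assert int(np.sum(ts.y == "normal")) == 3
        assert set(ts.specimen_ids) == {"sp1"}

    def test_fully_masked_box_errors(self, seven_by_seven):
        ann = seven_by_seven
        ann.boxes = [Box("gist", 2, 2, 4, 4)]
        fm = self.features_on((7, 7))
        keep = ~((fm.pixel_index[:, 0] >= 2) & (fm.pixel_index[:, 0] < 4)
                 & (fm.pixel_index[:, 1] >= 2) & (fm.pixel_index[:, 1] < 4))
        fm = FeatureMatrix(fm.X[keep], fm.pixel_index[keep], fm.wavelengths)
        with pytest.raises(ValueError, match="box #0"):
            extract_training_set(fm, ann)

    def test_label_counts_conserved(self, seven_by_seven):
        ann = seven_by_seven
        ann.boxes = [Box("gist", 2, 2, 4, 5), Box("normal", 5, 0, 7, 2)]
        ts = extract_training_set(self.features_on((7, 7)), ann)
        assert len(ts) == (2 * 3) + (2 * 2)
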