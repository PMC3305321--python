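"""Grid construction, Monte Carlo point sampling, tissue masking."""

import numpy as np
import pytest

from ihcmap.geometry import Polygon, RigidTransform
from ihcmap.grid import (
    CellStatus,
    GridCell,
    GridSpec,
    cell_rng,
    filter_grid,
    make_grid,
    make_tissue_mask,
    monte_carlo_fraction,
    retained,
)
from ihcmap.slide_io import AnnotationSet, SlideImage


def white_slide(w, h, mpp=0.5):
    return SlideImage(np.full((h, w, 3), 255, np.uint8), mpp)


class TestMakeGrid:
    def test_250um_cells_on_1000px_slide(self):
        """250 um at 0.5 um/px = 500 px cells: a 1000 px slide tiles 2x2."""
        cells = make_grid(white_slide(1000, 1000), GridSpec())
        assert len(cells) == 4
        assert {(c.row, c.col) for c in cells} == {(0, 0), (0, 1), (1, 0), (1, 1)}
        assert all(c.x1 - c.x0 == 500 and c.y1 - c.y0 == 500 for c in cells)

    def test_cell_equal_to_image_gives_single_cell(self):
        cells = make_grid(white_slide(500, 500), GridSpec())
        assert len(cells) == 1

    def test_half_open_tiling_covers_every_pixel_once(self):
        slide = white_slide(130, 70, mpp=1.0)
        cells = make_grid(slide, GridSpec(cell_width_um=40, cell_height_um=30))
        count = np.zeros((70, 130), dtype=int)
        for c in cells:
            count[int(c.y0):int(c.y1), int(c.x0):int(c.x1)] += 1
        assert (count == 1).all()

    def test_oversized_cell_warns(self):
        with pytest.warns(UserWarning, match="larger"):
            cells = make_grid(white_slide(100, 100), GridSpec(cell_width_um=500, cell_height_um=500, ))
        assert len(cells) == 1

    def test_subpixel_cell_rejected(self):
        with pytest.raises(ValueError):
            make_grid(white_slide(10, 10, mpp=300.0), GridSpec())


UNIT_CELL = GridCell(0, 0, 0.0, 0.0, 1.0, 1.0)


class TestMonteCarloFraction:
    def test_cell_inside_polygon(self):
        big = Polygon(np.array([[-5, -5], [5, -5], [5, 5], [-5, 5]]))
        assert monte_carlo_fraction(UNIT_CELL, [big], 100, cell_rng(0, 0, 0)) == 1.0

    def test_cell_outside_polygon(self):
        far = Polygon(np.array([[10, 10], [11, 10], [11, 11], [10, 11]]))
        assert monte_carlo_fraction(UNIT_CELL, [far], 100, cell_rng(0, 0, 0)) == 0.0

    def test_empty_polygon_list(self):
        assert monte_carlo_fraction(UNIT_CELL, [], 100, cell_rng(0, 0, 0)) == 0.0

    def test_half_plane_binomial_bound(self):
        """Half-covered cell at n=500: fraction within 0.5 +- 0.07 (3 sigma)."""
        half = Polygon(np.array([[-1, -1], [0.5, -1], [0.5, 2], [-1, 2]]))
        f = monte_carlo_fraction(UNIT_CELL, [half], 500, cell_rng(7, 0, 0))
        assert abs(f - 0.5) < 0.07

    def test_estimator_unbiased_on_30pct_cover(self):
        """Mean over 1000 seeded repeats of a 30%-covered cell in 0.30 +- 0.005."""
        strip = Polygon(np.array([[-1, -1], [0.3, -1], [0.3, 2], [-1, 2]]))
        vals = [
            monte_carlo_fraction(UNIT_CELL, [strip], 500, cell_rng(k, 0, 0))
            for k in range(1000)
        ]
        assert abs(np.mean(vals) - 0.30) < 0.005


class TestTissueMask:
    def test_all_white_is_empty(self):
        assert not make_tissue_mask(white_slide(64, 64)).any()

    def test_gray_disk_area_within_2pct(self):
        slide = white_slide(400, 400)
        yy, xx = np.mgrid[0:400, 0:400]
        disk_mask = (xx - 200) ** 2 + (yy - 200) ** 2 < 80**2
        px = slide.pixels.copy()
        px[disk_mask] = 150
        mask = make_tissue_mask(SlideImage(px, 0.5))
        assert mask.sum() == pytest.approx(np.pi * 80**2, rel=0.02)

    def test_closing_idempotent(self):
        from skimage.morphology import closing, disk

        slide = white_slide(200, 200)
        px = slide.pixels.copy()
        px[50:150, 50:150] = 100
        px[90:95, 90:95] = 255  # small hole, closed away
        mask = make_tissue_mask(SlideImage(px, 0.5))
        assert np.array_equal(closing(mask, disk(5)), mask)


def _square_annotation(x0, y0, x1, y1, label="3+3", negative=False):
    poly = Polygon(np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]], float),
                   label=label, negative=negative)
    return poly


class TestFilterGrid:
    def setup_method(self):
        self.slide = white_slide(400, 400, mpp=1.0)
        self.spec = GridSpec(cell_width_um=100, cell_height_um=100, seed=5)
        self.cells = make_grid(self.slide, self.spec)
        self.tissue = np.ones((400, 400), dtype=bool)

    def test_cell_inside_annotation_retained_with_label(self):
        aset = AnnotationSet(layers=[("3+4", [_square_annotation(-10, -10, 210, 210, "3+4")])])
        out = filter_grid(self.cells, aset, self.tissue, spec=self.spec)
        cell00 = next(c for c in out if (c.row, c.col) == (0, 0))
        assert cell00.status == CellStatus.RETAINED
        assert cell00.region_label == "3+4"

    def test_cell_outside_tissue_discarded(self):
        aset = AnnotationSet(layers=[("3+3", [_square_annotation(-10, -10, 500, 500)])])
        tissue = np.zeros((400, 400), dtype=bool)
        out = filter_grid(self.cells, aset, tissue, spec=self.spec)
        assert all(c.status == CellStatus.OUTSIDE_TISSUE for c in out)

    def test_cell_inside_negative_region_excluded(self):
        pos = _square_annotation(-10, -10, 500, 500)
        neg = _square_annotation(0, 0, 110, 110, negative=True)
        aset = AnnotationSet(layers=[("3+3", [pos, neg])])
        out = filter_grid(self.cells, aset, self.tissue, spec=self.spec)
        cell00 = next(c for c in out if (c.row, c.col) == (0, 0))
        assert cell00.status == CellStatus.NEGATIVE_EXCLUDED
        assert sum(1 for c in out if c.status == CellStatus.RETAINED) > 0

    def test_ihc_negative_mapped_through_transform(self):
        """A negative pen mark on an IHC slide excludes the reference cell it covers."""
        pos = _square_annotation(-10, -10, 500, 500)
        aset = AnnotationSet(layers=[("3+3", [pos])], source_slide="H&E")
        # negative polygon drawn at the origin of an IHC slide that is translated
        # by (+200, +200) relative to the reference
        neg_set = AnnotationSet(
            layers=[("neg", [_square_annotation(-210, -210, -90, -90, negative=True)])],
            source_slide="ACPP",
        )
        t = RigidTransform(tx=200.0, ty=200.0, image_size=(400, 400))
        out = filter_grid(self.cells, aset, self.tissue, [neg_set], self.spec, {"ACPP": t})
        cell00 = next(c for c in out if (c.row, c.col) == (0, 0))
        assert cell00.status == CellStatus.NEGATIVE_EXCLUDED

    def test_same_seed_reproducible(self):
        aset = AnnotationSet(layers=[("3+3", [_square_annotation(30, 30, 350, 230)])])
        a = filter_grid(self.cells, aset, self.tissue, spec=self.spec)
        b = filter_grid(self.cells, aset, self.tissue, spec=self.spec)
        assert [(c.status, c.region_label) for c in a] == [(c.status, c.region_label) for c in b]

    def test_retained_count_monotone_in_threshold(self):
        aset = AnnotationSet(layers=[("3+3", [_square_annotation(30, 30, 350, 230)])])
        counts = []
        for thr in (0.2, 0.5, 0.8):
            spec = GridSpec(cell_width_um=100, cell_height_um=100, seed=5, mc_threshold=thr)
            counts.append(len(retained(filter_grid(self.cells, aset, self.tissue, spec=spec))))
        assert counts[0] >= counts[1] >= counts[2]

    def test_overlapping_layers_assigned_to_highest_fraction(self):
        a = _square_annotation(-10, -10, 210, 210, "A")
        b = _square_annotation(50, -10, 210, 210, "B")
        aset = AnnotationSet(layers=[("A", [a]), ("B", [b])])
        out = filter_grid(self.cells, aset, self.tissue, spec=self.spec)
        cell00 = next(c for c in out if (c.row, c.col) == (0, 0))
        assert cell00.region_label == "A"  # covers all of cell (0,0); B covers half
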