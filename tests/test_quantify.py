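import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

from mitopop import quantify, segment, simulate
from mitopop.imio import Tile
from mitopop.quantify import (CellRecord, granularity_score,
                              granularity_spectrum, measure_cell,
                              measure_cells, morphology_scatter,
                              records_to_frame)
from mitopop.segment import CellObject


def make_cell_object(coords, size=64):
    coords = np.asarray(coords)
    return CellObject(label=1, coords=coords, area=len(coords),
                      centroid=(float(coords[:, 1].mean()),
                                float(coords[:, 0].mean())),
                      cls="singlet", class_prob=1.0, touches_border=False)


def uniform_tile(value=500.0, bg=0.0, size=64, block=10):
    """A tile whose mt channel is `value` on a block x block cell, bg elsewhere."""
    mt = np.full((size, size), bg)
    mt[20:20 + block, 20:20 + block] = value
    coords = np.argwhere(mt == value) if value != bg else \
        np.argwhere(np.zeros((size, size), dtype=bool))
    tile = Tile(mt=mt.astype(np.uint16), ppix=np.zeros((size, size), np.uint16),
                trans=np.full((size, size), 1000, np.uint16),
                subject_id=1, tile_index=0, um_per_px=0.44)
    return tile, make_cell_object(np.argwhere(
        np.isin(np.arange(size), np.arange(20, 20 + block))[:, None]
        & np.isin(np.arange(size), np.arange(20, 20 + block))[None, :]))


class TestMeasureCell:
    def test_uniform_cell_totals(self):
        tile, obj = uniform_tile(value=500.0, bg=0.0, block=10)
        rec = measure_cell(tile, obj, with_granularity=False)
        assert rec.object_size == 100
        assert rec.mt_total == pytest.approx(50000.0)
        assert rec.mt_mean == pytest.approx(500.0)

    def test_background_equal_raw_gives_zero(self):
        tile, obj = uniform_tile(value=300.0, bg=300.0, block=10)
        rec = measure_cell(tile, obj, with_granularity=False)
        assert rec.mt_total == 0.0

    def test_empty_pixel_set_raises(self):
        tile, obj = uniform_tile()
        obj.coords = np.empty((0, 2), dtype=int)
        with pytest.raises(ValueError):
            measure_cell(tile, obj)

    def test_mean_equals_total_over_area_exactly(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            size = 64
            mt = rng.integers(0, 60000, (size, size)).astype(np.uint16)
            n = int(rng.integers(5, 80))
            idx = rng.choice(size * size, size=n, replace=False)
            coords = np.c_[idx // size, idx % size]
            tile = Tile(mt=mt, ppix=mt.copy(), trans=mt.copy(),
                        subject_id=1, tile_index=0, um_per_px=0.44)
            rec = measure_cell(tile, make_cell_object(coords),
                               with_granularity=False)
            assert rec.mt_mean == rec.mt_total / rec.object_size
            assert rec.ppix_mean == rec.ppix_total / rec.object_size

    def test_invariant_to_additive_offset(self):
        tile, obj = uniform_tile(value=800.0, bg=100.0, block=10)
        rec1 = measure_cell(tile, obj, with_granularity=False)
        shifted = Tile(mt=(tile.mt + 2000).astype(np.uint16), ppix=tile.ppix,
                       trans=tile.trans, subject_id=1, tile_index=0,
                       um_per_px=0.44)
        rec2 = measure_cell(shifted, obj, with_granularity=False)
        assert rec2.mt_total == pytest.approx(rec1.mt_total)

    def test_conservation_against_ground_truth(self, noiseless_tile_truth):
        tile, truth = noiseless_tile_truth
        cfg = segment.SegmentationConfig()
        objs = segment.classify_objects(
            segment.pixel_classify(tile.trans, cfg), cfg)
        retained = segment.filter_singlets(objs, cfg)
        recs = measure_cells(tile, retained, with_granularity=False)
        gt = truth.to_frame()
        singlets = gt[gt.kind == "singlet"]
        tree = cKDTree(np.c_[singlets.centroid_x, singlets.centroid_y])
        n_checked = 0
        for o, rec in zip(retained, recs):
            d, i = tree.query(o.centroid)
            if d < singlets.radius_px.iloc[i]:
                assert rec.mt_total == pytest.approx(
                    singlets.mt_total.iloc[i], rel=0.05)
                n_checked += 1
        assert n_checked >= 10


class TestGranularity:
    def make_patch_tile(self, trans):
        size = trans.shape[0]
        return Tile(mt=np.zeros_like(trans, np.uint16),
                    ppix=np.zeros_like(trans, np.uint16),
                    trans=trans.astype(np.uint16), subject_id=1, tile_index=0,
                    um_per_px=0.44)

    def disk_object(self, radius, size=64):
        yy, xx = np.mgrid[0:size, 0:size]
        d = np.hypot(xx - size // 2, yy - size // 2)
        return np.argwhere(d <= radius), d

    def test_uniform_disk_radius5_score_near_6(self):
        coords, d = self.disk_object(5)
        trans = np.full((64, 64), 1000.0)
        trans[tuple(coords.T)] = 500.0
        score = granularity_score(trans, make_cell_object(coords))
        assert score == pytest.approx(6.0, abs=1.0)

    def test_fine_speckle_score_near_1(self):
        coords, _ = self.disk_object(8)
        trans = np.full((64, 64), 1000.0)
        rng = np.random.default_rng(0)
        pts = coords[rng.choice(len(coords), 25, replace=False)]
        # isolated dark pixels = radius-1 grains in the inverted image
        trans[tuple(pts.T)] = 400.0
        score = granularity_score(trans, make_cell_object(coords))
        assert score == pytest.approx(1.0, abs=0.35)

    def test_spectrum_properties(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            coords, _ = self.disk_object(10)
            trans = np.full((64, 64), 1000.0)
            trans[tuple(coords.T)] = rng.uniform(200, 990, len(coords))
            g = granularity_spectrum(trans, make_cell_object(coords))
            assert np.all(g >= -1e-12)
            assert g.sum() <= 1.0 + 1e-12

    def test_zero_signal_warns_and_scores_zero(self):
        coords, _ = self.disk_object(5)
        trans = np.full((64, 64), 1000.0)  # object identical to background
        with pytest.warns(UserWarning, match="zero signal"):
            score = granularity_score(trans, make_cell_object(coords))
        assert score == 0.0

    def test_planted_texture_scales_ordered(self):
        rng = np.random.default_rng(2)
        fine_scores, coarse_scores = [], []
        for rep in range(4):
            coords, _ = self.disk_object(12)
            # fine: isolated dark pixels
            trans = np.full((64, 64), 1000.0)
            pts = coords[rng.choice(len(coords), 40, replace=False)]
            trans[tuple(pts.T)] = 300.0
            fine_scores.append(granularity_score(trans, make_cell_object(coords)))
            # coarse: a few radius-3 dark blobs
            trans = np.full((64, 64), 1000.0)
            yy, xx = np.mgrid[0:64, 0:64]
            for _ in range(4):
                c = coords[rng.integers(len(coords))]
                blob = np.hypot(xx - c[1], yy - c[0]) <= 3
                trans[blob] = 300.0
            coarse_scores.append(granularity_score(trans, make_cell_object(coords)))
        assert np.mean(fine_scores) < np.mean(coarse_scores)


class TestMorphologyScatter:
    def make_records(self, sizes, granularities):
        return [CellRecord(patient_id=1, tile_index=0, object_size=int(s),
                           granularity=float(g), mt_total=1000.0,
                           mt_mean=1000.0 / s, ppix_total=0.0, ppix_mean=0.0)
                for s, g in zip(sizes, granularities)]

    def test_single_record_k1(self):
        recs = self.make_records([800], [3.0])
        _, diag = morphology_scatter(recs)
        assert diag["preferred_k"] == 1

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            morphology_scatter([])

    def test_one_morphology_class_prefers_k1(self):
        rng = np.random.default_rng(3)
        recs = self.make_records(rng.normal(800, 60, 150).clip(min=300),
                                 rng.normal(3.0, 0.3, 150))
        _, diag = morphology_scatter(recs)
        assert diag["preferred_k"] == 1

    def test_two_separated_classes_prefer_k2(self):
        rng = np.random.default_rng(4)
        sizes = np.r_[rng.normal(500, 30, 75), rng.normal(2500, 30, 75)]
        gran = np.r_[rng.normal(2.0, 0.1, 75), rng.normal(6.0, 0.1, 75)]
        _, diag = morphology_scatter(self.make_records(sizes, gran))
        assert diag["preferred_k"] == 2

    def test_scatter_columns(self):
        recs = self.make_records([800, 900], [3.0, 3.1])
        scatter, _ = morphology_scatter(recs)
        assert list(scatter.columns) == ["size", "granularity", "mt_mean"]


def test_records_to_frame_round_trip():
    recs = [CellRecord(patient_id=2, tile_index=1, object_size=100,
                       granularity=2.5, mt_total=1e4, mt_mean=100.0,
                       ppix_total=2e4, ppix_mean=200.0)]
    df = records_to_frame(recs)
    assert df.iloc[0].patient_id == 2
    assert df.iloc[0].mt_mean == pytest.approx(100.0)
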