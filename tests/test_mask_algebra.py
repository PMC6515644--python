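import numpy as np
import pandas as pd
import pytest

from _oracles import count_and, point_in_polygon
from amyquant import (QuantRecord, Region, RoiPolygon, aggregate_per_animal,
                      associated_fraction, parenchymal_fraction,
                      rasterize_roi, total_area_fraction)
from amyquant.mask_algebra import MetricDefinition, dilate_mask, \
    evaluate_metrics
from amyquant.io import records_to_frame
from amyquant.types import BinaryMask


def _m(arr):
    return BinaryMask(np.asarray(arr, dtype=bool))


def _random_masks(rng, shape=(16, 16), p=0.4):
    return (_m(rng.uniform(size=shape) < p),
            _m(rng.uniform(size=shape) < p),
            _m(rng.uniform(size=shape) < 0.8))


class TestRasterizeRoi:
    def test_square_on_pixel_centers(self):
        poly = RoiPolygon(Region.CORTEX, [(3, 3), (12, 3), (12, 12), (3, 12)])
        mask = rasterize_roi(poly, (20, 20)).pixels
        assert mask.sum() == 100  # 10x10 with boundary centers inside
        # cross-check every pixel against the point-in-polygon oracle
        for y in range(20):
            for x in range(20):
                assert mask[y, x] == point_in_polygon(x, y, poly.vertices)

    def test_triangle_outside_image_empty(self):
        poly = RoiPolygon(Region.CORTEX, [(100, 100), (110, 100), (105, 110)])
        assert rasterize_roi(poly, (20, 20)).area_px == 0

    def test_whole_image_rectangle_full(self):
        poly = RoiPolygon(Region.CORTEX, [(0, 0), (19, 0), (19, 19), (0, 19)])
        assert rasterize_roi(poly, (20, 20)).pixels.all()

    def test_oblique_polygon_matches_oracle(self, rng):
        poly = RoiPolygon(Region.HIPPOCAMPUS,
                          [(2.5, 1.0), (14.2, 4.7), (10.0, 13.3), (1.2, 9.9)])
        mask = rasterize_roi(poly, (16, 16)).pixels
        for y in range(16):
            for x in range(16):
                assert mask[y, x] == point_in_polygon(x, y, poly.vertices)


class TestFractionMetrics:
    def test_marker_equals_roi_is_100pct(self):
        roi = _m(np.ones((8, 8)))
        rec = total_area_fraction(roi, roi)
        assert rec.value == 100.0

    def test_disjoint_marker_is_0pct(self):
        roi = _m(np.ones((8, 8)))
        rec = total_area_fraction(_m(np.zeros((8, 8))), roi)
        assert rec.value == 0.0

    def test_empty_roi_undefined(self):
        rec = total_area_fraction(_m(np.ones((4, 4))), _m(np.zeros((4, 4))))
        assert rec.undefined

    def test_target_superset_of_reference_is_full(self):
        ref = _m(np.eye(6))
        roi = _m(np.ones((6, 6)))
        rec = associated_fraction(_m(np.ones((6, 6))), ref, roi,
                                  scale="fraction")
        assert rec.value == 1.0

    def test_disjoint_target_reference_zero(self):
        ref = _m(np.eye(6))
        tgt = _m(np.rot90(np.triu(np.ones((6, 6)), 2)))
        roi = _m(np.ones((6, 6)))
        rec = associated_fraction(tgt & ~ref, ref, roi, scale="fraction")
        assert rec.value == 0.0

    def test_empty_reference_undefined(self):
        roi = _m(np.ones((4, 4)))
        rec = associated_fraction(_m(np.ones((4, 4))), _m(np.zeros((4, 4))),
                                  roi)
        assert rec.undefined

    def test_fractions_match_double_loop_oracle(self, rng):
        for _ in range(25):
            t, r, roi = _random_masks(rng)
            tot = total_area_fraction(t, roi)
            assert tot.numerator_px == count_and(t.pixels, roi.pixels)
            assert tot.denominator_px == count_and(roi.pixels)
            assoc = associated_fraction(t, r, roi)
            assert assoc.numerator_px == count_and(t.pixels, r.pixels,
                                                   roi.pixels)
            assert assoc.denominator_px == count_and(r.pixels, roi.pixels)
            par = parenchymal_fraction(t, r, roi)
            assert par.numerator_px == count_and(t.pixels, ~r.pixels,
                                                 roi.pixels)

    def test_parenchymal_trivial_cases(self):
        roi = _m(np.ones((6, 6)))
        marker = _m(np.tri(6))
        # marker disjoint from reference -> parenchymal == total
        ref0 = _m(np.zeros((6, 6)))
        assert (parenchymal_fraction(marker, ref0, roi).numerator_px
                == total_area_fraction(marker, roi).numerator_px)
        # marker subset of reference -> parenchymal == 0
        assert parenchymal_fraction(marker, marker, roi).numerator_px == 0

    def test_additivity_identity(self, rng):
        """|M ∩ Ω| == |M ∩ R ∩ Ω| + |M ∩ ¬R ∩ Ω| exactly."""
        for _ in range(300):
            m, r, roi = _random_masks(rng, shape=(12, 12))
            total = int((m.pixels & roi.pixels).sum())
            vasc = int((m.pixels & r.pixels & roi.pixels).sum())
            par = parenchymal_fraction(m, r, roi).numerator_px
            assert total == vasc + par

    def test_dilation_monotone_numerator(self, rng):
        t, r, roi = _random_masks(rng, shape=(24, 24), p=0.2)
        prev = -1
        for d in (0, 1, 2, 4):
            num = associated_fraction(t, r, roi, dilation_px=d).numerator_px
            assert num >= prev
            prev = num

    def test_values_bounded(self, rng):
        for _ in range(20):
            t, r, roi = _random_masks(rng)
            for rec in (total_area_fraction(t, roi),
                        associated_fraction(t, r, roi),
                        parenchymal_fraction(t, r, roi)):
                if not rec.undefined:
                    assert 0.0 <= rec.value <= 100.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            total_area_fraction(_m(np.ones((4, 4))), _m(np.ones((5, 5))))


class TestMetricDefinitions:
    def test_complement_expression(self, rng):
        t, r, roi = _random_masks(rng)
        d = MetricDefinition("par", ("T", "~R"))
        rec = d.evaluate({"T": t, "R": r}, roi)
        assert rec.numerator_px == count_and(t.pixels, ~r.pixels, roi.pixels)

    def test_vgfap_derived_automatically(self, rng):
        g, c, roi = _random_masks(rng)
        recs = evaluate_metrics({"GFAP": g, "CD31": c}, roi)
        names = {r.metric for r in recs}
        assert "vascular_fraction.GFAP" in names
        rec = next(r for r in recs if r.metric == "vascular_fraction.GFAP")
        assert rec.numerator_px == count_and(g.pixels, c.pixels, roi.pixels)

    def test_metrics_with_missing_masks_skipped(self, rng):
        g, _, roi = _random_masks(rng)
        recs = evaluate_metrics({"GFAP": g}, roi)
        assert {r.metric for r in recs} == {"total_area_pct.GFAP"}


class TestAggregation:
    def _frame(self):
        recs = [
            QuantRecord("A1", "s1", "cortex", "m", 10, 100),
            QuantRecord("A1", "s2", "cortex", "m", 30, 100),
            QuantRecord("A1", "s3", "cortex", "m", 0, 0),     # undefined
            QuantRecord("A2", "s1", "cortex", "m", 50, 100),
        ]
        return records_to_frame(recs)

    def test_mean_drops_undefined(self):
        out = aggregate_per_animal(self._frame(), "mean")
        a1 = out[out.animal_id == "A1"]["value"].iloc[0]
        assert a1 == pytest.approx((10.0 + 30.0) / 2)

    def test_pooled_counts(self):
        out = aggregate_per_animal(self._frame(), "pooled")
        a1 = out[out.animal_id == "A1"]["value"].iloc[0]
        assert a1 == pytest.approx(100.0 * 40 / 200)

    def test_all_undefined_stays_na(self):
        recs = [QuantRecord("A3", "s1", "cortex", "m", 0, 0)]
        out = aggregate_per_animal(records_to_frame(recs), "pooled")
        assert np.isnan(out["value"].iloc[0])
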