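import dataclasses

import numpy as np
import pandas as pd
import pytest

from amyquant import (SectionSpec, generate_cohort, generate_section,
                      rasterize_roi, simulate_metric_table)
from amyquant.mask_algebra import BUILTIN_METRICS, evaluate_metrics
from amyquant.synthetic import GROUPS, InfeasibleSpecError, \
    truth_metric_masks


class TestGenerateSection:
    def test_determinism_byte_identical(self):
        spec = SectionSpec(seed=42)
        im1, tr1 = generate_section(spec)
        im2, tr2 = generate_section(spec)
        for ch in im1:
            assert np.array_equal(im1[ch].pixels, im2[ch].pixels)
        for k in tr1.masks:
            assert np.array_equal(tr1.masks[k].pixels, tr2.masks[k].pixels)

    def test_different_seeds_differ(self):
        im1, _ = generate_section(SectionSpec(seed=1))
        im2, _ = generate_section(SectionSpec(seed=2))
        assert any(not np.array_equal(im1[ch].pixels, im2[ch].pixels)
                   for ch in im1)

    def test_no_plaques_empty_amyloid(self):
        spec = SectionSpec(seed=3, n_plaques=0, caa_segment_count=0)
        _, truth = generate_section(spec)
        assert truth.masks["plaque"].area_px == 0
        assert truth.masks["caa"].area_px == 0

    def test_vessel_density_realized(self):
        spec = SectionSpec(seed=4, vessel_density=0.05)
        _, truth = generate_section(spec)
        realized = truth.masks["vessel"].area_px / np.prod(spec.shape_px)
        assert abs(realized - 0.05) / 0.05 <= 0.20

    def test_structural_subset_invariants(self, default_section):
        _, _, truth = default_section
        m = truth.masks
        amyloid = m["plaque"].pixels | m["caa"].pixels
        assert not (m["caa"].pixels & ~amyloid).any()
        assert not (m["astro_vascular"].pixels & ~m["astro"].pixels).any()
        assert not (m["icam_vascular"].pixels & ~m["vessel"].pixels).any()

    def test_truth_metrics_reproducible_from_masks(self, default_section):
        spec, _, truth = default_section
        metric_masks = truth_metric_masks(truth.masks)
        for poly in truth.rois:
            roi = rasterize_roi(poly, spec.shape_px)
            recs = evaluate_metrics(metric_masks, roi, BUILTIN_METRICS,
                                    region=poly.region.value)
            stored = [r for r in truth.true_records
                      if r.region == poly.region.value]
            assert len(recs) == len(stored)
            for r0, r1 in zip(stored, recs):
                assert (r0.metric, r0.numerator_px, r0.denominator_px) == \
                    (r1.metric, r1.numerator_px, r1.denominator_px)

    def test_channels_are_8bit(self, default_section):
        _, images, _ = default_section
        for img in images.values():
            assert img.pixels.dtype == np.uint8

    def test_infeasible_spec_fails_explicitly(self):
        # field too small to hold any minimum-length vessel centreline
        with pytest.raises(InfeasibleSpecError):
            generate_section(SectionSpec(seed=0, shape_px=(12, 12),
                                         vessel_density=0.05, n_plaques=0,
                                         caa_segment_count=0, astro_count=1))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SectionSpec(vessel_density=1.5)
        with pytest.raises(ValueError):
            SectionSpec(astro_vessel_assoc_prob=0.7,
                        astro_plaque_assoc_prob=0.7)
        with pytest.raises(ValueError):
            SectionSpec(background_level=300.0)


class TestGenerateCohort:
    BASE = dict(shape_px=(128, 128), n_plaques=4, caa_segment_count=1,
                astro_count=20, icam_parenchymal_blob_count=3)

    def test_missing_group_rejected(self):
        specs = {("WT", "HEM"): SectionSpec(**self.BASE)}
        with pytest.raises(ValueError, match="missing group"):
            generate_cohort(specs, n_per_group=2)

    def test_zero_animals_rejected(self):
        specs = {g: SectionSpec(**self.BASE) for g in GROUPS}
        with pytest.raises(ValueError):
            generate_cohort(specs, n_per_group=0)

    def test_cohort_structure_and_determinism(self):
        specs = {g: SectionSpec(**self.BASE) for g in GROUPS}
        s1, d1, t1 = generate_cohort(specs, n_per_group=2,
                                     sections_per_animal=2, seed=5)
        s2, d2, t2 = generate_cohort(specs, n_per_group=2,
                                     sections_per_animal=2, seed=5)
        assert len(d1) == 8 and len(s1) == 16
        assert [r.animal_id for r in d1] == [r.animal_id for r in d2]
        pd.testing.assert_frame_equal(t1, t2)

    def test_configured_effect_shows_in_truth(self):
        specs = {g: SectionSpec(**self.BASE) for g in GROUPS}
        boosted = dict(self.BASE)
        boosted["caa_segment_count"] = 3
        specs[("APPPS1", "KO")] = SectionSpec(**boosted)
        _, design, truth = generate_cohort(specs, n_per_group=3,
                                           sections_per_animal=2, seed=9)
        dd = pd.DataFrame([dataclasses.asdict(r) for r in design])
        caa = truth[(truth.metric == "caa_area_pct")
                    & (truth.region == "cortex")]
        caa = caa.merge(dd, on="animal_id")
        means = caa.groupby("apoa1_genotype")["value"].mean()
        ko = caa[(caa.app_genotype == "APPPS1")
                 & (caa.apoa1_genotype == "KO")]["value"].mean()
        hem = caa[(caa.app_genotype == "APPPS1")
                  & (caa.apoa1_genotype == "HEM")]["value"].mean()
        assert ko > 1.5 * hem  # 3x configured burden, wide sampling noise


class TestSimulateMetricTable:
    def test_group_means_recovered(self):
        means = {("WT", "HEM"): 1.0, ("WT", "KO"): 1.0,
                 ("APPPS1", "HEM"): 2.0, ("APPPS1", "KO"): 6.0}
        df = simulate_metric_table(means, n_per_group=400, cv=0.3, seed=0)
        got = df.groupby(["app_genotype", "apoa1_genotype"])["value"].mean()
        for (app, apo), mu in means.items():
            assert got[(app, apo)] == pytest.approx(mu, rel=0.1)

    def test_deterministic(self):
        means = {g: 1.0 for g in GROUPS}
        df1 = simulate_metric_table(means, 5, seed=3)
        df2 = simulate_metric_table(means, 5, seed=3)
        pd.testing.assert_frame_equal(df1, df2)

    def test_positive_values(self):
        df = simulate_metric_table({g: 0.05 for g in GROUPS}, 20, seed=1)
        assert (df["value"] > 0).all()
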