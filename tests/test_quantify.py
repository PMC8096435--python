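"""N/C ratios, cell sampling, inner/outer classes, profiles, expression."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from embryopulse import quantify, synthetic


class TestNCRatio:
    def test_uniform_image_gives_one(self):
        img = np.full((60, 60), 37.0)
        r = quantify.nc_ratio(img, (20, 20), (40, 40), pixel_size=0.5)
        assert r == pytest.approx(1.0)

    def test_two_compartment_truth_recovered(self):
        stack, rois, px = synthetic.make_stain_stack(12, 2.0, seed=0,
                                                     noise_sd=0.0)
        recs = quantify.measure_cells(stack[0], rois, px)
        for r in recs:
            assert r.nc_ratio == pytest.approx(2.0, abs=0.02)

    @given(scale=st.floats(0.1, 100.0))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_scale_invariant_offset_not(self, scale):
        rng = np.random.default_rng(4)
        img = rng.uniform(50, 150, (60, 60))
        base = quantify.nc_ratio(img, (15, 15), (45, 45), pixel_size=0.5)
        scaled = quantify.nc_ratio(img * scale, (15, 15), (45, 45),
                                   pixel_size=0.5)
        offset = quantify.nc_ratio(img + 100.0, (15, 15), (45, 45),
                                   pixel_size=0.5)
        assert scaled == pytest.approx(base, rel=1e-9)
        assert offset != pytest.approx(base, rel=1e-3)

    def test_roi_off_image_rejected(self):
        img = np.ones((20, 20))
        with pytest.raises(ValueError):
            quantify.nc_ratio(img, (1, 1), (50, 50), pixel_size=0.5)

    def test_zero_cytoplasm_rejected(self):
        img = np.zeros((60, 60))
        img[10:20, 10:20] = 5.0
        with pytest.raises(ValueError, match="cytoplasm"):
            quantify.nc_ratio(img, (15, 15), (45, 45), pixel_size=0.5)


class TestSampleCells:
    @staticmethod
    def _cells(n_icm, n_polar, n_mural):
        rows = ([{"lineage_class": "ICM"}] * n_icm
                + [{"lineage_class": "polar-TE"}] * n_polar
                + [{"lineage_class": "mural-TE"}] * n_mural)
        return pd.DataFrame(rows)

    def test_small_embryo_measured_in_full(self):
        cells = self._cells(2, 3, 3)
        assert len(quantify.sample_cells(cells)) == 8

    def test_icm_shortfall_replaced_by_te(self):
        cells = self._cells(3, 10, 10)
        sel = quantify.sample_cells(cells, seed=1)
        assert len(sel) == 15
        assert (sel.lineage_class == "ICM").sum() == 3
        assert sel.lineage_class.str.endswith("TE").sum() == 12

    def test_full_complement_gives_15(self):
        cells = self._cells(8, 9, 7)
        sel = quantify.sample_cells(cells, seed=2)
        assert len(sel) == 15
        assert (sel.lineage_class == "ICM").sum() == 5
        assert (sel.lineage_class == "polar-TE").sum() == 5
        assert (sel.lineage_class == "mural-TE").sum() == 5


class TestInnerOuter:
    def test_single_cell_is_outer(self):
        labels, mask, _ = synthetic.stain_label_image(1, seed=0)
        cls = quantify.classify_inner_outer(labels, mask)
        assert cls.position_class.tolist() == ["outer"]

    def test_concentric_enclosed_cell_is_inner(self):
        mask = np.zeros((40, 40), dtype=bool)
        yy, xx = np.ogrid[:40, :40]
        mask[(yy - 20) ** 2 + (xx - 20) ** 2 <= 15 ** 2] = True
        labels = np.where(mask, 1, 0)
        labels[(yy - 20) ** 2 + (xx - 20) ** 2 <= 6 ** 2] = 2
        cls = quantify.classify_inner_outer(labels, mask)
        assert dict(zip(cls.cell_id, cls.position_class)) == \
            {1: "outer", 2: "inner"}

    def test_generator_truth_recovered(self):
        labels, mask, rois = synthetic.stain_label_image(
            20, inner_fraction=0.3, seed=0)
        cls = quantify.classify_inner_outer(labels, mask)
        assert (cls.position_class == "inner").sum() == 6
        truth = rois.sort_values("cell_id").position_true.to_numpy()
        assert (cls.sort_values("cell_id").position_class.to_numpy()
                == truth).all()

    def test_partition_is_complete(self):
        labels, mask, _ = synthetic.stain_label_image(
            14, inner_fraction=0.25, seed=3)
        cls = quantify.classify_inner_outer(labels, mask)
        inner = (cls.position_class == "inner").sum()
        outer = (cls.position_class == "outer").sum()
        assert inner + outer == len(cls) == 14

    def test_removing_interior_cell_preserves_other_classes(self):
        labels, mask, _ = synthetic.stain_label_image(
            20, inner_fraction=0.3, seed=0)
        before = quantify.classify_inner_outer(labels, mask)
        some_inner = int(before.cell_id[
            before.position_class == "inner"].iloc[0])
        pruned = labels.copy()
        pruned[pruned == some_inner] = 0
        after = quantify.classify_inner_outer(pruned, mask)
        merged = before.merge(after, on="cell_id",
                              suffixes=("_before", "_after"))
        assert (merged.position_class_before
                == merged.position_class_after).all()


class TestLineProfile:
    def test_constant_image_degenerate_zeros(self):
        img = np.full((50, 80), 9.0)
        prof = quantify.line_profile(img, (25, 5), (0, 1), pixel_size=0.5)
        assert np.allclose(prof.normalized_intensity, 0.0)
        assert prof.attrs["degenerate"]

    def test_linear_gradient_is_unit_ramp(self):
        img = np.tile(np.arange(80.0), (50, 1))
        prof = quantify.line_profile(img, (25, 5), (0, 1), pixel_size=0.5)
        ramp = prof.normalized_intensity.to_numpy()
        assert ramp[0] == pytest.approx(0.0, abs=1e-9)
        assert ramp[-1] == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(ramp) >= -1e-9)

    def test_membrane_band_peak_at_generated_depth(self):
        img, start, direction = synthetic.make_polarity_image(8.0)
        prof = quantify.line_profile(img, start, direction, pixel_size=0.5)
        peak_depth = prof.distance_um[prof.normalized_intensity.idxmax()]
        assert peak_depth == pytest.approx(8.0, abs=0.5)


class TestReporterIntensity:
    def test_embryo_equal_to_background_gives_zero(self):
        img = np.full((300, 300), 80.0)
        val = quantify.reporter_intensity(img, (150, 150), (20, 20),
                                          pixel_size=0.5)
        assert val == pytest.approx(0.0)

    def test_background_subtraction(self):
        img = np.full((300, 300), 50.0)
        yy, xx = np.ogrid[:300, :300]
        img[(yy - 150) ** 2 + (xx - 150) ** 2 <= 100 ** 2] = 300.0
        val = quantify.reporter_intensity(img, (150, 150), (15, 15),
                                          pixel_size=0.5)
        assert val == pytest.approx(250.0)

    def test_normalization_maps_zygote_mean_to_one(self):
        values = pd.Series([10.0, 12.0, 5.0, 6.0])
        stages = pd.Series(["zygote", "zygote", "morula", "morula"])
        normed = quantify.normalize_to_stage(values, stages)
        assert normed[stages == "zygote"].mean() == pytest.approx(1.0)


class TestRelativeExpression:
    def test_closed_forms(self):
        assert quantify.relative_expression(20.0, 20.0) == pytest.approx(1.0)
        assert quantify.relative_expression(22.0, 20.0) == pytest.approx(0.25)
        assert quantify.relative_expression(19.0, 20.0) == pytest.approx(2.0)

    def test_triplicates_averaged_on_ct_scale(self):
        val = quantify.relative_expression([20.0, 21.0, 22.0], 20.0)
        assert val == pytest.approx(2.0 ** -1.0)

    def test_monotone_in_both_arguments(self):
        base = quantify.relative_expression(20.0, 18.0)
        assert quantify.relative_expression(21.0, 18.0) < base
        assert quantify.relative_expression(20.0, 19.0) > base

    def test_reference_scaling(self):
        assert quantify.relative_expression(20.0, 20.0, reference=4.0) == \
            pytest.approx(0.25)

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValueError):
            quantify.relative_expression(np.nan, 20.0)

    def test_expression_table_calibrated(self):
        ct = pd.DataFrame(
            {"sample": ["zygote"] * 6 + ["morula"] * 4,
             "gene": (["Myh9"] * 2 + ["Myh10"] * 2 + ["Gapdh"] * 2
                      + ["Myh9"] * 2 + ["Gapdh"] * 2),
             "ct": [20.0, 20.0, 24.0, 24.0, 20.0, 20.0,
                    19.0, 19.0, 20.0, 20.0],
             "replicate": [1, 2] * 5})
        out = quantify.expression_table(ct,
                                        calibrator=("zygote", "Myh9"))
        vals = out.set_index(["sample", "gene"]).fold_change
        assert vals[("zygote", "Myh9")] == pytest.approx(1.0)
        assert vals[("zygote", "Myh10")] == pytest.approx(2.0 ** -4)
        assert vals[("morula", "Myh9")] == pytest.approx(2.0)
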