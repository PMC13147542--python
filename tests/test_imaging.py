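"""Adhesion-imaging pipeline: normalization, layout, measurement, ratios."""

import numpy as np
import pandas as pd
import pytest

from mlpquant import imaging, synth
from mlpquant.imaging import (
    DensityGrid,
    GrayImage,
    LayoutError,
    adhesion_from_pair,
    build_reference_layout,
    fit_layout,
    invert_normalize,
    measure_grid,
    summarize_strain,
)


class TestInvertNormalize:
    def test_uniform_white_image_maps_to_zeros_with_warning(self):
        image = GrayImage(np.full((20, 20), 255.0))
        with pytest.warns(UserWarning, match="white level"):
            out = invert_normalize(image)
        assert np.all(out == 0)

    def test_endpoints_map_to_unit_interval_extremes(self):
        image = GrayImage(np.array([[0.0, 255.0]]))
        out = invert_normalize(image)
        assert out[0, 0] == 1.0 and out[0, 1] == 0.0

    def test_matches_elementwise_brute_force_on_rendered_plate(self):
        pre, _, _ = synth.render_plate_pair(synth.default_plate_spec(seed=3))
        out = invert_normalize(pre)
        inv = 255.0 - pre.pixels  # independent recomputation
        expected = inv / inv.max()
        np.testing.assert_allclose(out, expected)

    def test_rescaled_output_is_a_fixed_point_up_to_quantization(self):
        pre, _, _ = synth.render_plate_pair(synth.default_plate_spec(seed=4))
        once = invert_normalize(pre)
        requantized = np.round(255.0 * (1.0 - once))
        twice = invert_normalize(GrayImage(requantized))
        assert np.abs(once - twice).max() < 1.0 / 255.0 + 1e-12


class TestLayout:
    def test_recovers_planted_box_centers(self, filled_plate, reference_layout):
        spec, _ = filled_plate
        centers = reference_layout.centers
        planted_rows = spec.margin + spec.pitch * (np.arange(8) + 0.5)
        planted_cols = spec.margin + spec.pitch * (np.arange(12) + 0.5)
        assert np.abs(centers[:, 0, 0] - planted_rows).max() <= 3
        assert np.abs(centers[0, :, 1] - planted_cols).max() <= 3

    def test_translation_equivariance_of_layout_construction(self, filled_plate):
        spec, image = filled_plate
        shifted = np.roll(image.pixels, (10, 7), axis=(0, 1))
        layout_a = build_reference_layout(image)
        layout_b = build_reference_layout(GrayImage(shifted))
        delta = layout_b.centers - layout_a.centers
        assert np.abs(delta[..., 0] - 10).max() <= 3
        assert np.abs(delta[..., 1] - 7).max() <= 3

    def test_blank_image_raises_layout_error(self):
        blank = GrayImage(np.full((300, 420), 255.0))
        with pytest.raises(LayoutError), pytest.warns(UserWarning):
            build_reference_layout(blank)

    def test_edge_mask_has_36_perimeter_positions(self, reference_layout):
        mask = reference_layout.edge_mask
        assert mask.sum() == 36 and (~mask).sum() == 60

    def test_boxes_do_not_overlap(self, reference_layout):
        boxes = reference_layout.boxes.reshape(-1, 4)
        for i in range(len(boxes)):
            t1, l1, b1, r1 = boxes[i]
            for j in range(i + 1, len(boxes)):
                t2, l2, b2, r2 = boxes[j]
                assert b1 <= t2 or b2 <= t1 or r1 <= l2 or r2 <= l1


class TestFitLayout:
    def test_identity_image_gives_zero_offset(self, filled_plate, reference_layout):
        _, image = filled_plate
        fitted = fit_layout(reference_layout, image, max_shift_px=10)
        offset = fitted.boxes[0, 0, :2] - reference_layout.boxes[0, 0, :2]
        assert np.abs(offset).max() <= 1

    def test_recovers_planted_shift(self, reference_layout):
        spec = synth.default_plate_spec(seed=2, shift=(-6, 4))
        pre, _, _ = synth.render_plate_pair(spec)
        fitted = fit_layout(reference_layout, pre, max_shift_px=20)
        offset = fitted.boxes[0, 0, :2] - reference_layout.boxes[0, 0, :2]
        assert abs(offset[0] - (-6)) <= 1 and abs(offset[1] - 4) <= 1

    def test_shift_beyond_search_range_warns_on_boundary(self, reference_layout):
        spec = synth.default_plate_spec(seed=2, shift=(12, 0))
        pre, _, _ = synth.render_plate_pair(spec)
        with pytest.warns(UserWarning, match="boundary"):
            fit_layout(reference_layout, pre, max_shift_px=5)


class TestMeasureGrid:
    def test_all_white_image_measures_zero_everywhere(self, reference_layout):
        bottom, right = reference_layout.extent[2:]
        image = GrayImage(np.full((bottom + 20, right + 20), 255.0))
        with pytest.warns(UserWarning):
            grid = measure_grid(image, reference_layout, controls=[(7, 11)])
        assert np.all(grid.values == 0)

    def test_recovers_planted_densities_within_sidecar_tolerance(
        self, reference_layout
    ):
        spec = synth.default_plate_spec(seed=6, noise_sd=3.0)
        pre, _, truth = synth.render_plate_pair(spec)
        fitted = fit_layout(reference_layout, pre, max_shift_px=10)
        grid = measure_grid(pre, fitted, controls=[(7, 11)])
        expected = truth.set_index(["row", "col"])["expected_pre"]
        for (r, c), exp in expected.items():
            assert grid.values[r, c] == pytest.approx(exp, abs=0.02)

    def test_requires_at_least_one_control(self, reference_layout, filled_plate):
        _, image = filled_plate
        with pytest.raises(ValueError, match="control"):
            measure_grid(image, reference_layout, controls=[])

    def test_control_position_reports_zero(self, reference_layout):
        spec = synth.default_plate_spec(seed=7)
        pre, _, _ = synth.render_plate_pair(spec)
        fitted = fit_layout(reference_layout, pre, max_shift_px=10)
        grid = measure_grid(pre, fitted, controls=[(7, 11)])
        assert grid.values[7, 11] == pytest.approx(0.0, abs=0.005)

    def test_background_offset_is_absorbed_by_controls(self, reference_layout):
        # moderate densities keep every colony pixel inside the dynamic
        # range after the offset; only the black fiducial stays clipped
        rng = np.random.default_rng(8)
        spec = synth.PlateSpec(
            densities=rng.uniform(0.2, 0.5, (8, 12)),
            ratios=np.full((8, 12), 0.5),
            noise_sd=0.5,
            seed=8,
        )
        pre, _, _ = synth.render_plate_pair(spec)
        fitted = fit_layout(reference_layout, pre, max_shift_px=10)
        base = measure_grid(pre, fitted, controls=[(7, 11)])
        offset_img = GrayImage(np.clip(pre.pixels - 15.0, 0, 255))
        shifted = measure_grid(offset_img, fitted, controls=[(7, 11)])
        assert np.abs(base.values - shifted.values).max() < 0.01


class TestAdhesionFromPair:
    def _grid(self, values):
        return DensityGrid(
            values=np.asarray(values, dtype=float),
            control_positions=((0, 0),),
            background=0.0,
        )

    def test_identical_grids_give_unit_ratios(self):
        grid = self._grid(np.full((2, 3), 0.5))
        table = adhesion_from_pair(grid, grid)
        assert np.allclose(table["ratio"], 1.0)

    def test_strong_adhesion_boundary_value(self):
        pre = self._grid([[0.5]])
        post = self._grid([[0.1]])
        table = adhesion_from_pair(pre, post)
        assert table["ratio"].iloc[0] == pytest.approx(0.2)

    def test_low_prewash_density_flags_no_growth(self):
        pre = self._grid([[0.05]])
        post = self._grid([[0.04]])
        table = adhesion_from_pair(pre, post)
        assert not table["grew"].iloc[0]
        assert np.isnan(table["ratio"].iloc[0])

    def test_mismatched_shapes_raise(self):
        with pytest.raises(ValueError, match="shape"):
            adhesion_from_pair(
                self._grid(np.zeros((2, 2))), self._grid(np.zeros((3, 2)))
            )

    def test_ratios_above_one_are_reported_and_flagged(self):
        table = adhesion_from_pair(self._grid([[0.4]]), self._grid([[0.5]]))
        assert table["ratio"].iloc[0] == pytest.approx(1.25)
        assert bool(table["ratio_above_one"].iloc[0])


class TestSummarizeStrain:
    def _records(self, rows):
        return pd.DataFrame(
            rows, columns=["row", "col", "pre_density", "post_density", "ratio", "grew"]
        )

    def _map(self):
        grid = np.array(
            [[f"s{r}_{c}" for c in range(12)] for r in range(8)], dtype=object
        )
        grid[7, 11] = "EMPTY"
        return grid

    def test_low_growth_strain_is_excluded(self):
        records = self._records(
            [(1, 1, 0.05, 0.01, 0.2, False), (1, 1, 0.08, 0.01, 0.125, False)]
        )
        out = summarize_strain(records, self._map())
        assert bool(out.loc[out.strain == "s1_1", "excluded"].iloc[0])
        assert out["mean_pre"].iloc[0] == pytest.approx(0.065)

    def test_interior_only_keeps_the_middle_60_positions(self):
        rows = [
            (r, c, 0.5, 0.25, 0.5, True) for r in range(8) for c in range(12)
        ]
        out = summarize_strain(self._records(rows), self._map(), interior_only=True)
        assert out["n_replicates"].sum() == 60

    def test_single_grown_replicate_summary_is_identity(self):
        records = self._records([(2, 3, 0.6, 0.3, 0.5, True)])
        out = summarize_strain(records, self._map())
        row = out.iloc[0]
        assert row["mean_pre"] == 0.6 and row["mean_ratio"] == 0.5
        assert row["n_valid"] == 1 and not row["excluded"]

    def test_unmapped_position_raises_with_location(self):
        grid = self._map()
        grid[3, 3] = ""
        records = self._records([(3, 3, 0.5, 0.2, 0.4, True)])
        with pytest.raises(ValueError, match=r"\(3, 3\)"):
            summarize_strain(records, grid)


def test_full_pipeline_through_image_files(tmp_path, filled_plate):
    """Folder-level pipeline: PNG round trip, pairing, mapping, summary."""
    from skimage import io as skio

    _, filled = filled_plate
    (tmp_path / "pre").mkdir()
    (tmp_path / "post").mkdir()
    spec = synth.default_plate_spec(seed=9, noise_sd=2.0)
    pre, post, truth = synth.render_plate_pair(spec)
    skio.imsave(str(tmp_path / "pre" / "p1.png"), pre.pixels.astype(np.uint8))
    skio.imsave(str(tmp_path / "post" / "p1.png"), post.pixels.astype(np.uint8))
    skio.imsave(str(tmp_path / "filled.png"), filled.pixels.astype(np.uint8))
    strain_map = np.array(
        [[f"s{r}_{c}" for c in range(12)] for r in range(8)], dtype=object
    )
    strain_map[7, 11] = "EMPTY"
    pd.DataFrame(strain_map).to_csv(tmp_path / "map.csv", header=False, index=False)

    long, summary = imaging.quantify_adhesion(
        tmp_path / "pre", tmp_path / "post", tmp_path / "map.csv",
        tmp_path / "filled.png",
    )
    assert len(long) == 96
    merged = long.merge(truth, on=["row", "col"], suffixes=("_m", "_t"))
    grown = merged[merged["expected_pre"] >= 0.2]
    assert (grown["ratio_m"] - grown["ratio_t"]).abs().max() < 0.05
    assert "s3_4" in set(summary["strain"]) and "EMPTY" not in set(summary["strain"])
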