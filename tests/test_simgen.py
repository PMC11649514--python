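"""Synthetic-slide generator: regions, point process, rendering, I/O."""

import numpy as np
import pandas as pd
import pytest
import shapely
from scipy.spatial import cKDTree

import ki67hotspot as k
from ki67hotspot.errors import ConfigurationError
from ki67hotspot.simgen import (HOTSPOT_WINDOW_SIDE_UM, positivity_field,
                                rasterize_polygons)
from .conftest import compact_spec, registration_spec


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestRegions:
    def test_degenerate_counts_give_invasive_plus_stroma(self):
        spec = compact_spec(0)
        regions = k.generate_regions(spec, _rng())
        classes = sorted(r.region_class for r in regions)
        assert classes == ["invasive_tumour", "stroma"]

    def test_regions_are_simple_and_disjoint(self):
        spec = k.SlideSpec(width_um=2000, height_um=2000,
                           hotspot_center_um=(900, 900), seed=1)
        regions = k.generate_regions(spec, _rng(1))
        assert sum(r.region_class == "invasive_tumour" for r in regions) == 1
        assert sum(r.region_class == "benign_epithelium" for r in regions) == 2
        assert sum(r.region_class == "carcinoma_in_situ" for r in regions) == 1
        for r in regions:
            assert r.polygon.is_valid
        for i, a in enumerate(regions):
            for b in regions[i + 1:]:
                overlap = a.polygon.intersection(b.polygon).area
                assert overlap < 1e-6 * min(a.polygon.area, b.polygon.area)

    def test_invasive_covers_30pct_and_contains_window(self):
        spec = k.SlideSpec(seed=3)
        regions = k.generate_regions(spec, _rng(3))
        invasive = next(r for r in regions if r.region_class == "invasive_tumour")
        assert invasive.polygon.area >= 0.30 * spec.width_um * spec.height_um
        half = HOTSPOT_WINDOW_SIDE_UM / 2
        cx, cy = spec.hotspot_center_um
        window = shapely.box(cx - half, cy - half, cx + half, cy + half)
        assert invasive.polygon.contains(window)

    def test_corner_hotspot_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            k.SlideSpec(width_um=1000, height_um=1000, hotspot_center_um=(10, 10))

    def test_extent_below_window_rejected(self):
        with pytest.raises(ConfigurationError):
            k.SlideSpec(width_um=500, height_um=500, hotspot_center_um=(250, 250))


class TestSampleCells:
    def test_zero_positivity_means_all_negative(self):
        spec = compact_spec(4, baseline_positivity=0.0, hotspot_peak_positivity=0.0)
        regions = k.generate_regions(spec, _rng(4))
        cells = k.sample_cells(spec, regions, _rng(4))
        assert (cells["ki67_class"] == "negative").all()

    def test_count_matches_density_times_area(self):
        spec = k.SlideSpec(seed=5)
        regions = k.generate_regions(spec, _rng(5))
        cells = k.sample_cells(spec, regions, _rng(5))
        invasive = next(r for r in regions if r.region_class == "invasive_tumour")
        expected = spec.tumour_density_per_mm2 * invasive.polygon.area / 1e6
        n = (cells["region_class"] == "invasive_tumour").sum()
        assert abs(n - expected) <= 3 * np.sqrt(expected)

    def test_hard_core_separation(self):
        spec = compact_spec(6)
        regions = k.generate_regions(spec, _rng(6))
        cells = k.sample_cells(spec, regions, _rng(6))
        xy = cells[["x_um", "y_um"]].to_numpy()
        diam = cells["diameter_um"].to_numpy()
        pairs = cKDTree(xy).query_pairs(spec.nucleus_diameter_range_um[1],
                                        output_type="ndarray")
        for i, j in pairs:
            dist = np.hypot(*(xy[i] - xy[j]))
            assert dist >= max(diam[i], diam[j]) - 1e-9

    def test_no_cell_in_stroma_and_each_in_its_region(self):
        spec = registration_spec(8)
        regions = k.generate_regions(spec, _rng(8))
        cells = k.sample_cells(spec, regions, _rng(8))
        assert not (cells["region_class"] == "stroma").any()
        sample = cells.sample(n=min(400, len(cells)), random_state=0)
        lookup = {r.region_class: r.polygon for r in regions}
        for _, row in sample.iterrows():
            pt = shapely.points(row.x_um, row.y_um)
            hits = [cls for cls, poly in lookup.items()
                    if poly.buffer(1e-6).contains(pt)]
            assert row.region_class in hits

    def test_planted_gradient_across_bank(self, default_bank):
        """Near-centre positivity beats far positivity in ≥99% of seeds."""
        wins = 0
        for case in default_bank:
            spec = case.spec
            inv = case.cells[case.cells["region_class"] == "invasive_tumour"]
            cx, cy = spec.hotspot_center_um
            d = np.hypot(inv["x_um"] - cx, inv["y_um"] - cy)
            pos = (inv["ki67_class"] == "positive").to_numpy()
            near = pos[d <= spec.hotspot_radius_um]
            far = pos[d > 3 * spec.hotspot_radius_um]
            wins += near.mean() >= far.mean()
        assert wins >= 99

    def test_planted_window_positivity_within_3sd(self, default_bank):
        for case in default_bank[:20]:
            spec = case.spec
            half = HOTSPOT_WINDOW_SIDE_UM / 2
            cx, cy = spec.hotspot_center_um
            inv = case.cells[case.cells["region_class"] == "invasive_tumour"]
            sel = ((inv["x_um"] >= cx - half) & (inv["x_um"] < cx + half)
                   & (inv["y_um"] >= cy - half) & (inv["y_um"] < cy + half))
            win = inv[sel]
            pbar = k.simgen.planted_window_positivity(spec)
            sd = np.sqrt(pbar * (1 - pbar) / len(win))
            assert abs((win["ki67_class"] == "positive").mean() - pbar) <= 3 * sd


class TestRendering:
    def test_zero_cells_renders_pure_background(self):
        spec = compact_spec(9, tumour_density_per_mm2=0)
        empty = pd.DataFrame(columns=["x_um", "y_um", "diameter_um",
                                      "ki67_class", "region_class"])
        img = k.simgen.render_ki67_image(empty, [], spec, _rng(9))
        od = k.rgb_to_od(img)
        assert od.max() < 0.05

    def test_single_positive_nucleus_dab_profile(self):
        spec = compact_spec(10)
        cells = pd.DataFrame({"x_um": [500.0], "y_um": [500.0],
                              "diameter_um": [8.0], "ki67_class": ["positive"],
                              "region_class": ["invasive_tumour"]})
        img = k.simgen.render_ki67_image(cells, [], spec, _rng(10))
        conc = k.deconvolve(k.rgb_to_od(img))
        yy, xx = np.mgrid[0:1000, 0:1000]
        dist = np.hypot(xx + 0.5 - 500, yy + 0.5 - 500)
        assert conc.dab[dist <= 3.0].mean() > 0.3
        assert np.abs(conc.dab[dist > 8.0]).max() < 0.05

    def test_same_seed_bit_identical(self):
        spec = compact_spec(11)
        a = k.generate_case(spec)
        b = k.generate_case(spec)
        assert np.array_equal(a.ki67_image, b.ki67_image)
        assert np.array_equal(a.ck_image, b.ck_image)
        assert a.cells.equals(b.cells)
        assert a.true_serial_transform == b.true_serial_transform

    def test_vector_raster_consistency(self, rendered_case):
        """Rendered disc centroids sit on the table centroids (≤1 px)."""
        from scipy import ndimage as ndi

        conc = k.deconvolve(k.rgb_to_od(rendered_case.ki67_image))
        total = np.clip(conc.haematoxylin, 0, None) + np.clip(conc.dab, 0, None)
        labels, n = ndi.label(total > 0.4)
        centroids = np.array(ndi.center_of_mass(total > 0.4, labels,
                                                np.arange(1, n + 1)))
        centroids_um = centroids[:, ::-1] + 0.5
        tree = cKDTree(centroids_um)
        xy = rendered_case.cells[["x_um", "y_um"]].to_numpy()
        d, _ = tree.query(xy, k=1)
        # isolated nuclei must land within a pixel; merged blobs are excluded
        assert np.median(d) <= 1.0


class TestCkSerial:
    def test_identity_transform_matches_polygon_raster(self, identity_pair):
        spec = identity_pair.spec
        conc = k.deconvolve(k.rgb_to_od(identity_pair.ck_image))
        ck_mask = conc.dab > 0.15
        gt = rasterize_polygons(
            [r for r in identity_pair.regions if r.region_class != "stroma"],
            spec.shape_px, spec.resolution_um_per_px)
        inter = (ck_mask & gt).sum()
        union = (ck_mask | gt).sum()
        assert inter / union >= 0.98

    def test_known_shift_matches_shifted_raster(self, serial_pair):
        import shapely.affinity

        spec = serial_pair.spec
        t = serial_pair.true_serial_transform
        assert (t.dx_um, t.dy_um, t.theta_deg) == (120.0, -80.0, 1.0)
        centre = (spec.width_um / 2, spec.height_um / 2)
        moved = [shapely.affinity.translate(
            shapely.affinity.rotate(r.polygon, t.theta_deg, origin=centre),
            t.dx_um, t.dy_um)
            for r in serial_pair.regions if r.region_class != "stroma"]
        gt = rasterize_polygons(moved, spec.shape_px, spec.resolution_um_per_px)
        conc = k.deconvolve(k.rgb_to_od(serial_pair.ck_image))
        ck_mask = conc.dab > 0.15
        inter = (ck_mask & gt).sum()
        union = (ck_mask | gt).sum()
        assert inter / union >= 0.98

    def test_non_serial_has_no_rigid_alignment(self, nonserial_pair):
        reg = k.register_serial(nonserial_pair.ck_image, nonserial_pair.ki67_image,
                                nonserial_pair.resolution_um_per_px)
        assert reg.alignment_score < 0.6


class TestCaseIO:
    def test_write_read_round_trip_and_determinism(self, tmp_path, rendered_case):
        m1 = k.write_case(rendered_case, tmp_path / "case")
        again = k.read_case(tmp_path / "case")
        pd.testing.assert_frame_equal(again.cells, rendered_case.cells)
        assert np.array_equal(again.ki67_image, rendered_case.ki67_image)
        assert again.spec.as_dict() == rendered_case.spec.as_dict()
        m2 = k.write_case(rendered_case, tmp_path / "case2")
        assert m1 == m2

    def test_geojson_vertices_preserved(self, tmp_path, rendered_case):
        k.write_case(rendered_case, tmp_path / "case")
        again = k.read_case(tmp_path / "case")
        for a, b in zip(rendered_case.regions, again.regions):
            assert a.region_class == b.region_class
            assert a.polygon.symmetric_difference(b.polygon).area < 1e-6
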