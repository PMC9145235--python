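"""Shape descriptors, zone thicknesses and the 36-trait vector."""

import math

import numpy as np
import pytest

from shankvb import registry
from shankvb.exceptions import ValidationError
from shankvb.geometry import chain_perimeter_px, pixel_corner_points, region_geometry
from shankvb.imaging import BundleRegion, partition_zones, segment_section
from shankvb.synthetic import rasterize_scene
from shankvb.traits import compute_trait_vector, zone_thickness

from conftest import brute_force_hull_area, random_blob


def disk_mask(r, pad=4):
    yy, xx = np.mgrid[0 : 2 * r + 2 * pad + 1, 0 : 2 * r + 2 * pad + 1]
    return (yy - r - pad) ** 2 + (xx - r - pad) ** 2 <= r * r


class TestRegionGeometry:
    def test_digital_disk_analytic(self):
        # radius 50 px at 13.55 um/px: area ~ pi * 0.6775^2 = 1.4419 mm^2
        g = region_geometry(disk_mask(50), 13.55)
        assert abs(g.area_mm2 - 1.4419) / 1.4419 < 0.02
        assert 0.97 <= g.car <= 1.0
        true_p = 2 * math.pi * 50 * 13.55 / 1000
        assert abs(g.perimeter_mm - true_p) / true_p < 0.05

    def test_square_circumcircle_ratio(self):
        g = region_geometry(np.ones((40, 40), bool), 13.55)
        assert abs(g.circumcircle_area_mm2 / g.area_mm2 - math.pi / 2) < 0.03 * math.pi / 2

    def test_hull_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            blob = random_blob(rng, n_px=int(rng.integers(5, 31)))
            g = region_geometry(blob, 1000.0)
            oracle = brute_force_hull_area(pixel_corner_points(blob))
            assert g.convex_area_mm2 == pytest.approx(oracle, rel=1e-9)

    def test_geometry_chain_inequality(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            blob = random_blob(rng, n_px=int(rng.integers(1, 60)))
            g = region_geometry(blob, 13.55)
            assert g.area_mm2 <= g.convex_area_mm2 * (1 + 1e-12)
            assert g.convex_area_mm2 <= g.circumcircle_area_mm2 * (1 + 1e-9)
            assert g.major_axis_mm >= g.minor_axis_mm > 0
            assert g.lwr >= 1.0
            assert 0 < g.car <= 1.0

    def test_scale_equivariance_is_exact(self):
        blob = random_blob(np.random.default_rng(3), 40)
        g1 = region_geometry(blob, 10.0)
        g2 = region_geometry(blob, 20.0)
        assert g2.area_mm2 == pytest.approx(4 * g1.area_mm2, rel=1e-12)
        assert g2.convex_area_mm2 == pytest.approx(4 * g1.convex_area_mm2, rel=1e-12)
        assert g2.circumcircle_area_mm2 == pytest.approx(
            4 * g1.circumcircle_area_mm2, rel=1e-12)
        assert g2.perimeter_mm == pytest.approx(2 * g1.perimeter_mm, rel=1e-12)
        assert g2.major_axis_mm == pytest.approx(2 * g1.major_axis_mm, rel=1e-12)
        assert g2.lwr == pytest.approx(g1.lwr, rel=1e-12)

    def test_single_pixel_region(self):
        g = region_geometry(np.array([[5, 5]]), 1000.0)
        assert g.area_mm2 == pytest.approx(1.0)
        assert g.car == pytest.approx(1.0)
        assert g.perimeter_mm == pytest.approx(4.0)

    def test_empty_region_raises(self):
        with pytest.raises(ValidationError):
            region_geometry(np.empty((0, 2), int), 13.55)

    def test_plain_chain_weights_on_square(self):
        # a k x k square traversed axially: 4(k-1) steps of weight 1
        assert chain_perimeter_px(np.ones((12, 12), bool),
                                  corner_corrected=False) == pytest.approx(44.0)


@pytest.fixture(scope="module")
def round_partition():
    m = disk_mask(369)  # 5 mm at 13.55 um/px
    img = rasterize_scene(m, [], [])
    mask = segment_section(img)
    return partition_zones(mask, [], ez_thickness_mm=0.08,
                           pz_policy=("fixed_depth", 1.08))


@pytest.fixture(scope="module")
def scene_traits(analyzed_scene):
    img, truth, mask, part_valley, det = analyzed_scene
    part = partition_zones(
        mask, det.bundles,
        pz_policy=("fixed_depth", truth.pz_boundary_depth_mm),
    )
    from shankvb.imaging import assign_zones

    assign_zones(det.bundles, part)
    return compute_trait_vector(mask, part, det.bundles), truth


class TestZoneThickness:
    def test_ez_thickness_recovered(self, round_partition):
        assert abs(zone_thickness(round_partition, "EZ") - 0.08) <= 0.01355

    def test_band_additivity(self, round_partition):
        ez = zone_thickness(round_partition, "EZ")
        pz = zone_thickness(round_partition, "PZ")
        assert abs(ez + pz - 1.08) <= 0.01355

    def test_iz_radius_recovered(self, round_partition):
        # IZ_T is the radial distance to the PZ/IZ boundary: 5.0 - 1.08
        assert abs(zone_thickness(round_partition, "IZ") - (5.0 - 1.08)) <= 0.0271


class TestTraitVector:
    def test_counts_match_planted_truth(self, scene_traits):
        tv, truth = scene_traits
        assert tv["VB_N"] == len(truth.bundles)
        assert tv["PZ_VB_N"] == truth.n_pz
        assert tv["IZ_VB_N"] == truth.n_iz

    def test_all_36_traits_present_and_finite(self, scene_traits):
        tv, _ = scene_traits
        s = tv.to_series()
        assert list(s.index) == registry.trait_names()
        assert np.isfinite(s.to_numpy(float)).all()

    def test_density_identity(self, scene_traits):
        tv, _ = scene_traits
        assert tv["VB_D"] * tv["SZ_A"] == pytest.approx(tv["VB_N"], rel=1e-9)
        assert tv["PZ_VB_D"] * tv["PZ_A"] == pytest.approx(tv["PZ_VB_N"], rel=1e-9)
        assert tv["IZ_VB_D"] * tv["IZ_A"] == pytest.approx(tv["IZ_VB_N"], rel=1e-9)

    def test_conservation_across_zones(self, scene_traits):
        tv, _ = scene_traits
        assert tv["VB_N"] == tv["PZ_VB_N"] + tv["IZ_VB_N"]
        assert tv["VB_A"] == pytest.approx(tv["PZ_VB_A"] + tv["IZ_VB_A"], rel=1e-9)

    def test_arivb_unity_for_equal_bundle_sizes(self):
        m = disk_mask(300)
        centers, radii = [], []
        for ang in np.linspace(0, 2 * np.pi, 12, endpoint=False):
            centers.append((304 + 270 * np.sin(ang), 304 + 270 * np.cos(ang)))
            radii.append(10.0)
        for ang in np.linspace(0, 2 * np.pi, 8, endpoint=False):
            centers.append((304 + 130 * np.sin(ang), 304 + 130 * np.cos(ang)))
            radii.append(10.0)
        img = rasterize_scene(m, centers, radii)
        mask = segment_section(img)
        from shankvb.imaging import assign_zones, detect_bundles

        det = detect_bundles(img, mask)
        part = partition_zones(mask, det.bundles, pz_policy=("fixed_depth", 1.0))
        assign_zones(det.bundles, part)
        tv = compute_trait_vector(mask, part, det.bundles)
        assert tv["ARIVB"] == pytest.approx(1.0, abs=0.05)

    def test_rotation_robustness(self, small_scene):
        img, _ = small_scene
        from shankvb.imaging import analyze_section

        tvs = []
        for arr in (img.pixels, np.rot90(img.pixels)):
            im = type(img)(np.ascontiguousarray(arr), img.resolution_um)
            mask, part, det = analyze_section(im)
            tvs.append(compute_trait_vector(mask, part, det.bundles).to_series())
        a, b = tvs
        for name in registry.trait_names():
            if name in ("VB_N", "PZ_VB_N", "IZ_VB_N"):
                assert a[name] == b[name]
            elif name.endswith(("_A", "_CA", "_CCA", "CAave", "Aave", "CCAave")):
                assert b[name] == pytest.approx(a[name], rel=0.005)

    def test_adding_a_bundle_increases_counts(self, scene_traits, analyzed_scene):
        tv, truth = scene_traits
        img, _, mask, _, det = analyzed_scene
        part = partition_zones(
            mask, det.bundles,
            pz_policy=("fixed_depth", truth.pz_boundary_depth_mm),
        )
        # plant one extra synthetic bundle region in the pith
        rr, cc = np.nonzero((part.labels == 3))
        free = None
        taken = np.vstack([b.coords for b in det.bundles])
        for i in range(len(rr) // 2, len(rr)):
            if not ((np.abs(taken[:, 0] - rr[i]) < 15)
                    & (np.abs(taken[:, 1] - cc[i]) < 15)).any():
                free = (rr[i], cc[i])
                break
        yy, xx = np.mgrid[0 : part.labels.shape[0], 0 : part.labels.shape[1]]
        disk = (yy - free[0]) ** 2 + (xx - free[1]) ** 2 <= 36
        extra = BundleRegion(999, np.argwhere(disk),
                             (float(free[0]), float(free[1])),
                             int(disk.sum()), 1.0, zone="IZ")
        tv2 = compute_trait_vector(mask, part, list(det.bundles) + [extra])
        assert tv2["VB_N"] == tv["VB_N"] + 1
        assert tv2["VB_A"] > tv["VB_A"]
        assert tv2["VB_D"] > tv["VB_D"]

    def test_no_bundles_is_an_error(self, analyzed_scene):
        img, truth, mask, part, det = analyzed_scene
        with pytest.raises(ValidationError):
            compute_trait_vector(mask, part, [])


class TestRegistry:
    def test_registry_has_36_traits_in_5_categories(self):
        assert len(registry.TRAITS) == 36
        by_cat = registry.traits_by_category()
        sizes = {c: len(v) for c, v in by_cat.items()}
        assert sizes == {
            "cross_section": 7,
            "epidermis": 2,
            "periphery": 7,
            "inner": 7,
            "vascular_bundle": 13,
        }
        assert len(set(registry.trait_names())) == 36
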