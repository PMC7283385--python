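"""Cross-section metrics, coarctation ratios and plane cuts."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from echobc import (
    CrossSection,
    InvalidGeometryError,
    InvalidParameterError,
    PatchGeometry,
    coarctation_ratio,
    extension_length,
    geometry_report,
    hydraulic_diameter,
    polygon_metrics,
)
from echobc.geometry import min_hydraulic_diameter, plane_cut_contour, read_contour


def regular_polygon(n, r=1.0):
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


class TestPolygonMetrics:
    def test_unit_square(self):
        area, perim = polygon_metrics(np.array([[0, 0], [1, 0], [1, 1], [0, 1]]))
        assert area == pytest.approx(1.0)
        assert perim == pytest.approx(4.0)

    def test_256_gon_approaches_circle(self):
        r = 3.7
        area, perim = polygon_metrics(regular_polygon(256, r))
        assert area == pytest.approx(np.pi * r * r, rel=1e-3)
        assert perim == pytest.approx(2 * np.pi * r, rel=1e-3)

    def test_orientation_invariance(self):
        pts = regular_polygon(17, 2.0)
        fwd = polygon_metrics(pts)
        rev = polygon_metrics(pts[::-1])
        assert fwd == pytest.approx(rev, rel=1e-12)

    def test_self_intersecting_rejected(self):
        bowtie = np.array([[0, 0], [1, 1], [1, 0], [0, 1]])
        with pytest.raises(InvalidGeometryError):
            polygon_metrics(bowtie)

    def test_degenerate_rejected(self):
        with pytest.raises(InvalidGeometryError):
            polygon_metrics(np.array([[0, 0], [1, 0], [2, 0]]))


class TestHydraulicDiameter:
    @pytest.mark.parametrize(
        "area, perimeter, expected",
        [(8.08, 9.59, 3.37), (48.25, 24.66, 7.83), (25.91, 17.99, 5.76),
         (61.82, 27.61, 8.96)],
    )
    def test_clinical_pairs_2dp(self, area, perimeter, expected):
        assert round(hydraulic_diameter(area, perimeter), 2) == expected

    def test_circle_gives_diameter(self):
        r = 2.5
        assert hydraulic_diameter(np.pi * r * r, 2 * np.pi * r) == pytest.approx(
            2 * r, rel=1e-12
        )

    def test_non_positive_rejected(self):
        with pytest.raises(InvalidParameterError):
            hydraulic_diameter(0.0, 1.0)

    @given(scale=st.floats(0.1, 50.0))
    def test_degree_one_homogeneity_under_contour_scaling(self, scale):
        pts = regular_polygon(32, 1.5)
        a1, p1 = polygon_metrics(pts)
        a2, p2 = polygon_metrics(pts * scale)
        assert hydraulic_diameter(a2, p2) == pytest.approx(
            scale * hydraulic_diameter(a1, p1), rel=1e-9
        )


class TestCoarctationRatio:
    dao = PatchGeometry(CrossSection(48.25, 24.66, "descending_aorta"))

    @pytest.mark.parametrize(
        "area, perimeter, expected",
        [(8.08, 9.59, 0.43), (25.91, 17.99, 0.74), (61.82, 27.61, 1.14)],
    )
    def test_clinical_ratios_2dp(self, area, perimeter, expected):
        coarct = PatchGeometry(CrossSection(area, perimeter, "coarctation"))
        assert round(coarctation_ratio(coarct, self.dao), 2) == expected

    def test_identical_sections_give_one(self):
        assert coarctation_ratio(self.dao, self.dao) == 1.0

    @given(scale=st.floats(0.2, 20.0))
    def test_scale_invariance(self, scale):
        coarct = PatchGeometry(CrossSection(8.08, 9.59, "c"))
        scaled_c = PatchGeometry(
            CrossSection(8.08 * scale * scale, 9.59 * scale, "c")
        )
        scaled_d = PatchGeometry(
            CrossSection(48.25 * scale * scale, 24.66 * scale, "d")
        )
        assert coarctation_ratio(scaled_c, scaled_d) == pytest.approx(
            coarctation_ratio(coarct, self.dao), rel=1e-12
        )


class TestExtensionLength:
    def test_ten_diameters_default(self):
        dao = PatchGeometry(CrossSection(48.25, 24.66, "dao"))
        assert extension_length(dao) == pytest.approx(
            10 * dao.hydraulic_diameter
        )
        assert round(extension_length(dao), 1) == pytest.approx(78.3, abs=0.1)

    def test_custom_multiple(self):
        patch = PatchGeometry(CrossSection(np.pi, 2 * np.pi, "c"))  # D_h = 2
        assert extension_length(patch, multiple=0.5) == pytest.approx(1.0)

    def test_non_positive_multiple_rejected(self):
        patch = PatchGeometry(CrossSection(1.0, 1.0, "c"))
        with pytest.raises(InvalidParameterError):
            extension_length(patch, multiple=0.0)


class TestPlaneCut:
    def test_cylinder_cross_section_recovers_diameter(self):
        import trimesh

        radius, height = 4.0, 30.0
        mesh = trimesh.creation.cylinder(radius=radius, height=height, sections=128)
        contour = plane_cut_contour(mesh, [0, 0, 0], [0, 0, 1])
        patch = PatchGeometry(CrossSection.from_contour(contour, "cyl"))
        assert patch.hydraulic_diameter == pytest.approx(2 * radius, rel=1e-2)

    def test_minimum_sweep_finds_waist(self):
        import trimesh

        mesh = trimesh.creation.cylinder(radius=2.0, height=10.0, sections=64)
        planes = [([0, 0, z], [0, 0, 1]) for z in (-4.0, 0.0, 4.0)]
        patch = min_hydraulic_diameter(mesh, planes)
        assert patch.hydraulic_diameter == pytest.approx(4.0, rel=1e-2)

    def test_non_intersecting_plane_rejected(self):
        import trimesh

        mesh = trimesh.creation.cylinder(radius=1.0, height=2.0)
        with pytest.raises(InvalidGeometryError):
            plane_cut_contour(mesh, [0, 0, 100.0], [0, 0, 1])


class TestReportsAndIO:
    def test_geometry_report_layout(self):
        dao = PatchGeometry(CrossSection(48.25, 24.66, "descending_aorta"))
        cases = [
            PatchGeometry(CrossSection(8.08, 9.59, "case1")),
            PatchGeometry(CrossSection(25.91, 17.99, "case2")),
        ]
        table = geometry_report(cases, dao)
        assert list(table["label"]) == ["case1", "case2", "descending_aorta"]
        assert round(table["coarct_to_dao_ratio"].iloc[0], 2) == 0.43
        assert np.isnan(table["coarct_to_dao_ratio"].iloc[-1])

    def test_read_contour(self, tmp_path):
        path = tmp_path / "contour.txt"
        path.write_text("# x_mm, y_mm\n0,0\n1,0\n1,1\n0,1\n")
        pts = read_contour(path)
        area, perim = polygon_metrics(pts)
        assert (area, perim) == (1.0, 4.0)
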