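"""Surface extraction and opposing-surface thickness measurement."""

import numpy as np
import pytest
import trimesh
from scipy import ndimage

from crownct.thickness import (ThicknessField, ThicknessParams,
                               TissueAbsentError, extract_surfaces,
                               measure_thickness, summarize_regions,
                               thickness_histogram)
from crownct.volume import BACKGROUND, DENTINE, ENAMEL, TissueLabelMap

VOX = 0.04  # sphere-shell fixtures voxel size (mm)


@pytest.fixture(scope="module")
def concentric_meshes(concentric_shell):
    return extract_surfaces(concentric_shell, ENAMEL)


@pytest.fixture(scope="module")
def phantom_field(noiseless_phantom):
    """Thickness of the phantom's enamel cap, measured on the truth labels."""
    _, truth = noiseless_phantom
    outer, inner = extract_surfaces(truth.labelmap, ENAMEL)
    return truth, outer, measure_thickness(outer, inner)


class TestExtractSurfaces:
    def test_sphere_shell_areas_match_closed_form(self, concentric_meshes):
        outer, inner = concentric_meshes
        assert outer.area == pytest.approx(4 * np.pi * 1.0 ** 2, rel=0.05)
        assert inner.area == pytest.approx(4 * np.pi * 0.8 ** 2, rel=0.05)

    def test_solid_region_returns_single_mesh_with_warning(self):
        labels = np.zeros((12, 12, 12), dtype=np.uint8)
        labels[3:9, 3:9, 3:9] = ENAMEL
        with pytest.warns(UserWarning, match="no interior boundary"):
            outer, inner = extract_surfaces(TissueLabelMap(labels, 0.05),
                                            ENAMEL)
        assert inner is None
        assert len(outer.faces) > 0

    def test_absent_tissue_rejected(self):
        labels = np.zeros((6, 6, 6), dtype=np.uint8)
        with pytest.raises(TissueAbsentError):
            extract_surfaces(TissueLabelMap(labels, 0.05), ENAMEL)

    def test_normals_point_away_from_tissue(self, concentric_meshes):
        outer, inner = concentric_meshes
        centre = outer.vertices.mean(axis=0)
        radial = outer.triangles_center - centre
        radial /= np.linalg.norm(radial, axis=1, keepdims=True)
        assert (np.einsum("ij,ij->i", outer.face_normals, radial) > 0).mean() > 0.99
        radial_in = inner.triangles_center - centre
        radial_in /= np.linalg.norm(radial_in, axis=1, keepdims=True)
        assert (np.einsum("ij,ij->i", inner.face_normals, radial_in) < 0).mean() > 0.99


class TestMeasureThickness:
    def test_concentric_shell_thickness_within_one_voxel(self, concentric_meshes):
        outer, inner = concentric_meshes
        fld = measure_thickness(outer, inner)
        assert fld.n_defined == len(fld.thickness_mm)
        assert np.all(np.abs(fld.defined_values - 0.20) <= VOX)

    def test_eccentric_shell_extremes(self, eccentric_shell):
        outer, inner = extract_surfaces(eccentric_shell, ENAMEL)
        fld = measure_thickness(outer, inner)
        v = fld.defined_values
        assert v.min() == pytest.approx(0.10, abs=VOX)
        assert v.max() == pytest.approx(0.30, abs=VOX)

    def test_scale_equivariance(self, concentric_meshes):
        outer, inner = concentric_meshes
        fld = measure_thickness(outer, inner)
        s = 2.0
        outer2 = trimesh.Trimesh(outer.vertices * s, outer.faces, process=False)
        inner2 = trimesh.Trimesh(inner.vertices * s, inner.faces, process=False)
        fld2 = measure_thickness(outer2, inner2)
        assert np.array_equal(fld.defined, fld2.defined)
        assert np.allclose(fld2.defined_values, s * fld.defined_values,
                           rtol=1e-8)

    def test_requires_inner_surface(self, concentric_meshes):
        outer, _ = concentric_meshes
        with pytest.raises(ValueError, match="inner surface"):
            measure_thickness(outer, None)

    def test_phantom_apex_thinner_than_base(self, phantom_field):
        truth, outer, fld = phantom_field
        spec = truth.spec
        vs = spec.voxel_size_mm
        nz, ny, nx = spec.shape
        z0 = 2.5 * vs
        u = (outer.triangles_center[:, 0] - z0) / spec.crown_height_mm
        apex = (u > 0.85) & fld.defined
        basal = (u > 0.05) & (u < 0.5) & fld.defined
        assert np.median(fld.thickness_mm[apex]) < \
            np.median(fld.thickness_mm[basal])
        assert np.median(fld.thickness_mm[apex]) < \
            np.median(fld.defined_values)

    def test_phantom_ridge_maximum_in_constructed_band(self, phantom_field):
        truth, outer, fld = phantom_field
        spec = truth.spec
        vs = spec.voxel_size_mm
        _, ny, nx = spec.shape
        cx, cy = nx * vs / 2, ny * vs / 2
        z0 = 2.5 * vs
        c = outer.triangles_center
        u = (c[:, 0] - z0) / spec.crown_height_mm
        theta = np.arctan2(c[:, 1] - cy, c[:, 2] - cx)
        ridge = (np.cos(spec.ridge_count * theta) > 0.95) & \
            (u > 0.1) & (u < 0.5) & fld.defined
        assert ridge.sum() > 100
        assert 0.30 <= fld.thickness_mm[ridge].max() <= 0.50

    def test_dentine_shell_thickness_in_constructed_range(self, noiseless_phantom):
        _, truth = noiseless_phantom
        lm, spec = truth.labelmap, truth.spec
        vs = spec.voxel_size_mm
        outer, inner = extract_surfaces(lm, DENTINE,
                                        exterior_labels=(BACKGROUND, ENAMEL))
        fld = measure_thickness(outer, inner)
        z0 = 2.5 * vs
        u = (outer.triangles_center[:, 0] - z0) / spec.crown_height_mm
        mid = fld.defined & (u > 0.1) & (u < 0.85)
        measured_median = np.median(fld.thickness_mm[mid])
        # constructed dentine gap: distance from the core boundary to the pulp
        pulp = lm.labels == 3
        core = (lm.labels == DENTINE) | pulp
        gap = ndimage.distance_transform_edt(~pulp, sampling=vs)
        boundary = core & ndimage.binary_dilation(~core)
        uz = ((np.arange(lm.shape[0]) + 0.5) * vs - z0) / spec.crown_height_mm
        band = boundary & ((uz > 0.1) & (uz < 0.85))[:, None, None]
        true_gap = gap[band]
        assert true_gap.min() - 2 * vs <= measured_median <= true_gap.max() + 2 * vs


class TestHistogram:
    def test_constant_field_occupies_single_bin(self):
        fld = ThicknessField(np.full(50, 0.20), np.ones(50, bool),
                             np.ones(50))
        hist = thickness_histogram(fld, 0.026)
        assert (hist.counts > 0).sum() == 1
        lo = hist.bin_edges_mm[np.argmax(hist.counts)]
        assert lo <= 0.20 < lo + 0.026
        assert abs(hist.modal_thickness_mm - 0.20) <= 0.026

    def test_two_values_two_bins(self):
        fld = ThicknessField(np.array([0.10, 0.30]), np.ones(2, bool),
                             np.ones(2))
        hist = thickness_histogram(fld, 0.026)
        assert (hist.counts == 1).sum() == 2
        assert hist.counts.sum() == 2

    def test_counts_conserve_defined_elements(self, phantom_field):
        _, _, fld = phantom_field
        hist = thickness_histogram(fld)
        assert hist.counts.sum() == fld.n_defined

    def test_all_undefined_rejected(self):
        fld = ThicknessField(np.full(5, np.nan), np.zeros(5, bool),
                             np.ones(5))
        with pytest.raises(ValueError, match="undefined"):
            thickness_histogram(fld)

    def test_invalid_bin_width(self, phantom_field):
        with pytest.raises(ValueError, match="bin width"):
            thickness_histogram(phantom_field[2], -0.01)


class TestRegionSummary:
    def test_single_region_equals_global_stats(self, phantom_field):
        _, _, fld = phantom_field
        table = summarize_regions(fld, {"all": np.ones(len(fld.thickness_mm),
                                                       bool)})
        v = fld.defined_values
        assert table.loc["all", "min_mm"] == pytest.approx(v.min())
        assert table.loc["all", "median_mm"] == pytest.approx(np.median(v))
        assert table.loc["all", "max_mm"] == pytest.approx(v.max())

    def test_empty_region_rejected(self, phantom_field):
        _, _, fld = phantom_field
        with pytest.raises(ValueError, match="no measured elements"):
            summarize_regions(fld, {"nowhere": np.zeros(len(fld.thickness_mm),
                                                        bool)})
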