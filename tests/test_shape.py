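import numpy as np
import pytest

from flicmseg import (
    LabelMap,
    descriptor_distance,
    fourier_descriptor,
    match_h_region,
    normalize_descriptor,
    trace_boundary,
)
from flicmseg import phantom as ph
from flicmseg.containers import Contour
from flicmseg.exceptions import DegenerateInputError, EmptyRegionError
from flicmseg.shape import default_h_template


def embed(mask_rows, shape=(12, 12), offset=(3, 3)):
    lab = np.zeros(shape, dtype=np.int64)
    arr = np.asarray(mask_rows)
    lab[offset[0]:offset[0] + arr.shape[0], offset[1]:offset[1] + arr.shape[1]] = arr
    return LabelMap(lab)


class TestTraceBoundary:
    def test_solid_square_has_eight_boundary_pixels(self):
        contour = trace_boundary(embed(np.ones((3, 3), dtype=int)), 1)
        assert len(contour) == 8
        pts = {tuple(p) for p in contour.points.astype(int)}
        expected = {(x, y) for x in (3, 4, 5) for y in (3, 4, 5)} - {(4, 4)}
        assert pts == expected
        assert contour.signed_area > 0

    def test_single_row_traverses_out_and_back(self):
        contour = trace_boundary(embed(np.ones((1, 5), dtype=int)), 1)
        assert len(contour) == 8
        # every pixel of the row appears; end pixels once, middles twice
        xs = sorted(int(x) for x, _ in contour.points)
        assert xs == [3, 4, 4, 5, 5, 6, 6, 7]

    def test_orientation_positive_for_region_with_area(self, rng):
        blob = (rng.random((7, 7)) > 0.4).astype(int)
        blob[3, 3] = 1
        from scipy import ndimage as ndi

        lab, _ = ndi.label(blob, structure=np.ones((3, 3)))
        biggest = np.argmax(np.bincount(lab.ravel())[1:]) + 1
        contour = trace_boundary(LabelMap((lab == biggest).astype(np.int64)), 1)
        if len(contour) >= 4:
            assert contour.signed_area >= 0

    def test_absent_class_rejected(self):
        with pytest.raises(EmptyRegionError):
            trace_boundary(embed(np.ones((2, 2), dtype=int)), 7)

    def test_multiple_components_traces_largest(self):
        lab = np.zeros((12, 12), dtype=np.int64)
        lab[1:3, 1:3] = 1
        lab[6:11, 6:11] = 1
        with pytest.warns(UserWarning, match="2 components"):
            contour = trace_boundary(LabelMap(lab), 1)
        assert contour.n_components == 2
        assert contour.points[:, 0].min() >= 5  # largest (bottom-right) traced


class TestFourierDescriptor:
    def test_dc_coefficient_is_centroid(self, rng):
        pts = rng.uniform(0, 50, (17, 2))
        d = fourier_descriptor(Contour(pts))
        centroid = pts[:, 0].mean() + 1j * pts[:, 1].mean()
        assert abs(d.coeffs[0] - centroid) < 1e-10

    def test_translation_only_changes_dc_term(self, rng):
        pts = rng.uniform(0, 50, (16, 2))
        d0 = fourier_descriptor(Contour(pts))
        d1 = fourier_descriptor(Contour(pts + np.array([3.0, -2.0])))
        assert abs(d1.coeffs[0] - d0.coeffs[0] - (3.0 - 2.0j)) < 1e-10
        assert np.allclose(d1.coeffs[1:], d0.coeffs[1:], atol=1e-10)

    def test_matches_direct_quadratic_sum(self, rng):
        pts = rng.uniform(0, 100, (16, 2))
        d = fourier_descriptor(Contour(pts))
        s = pts[:, 0] + 1j * pts[:, 1]
        N = len(s)
        for u in range(N):
            direct = sum(s[k] * np.exp(-2j * np.pi * u * k / N) for k in range(N)) / N
            assert abs(d.coeffs[u] - direct) < 1e-10

    def test_parseval_identity(self, rng):
        pts = rng.uniform(0, 100, (24, 2))
        d = fourier_descriptor(Contour(pts))
        s = pts[:, 0] + 1j * pts[:, 1]
        assert abs(np.sum(np.abs(s) ** 2) / len(s) - np.sum(np.abs(d.coeffs) ** 2)) < 1e-8


class TestNormalizeDescriptor:
    def test_scale_invariance(self, rng):
        pts = rng.uniform(0, 50, (20, 2))
        n1 = normalize_descriptor(fourier_descriptor(Contour(pts)))
        n2 = normalize_descriptor(fourier_descriptor(Contour(pts * 2.0)))
        assert np.allclose(np.abs(n1.coeffs), np.abs(n2.coeffs), atol=1e-10)

    def test_rotation_invariance(self, rng):
        pts = rng.uniform(0, 50, (20, 2))
        rot = np.stack([-pts[:, 1], pts[:, 0]], axis=1)  # 90 degrees
        n1 = normalize_descriptor(fourier_descriptor(Contour(pts)))
        n2 = normalize_descriptor(fourier_descriptor(Contour(rot)))
        assert np.allclose(np.abs(n1.coeffs), np.abs(n2.coeffs), atol=1e-10)

    def test_unit_first_harmonic_and_idempotence(self, rng):
        pts = rng.uniform(0, 50, (12, 2))
        n1 = normalize_descriptor(fourier_descriptor(Contour(pts)))
        assert abs(n1.coeffs[1]) == 1.0
        assert n1.coeffs[0] == 0.0
        n2 = normalize_descriptor(n1)
        assert np.allclose(n1.coeffs, n2.coeffs, atol=1e-12)

    def test_degenerate_shape_rejected(self):
        pts = np.zeros((8, 2))  # all points coincide: lambda(1) = 0
        with pytest.raises(DegenerateInputError):
            normalize_descriptor(fourier_descriptor(Contour(pts)))


class TestMatching:
    def test_distance_symmetric_and_zero_on_self(self, rng):
        d1 = normalize_descriptor(fourier_descriptor(Contour(rng.uniform(0, 9, (14, 2)))))
        d2 = normalize_descriptor(fourier_descriptor(Contour(rng.uniform(0, 9, (18, 2)))))
        assert descriptor_distance(d1, d1) == 0.0
        assert np.isclose(descriptor_distance(d1, d2), descriptor_distance(d2, d1))
        assert descriptor_distance(d1, d2) > 0

    def test_template_self_match_returns_exact_mask(self, default_phantom):
        _, truth = default_phantom
        mask, dist = match_h_region(truth, ph.CSF)
        assert dist < 1e-9
        assert np.array_equal(mask.labels == 1, truth.labels == ph.CSF)

    def test_scale_invariance_on_double_size_phantom(self):
        _, truth = ph.generate_phantom(ph.PhantomSpec(height=256, width=256))
        mask, dist = match_h_region(truth, ph.CSF)
        assert dist <= 0.25
        assert (mask.labels == 1).sum() > 0

    def test_h_selected_over_disk_decoy(self):
        _, truth = ph.generate_phantom(ph.PhantomSpec(geometry_seed=2, include_decoy=True))
        mask, dist = match_h_region(truth, ph.CSF)
        h, w = truth.shape
        assert mask.labels[h // 2, w // 2] == 1  # the centered H, not the decoy
        # and the decoy really is farther from the template
        from scipy import ndimage as ndi

        comp, n = ndi.label(truth.labels == ph.CSF, structure=np.ones((3, 3)))
        center_id = comp[h // 2, w // 2]
        decoy = comp == (1 if center_id != 1 else 2)
        d_decoy = descriptor_distance(
            normalize_descriptor(fourier_descriptor(
                trace_boundary(LabelMap(decoy.astype(np.int64)), 1))),
            default_h_template())
        assert d_decoy > dist

    def test_missing_csf_rejected(self):
        with pytest.raises(EmptyRegionError):
            match_h_region(LabelMap(np.zeros((8, 8), dtype=np.int64)), 1)
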