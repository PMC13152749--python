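import numpy as np
import pytest

from ctdem import (
    DemParams,
    ImageVolume,
    compress_normalize,
    derivative_fields,
    elasticity_response,
    gaussian_smooth,
    generate_dem,
    make_quadratic_field,
)
from ctdem.dem import DerivativeField
from ctdem.synthetic import make_lesion, metastatic_spec
from ctdem.volume import BinaryMask

INTERIOR = (slice(7, -7),) * 3


class TestGaussianSmooth:
    def test_constant_unchanged(self):
        v = ImageVolume(np.full((10, 10, 10), 7.0))
        np.testing.assert_allclose(gaussian_smooth(v, 1.0).data, 7.0, atol=1e-12)

    def test_impulse_response_is_gaussian(self):
        data = np.zeros((21, 21, 21))
        data[10, 10, 10] = 1.0
        out = gaussian_smooth(ImageVolume(data), 1.0).data
        assert np.unravel_index(out.argmax(), out.shape) == (10, 10, 10)
        # separable kernel: value at distance r follows exp(-r^2/2)
        ratio = out[10, 10, 11] / out[10, 10, 10]
        assert ratio == pytest.approx(np.exp(-0.5), rel=1e-3)
        assert out.sum() == pytest.approx(1.0, abs=1e-9)

    def test_linear_ramp_preserved_in_interior(self):
        x = np.arange(24, dtype=float)
        v = ImageVolume(np.broadcast_to(x[:, None, None], (24, 24, 24)).copy())
        out = gaussian_smooth(v, 1.0).data
        np.testing.assert_allclose(out[INTERIOR], v.data[INTERIOR], atol=1e-6)


class TestDerivativeFields:
    def test_affine_field(self):
        v, _ = make_quadratic_field(np.zeros((3, 3)), b=(2.0, 3.0, -1.0), shape=(20, 20, 20))
        d = derivative_fields(v)
        g = d.gradient[INTERIOR]
        np.testing.assert_allclose(g, np.broadcast_to([2.0, 3.0, -1.0], g.shape), atol=1e-4)
        np.testing.assert_allclose(d.hessian[INTERIOR], 0.0, atol=1e-4)

    def test_x_squared_hessian(self):
        M = np.zeros((3, 3))
        M[0, 0] = 1.0  # I = x^2
        v, _ = make_quadratic_field(M, shape=(20, 20, 20))
        d = derivative_fields(v)
        h = d.hessian[INTERIOR]
        np.testing.assert_allclose(h[..., 0, 0], 2.0, atol=1e-3)
        for i, j in [(0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]:
            np.testing.assert_allclose(h[..., i, j], 0.0, atol=1e-3)

    def test_constant_field(self):
        d = derivative_fields(ImageVolume(np.full((8, 8, 8), 5.0)))
        np.testing.assert_allclose(d.gradient, 0.0, atol=1e-10)
        np.testing.assert_allclose(d.hessian, 0.0, atol=1e-10)

    def test_hessian_symmetric(self, metastatic_dem):
        vol, _, _ = make_lesion(metastatic_spec(seed=2))
        d = derivative_fields(vol)
        np.testing.assert_allclose(d.hessian, np.swapaxes(d.hessian, -1, -2), atol=1e-12)

    def test_too_small_volume_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            derivative_fields(ImageVolume(np.zeros((3, 8, 8))))


class TestElasticityResponse:
    def test_constant_field_zero(self):
        e, diag = elasticity_response(derivative_fields(ImageVolume(np.full((8, 8, 8), 3.0))))
        np.testing.assert_allclose(e, 0.0, atol=1e-12)
        assert diag["singular_voxels"] == 0

    def test_isotropic_quadratic_closed_form(self):
        # I = |x|^2: H = 2I, g = 2x; E(x) = 4|x|^2/(2+eps) -> 6 at |x|^2=3
        v, o = make_quadratic_field(np.eye(3), shape=(17, 17, 17))
        eps = 1e-9
        d = DerivativeField(o.gradient_field(), o.hessian_field())
        e, _ = elasticity_response(d, epsilon=eps)
        c = 8  # centre index
        assert e[c + 1, c + 1, c + 1] == pytest.approx(6.0, rel=1e-6)

    def test_anisotropic_quadratic_closed_form_from_filters(self):
        M = np.diag([1.0, 2.0, 3.0])
        v, o = make_quadratic_field(M, shape=(24, 24, 24))
        eps = 1e-3
        d = derivative_fields(v)
        e, _ = elasticity_response(d, epsilon=eps)
        x = o.centred_coords()
        g = o.gradient_field()
        inv = np.linalg.inv(2 * M + eps * np.eye(3))
        expected = np.einsum("...i,ij,...j->...", g, inv, g)
        rel = np.abs(e[INTERIOR] - expected[INTERIOR]) / np.abs(expected[INTERIOR]).max()
        assert rel.max() < 1e-3

    def test_affine_invariance_on_oracle_derivatives(self, rng):
        # E = g' H^-1 g is exactly invariant under x -> Ax on analytic fields
        M = np.array([[2.0, 0.3, 0.1], [0.3, 1.5, 0.2], [0.1, 0.2, 3.0]])
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        pts = rng.normal(size=(50, 3))
        for x in pts:
            g = 2 * M @ x
            H = 2 * M
            e = g @ np.linalg.solve(H, g)
            # transformed field I'(y) = I(Ay): g' = A^T g(Ay), H' = A^T H A
            y = np.linalg.solve(A, x)
            gp = A.T @ (2 * M @ (A @ y))
            Hp = A.T @ (2 * M) @ A
            ep = gp @ np.linalg.solve(Hp, gp)
            assert ep == pytest.approx(e, rel=1e-10)

    def test_intensity_offset_invariance(self):
        vol, mask, _ = make_lesion(metastatic_spec(seed=4))
        d1 = derivative_fields(vol)
        d2 = derivative_fields(ImageVolume(vol.data + 137.0, vol.spacing, vol.origin))
        e1, _ = elasticity_response(d1, epsilon=1e-2)
        e2, _ = elasticity_response(d2, epsilon=1e-2)
        np.testing.assert_allclose(e1, e2, rtol=1e-8, atol=1e-8)

    def test_negative_fraction_reported(self):
        vol, mask, _ = make_lesion(metastatic_spec(seed=4))
        _, diag = elasticity_response(derivative_fields(vol))
        assert 0.0 <= diag["negative_fraction"] <= 1.0
        assert diag["epsilon"] > 0


class TestCompressNormalize:
    def test_arithmetic_example(self):
        out = compress_normalize(np.array([0.0, 1.0, 4.0]), r=0.5)
        np.testing.assert_allclose(out, [0.0, 127.5, 255.0])

    def test_argmax_preserved(self, rng):
        raw = rng.random((6, 6, 6)) * 10
        out = compress_normalize(raw, r=0.5)
        assert out.argmax() == raw.argmax()

    def test_monotone(self, rng):
        raw = rng.random(100)
        out = compress_normalize(raw, r=0.5)
        order = np.argsort(raw)
        assert np.all(np.diff(out[order]) >= 0)

    def test_constant_map_all_zero(self):
        np.testing.assert_array_equal(compress_normalize(np.full((4, 4), 3.0)), 0.0)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            compress_normalize(np.array([-1.0, 2.0]))


class TestGenerateDem:
    def test_constant_roi_gives_zero_dem(self):
        vol = ImageVolume(np.full((20, 20, 20), 50.0))
        m = np.zeros((20, 20, 20))
        m[6:14, 6:14, 6:14] = 1
        dem, mask = generate_dem(vol, BinaryMask(m))
        np.testing.assert_allclose(dem.normalized_values[mask.data], 0.0, atol=1e-9)

    def test_range_and_endpoints(self, metastatic_dem):
        dem, mask = metastatic_dem
        vals = dem.normalized_values[mask.data]
        assert vals.min() >= 0.0 and vals.max() <= 255.0
        # non-constant map attains both endpoints within the padded stats mask
        assert dem.normalized_values.max() == pytest.approx(255.0)
        assert dem.normalized_values.min() == pytest.approx(0.0)

    def test_rank_order_matches_closed_form(self):
        # quadratic intensity: DEM ranks must follow the analytic E ranks
        M = np.diag([1.0, 2.0, 3.0])
        v, o = make_quadratic_field(M, shape=(24, 24, 24))
        m = np.zeros((24, 24, 24))
        m[8:16, 8:16, 8:16] = 1
        # pad 8 keeps every mask voxel beyond the filter support of the
        # crop boundary, so the filtered derivatives are exact
        params = DemParams(epsilon=1e-3, sigma_smooth=1.0, roi_pad=8)
        dem, mask = generate_dem(v, BinaryMask(m), params)
        g = o.gradient_field()
        expected = np.einsum(
            "...i,ij,...j->...", g, np.linalg.inv(2 * M + 1e-3 * np.eye(3)), g
        )
        sel = mask.data
        got = dem.normalized_values[sel]
        want = expected[sel]
        # Spearman-style check: identical ordering of distinct values
        corr = np.corrcoef(np.argsort(np.argsort(got)), np.argsort(np.argsort(want)))[0, 1]
        assert corr > 0.999

    def test_lattice_rotation_symmetry(self):
        vol, mask, _ = make_lesion(metastatic_spec(seed=9))
        dem_a, m_a = generate_dem(vol, mask, DemParams(epsilon=1e-2))
        rot_vol = ImageVolume(np.rot90(vol.data, k=1, axes=(0, 1)).copy())
        rot_mask = BinaryMask(np.rot90(mask.data, k=1, axes=(0, 1)).copy())
        dem_b, m_b = generate_dem(rot_vol, rot_mask, DemParams(epsilon=1e-2))
        ha, _ = np.histogram(dem_a.normalized_values[m_a.data], bins=32, range=(0, 255))
        hb, _ = np.histogram(dem_b.normalized_values[m_b.data], bins=32, range=(0, 255))
        np.testing.assert_array_equal(ha, hb)

    def test_deterministic(self):
        vol, mask, _ = make_lesion(metastatic_spec(seed=5))
        a, _ = generate_dem(vol, mask)
        b, _ = generate_dem(vol, mask)
        np.testing.assert_array_equal(a.normalized_values, b.normalized_values)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            generate_dem(ImageVolume(np.zeros((8, 8, 8))), BinaryMask(np.zeros((8, 8, 8))))


class TestDemParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sigma_smooth": 0.0},
            {"epsilon": -1.0},
            {"compression_exponent": 0.0},
            {"compression_exponent": 1.5},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DemParams(**kwargs)
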