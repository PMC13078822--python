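"""Unit and property tests for the MINT32 representation itself."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mint32.box import (
    TWO31,
    TWO32,
    BoxSpec,
    InvalidBoxError,
    make_scale_factors,
    rescale_box,
)
from mint32.fixedpoint import (
    ConversionPolicy,
    decode,
    decode_fractional,
    delta_to_cartesian,
    encode,
    encode_fractional,
    load_mint,
    min_image_delta,
    quantization_stats,
    save_mint,
    triclinic_delta,
)

# Exact-arithmetic oracle values (Fraction-based multiply-and-round):
# round(24.9 * 2**32 / 50) and the self-wrapped difference for the pair
# at -24.9 / +24.9 in a 50 A box, which decodes to exactly -0.2000 A
# (to 3 significant figures).
X_249 = 2_138_893_713
DELTA_249 = -17_179_870


class TestScaleFactors:
    @pytest.mark.parametrize(
        "L, expected",
        [
            (50.0, 85_899_345.92),
            (100.0, 42_949_672.96),
            (float(TWO32), 1.0),
        ],
    )
    def test_scale_values(self, L, expected):
        S = make_scale_factors(BoxSpec.cubic(L))
        assert S.S == pytest.approx([expected] * 3, rel=1e-15)
        # S * L = 2**32 to within float64 round-off
        assert S.S * L == pytest.approx([TWO32] * 3, rel=1e-15)

    def test_per_axis_independence(self):
        S = make_scale_factors(BoxSpec.orthorhombic(25.0, 50.0, 100.0))
        assert S.S[0] == 2 * S.S[1] == 4 * S.S[2]

    @pytest.mark.parametrize("L", [0.0, -1.0, np.inf, np.nan])
    def test_invalid_box(self, L):
        with pytest.raises(InvalidBoxError):
            BoxSpec.cubic(L)


class TestEncodeDecode:
    def test_zero_maps_to_zero(self, scale50):
        assert np.all(encode([0.0, 0.0, 0.0], scale50) == 0)
        assert np.all(decode(np.zeros(3, np.int32), scale50) == 0.0)

    def test_domain_edge_maps_to_integer_minimum(self, scale50):
        X = encode([-25.0, -25.0, -25.0], scale50)
        assert np.all(X == -TWO31)
        assert decode(X, scale50) == pytest.approx([-25.0] * 3)

    def test_worked_example_encoding(self, scale50):
        assert encode([24.9, 0, 0], scale50)[0] == X_249
        assert encode([-24.9, 0, 0], scale50)[0] == -X_249

    def test_out_of_box_coordinates_wrap(self, scale50):
        inside = encode([10.0, -20.0, 3.0], scale50)
        outside = encode([10.0 + 50.0, -20.0 - 3 * 50.0, 3.0 + 50.0], scale50)
        np.testing.assert_array_equal(inside, outside)

    def test_nonfinite_rejected(self, scale50):
        with pytest.raises(ValueError):
            encode([np.nan, 0, 0], scale50)

    def test_round_trip_bound_sweep(self, rng):
        # |decode(encode(x)) - x| <= L / 2**33 per axis over 10**6 samples
        box = BoxSpec.orthorhombic(31.0, 50.0, 77.3)
        S = make_scale_factors(box)
        x = rng.uniform(-0.5, 0.5, size=(10**6, 3)) * box.lengths
        err = np.abs(decode(encode(x, S), S) - x)
        assert np.all(err <= box.lengths / 2.0**33 * (1 + 1e-12))

    def test_decode_domain(self, rng, scale50):
        X = rng.integers(-TWO31, TWO31, size=(10000, 3), dtype=np.int64).astype(np.int32)
        x = decode(X, scale50)
        assert np.all(x >= -25.0) and np.all(x < 25.0)

    def test_uniform_spacing(self, scale50):
        # decode(X+1) - decode(X) == 1/S for any X: the grid is uniform
        X = np.array([[-TWO31, 0, 123456789]], dtype=np.int32)
        gap = (decode(X + 1, scale50) - decode(X, scale50)).ravel()
        # the decoded difference cancels two ~25 A values, so the working-
        # precision error of the gap is ~ulp(25), not ulp(gap)
        assert gap == pytest.approx([1.0 / s for s in scale50.S], abs=1e-14)


def _brute_force_min_image(Xi, Xj):
    """27-image oracle, exact in integer space: try all k*2**32 shifts."""
    d = Xi.astype(np.int64) - Xj.astype(np.int64)
    cands = d[..., None] + np.array([-TWO32, 0, TWO32], dtype=np.int64)
    pick = np.argmin(np.abs(cands), axis=-1)
    return np.take_along_axis(cands, pick[..., None], axis=-1)[..., 0]


class TestMinImage:
    def test_identical_positions(self, scale50):
        X = encode([[1.2, -3.4, 5.6]], scale50)
        assert np.all(min_image_delta(X, X) == 0)

    def test_worked_example_wrap(self, scale50):
        Xi = encode([-24.9, 0, 0], scale50)
        Xj = encode([+24.9, 0, 0], scale50)
        dX = min_image_delta(Xj, Xi)  # displacement of j relative to i
        assert dX[0] == DELTA_249
        dx = delta_to_cartesian(dX, scale50)
        assert dx[0] == pytest.approx(-0.2, abs=5e-4)  # 3 significant figures
        # the naive difference would be ~49.8: wrapping is automatic
        assert abs(dx[0]) < 1.0

    def test_matches_brute_force_oracle(self, rng):
        # 10**5 random pairs across 10 random box sizes, exact integer match
        for L in rng.uniform(10.0, 400.0, size=10):
            S = make_scale_factors(BoxSpec.cubic(float(L)))
            x = rng.uniform(-0.5, 0.5, size=(10**4, 3)) * L
            y = rng.uniform(-0.5, 0.5, size=(10**4, 3)) * L
            Xi, Xj = encode(x, S), encode(y, S)
            got = min_image_delta(Xi, Xj).astype(np.int64)
            want = _brute_force_min_image(Xi, Xj)
            # the oracle may return +2**31 where wrapping pins -2**31
            tie = np.abs(want) == TWO31
            np.testing.assert_array_equal(got[~tie], want[~tie])
            assert np.all(np.abs(got[tie]) == TWO31)

    def test_agrees_with_branch_based_fp64(self, rng, box50, scale50):
        x = rng.uniform(-25.0, 25.0, size=(2000, 3))
        y = rng.uniform(-25.0, 25.0, size=(2000, 3))
        dX = min_image_delta(encode(x, scale50), encode(y, scale50))
        got = delta_to_cartesian(dX, scale50)
        d = x - y
        want = d - box50.lengths * np.rint(d / box50.lengths)
        assert np.all(np.abs(got - want) <= 2 * box50.lengths / 2.0**32)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        xi=st.integers(-TWO31, TWO31 - 1),
        xj=st.integers(-TWO31, TWO31 - 1),
        t=st.integers(-(2**40), 2**40),
    )
    def test_translational_invariance(self, xi, xj, t):
        Xi = np.array([xi], dtype=np.int32)
        Xj = np.array([xj], dtype=np.int32)
        shift = lambda X: ((X.astype(np.int64) + t + TWO31) % TWO32 - TWO31).astype(np.int32)
        np.testing.assert_array_equal(
            min_image_delta(Xi, Xj), min_image_delta(shift(Xi), shift(Xj)))

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(xi=st.integers(-TWO31, TWO31 - 1), xj=st.integers(-TWO31, TWO31 - 1))
    def test_antisymmetry(self, xi, xj):
        Xi = np.array([xi], dtype=np.int32)
        Xj = np.array([xj], dtype=np.int32)
        fwd = min_image_delta(Xi, Xj)[0]
        rev = min_image_delta(Xj, Xi)[0]
        if fwd == -TWO31:
            # half-box separation: the negation of -2**31 is itself
            assert rev == -TWO31
        else:
            assert fwd == -rev


class TestConversionPolicies:
    def test_zero_displacement(self, scale50):
        z = np.zeros(3, dtype=np.int32)
        assert np.all(delta_to_cartesian(z, scale50, ConversionPolicy.DIRECT_FP32) == 0)
        assert np.all(delta_to_cartesian(z, scale50, ConversionPolicy.PROMOTE_FP64) == 0)

    def test_worked_example_promote(self, scale50):
        dX = np.array([DELTA_249, 0, 0], dtype=np.int32)
        dx = delta_to_cartesian(dX, scale50, ConversionPolicy.PROMOTE_FP64)
        assert dx[0] == pytest.approx(-0.2, abs=5e-4)

    def test_staircase_bound(self, rng, scale50):
        # |direct_fp32 - promote_fp64| <= 1 ulp of the 32-bit result across
        # a stratified sample of displacement magnitudes
        mags = (10.0 ** rng.uniform(0, 9.3, size=20000)).astype(np.int64)
        dX = (mags * rng.choice([-1, 1], size=mags.shape)).astype(np.int64)
        dX = np.clip(dX, -TWO31, TWO31 - 1).astype(np.int32).reshape(-1, 1)
        dX = np.hstack([dX, dX, dX])
        direct = delta_to_cartesian(dX, scale50, ConversionPolicy.DIRECT_FP32)
        promote = delta_to_cartesian(dX, scale50, ConversionPolicy.PROMOTE_FP64)
        gap = np.abs(direct.astype(np.float64) - promote)
        ulp = np.spacing(np.abs(direct).astype(np.float32)).astype(np.float64)
        # three 32-bit rounding stages (1/S, float(dX), product) each
        # contribute up to half an ulp
        assert np.all(gap <= 1.5 * ulp)


class TestTriclinic:
    def test_zero(self):
        box = BoxSpec.truncated_octahedron(56.5)
        assert np.all(encode_fractional(np.zeros(3), box) == 0)

    def test_orthorhombic_consistency_exact(self):
        # power-of-two box lengths make both encoding paths bit-identical
        L = 32.0
        box = BoxSpec(lengths=[L, L, L], cell_matrix=np.diag([L, L, L]))
        S = make_scale_factors(box)
        rng = np.random.default_rng(7)
        x = rng.uniform(-L / 2, L / 2, size=(5000, 3))
        np.testing.assert_array_equal(encode_fractional(x, box), encode(x, S))

    def test_orthorhombic_delta_consistency(self):
        L = 32.0
        box = BoxSpec(lengths=[L, L, L], cell_matrix=np.diag([L, L, L]))
        S = make_scale_factors(box)
        rng = np.random.default_rng(8)
        x = rng.uniform(-L / 2, L / 2, size=(2000, 3))
        y = rng.uniform(-L / 2, L / 2, size=(2000, 3))
        Ui, Uj = encode_fractional(x, box), encode_fractional(y, box)
        got = triclinic_delta(Ui, Uj, box)
        want = delta_to_cartesian(min_image_delta(encode(x, S), encode(y, S)), S)
        np.testing.assert_array_equal(got, want)

    def test_trunc_oct_matches_image_oracle(self):
        # separations below the inscribed-sphere radius: the wrapped
        # fractional delta is the true Cartesian minimum image
        a = 56.5
        box = BoxSpec.truncated_octahedron(a)
        H = box.H
        rng = np.random.default_rng(9)
        base = (rng.uniform(-0.5, 0.5, size=(3000, 3))) @ H.T
        sep = rng.normal(size=(3000, 3))
        sep *= (rng.uniform(0.1, 8.0, size=3000) / np.linalg.norm(sep, axis=1))[:, None]
        other = base + sep
        Ui = encode_fractional(base, box)
        Uj = encode_fractional(other, box)
        got = triclinic_delta(Ui, Uj, box)
        # 27-image brute force in Cartesian space
        shifts = np.array(np.meshgrid([-1, 0, 1], [-1, 0, 1], [-1, 0, 1])).T.reshape(-1, 3)
        du = (decode_fractional(Ui, box) - decode_fractional(Uj, box)) @ np.linalg.inv(H).T
        cands = (du[:, None, :] + shifts[None]) @ H.T
        best = cands[np.arange(len(du)), np.argmin(np.linalg.norm(cands, axis=2), axis=1)]
        assert np.max(np.abs(np.linalg.norm(got, axis=1) - np.linalg.norm(best, axis=1))) < 1e-6

    def test_round_trip_error_within_bound(self):
        from mint32.precision import trunc_oct_cell
        a = 56.5
        box = BoxSpec.truncated_octahedron(a)
        rng = np.random.default_rng(10)
        r = (rng.uniform(-0.5, 0.5, size=(20000, 3))) @ box.H.T
        back = decode_fractional(encode_fractional(r, box), box)
        err = np.abs(back - r)
        # per-component quantization bound: sum_j |H_ij| / 2**33
        bound = np.abs(box.H) @ np.full(3, 1.0 / 2.0**33)
        assert np.all(err <= bound * (1 + 1e-9))


class TestRescale:
    def test_identity(self, scale50):
        S2 = rescale_box(scale50, [50.0, 50.0, 50.0])
        np.testing.assert_array_equal(S2.S, scale50.S)

    def test_positions_scale_exactly(self, rng, scale50):
        X = rng.integers(-TWO31, TWO31, size=(5000, 3), dtype=np.int64).astype(np.int32)
        S2 = rescale_box(scale50, [55.0, 55.0, 55.0])
        x_old = decode(X, scale50)
        x_new = decode(X, S2)
        nz = x_old != 0
        np.testing.assert_allclose(x_new[nz] / x_old[nz], 1.1, rtol=1e-15)

    def test_round_trip_bit_identical(self, rng, scale50):
        X = rng.integers(-TWO31, TWO31, size=(1000, 3), dtype=np.int64).astype(np.int32)
        S2 = rescale_box(rescale_box(scale50, [55.0] * 3), [50.0] * 3)
        np.testing.assert_array_equal(decode(X, scale50), decode(X, S2))

    def test_invalid(self, scale50):
        with pytest.raises(InvalidBoxError):
            rescale_box(scale50, [0.0, 50.0, 50.0])


class TestQuantizationStats:
    def test_variance_matches_closed_form(self, scale50):
        qs = quantization_stats(10**6, scale50, seed=123)
        np.testing.assert_allclose(qs.variance, qs.predicted_variance, rtol=0.05)
        sigma = np.sqrt(qs.predicted_variance)
        assert np.all(np.abs(qs.mean) <= 3 * sigma / np.sqrt(qs.n))

    def test_grid_points_have_zero_error(self, scale50):
        k = np.array([[-5, 0, 123456]], dtype=np.int64)
        x = k / scale50.S
        err = decode(encode(x, scale50), scale50) - x
        assert np.all(err == 0.0)

    def test_variance_scales_with_box_squared(self):
        v1 = quantization_stats(400000, make_scale_factors(BoxSpec.cubic(50.0)), 5).variance
        v2 = quantization_stats(400000, make_scale_factors(BoxSpec.cubic(100.0)), 5).variance
        np.testing.assert_allclose(v2 / v1, 4.0, rtol=0.05)

    def test_requires_samples(self, scale50):
        with pytest.raises(ValueError):
            quantization_stats(0, scale50, seed=1)


class TestSerialization:
    def test_bit_exact_round_trip(self, tmp_path, rng, box50, scale50):
        X = rng.integers(-TWO31, TWO31, size=(777, 3), dtype=np.int64).astype(np.int32)
        path = tmp_path / "coords.mint"
        save_mint(path, X, box50)
        X2, box2 = load_mint(path)
        np.testing.assert_array_equal(X, X2)
        np.testing.assert_array_equal(box2.lengths, box50.lengths)
        assert box2.centered == box50.centered

    def test_rejects_garbage(self, tmp_path):
        path = tmp_path / "bad.mint"
        path.write_bytes(b"not a container at all" * 3)
        with pytest.raises(ValueError):
            load_mint(path)
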