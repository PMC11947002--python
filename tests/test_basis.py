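"""Natural cubic spline and cross-basis contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from casets.basis import (
    CrossBasisSpec,
    SplineSpec,
    cross_basis,
    evaluate_exposure_basis,
    lag_basis_colsums,
    lag_matrix,
    natural_cubic_basis,
)


def truncated_power_natural(x, interior, boundary):
    """Independent natural-spline construction: truncated-power basis
    {1, x, d_k(x) - d_{K-1}(x)} with d_k(x) = [(x-k)+^3 - (x-kmax)+^3] /
    (kmax - k), all knots = interior + boundary (textbook form)."""
    knots = np.sort(np.r_[boundary[0], interior, boundary[1]])
    kmax = knots[-1]

    def d(x, k):
        return (np.maximum(x - k, 0) ** 3 - np.maximum(x - kmax, 0) ** 3) / (
            kmax - k
        )

    cols = [np.ones_like(x), x]
    for k in knots[:-2]:
        cols.append(d(x, k) - d(x, knots[-2]))
    return np.column_stack(cols)


def projector(A):
    u, s, _ = np.linalg.svd(A, full_matrices=False)
    u = u[:, s > s[0] * 1e-10]
    return u @ u.T


class TestNaturalCubicBasis:
    def test_pointwise_in_x(self):
        spec = SplineSpec(knots=(1.0, 2.0), boundary=(0.0, 3.0))
        same = natural_cubic_basis(np.full(5, 1.7), spec)
        assert np.allclose(same, same[0])

    def test_df1_is_affine_in_x(self):
        x = np.random.default_rng(0).normal(size=50)
        basis = natural_cubic_basis(x, SplineSpec(df=1).resolve(x))
        assert basis.shape[1] == 1
        r = np.corrcoef(basis[:, 0], x)[0, 1]
        assert abs(abs(r) - 1) < 1e-12

    def test_span_equals_truncated_power_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(-2, 12, 80)
        interior = (2.0, 5.0, 8.0)
        boundary = (-2.0, 12.0)
        spec = SplineSpec(knots=interior, boundary=boundary, intercept=True)
        ours = natural_cubic_basis(x, spec)
        # intercept-included span must equal {1} + our basis span
        ours_full = np.column_stack([np.ones_like(x), ours])
        oracle = truncated_power_natural(x, interior, boundary)
        assert (
            np.abs(projector(ours_full) - projector(oracle)).max() < 1e-8
        )

    def test_span_without_intercept_plus_constant(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 60)
        interior = (3.0, 7.0)
        spec = SplineSpec(knots=interior, boundary=(0.0, 10.0), intercept=False)
        ours = np.column_stack(
            [np.ones_like(x), natural_cubic_basis(x, spec)]
        )
        oracle = truncated_power_natural(x, interior, (0.0, 10.0))
        assert np.abs(projector(ours) - projector(oracle)).max() < 1e-8

    def test_tail_linearity(self):
        spec = SplineSpec(knots=(10.0, 20.0), boundary=(0.0, 30.0))
        for grid in (np.linspace(-20, -0.5, 50), np.linspace(30.5, 60, 50)):
            b = natural_cubic_basis(grid, spec)
            assert np.abs(np.diff(b, n=2, axis=0)).max() < 1e-8

    def test_rejects_nonfinite_and_bad_knots(self):
        with pytest.raises(ValueError):
            natural_cubic_basis(
                np.array([np.nan]), SplineSpec(knots=(1.0,), boundary=(0.0, 2.0))
            )
        with pytest.raises(ValueError):
            SplineSpec(knots=(5.0,), boundary=(0.0, 2.0))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_row_order_invariance(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 1, 30)
        spec = SplineSpec(knots=(0.5,), boundary=(0.0, 1.0))
        perm = rng.permutation(30)
        assert np.allclose(
            natural_cubic_basis(x, spec)[perm],
            natural_cubic_basis(x[perm], spec),
        )


class TestLagMatrix:
    def test_constant_series(self):
        Q, complete = lag_matrix(np.full(20, 3.5), 7)
        assert Q.shape == (20, 8)
        assert np.allclose(Q[complete], 3.5)

    def test_seven_day_lag_shape_and_incomplete_rows(self):
        x = np.arange(30.0)
        Q, complete = lag_matrix(x, 7)
        assert Q.shape[1] == 8
        assert (~complete).sum() == 7
        assert np.all(~complete[:7]) and np.all(complete[7:])
        # column l holds x[t-l]
        assert np.allclose(Q[10], np.arange(10, 2, -1.0))

    def test_lagging_never_crosses_zone_boundaries(self):
        x = np.r_[np.zeros(10), np.ones(10) * 100]
        groups = np.r_[["A"] * 10, ["B"] * 10]
        Q, complete = lag_matrix(x, 7, groups)
        assert (~complete).sum() == 14
        # zone B rows never contain zone A values
        assert np.all(Q[10:] == 100.0)


class TestCrossBasis:
    def test_linear_by_constant_reduces_to_moving_sum(self):
        rng = np.random.default_rng(3)
        x = rng.normal(15, 5, 120)
        espec = SplineSpec(df=1).resolve(x)
        cbspec = CrossBasisSpec(
            exposure=espec, lag=SplineSpec(df=1, intercept=True), max_lag=7
        )
        cbm = cross_basis(x, cbspec)
        # the affine exposure column is a*x+b; recover a, b exactly
        col = natural_cubic_basis(x, espec)[:, 0]
        a = (col[1] - col[0]) / (x[1] - x[0])
        b = col[0] - a * x[0]
        Q, complete = lag_matrix(x, 7)
        expected = a * Q.sum(axis=1) + 8 * b
        assert np.abs(cbm.values[complete, 0] - expected[complete]).max() < 1e-10

    def test_matches_elementwise_brute_force(self):
        rng = np.random.default_rng(4)
        x = rng.normal(10, 6, 50)
        spec = CrossBasisSpec(
            exposure=SplineSpec(knots=(8.0, 12.0), boundary=(-15.0, 35.0))
        )
        cbm = cross_basis(x, spec)
        C = spec.lag_basis()
        Q, _ = lag_matrix(x, 7)
        W = np.zeros_like(cbm.values)
        for t in range(50):
            R = natural_cubic_basis(Q[t], spec.exposure)  # (8, vx)
            for k in range(spec.vl):
                for j in range(spec.vx):
                    W[t, j + spec.vx * k] = sum(
                        R[l, j] * C[l, k] for l in range(8)
                    )
        assert np.abs(W - cbm.values).max() < 1e-12

    def test_constant_exposure_gives_identical_complete_rows(self):
        spec = CrossBasisSpec(
            exposure=SplineSpec(knots=(16.0,), boundary=(0.0, 30.0))
        )
        cbm = cross_basis(np.full(40, 21.3), spec)
        rows = cbm.values[cbm.complete]
        assert np.allclose(rows, rows[0])

    def test_affine_input_linearity_with_linear_exposure_basis(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=60)
        e1 = SplineSpec(df=1).resolve(x)
        e2 = SplineSpec(df=1).resolve(2.0 * x + 3.0)
        c1 = cross_basis(x, CrossBasisSpec(exposure=e1)).values
        c2 = cross_basis(2.0 * x + 3.0, CrossBasisSpec(exposure=e2)).values
        # both span the same affine space per lag-column: residual of lstsq is 0
        for k in range(c1.shape[1]):
            A = np.column_stack([c1[:, k], np.ones(60)])
            resid = c2[:, k] - A @ np.linalg.lstsq(A, c2[:, k], rcond=None)[0]
            assert np.abs(resid).max() < 1e-8


class TestCumulativeReduction:
    def test_lag_colsums_constant_basis(self):
        spec = CrossBasisSpec(
            exposure=SplineSpec(knots=(1.0,), boundary=(0.0, 2.0)),
            lag=SplineSpec(df=1, intercept=True),
        )
        assert np.allclose(lag_basis_colsums(spec), [8.0])

    def test_exposure_basis_consistency_with_fit_rows(self):
        rng = np.random.default_rng(6)
        x = rng.normal(15, 5, 40)
        spec = CrossBasisSpec(
            exposure=SplineSpec(knots=(14.0,), boundary=(0.0, 30.0))
        )
        R = evaluate_exposure_basis(x, spec)
        assert np.allclose(R, natural_cubic_basis(x, spec.exposure))

    def test_cumulative_log_rr_matches_brute_force(self):
        rng = np.random.default_rng(7)
        x = rng.normal(15, 5, 60)
        spec = CrossBasisSpec(
            exposure=SplineSpec(knots=(13.0, 17.0), boundary=(-5.0, 35.0))
        )
        beta = rng.normal(0, 0.02, spec.vx * spec.vl)
        x0, xq = 15.0, 28.0
        s = lag_basis_colsums(spec)
        R = evaluate_exposure_basis(np.array([xq, x0]), spec)
        a = np.einsum("k,j->kj", s, R[0] - R[1]).ravel()
        quick = a @ beta
        # brute force: sum over lags of [R(x)-R(x0)] C beta arranged (j,k)
        C = spec.lag_basis()
        brute = 0.0
        for l in range(8):
            for k in range(spec.vl):
                for j in range(spec.vx):
                    brute += (R[0, j] - R[1, j]) * C[l, k] * beta[j + spec.vx * k]
        assert abs(quick - brute) < 1e-10


class TestSerialization:
    def test_spec_json_roundtrip_preserves_basis(self):
        rng = np.random.default_rng(8)
        x = rng.normal(15, 8, 100)
        spec = CrossBasisSpec(
            exposure=SplineSpec(knots=(10.0, 15.0, 20.0), boundary=(-10.0, 35.0))
        )
        back = CrossBasisSpec.from_json(spec.to_json())
        assert back == spec
        assert back.fingerprint() == spec.fingerprint()
        assert np.allclose(
            cross_basis(x, back).values, cross_basis(x, spec).values
        )

    def test_fingerprint_distinguishes_knots(self):
        a = CrossBasisSpec(exposure=SplineSpec(knots=(10.0,), boundary=(0.0, 30.0)))
        b = CrossBasisSpec(exposure=SplineSpec(knots=(12.0,), boundary=(0.0, 30.0)))
        assert a.fingerprint() != b.fingerprint()
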