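"""Forward pooling operator and the l1-minimization decoder."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from poolmc import (
    DecodeOptions,
    PoolingDesign,
    build_design,
    decode_matrix,
    decode_profile,
    estimate_baseline,
    pool_profile,
)

from conftest import basis_pursuit_oracle


class TestPoolProfile:
    def test_single_spike_lands_in_its_sample_pools(self, paper_scale_design):
        d = paper_scale_design
        x = np.zeros(15)
        x[2] = 7.0  # sample 3
        y = pool_profile(x, d)
        expected_pools = set(d.column_support(2))
        assert set(np.flatnonzero(y)) == expected_pools
        assert all(y[i] == 7.0 for i in expected_pools)

    def test_zero_profile_and_row_sums(self, paper_scale_design):
        d = paper_scale_design
        assert (pool_profile(np.zeros(15), d) == 0).all()
        ones = pool_profile(np.ones(15), d)
        assert (ones == d.matrix.sum(axis=1)).all()

    def test_negative_intensities_rejected(self, paper_scale_design):
        x = np.zeros(15)
        x[0] = -1.0
        with pytest.raises(ValueError, match="nonnegative"):
            pool_profile(x, paper_scale_design)

    def test_weights_must_match_design_sparsity(self, square_design):
        weights = square_design.matrix * 0.5
        weights[0, 1] = 0.1  # design has a zero there
        with pytest.raises(ValueError, match="zero exactly where"):
            pool_profile(np.ones(4), square_design, weights=weights)
        halved = pool_profile(np.ones(4), square_design, weights=square_design.matrix * 0.5)
        assert np.allclose(halved, 0.5 * pool_profile(np.ones(4), square_design))

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        a=st.floats(0, 100),
        b=st.floats(0, 100),
        seed=st.integers(0, 10_000),
    )
    def test_forward_operator_is_exactly_linear(self, paper_scale_design, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0, 50, size=15)
        w = rng.uniform(0, 50, size=15)
        lhs = pool_profile(a * x + b * w, paper_scale_design)
        rhs = a * pool_profile(x, paper_scale_design) + b * pool_profile(w, paper_scale_design)
        # linear to floating-point round-off (sums reassociate)
        np.testing.assert_allclose(lhs, rhs, rtol=1e-12, atol=1e-9)


class TestDecodeProfile:
    def test_zero_measurements_decode_to_zero(self, paper_scale_design):
        res = decode_profile(paper_scale_design, np.zeros(12))
        assert res.success
        assert res.l1_norm == 0.0
        assert (res.x_hat == 0).all()

    def test_square_design_one_dim_feasible_set(self, square_design):
        # feasible set is (5+t, t, -t, -t); |5+t| + 3|t| is minimal at t=0
        res = decode_profile(square_design, np.array([5.0, 5.0, 0.0, 0.0]))
        assert res.success
        assert np.allclose(res.x_hat, [5, 0, 0, 0], atol=1e-7)
        assert res.l1_norm == pytest.approx(5.0, abs=1e-7)
        assert res.residual_l1 <= 1e-7

    @pytest.mark.parametrize("magnitude", [1.0, 10.0, 1e2, 1e3, 1e4])
    @pytest.mark.parametrize("sample", [0, 7, 14])
    def test_one_sparse_exact_recovery_across_magnitudes(
        self, paper_scale_design, magnitude, sample
    ):
        x = np.zeros(15)
        x[sample] = magnitude
        res = decode_profile(paper_scale_design, pool_profile(x, paper_scale_design))
        assert np.abs(res.x_hat - x).max() < 1e-6 * magnitude

    def test_decoded_l1_never_exceeds_any_feasible_vector(self, paper_scale_design):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = np.zeros(15)
            x[rng.choice(15, size=2, replace=False)] = rng.uniform(1, 100, size=2)
            res = decode_profile(paper_scale_design, pool_profile(x, paper_scale_design))
            assert res.l1_norm <= np.abs(x).sum() + 1e-6

    def test_matches_exhaustive_support_oracle_on_small_instances(self):
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 100:
            m = int(rng.integers(3, 7))
            n = int(rng.integers(m, 9))
            deg = int(rng.integers(1, min(m, 3) + 1))
            if math.comb(m, deg) < n:
                continue
            design = build_design(n, m, deg, seed=int(rng.integers(0, 2**31)))
            x = np.zeros(n)
            k = int(rng.integers(1, 3))
            x[rng.choice(n, size=k, replace=False)] = rng.uniform(0.5, 20, size=k)
            y = pool_profile(x, design)
            res = decode_profile(design, y)
            oracle = basis_pursuit_oracle(design.matrix.astype(float), y)
            assert res.l1_norm == pytest.approx(oracle, rel=1e-6, abs=1e-7)
            checked += 1

    def test_nonnegative_option_constrains_solution(self, square_design):
        y = np.array([3.0, 3.0, 1.0, 1.0])
        res = decode_profile(square_design, y, DecodeOptions(nonnegative=True))
        assert res.success
        assert (res.x_hat >= 0).all()
        assert res.residual_l1 <= 1e-6

    def test_relaxed_constraint_allows_noisy_measurements(self, paper_scale_design):
        x = np.zeros(15)
        x[4] = 50.0
        y = pool_profile(x, paper_scale_design)
        noise = np.full(12, 0.1)
        res = decode_profile(
            paper_scale_design, y + noise, DecodeOptions(noise_tolerance=1.3)
        )
        assert res.success
        assert res.residual_l1 <= 1.3 + 1e-6
        # the relaxed program can only lower the l1 norm vs exact fitting
        exact = decode_profile(paper_scale_design, y + noise)
        assert res.l1_norm <= exact.l1_norm + 1e-6

    def test_infeasible_system_is_reported_not_zero_filled(self):
        # second pool is empty, so any nonzero measurement there is
        # outside the column space
        d = PoolingDesign(matrix=np.array([[1], [0]]), left_degree=1)
        res = decode_profile(d, np.array([0.0, 1.0]))
        assert not res.success
        assert np.isnan(res.l1_norm)

    def test_baseline_centering_recovers_constant_plus_spike(self, paper_scale_design):
        x = np.full(15, 200.0)
        x[6] = 1700.0
        y = pool_profile(x, paper_scale_design)
        plain = decode_profile(paper_scale_design, y)
        centered = decode_profile(
            paper_scale_design, y, DecodeOptions(baseline_centering=True)
        )
        assert np.abs(centered.x_hat - x).sum() < 1e-5
        # without centering the dense profile is not identifiable
        assert np.abs(plain.x_hat - x).sum() > 1.0


class TestDecodeMatrix:
    def test_single_row_matches_decode_profile(self, paper_scale_design):
        x = np.zeros(15)
        x[3] = 42.0
        y = pool_profile(x, paper_scale_design)
        frame = pd.DataFrame([y], index=["g1"], columns=paper_scale_design.pool_labels)
        out = decode_matrix(paper_scale_design, frame)
        ref = decode_profile(paper_scale_design, y)
        assert np.allclose(out.linear.loc["g1"].to_numpy(), ref.x_hat)
        assert out.log2 is None

    def test_row_permutation_permutes_results(self, paper_scale_design):
        rng = np.random.default_rng(5)
        rows = []
        for _ in range(6):
            x = np.zeros(15)
            x[rng.integers(0, 15)] = rng.uniform(1, 100)
            rows.append(pool_profile(x, paper_scale_design))
        frame = pd.DataFrame(
            rows, index=[f"g{i}" for i in range(6)], columns=paper_scale_design.pool_labels
        )
        shuffled = frame.iloc[::-1]
        a = decode_matrix(paper_scale_design, frame).linear
        b = decode_matrix(paper_scale_design, shuffled).linear
        pd.testing.assert_frame_equal(a.iloc[::-1], b)

    def test_missing_values_rejected_by_gene_name(self, paper_scale_design):
        frame = pd.DataFrame(
            np.ones((2, 12)), index=["gA", "gB"], columns=paper_scale_design.pool_labels
        )
        frame.iloc[1, 3] = np.nan
        with pytest.raises(ValueError, match="gB"):
            decode_matrix(paper_scale_design, frame)

    def test_log2_scale_roundtrip(self, paper_scale_design):
        x = np.zeros(15)
        x[9] = 1024.0
        y = pool_profile(x, paper_scale_design)
        frame = pd.DataFrame(
            [np.log2(y + 1e-12)], index=["g"], columns=paper_scale_design.pool_labels
        )
        out = decode_matrix(paper_scale_design, frame, DecodeOptions(scale="log2"))
        assert out.log2 is not None
        assert out.linear.loc["g"].to_numpy()[9] == pytest.approx(1024.0, rel=1e-5)
        assert out.log2.loc["g"].to_numpy()[9] == pytest.approx(10.0, abs=1e-4)

    def test_shape_mismatch_rejected(self, paper_scale_design):
        frame = pd.DataFrame(np.ones((1, 5)))
        with pytest.raises(ValueError, match="pools"):
            decode_matrix(paper_scale_design, frame)


class TestEstimateBaseline:
    def test_constant_profile_recovers_its_level(self, paper_scale_design):
        y = pool_profile(np.full(15, 3.5), paper_scale_design)
        assert estimate_baseline(y, paper_scale_design) == pytest.approx(3.5)

    def test_zero_measurements_give_zero(self, square_design):
        assert estimate_baseline(np.zeros(4), square_design) == 0.0

    def test_single_spike_on_zero_background_gives_zero(self, paper_scale_design):
        # with d=2 and 12 occupied pools, 10 of 12 ratios are exactly zero
        x = np.zeros(15)
        x[5] = 99.0
        y = pool_profile(x, paper_scale_design)
        assert estimate_baseline(y, paper_scale_design) == 0.0

    def test_empty_pool_is_an_error(self):
        d = PoolingDesign(matrix=np.array([[1], [0]]), left_degree=1)
        with pytest.raises(ValueError, match="pool"):
            estimate_baseline(np.zeros(2), d)
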