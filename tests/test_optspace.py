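"""Unit and property tests of the low-rank completion core."""

import numpy as np
import pytest
import scipy.optimize
from hypothesis import given, settings, strategies as st

from eegrepair import (
    DataError,
    Factorization,
    InfeasibleBlockError,
    InvalidRankError,
    LowRankCompletion,
    MaskedMatrix,
    SingularSystemError,
    complete,
    cost,
    solve_core,
    svd_initialize,
    trim,
    zero_fill,
)

from conftest import masked_low_rank, random_low_rank


class TestMaskedMatrix:
    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            MaskedMatrix(np.zeros((2, 3)), np.ones((3, 2), dtype=bool))

    def test_severity(self):
        m = np.ones((4, 5), dtype=bool)
        m[0, :2] = False
        assert MaskedMatrix(np.zeros((4, 5)), m).severity() == pytest.approx(10.0)

    def test_completability_detection(self):
        m = np.ones((3, 3), dtype=bool)
        m[1, :] = False
        blk = MaskedMatrix(np.zeros((3, 3)), m)
        assert not blk.is_completable()
        assert blk.missing_rows() == [1]
        assert blk.missing_cols() == []


class TestZeroFill:
    def test_fully_observed_identity(self, rng):
        v = rng.normal(size=(3, 4))
        assert np.array_equal(zero_fill(MaskedMatrix(v, np.ones_like(v, bool))), v)

    def test_fully_corrupted_all_zero(self, rng):
        v = rng.normal(size=(3, 4))
        out = zero_fill(MaskedMatrix(v, np.zeros_like(v, bool)))
        assert np.array_equal(out, np.zeros((3, 4)))

    def test_hand_case(self):
        blk = MaskedMatrix([[1.0, 2.0], [3.0, 4.0]],
                           [[True, True], [True, False]])
        assert np.array_equal(zero_fill(blk), [[1.0, 2.0], [3.0, 0.0]])


class TestTrim:
    def test_uniform_density_untouched(self, rng):
        v = rng.normal(size=(6, 6))
        blk = MaskedMatrix(v, np.ones_like(v, bool))
        out = trim(blk)
        assert np.array_equal(out.values, v)
        assert out.mask.all()

    def test_overrepresented_row_trimmed(self, rng):
        # one fully observed row among rows observed at 10%:
        # mean row degree = (10 + 9) / 10 = 1.9, threshold 3.8 < 10
        mask = np.zeros((10, 10), dtype=bool)
        for i in range(1, 10):
            mask[i, i - 1] = True
        mask[0, :] = True
        blk = MaskedMatrix(rng.normal(size=(10, 10)), mask)
        out = trim(blk, degree_factor=2.0)
        assert not out.mask[0].any()
        assert np.array_equal(out.values[0], np.zeros(10))
        # other rows untouched
        assert np.array_equal(out.mask[1:], mask[1:])

    def test_empty_mask_unchanged(self):
        blk = MaskedMatrix(np.zeros((4, 4)), np.zeros((4, 4), bool))
        out = trim(blk)
        assert not out.mask.any()

    def test_input_not_mutated(self, rng):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0, :] = True
        mask[1:, 0] = True
        blk = MaskedMatrix(rng.normal(size=(10, 10)), mask)
        trim(blk)
        assert blk.mask[0].all()


class TestSvdInitialize:
    def test_full_rank_reconstruction(self, rng):
        v = rng.normal(size=(5, 7))
        blk = MaskedMatrix(v, np.ones_like(v, bool))
        f = svd_initialize(blk, rank=5)
        assert np.allclose(f.model(), v, atol=1e-10)
        assert f.check_orthonormal()

    def test_rank_one_exact(self, rng):
        a, b = rng.normal(size=(6, 1)), rng.normal(size=(1, 8))
        v = a @ b
        f = svd_initialize(MaskedMatrix(v, np.ones_like(v, bool)), rank=1)
        assert np.allclose(f.model(), v, atol=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_partial_mask_correlates_with_truth(self, seed):
        # spectral initialization alone already tracks the hidden truth
        # once the matrix is large enough for the sampled spectrum to
        # concentrate (checked numerically over seeds before freezing)
        rng = np.random.default_rng(seed)
        blk, truth = masked_low_rank(rng, 40, 40, rank=2, hidden_frac=0.25)
        f = svd_initialize(blk, rank=2)
        hid = ~blk.mask
        r = np.corrcoef(f.model()[hid], truth[hid])[0, 1]
        assert r > 0.9

    def test_core_diagonal_nonincreasing(self, rng):
        blk, _ = masked_low_rank(rng, 10, 12, rank=3, hidden_frac=0.2)
        f = svd_initialize(blk, rank=3)
        d = np.diag(f.core)
        assert np.all(np.diff(d) <= 0)

    def test_invalid_rank(self, rng):
        blk = MaskedMatrix(rng.normal(size=(3, 4)), np.ones((3, 4), bool))
        with pytest.raises(InvalidRankError):
            svd_initialize(blk, rank=4)


class TestSolveCore:
    def test_exact_recovery_of_core(self, rng):
        x, _ = np.linalg.qr(rng.normal(size=(7, 3)))
        y, _ = np.linalg.qr(rng.normal(size=(9, 3)))
        s0 = rng.normal(size=(3, 3))
        v = x @ s0 @ y.T
        s = solve_core(x, y, MaskedMatrix(v, np.ones_like(v, bool)))
        assert np.allclose(s, s0, atol=1e-10)

    def test_zero_values_zero_core(self, rng):
        x, _ = np.linalg.qr(rng.normal(size=(5, 2)))
        y, _ = np.linalg.qr(rng.normal(size=(6, 2)))
        blk = MaskedMatrix(np.zeros((5, 6)), np.ones((5, 6), bool))
        assert np.allclose(solve_core(x, y, blk), 0.0)

    def test_matches_brute_force_minimizer(self, rng):
        # 4x4 rank-1 data with 2 hidden entries
        truth = random_low_rank(rng, 4, 4, 1)
        mask = np.ones((4, 4), dtype=bool)
        mask[0, 3] = mask[2, 1] = False
        blk = MaskedMatrix(truth, mask)
        x, _ = np.linalg.qr(rng.normal(size=(4, 1)))
        y, _ = np.linalg.qr(rng.normal(size=(4, 1)))
        s = solve_core(x, y, blk)

        def objective(sv):
            r = (truth - x @ sv.reshape(1, 1) @ y.T)[mask]
            return float(r @ r)

        opt = scipy.optimize.minimize_scalar(lambda v: objective(np.array([v])))
        assert s[0, 0] == pytest.approx(opt.x, abs=1e-6)

    def test_cg_matches_direct_for_large_rank(self, rng):
        # r > 8 goes through conjugate gradients; check against the dense path
        from eegrepair.optspace import _solve_core_direct

        blk, _ = masked_low_rank(rng, 30, 40, rank=5, hidden_frac=0.2)
        x, _ = np.linalg.qr(rng.normal(size=(30, 10)))
        y, _ = np.linalg.qr(rng.normal(size=(40, 10)))
        s_cg = solve_core(x, y, blk)
        s_direct = _solve_core_direct(x, y, blk)
        assert np.allclose(s_cg, s_direct, atol=1e-7)

    def test_too_few_entries_raises(self, rng):
        x, _ = np.linalg.qr(rng.normal(size=(4, 2)))
        y, _ = np.linalg.qr(rng.normal(size=(4, 2)))
        mask = np.zeros((4, 4), dtype=bool)
        mask[np.arange(3), np.arange(3)] = True  # 3 < r^2 = 4
        with pytest.raises(SingularSystemError):
            solve_core(x, y, MaskedMatrix(np.ones((4, 4)), mask))


class TestCost:
    def test_exact_fit_zero_cost(self, rng):
        x, _ = np.linalg.qr(rng.normal(size=(6, 2)))
        y, _ = np.linalg.qr(rng.normal(size=(8, 2)))
        v = x @ rng.normal(size=(2, 2)) @ y.T
        assert cost(x, y, MaskedMatrix(v, np.ones_like(v, bool))) <= 1e-10

    def test_constant_residual_frobenius(self):
        # residual c over k observed entries -> cost = c * sqrt(k)
        c, k = 2.5, 6
        x = np.eye(3)[:, :1]
        y = np.eye(4)[:, :1]
        mask = np.zeros((3, 4), dtype=bool)
        mask[0, 0] = True       # the only entry the rank-1 model can touch
        mask[1, :3] = True
        mask[2, :3] = True
        vals = np.full((3, 4), c)
        # S* fits (0,0) exactly; the k remaining observed residuals equal c
        got = cost(x, y, MaskedMatrix(vals, mask))
        assert got == pytest.approx(c * np.sqrt(k), abs=1e-10)

    def test_agrees_with_direct_recomputation(self, rng):
        blk, _ = masked_low_rank(rng, 10, 12, rank=3, hidden_frac=0.3)
        blk = MaskedMatrix(blk.values + rng.normal(size=blk.shape), blk.mask)
        x, _ = np.linalg.qr(rng.normal(size=(10, 3)))
        y, _ = np.linalg.qr(rng.normal(size=(12, 3)))
        s = solve_core(x, y, blk)
        direct = np.linalg.norm((blk.values - x @ s @ y.T)[blk.mask])
        assert cost(x, y, blk) == pytest.approx(direct, abs=1e-12)


class TestComplete:
    def test_exact_recovery_large_block(self, rng):
        blk, truth = masked_low_rank(rng, 128, 120, rank=4, hidden_frac=0.10)
        res = complete(blk, rank=4)
        hid = ~blk.mask
        r = np.corrcoef(res.completed[hid], truth[hid])[0, 1]
        rel = np.linalg.norm((res.completed - truth)[hid]) / np.linalg.norm(truth[hid])
        assert r > 0.999
        assert rel < 1e-3

    def test_fully_observed_identity(self, rng):
        truth = random_low_rank(rng, 12, 15, 3)
        blk = MaskedMatrix(truth, np.ones_like(truth, bool))
        res = complete(blk, rank=3)
        assert np.allclose(res.completed, truth, atol=1e-8)

    def test_missing_row_infeasible(self, rng):
        mask = np.ones((5, 6), dtype=bool)
        mask[2, :] = False
        with pytest.raises(InfeasibleBlockError) as exc:
            complete(MaskedMatrix(rng.normal(size=(5, 6)), mask), rank=1)
        assert exc.value.rows == [2]

    def test_nonfinite_rejected(self, rng):
        v = rng.normal(size=(4, 5))
        v[1, 1] = np.nan
        with pytest.raises(DataError):
            complete(MaskedMatrix(v, np.ones_like(v, bool)), rank=1)

    def test_cost_monotone_and_orthonormal(self, rng):
        blk, _ = masked_low_rank(rng, 20, 25, rank=3, hidden_frac=0.3)
        noisy = MaskedMatrix(blk.values + 0.1 * rng.normal(size=blk.shape), blk.mask)
        res = complete(noisy, rank=3)
        assert np.all(np.diff(res.cost_history) <= 1e-9)
        assert res.factorization.check_orthonormal()
        assert res.final_cost == pytest.approx(res.cost_history[-1])

    def test_completed_equals_model(self, rng):
        blk, _ = masked_low_rank(rng, 10, 10, rank=2, hidden_frac=0.2)
        res = complete(blk, rank=2)
        assert np.array_equal(res.completed, res.factorization.model())

    def test_model_front_end_equivalent(self, rng):
        blk, _ = masked_low_rank(rng, 10, 12, rank=2, hidden_frac=0.2)
        res_fn = complete(blk, rank=2)
        res_model = LowRankCompletion(blk.values, blk.mask, rank=2).fit()
        assert np.allclose(res_fn.completed, res_model.completed)
        assert "rank" in res_model.summary()


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    c=st.integers(10, 16),
    t=st.integers(10, 16),
    rank=st.integers(1, 2),
    seed=st.integers(0, 10_000),
)
def test_exact_recovery_property(c, t, rank, seed):
    """Noiseless low-rank blocks with a feasible uniform hidden set are
    recovered to high accuracy (rank well below the dimensions, so the
    observed entries carry enough information for exact completion)."""
    rng = np.random.default_rng(seed)
    blk, truth = masked_low_rank(rng, c, t, rank, hidden_frac=0.15)
    res = complete(blk, rank=rank)
    assert np.all(np.diff(res.cost_history) <= 1e-9)
    assert res.final_cost <= 1e-5 * max(1.0, np.linalg.norm(truth))


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_factorization_orthonormal_property(seed):
    rng = np.random.default_rng(seed)
    blk, _ = masked_low_rank(rng, 12, 16, 2, hidden_frac=0.25)
    noisy = MaskedMatrix(blk.values + 0.05 * rng.normal(size=blk.shape), blk.mask)
    res = complete(noisy, rank=2)
    assert res.factorization.check_orthonormal(tol=1e-8)
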