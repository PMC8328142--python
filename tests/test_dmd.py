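"""Decomposition core: snapshot splitting, truncated SVD, rank selection,
mode extraction, reconstruction and extrapolation."""

import numpy as np
import pytest
import scipy.linalg as la
from hypothesis import given, settings
from hypothesis import strategies as st

from amrdmd.dmd import (
    SnapshotSeries,
    evaluate,
    evaluate_complex,
    fit_dmd,
    hard_threshold_rank,
    split_snapshots,
    truncated_svd,
)
from amrdmd.fixtures import planted_spectrum_series


def brute_force_rank(s, tau):
    """Independent oracle: scan kappa(r) = 1 - sum_{i<=r} s_i^2 / sum s_i^2."""
    s = np.asarray(s, dtype=float)
    total = np.sum(s**2)
    for r in range(1, len(s) + 1):
        kappa = 1.0 - np.sum(s[:r] ** 2) / total
        if kappa <= tau:
            return r, max(kappa, 0.0)
    return len(s), 0.0


class TestSplit:
    def test_three_columns(self):
        Y = SnapshotSeries(np.arange(6.0).reshape(2, 3), dt_o=1.0)
        Y1, Y2 = split_snapshots(Y)
        np.testing.assert_array_equal(Y1, Y.values[:, :2])
        np.testing.assert_array_equal(Y2, Y.values[:, 1:])

    def test_176_snapshot_stream_gives_175_column_pair(self):
        Y = SnapshotSeries(np.random.default_rng(0).normal(size=(4, 176)), dt_o=0.25)
        Y1, Y2 = split_snapshots(Y)
        assert Y1.shape == Y2.shape == (4, 175)

    def test_shift_identity(self, rng):
        Y = SnapshotSeries(rng.normal(size=(5, 4)), dt_o=1.0)
        Y1, Y2 = split_snapshots(Y)
        for j in range(3):
            np.testing.assert_array_equal(Y2[:, j], Y.values[:, j + 1])
            if j < 2:
                np.testing.assert_array_equal(Y2[:, j], Y1[:, j + 1])

    def test_too_few_columns_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            SnapshotSeries(np.ones((3, 1)), dt_o=1.0)


class TestTruncatedSVD:
    def test_rank_one_exact(self, rng):
        u, v = rng.normal(size=8), rng.normal(size=5)
        Y = np.outer(u, v)
        f = truncated_svd(Y, 1)
        assert f.S_r[0] == pytest.approx(np.linalg.norm(u) * np.linalg.norm(v))
        assert np.linalg.norm(Y - f.U_r * f.S_r @ f.V_r.T) < 1e-12 * f.S_r[0]

    def test_diagonal_truncation_residual(self):
        Y = np.zeros((5, 3))
        Y[:3, :3] = np.diag([3.0, 2.0, 1.0])
        f = truncated_svd(Y, 2)
        np.testing.assert_allclose(f.S_r, [3.0, 2.0])
        assert np.linalg.norm(Y - f.U_r * f.S_r @ f.V_r.T) == pytest.approx(1.0)

    def test_randomized_matches_deterministic_on_low_rank(self, rng):
        Y = rng.normal(size=(50, 5)) @ rng.normal(size=(5, 20))
        det = truncated_svd(Y, 5, "deterministic")
        rnd = truncated_svd(Y, 5, "randomized", seed=7)
        np.testing.assert_allclose(rnd.S_r, det.S_r, atol=1e-8 * det.S_r[0])

    def test_orthonormal_factors(self, rng):
        Y = rng.normal(size=(12, 7))
        f = truncated_svd(Y, 4)
        np.testing.assert_allclose(f.U_r.T @ f.U_r, np.eye(4), atol=1e-10)
        np.testing.assert_allclose(f.V_r.T @ f.V_r, np.eye(4), atol=1e-10)

    def test_eckart_young_monotone_in_rank(self, rng):
        Y = rng.normal(size=(10, 6))
        residuals = [
            np.linalg.norm(Y - (f := truncated_svd(Y, r)).U_r * f.S_r @ f.V_r.T)
            for r in range(1, 7)
        ]
        assert np.all(np.diff(residuals) <= 1e-12)

    @pytest.mark.parametrize("r", [0, 4])
    def test_rank_out_of_range(self, r, rng):
        with pytest.raises(ValueError, match="out of range"):
            truncated_svd(rng.normal(size=(5, 3)), r)


class TestHardThreshold:
    def test_exact_low_rank(self):
        sel = hard_threshold_rank([5.0, 0.0, 0.0], 1e-6)
        assert sel.r == 1 and sel.kappa == 0.0

    def test_three_values(self):
        sel = hard_threshold_rank([3.0, 2.0, 1.0], 0.1)
        assert sel.r == 2
        assert sel.kappa == pytest.approx(1.0 / 14.0)

    def test_default_tolerance_retains_variance(self, rng):
        s = np.sort(rng.uniform(0.1, 5.0, size=20))[::-1]
        sel = hard_threshold_rank(s)  # default tau = 1e-6
        retained = np.sum(s[: sel.r] ** 2) / np.sum(s**2)
        assert retained > 1.0 - 1e-6

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            hard_threshold_rank([0.0, 0.0])

    @given(st.integers(0, 2**31 - 1), st.floats(1e-8, 0.5))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_matches_brute_force(self, seed, tau):
        s = np.sort(np.random.default_rng(seed).uniform(0, 3, size=12))[::-1]
        if s[0] == 0:
            return
        sel = hard_threshold_rank(s, tau)
        r_ref, kappa_ref = brute_force_rank(s, tau)
        assert sel.r == r_ref
        assert sel.kappa == pytest.approx(kappa_ref, abs=1e-12)

    def test_kappa_non_increasing_and_hits_zero_at_rank(self, rng):
        s = np.array([4.0, 2.0, 1.0, 0.0, 0.0])
        kappas = []
        total = np.sum(s**2)
        for r in range(1, 6):
            kappas.append(1 - np.sum(s[:r] ** 2) / total)
        assert np.all(np.diff(kappas) <= 0)
        assert kappas[2] == pytest.approx(0.0, abs=1e-15)


class TestFitDMD:
    def test_constant_snapshots_fixed_point(self):
        c = np.array([2.0, -1.0, 0.5])
        Y = SnapshotSeries(np.tile(c[:, None], (1, 6)), dt_o=0.5)
        model = fit_dmd(Y, r=1)
        assert model.lam[0] == pytest.approx(1.0, abs=1e-12)
        assert abs(model.omega[0]) < 1e-12
        np.testing.assert_allclose(evaluate(model, Y.times), Y.values, atol=1e-12)

    def test_scalar_geometric_growth(self):
        u = 3.0 * 2.0 ** np.arange(8)
        Y = SnapshotSeries(u[None, :], dt_o=1.0)
        model = fit_dmd(Y, r=1)
        assert model.lam[0] == pytest.approx(2.0, abs=1e-12)
        assert model.omega[0] == pytest.approx(np.log(2.0), abs=1e-12)

    def test_planted_spectrum_recovery(self):
        eigs = [0.95, 0.8 * np.exp(1j * np.pi / 8), 0.8 * np.exp(-1j * np.pi / 8)]
        series, truth = planted_spectrum_series(40, 30, eigs, seed=3)
        model = fit_dmd(series, r=3)
        assert (
            np.abs(np.sort_complex(model.lam) - np.sort_complex(truth.lam)).max() < 1e-8
        )

    def test_omega_lambda_consistency(self):
        series, _ = planted_spectrum_series(
            30, 25, [0.9, 0.7 + 0.2j, 0.7 - 0.2j], seed=5, dt_o=0.25
        )
        model = fit_dmd(series, r=3)
        np.testing.assert_allclose(
            np.exp(model.omega * model.dt_o), model.lam, atol=1e-12
        )

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exact_recovery_of_linear_dynamics(self, seed):
        """Snapshots of u_{k+1} = A u_k with diagonalizable low-rank A: the
        reduced-operator spectrum matches A's nonzero spectrum and the
        reconstruction is exact."""
        rng = np.random.default_rng(seed)
        q, n, m = 4, 20, 15
        eigs = rng.uniform(0.5, 1.0, size=q)
        V = rng.normal(size=(n, q))
        A = V @ np.diag(eigs) @ np.linalg.pinv(V)
        u = rng.normal(size=n)
        u = A @ u  # restrict the state to the range of A
        cols = [u]
        for _ in range(m):
            cols.append(A @ cols[-1])
        Y = SnapshotSeries(np.column_stack(cols), dt_o=1.0)
        model = fit_dmd(Y, r=q)
        assert np.abs(np.sort(model.lam.real) - np.sort(eigs)).max() < 1e-8
        rec = evaluate(model, Y.times)
        assert np.linalg.norm(rec - Y.values) < 1e-8 * np.linalg.norm(Y.values)

    def test_rank_above_data_rank_is_shrunk_with_warning(self):
        series, _ = planted_spectrum_series(30, 20, [0.9, 0.8], seed=1)
        with pytest.warns(UserWarning, match="floor"):
            model = fit_dmd(series, r=10)
        assert model.r == 2

    def test_zero_eigenvalue_mode_dropped(self):
        # one decaying mode plus a direction annihilated after the first step
        n, m = 6, 10
        rng = np.random.default_rng(0)
        v1, v2 = rng.normal(size=n), rng.normal(size=n)
        cols = [v1 + v2] + [0.5**k * v1 for k in range(1, m + 1)]
        Y = SnapshotSeries(np.column_stack(cols), dt_o=1.0)
        with pytest.warns(UserWarning, match="λ = 0|nilpotent"):
            model = fit_dmd(Y, r=2)
        assert model.r == 1
        assert model.lam[0] == pytest.approx(0.5, abs=1e-10)

    def test_negative_eigenvalue_maps_to_nyquist_frequency(self):
        u = (-0.5) ** np.arange(10)
        Y = SnapshotSeries(np.outer([1.0, 2.0], u), dt_o=0.5)
        model = fit_dmd(Y, r=1)
        assert model.omega[0].imag == pytest.approx(np.pi / 0.5, abs=1e-12)

    def test_shift_invariance_of_spectrum_and_modes(self):
        eigs = [0.95, 0.85 + 0.1j, 0.85 - 0.1j]
        series, _ = planted_spectrum_series(25, 30, eigs, seed=9)
        full = fit_dmd(series, r=3)
        shifted = SnapshotSeries(series.values[:, 2:], series.dt_o, series.t0 + 2 * series.dt_o)
        late = fit_dmd(shifted, r=3)
        i_full = np.argsort(full.lam.real + 1e-6 * full.lam.imag)
        i_late = np.argsort(late.lam.real + 1e-6 * late.lam.imag)
        np.testing.assert_allclose(full.lam[i_full], late.lam[i_late], atol=1e-8)
        # modes agree up to a per-mode complex scaling
        for a, b in zip(i_full, i_late):
            pa, pb = full.Psi[:, a], late.Psi[:, b]
            scale = (pa.conj() @ pb) / (pa.conj() @ pa)
            assert np.abs(pb - scale * pa).max() < 1e-8 * np.abs(pb).max()
        assert not np.allclose(np.sort(np.abs(full.b)), np.sort(np.abs(late.b)))

    def test_modes_ordered_by_amplitude(self):
        series, _ = planted_spectrum_series(30, 25, [0.9, 0.8, 0.7], seed=2)
        model = fit_dmd(series, r=3)
        assert np.all(np.diff(np.abs(model.b)) <= 1e-12)


class TestEvaluate:
    def test_time_zero_reproduces_initial_snapshot(self):
        series, _ = planted_spectrum_series(30, 25, [0.9, 0.6 + 0.3j, 0.6 - 0.3j], seed=4)
        model = fit_dmd(series, r=3)
        np.testing.assert_allclose(
            evaluate(model, series.t0)[:, 0], series.values[:, 0], atol=1e-8
        )

    def test_extrapolation_matches_ground_truth(self):
        eigs = [0.95, 0.8 * np.exp(1j * np.pi / 8), 0.8 * np.exp(-1j * np.pi / 8)]
        series, truth = planted_spectrum_series(40, 30, eigs, seed=6)
        model = fit_dmd(series, r=3)
        t_ext = series.times[-1] + np.arange(1, 11) * series.dt_o
        powers = truth.lam[:, None] ** t_ext[None, :]
        expected = np.real(truth.Psi @ (powers * truth.b[:, None]))
        err = np.linalg.norm(evaluate(model, t_ext) - expected)
        assert err <= 1e-6 * np.linalg.norm(expected)

    def test_imaginary_residual_negligible_for_real_data(self):
        series, _ = planted_spectrum_series(30, 40, [0.9, 0.7 + 0.4j, 0.7 - 0.4j], seed=8)
        model = fit_dmd(series, r=3)
        rec = evaluate_complex(model, series.times)
        assert np.abs(rec.imag).max() <= 1e-6 * np.linalg.norm(series.values)
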