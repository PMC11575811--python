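import numpy as np
import pytest

import pollengap as pg
from pollengap.imputers import GappyMatrix, GsvdConfig
from conftest import make_series

nan = np.nan


class TestMovingMean:
    def test_single_gap_symmetric_window(self):
        filled = pg.moving_mean_fill(np.array([1.0, 2.0, nan, 4.0, 5.0]))
        np.testing.assert_allclose(filled, [1, 2, 3, 4, 5])

    def test_no_missing_identity(self):
        v = np.array([1.0, 2.0, 3.0])
        np.testing.assert_array_equal(pg.moving_mean_fill(v), v)

    def test_leading_double_gap(self):
        filled = pg.moving_mean_fill(np.array([nan, nan, 6.0, 6.0, 6.0, 6.0]))
        np.testing.assert_allclose(filled, [6, 6, 6, 6, 6, 6])

    def test_window_widens_until_observed(self):
        # 4-day gap far from the only observations: half-width doubles
        v = np.array([2.0] + [nan] * 9 + [4.0])
        filled = pg.moving_mean_fill(v)
        assert not np.isnan(filled).any()
        assert (filled >= 2.0).all() and (filled <= 4.0).all()

    def test_fully_missing_errors(self):
        with pytest.raises(ValueError, match="fully missing"):
            pg.moving_mean_fill(np.array([nan, nan]))

    @pytest.mark.parametrize("seed", range(25))
    def test_imputed_values_within_observed_window_range(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.gamma(1.0, 10.0, 60)
        truth = v.copy()
        plan = pg.plan_gaps(60, 0.2, rng.integers(1, 8))
        mask = pg.place_gaps(60, plan, seed=seed)
        v[mask] = nan
        filled = pg.moving_mean_fill(v)
        np.testing.assert_array_equal(filled[~mask], truth[~mask])
        lo, hi = np.nanmin(v), np.nanmax(v)
        assert (filled[mask] >= lo - 1e-12).all()
        assert (filled[mask] <= hi + 1e-12).all()

    def test_series_wrapper_preserves_metadata(self):
        s = make_series([1.0, nan, 3.0])
        out = pg.impute_moving_mean(s)
        assert out.station_id == s.station_id and out.taxon == s.taxon
        np.testing.assert_allclose(out.values, [1, 2, 3])


class TestInitialFill:
    def test_linear_midpoint(self):
        np.testing.assert_allclose(
            pg.initial_fill(np.array([1.0, nan, 3.0]), method="linear"), [1, 2, 3]
        )

    def test_mean_fill(self):
        np.testing.assert_allclose(
            pg.initial_fill(np.array([1.0, nan, 3.0]), method="mean"), [1, 2, 3]
        )

    def test_linear_edge_flat_extension(self):
        np.testing.assert_allclose(
            pg.initial_fill(np.array([nan, 5.0, 5.0]), method="linear"), [5, 5, 5]
        )

    def test_fully_masked_errors(self):
        with pytest.raises(ValueError, match="fully masked"):
            pg.initial_fill(np.array([nan, nan]))


class TestAssembleMatrix:
    def _historical(self, n=20, years=5):
        rng = np.random.default_rng(0)
        return {str(2018 + i): rng.gamma(2.0, 5.0, n) for i in range(years)}

    def test_historical_plus_replicates_column_count(self):
        hist = self._historical()
        reps = [np.where(np.arange(20) % 7 == 0, nan, 1.0) for _ in range(100)]
        gm = pg.assemble_matrix(hist, reps, reference_label="2022")
        assert gm.shape == (20, 105)
        assert gm.columns[:5] == ["2018", "2019", "2020", "2021", "2022"]

    def test_reference_year_excluded_on_request(self):
        hist = self._historical()
        gm = pg.assemble_matrix(
            hist, [], include_reference_year=False, reference_label="2022"
        )
        assert gm.shape == (20, 4)
        assert "2022" not in gm.columns

    def test_historical_only_masks_historical_missing(self):
        hist = self._historical(n=10, years=2)
        hist["2018"][3] = nan
        gm = pg.assemble_matrix(hist)
        assert gm.mask.sum() == 1
        assert gm.mask[3, 0]

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError, match="mismatched"):
            pg.assemble_matrix({"a": np.ones(5), "b": np.ones(6)})


def rank1_problem(seed=0, shape=(20, 8), mask_frac=0.10):
    """Exact rank-1 gappy matrix with known ground truth."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0, np.pi, shape[0])
    u = 1.0 + np.sin(t)  # positive smooth day profile
    w = 2.0 + np.cos(np.linspace(0, 1, shape[1]))  # positive series weights
    truth = np.outer(u, w)
    mask = rng.random(shape) < mask_frac
    mask[:, mask.all(axis=0)] = False  # keep every column partly observed
    values = truth.copy()
    values[mask] = nan
    return truth, GappyMatrix(values=values, mask=mask)


class TestGsvdImpute:
    def test_empty_mask_noop(self):
        truth, _ = rank1_problem()
        gm = GappyMatrix(values=truth, mask=np.zeros_like(truth, dtype=bool))
        res = pg.gsvd_impute(gm, GsvdConfig(n_modes=1))
        assert res.converged
        assert res.final_delta == 0.0
        np.testing.assert_array_equal(res.completed, truth)

    def test_constant_matrix_any_mask(self):
        c = 3.7
        values = np.full((12, 6), c)
        mask = np.zeros((12, 6), dtype=bool)
        mask[::3, ::2] = True
        gm = GappyMatrix(values=np.where(mask, nan, values), mask=mask)
        res = pg.gsvd_impute(gm, GsvdConfig(n_modes=1, init="mean"))
        assert res.converged
        np.testing.assert_allclose(res.completed, c, rtol=1e-5)

    def test_rank1_oracle_recovery(self):
        truth, gm = rank1_problem(seed=0)
        res = pg.gsvd_impute(gm, GsvdConfig(n_modes=1, init="mean"))
        assert res.converged
        assert np.max(np.abs(res.completed - truth)) < 1e-3

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("rank", [1, 2, 3])
    def test_exact_rank_r_recovery_across_seeds(self, seed, rank):
        rng = np.random.default_rng(seed)
        U = rng.gamma(2.0, 1.0, (25, rank))
        V = rng.gamma(2.0, 1.0, (10, rank))
        truth = U @ V.T
        mask = rng.random(truth.shape) < 0.08
        mask[:, mask.all(axis=0)] = False
        values = np.where(mask, nan, truth)
        gm = GappyMatrix(values=values, mask=mask)
        # mean init: for unstructured columns linear interpolation along the
        # day axis is a poor initial guess and the iteration can stall
        res = pg.gsvd_impute(gm, GsvdConfig(n_modes=rank, init="mean", tol=1e-10))
        rel = np.max(np.abs(res.completed - truth)) / truth.max()
        assert rel < 1e-2

    def test_observed_entries_never_modified(self):
        truth, gm = rank1_problem(seed=3, mask_frac=0.3)
        res = pg.gsvd_impute(gm, GsvdConfig(n_modes=2, init="mean"))
        np.testing.assert_array_equal(res.completed[~gm.mask], truth[~gm.mask])

    def test_convergence_flag_honest(self):
        truth, gm = rank1_problem(seed=1, mask_frac=0.2)
        res = pg.gsvd_impute(gm, GsvdConfig(n_modes=1, tol=1e-12, max_iter=2))
        assert not res.converged
        assert res.final_delta >= 1e-12
        res2 = pg.gsvd_impute(gm, GsvdConfig(n_modes=1, tol=1e-8, max_iter=500))
        assert res2.converged
        assert res2.final_delta < 1e-8

    def test_scale_invariance_with_relative_tolerance(self):
        truth, gm = rank1_problem(seed=5, mask_frac=0.15)
        cfg = GsvdConfig(n_modes=1, tol=1e-10, relative=True)
        res1 = pg.gsvd_impute(gm, cfg)
        scaled = GappyMatrix(values=gm.values * 1000.0, mask=gm.mask)
        res2 = pg.gsvd_impute(scaled, cfg)
        np.testing.assert_allclose(
            res2.completed / 1000.0, res1.completed, rtol=1e-6
        )

    def test_n_modes_beyond_rank_bound_errors(self):
        _, gm = rank1_problem()
        with pytest.raises(ValueError, match="rank bound"):
            pg.gsvd_impute(gm, GsvdConfig(n_modes=9))

    def test_fully_masked_column_errors(self):
        values = np.ones((5, 3))
        mask = np.zeros((5, 3), dtype=bool)
        mask[:, 1] = True
        gm = GappyMatrix(values=np.where(mask, nan, values), mask=mask)
        with pytest.raises(ValueError, match="fully masked"):
            pg.gsvd_impute(gm, GsvdConfig(n_modes=1))

    def test_imputed_concentrations_clipped_nonnegative(self):
        rng = np.random.default_rng(2)
        values = rng.gamma(0.3, 1.0, (30, 6))
        mask = rng.random(values.shape) < 0.2
        mask[:, mask.all(axis=0)] = False
        gm = GappyMatrix(values=np.where(mask, nan, values), mask=mask)
        res = pg.gsvd_impute(gm, GsvdConfig(n_modes=3, init="mean"))
        assert (res.completed >= 0).all()
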