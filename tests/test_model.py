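import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nerdmap as nm
from nerdmap.constants import NM2_PER_UM2, PERCOLATION_COVERAGE
from nerdmap.model import fit_radius_batch


class TestObstacleMobility:
    def test_no_obstacles_full_mobility(self):
        assert nm.obstacle_mobility_ratio(0.0, 2.6) == 1.0

    def test_printed_scalar_value(self):
        assert nm.obstacle_mobility_ratio(500.0, 2.6) == pytest.approx(
            0.8752, abs=5e-5)

    def test_half_mobility_identity(self):
        # exponent = ln(4/3)  =>  ratio = 1 - sqrt(1 - 3/4) = 1/2
        r = 2.0
        rho = np.log(4 / 3) * PERCOLATION_COVERAGE / (
            np.pi * r**2 * NM2_PER_UM2)
        assert nm.obstacle_mobility_ratio(rho, r) == pytest.approx(0.5,
                                                                   abs=1e-12)

    def test_strictly_decreasing_in_density_and_radius(self):
        rho = np.linspace(0, 3000, 50)
        vals = nm.obstacle_mobility_ratio(rho, 2.6)
        assert np.all(np.diff(vals) < 0)
        radii = np.linspace(0.5, 10, 50)
        vals_r = [nm.obstacle_mobility_ratio(800.0, r) for r in radii]
        assert np.all(np.diff(vals_r) < 0)

    def test_limits(self):
        assert nm.obstacle_mobility_ratio(1e9, 2.6) == pytest.approx(0.0,
                                                                     abs=1e-6)
        assert nm.obstacle_mobility_ratio(500.0, 1e-6) == pytest.approx(
            1.0, abs=1e-6)


class TestNERDMobility:
    @pytest.mark.parametrize("d,f", [(0.0, 0.3), (0.0, 1.0), (1.4, 1.0)])
    def test_reduces_to_bare_obstacle_model(self, d, f):
        params = nm.NERDParams(r_poi=2.0, r_lipid=0.5, d_nerd=d, f_nerd=f)
        rho = np.linspace(0, 2500, 40)
        np.testing.assert_allclose(
            nm.nerd_mobility_ratio(params, rho),
            nm.obstacle_mobility_ratio(rho, 2.5), rtol=1e-14)

    def test_impenetrable_ring_reduction(self):
        # f = 0 collapses the ring factor to exp(-2·rho·pi·x)
        params = nm.NERDParams(r_poi=2.0, r_lipid=0.5, d_nerd=0.7,
                               f_nerd=0.0)
        rho = 500.0
        q = rho * np.pi * params.ring_area * NM2_PER_UM2
        expected = nm.obstacle_mobility_ratio(rho, 2.5) * np.exp(-2 * q)
        assert nm.nerd_mobility_ratio(params, rho) == pytest.approx(
            expected, rel=1e-12)

    def test_ring_never_speeds_up_tracers(self):
        rho = np.linspace(10, 2500, 30)
        for d in (0.35, 0.7, 1.4):
            for f in (0.0, 0.3, 0.8):
                params = nm.NERDParams(r_poi=2.0, r_lipid=0.5, d_nerd=d,
                                       f_nerd=f)
                assert np.all(nm.nerd_mobility_ratio(params, rho)
                              <= nm.obstacle_mobility_ratio(rho, 2.5) + 1e-12)

    def test_monotone_in_ring_parameters(self):
        rho = np.linspace(50, 2000, 20)
        d_grid = np.linspace(0, 2.1, 8)
        vals = [nm.nerd_mobility_ratio(
            nm.NERDParams(r_poi=2.0, r_lipid=0.5, d_nerd=d, f_nerd=0.3), rho)
            for d in d_grid]
        for a, b in zip(vals, vals[1:]):
            assert np.all(b <= a + 1e-12)
        f_grid = np.linspace(0.0, 1.0, 8)
        vals = [nm.nerd_mobility_ratio(
            nm.NERDParams(r_poi=2.0, r_lipid=0.5, d_nerd=0.7, f_nerd=f), rho)
            for f in f_grid]
        for a, b in zip(vals, vals[1:]):
            assert np.all(b >= a - 1e-12)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            nm.NERDParams(r_poi=-1.0)
        with pytest.raises(ValueError):
            nm.NERDParams(r_poi=2.0, f_nerd=1.5)
        with pytest.raises(ValueError):
            nm.NERDParams(r_poi=2.0, d_nerd=-0.1)


def _dataset(rho, ratio, err=None):
    from nerdmap.tracking import CellMeasurement

    err = err if err is not None else np.full(len(rho), np.nan)
    cells = [CellMeasurement(cell_id=str(i), rho_mgfp=r / 1.2,
                             rho_obstacle=r, ratio=y, ratio_error=e)
             for i, (r, y, e) in enumerate(zip(rho, ratio, err))]
    return nm.StudyDataset(cells=cells)


class TestApparentRadiusFit:
    def test_noiseless_recovery_machine_precision(self):
        rho = np.linspace(100, 2000, 12)
        ds = _dataset(rho, nm.obstacle_mobility_ratio(rho, 3.0))
        fit = nm.fit_apparent_radius(ds)
        assert fit.r_app == pytest.approx(3.0, abs=1e-9)
        assert fit.r_poi_app == pytest.approx(3.0 - 0.49, abs=1e-9)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(r_true=st.floats(0.5, 8.0))
    def test_noiseless_recovery_over_radius_range(self, r_true):
        rho = np.linspace(50, 1500, 8)
        ds = _dataset(rho, nm.obstacle_mobility_ratio(rho, r_true))
        fit = nm.fit_apparent_radius(ds)
        assert fit.r_app == pytest.approx(r_true, abs=1e-7)

    def test_invariant_to_cell_order_and_duplication(self):
        rng = np.random.default_rng(4)
        rho = rng.uniform(100, 2000, 20)
        y = nm.obstacle_mobility_ratio(rho, 2.6) * (
            1 + 0.05 * rng.standard_normal(20))
        fit = nm.fit_apparent_radius(_dataset(rho, y))
        perm = rng.permutation(20)
        fit_perm = nm.fit_apparent_radius(_dataset(rho[perm], y[perm]))
        fit_dup = nm.fit_apparent_radius(
            _dataset(np.tile(rho, 2), np.tile(y, 2)))
        assert fit_perm.r_app == pytest.approx(fit.r_app, abs=1e-9)
        assert fit_dup.r_app == pytest.approx(fit.r_app, abs=1e-6)

    def test_needs_three_cells(self):
        with pytest.raises(ValueError):
            nm.fit_apparent_radius(_dataset([100.0, 500.0], [0.9, 0.8]))

    def test_flat_data_warns_unidentifiable(self, caplog):
        rho = np.linspace(1, 3, 5)
        with caplog.at_level("WARNING"):
            nm.fit_apparent_radius(_dataset(rho, np.full(5, 0.999)))
        assert "unidentifiable" in caplog.text

    def test_batch_fitter_agrees_with_reference_fit(self):
        rng = np.random.default_rng(9)
        rho = rng.uniform(100, 2000, (6, 30))
        y = nm.obstacle_mobility_ratio(rho, 2.6) * (
            1 + 0.05 * rng.standard_normal(rho.shape))
        batch = fit_radius_batch(rho, y)
        for k in range(6):
            ref = nm.fit_apparent_radius(_dataset(rho[k], y[k]))
            assert batch[k] == pytest.approx(ref.r_app, abs=1e-5)

    def test_weighted_fit_changes_estimate(self):
        rng = np.random.default_rng(3)
        rho = rng.uniform(100, 2000, 25)
        y = nm.obstacle_mobility_ratio(rho, 2.6) * (
            1 + 0.05 * rng.standard_normal(25))
        err = np.where(rho > 1000, 0.01, 0.2)
        unw = nm.fit_apparent_radius(_dataset(rho, y, err))
        w = nm.fit_apparent_radius(_dataset(rho, y, err), weighted=True)
        assert w.r_app != pytest.approx(unw.r_app, abs=1e-6)


class TestFitError:
    def _noisy_dataset(self, seed, n_cells=88, rel=0.05, r_true=2.6):
        rng = np.random.default_rng(seed)
        rho_t = rng.uniform(0, 2000, n_cells)
        y = nm.obstacle_mobility_ratio(rho_t, r_true) * (
            1 + rel * rng.standard_normal(n_cells))
        rho_o = np.abs(rho_t * (1 + rel * rng.standard_normal(n_cells)))
        return _dataset(rho_o, np.clip(y, 1e-6, 1.05),
                        err=rel * np.abs(y))

    def test_zero_errors_give_zero_spread(self):
        rho = np.linspace(100, 2000, 30)
        ds = _dataset(rho, nm.obstacle_mobility_ratio(rho, 2.6),
                      err=np.zeros(30))
        fit = nm.fit_apparent_radius(ds)
        err = nm.estimate_fit_error(fit, ds, n_sim=100, seed=1,
                                    rel_err_ratio=0.0)
        assert err == pytest.approx(0.0, abs=1e-6)

    def test_seed_reproducible(self):
        ds = self._noisy_dataset(2)
        fit = nm.fit_apparent_radius(ds)
        a = nm.estimate_fit_error(fit, ds, n_sim=200, seed=7,
                                  rel_err_density=0.05)
        b = nm.estimate_fit_error(fit, ds, n_sim=200, seed=7,
                                  rel_err_density=0.05)
        assert a == b

    def test_error_scales_with_cell_count(self):
        # 88 vs 22 cells, same error model: expect a ~2x error ratio
        ratios = []
        for seed in range(4):
            errs = []
            for n in (88, 22):
                ds = self._noisy_dataset(seed + 10, n_cells=n)
                fit = nm.fit_apparent_radius(ds)
                errs.append(nm.estimate_fit_error(fit, ds, n_sim=400,
                                                  seed=seed,
                                                  rel_err_density=0.05))
            ratios.append(errs[1] / errs[0])
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.3)

    def test_closed_loop_recovery_unbiased(self):
        # mean recovered radius over seeds within one fit error of truth
        recovered = []
        err = None
        for seed in range(40):
            ds = self._noisy_dataset(seed + 50)
            fit = nm.fit_apparent_radius(ds)
            recovered.append(fit.r_app)
            if seed == 0:
                err = nm.estimate_fit_error(fit, ds, n_sim=400, seed=seed,
                                            rel_err_density=0.05)
        assert abs(np.mean(recovered) - 2.6) < err

    def test_lognormal_density_model_runs(self):
        ds = self._noisy_dataset(3)
        fit = nm.fit_apparent_radius(ds)
        err = nm.estimate_fit_error(fit, ds, n_sim=200, seed=1,
                                    density_model="lognormal")
        assert 0.0 < err < 1.0


class TestStudyDatasetIO:
    def test_csv_round_trip(self, tmp_path):
        rho = np.linspace(100, 2000, 8)
        ds = _dataset(rho, nm.obstacle_mobility_ratio(rho, 2.6),
                      err=np.full(8, 0.03))
        p = tmp_path / "cells.csv"
        ds.write(p)
        back = nm.StudyDataset.read(p)
        np.testing.assert_allclose(back.rho, ds.rho)
        np.testing.assert_allclose(back.ratio, ds.ratio)
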