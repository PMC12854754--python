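import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nerdmap as nm
from nerdmap.tracking import TrajectorySet


def _ts(rows, frame_spacing=0.010):
    df = pd.DataFrame(rows,
                      columns=["track_id", "frame", "x_um", "y_um", "mass"])
    return TrajectorySet(data=df, frame_spacing=frame_spacing)


class TestTrajectoryIO:
    def test_read_well_formed_file(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("track_id,frame,x_um,y_um,mass\n"
                     "1,0,0.0,0.0,500\n1,1,0.1,0.0,500\n1,2,0.2,0.0,500\n")
        ts = nm.read_trajectories(p, 0.010)
        assert ts.n_tracks == 1 and len(ts) == 3

    def test_round_trip_identity(self, tmp_path, make_brownian):
        ts = make_brownian(1.0, 5, 8, seed=3)
        p = tmp_path / "t.csv"
        ts.write(p)
        back = nm.read_trajectories(p, ts.frame_spacing)
        pd.testing.assert_frame_equal(ts.data, back.data)

    def test_duplicate_frame_names_track(self):
        with pytest.raises(ValueError, match=r"\[7\]"):
            _ts([(7, 0, 0.0, 0.0, 1.0), (7, 0, 0.1, 0.0, 1.0)])

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("track_id,frame,x_um\n1,0,0.0\n")
        with pytest.raises(ValueError, match="missing"):
            nm.read_trajectories(p, 0.010)

    def test_malformed_rows_dropped(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("track_id,frame,x_um,y_um,mass\n"
                     "1,0,0.0,0.0,500\n1,1,oops,0.0,500\n1,2,0.2,0.0,500\n")
        ts = nm.read_trajectories(p, 0.010)
        assert len(ts) == 2


class TestClassification:
    def test_track_inside_dot_is_on(self):
        mask = nm.render_pattern_mask(3.0, 6.0, 0.05, 6.0)
        ts = _ts([(0, f, 3.0 + 0.01 * f, 3.0, 1.0) for f in range(5)])
        on, off, disc = nm.classify_trajectories(ts, mask)
        assert on.n_tracks == 1 and off.n_tracks == 0 and disc == 0

    def test_edge_straddling_track_discarded(self):
        mask = nm.render_pattern_mask(3.0, 6.0, 0.05, 6.0)
        ts = _ts([(0, 0, 3.0, 3.0, 1.0), (0, 1, 5.5, 5.5, 1.0)])
        on, off, disc = nm.classify_trajectories(ts, mask)
        assert on.n_tracks == 0 and off.n_tracks == 0 and disc == 1

    def test_all_off_mask_keeps_everything_off(self):
        mask = nm.render_pattern_mask(0.0, 6.0, 0.05, 6.0)
        ts = _ts([(t, f, 1.0 + t, 1.0, 1.0)
                  for t in range(3) for f in range(4)])
        on, off, disc = nm.classify_trajectories(ts, mask)
        assert off.n_tracks == 3 and disc == 0

    def test_outside_extent_discarded_with_warning(self, caplog):
        mask = nm.render_pattern_mask(3.0, 6.0, 0.05, 6.0)
        ts = _ts([(0, 0, 3.0, 3.0, 1.0), (0, 1, 9.0, 3.0, 1.0)])
        with caplog.at_level("WARNING"):
            _, _, disc = nm.classify_trajectories(ts, mask)
        assert disc == 1 and "extent" in caplog.text

    def test_segment_rule_splits_mixed_tracks(self):
        mask = nm.render_pattern_mask(3.0, 6.0, 0.05, 6.0)
        pts = ([(0, f, 3.0, 3.0, 1.0) for f in range(3)]
               + [(0, f, 0.2, 0.2, 1.0) for f in range(3, 6)])
        on, off, _ = nm.classify_trajectories(_ts(pts), mask, rule="segment")
        assert len(on) == 3 and len(off) == 3


class TestMSD:
    def test_stationary_track_zero_msd(self):
        ts = _ts([(0, f, 1.0, 2.0, 1.0) for f in range(6)])
        curve = nm.compute_msd(ts, 3)
        np.testing.assert_allclose(curve.msd, 0.0)

    def test_ballistic_closed_form(self):
        v, dt = 0.3, 0.010
        ts = _ts([(0, f, v * f * dt, 0.0, 1.0) for f in range(10)], dt)
        curve = nm.compute_msd(ts, 4)
        np.testing.assert_allclose(curve.msd,
                                   (v * np.arange(1, 5) * dt) ** 2,
                                   rtol=1e-12)

    def test_brownian_msd_within_sampling_error(self, make_brownian):
        D, dt = 1.0, 0.010
        ts = make_brownian(D, 400, 12, frame_spacing=dt, seed=8)
        curve = nm.compute_msd(ts, 3)
        for k in range(3):
            se = curve.msd[k] / np.sqrt(curve.n_pairs[k])
            assert abs(curve.msd[k] - 4 * D * dt * (k + 1)) < 3.5 * se

    def test_pooling_counts_and_gap_handling(self):
        # frames 0,1,3: one pair each at lags 1, 2 and 3
        ts = _ts([(0, 0, 0.0, 0.0, 1.0), (0, 1, 1.0, 0.0, 1.0),
                  (0, 3, 3.0, 0.0, 1.0)])
        curve = nm.compute_msd(ts, 3)
        np.testing.assert_array_equal(curve.n_pairs, [1, 1, 1])
        np.testing.assert_allclose(curve.msd, [1.0, 4.0, 9.0])

    def test_invariance_to_track_order_and_translation(self, make_brownian):
        ts = make_brownian(0.5, 10, 8, seed=5)
        curve = nm.compute_msd(ts, 4)
        shuffled = ts.data.sample(frac=1.0, random_state=1)
        moved = shuffled.assign(x_um=shuffled.x_um + 50.0,
                                y_um=shuffled.y_um - 20.0)
        curve2 = nm.compute_msd(
            TrajectorySet(data=moved, frame_spacing=ts.frame_spacing), 4)
        np.testing.assert_allclose(curve.msd, curve2.msd, rtol=1e-9)

    def test_truncation_beyond_longest_track(self):
        ts = _ts([(0, f, 0.1 * f, 0.0, 1.0) for f in range(4)])
        curve = nm.compute_msd(ts, 10)
        assert len(curve.msd) == 3


class TestDiffusionFit:
    def test_exact_two_point_solution(self):
        # constructed from MSD(t) = 4·1·(t − 0.001) + 4·0.04²
        curve = nm.MSDCurve(lag_times=[0.01, 0.02], msd=[0.0424, 0.0824],
                            n_pairs=[100, 90])
        est = nm.fit_diffusion(curve, t_ill=0.003)
        assert est.D == pytest.approx(1.0, abs=1e-12)
        assert est.sigma_loc == pytest.approx(0.040, abs=1e-12)

    def test_linearity_under_scaling(self):
        curve = nm.MSDCurve(lag_times=[0.01, 0.02], msd=[0.0424, 0.0824],
                            n_pairs=[100, 90])
        base = nm.fit_diffusion(curve, t_ill=0.003)
        doubled = nm.MSDCurve(lag_times=[0.01, 0.02],
                              msd=[0.0848, 0.1648], n_pairs=[100, 90])
        est = nm.fit_diffusion(doubled, t_ill=0.003)
        assert est.D == pytest.approx(2 * base.D)
        assert est.sigma_loc**2 == pytest.approx(2 * base.sigma_loc**2)

    def test_negative_intercept_flagged(self):
        curve = nm.MSDCurve(lag_times=[0.01, 0.02], msd=[0.030, 0.070],
                            n_pairs=[10, 10])
        est = nm.fit_diffusion(curve, t_ill=0.003)
        assert est.negative_intercept and est.sigma_loc == 0.0

    def test_too_few_points_rejected(self):
        curve = nm.MSDCurve(lag_times=[0.01], msd=[0.04], n_pairs=[10])
        with pytest.raises(ValueError):
            nm.fit_diffusion(curve, t_ill=0.003)
        with pytest.raises(ValueError):
            nm.fit_diffusion(curve, t_ill=0.003, n_points=1)


class TestBootstrap:
    def test_identical_tracks_zero_error(self):
        rows = []
        for t in range(8):
            rows += [(t, f, 0.1 * f, 0.0, 1.0) for f in range(6)]
        err = nm.bootstrap_diffusion(_ts(rows), t_ill=0.003, n_boot=50,
                                     seed=1)
        assert err == pytest.approx(0.0, abs=1e-12)

    def test_seed_reproducible(self, make_brownian):
        ts = make_brownian(1.0, 30, 8, seed=2)
        a = nm.bootstrap_diffusion(ts, 0.003, n_boot=60, seed=5)
        b = nm.bootstrap_diffusion(ts, 0.003, n_boot=60, seed=5)
        assert a == b

    def test_error_shrinks_with_track_count(self, make_brownian):
        errs = []
        for n in (100, 400):
            ts = make_brownian(1.0, n, 8, seed=3)
            errs.append(nm.bootstrap_diffusion(ts, 0.003, n_boot=150,
                                               seed=7))
        # ~1/sqrt(n) scaling: expect a factor of 2, within 30 %
        assert errs[0] / errs[1] == pytest.approx(2.0, rel=0.3)

    def test_too_few_tracks_rejected(self, make_brownian):
        ts = make_brownian(1.0, 3, 8, seed=1)
        with pytest.raises(ValueError):
            nm.bootstrap_diffusion(ts, 0.003, n_boot=10, seed=1)


class TestMobilityRatio:
    def test_equal_coefficients_give_unity(self):
        est = nm.DiffusionEstimate(D=0.8, sigma_loc=0.04, D_error=0.0)
        ratio, err = nm.mobility_ratio(est, est)
        assert ratio == 1.0 and err == 0.0

    def test_delta_method_propagation(self):
        on = nm.DiffusionEstimate(D=0.5, sigma_loc=0.04, D_error=0.05)
        off = nm.DiffusionEstimate(D=1.0, sigma_loc=0.04, D_error=0.1)
        ratio, err = nm.mobility_ratio(on, off)
        assert ratio == pytest.approx(0.5)
        assert err == pytest.approx(0.5 * np.sqrt(0.01 + 0.01), rel=1e-9)

    def test_zero_off_rejected(self):
        on = nm.DiffusionEstimate(D=0.5, sigma_loc=0.04)
        off = nm.DiffusionEstimate(D=0.0, sigma_loc=0.04)
        with pytest.raises(ValueError):
            nm.mobility_ratio(on, off)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(scale=st.floats(0.1, 10.0), shift=st.floats(-100.0, 100.0))
def test_msd_translation_invariance_property(scale, shift):
    """Pooled MSD depends only on displacements, not absolute positions."""
    rng = np.random.default_rng(12)
    pos = np.cumsum(rng.normal(0, 0.1, (12, 2)), axis=0) * scale
    rows = [(0, f, pos[f, 0], pos[f, 1], 1.0) for f in range(12)]
    base = nm.compute_msd(_ts(rows), 4).msd
    rows2 = [(0, f, pos[f, 0] + shift, pos[f, 1] - shift, 1.0)
             for f in range(12)]
    moved = nm.compute_msd(_ts(rows2), 4).msd
    np.testing.assert_allclose(base, moved, rtol=1e-7, atol=1e-12)
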