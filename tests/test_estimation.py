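import numpy as np
import pandas as pd
import pytest

from phasedfba.estimation import (DataSet, FitContext, bootstrap_ensemble,
                                  ensemble_predict, fit,
                                  generate_synthetic_dataset,
                                  leave_out_fractions, nll, resample_dataset)


@pytest.fixture(scope="module")
def fast_ctx(short_study):
    st = short_study
    return FitContext(st.network, st.params, ["vmaxG"], st.init,
                      st.schedule.t0, st.schedule.tF,
                      sim_options={"rtol": 1e-4, "atol": 1e-7})


@pytest.fixture(scope="module")
def clean_data(short_study, fast_ctx):
    """Noise-free dataset produced by the same simulation settings the
    fit context uses, so residuals at truth are exactly zero."""
    st = short_study
    times = np.linspace(1.0, st.schedule.tF, 8)
    traj = fast_ctx.simulate(st.params)
    rows = []
    for obs in ("Glx", "P_etoh", "X_A"):
        y = fast_ctx.predict(traj, obs, times)
        rows.append(pd.DataFrame({
            "experiment": "e1", "observable": obs, "time_h": times,
            "replicate": 1, "value": y, "sigma": 1.0}))
    return DataSet(pd.concat(rows, ignore_index=True))


class TestDataSet:
    def test_zero_sigma_rejected(self):
        df = pd.DataFrame({"experiment": ["e"], "observable": ["Glx"],
                           "time_h": [1.0], "replicate": [1],
                           "value": [1.0], "sigma": [0.0]})
        with pytest.raises(ValueError, match="sigma"):
            DataSet(df)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing columns"):
            DataSet(pd.DataFrame({"value": [1.0]}))

    def test_csv_round_trip(self, clean_data, tmp_path):
        path = tmp_path / "data.csv"
        clean_data.to_csv(path)
        back = DataSet.from_csv(path)
        pd.testing.assert_frame_equal(back.records, clean_data.records)


class TestNll:
    def test_zero_at_truth(self, short_study, fast_ctx, clean_data):
        theta = fast_ctx.theta_from_params(short_study.params)
        assert nll(theta, clean_data, fast_ctx) == pytest.approx(0.0,
                                                                 abs=1e-16)

    def test_single_two_sigma_residual_scores_four(self, fast_ctx,
                                                   clean_data, short_study):
        rec = clean_data.records.copy().iloc[:1]
        rec["value"] += 2.0 * rec["sigma"]
        theta = fast_ctx.theta_from_params(short_study.params)
        assert nll(theta, DataSet(rec), fast_ctx) == pytest.approx(4.0)

    def test_residuals_add_in_quadrature(self, fast_ctx, clean_data,
                                         short_study):
        rec = clean_data.records.copy().iloc[:2].reset_index(drop=True)
        rec.loc[0, "value"] += 1.0 * rec.loc[0, "sigma"]
        rec.loc[1, "value"] += 3.0 * rec.loc[1, "sigma"]
        theta = fast_ctx.theta_from_params(short_study.params)
        assert nll(theta, DataSet(rec), fast_ctx) == pytest.approx(10.0)

    def test_units_invariance_via_observation_scaling(self, short_study,
                                                      fast_ctx):
        """Fitting X_V directly or as CFU (scaled by c_CFU, with sigma
        scaled identically) gives the same objective."""
        st = short_study
        times = np.linspace(1.0, st.schedule.tF, 6)
        traj = fast_ctx.simulate(st.params)
        xv = fast_ctx.predict(traj, "X_V", times) + 0.01
        c = st.params.c_CFU
        base = pd.DataFrame({
            "experiment": "e1", "observable": "X_V", "time_h": times,
            "replicate": 1, "value": xv, "sigma": 0.05})
        scaled = base.assign(observable="CFU", value=xv * c,
                             sigma=0.05 * c)
        theta = fast_ctx.theta_from_params(st.params)
        a = nll(theta, DataSet(base), fast_ctx)
        b = nll(theta, DataSet(scaled), fast_ctx)
        assert a == pytest.approx(b, rel=1e-9)
        assert a > 0

    def test_failed_simulation_penalized(self, fast_ctx, clean_data):
        # vmaxG far outside any simulable regime still returns a finite
        # ranked penalty rather than raising
        bad = nll(np.array([np.nan]), clean_data, fast_ctx)
        assert bad >= 1e10


class TestFit:
    def test_one_dimensional_fit_matches_grid_scan(self, short_study,
                                                   fast_ctx, clean_data):
        bounds = {"vmaxG": (1.0, 4.0)}
        res = fit(clean_data, bounds, seed=3, ctx=fast_ctx, maxiter=8,
                  popsize=5)
        grid = np.linspace(1.0, 4.0, 41)
        grid_obj = [nll(np.array([g]), clean_data, fast_ctx) for g in grid]
        g_star = grid[int(np.argmin(grid_obj))]
        assert res.theta[0] == pytest.approx(g_star, abs=0.1)
        assert res.theta[0] == pytest.approx(short_study.params.vmaxG,
                                             rel=0.05)

    def test_same_seed_identical_result(self, fast_ctx, clean_data):
        bounds = {"vmaxG": (1.0, 4.0)}
        a = fit(clean_data, bounds, seed=7, ctx=fast_ctx, maxiter=2,
                popsize=3, polish=False)
        b = fit(clean_data, bounds, seed=7, ctx=fast_ctx, maxiter=2,
                popsize=3, polish=False)
        assert a.theta == pytest.approx(b.theta, abs=0.0)
        assert a.objective == b.objective

    def test_unbounded_parameter_rejected(self, fast_ctx, clean_data):
        with pytest.raises(ValueError, match="bounds"):
            fit(clean_data, {"vmaxG": (0.0, np.inf)}, 1, fast_ctx)

    def test_empty_dataset_rejected(self, fast_ctx, clean_data):
        empty = DataSet(clean_data.records.iloc[:0])
        with pytest.raises(ValueError, match="empty"):
            fit(empty, {"vmaxG": (1.0, 4.0)}, 1, fast_ctx)


class TestLogScale:
    def test_round_trip(self, short_study):
        st = short_study
        ctx = FitContext(st.network, st.params, ["lam", "A"], st.init,
                         log_params=("lam",))
        theta = ctx.theta_from_params(st.params)
        assert theta[0] == pytest.approx(np.log10(st.params.lam))
        p = ctx.make_params(theta)
        assert p.lam == pytest.approx(st.params.lam)
        assert ctx.natural_theta(theta)[0] == pytest.approx(st.params.lam)


class TestSyntheticData:
    def test_record_count(self, short_study):
        st = short_study
        data = generate_synthetic_dataset(
            st.params, st.network, st.schedule, noise_cv=0.05,
            n_replicates=3, seed=5, init=st.init,
            observables=("Glx", "X_A"), sample_times=np.linspace(1, 19, 7))
        assert len(data) == 7 * 2 * 3

    def test_zero_noise_replicates_identical(self, short_study):
        st = short_study
        data = generate_synthetic_dataset(
            st.params, st.network, st.schedule, noise_cv=0.0,
            n_replicates=2, seed=5, init=st.init, observables=("Glx",),
            sample_times=np.linspace(1, 19, 5))
        wide = data.records.pivot_table(index="time_h", columns="replicate",
                                        values="value")
        np.testing.assert_array_equal(wide[1], wide[2])

    def test_empirical_cv_matches_request(self, short_study):
        st = short_study
        data = generate_synthetic_dataset(
            st.params, st.network, st.schedule, noise_cv=0.05,
            n_replicates=300, seed=5, init=st.init, observables=("Glx",),
            sample_times=np.array([2.0]))
        values = data.records["value"]
        cv = values.std() / values.mean()
        assert cv == pytest.approx(0.05, rel=0.2)

    def test_sigma_is_cv_times_signal(self, short_study):
        st = short_study
        data = generate_synthetic_dataset(
            st.params, st.network, st.schedule, noise_cv=0.1,
            n_replicates=4, seed=5, init=st.init, observables=("Glx",),
            sample_times=np.array([2.0, 10.0]))
        rec = data.records
        # sigma is recorded per sampling point (identical across
        # replicates) and tracks the noise-free signal at high signal
        per_time = rec.groupby("time_h").agg(sigma=("sigma", "first"),
                                             mean=("value", "mean"))
        assert (rec.groupby("time_h")["sigma"].nunique() == 1).all()
        ratio = per_time["sigma"] / per_time["mean"].abs()
        assert ratio.to_numpy() == pytest.approx([0.1, 0.1], rel=0.3)


class TestBootstrap:
    def test_leave_out_fraction_near_one_over_e(self):
        fracs = leave_out_fractions(100, 1000, seed=0)
        assert 100 * fracs.mean() == pytest.approx(36.8, abs=1.0)

    def test_leave_out_converges_with_size(self):
        small = leave_out_fractions(10, 2000, seed=1).mean()
        large = leave_out_fractions(5000, 50, seed=1).mean()
        assert abs(large - 1 / np.e) < abs(small - 1 / np.e)
        assert large == pytest.approx(1 / np.e, abs=5e-3)

    def test_resample_preserves_size(self, clean_data, rng):
        sample, frac = resample_dataset(clean_data, rng)
        assert len(sample) == len(clean_data)
        assert 0.0 <= frac < 1.0

    def test_same_seed_identical_ensemble(self, fast_ctx, clean_data):
        bounds = {"vmaxG": (1.0, 4.0)}
        kw = dict(maxiter=1, popsize=3, polish=False)
        a = bootstrap_ensemble(clean_data, 2, 11, fast_ctx, bounds, **kw)
        b = bootstrap_ensemble(clean_data, 2, 11, fast_ctx, bounds, **kw)
        np.testing.assert_array_equal(a.Theta, b.Theta)
        assert a.seeds == b.seeds

    def test_no_resampling_single_fit_reduction(self, fast_ctx, clean_data):
        bounds = {"vmaxG": (1.0, 4.0)}
        ens = bootstrap_ensemble(clean_data, 1, 13, fast_ctx, bounds,
                                 resample=False, maxiter=2, popsize=3,
                                 polish=False)
        sub_seed = int(np.random.default_rng(13).integers(0, 2**31 - 1))
        direct = fit(clean_data, bounds, sub_seed, fast_ctx, maxiter=2,
                     popsize=3, polish=False)
        assert len(ens) == 1
        assert ens.Theta[0] == pytest.approx(direct.theta, abs=0.0)


class TestEnsemblePredict:
    def test_identical_members_zero_width_band(self, short_study, fast_ctx):
        from phasedfba.estimation import EnsembleMatrix

        st = short_study
        theta = fast_ctx.theta_from_params(st.params)
        ens = EnsembleMatrix(np.vstack([theta, theta]), np.zeros(2),
                             ["vmaxG"], [1, 2])
        t_grid = np.linspace(1, 19, 5)
        band = ensemble_predict(ens, fast_ctx, ["Glx"], t_grid,
                                quantiles=(0.05, 0.5, 0.95))
        wide = band.pivot_table(index="time", columns="quantile",
                                values="value")
        np.testing.assert_allclose(wide[0.05], wide[0.95])

    def test_single_member_collapses_to_trajectory(self, short_study,
                                                   fast_ctx):
        from phasedfba.estimation import EnsembleMatrix

        st = short_study
        theta = fast_ctx.theta_from_params(st.params)
        ens = EnsembleMatrix(theta[None, :], np.zeros(1), ["vmaxG"], [1])
        t_grid = np.linspace(1, 19, 5)
        band = ensemble_predict(ens, fast_ctx, ["X_A"], t_grid,
                                quantiles=(0.5,))
        traj = fast_ctx.simulate(st.params)
        expected = fast_ctx.predict(traj, "X_A", t_grid)
        np.testing.assert_allclose(band["value"].to_numpy(), expected,
                                   rtol=1e-9)
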