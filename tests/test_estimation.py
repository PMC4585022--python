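import numpy as np
import pandas as pd
import pytest

from lvsynapse import (BinnedSignal, EventTrain, LaguerreVolterraRegressor,
                       TrainingProtocol, TrainingRecord, bin_events,
                       build_basis, build_design_matrix, convolve_basis,
                       enumerate_terms, event_windowed_nrmse, fit_coefficients,
                       frequency_sweep, generate_poisson_rit, nrmse,
                       optimize_decays, predict, train_receptor_model)
from conftest import random_small_model


def make_vx(rng, L=(3, 2), T=400, dt=1e-3, decays=(0.4, 0.05)):
    x = np.zeros(T)
    x[rng.choice(T, size=8, replace=False)] = 1.0
    sig = BinnedSignal(dt=dt, values=x)
    bases = [build_basis(p, n, dt, 0.05) for p, n in zip(decays, L)]
    v = [convolve_basis(b, sig) for b in bases]
    return bases, v, sig


class TestDesignMatrix:
    def test_first_order_columns_are_the_convolutions(self, rng):
        bases, v, _ = make_vx(rng)
        terms = enumerate_terms(1, (3, 2), False)
        V = build_design_matrix(terms, v)
        np.testing.assert_array_equal(V[:, 0], 1.0)
        k = 1
        for n, basis in enumerate(bases):
            for j in range(basis.L):
                np.testing.assert_array_equal(V[:, k], v[n][j])
                k += 1

    def test_zero_input_only_constant_column(self, rng):
        bases = [build_basis(0.4, 2, 1e-3, 0.05)]
        sig = BinnedSignal(dt=1e-3, values=np.zeros(100))
        v = [convolve_basis(bases[0], sig)]
        V = build_design_matrix(enumerate_terms(2, (2,), False), v)
        np.testing.assert_array_equal(V[:, 0], 1.0)
        assert np.all(V[:, 1:] == 0.0)

    def test_product_column_matches_elementwise_multiplication(self, rng):
        _, v, _ = make_vx(rng)
        terms = enumerate_terms(2, (3, 2), True)
        V = build_design_matrix(terms, v)
        for i, term in enumerate(terms):
            if len(term) == 2:
                (n1, j1), (n2, j2) = term
                np.testing.assert_allclose(V[:, 1 + i], v[n1][j1] * v[n2][j2])

    def test_missing_series_rejected(self, rng):
        _, v, _ = make_vx(rng)
        with pytest.raises(ValueError):
            build_design_matrix([((0, 0),), ((5, 1),)], v)


class TestFitCoefficients:
    def test_exact_recovery_of_planted_coefficients(self, rng):
        _, v, _ = make_vx(rng)
        terms = enumerate_terms(3, (3, 2), False)
        V = build_design_matrix(terms, v)
        c_true = rng.normal(size=V.shape[1])
        y = V @ c_true
        c = fit_coefficients(V, y)
        np.testing.assert_allclose(c, c_true, rtol=1e-8)

    def test_constant_target_zero_input(self):
        V = np.zeros((50, 4))
        V[:, 0] = 1.0
        c = fit_coefficients(V, np.full(50, 3.25))
        assert c[0] == pytest.approx(3.25)
        np.testing.assert_allclose(c[1:], 0.0, atol=1e-12)

    def test_duplicated_column_minimum_norm_split(self, rng):
        base = rng.normal(size=(60, 2))
        V = np.column_stack([np.ones(60), base[:, 0], base[:, 0], base[:, 1]])
        y = 2.0 * base[:, 0] + base[:, 1]
        c = fit_coefficients(V, y)
        assert np.isfinite(c).all()
        assert c[1] == pytest.approx(c[2], rel=1e-9)
        assert c[1] + c[2] == pytest.approx(2.0, rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fit_coefficients(np.zeros((0, 3)), np.zeros(0))


class TestNRMSE:
    def test_perfect_prediction_zero(self, rng):
        y = rng.normal(size=100)
        assert nrmse(y, y) == 0.0

    def test_zero_prediction_is_one(self, rng):
        y = rng.normal(size=100)
        assert nrmse(y, np.zeros(100)) == pytest.approx(1.0)

    def test_doubled_prediction_is_one(self, rng):
        y = rng.normal(size=100)
        assert nrmse(y, 2 * y) == pytest.approx(1.0)

    def test_scale_equivariance_in_error(self, rng):
        y = rng.normal(size=200)
        e = rng.normal(size=200)
        assert nrmse(y, y + 2 * e) == pytest.approx(2 * nrmse(y, y + e))

    def test_all_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            nrmse(np.zeros(5), np.ones(5))


class TestEventWindowedNRMSE:
    def test_identical_signals_all_zero(self):
        y = BinnedSignal(dt=0.01, values=np.random.default_rng(0).random(500))
        events = EventTrain(times=np.array([0.5, 2.0, 4.0]), duration=5.0)
        table = event_windowed_nrmse(y, y, events, window=1.0)
        assert len(table) == 3
        assert np.all(table["nrmse"] == 0.0)

    def test_error_localized_to_one_event(self):
        vals = np.zeros(500)
        vals[[60, 210, 410]] = 1.0
        y = BinnedSignal(dt=0.01, values=vals)
        yh_vals = vals.copy()
        yh_vals[215] = 0.7  # corrupt only the second event's segment
        yh = BinnedSignal(dt=0.01, values=yh_vals)
        events = EventTrain(times=np.array([0.6, 2.1, 4.1]), duration=5.0)
        table = event_windowed_nrmse(y, yh, events, window=1.0)
        nz = table[table["nrmse"] > 0]
        assert list(nz.index) == [1]

    def test_close_events_merged_against_manual_segmentation(self):
        y = BinnedSignal(dt=0.01, values=np.ones(600))
        yh = BinnedSignal(dt=0.01, values=np.ones(600) * 1.1)
        events = EventTrain(times=np.array([1.0, 1.3, 4.0]), duration=6.0)
        table = event_windowed_nrmse(y, yh, events, window=1.0)
        assert len(table) == 2
        assert table.loc[0, "events"] == "1-2"
        # manual segmentation: cluster segment [1.0, 2.3), single [4.0, 5.0)
        assert table.loc[0, "t_start"] == pytest.approx(1.0)
        assert table.loc[0, "t_end"] == pytest.approx(2.3)
        assert table.loc[1, "t_start"] == pytest.approx(4.0)

    def test_no_events_empty_table(self):
        y = BinnedSignal(dt=0.01, values=np.ones(10))
        events = EventTrain(times=np.array([]), duration=0.1)
        assert len(event_windowed_nrmse(y, y, events, window=1.0)) == 0


class TestFrequencySweep:
    def test_self_oracle_gives_zero_everywhere(self, rng):
        model = random_small_model(rng, order=2, cross_terms=False)
        table = frequency_sweep(model, model, rates=[1.0, 4.0, 10.0],
                                duration=5.0, seed=3)
        np.testing.assert_allclose(table["nrmse"], 0.0, atol=1e-12)
        assert list(table["rate_hz"]) == [1.0, 4.0, 10.0]

    def test_seeded_and_deterministic(self, rng):
        model = random_small_model(rng, order=2, cross_terms=False)
        ref = random_small_model(np.random.default_rng(77), order=2,
                                 cross_terms=False)
        a = frequency_sweep(model, ref, rates=[2.0, 6.0], duration=5.0, seed=9)
        b = frequency_sweep(model, ref, rates=[2.0, 6.0], duration=5.0, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_nonpositive_rate_rejected(self, rng):
        model = random_small_model(rng, order=1, cross_terms=False)
        with pytest.raises(ValueError):
            frequency_sweep(model, model, rates=[0.0], duration=1.0, seed=0)


class TestRegressor:
    def test_sklearn_params_round_trip(self):
        est = LaguerreVolterraRegressor(order=2, decays=(0.3, 0.02))
        params = est.get_params()
        est2 = LaguerreVolterraRegressor(**params)
        assert est2.get_params() == params
        est.set_params(order=3)
        assert est.order == 3

    def test_recovers_model_in_class(self, rng):
        # target generated by a Volterra model inside the fitted class:
        # coefficients recovered to high relative accuracy
        truth = random_small_model(rng, order=2, cross_terms=False,
                                   L=(3, 2), dt=1e-3, window=0.05,
                                   decays=(0.4, 0.05))
        train = generate_poisson_rit(20.0, 150, seed=5)
        n = int(np.floor(train.duration / 1e-3)) + 1
        x = bin_events(train, 1e-3, n_bins=n)
        y = predict(truth, x)
        est = LaguerreVolterraRegressor(order=2, n_functions=(3, 2),
                                        decays=(0.4, 0.05), dt=1e-3,
                                        memory_window=0.05)
        est.fit(x.values, y.values)
        assert est.c0_ == pytest.approx(truth.c0, abs=1e-8)
        np.testing.assert_allclose(est.coef_, truth.coefficients, rtol=1e-6,
                                   atol=1e-9)
        val = np.zeros(300)
        val[[10, 50, 90]] = 1.0
        assert nrmse(predict(truth, BinnedSignal(dt=1e-3, values=val)).values,
                     est.predict(val)) < 1e-6

    def test_nested_models_never_increase_training_residual(self, rng):
        oracle = random_small_model(rng, order=3, cross_terms=False,
                                    L=(3, 2), dt=1e-3)
        train = generate_poisson_rit(15.0, 120, seed=8)
        n = int(np.floor(train.duration / 1e-3)) + 1
        x = bin_events(train, 1e-3, n_bins=n)
        y = predict(oracle, x).values
        res = []
        for Q in (1, 2, 3):
            est = LaguerreVolterraRegressor(order=Q, n_functions=(3, 2),
                                            decays=(0.4, 0.05), dt=1e-3,
                                            memory_window=0.05)
            est.fit(x.values, y)
            res.append(np.sum((y - est.predict(x.values)) ** 2))
        assert res[1] <= res[0] + 1e-12
        assert res[2] <= res[1] + 1e-12

    def test_input_validation(self):
        est = LaguerreVolterraRegressor()
        with pytest.raises(ValueError):
            est.fit(np.zeros((10, 2)), np.zeros(10))
        with pytest.raises(ValueError):
            est.fit(np.zeros(10), np.zeros(12))
        with pytest.raises(AttributeError):
            LaguerreVolterraRegressor().predict(np.zeros(5))


class TestOptimizeDecays:
    def test_recovers_planted_decays_first_order(self, rng):
        # synthetic first-order data with known decay constants
        dt = 1e-3
        truth = random_small_model(rng, order=1, cross_terms=False,
                                   L=(3, 3), dt=dt, window=0.2,
                                   decays=(0.5, 0.03))
        truth.c0 = 0.0
        train = generate_poisson_rit(10.0, 200, seed=21)
        n = int(np.floor(train.duration / dt)) + 1
        x = bin_events(train, dt, n_bins=n)
        y = predict(truth, x)
        record = TrainingRecord(inputs=train, target=y, dt=dt)
        result = optimize_decays(record, n_functions=(3, 3), order=1,
                                 cross_terms=False,
                                 decay_bounds=((0.1, 2.0), (0.005, 0.09)),
                                 decay_grid=6, decay_tol=0.02,
                                 memory_window=0.2)
        # within one refinement step of the planted values (log scale)
        assert abs(np.log(result.decays[0] / 0.5)) < 0.15
        assert abs(np.log(result.decays[1] / 0.03)) < 0.15
        # residual fit error at the recovered decays stays small
        assert result.validation_nrmse < 0.01

    def test_objective_at_optimum_not_worse_than_bounds(self, rng):
        dt = 1e-3
        truth = random_small_model(rng, order=1, cross_terms=False,
                                   L=(2, 2), dt=dt, window=0.1,
                                   decays=(0.4, 0.04))
        train = generate_poisson_rit(10.0, 80, seed=4)
        n = int(np.floor(train.duration / dt)) + 1
        x = bin_events(train, dt, n_bins=n)
        y = predict(truth, x)
        record = TrainingRecord(inputs=train, target=y, dt=dt)

        def fit_err(decays):
            est = LaguerreVolterraRegressor(order=1, n_functions=(2, 2),
                                            decays=decays, dt=dt,
                                            memory_window=0.1)
            est.fit(bin_events(train, dt, n_bins=n).values, y.values)
            return est.train_abs_error_

        result = optimize_decays(record, n_functions=(2, 2), order=1,
                                 cross_terms=False,
                                 decay_bounds=((0.1, 1.0), (0.01, 0.08)),
                                 decay_grid=4, decay_tol=0.05,
                                 memory_window=0.1)
        assert result.train_abs_error <= fit_err((1.0, 0.08)) + 1e-9
        assert result.train_abs_error <= fit_err((0.1, 0.01)) + 1e-9

    def test_deterministic_given_spec(self, rng):
        dt = 1e-3
        truth = random_small_model(rng, order=1, cross_terms=False,
                                   L=(2, 2), dt=dt, window=0.1)
        train = generate_poisson_rit(10.0, 60, seed=2)
        n = int(np.floor(train.duration / dt)) + 1
        y = predict(truth, bin_events(train, dt, n_bins=n))
        record = TrainingRecord(inputs=train, target=y, dt=dt)
        kwargs = dict(n_functions=(2, 2), order=1, cross_terms=False,
                      decay_bounds=((0.1, 1.0), (0.01, 0.08)),
                      decay_grid=3, decay_tol=0.05, memory_window=0.1)
        a = optimize_decays(record, **kwargs)
        b = optimize_decays(record, **kwargs)
        assert a.decays == b.decays
        np.testing.assert_array_equal(a.model.coefficients,
                                      b.model.coefficients)

    def test_invalid_bounds_rejected(self, rng):
        dt = 1e-3
        train = generate_poisson_rit(10.0, 20, seed=2)
        n = int(np.floor(train.duration / dt)) + 1
        y = BinnedSignal(dt=dt, values=np.ones(n))
        record = TrainingRecord(inputs=train, target=y, dt=dt)
        with pytest.raises(ValueError):
            optimize_decays(record, n_functions=(2, 2), order=1,
                            cross_terms=False,
                            decay_bounds=((0.01, 0.05), (0.1, 1.0)))


class TestTrainReceptorModel:
    def test_oracle_in_model_class_gives_tiny_error(self, rng):
        # the oracle is itself a first-order Volterra model
        oracle = random_small_model(rng, order=1, cross_terms=False,
                                    L=(3, 2), dt=1e-3, window=0.05,
                                    decays=(0.4, 0.05))
        oracle.c0 = 0.0
        protocol = TrainingProtocol(
            rates=(10.0,), n_events=150, dt=1e-3, order=1,
            n_functions=(3, 2), cross_terms=False, seed=12,
            memory_window=0.05, decays=(0.4, 0.05), optimize_decays=False,
            validation_rate=10.0, validation_duration=5.0)
        result = train_receptor_model(oracle, protocol)
        assert result.validation_nrmse < 1e-6

    def test_protocol_rerun_bit_identical(self, tmp_path, rng):
        from lvsynapse import save_model
        oracle = random_small_model(rng, order=2, cross_terms=False,
                                    L=(2, 2), dt=1e-3, window=0.05)
        protocol = TrainingProtocol(
            rates=(10.0,), n_events=80, dt=1e-3, order=2,
            n_functions=(2, 2), cross_terms=False, seed=5,
            memory_window=0.05, decays=(0.4, 0.05),
            optimize_decays=True, decay_bounds=((0.2, 0.8), (0.02, 0.1)),
            decay_grid=3, decay_search_events=40,
            validation_rate=10.0, validation_duration=3.0)
        r1 = train_receptor_model(oracle, protocol)
        r2 = train_receptor_model(oracle, protocol)
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        save_model(r1.model, p1, provenance={"protocol": r1.protocol})
        save_model(r2.model, p2, provenance={"protocol": r2.protocol})
        assert p1.read_bytes() == p2.read_bytes()
        assert r1.validation_nrmse == r2.validation_nrmse
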