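"""Connectivity, short-term plasticity and the recurrent engine."""

import numpy as np
import pytest
from scipy.stats import binom

from surroneuron.network import (
    ConnectivityMatrix,
    IzhikevichBackend,
    NetworkConfig,
    ScriptedBackend,
    TMParams,
    TMState,
    build_connectivity,
    run_network,
    tm_update,
)


class TestConnectivity:
    def test_zero_probability_gives_empty_matrix(self):
        conn = build_connectivity(50, 0.0, seed=1)
        assert conn.x.sum() == 0

    def test_zero_diagonal(self):
        conn = build_connectivity(80, 0.3, seed=2)
        assert np.all(np.diag(conn.x) == 0)

    def test_realized_frequencies_within_binomial_ci(self):
        n, p_uni = 150, 0.10
        conn = build_connectivity(n, p_uni, seed=3)
        f_uni, f_bi = conn.pair_frequencies()
        n_pairs = n * (n - 1) // 2
        lo_u, hi_u = binom.ppf([0.005, 0.995], n_pairs, p_uni) / n_pairs
        lo_b, hi_b = binom.ppf([0.005, 0.995], n_pairs, 0.5 * p_uni) / n_pairs
        assert lo_u <= f_uni <= hi_u
        assert lo_b <= f_bi <= hi_b

    def test_reciprocal_pairs_have_both_edges_and_boost(self):
        conn = build_connectivity(60, 0.2, seed=4)
        both = (conn.x == 1) & (conn.x.T == 1)
        assert both.any()
        assert np.all(conn.multiplier[both] == 1.5)
        one_way = (conn.x == 1) & (conn.x.T == 0)
        assert np.all(conn.multiplier[one_way] == 1.0)


def tm_closed_form_steady_state(params: TMParams, period_ms: float):
    """Independent closed-form steady state under periodic firing."""
    eF = np.exp(-period_ms / params.F_ms)
    eD = np.exp(-period_ms / params.D_ms)
    u_post = params.U / (1.0 - (1.0 - params.U) * eF)
    r_pre = (1.0 - eD) / (1.0 - (1.0 - u_post) * eD)
    return u_post * r_pre


class TestTsodyksMarkram:
    def test_long_silence_returns_to_rest(self):
        state = TMState(u=np.array([0.7]), R=np.array([0.2]))
        tm_update(state, 5000.0, [False])
        assert state.u[0] == pytest.approx(0.0, abs=1e-40)
        assert state.R[0] == pytest.approx(1.0, abs=1e-6)

    def test_first_spike_from_rest_releases_exactly_U(self):
        state = TMState.rested(1)
        release = tm_update(state, 1.0, [True])
        assert release[0] == 0.38

    def test_periodic_train_converges_to_closed_form(self):
        params = TMParams()
        period = 50.0  # 20 Hz: relax one period, then spike, repeatedly
        state = TMState.rested(1)
        release = None
        for _ in range(400):
            release = tm_update(state, period, [True], params)
        expected = tm_closed_form_steady_state(params, period)
        assert release[0] == pytest.approx(expected, abs=1e-6)

    def test_bounds_invariant_under_random_trains(self):
        rng = np.random.default_rng(0)
        params = TMParams()
        state = TMState.rested(4)
        for _ in range(500):
            release = tm_update(state, float(rng.uniform(0.5, 30.0)),
                                rng.random(4) < 0.3, params)
            assert np.all((state.u >= 0) & (state.u <= 1))
            assert np.all((state.R >= 0) & (state.R <= 1))
            assert np.all((release >= 0) & (release <= 1))

    def test_invalid_constants_rejected(self):
        with pytest.raises(ValueError):
            TMParams(U=0.0)
        with pytest.raises(ValueError):
            TMParams(D_ms=-1.0)


def two_cell_setup(duration=20, spike_at=5):
    raster = np.zeros((2, duration), dtype=bool)
    raster[0, spike_at] = True
    backend = ScriptedBackend(raster)
    x = np.array([[0, 1], [0, 0]], dtype=np.int8)
    mult = np.array([[0.0, 1.0], [0.0, 0.0]])
    conn = ConnectivityMatrix(x=x, multiplier=mult, p_uni=0.0, p_bi=0.0)
    config = NetworkConfig(
        n_cells=2, duration_ms=float(duration), stimulus_time_ms=15.0,
        stimulus_nS=0.0, background_rate_hz=0.0, seed=0,
    )
    return backend, conn, config


class TestEngine:
    def test_two_cell_propagation_contract(self):
        """A's spike at t arrives on B's excitatory channel at t+1 ms with
        conductance g_conn * contacts * release."""
        backend, conn, config = two_cell_setup()
        run_network(config, backend, connectivity=conn)
        received = np.stack(backend.received_exc)  # (T, n_cells)
        expected = config.g_conn_nS * config.n_contacts * 0.38
        assert received[6, 1] == pytest.approx(expected)
        assert np.sum(received) == pytest.approx(expected)

    def test_delivery_conservation_audit(self):
        backend, conn, config = two_cell_setup()
        result = run_network(config, backend, connectivity=conn)
        assert result.delivered_total_nS == pytest.approx(result.expected_delivered_nS)
        assert result.delivered_total_nS > 0

    def test_reciprocal_multiplier_scales_delivery(self):
        raster = np.zeros((2, 20), dtype=bool)
        raster[0, 5] = True
        backend = ScriptedBackend(raster)
        x = np.ones((2, 2), dtype=np.int8) - np.eye(2, dtype=np.int8)
        conn = ConnectivityMatrix(x=x, multiplier=1.5 * (x > 0), p_uni=0.0, p_bi=0.0)
        config = NetworkConfig(n_cells=2, duration_ms=20.0, stimulus_time_ms=15.0,
                               stimulus_nS=0.0, background_rate_hz=0.0, seed=0)
        run_network(config, backend, connectivity=conn)
        received = np.stack(backend.received_exc)
        assert received[6, 1] == pytest.approx(1.5 * config.g_conn_nS * 5 * 0.38)

    def test_backend_identity_gives_identical_rasters(self):
        """Two backends producing identical per-step outputs yield identical
        engine rasters."""
        raster = np.zeros((3, 30), dtype=bool)
        raster[0, 4] = raster[1, 10] = raster[2, 20] = True
        conn = build_connectivity(3, 0.5, seed=7)
        config = NetworkConfig(n_cells=3, duration_ms=30.0, stimulus_time_ms=25.0,
                               background_rate_hz=0.0, seed=1)
        results = [
            run_network(config, ScriptedBackend(raster.copy()), connectivity=conn)
            for _ in range(2)
        ]
        assert results[0].raster == results[1].raster

    def test_disconnected_network_equals_independent_cells(self):
        """With zero connectivity and shared background, the population
        raster equals the union of single-cell runs."""
        n_steps = 150
        rng = np.random.default_rng(5)
        bg_exc = (rng.random((3, n_steps)) < 0.2) * 20.0
        bg_inh = np.zeros((3, n_steps))
        conn = build_connectivity(3, 0.0, seed=0)
        config = NetworkConfig(n_cells=3, duration_ms=float(n_steps),
                               stimulus_time_ms=140.0, stimulus_nS=0.0,
                               background_rate_hz=0.0, seed=2)
        full = run_network(config, IzhikevichBackend(3), connectivity=conn,
                           background=(bg_exc, bg_inh))
        merged = []
        for c in range(3):
            cfg1 = NetworkConfig(n_cells=1, duration_ms=float(n_steps),
                                 stimulus_time_ms=140.0, stimulus_nS=0.0,
                                 background_rate_hz=0.0, seed=2)
            single = run_network(cfg1, IzhikevichBackend(1),
                                 connectivity=build_connectivity(1, 0.0, seed=0),
                                 background=(bg_exc[c : c + 1], bg_inh[c : c + 1]))
            merged += [(c, t) for _, t in single.raster]
        assert sorted(full.raster) == sorted(merged)

    def test_stimulus_recruits_population(self):
        config = NetworkConfig(n_cells=20, duration_ms=150.0, background_rate_hz=0.0,
                               seed=3)
        result = run_network(config, IzhikevichBackend(20))
        assert result.immediate_response() == 20
        assert result.pre_stimulus_count() == 0

    def test_config_validation(self):
        with pytest.raises(ValueError):
            NetworkConfig(delay_ms=0)
        with pytest.raises(ValueError):
            NetworkConfig(duration_ms=50.0, stimulus_time_ms=100.0)
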