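"""Directed connectivity: DEKF tracking, PDC spectra, surrogates, TRT, graphs."""

import math

import numpy as np
import pytest

from dynconn.core import MU_BAND, BandDefinition, MultichannelSeries
from dynconn.synth import (
    DENSE_LONGRANGE,
    MVARSpec,
    make_group_network,
    simulate_mvar,
)
from dynconn.tpdc import (
    DEKF,
    ConnectivityGraph,
    bootstrap_threshold,
    build_graph,
    edge_strengths,
    fit_mvar_ls,
    group_mean_directional_coherence,
    pdc_spectrum,
    recover_network,
    time_reversal_test,
    tpdc_compute,
)

WIDE = BandDefinition("wide", 2.0, 40.0)


def _mild_trivariate():
    A = np.zeros((2, 3, 3))
    A[0] = [[0.5, 0, 0], [0.4, 0.5, 0], [0, 0.3, 0.5]]
    A[1] = [[-0.3, 0, 0], [0, -0.2, 0], [0.2, 0, -0.25]]
    return MVARSpec(A, np.eye(3))


class TestPDCSpectrum:
    def test_diagonal_model_has_no_cross_influence(self):
        A = np.zeros((2, 3, 3))
        for i in range(3):
            A[0, i, i], A[1, i, i] = 0.5, -0.2
        pdc = pdc_spectrum(A, np.linspace(0, 0.5, 8), rate=1.0)
        off = ~np.eye(3, dtype=bool)
        assert np.allclose(pdc[off], 0.0)
        assert np.allclose(pdc[np.eye(3, dtype=bool)], 1.0)

    def test_bivariate_closed_form_at_zero_frequency(self):
        # AR(1): a11=a22=0.5, a21=0.5 -> Abar(0) = [[0.5, 0], [-0.5, 0.5]]
        # pi_21(0) = 0.5 / sqrt(0.25 + 0.25) = 1/sqrt(2)
        A = np.zeros((1, 2, 2))
        A[0] = [[0.5, 0.0], [0.5, 0.5]]
        pdc = pdc_spectrum(A, np.array([0.0]), rate=1.0)
        assert pdc[1, 0, 0] == pytest.approx(1 / math.sqrt(2), abs=1e-12)

    def test_column_normalization_identity_random_models(self):
        """sum_i pi_ij^2 == 1 for every (j, f) on random stable models."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            m, p = int(rng.integers(2, 5)), int(rng.integers(1, 4))
            A = rng.standard_normal((p, m, m)) * 0.3 / (p * m)
            pdc = pdc_spectrum(A, rng.uniform(0, 250, 11), rate=500.0)
            colsum = (pdc**2).sum(axis=0)
            assert np.abs(colsum - 1.0).max() < 1e-12


class TestDEKF:
    def test_recovers_stationary_coefficients(self):
        spec = _mild_trivariate()
        s = simulate_mvar(spec, 10000, seed=11)
        res = DEKF(s, order=2).fit()
        est = res.time_averaged_coeffs
        ls, _ = fit_mvar_ls(s.data, 2)
        assert np.sqrt(np.mean((est - spec.coeffs) ** 2)) < 0.05
        assert np.sqrt(np.mean((est - ls) ** 2)) < 0.05

    def test_white_noise_estimates_near_zero(self, white_series):
        res = DEKF(white_series, order=2).fit()
        assert np.abs(res.time_averaged_coeffs).max() < 0.05

    def test_tracks_step_change_within_500_samples(self):
        T = 10000
        traj = np.zeros((T, 1, 2, 2))
        traj[:, 0, 0, 0] = 0.5
        traj[:, 0, 1, 1] = 0.5
        traj[T // 2 :, 0, 1, 0] = 0.5
        spec = MVARSpec(traj, np.eye(2))
        s = simulate_mvar(spec, T, seed=7)
        res = DEKF(s, order=1).fit()
        c = res.coeff_trajectory[:, 0, 1, 0]
        after = c[T // 2 - res.warmup :]
        crossing = np.flatnonzero(after >= 0.25)
        assert crossing.size and crossing[0] <= 500

    def test_divergence_reported(self):
        # non-finite input is rejected before filtering
        bad = MultichannelSeries(np.full((2, 2000), np.nan), 500.0)
        with pytest.raises(ValueError, match="non-finite"):
            DEKF(bad, order=2)

    def test_short_series_rejected(self, rng):
        s = MultichannelSeries(rng.standard_normal((4, 100)), 500.0)
        with pytest.raises(ValueError, match="too short"):
            DEKF(s, order=5)

    def test_band_mean_tpdc_agrees_with_ls_oracle(self):
        """On stationary data the dual-Kalman and static least-squares
        routes rank edges the same way (dual-route agreement)."""
        spec = _mild_trivariate()
        s = simulate_mvar(spec, 10000, seed=13)
        Sd = edge_strengths(s, 2, WIDE, estimator="dekf")
        Sl = edge_strengths(s, 2, WIDE, estimator="ls")
        off = ~np.eye(3, dtype=bool)
        r = np.corrcoef(Sd[off], Sl[off])[0, 1]
        assert r > 0.9


class TestTPDCTensor:
    def test_stationary_input_low_time_variation(self):
        spec = _mild_trivariate()
        s = simulate_mvar(spec, 8000, seed=3)
        res = DEKF(s, order=2).fit()
        tensor = res.tpdc(band=WIDE, stride=10)
        # coefficient of variation of a true edge over time
        tv = tensor.values[1, 0].mean(axis=0)  # band-mean over time
        assert tv.std() / tv.mean() < 0.2

    def test_step_change_alters_band_mean(self):
        T = 12000
        traj = np.zeros((T, 1, 2, 2))
        traj[:, 0, 0, 0] = 0.5
        traj[:, 0, 1, 1] = 0.5
        traj[T // 2 :, 0, 1, 0] = 0.5
        s = simulate_mvar(MVARSpec(traj, np.eye(2)), T, seed=5)
        res = DEKF(s, order=1, q_param=1e-4).fit()
        tensor = res.tpdc(band=WIDE, stride=5)
        half = tensor.values.shape[-1] // 2
        first = tensor.values[1, 0, :, :half].mean()
        second = tensor.values[1, 0, :, half:].mean()
        assert second > first + 0.1

    def test_column_normalization_holds_everywhere(self):
        spec = _mild_trivariate()
        s = simulate_mvar(spec, 6000, seed=8)
        tensor = DEKF(s, order=2).fit().tpdc(band=WIDE, stride=20)
        assert tensor.column_norm_deviation() < 1e-6

    def test_memory_guard(self):
        A = np.zeros((1000, 1, 4, 4))
        with pytest.raises(MemoryError, match="decimate|stride"):
            tpdc_compute(A, np.linspace(1, 40, 50), 500.0, max_elements=1e4)


class TestBootstrapThreshold:
    def test_strong_edge_exceeds_threshold(self):
        """A strong lagged edge is detected in >= 90% of seeded runs."""
        hits = 0
        for k in range(20):
            A = np.zeros((1, 2, 2))
            A[0] = [[0.5, 0.0], [0.6, 0.5]]
            s = simulate_mvar(MVARSpec(A, np.eye(2)), 4000, seed=200 + k)
            S = edge_strengths(s, 1, WIDE, estimator="ls")
            thr = bootstrap_threshold(
                s, 1, WIDE, n_boot=100, seed=300 + k, estimator="ls"
            )
            hits += S[1, 0] > thr[1, 0]
        assert hits >= 18

    def test_n_boot_default_is_100(self):
        import inspect

        assert inspect.signature(bootstrap_threshold).parameters[
            "n_boot"
        ].default == 100

    def test_window_longer_than_series_rejected(self, white_series):
        with pytest.raises(ValueError, match="window"):
            bootstrap_threshold(white_series, 2, MU_BAND, window_len=100.0)

    def test_mean_mode_and_global_scope_run(self, white_series):
        thr = bootstrap_threshold(
            white_series, 1, MU_BAND, n_boot=5, mode="mean", scope="global",
            estimator="ls",
        )
        off = ~np.eye(3, dtype=bool)
        assert np.all(thr[off] == thr[off][0])


class TestTimeReversal:
    def test_lagged_causal_edge_passes(self):
        from tests.conftest import oscillator_spec

        spec = oscillator_spec(10.0, m=2)
        A = np.zeros((5, 2, 2))
        A[:2] = spec.coeffs
        A[4, 1, 0] = 0.35 * abs(
            1 - spec.coeffs[0, 1, 1] * np.exp(-2j * np.pi * 10 / 500)
            - spec.coeffs[1, 1, 1] * np.exp(-4j * np.pi * 10 / 500)
        )
        s = simulate_mvar(MVARSpec(A, spec.innovation_cov), 20000, seed=31)
        flags = time_reversal_test(
            s, [(0, 1)], 3, MU_BAND, estimator="ls", decimate=4
        )
        assert flags[(0, 1)]

    def test_instantaneous_mixing_fails(self):
        from tests.conftest import oscillator_series

        z = oscillator_series(10.0, 20000, seed=32).data[0]
        rng = np.random.default_rng(33)
        x1 = z + 0.35 * rng.standard_normal(z.size)
        x2 = 0.8 * z + 0.35 * rng.standard_normal(z.size)
        s = MultichannelSeries(np.vstack([x1, x2]), 500.0)
        flags = time_reversal_test(
            s, [(0, 1), (1, 0)], 3, MU_BAND, estimator="ls", decimate=4
        )
        assert not flags[(0, 1)] and not flags[(1, 0)]

    def test_empty_candidates_vacuous(self, white_series):
        assert time_reversal_test(white_series, [], 2, MU_BAND) == {}


class TestGraphs:
    def test_edge_length_is_euclidean(self):
        coords = np.array([[0.0, 0, 0], [30.0, 40.0, 0]])
        g = build_graph(
            ["a", "b"], np.full((2, 2), 0.5), np.zeros((2, 2)), MU_BAND,
            coords=coords,
        )
        assert all(e.length_mm == pytest.approx(50.0) for e in g.edges)

    def test_all_below_threshold_no_significant_edges(self):
        g = build_graph(
            ["a", "b"], np.full((2, 2), 0.1), np.full((2, 2), 0.5), MU_BAND,
            coords=np.zeros((2, 3)),
        )
        assert g.significant_edges() == []

    def test_missing_coords_warns_and_omits_lengths(self):
        with pytest.warns(UserWarning, match="coordinates"):
            g = build_graph(
                ["a", "b"], np.full((2, 2), 0.5), np.zeros((2, 2)), MU_BAND
            )
        assert all(e.length_mm is None for e in g.edges)

    def test_mean_directional_coherence(self):
        coords = np.zeros((2, 3))
        g = build_graph(
            ["a", "b"],
            np.array([[0.0, 0.4], [0.0, 0.0]]),
            np.full((2, 2), 0.1),
            MU_BAND,
            coords=coords,
        )
        val, flag = group_mean_directional_coherence(g)
        assert val == pytest.approx(0.4) and flag

    def test_no_significant_edges_flagged(self):
        g = build_graph(
            ["a", "b"], np.zeros((2, 2)), np.full((2, 2), 0.5), MU_BAND,
            coords=np.zeros((2, 3)),
        )
        val, flag = group_mean_directional_coherence(g)
        assert val == 0.0 and not flag


class TestRecovery:
    def test_dense_network_recovered_with_dekf(self):
        """Default dual-Kalman route recovers a dense ground-truth net."""
        spec = make_group_network(DENSE_LONGRANGE, MU_BAND, seed=2)
        s = simulate_mvar(spec, 20000, seed=502)
        g = recover_network(
            s, order=3, band=MU_BAND, coords=spec.coords, n_boot=100,
            seed=902, estimator="dekf", decimate=4, q_param=1e-6,
        )
        true = {(e.src, e.dst) for e in spec.edges}
        sig = {(e.src, e.dst) for e in g.significant_edges()}
        assert len(true & sig) >= 8
        assert len(sig - true) <= 2
        assert isinstance(g, ConnectivityGraph)
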