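"""DICS beamforming: CSD, filters, maps, extraction, pooling, significance."""

import numpy as np
import pytest
from scipy import stats as sps

from dynconn.core import MU_BAND, MultichannelSeries
from dynconn.dics import (
    DICS,
    CSDMatrix,
    LeadField,
    compute_csd,
    make_toy_leadfield,
    pool_source_signal,
    source_significance,
    toy_grid,
)
from dynconn.preprocess import band_power
from dynconn.synth import project_to_sensors
from tests.conftest import oscillator_series


def _identity_csd(n, freqs=(10.0,)):
    vals = np.tile(np.eye(n, dtype=complex), (len(freqs), 1, 1))
    return CSDMatrix(vals, np.array(freqs), n_segments=1)


class TestComputeCSD:
    def test_identical_channels_fully_coherent(self, rng):
        x = rng.standard_normal(4000)
        s = MultichannelSeries(np.vstack([x, x]), 500.0)
        csd = compute_csd(s, MU_BAND)
        for k in range(len(csd.freqs)):
            S = csd.values[k]
            coh = np.abs(S[0, 1]) ** 2 / (S[0, 0].real * S[1, 1].real)
            assert coh == pytest.approx(1.0, abs=1e-9)

    def test_independent_channels_incoherent(self, rng):
        s = MultichannelSeries(rng.standard_normal((2, 60000)), 500.0)
        csd = compute_csd(s, MU_BAND)
        S = csd.band_mean()
        coh = np.abs(S[0, 1]) ** 2 / (S[0, 0].real * S[1, 1].real)
        assert coh < 0.05

    def test_common_sinusoid_snr1_coherence(self, rng):
        """Two channels sharing a sinusoid plus independent noise: with
        signal and noise PSDs equal at the 10 Hz bin (SNR 1 at that bin),
        the closed form gives |coherency| = P_s/(P_s+P_n) = 0.5, i.e.
        magnitude-squared coherence 0.25."""
        from scipy.signal import welch

        rate, n, seg = 500.0, 200000, 2.0
        t = np.arange(n) / rate
        sig = np.sin(2 * np.pi * 10 * t)
        n1 = rng.standard_normal(n)
        n2 = rng.standard_normal(n)
        nper = int(seg * rate)
        f, psd_s = welch(sig, fs=rate, nperseg=nper, noverlap=nper // 2)
        _, psd_n = welch(n1, fs=rate, nperseg=nper, noverlap=nper // 2)
        k = int(np.argmin(np.abs(f - 10.0)))
        scale = np.sqrt(psd_s[k] / psd_n[k])  # equalize PSDs at 10 Hz
        s = MultichannelSeries(
            np.vstack([sig + scale * n1, sig + scale * n2]), rate
        )
        csd = compute_csd(s, MU_BAND, segment_len=seg)
        kk = int(np.argmin(np.abs(csd.freqs - 10.0)))
        S = csd.values[kk]
        msc = np.abs(S[0, 1]) ** 2 / (S[0, 0].real * S[1, 1].real)
        assert np.sqrt(msc) == pytest.approx(0.5, abs=0.08)

    def test_band_outside_nyquist_rejected(self, rng):
        from dynconn.core import BandDefinition

        s = MultichannelSeries(rng.standard_normal((2, 2000)), 100.0)
        with pytest.raises(ValueError, match="Nyquist"):
            compute_csd(s, BandDefinition("x", 40.0, 60.0))

    def test_hermitian_invariant(self, white_series):
        csd = compute_csd(white_series, MU_BAND)
        dev = np.abs(
            csd.values - csd.values.conj().transpose(0, 2, 1)
        ).max()
        assert dev < 1e-12


class TestDICSFilters:
    def test_whitened_case_recovers_leadfield_rows(self, rng):
        q, _ = np.linalg.qr(rng.standard_normal((6, 3)))
        lf = LeadField(q, rng.standard_normal((6, 3)), rng.standard_normal((3, 3)))
        res = DICS(_identity_csd(6), lf, regularization=0.0).fit()
        assert np.allclose(res.filters, q.T, atol=1e-10)

    def test_unit_gain_property(self, rng):
        """w_s L_s = 1 for random PSD CSDs and random lead fields."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            n, m = 8, 12
            A = r.standard_normal((n, n)) + 1j * r.standard_normal((n, n))
            C = (A @ A.conj().T)[np.newaxis]
            csd = CSDMatrix(C, np.array([10.0]), 1)
            lf = LeadField(
                r.standard_normal((n, m)), r.standard_normal((n, 3)),
                r.standard_normal((m, 3)),
            )
            res = DICS(csd, lf).fit()
            gains = np.einsum("sk,ks->s", res.filters, lf.gain)
            assert np.abs(gains - 1).max() < 1e-8

    def test_localizes_single_simulated_source(self):
        grid = toy_grid(5, 20.0)
        lf = make_toy_leadfield(32, grid)
        gidx = 62  # center of the grid
        src = oscillator_series(10.0, 4000, seed=3)
        lf1 = LeadField(lf.gain[:, [gidx]], lf.sensor_coords,
                        lf.source_coords[[gidx]])
        sens = project_to_sensors(src, lf1, sensor_noise_sd=1e-4, seed=4)
        res = DICS(compute_csd(sens, MU_BAND), lf).fit()
        assert int(np.argmax(res.power_map())) == gidx

    def test_mismatched_sensor_count_rejected(self, rng):
        lf = make_toy_leadfield(16)
        with pytest.raises(ValueError, match="sensors"):
            DICS(_identity_csd(8), lf)


class TestMapsAndExtraction:
    def test_zero_csd_gives_zero_power(self, rng):
        lf = make_toy_leadfield(8, toy_grid(2, 30.0))
        fit_csd = _identity_csd(8)
        res = DICS(fit_csd, lf).fit()
        zero = CSDMatrix(
            np.zeros((1, 8, 8), dtype=complex), np.array([10.0]), 1
        )
        assert np.allclose(res.power_map(zero), 0.0)

    def test_power_decays_with_distance_from_true_source(self):
        grid = toy_grid(5, 20.0)
        lf = make_toy_leadfield(32, grid)
        gidx = 62
        src = oscillator_series(10.0, 8000, seed=6)
        lf1 = LeadField(lf.gain[:, [gidx]], lf.sensor_coords,
                        lf.source_coords[[gidx]])
        sens = project_to_sensors(src, lf1, sensor_noise_sd=1e-4, seed=7)
        res = DICS(compute_csd(sens, MU_BAND), lf).fit()
        power = res.power_map()
        d = np.linalg.norm(grid - grid[gidx], axis=1)
        near = power[(d > 0) & (d <= 20)].mean()
        far = power[d >= 60].mean()
        assert power[gidx] > near > far

    def test_coherence_map_self_is_one_and_bounded(self, white_series):
        lf = make_toy_leadfield(3, toy_grid(2, 30.0)[:8])
        csd = compute_csd(white_series, MU_BAND)
        res = DICS(csd, lf).fit()
        coh = res.coherence_map(reference=0)
        assert coh[0] == pytest.approx(1.0, abs=1e-9)
        assert np.all((coh >= 0) & (coh <= 1))

    def test_extract_identity_leadfield_passthrough(self, white_series):
        n = white_series.n_channels
        lf = LeadField(np.eye(n), np.zeros((n, 3)), np.zeros((n, 3)))
        res = DICS(_identity_csd(n), lf, regularization=0.0).fit()
        out = res.extract_source_series(white_series)
        assert np.allclose(out.data, white_series.data)

    def test_extract_recovers_noiseless_source(self):
        grid = toy_grid(3, 30.0)
        lf = make_toy_leadfield(16, grid)
        gidx = 13
        src = oscillator_series(10.0, 4000, seed=8)
        lf1 = LeadField(lf.gain[:, [gidx]], lf.sensor_coords,
                        lf.source_coords[[gidx]])
        sens = project_to_sensors(src, lf1, sensor_noise_sd=0.0, seed=0)
        res = DICS(compute_csd(sens, MU_BAND), lf).fit()
        est = res.extract_source_series(sens, indices=[gidx])
        r = np.corrcoef(est.data[0], src.data[0])[0, 1]
        assert abs(r) > 0.99

    def test_zero_input_zero_output(self):
        lf = make_toy_leadfield(8, toy_grid(2, 30.0))
        res = DICS(_identity_csd(8), lf).fit()
        zero = MultichannelSeries(np.zeros((8, 100)), 500.0)
        assert np.allclose(res.extract_source_series(zero).data, 0.0)


class TestPooling:
    def test_single_voxel_passthrough(self):
        s = oscillator_series(10.0, 2000, seed=1)
        pooled = pool_source_signal(s, MU_BAND)
        assert pooled.weights == pytest.approx([1.0])
        assert np.allclose(pooled.series.data[0], s.data[0])

    def test_weights_proportional_to_band_power(self):
        s = oscillator_series(10.0, 4000, seed=2, m=2)
        data = np.vstack([np.sqrt(3.0) * s.data[0], s.data[0]])
        vox = MultichannelSeries(data, s.rate)
        pooled = pool_source_signal(vox, MU_BAND)
        assert pooled.weights[0] == pytest.approx(0.75, abs=0.02)
        assert pooled.weights.sum() == pytest.approx(1.0)

    def test_equal_power_equal_weights(self, rng):
        x = rng.standard_normal((3, 4000))
        vox = MultichannelSeries(x, 500.0)
        pooled = pool_source_signal(vox, MU_BAND)
        assert np.allclose(pooled.weights, 1 / 3, atol=0.1)

    def test_all_zero_rejected(self):
        vox = MultichannelSeries(np.zeros((2, 2000)), 500.0)
        with pytest.raises(ValueError, match="zero band power"):
            pool_source_signal(vox, MU_BAND)


class TestSourceSignificance:
    def test_observed_below_all_permutations_gives_p_one(self, white_series):
        res = source_significance(
            lambda s: -np.inf, white_series, n_perm=20, seed=0
        )
        assert res.p_value == 1.0

    def test_observed_above_all_permutations(self):
        s = oscillator_series(10.0, 4000, seed=9)
        calls = {"first": True}

        def stat(series):
            if calls["first"]:
                calls["first"] = False
                return 1e9  # observed exceeds every surrogate
            return float(band_power(series, MU_BAND).mean())

        res = source_significance(stat, s, n_perm=100, seed=1)
        assert res.p_value == pytest.approx(1 / 101)
        assert res.significant

    def test_null_p_values_uniform(self):
        """Shuffling stationary white noise leaves band power distribution
        unchanged, so p-values over repeated runs are uniform."""
        ps = []
        for k in range(200):
            r = np.random.default_rng(k)
            s = MultichannelSeries(r.standard_normal((1, 3000)), 500.0)
            res = source_significance(
                lambda x: float(band_power(x, MU_BAND)[0]),
                s, n_perm=39, seed=k + 1,
            )
            ps.append(res.p_value)
        stat, p = sps.kstest(ps, "uniform")
        assert p > 0.01

    def test_too_few_segments_rejected(self):
        s = MultichannelSeries(np.random.default_rng(0).standard_normal((1, 600)), 500.0)
        with pytest.raises(ValueError, match="segments"):
            source_significance(lambda x: 0.0, s, n_perm=10)
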