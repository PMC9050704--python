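import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from scmotormap.geometry import MapGrid
from scmotormap.network import (NetworkConfig, SpikeRecord, build_network,
                                lateral_weight, location_params,
                                net_lateral_kernel, route_signed_weights)

CFG = NetworkConfig()


class TestLocationParams:
    @pytest.mark.parametrize("u, expected", [
        (0.0, (60.0, 10.0, 1.0)),
        (2.5, (30.0, 7.0, 0.75)),   # tau_q = 60-12u, w_FS = 10-1.2u, S = 1-0.04u^2
        (5.0, (0.0, 4.0, 0.0)),
    ])
    def test_gradient_evaluation(self, u, expected):
        assert location_params(u, CFG) == pytest.approx(expected, abs=1e-12)

    def test_out_of_range_rejected(self):
        for u in (-0.1, 5.1):
            with pytest.raises(ValueError):
                location_params(u, CFG)

    def test_gradients_positive_on_grid(self):
        tau_q, w_FS, S = location_params(MapGrid().positions, CFG)
        assert np.all(tau_q > 0) and np.all(w_FS > 0) and np.all(S >= 0)


class TestLateralWeights:
    def test_net_central_excitation_at_15deg_site(self):
        # S(2.5) * (W_exc - 1 + W_inh) = 0.75 * 0.31
        assert net_lateral_kernel(0.0, 2.5, CFG) == pytest.approx(0.2325, abs=1e-12)

    def test_short_range_disinhibition_at_rostral_pole(self):
        w_exc, w_inh = lateral_weight(0.0, 1e-9, CFG)
        assert w_inh == pytest.approx(1.0 - 1.15, abs=1e-6)

    def test_long_range_pure_inhibition(self):
        w_exc, w_inh = lateral_weight(2.5, 2.5 + 4.0, CFG)
        S = location_params(2.5, CFG)[2]
        assert w_exc == pytest.approx(0.0, abs=1e-6)
        assert w_inh == pytest.approx(S, abs=1e-6)

    def test_self_connection_rejected(self):
        with pytest.raises(ValueError):
            lateral_weight(2.5, 2.5, CFG)

    def test_kernel_matches_bruteforce_tabulation(self):
        # independent recomputation of the two-Gaussian kernel on a 0.01 mm grid
        d = np.arange(0.01, 2.5, 0.01)
        S = 1.0 - 0.04 * 2.5**2
        expected = (S * 0.16 * np.exp(-d**2 / (2 * 0.2**2))
                    - S * (1.0 - 1.15 * np.exp(-d**2 / (2 * 0.7**2))))
        got = net_lateral_kernel(d, 2.5, CFG)
        assert np.allclose(got, expected, atol=1e-12)

    def test_mexican_hat_shape(self):
        d = np.linspace(0, 2.0, 400)
        net = net_lateral_kernel(d, 2.5, CFG)
        assert net[0] > 0
        assert net[-1] < 0
        sign_changes = np.sum(np.diff(np.sign(net)) != 0)
        assert sign_changes == 1
        assert np.allclose(net, net_lateral_kernel(-d, 2.5, CFG))

    def test_outgoing_strength_decreases_rostral_to_caudal(self):
        mags = [abs(net_lateral_kernel(0.0, u, CFG)) for u in (0.5, 1.5, 2.5, 3.5, 4.5)]
        assert all(a > b for a, b in zip(mags, mags[1:]))


class TestRouting:
    @pytest.mark.parametrize("pair, expected", [
        ((0.12, -0.1125), (0.2325, 0.0)),   # central pair for the 15-deg site
        ((0.0, 0.75), (0.0, 0.75)),
        ((0.0, 0.0), (0.0, 0.0)),
    ])
    def test_examples(self, pair, expected):
        assert route_signed_weights(*pair) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(0.0, 1.0), st.floats(-1.0, 1.0))
    def test_nonnegative_and_net_preserving(self, w_exc, w_inh):
        exc, inh = route_signed_weights(w_exc, w_inh)
        assert exc >= 0.0 and inh >= 0.0
        assert exc - inh == pytest.approx(w_exc - w_inh, abs=1e-12)


class TestBuildNetwork:
    def test_feedforward_is_identity_with_rostral_bias(self, model):
        net = model.network
        w = net.w_FS_nS
        assert w.shape == (200,)
        assert np.all(np.diff(w) < 0)  # rostral > caudal
        assert w[0] == pytest.approx(10.0)

    def test_lateral_matrices_exclude_self(self, model):
        net = model.network
        assert np.all(np.diag(net.M_exc_nS) == 0)
        assert np.all(np.diag(net.M_inh_nS) == 0)
        off_diag = ~np.eye(200, dtype=bool)
        assert np.all(net.M_exc_nS[off_diag] > 0)
        assert np.all(net.M_inh_nS >= 0)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(sigma_exc_mm=0.9, sigma_inh_mm=0.7)

    def test_oversized_grid_rejected(self, cfg):
        with pytest.raises(ValueError):
            build_network(NetworkConfig(), MapGrid(length_mm=6.0),
                          cfg.adex_input, cfg.adex_sc)


class TestSimulate:
    def test_zero_input_zero_spikes(self, model):
        spec = model.default_spec(I0_pA=0.0)
        rec_in, rec_sc = model.run(spec)
        assert rec_in.total() == 0 and rec_sc.total() == 0

    def test_determinism(self, model, default_records):
        rec_in2, rec_sc2 = model.run(model.default_spec())
        for a, b in zip(default_records[1].times_ms, rec_sc2.times_ms):
            assert np.array_equal(a, b)
        for a, b in zip(default_records[0].times_ms, rec_in2.times_ms):
            assert np.array_equal(a, b)

    def test_spike_records_well_formed(self, default_records):
        for rec in default_records:
            for t in rec.times_ms:
                assert np.all(np.diff(t) > 0)
                if len(t):
                    assert t[0] >= 0 and t[-1] <= rec.t_end_ms

    def test_refractory_respected_in_network(self, cfg, default_records):
        rec_in, rec_sc = default_records
        assert rec_in.min_isi_ms() >= cfg.adex_input.t_ref_ms
        assert rec_sc.min_isi_ms() >= cfg.adex_sc.t_ref_ms

    def test_population_synchronized_around_image_point(self, model,
                                                        default_records):
        # active SC cells concentrate around u_T = 2.5 mm (~0.5 mm extent)
        _, rec_sc = default_records
        counts = rec_sc.counts()
        csum = np.cumsum(counts) / counts.sum()
        lo = np.searchsorted(csum, 0.05)
        hi = np.searchsorted(csum, 0.95)
        width_mm = (hi - lo) * 0.025
        center = rec_sc.positions_mm[np.argmax(counts)]
        assert abs(center - 2.5) < 0.2
        assert width_mm < 1.0

    def test_dt_validation(self, model):
        with pytest.raises(ValueError):
            model.network.simulate(model.default_spec(), dt_ms=0.2)


class TestSpikeRecordIO:
    def test_dataframe_round_trip(self, default_records, tmp_path):
        _, rec_sc = default_records
        path = tmp_path / "spikes.csv"
        rec_sc.write(path)
        import pandas as pd
        df = pd.read_csv(path)
        back = SpikeRecord.from_dataframe(df, "sc", rec_sc.n_neurons,
                                          rec_sc.positions_mm)
        for a, b in zip(rec_sc.times_ms, back.times_ms):
            assert np.allclose(a, b)
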