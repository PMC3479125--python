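"""Simulator: presets, semi-Markov paths, Ohmic rendering, decimation."""

import math

import numpy as np
import pytest
from scipy import stats as sps

import vdacgate as vg


class TestPresets:
    def test_native_conductances_and_dwells(self, native):
        assert native.conductance("S0") == pytest.approx(3.94)
        assert native.conductance("S1") == pytest.approx(2.61)
        assert native.conductance("S2A") == pytest.approx(2.03)
        assert native.conductance("S2B") == pytest.approx(1.48)
        assert native.mean_dwell_s["S0"] == pytest.approx(27.40)
        assert native.mean_dwell_s["S1"] == pytest.approx(2.92)
        # S2A and S2B share the single measured S2 dwell
        assert native.mean_dwell_s["S2A"] == native.mean_dwell_s["S2B"] == pytest.approx(2.45)

    def test_native_theoretical_overall_dwell(self, native):
        """Stationary sojourn mix x per-state means gives the overall mean."""
        labels = list(native.labels)
        P = np.zeros((4, 4))
        for i, a in enumerate(labels):
            for b, w in native.transition_weights[a].items():
                P[i, labels.index(b)] = w
        w, v = np.linalg.eig(P.T)
        pi = np.real(v[:, np.argmax(np.real(w))])
        pi /= pi.sum()
        d = np.array([native.mean_dwell_s[l] for l in labels])
        assert pi @ d == pytest.approx(10.34, abs=0.01)

    def test_delta21_single_open_state(self):
        p = vg.build_preset("delta21")
        assert p.labels == ("S0",)
        assert p.conductance("S0") == pytest.approx(4.00)

    def test_asymmetric_flag(self):
        assert vg.build_preset("V3C-K119C_ox").asymmetric
        assert vg.build_preset("V3C-K119C_ox").orientation == +1
        assert not vg.build_preset("native").asymmetric

    def test_unknown_name_lists_registry(self):
        with pytest.raises(KeyError, match="native"):
            vg.build_preset("nope")

    @pytest.mark.parametrize("name", vg.PRESET_NAMES)
    def test_transition_rows_are_distributions(self, name):
        p = vg.build_preset(name)
        for lab in p.labels:
            row = p.transition_weights[lab]
            assert lab not in row
            if row:
                assert sum(row.values()) == pytest.approx(1.0)

    def test_registry_json_roundtrips(self):
        import json

        blob = json.dumps(vg.gating_model.preset_registry_json())
        assert "native" in json.loads(blob)


class TestStatePath:
    def test_single_state_preset_one_sojourn(self):
        p = vg.build_preset("delta21")
        proto = vg.VoltageProtocol(((5.0, 40.0), (5.0, -40.0)))
        path = vg.simulate_state_path(p, proto, seed=0)
        assert len(path.sojourns) == 1
        assert path.sojourns[0].state == "S0"
        assert path.duration_s == pytest.approx(proto.total_duration_s)

    def test_path_covers_protocol_duration(self, native):
        proto = vg.VoltageProtocol.constant(40.0, 123.0)
        path = vg.simulate_state_path(native, proto, seed=3)
        assert path.start_s == 0.0
        assert path.end_s == pytest.approx(123.0)
        total = sum(s.duration_s for s in path.sojourns)
        assert total == pytest.approx(123.0)

    def test_consecutive_states_differ(self, native):
        path = vg.simulate_state_path(native, vg.VoltageProtocol.constant(40.0, 2000.0), seed=5)
        for a, b in zip(path.sojourns, path.sojourns[1:]):
            assert a.state != b.state

    def test_asymmetric_never_closes_at_wrong_polarity(self):
        p = vg.build_preset("V3C-K119C_ox")  # orientation +1: closes at V > 0
        proto = vg.VoltageProtocol.constant(-40.0, 500.0)
        path = vg.simulate_state_path(p, proto, seed=7)
        assert [s.state for s in path.sojourns] == ["S0"]

    def test_asymmetric_closed_time_zero_under_nonclosing_polarity(self):
        p = vg.build_preset("V3C-K119C_ox")
        proto = vg.VoltageProtocol.alternating(40.0, 20.0, 10)
        path = vg.simulate_state_path(p, proto, seed=11)
        closed_neg = 0.0
        for s in path.sojourns:
            if s.state == "S0":
                continue
            # overlap of the sojourn with negative-voltage steps
            for e0, (dur, v) in zip(proto.edges_s[:-1], proto.steps):
                if v < 0:
                    closed_neg += max(0.0, min(s.end_s, e0 + dur) - max(s.start_s, e0))
        assert closed_neg == 0.0
        assert any(s.state != "S0" for s in path.sojourns)  # it does close at V > 0

    def test_sojourn_mean_matches_exponential(self):
        """~10k S0 sojourns of a two-state toy recover the 10 s mean."""
        p = vg.ChannelPreset(
            name="toy", states=(vg.GatingState("S0", 3.9), vg.GatingState("S1", 2.6)),
            mean_dwell_s={"S0": 10.0, "S1": 0.5},
            transition_weights={"S0": {"S1": 1.0}, "S1": {"S0": 1.0}},
            noise_sd_pA=0.0, conductance_jitter_sd_nS=0.0)
        proto = vg.VoltageProtocol.constant(40.0, 110_000.0)
        path = vg.simulate_state_path(p, proto, seed=4)
        d = np.array([s.duration_s for s in path.sojourns[1:-1] if s.state == "S0"])
        assert len(d) > 5000
        assert abs(d.mean() - 10.0) < 3 * d.std(ddof=1) / math.sqrt(len(d))

    def test_sojourn_distribution_is_exponential(self):
        p = vg.ChannelPreset(
            name="toy", states=(vg.GatingState("S0", 3.9), vg.GatingState("S1", 2.6)),
            mean_dwell_s={"S0": 10.0, "S1": 0.5},
            transition_weights={"S0": {"S1": 1.0}, "S1": {"S0": 1.0}},
            noise_sd_pA=0.0, conductance_jitter_sd_nS=0.0)
        proto = vg.VoltageProtocol.constant(40.0, 110_000.0)
        path = vg.simulate_state_path(p, proto, seed=4)
        d = [s.duration_s for s in path.sojourns[1:-1] if s.state == "S0"]
        assert sps.kstest(d, "expon", args=(0, 10.0)).pvalue > 0.01

    def test_determinism(self, native):
        proto = vg.VoltageProtocol.constant(40.0, 300.0)
        a = vg.simulate_state_path(native, proto, seed=9)
        b = vg.simulate_state_path(native, proto, seed=9)
        assert a == b


class TestRenderCurrent:
    def test_ohms_law_zero_noise(self, quiet_native):
        proto = vg.VoltageProtocol.constant(40.0, 2.0)
        path = vg.StatePath((vg.Sojourn("S0", 0.0, 2.0),))
        tr = vg.render_current(path, quiet_native, proto, fs_Hz=1000.0, seed=0)
        assert np.all(tr.current_pA == pytest.approx(3.94 * 40))  # 157.6 pA

    def test_zero_voltage_means_zero_current(self, quiet_native):
        proto = vg.VoltageProtocol.constant(0.0, 1.0)
        path = vg.StatePath((vg.Sojourn("S0", 0.0, 1.0),))
        tr = vg.render_current(path, quiet_native, proto, fs_Hz=1000.0, seed=0)
        assert np.all(tr.current_pA == 0.0)

    def test_noise_sd_recovered(self, native):
        p = native.with_(conductance_jitter_sd_nS=0.0)
        proto = vg.VoltageProtocol.constant(40.0, 20.0)
        path = vg.StatePath((vg.Sojourn("S0", 0.0, 20.0),))
        tr = vg.render_current(path, p, proto, fs_Hz=5000.0, seed=2)
        resid = tr.current_pA - 3.94 * 40
        assert len(resid) == 100_000
        assert resid.std() == pytest.approx(2.0, rel=0.02)

    def test_zero_noise_bit_reproducible(self, quiet_native, step_protocol):
        a = vg.simulate_trace(quiet_native, step_protocol, seed=5)
        b = vg.simulate_trace(quiet_native, step_protocol, seed=5)
        assert np.array_equal(a.current_pA, b.current_pA)

    def test_same_seed_same_trace(self, native, step_protocol):
        a = vg.simulate_trace(native, step_protocol, seed=6)
        b = vg.simulate_trace(native, step_protocol, seed=6)
        assert np.array_equal(a.current_pA, b.current_pA)
        assert np.array_equal(a.voltage_mV, b.voltage_mV)

    def test_multichannel_sums_and_caps(self, quiet_native):
        proto = vg.VoltageProtocol.constant(40.0, 3.0)
        tr = vg.simulate_trace(quiet_native, proto, seed=8, n_channels=3)
        # all channels overwhelmingly open: current ~ 3 x S0 at the start
        assert tr.current_pA[0] == pytest.approx(3 * 3.94 * 40, rel=0.2)
        with pytest.raises(ValueError, match="1..5"):
            vg.simulate_trace(quiet_native, proto, seed=8, n_channels=6)


class TestDecimate:
    def test_constant_trace_unchanged(self):
        tr = vg.CurrentTrace(1000.0, np.full(1000, 7.0), np.full(1000, 40.0))
        out = vg.decimate(tr, 200.0)
        assert out.fs_Hz == 200.0
        assert np.all(out.current_pA == 7.0)

    def test_5khz_to_200hz_length(self, native, step_protocol):
        tr = vg.simulate_trace(native, step_protocol, fs_Hz=5000.0, seed=1)
        out = vg.decimate(tr, 200.0)
        assert out.n_samples == tr.n_samples // 25

    def test_block_means_match_bruteforce(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=250)
        tr = vg.CurrentTrace(5000.0, x, np.full(250, 40.0))
        out = vg.decimate(tr, 200.0)
        expected = np.array([x[i * 25:(i + 1) * 25].mean() for i in range(10)])
        np.testing.assert_allclose(out.current_pA, expected, rtol=0, atol=1e-12)

    def test_alternating_parity(self):
        x = np.tile([1.0, -1.0], 625)  # 1250 samples, blocks of 25 -> mean +-0.04
        tr = vg.CurrentTrace(5000.0, x, np.zeros(1250))
        out = vg.decimate(tr, 200.0)
        np.testing.assert_allclose(np.abs(out.current_pA), 0.04, atol=1e-12)

    def test_non_integer_ratio_rejected(self):
        tr = vg.CurrentTrace(5000.0, np.zeros(100), np.zeros(100))
        with pytest.raises(ValueError, match="integer multiple"):
            vg.decimate(tr, 300.0)
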