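"""Hydraulic network assembly, integration and valve calibration.

The primary correctness gate for the integrator is the small-signal
equivalence with the closed-form response of the linearized RC network,
computed here independently in the frequency domain.
"""

import numpy as np
import pytest

import csftwin as ct
from csftwin.errors import ConfigError, DriftError, InvalidParameterError
from csftwin.network import CanalSegment, _with_resistances


def small_network(r_path=0.02, r_v2=0.03):
    """Compact network with Table-1 chambers and given valve resistances."""
    p_op = 760.0 + 12.68
    return ct.NetworkModel(
        cranial_chamber=ct.AirChamber(v0_air=ct.size_air_volume(0.31, p_op), p0_abs=p_op),
        spinal_chamber=ct.AirChamber(v0_air=ct.size_air_volume(0.84, p_op), p0_abs=p_op),
        r_valve1=ct.ValveResistance(r=r_path / 2),
        r_aqueduct=r_path / 2,
        r_valve2=ct.ValveResistance(r=r_v2),
        canal=(CanalSegment(length_mm=500, hydraulic_diameter_mm=8),),
        baseline_icp_gauge=12.68,
    )


class TestPoiseuille:
    def test_hand_converted_reference_value(self):
        # 128*mu*L/(pi*d^4) for d=5mm, L=100mm, mu=1 mPa*s is 6.52e6 Pa/(m^3/s),
        # i.e. 8.15e-4 mmHg/(ml/min) after unit conversion (hand oracle)
        seg = CanalSegment(length_mm=100, hydraulic_diameter_mm=5, viscosity_mpa_s=1.0)
        assert ct.poiseuille_resistance(seg) == pytest.approx(8.149e-4, rel=1e-3)

    def test_linear_in_length(self):
        r1 = ct.poiseuille_resistance(CanalSegment(length_mm=100, hydraulic_diameter_mm=5))
        r2 = ct.poiseuille_resistance(CanalSegment(length_mm=200, hydraulic_diameter_mm=5))
        assert r2 == pytest.approx(2 * r1, rel=1e-12)

    def test_fourth_power_diameter_law(self):
        r1 = ct.poiseuille_resistance(CanalSegment(length_mm=100, hydraulic_diameter_mm=5))
        r2 = ct.poiseuille_resistance(CanalSegment(length_mm=100, hydraulic_diameter_mm=10))
        assert r1 == pytest.approx(16 * r2, rel=1e-12)


class TestAssemble:
    def test_default_config_reproduces_compliance_budget(self, default_network):
        p_op = default_network.baseline_abs
        c_cran = ct.compliance_at(default_network.cranial_chamber, p_op)
        c_spin = ct.compliance_at(default_network.spinal_chamber, p_op)
        assert c_cran == pytest.approx(0.31, rel=1e-12)
        assert c_spin == pytest.approx(0.84, rel=1e-12)
        assert c_cran + c_spin == pytest.approx(1.15, rel=1e-12)

    def test_canal_resistance_is_series_sum(self, default_network):
        total = sum(ct.poiseuille_resistance(s) for s in default_network.canal)
        assert default_network.r_canal == pytest.approx(total, rel=1e-14)

    def test_contradictory_chamber_spec_rejected(self, tmp_path):
        cfg = tmp_path / "bad.json"
        cfg.write_text(
            '{"chambers": {"cranial": {"v0_air_ml": 300, "c_target_ml_per_mmHg": 0.31}}}'
        )
        with pytest.raises(ConfigError):
            ct.load_config(cfg)

    def test_zero_resistance_loop_rejected(self):
        with pytest.raises(ConfigError):
            small_network(r_path=0.0, r_v2=0.0)


class TestOperatingPoint:
    def test_zero_pump_stays_at_baseline(self, default_network):
        pump = ct.SampledWaveform(period=60 / 70, values=np.zeros(64))
        res = ct.simulate(default_network, pump, n_cycles=2, warmup_cycles=0, dt=pump.period / 256)
        assert np.allclose(res.icp, 12.68, atol=1e-9)
        assert np.allclose(res.q_spinal, 0.0, atol=1e-9)
        assert np.allclose(res.p_cistern, 12.68, atol=1e-9)

    def test_chamber_volumes_consistent_with_baseline(self, default_network):
        state = ct.operating_point(default_network)
        p_abs = default_network.baseline_abs
        assert ct.chamber_pressure(default_network.cranial_chamber, state.v_air_cranial) == pytest.approx(p_abs)
        assert ct.chamber_pressure(default_network.spinal_chamber, state.v_air_spinal) == pytest.approx(p_abs)


class TestSimulate:
    def test_nonzero_net_pump_volume_refused(self, default_network):
        pump = ct.SampledWaveform(period=60 / 70, values=np.ones(64))
        with pytest.raises(DriftError):
            ct.simulate(default_network, pump)

    def test_dt_must_divide_period(self, default_network, default_av):
        with pytest.raises(ct.errors.GridMismatchError):
            ct.simulate(default_network, default_av, dt=default_av.period / 100.5)

    def test_small_signal_matches_linear_rc_closed_form(self):
        """Sinusoidal pump at the fundamental: the simulated spinal-flow
        amplitude must match |H| of the linearized network within 1%, with
        H = (Cs/(Cc+Cs)) / (1 + j*omega*tau), tau = Rs*Cc*Cs/(Cc+Cs)."""
        net = small_network(r_path=0.02, r_v2=0.03)
        period = 60 / 70
        n = 256
        t = np.arange(n) * period / n
        amp = 5.0  # ml/min, small-signal regime
        pump = ct.SampledWaveform(period=period, values=amp * np.sin(2 * np.pi * t / period))
        res = ct.simulate(net, pump, n_cycles=3, warmup_cycles=3)
        q = res.cycle_mean_flow().values

        p_op = net.baseline_abs
        cc = ct.compliance_at(net.cranial_chamber, p_op)
        cs = ct.compliance_at(net.spinal_chamber, p_op)
        r_parallel = 1.0 / (1.0 / net.r_parenchyma_path + 1.0 / net.r_valve2.r)
        r_s = r_parallel + net.r_canal  # mmHg/(ml/min)
        omega = 2 * np.pi / (period / 60.0)  # rad/min
        h = (cs / (cc + cs)) / (1 + 1j * omega * (r_s * cc * cs / (cc + cs)))
        expected_amp = amp * abs(h)

        simulated_amp = (q.max() - q.min()) / 2
        assert simulated_amp == pytest.approx(expected_amp, rel=0.01)
        # phase lag also matches the closed form
        fund = np.fft.rfft(q)[1]
        pump_fund = np.fft.rfft(pump.values)[1]
        phase_err = np.angle(fund / pump_fund) - np.angle(h)
        assert abs(phase_err) < 0.01

    def test_net_spinal_volume_vanishes_over_whole_cycles(self, calibrated):
        _, res = calibrated
        s = res.steps_per_cycle
        for k in range(res.n_cycles):
            seg = res.q_spinal[k * s : (k + 1) * s]
            net_ml = seg.mean() * res.period / 60.0
            assert abs(net_ml) < 1e-3

    def test_periodic_steady_state_after_warmup(self, calibrated):
        _, res = calibrated
        s = res.steps_per_cycle
        means = [res.icp[k * s : (k + 1) * s].mean() for k in range(res.n_cycles)]
        assert max(means) - min(means) < 1e-3

    def test_deterministic_rerun_bitwise(self, default_network, default_av):
        a = ct.simulate(default_network, default_av, n_cycles=2, dt=default_av.period / 512)
        b = ct.simulate(default_network, default_av, n_cycles=2, dt=default_av.period / 512)
        assert np.array_equal(a.icp, b.icp)
        assert np.array_equal(a.q_spinal, b.q_spinal)


class TestMonotonicity:
    def test_higher_canal_resistance_lowers_caudal_maximum(self, default_av):
        dt = default_av.period / 512
        short = small_network()
        long = ct.NetworkModel(
            **{
                **{f: getattr(short, f) for f in (
                    "cranial_chamber", "spinal_chamber", "r_valve1", "r_aqueduct",
                    "r_valve2", "baseline_icp_gauge", "atm_mmHg")},
                "canal": (CanalSegment(length_mm=500, hydraulic_diameter_mm=4),),
            }
        )
        qa = ct.simulate(short, default_av, n_cycles=2, dt=dt).cycle_mean_flow().values
        qb = ct.simulate(long, default_av, n_cycles=2, dt=dt).cycle_mean_flow().values
        assert qb.max() < qa.max()

    def test_higher_spinal_compliance_raises_spinal_stroke_volume(self, default_av):
        dt = default_av.period / 512
        p_op = 760.0 + 12.68

        def with_cs(c_spinal):
            base = small_network()
            return ct.NetworkModel(
                **{
                    **{f: getattr(base, f) for f in (
                        "cranial_chamber", "r_valve1", "r_aqueduct", "r_valve2",
                        "canal", "baseline_icp_gauge", "atm_mmHg")},
                    "spinal_chamber": ct.AirChamber(
                        v0_air=ct.size_air_volume(c_spinal, p_op), p0_abs=p_op
                    ),
                }
            )

        sv_low = ct.stroke_volume(
            ct.simulate(with_cs(0.5), default_av, n_cycles=2, dt=dt).cycle_mean_flow()
        )
        sv_high = ct.stroke_volume(
            ct.simulate(with_cs(1.2), default_av, n_cycles=2, dt=dt).cycle_mean_flow()
        )
        assert sv_high > sv_low


class TestCalibration:
    def test_targets_must_bracket_zero(self, default_network, default_av):
        with pytest.raises(InvalidParameterError):
            ct.calibrate_resistances(default_network, default_av, 100.0, 50.0)

    def test_parameter_recovery_from_synthetic_targets(self, default_network, default_av):
        """Self-consistency: extrema simulated with known resistances are
        recovered by the fit.  The spinal flow senses the two cranial paths
        only through their parallel combination, so that combination (and the
        achieved extrema) must come back within 2%."""
        truth = _with_resistances(default_network, 0.018, 0.025)
        res = ct.simulate(truth, default_av, n_cycles=2, dt=default_av.period / 512)
        q = res.cycle_mean_flow().values
        fit = ct.calibrate_resistances(
            default_network, default_av, float(q.max()), float(q.min())
        )
        r_parallel_truth = 1.0 / (1.0 / 0.018 + 1.0 / 0.025)
        assert fit.r_parallel == pytest.approx(r_parallel_truth, rel=0.02)
        assert fit.achieved_caudal_max == pytest.approx(q.max(), rel=0.02)
        assert fit.achieved_cranial_max == pytest.approx(q.min(), rel=0.02)

    def test_bench_targets_reached_within_five_percent(self, calibrated):
        fit, _ = calibrated
        assert fit.converged
        assert abs(fit.achieved_caudal_max - 133.60) / 133.60 < 0.05
        assert abs(fit.achieved_cranial_max + 68.01) / 68.01 < 0.05
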