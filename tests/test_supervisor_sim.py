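import numpy as np
import pytest

from lpvsup.patient_model import (MAP_PATIENT, make_trajectory, sample_patient)
from lpvsup.supervisor_sim import (HysteresisLogic, PerformanceSpecs,
                                   SimulationOptions, SimulationTrace,
                                   build_hysteresis, performance_metrics,
                                   simulate_closed_loop, supervisor_step)
from lpvsup.synthesis import OperatingRegion, default_partition

THETA_RANGE = (-9.5, -0.25)

# published switching thresholds: boundary +/- 0.2
UP_SWITCHES = [-5.60, -2.83, -1.22, -0.40]
DOWN_SWITCHES = [-6.00, -3.23, -1.62, -0.80]


class TestHysteresis:
    def test_thresholds_reproduce_published_table(self):
        logic = build_hysteresis(default_partition(), 0.2)
        assert logic.up_thresholds == pytest.approx(UP_SWITCHES)
        assert logic.down_thresholds == pytest.approx(DOWN_SWITCHES)

    def test_excessive_half_width_rejected(self):
        with pytest.raises(ValueError):
            build_hysteresis(default_partition(), 0.35)  # narrowest region 0.35

    def test_zero_half_width_warns(self):
        with pytest.warns(UserWarning):
            build_hysteresis(default_partition(), 0.0)

    def test_monotone_sweep_switch_locations(self):
        logic = build_hysteresis(default_partition(), 0.2)
        thetas = np.arange(-9.5, -0.25, 1e-4)
        idx, events = 0, []
        for th in thetas:
            new = supervisor_step(th, idx, logic)
            if new != idx:
                events.append((idx, new, th))
                idx = new
        assert [e[:2] for e in events] == [(0, 1), (1, 2), (2, 3), (3, 4)]
        assert [e[2] for e in events] == pytest.approx(UP_SWITCHES, abs=2e-4)

        events = []
        for th in thetas[::-1]:
            new = supervisor_step(th, idx, logic)
            if new != idx:
                events.append((idx, new, th))
                idx = new
        assert [e[:2] for e in events] == [(4, 3), (3, 2), (2, 1), (1, 0)]
        assert [e[2] for e in events] == pytest.approx(DOWN_SWITCHES[::-1],
                                                       abs=2e-4)

    def test_small_oscillation_never_switches(self):
        # oscillation with amplitude below the half-width around a boundary
        logic = build_hysteresis(default_partition(), 0.2)
        t = np.linspace(0.0, 100.0, 5001)
        theta = -5.80 + 0.19 * np.sin(t)
        idx = 0
        for th in theta:
            assert supervisor_step(th, idx, logic) == idx


@pytest.fixture(scope="module")
def nominal_trace(bank, smiths, logic):
    traj = make_trajectory("constant", THETA_RANGE, 0.0, 2000.0, value=-7.65)
    patient = sample_patient(MAP_PATIENT, 1, trajectory=traj, nominal=True)
    return simulate_closed_loop(patient, bank, smiths, logic)


@pytest.fixture(scope="module")
def switching_trace(bank, smiths, logic):
    traj = make_trajectory("fig7_like", THETA_RANGE, 0.0085, 2000.0)
    patient = sample_patient(MAP_PATIENT, 1, trajectory=traj, nominal=True)
    return simulate_closed_loop(patient, bank, smiths, logic)


class TestSimulation:
    def test_equilibrium_stays_at_setpoint(self, bank, smiths, logic):
        traj = make_trajectory("constant", THETA_RANGE, 0.0, 600.0, value=-7.65)
        patient = sample_patient(MAP_PATIENT, 1, trajectory=traj, nominal=True)
        tr = simulate_closed_loop(patient, bank, smiths, logic, T=600.0,
                                  options=SimulationOptions(x0=0.0))
        assert np.max(np.abs(tr.map_mmHg - 100.0)) < 1e-9
        assert np.max(np.abs(tr.infusion)) < 1e-9

    def test_no_drug_effect_before_transport_delay(self, nominal_trace):
        # during the first h = 40 s the pressure follows the free decay
        # 100 + 50 exp(-t/35) exactly: the delay buffer still outputs zeros
        tr = nominal_trace
        k = np.nonzero(tr.t <= 40.0 - tr.dt)[0]
        expected = 100.0 + 50.0 * np.exp(-tr.t[k] / 35.0)
        assert tr.map_mmHg[k] == pytest.approx(expected, abs=1e-6)

    def test_nominal_transient_settles_in_spec_time(self, nominal_trace):
        rep = performance_metrics(nominal_trace)
        assert rep.settling_time_min <= 10.0
        assert not rep.unstable
        assert rep.infusion_min >= 0.0 and rep.infusion_max < 180.0

    def test_terminal_pressure_reaches_setpoint(self, nominal_trace):
        assert nominal_trace.map_mmHg[-1] == pytest.approx(100.0, abs=0.01)

    def test_switch_sequence_follows_trajectory(self, switching_trace):
        assert [s[1:] for s in switching_trace.switch_times] == [
            (0, 1), (1, 2), (2, 3), (3, 4)]
        # switches occur when theta crosses the published thresholds
        for (t_sw, _, new), expect in zip(switching_trace.switch_times, UP_SWITCHES):
            th = np.interp(t_sw, switching_trace.t, switching_trace.theta)
            assert th == pytest.approx(expect, abs=0.0085 * 0.2)

    def test_no_chattering_spacing(self, switching_trace):
        # consecutive switches are separated by at least 2*half_width/sup_rate
        times = [s[0] for s in switching_trace.switch_times]
        gaps = np.diff(times)
        assert np.all(gaps >= 2 * 0.2 / 0.0085 - 1e-9)

    def test_integration_converges_under_dt_halving(self, bank, smiths, logic):
        traj = make_trajectory("constant", THETA_RANGE, 0.0, 800.0, value=-7.65)
        patient = sample_patient(MAP_PATIENT, 1, trajectory=traj, nominal=True)
        tr1 = simulate_closed_loop(patient, bank, smiths, logic, dt=0.1, T=800.0)
        tr2 = simulate_closed_loop(patient, bank, smiths, logic, dt=0.05, T=800.0)
        assert abs(tr1.map_mmHg[-1] - tr2.map_mmHg[-1]) < 0.1

    def test_bit_reproducibility(self, bank, smiths, logic):
        traj = make_trajectory("fig7_like", THETA_RANGE, 0.0085, 2000.0)
        patient = sample_patient(MAP_PATIENT, 1, trajectory=traj, nominal=True)
        a = simulate_closed_loop(patient, bank, smiths, logic)
        b = simulate_closed_loop(patient, bank, smiths, logic)
        assert np.array_equal(a.map_mmHg, b.map_mmHg)
        assert np.array_equal(a.infusion, b.infusion)

    def test_coarse_dt_rejected(self, bank, smiths, logic):
        patient = sample_patient(MAP_PATIENT, 1, nominal=True)
        with pytest.raises(ValueError):
            simulate_closed_loop(patient, bank, smiths, logic, dt=10.0)

    def test_single_controller_much_worse_than_bank(self, bank, smiths, logic,
                                                    switching_trace):
        # a lone mid-range compensator over the whole scenario degrades the
        # transient severely compared with the switching bank
        traj = make_trajectory("fig7_like", THETA_RANGE, 0.0085, 2000.0)
        patient = sample_patient(MAP_PATIENT, 1, trajectory=traj, nominal=True)
        single_logic = build_hysteresis([bank[2].region], 0.2)
        tr = simulate_closed_loop(patient, [bank[2]], [smiths[2]], single_logic)
        rep_single = performance_metrics(tr)
        rep_bank = performance_metrics(switching_trace)
        assert not rep_single.all_pass
        assert rep_single.undershoot_mmHg > 3.0 * rep_bank.undershoot_mmHg


class TestMetrics:
    def _flat_trace(self, values, setpoint=100.0, dt=1.0):
        n = len(values)
        return SimulationTrace(t=np.arange(n) * dt, theta=np.full(n, -7.65),
                               map_mmHg=np.asarray(values, dtype=float),
                               infusion=np.zeros(n),
                               controller_index=np.zeros(n, dtype=int),
                               controller_states=np.zeros((n, 0)),
                               switch_times=[], dt=dt, setpoint=setpoint)

    def test_trace_at_setpoint_scores_zero(self):
        rep = performance_metrics(self._flat_trace([100.0] * 200))
        assert rep.settling_time_min == 0.0
        assert rep.undershoot_mmHg == 0.0
        assert rep.steady_state_band_mmHg == 0.0

    def test_dip_below_band_fails_undershoot(self):
        vals = np.full(600, 100.0)
        vals[:50] = 150.0
        vals[100:120] = 88.0  # dips to 88 against setpoint 100
        rep = performance_metrics(self._flat_trace(vals))
        assert rep.undershoot_mmHg == pytest.approx(12.0)
        assert not rep.passes["undershoot"]

    def test_unstable_trace_fails_everything(self):
        tr = self._flat_trace([100.0] * 100)
        tr.unstable = True
        rep = performance_metrics(tr)
        assert not any(rep.passes.values())

    def test_sustained_oscillation_flagged(self):
        t = np.arange(2000)
        vals = 100.0 + 3.0 * np.sin(t / 10.0)
        rep = performance_metrics(self._flat_trace(vals))
        assert rep.oscillatory
        assert not rep.passes["oscillation"]
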