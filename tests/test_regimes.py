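"""Spike/burst statistics, envelope periods, regime classification."""

import numpy as np
import pytest

import ionhh as ih
from ionhh.dynamics import Trajectory
from ionhh.regimes import (classify_regime, slow_oscillation_period,
                           spike_and_burst_stats)


def make_traj(params, t, V=None, K_e=None, spikes=()):
    """Synthetic trajectory with prescribed V and K_e histories."""
    y = np.zeros((t.size, 6))
    y[:, 0] = -70.0 if V is None else V
    y[:, 1] = 0.07
    ke = np.full(t.size, params.K_e0) if K_e is None else np.asarray(K_e)
    # invert the constraint: choose K_i to produce the requested K_e
    y[:, 2] = params.K_i0 - (ke - params.K_e0) / params.vol_ratio
    y[:, 3] = params.Cl_i0
    return Trajectory(times=t, y=y, variant="bath", params=params,
                      spike_times=np.asarray(spikes, float))


class TestSpikeStats:
    def test_exact_100hz_train(self):
        spikes = np.arange(0.0, 1.0, 0.01)
        st = spike_and_burst_stats(spikes)
        assert st.intraburst_freq == pytest.approx(100.0)
        assert st.n_bursts == 1

    def test_empty_train(self):
        st = spike_and_burst_stats(np.empty(0))
        assert st.n_spikes == 0 and st.n_bursts == 0
        assert st.intraburst_freq is None

    def test_burst_grouping(self):
        # three bursts of 5 spikes at 50 Hz, 2 s apart
        bursts = [b + np.arange(5) * 0.02 for b in (0.0, 2.0, 4.0)]
        st = spike_and_burst_stats(np.concatenate(bursts))
        assert st.n_bursts == 3
        assert st.burst_spike_counts == [5, 5, 5]
        assert st.intraburst_freq == pytest.approx(50.0)


class TestSlowPeriod:
    def test_sinusoid_450s(self, params):
        t = np.arange(0.0, 2500.0, 0.5)
        ke = params.K_e0 + 20.0 * np.sin(2 * np.pi * t / 450.0)
        assert slow_oscillation_period((t, ke)) == pytest.approx(450.0,
                                                                 rel=0.01)

    def test_flat_signal_is_none(self, params):
        t = np.arange(0.0, 500.0, 0.5)
        ke = np.full_like(t, params.K_e0) + 0.01 * np.sin(t)
        assert slow_oscillation_period((t, ke)) is None


class TestClassification:
    def test_resting_trace(self, params):
        t = np.arange(0.0, 600.0, 0.5)
        rs = classify_regime(make_traj(params, t), params)
        assert rs.label == "resting"

    def test_fes_trace(self, params):
        t = np.arange(0.0, 600.0, 0.5)
        rs = classify_regime(make_traj(params, t, V=-30.0,
                                       K_e=np.full(t.size, 30.0)), params)
        assert rs.label == "FES"

    def test_tonic_trace(self, params):
        t = np.arange(0.0, 600.0, 0.5)
        spikes = np.arange(0.0, 600.0, 0.2)
        rs = classify_regime(make_traj(params, t, spikes=spikes), params)
        assert rs.label == "tonic"

    def test_sla_trace(self, params):
        t = np.arange(0.0, 600.0, 0.5)
        ke = params.K_e0 + 2.0 + 2.0 * np.sin(2 * np.pi * t / 25.0)
        spikes = np.concatenate([b + np.arange(40) * 0.15
                                 for b in np.arange(100.0, 580.0, 25.0)])
        rs = classify_regime(make_traj(params, t, K_e=ke, spikes=spikes),
                             params)
        assert rs.label == "SLA"
        assert rs.slow_period == pytest.approx(25.0, rel=0.05)

    def test_periodic_sd_trace(self, params):
        t = np.arange(0.0, 3000.0, 0.5)
        ke = params.K_e0 + 22.0 + 22.0 * np.sin(2 * np.pi * t / 450.0)
        spikes = np.arange(100.0, 2900.0, 50.0)
        rs = classify_regime(make_traj(params, t, K_e=ke, spikes=spikes),
                             params)
        assert rs.label == "periodic_SD"
        assert rs.slow_period == pytest.approx(450.0, rel=0.05)


class TestSimulatedRegimes:
    def test_closed_rest_classifies_as_resting(self, params):
        traj = ih.simulate(params, "closed", t_end=300.0, dt_out=0.5)
        rs = classify_regime(traj, params)
        assert rs.label == "resting"

    def test_sla_and_sd_amplitude_separation(self, sla_results, sd_results):
        """Ionic amplitude of periodic SD is an order of magnitude above
        SLA's."""
        sla_amp = [r.K_e_amplitude for r in sla_results if r.label == "SLA"]
        sd_amp = [r.K_e_amplitude for r in sd_results
                  if r.label == "periodic_SD"]
        assert sla_amp and sd_amp
        assert min(sd_amp) >= 10.0 * max(sla_amp) / 2.0
        assert min(sd_amp) / max(sla_amp) > 10.0

    def test_periodic_sd_visits_fes_sodium_levels(self, params, sd_results,
                                                  sla_results):
        """Periodic SD swings between FES-like and physiological sodium;
        SLA stays near the physiological Na_e."""
        for r in sd_results:
            if r.label == "periodic_SD":
                assert r.Na_e_min < 40.0
        for r in sla_results:
            if r.label == "SLA":
                assert r.Na_e_min > 100.0

    def test_sweep_below_first_instability_is_resting(self, params):
        from ionhh.regimes import track_branch_by_ramp
        res = track_branch_by_ramp(params, [4.5, 5.0, 5.5], window=250.0,
                                   transient=100.0)
        assert all(r.label == "resting" for r in res)

    def test_period_invariant_under_tolerance_halving(self, params):
        """The SLA envelope period changes by < 2% when the integration
        tolerances are halved."""
        from ionhh.regimes import dynamics_resting
        pp = params.replace(K_bath=9.25)
        st = dynamics_resting(pp)
        periods = []
        for rtol, atol in ((1e-8, 1e-10), (5e-9, 5e-11)):
            tr = ih.simulate(pp, "bath", t_end=850.0, initial_state=st,
                             dt_out=0.05, rtol=rtol, atol=atol)
            m = tr.times > 250.0
            periods.append(slow_oscillation_period((tr.times[m], tr.K_e[m])))
        assert periods[0] is not None and periods[1] is not None
        assert abs(periods[0] - periods[1]) / periods[0] < 0.02

    def test_tonic_coexists_at_sd_branch_end(self, params,
                                             sd_branch_end_result):
        """Hysteresis: tonic firing is stable where the down-swept SD
        branch ends."""
        from ionhh.regimes import track_branch_by_ramp
        kb = round(sd_branch_end_result.K_bath_end + 0.2, 2)
        res = track_branch_by_ramp(params, [kb - 1.5, kb], window=600.0,
                                   transient=200.0)
        assert res[-1].label == "tonic"
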