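"""Shared fixtures.

The expensive computations (SD episode, regime sweeps, continuations) are
session-scoped so that unit tests and the acceptance tests share one run.
Everything is deterministic; sizes follow the canonical experiment
definitions in ionhh.experiments.
"""

import numpy as np
import pytest

import ionhh as ih
from ionhh import experiments


@pytest.fixture(scope="session")
def params():
    return ih.table1()


@pytest.fixture(scope="session")
def rest_closed(params):
    return ih.resting_state(params, "closed")


@pytest.fixture(scope="session")
def rest_buffered(params):
    return ih.resting_state(params, "buffered")


@pytest.fixture(scope="session")
def sd_ep(params):
    """Buffered SD episode from a 10 s pump interruption."""
    return experiments.sd_episode(params)


@pytest.fixture(scope="session")
def dnk_branch(params, rest_closed):
    """Closed-model fixed-point branch in the potassium gain/loss."""
    return ih.continue_fixed_points(rest_closed, params, parameter="dNK",
                                    p_range=(-80.0, 60.0), direction=+1,
                                    max_points=8000)


@pytest.fixture(scope="session")
def kbath_branch(params):
    p = params.replace(K_bath=4.0)
    start = ih.resting_state(p, "bath")
    return ih.continue_fixed_points(start, p, parameter="K_bath",
                                    p_range=(2.0, 30.0), direction=+1,
                                    max_points=8000)


@pytest.fixture(scope="session")
def hopf_line(params):
    return ih.hopf_line_clamped_chloride([8, 12, 16, 20, 24, 28, 32], params)


@pytest.fixture(scope="session")
def sla_results(params):
    """0.25 mM bath sweep across the burst window."""
    return experiments.sla_sweep(params)


@pytest.fixture(scope="session")
def sd_results(params):
    """Long-window sweep across the periodic-SD regime."""
    return experiments.sd_sweep(params)


@pytest.fixture(scope="session")
def sd_branch_end_result(params):
    """Quasi-static downward bath ramp off the periodic-SD branch."""
    return experiments.sd_branch_end(params)


@pytest.fixture(scope="session")
def oracle_comparison(params, rest_buffered, sd_ep):
    """Redundant six-concentration integration vs the constrained run.

    All six concentrations are integrated as independent ODEs (LSODA,
    rtol 1e-12) with the species fluxes of the model — sodium via the
    electroneutral flux identity — and compared pointwise against the
    constrained-algebra trajectory over an SD episode.  Returns per-species
    maximal absolute differences outside and inside the ignition/flurry
    window, plus the repolarization-time difference.
    """
    from scipy.integrate import solve_ivp
    from ionhh import membrane
    from ionhh.reservoirs import buffer_rate

    p = params

    def make_rhs(pump_on):
        def rhs(t, y):
            V, n, Na_i, Na_e, K_i, K_e, Cl_i, Cl_e, dNK, B = y
            E_Na = p.RTF * np.log(Na_e / Na_i)
            E_K = p.RTF * np.log(K_e / K_i)
            E_Cl = -p.RTF * np.log(Cl_e / Cl_i)
            I_Na, I_K, I_Cl, _ = membrane.currents_raw(
                V, n, Na_i, K_e, E_Na, E_K, E_Cl, p, pump_on=pump_on)
            an = membrane.alpha_n(V)
            bn = membrane.beta_n(V)
            gow = p.gamma_over_wi * 1000.0
            r = p.vol_ratio
            dB = -buffer_rate(K_e, p) * K_e * B + p.lambda_bb * (p.B0 - B)
            dK_i = -gow * I_K
            dCl_i = gow * I_Cl
            dNa_i = gow * (I_K + I_Cl)  # electroneutral flux identity
            return [-(I_Na + I_K + I_Cl) / p.Cm * 1000.0,
                    p.phi * (an * (1 - n) - bn * n) * 1000.0,
                    dNa_i, -r * dNa_i, dK_i, -r * dK_i + dB,
                    dCl_i, -r * dCl_i, dB, dB]
        return rhs

    d0 = ih.dependent_state(rest_buffered, p)
    y = np.array([rest_buffered.V, rest_buffered.n, d0.Na_i, d0.Na_e,
                  rest_buffered.K_i, d0.K_e, rest_buffered.Cl_i, d0.Cl_e,
                  rest_buffered.dNK, rest_buffered.B])
    # a round stop time keeps the output grids of the two runs aligned, so
    # the comparison is solver error, not interpolation of spiky signals
    t_stop = np.floor((sd_ep.offset - 1.0) * 10.0) / 10.0
    ts, ys = [], []
    for a, b, on in [(0.0, 10.0, True), (10.0, 20.0, False),
                     (20.0, t_stop, True)]:
        te = np.arange(a, b, 0.05)
        sol = solve_ivp(make_rhs(on), (a, b), y, method="LSODA",
                        rtol=1e-12, atol=1e-14,
                        t_eval=list(te) + [b], max_step=0.5)
        assert sol.status == 0, sol.message
        ts.append(sol.t[:-1])
        ys.append(sol.y[:, :-1])
        y = sol.y[:, -1]
    T = np.concatenate(ts)
    Y = np.concatenate(ys, axis=1)

    t_full = np.ceil(sd_ep.offset + 4.0)
    prot = ih.Protocol(pump_off_window=(10.0, 20.0), pump_ramp=1e-6)
    tr = ih.simulate(p, "buffered", protocol=prot, t_end=t_full,
                     dt_out=0.01, rtol=1e-11, atol=1e-13)
    d = tr.derived()
    series = {"Na_i": (2, d["Na_i"]), "Na_e": (3, d["Na_e"]),
              "K_i": (4, tr.K_i), "K_e": (5, tr.K_e),
              "Cl_i": (6, tr.Cl_i), "Cl_e": (7, d["Cl_e"])}
    flurry = (T >= 10.0) & (T <= 25.0)
    diffs = {}
    for name, (idx, s) in series.items():
        diff = np.abs(np.interp(T, tr.times, s) - Y[idx])
        diffs[name] = (float(diff[~flurry].max()), float(diff[flurry].max()))

    # repolarization times of both tight runs, each from its own V series
    sol_tail = solve_ivp(make_rhs(True), (t_stop, t_full), y,
                         method="LSODA", rtol=1e-12, atol=1e-14,
                         t_eval=np.arange(t_stop, t_full, 0.01),
                         max_step=0.5)

    def downcross(tt, vv):
        idx = np.nonzero((vv[:-1] > -50.0) & (vv[1:] <= -50.0))[0]
        return float(tt[idx[0]]) if len(idx) else np.nan

    t_off_oracle = downcross(sol_tail.t, sol_tail.y[0])
    late = tr.times > 50.0
    t_off_constrained = downcross(tr.times[late], tr.V[late])
    return {"diffs": diffs,
            "offset_constrained": t_off_constrained,
            "offset_oracle": t_off_oracle}
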