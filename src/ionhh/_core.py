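"""Compiled right-hand side and adaptive integrator.

Everything here works in raw arrays and model units (ms, mV, mM, uA/cm^2);
the friendly layer lives in :mod:`ionhh.dynamics`.  The integrator is an
adaptive Dormand-Prince 5(4) loop with

* output sampled on a caller-supplied time grid (linear interpolation across
  accepted steps; the grid is chosen fine enough for the slow variables),
* upward threshold-crossing detection for spikes recorded at interpolated
  crossing times, independent of the output grid.

An explicit method is adequate: sodium activation is adiabatic, so the
stiffest remaining rate is the membrane time constant (sub-millisecond only
during spikes and depolarized plateaus, where accuracy demands small steps
anyway).
"""

from __future__ import annotations

import numba as nb
import numpy as np

from .params import ModelParams

# --- parameter-vector layout -------------------------------------------------
(IP_CM, IP_PHI, IP_GNAL, IP_GNAG, IP_GKL, IP_GKG, IP_GCLL, IP_RHO,
 IP_NAI0, IP_NAE0, IP_KI0, IP_KE0, IP_CLI0, IP_CLE0,
 IP_VR, IP_GOW, IP_RTF,
 IP_LBUF, IP_LBB, IP_LDIFF, IP_KBATH, IP_B0,
 IP_KBRATE, IP_BUFMID, IP_BUFSTEEP, IP_CLAMPCL) = range(26)
N_PAR = 26

#: variant codes
V_CLOSED, V_BUFFERED, V_BATH = 0, 1, 2
VARIANT_CODES = {"closed": V_CLOSED, "buffered": V_BUFFERED, "bath": V_BATH}

#: protocol-vector layout: pump-off window + smooth ramp, square stim pulse
(PR_PUMP_T0, PR_PUMP_T1, PR_PUMP_RAMP, PR_STIM_T0, PR_STIM_T1, PR_STIM_AMP) = range(6)
N_PROT = 6

MS_PER_S = 1000.0


def pack_params(p: ModelParams, kbath_rate_per_s: float = 0.0,
                clamp_cl: bool = False) -> np.ndarray:
    """Pack a ModelParams into the flat vector; per-second reservoir rates
    are converted to per-millisecond here."""
    pa = np.zeros(N_PAR)
    pa[IP_CM] = p.Cm
    pa[IP_PHI] = p.phi
    pa[IP_GNAL] = p.gNa_l
    pa[IP_GNAG] = p.gNa_g
    pa[IP_GKL] = p.gK_l
    pa[IP_GKG] = p.gK_g
    pa[IP_GCLL] = p.gCl_l
    pa[IP_RHO] = p.rho_pump
    pa[IP_NAI0] = p.Na_i0
    pa[IP_NAE0] = p.Na_e0
    pa[IP_KI0] = p.K_i0
    pa[IP_KE0] = p.K_e0
    pa[IP_CLI0] = p.Cl_i0
    pa[IP_CLE0] = p.Cl_e0
    pa[IP_VR] = p.vol_ratio
    pa[IP_GOW] = p.gamma_over_wi
    pa[IP_RTF] = p.RTF
    pa[IP_LBUF] = p.lambda_buf / MS_PER_S
    pa[IP_LBB] = p.lambda_bb / MS_PER_S
    pa[IP_LDIFF] = p.lambda_diff / MS_PER_S
    pa[IP_KBATH] = p.K_bath
    pa[IP_B0] = p.B0
    pa[IP_KBRATE] = kbath_rate_per_s / MS_PER_S  # mM/s -> mM/ms
    pa[IP_BUFMID] = p.buf_mid
    pa[IP_BUFSTEEP] = p.buf_steep
    pa[IP_CLAMPCL] = 1.0 if clamp_cl else 0.0
    return pa


def no_protocol() -> np.ndarray:
    prot = np.zeros(N_PROT)
    prot[PR_PUMP_T1] = -1.0  # inactive (t1 < t0)
    prot[PR_STIM_T1] = -1.0
    return prot


@nb.njit(inline="always")
def _pump_factor(t: float, prot: np.ndarray) -> float:
    t0 = prot[PR_PUMP_T0]
    t1 = prot[PR_PUMP_T1]
    ramp = prot[PR_PUMP_RAMP]
    if t1 <= t0:
        return 1.0
    if t <= t0 or t >= t1 + ramp:
        return 1.0
    if t < t0 + ramp:
        s = (t - t0) / ramp
        return 1.0 - s * s * (3.0 - 2.0 * s)
    if t <= t1:
        return 0.0
    s = (t - t1) / ramp
    return s * s * (3.0 - 2.0 * s)


@nb.njit
def rhs(t: float, y: np.ndarray, pa: np.ndarray, variant: int,
        prot: np.ndarray, dy: np.ndarray) -> int:
    """Time derivative of [V, n, K_i, Cl_i, dNK, B] (per ms).

    Returns 0 on success, 1 if a derived concentration left the positive
    domain (the caller treats this like a failed step).
    """
    V = y[0]
    n = y[1]
    K_i = y[2]
    Cl_i = y[3]
    dNK = y[4]
    B = y[5]

    # constraint algebra
    Na_i = pa[IP_NAI0] + (pa[IP_KI0] - K_i) + (Cl_i - pa[IP_CLI0])
    r = pa[IP_VR]
    Na_e = pa[IP_NAE0] - r * (Na_i - pa[IP_NAI0])
    K_e = pa[IP_KE0] - r * (K_i - pa[IP_KI0]) + dNK
    Cl_e = pa[IP_CLE0] - r * (Cl_i - pa[IP_CLI0])
    if Na_i <= 0.0 or Na_e <= 0.0 or K_e <= 0.0 or Cl_e <= 0.0 \
            or K_i <= 0.0 or Cl_i <= 0.0:
        return 1

    RTF = pa[IP_RTF]
    E_Na = RTF * np.log(Na_e / Na_i)
    E_K = RTF * np.log(K_e / K_i)
    E_Cl = -RTF * np.log(Cl_e / Cl_i)

    # gating (removable singularities via series within 1e-7)
    x = 0.1 * (V + 30.0)
    if abs(x) < 1e-7:
        am = 1.0 + 0.5 * x
    else:
        am = x / (-np.expm1(-x))
    bm = 4.0 * np.exp(-(V + 55.0) / 18.0)
    x = 0.1 * (V + 34.0)
    if abs(x) < 1e-7:
        an = 0.1 * (1.0 + 0.5 * x)
    else:
        an = 0.1 * x / (-np.expm1(-x))
    bn = 0.125 * np.exp(-(V + 44.0) / 80.0)
    m = am / (am + bm)
    h = 1.1 - 1.0 / (1.0 + np.exp(-8.0 * (n - 0.4)))

    Ip = _pump_factor(t, prot) * pa[IP_RHO] \
        / (1.0 + np.exp((25.0 - Na_i) / 3.0)) \
        / (1.0 + np.exp(5.5 - K_e))

    I_Na = (pa[IP_GNAL] + pa[IP_GNAG] * m * m * m * h) * (V - E_Na) + 3.0 * Ip
    I_K = (pa[IP_GKL] + pa[IP_GKG] * n * n * n * n) * (V - E_K) - 2.0 * Ip
    if pa[IP_CLAMPCL] != 0.0:
        I_Cl = 0.0
    else:
        I_Cl = pa[IP_GCLL] * (V - E_Cl)

    I_stim = 0.0
    if prot[PR_STIM_T0] <= t < prot[PR_STIM_T1]:
        I_stim = prot[PR_STIM_AMP]

    gow = pa[IP_GOW]
    dy[0] = (-(I_Na + I_K + I_Cl) + I_stim) / pa[IP_CM]
    dy[1] = pa[IP_PHI] * (an * (1.0 - n) - bn * n)
    dy[2] = -gow * I_K
    if pa[IP_CLAMPCL] != 0.0:
        dy[3] = 0.0
    else:
        dy[3] = gow * I_Cl

    if variant == 1:  # glial buffer
        lam_k = pa[IP_LBUF] / (1.0 + np.exp((pa[IP_BUFMID] - K_e) / pa[IP_BUFSTEEP]))
        dB = -lam_k * K_e * B + pa[IP_LBB] * (pa[IP_B0] - B)
        dy[4] = dB
        dy[5] = dB
    elif variant == 2:  # bath coupling (with optional slow ramp of K_bath)
        kb = pa[IP_KBATH] + pa[IP_KBRATE] * t
        dy[4] = pa[IP_LDIFF] * (kb - K_e)
        dy[5] = 0.0
    else:
        dy[4] = 0.0
        dy[5] = 0.0
    return 0


# Dormand-Prince 5(4) tableau
_C = np.array([0.0, 1.0 / 5.0, 3.0 / 10.0, 4.0 / 5.0, 8.0 / 9.0, 1.0, 1.0])
_A = np.zeros((7, 7))
_A[1, 0] = 1.0 / 5.0
_A[2, :2] = (3.0 / 40.0, 9.0 / 40.0)
_A[3, :3] = (44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0)
_A[4, :4] = (19372.0 / 6561.0, -25360.0 / 2187.0, 64448.0 / 6561.0, -212.0 / 729.0)
_A[5, :5] = (9017.0 / 3168.0, -355.0 / 33.0, 46732.0 / 5247.0, 49.0 / 176.0,
             -5103.0 / 18656.0)
_A[6, :6] = (35.0 / 384.0, 0.0, 500.0 / 1113.0, 125.0 / 192.0, -2187.0 / 6784.0,
             11.0 / 84.0)
_B5 = _A[6].copy()  # 5th order solution
_B4 = np.array([5179.0 / 57600.0, 0.0, 7571.0 / 16695.0, 393.0 / 640.0,
                -92097.0 / 339200.0, 187.0 / 2100.0, 1.0 / 40.0])

STATUS_OK = 0
STATUS_MAX_STEPS = 1
STATUS_DOMAIN = 2
STATUS_DT_UNDERFLOW = 3


@nb.njit
def integrate_segment(y0: np.ndarray, t0: float, t1: float,
                      pa: np.ndarray, variant: int, prot: np.ndarray,
                      rtol: float, atol: float, dt_max: float,
                      t_samples: np.ndarray, ys_out: np.ndarray,
                      spike_times: np.ndarray, n_spikes_in: int,
                      spike_thresh: float, spike_refract: float,
                      max_steps: int):
    """Integrate from t0 to t1 (ms), filling ``ys_out`` at ``t_samples`` and
    appending spike times.  Returns (status, y_end, n_spikes, n_steps)."""
    y = y0.copy()
    dy = np.zeros(6)
    k = np.zeros((7, 6))
    ytmp = np.zeros(6)
    ynew = np.zeros(6)
    yerr = np.zeros(6)

    n_samp = t_samples.shape[0]
    isamp = 0
    nspk = n_spikes_in
    max_spk = spike_times.shape[0]
    last_spike = -1e30
    if nspk > 0:
        last_spike = spike_times[nspk - 1]

    t = t0
    dt = min(0.01, t1 - t0)
    nsteps = 0
    # sample anything at/before t0
    while isamp < n_samp and t_samples[isamp] <= t0:
        for j in range(6):
            ys_out[isamp, j] = y[j]
        isamp += 1

    err_prev = 1.0
    while t < t1:
        if nsteps >= max_steps:
            return STATUS_MAX_STEPS, y, nspk, nsteps
        if dt > dt_max:
            dt = dt_max
        if t + dt > t1:
            dt = t1 - t

        bad = rhs(t, y, pa, variant, prot, dy)
        if bad != 0:
            return STATUS_DOMAIN, y, nspk, nsteps
        for j in range(6):
            k[0, j] = dy[j]

        failed = False
        for s in range(1, 7):
            for j in range(6):
                acc = 0.0
                for q in range(s):
                    acc += _A[s, q] * k[q, j]
                ytmp[j] = y[j] + dt * acc
            bad = rhs(t + _C[s] * dt, ytmp, pa, variant, prot, dy)
            if bad != 0:
                failed = True
                break
            for j in range(6):
                k[s, j] = dy[j]

        if not failed:
            err = 0.0
            for j in range(6):
                acc5 = 0.0
                acc4 = 0.0
                for s in range(7):
                    acc5 += _B5[s] * k[s, j]
                    acc4 += _B4[s] * k[s, j]
                ynew[j] = y[j] + dt * acc5
                e = dt * (acc5 - acc4)
                sc = atol + rtol * max(abs(y[j]), abs(ynew[j]))
                err += (e / sc) ** 2
            err = np.sqrt(err / 6.0)
            if not np.isfinite(err):
                failed = True

        if failed:
            dt *= 0.25
            if dt < 1e-12:
                return STATUS_DT_UNDERFLOW, y, nspk, nsteps
            continue

        if err <= 1.0:
            # accepted
            t_new = t + dt
            # spike detection: upward crossing of threshold
            if y[0] < spike_thresh <= ynew[0]:
                frac = (spike_thresh - y[0]) / (ynew[0] - y[0])
                t_sp = t + frac * dt
                if t_sp - last_spike > spike_refract and nspk < max_spk:
                    spike_times[nspk] = t_sp
                    nspk += 1
                    last_spike = t_sp
            # output sampling (linear within the step)
            while isamp < n_samp and t_samples[isamp] <= t_new:
                ts = t_samples[isamp]
                w = (ts - t) / dt if dt > 0 else 0.0
                for j in range(6):
                    ys_out[isamp, j] = y[j] + w * (ynew[j] - y[j])
                isamp += 1
            for j in range(6):
                y[j] = ynew[j]
            t = t_new
            nsteps += 1
            # PI step-size control
            fac = 0.9 * err ** (-0.7 / 5.0) * err_prev ** (0.4 / 5.0)
            if fac > 5.0:
                fac = 5.0
            if fac < 0.2:
                fac = 0.2
            dt *= fac
            err_prev = max(err, 1e-10)
        else:
            fac = max(0.2, 0.9 * err ** (-0.2))
            dt *= fac
            if dt < 1e-12:
                return STATUS_DT_UNDERFLOW, y, nspk, nsteps

    # trailing samples exactly at t1
    while isamp < n_samp and t_samples[isamp] <= t1 + 1e-9:
        for j in range(6):
            ys_out[isamp, j] = y[j]
        isamp += 1
    return STATUS_OK, y, nspk, nsteps


def rhs_py(t: float, y: np.ndarray, pa: np.ndarray, variant: int,
           prot: np.ndarray) -> np.ndarray:
    """Convenience wrapper around the compiled RHS returning a fresh array.

    Raises if the state is outside the positive-concentration domain.
    """
    dy = np.zeros(6)
    bad = rhs(float(t), np.asarray(y, float), pa, int(variant), prot, dy)
    if bad != 0:
        raise FloatingPointError("state outside the physical domain")
    return dy
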