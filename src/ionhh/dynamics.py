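"""Full model assembly: protocols, integration, trajectories, SD metrics.

Public time units are seconds (slow ion dynamics is what this package is
about); the integrator core works in milliseconds internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _core, membrane, reservoirs
from ._core import MS_PER_S, VARIANT_CODES
from .params import ModelParams
from .state import DynamicState, dependent_state

__all__ = ["Protocol", "Trajectory", "rhs", "simulate", "resting_state",
           "depolarization_metrics", "DepolarizationPhase", "IntegrationError"]


class IntegrationError(RuntimeError):
    def __init__(self, msg: str, last_state: Optional[DynamicState] = None,
                 last_time: Optional[float] = None):
        super().__init__(msg)
        self.last_state = last_state
        self.last_time = last_time


@dataclass
class Protocol:
    """Stimulation protocol.

    pump_off_window : (t_start, t_end) in s — Na/K pump current gated to zero
        inside the window, with a smooth 1 ms ramp at both edges.
    K_bolus : (time s, dK mM) — dK added instantaneously to the potassium
        gain/loss dNK (i.e. to the ECS potassium content), dK >= 0.
    I_stim : (onset s, duration s, amplitude uA/cm^2) square current pulse.
    kbath_ramp_rate : mM/s, linear drift of the bath concentration
        (bath variant only; quasi-static parameter ramps).
    """

    pump_off_window: Optional[tuple[float, float]] = None
    K_bolus: Optional[tuple[float, float]] = None
    I_stim: Optional[tuple[float, float, float]] = None
    pump_ramp: float = 1e-3
    kbath_ramp_rate: float = 0.0

    def validate(self, t_end: float) -> None:
        if self.pump_off_window is not None:
            a, b = self.pump_off_window
            if not (0.0 <= a < b <= t_end):
                raise ValueError(f"pump_off_window {self.pump_off_window} outside [0, {t_end}]")
        if self.K_bolus is not None:
            t, dk = self.K_bolus
            if not (0.0 <= t <= t_end):
                raise ValueError(f"K_bolus time {t} outside [0, {t_end}]")
            if dk < 0:
                raise ValueError("K_bolus amount must be >= 0")
        if self.I_stim is not None:
            t0, dur, _ = self.I_stim
            if not (0.0 <= t0 and t0 + dur <= t_end and dur > 0):
                raise ValueError(f"I_stim window outside [0, {t_end}]")

    def to_vector(self) -> np.ndarray:
        prot = _core.no_protocol()
        if self.pump_off_window is not None:
            prot[_core.PR_PUMP_T0] = self.pump_off_window[0] * MS_PER_S
            prot[_core.PR_PUMP_T1] = self.pump_off_window[1] * MS_PER_S
            prot[_core.PR_PUMP_RAMP] = self.pump_ramp * MS_PER_S
        if self.I_stim is not None:
            t0, dur, amp = self.I_stim
            prot[_core.PR_STIM_T0] = t0 * MS_PER_S
            prot[_core.PR_STIM_T1] = (t0 + dur) * MS_PER_S
            prot[_core.PR_STIM_AMP] = amp
        return prot

    def breakpoints(self, t_end: float) -> list[float]:
        """Times (s) where the RHS is non-smooth; integration restarts there."""
        pts = set()
        if self.pump_off_window is not None:
            a, b = self.pump_off_window
            pts.update((a, a + self.pump_ramp, b, b + self.pump_ramp))
        if self.K_bolus is not None:
            pts.add(self.K_bolus[0])
        if self.I_stim is not None:
            t0, dur, _ = self.I_stim
            pts.update((t0, t0 + dur))
        return sorted(t for t in pts if 0.0 < t < t_end)


def rhs(t: float, state: DynamicState, params: ModelParams,
        protocol: Optional[Protocol] = None) -> np.ndarray:
    """Reference right-hand side d/dt [V, n, K_i, Cl_i, dNK, B] (per second),
    assembled from the membrane and reservoir modules.

    ``t`` in seconds.  This is the readable counterpart of the compiled core
    RHS; the two are cross-checked in the test suite.
    """
    pump_on = True
    I_stim = 0.0
    if protocol is not None:
        if protocol.pump_off_window is not None:
            a, b = protocol.pump_off_window
            if a + protocol.pump_ramp <= t <= b:
                pump_on = False
        if protocol.I_stim is not None:
            t0, dur, amp = protocol.I_stim
            if t0 <= t < t0 + dur:
                I_stim = amp

    der = dependent_state(state, params, pump_on=pump_on)
    dy = np.zeros(6)
    # membrane equations are per ms; convert to per s
    dy[0] = (-(der.I_Na + der.I_K + der.I_Cl) + I_stim) / params.Cm * MS_PER_S
    an = membrane.alpha_n(state.V)
    bn = membrane.beta_n(state.V)
    dy[1] = params.phi * (an * (1.0 - state.n) - bn * state.n) * MS_PER_S
    gow = params.gamma_over_wi
    dy[2] = -gow * der.I_K * MS_PER_S
    dy[3] = gow * der.I_Cl * MS_PER_S
    if state.variant != "closed":
        d_dNK, d_B = reservoirs.reservoir_rhs(state, der, params)
        dy[4] = d_dNK
        dy[5] = d_B
    return dy


@dataclass
class Trajectory:
    """Time-stamped integrated states plus derived quantities.

    ``times`` in seconds, ``y`` the raw sample matrix with columns
    (V, n, K_i, Cl_i, dNK, B), ``spike_times`` in seconds (upward 0 mV
    crossings detected inside the integrator, refractory 2 ms).
    """

    times: np.ndarray
    y: np.ndarray
    variant: str
    params: ModelParams
    protocol: Optional[Protocol] = None
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("trajectory times must be strictly increasing")

    # raw columns
    @property
    def V(self) -> np.ndarray:
        return self.y[:, 0]

    @property
    def n(self) -> np.ndarray:
        return self.y[:, 1]

    @property
    def K_i(self) -> np.ndarray:
        return self.y[:, 2]

    @property
    def Cl_i(self) -> np.ndarray:
        return self.y[:, 3]

    @property
    def dNK(self) -> np.ndarray:
        return self.y[:, 4]

    @property
    def B(self) -> np.ndarray:
        return self.y[:, 5]

    # derived columns (vectorized constraint algebra)
    def derived(self) -> dict[str, np.ndarray]:
        p = self.params
        r = p.vol_ratio
        Na_i = p.Na_i0 + (p.K_i0 - self.K_i) + (self.Cl_i - p.Cl_i0)
        Na_e = p.Na_e0 - r * (Na_i - p.Na_i0)
        K_e = p.K_e0 - r * (self.K_i - p.K_i0) + self.dNK
        Cl_e = p.Cl_e0 - r * (self.Cl_i - p.Cl_i0)
        E_Na = p.RTF * np.log(Na_e / Na_i)
        E_K = p.RTF * np.log(K_e / self.K_i)
        E_Cl = -p.RTF * np.log(Cl_e / self.Cl_i)
        Ip = membrane.pump_current(Na_i, K_e, p)
        m_inf, n_inf, tau_n, h = membrane.gating(self.V, self.n, p)
        I_Na = (p.gNa_l + p.gNa_g * m_inf ** 3 * h) * (self.V - E_Na) + 3.0 * Ip
        I_K = (p.gK_l + p.gK_g * self.n ** 4) * (self.V - E_K) - 2.0 * Ip
        I_Cl = p.gCl_l * (self.V - E_Cl)
        return {"Na_i": Na_i, "Na_e": Na_e, "K_e": K_e, "Cl_e": Cl_e,
                "E_Na": E_Na, "E_K": E_K, "E_Cl": E_Cl,
                "I_Na": I_Na, "I_K": I_K, "I_Cl": I_Cl, "Ip": Ip}

    @property
    def K_e(self) -> np.ndarray:
        p = self.params
        return p.K_e0 - p.vol_ratio * (self.K_i - p.K_i0) + self.dNK

    def state_at(self, i: int) -> DynamicState:
        return DynamicState.from_vector(self.y[i], self.variant)

    def final_state(self) -> DynamicState:
        return self.state_at(-1)

    def to_frame(self) -> pd.DataFrame:
        d = self.derived()
        cols = {"t": self.times, "V": self.V, "n": self.n,
                "Na_i": d["Na_i"], "Na_e": d["Na_e"],
                "K_i": self.K_i, "K_e": d["K_e"],
                "Cl_i": self.Cl_i, "Cl_e": d["Cl_e"],
                "E_Na": d["E_Na"], "E_K": d["E_K"], "E_Cl": d["E_Cl"],
                "I_Na": d["I_Na"], "I_K": d["I_K"], "I_Cl": d["I_Cl"],
                "Ip": d["Ip"], "dNK": self.dNK, "B": self.B}
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")


def resting_state(params: ModelParams, variant: str = "closed",
                  dNK: float = 0.0, K_bath: Optional[float] = None,
                  tol: float = 1e-11) -> DynamicState:
    """Newton-polished resting fixed point of the requested variant.

    The reference concentrations are printed to two decimals only; every
    experiment starts from the machine-precision fixed point near them.
    For the buffered variant the conserved bookkeeping dNK - B = -B0 of the
    standard initial condition (dNK=0, B=B0) is imposed.
    """
    from .continuation import newton  # deferred import

    p = params if K_bath is None else params.replace(K_bath=K_bath)
    V0 = -p.RTF * math.log(p.Cl_e0 / p.Cl_i0)
    an, bn = membrane.alpha_n(V0), membrane.beta_n(V0)
    n0 = an / (an + bn)

    if variant == "closed":
        x0 = np.array([V0, n0, p.K_i0, p.Cl_i0])

        def f(x):
            st = DynamicState("closed", x[0], x[1], x[2], x[3], dNK=dNK)
            return rhs(0.0, st, p)[:4]

        x, _ = newton(f, x0, tol=tol)
        return DynamicState("closed", *x, dNK=dNK)

    if variant == "buffered":
        x0 = np.array([V0, n0, p.K_i0, p.Cl_i0, p.B0])

        def f(x):
            st = DynamicState("buffered", x[0], x[1], x[2], x[3],
                              dNK=x[4] - p.B0, B=x[4])
            dy = rhs(0.0, st, p)
            return np.array([dy[0], dy[1], dy[2], dy[3], dy[5]])

        x, _ = newton(f, x0, tol=tol)
        return DynamicState("buffered", x[0], x[1], x[2], x[3],
                            dNK=x[4] - p.B0, B=x[4])

    if variant == "bath":
        x0 = np.array([V0, n0, p.K_i0, p.Cl_i0, 0.0])

        def f(x):
            st = DynamicState("bath", x[0], x[1], x[2], x[3], dNK=x[4])
            return rhs(0.0, st, p)[:5]

        x, _ = newton(f, x0, tol=tol)
        return DynamicState("bath", *x)

    raise ValueError(f"unknown variant {variant!r}")


def simulate(params: ModelParams, variant: str = "closed",
             protocol: Optional[Protocol] = None, t_end: float = 100.0,
             initial_state: Optional[DynamicState] = None,
             dt_out: Optional[float] = None,
             rtol: float = 1e-8, atol: float = 1e-10,
             dt_max: float = 20.0,
             spike_threshold: float = 0.0, spike_refractory: float = 2.0,
             max_spikes: int = 2_000_000, max_steps: int = 400_000_000,
             ) -> Trajectory:
    """Integrate the model for ``t_end`` seconds.

    Starts from the Newton-polished resting state unless ``initial_state``
    is given.  ``dt_out`` (s) is the output sampling interval (default:
    t_end/20000, at most 50 ms — fine enough for the slow ionic envelope;
    pass e.g. 1e-4 to resolve individual spikes in V).  Spike times are
    always recorded at full resolution regardless of ``dt_out``.
    ``dt_max`` and the refractory period are in ms.
    """
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if variant not in VARIANT_CODES:
        raise ValueError(f"unknown variant {variant!r}")
    protocol = protocol or Protocol()
    protocol.validate(t_end)
    if protocol.kbath_ramp_rate != 0.0 and variant != "bath":
        raise ValueError("kbath_ramp_rate requires the bath variant")

    if initial_state is None:
        initial_state = resting_state(params, variant)
    if initial_state.variant != variant:
        raise ValueError("initial_state variant does not match")

    if dt_out is None:
        dt_out = min(0.05, t_end / 20000.0)
    n_out = int(round(t_end / dt_out)) + 1
    t_samples_s = np.linspace(0.0, t_end, n_out)

    pa = _core.pack_params(params, kbath_rate_per_s=protocol.kbath_ramp_rate)
    prot = protocol.to_vector()
    vcode = VARIANT_CODES[variant]

    edges_s = [0.0] + protocol.breakpoints(t_end) + [t_end]
    bolus_t = protocol.K_bolus[0] if protocol.K_bolus else None

    ys_out = np.full((n_out, 6), np.nan)
    spike_buf = np.empty(max_spikes)
    t_samples_ms = t_samples_s * MS_PER_S

    y = initial_state.to_vector()
    nspk = 0
    total_steps = 0
    for a, b in zip(edges_s[:-1], edges_s[1:]):
        if b <= a:
            continue
        if bolus_t is not None and math.isclose(a, bolus_t, abs_tol=1e-12):
            y = y.copy()
            y[4] += protocol.K_bolus[1]
        lo = np.searchsorted(t_samples_ms, a * MS_PER_S, side="right")
        hi = np.searchsorted(t_samples_ms, b * MS_PER_S, side="right")
        if a == 0.0:
            lo = 0
        seg_samples = t_samples_ms[lo:hi]
        seg_out = np.empty((len(seg_samples), 6))
        status, y, nspk, nsteps = _core.integrate_segment(
            y, a * MS_PER_S, b * MS_PER_S, pa, vcode, prot,
            rtol, atol, dt_max, seg_samples, seg_out,
            spike_buf, nspk, spike_threshold, spike_refractory,
            max_steps - total_steps)
        total_steps += nsteps
        ys_out[lo:hi] = seg_out
        if status != _core.STATUS_OK:
            last = DynamicState.from_vector(y, variant)
            raise IntegrationError(
                f"integration failed with status {status} "
                f"(1=max_steps, 2=left physical domain, 3=step underflow)",
                last_state=last, last_time=b)

    return Trajectory(times=t_samples_s, y=ys_out, variant=variant,
                      params=params, protocol=protocol,
                      spike_times=spike_buf[:nspk] / MS_PER_S)


@dataclass
class DepolarizationPhase:
    onset: float     # s
    offset: float    # s
    peak_K_e: float  # mM
    min_Na_e: float  # mM

    @property
    def duration(self) -> float:
        return self.offset - self.onset


def depolarization_metrics(traj: Trajectory, V_threshold: float = -50.0
                           ) -> list[DepolarizationPhase]:
    """Contiguous intervals with V above threshold, with per-episode peak
    extracellular potassium and minimal extracellular sodium.

    Crossing times are interpolated linearly between samples.  An episode
    still open at the end of the trajectory is closed at the final time.
    """
    t = traj.times
    V = traj.V
    d = traj.derived()
    above = V > V_threshold
    phases: list[DepolarizationPhase] = []
    i = 0
    n = len(t)
    while i < n:
        if not above[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and above[j + 1]:
            j += 1
        # interpolate crossings
        if i > 0:
            f = (V_threshold - V[i - 1]) / (V[i] - V[i - 1])
            onset = t[i - 1] + f * (t[i] - t[i - 1])
        else:
            onset = t[0]
        if j + 1 < n:
            f = (V_threshold - V[j]) / (V[j + 1] - V[j])
            offset = t[j] + f * (t[j + 1] - t[j])
        else:
            offset = t[-1]
        phases.append(DepolarizationPhase(
            onset=float(onset), offset=float(offset),
            peak_K_e=float(np.max(d["K_e"][i:j + 1])),
            min_Na_e=float(np.min(d["Na_e"][i:j + 1]))))
        i = j + 1
    return phases
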