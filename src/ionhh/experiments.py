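"""Canonical numerical experiments.

Each function builds its inputs from the reference parameter set, runs the
model, and measures one of the headline quantities: the duration of a
single spreading-depression episode, the oscillation periods of the
seizure-like-activity and periodic-SD regimes, the lower end of the SD
branch under a quasi-static bath ramp, and the intraburst spike rate
during SLA.  The same functions back the acceptance tests and the
command-line scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .dynamics import Protocol, Trajectory, depolarization_metrics, simulate
from .params import ModelParams, table1
from .regimes import (RegimeSummary, classify_regime, dynamics_resting,
                      spike_and_burst_stats)

__all__ = ["sd_episode", "sla_sweep", "sd_sweep", "sd_branch_end",
           "sla_burst_stats", "SDEpisode", "SDBranchEnd"]


@dataclass
class SDEpisode:
    duration: float     # s, longest depolarized phase (V > threshold)
    onset: float        # s
    offset: float       # s
    peak_K_e: float     # mM
    min_Na_e: float     # mM
    trajectory: Trajectory


def sd_episode(params: Optional[ModelParams] = None, t_end: float = 300.0,
               pump_off: tuple[float, float] = (10.0, 20.0),
               V_threshold: float = -50.0, rtol: float = 1e-8,
               atol: float = 1e-10, dt_out: float = 0.01) -> SDEpisode:
    """Single SD excursion in the glia-buffered model, triggered by a 10 s
    interruption of the pump current from the polished resting state.

    The reported duration is the longest contiguous interval with
    V > ``V_threshold`` (individual action potentials during the ignition
    flurry also cross the threshold but only for milliseconds).
    """
    p = params or table1()
    prot = Protocol(pump_off_window=pump_off)
    traj = simulate(p, variant="buffered", protocol=prot, t_end=t_end,
                    dt_out=dt_out, rtol=rtol, atol=atol)
    phases = depolarization_metrics(traj, V_threshold=V_threshold)
    if not phases:
        raise RuntimeError("no depolarized phase detected")
    main = max(phases, key=lambda ph: ph.duration)
    return SDEpisode(duration=main.duration, onset=main.onset,
                     offset=main.offset, peak_K_e=main.peak_K_e,
                     min_Na_e=main.min_Na_e, trajectory=traj)


def sla_sweep(params: Optional[ModelParams] = None,
              kb_values: Optional[Sequence[float]] = None,
              window: float = 600.0, transient: float = 250.0,
              rtol: float = 1e-8, atol: float = 1e-10,
              ) -> list[RegimeSummary]:
    """Sweep the bath concentration across the seizure-like-activity regime
    (0.25 mM steps around the burst window) from physiological cold starts
    and classify each trajectory."""
    p = params or table1()
    if kb_values is None:
        kb_values = np.arange(8.0, 11.01, 0.25)
    out = []
    for kb in kb_values:
        pp = p.replace(K_bath=float(kb))
        st = dynamics_resting(pp)
        traj = simulate(pp, variant="bath", t_end=transient + window,
                        initial_state=st, dt_out=0.05, rtol=rtol, atol=atol)
        out.append(classify_regime(traj, pp, parameter=float(kb),
                                   transient=transient))
    return out


def sd_sweep(params: Optional[ModelParams] = None,
             kb_values: Optional[Sequence[float]] = None,
             window: float = 4000.0, transient: float = 500.0,
             rtol: float = 1e-8, atol: float = 1e-10,
             ) -> list[RegimeSummary]:
    """Sweep the bath concentration across the periodic-SD regime with
    windows long enough (>= 4000 s after transient) to resolve several
    350-550 s ion cycles."""
    p = params or table1()
    if kb_values is None:
        kb_values = np.arange(14.0, 20.01, 1.0)
    out = []
    for kb in kb_values:
        pp = p.replace(K_bath=float(kb))
        st = dynamics_resting(pp)
        traj = simulate(pp, variant="bath", t_end=transient + window,
                        initial_state=st, dt_out=0.1, rtol=rtol, atol=atol)
        out.append(classify_regime(traj, pp, parameter=float(kb),
                                   transient=transient))
    return out


@dataclass
class SDBranchEnd:
    K_bath_end: float          # mM, bath level at the last full SD cycle
    ramp_rate: float           # mM/s (signed)
    peak_K_bath_values: np.ndarray

    def __repr__(self) -> str:  # pragma: no cover
        return (f"SDBranchEnd(K_bath_end={self.K_bath_end:.3f}, "
                f"ramp_rate={self.ramp_rate})")


def sd_branch_end(params: Optional[ModelParams] = None,
                  kb_start: float = 14.0, kb_stop: float = 11.0,
                  ramp_rate: float = 5e-4, settle: float = 1500.0,
                  rtol: float = 1e-8, atol: float = 1e-10) -> SDBranchEnd:
    """Lower end of the periodic-SD branch under a slow downward bath ramp.

    The model is first settled onto the periodic-SD attractor at
    ``kb_start``, then the bath concentration is ramped down at
    ``ramp_rate`` (mM/s, well inside the quasi-static regime: halving the
    rate moves the detected end by only a few 1e-3 mM).  The branch end is
    the bath concentration at the last large-amplitude (prominence > 10 mM)
    K_e excursion before the oscillation collapses to tonic firing.
    """
    p = (params or table1()).replace(K_bath=kb_start)
    st = dynamics_resting(p)
    settle_traj = simulate(p, variant="bath", t_end=settle, initial_state=st,
                           dt_out=0.1, rtol=rtol, atol=atol)
    if settle_traj.K_e.max() < p.K_e0 + 10.0:
        raise RuntimeError(f"no periodic SD at K_bath={kb_start}")
    t_ramp = (kb_start - kb_stop) / ramp_rate
    prot = Protocol(kbath_ramp_rate=-ramp_rate)
    traj = simulate(p, variant="bath", protocol=prot, t_end=t_ramp,
                    initial_state=settle_traj.final_state(), dt_out=0.1,
                    rtol=rtol, atol=atol)
    smooth = uniform_filter1d(traj.K_e, 10, mode="nearest")
    peaks, _ = find_peaks(smooth, prominence=10.0)
    if len(peaks) == 0:
        raise RuntimeError("no SD cycles during the ramp")
    kb_at_peaks = kb_start - ramp_rate * traj.times[peaks]
    return SDBranchEnd(K_bath_end=float(kb_at_peaks[-1]),
                       ramp_rate=-ramp_rate,
                       peak_K_bath_values=kb_at_peaks)


def sla_burst_stats(params: Optional[ModelParams] = None,
                    K_bath: float = 9.5, t_end: float = 400.0,
                    transient: float = 100.0, rtol: float = 1e-8,
                    atol: float = 1e-10):
    """Spike/burst statistics at a bath concentration inside the SLA regime
    (>= 300 s analysed; spike times recorded at integrator resolution)."""
    p = (params or table1()).replace(K_bath=K_bath)
    st = dynamics_resting(p)
    traj = simulate(p, variant="bath", t_end=t_end, initial_state=st,
                    dt_out=0.05, rtol=rtol, atol=atol)
    spikes = traj.spike_times[traj.spike_times >= transient]
    return spike_and_burst_stats(spikes)
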