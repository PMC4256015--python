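"""Detection and classification of oscillatory regimes.

The bath-coupled model shows, depending on the bath concentration: resting,
tonic firing (almost constant ion concentrations), seizure-like activity
(SLA: bursts riding on a moderate slow ion oscillation), periodic spreading
depression (large-amplitude slow ion oscillation visiting FES-like peaks),
and the permanently depolarized FES state itself.  All regimes are detected
from simulated trajectories; stable branches are tracked quasi-statically
by sweeping the bath concentration with attractor hand-over.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

from .dynamics import Trajectory, simulate
from .params import ModelParams
from .state import DynamicState

__all__ = ["SpikeStats", "spike_and_burst_stats", "slow_oscillation_period",
           "RegimeSummary", "classify_regime", "track_branch_by_ramp",
           "TONIC_KE_AMPLITUDE", "SD_KE_AMPLITUDE", "BURST_GAP_FACTOR"]

#: K_e peak-to-peak below which spiking counts as tonic (mM)
TONIC_KE_AMPLITUDE = 0.5
#: K_e peak-to-peak at/above which a slow oscillation counts as SD-scale (mM)
SD_KE_AMPLITUDE = 10.0
#: a gap longer than this multiple of the median ISI separates bursts
BURST_GAP_FACTOR = 5.0
#: resting classification: |K_e - reference| below this (mM)
RESTING_KE_TOL = 1.0


@dataclass
class SpikeStats:
    n_spikes: int
    n_bursts: int
    burst_spike_counts: list[int]
    intraburst_freq: Optional[float]   # Hz, mean reciprocal intraburst ISI
    mean_rate: Optional[float]         # Hz over the analysed window
    bursts: list[np.ndarray] = field(default_factory=list)


def spike_and_burst_stats(traj: Trajectory | np.ndarray,
                          gap_factor: float = BURST_GAP_FACTOR) -> SpikeStats:
    """Spike and burst statistics from a trajectory's spike times.

    Spikes are the upward 0 mV crossings recorded by the integrator
    (refractory 2 ms).  Spikes are grouped into bursts wherever the gap
    exceeds ``gap_factor`` times the median inter-spike interval; the
    intraburst frequency is the mean of 1/ISI within bursts.
    """
    spikes = traj.spike_times if isinstance(traj, Trajectory) else np.asarray(traj, float)
    n = len(spikes)
    if n == 0:
        return SpikeStats(0, 0, [], None, None)
    if n == 1:
        return SpikeStats(1, 1, [1], None, None)
    isi = np.diff(spikes)
    med = float(np.median(isi))
    cut = np.nonzero(isi > gap_factor * med)[0]
    bursts = np.split(spikes, cut + 1)
    intr = []
    for b in bursts:
        if len(b) >= 2:
            intr.extend(1.0 / np.diff(b))
    freq = float(np.mean(intr)) if intr else None
    span = spikes[-1] - spikes[0]
    rate = float((n - 1) / span) if span > 0 else None
    return SpikeStats(n, len(bursts), [len(b) for b in bursts], freq, rate,
                      bursts=list(bursts))


def slow_oscillation_period(traj: Trajectory | tuple[np.ndarray, np.ndarray],
                            smooth_window: float = 1.0,
                            amplitude_floor: float = TONIC_KE_AMPLITUDE,
                            ) -> Optional[float]:
    """Period (s) of the slow extracellular-potassium envelope, or None.

    Spike-scale content is removed with a moving average of ``smooth_window``
    seconds; the period is the mean interval between K_e peaks (prominence
    a quarter of the peak-to-peak amplitude).  Returns None when the K_e
    amplitude is below the tonic threshold; warns when fewer than three
    peaks support the estimate.
    """
    if isinstance(traj, Trajectory):
        t, ke = traj.times, traj.K_e
    else:
        t, ke = traj
    if len(t) < 8:
        return None
    dt = float(np.median(np.diff(t)))
    w = max(1, int(round(smooth_window / dt)))
    smooth = uniform_filter1d(np.asarray(ke, float), w, mode="nearest")
    amp = float(np.max(smooth) - np.min(smooth))
    if amp < amplitude_floor:
        return None
    dist = max(1, int(round(2.0 * smooth_window / dt)))
    peaks, _ = find_peaks(smooth, prominence=0.25 * amp, distance=dist)
    if len(peaks) < 2:
        return None
    if len(peaks) < 3:
        warnings.warn("slow-oscillation period estimated from fewer than 3 peaks")
    return float(np.mean(np.diff(t[peaks])))


@dataclass
class RegimeSummary:
    label: str                 # resting|tonic|SLA|periodic_SD|FES|ambiguous
    parameter: float           # e.g. the bath concentration (mM)
    n_spikes: int
    n_bursts: int
    intraburst_freq: Optional[float]  # Hz
    slow_period: Optional[float]      # s
    K_e_amplitude: float              # mM peak-to-peak (smoothed)
    K_e_max: float
    Na_e_min: float
    mean_V: float

    def to_dict(self) -> dict:
        return {k: (None if v is None else (float(v) if not isinstance(v, (str, int)) else v))
                for k, v in self.__dict__.items()}


def classify_regime(traj: Trajectory, params: ModelParams,
                    parameter: Optional[float] = None,
                    transient: Optional[float] = None) -> RegimeSummary:
    """Classify a (bath-variant) trajectory into one of the regimes.

    ``transient``: leading time span to discard (default: max(20% of the
    trajectory, 100 s)).  Decision rules: no spikes and K_e near reference
    -> resting; no spikes and depolarized -> FES; spiking with sub-0.5 mM
    K_e amplitude -> tonic; burst-modulated spiking with amplitude in
    [0.5, 10) mM -> SLA; slow oscillation with amplitude >= 10 mM visiting
    FES-like peaks -> periodic_SD; conflicting evidence -> ambiguous.
    """
    t_end = traj.times[-1] - traj.times[0]
    if transient is None:
        transient = max(0.2 * t_end, min(100.0, 0.5 * t_end))
    t0 = traj.times[0] + transient
    m = traj.times >= t0
    t = traj.times[m]
    ke = traj.K_e[m]
    d = traj.derived()
    nae = d["Na_e"][m]
    V = traj.V[m]
    spikes = traj.spike_times[traj.spike_times >= t0]

    stats = spike_and_burst_stats(spikes)
    period = slow_oscillation_period((t, ke))
    dt = float(np.median(np.diff(t)))
    w = max(1, int(round(1.0 / dt)))
    smooth = uniform_filter1d(np.asarray(ke, float), w, mode="nearest")
    amp = float(np.max(smooth) - np.min(smooth))

    if parameter is None:
        parameter = params.K_bath

    # the quiescent reference level: the bath pins K_e at K_bath, otherwise
    # the physiological reference applies
    ke_ref = params.K_bath if traj.variant == "bath" else params.K_e0
    label = "ambiguous"
    if stats.n_spikes == 0:
        if abs(float(np.mean(ke)) - ke_ref) < RESTING_KE_TOL and \
                float(np.mean(V)) < -55.0 and amp < TONIC_KE_AMPLITUDE:
            label = "resting"
        elif float(np.mean(V)) > -50.0:
            label = "FES"
    else:
        if amp < TONIC_KE_AMPLITUDE:
            label = "tonic"
        elif amp < SD_KE_AMPLITUDE:
            if stats.n_bursts >= 2:
                label = "SLA"
        else:
            if period is not None and float(np.max(ke)) > params.K_e0 + SD_KE_AMPLITUDE:
                label = "periodic_SD"

    return RegimeSummary(
        label=label, parameter=float(parameter),
        n_spikes=stats.n_spikes, n_bursts=stats.n_bursts,
        intraburst_freq=stats.intraburst_freq, slow_period=period,
        K_e_amplitude=amp, K_e_max=float(np.max(ke)),
        Na_e_min=float(np.min(nae)), mean_V=float(np.mean(V)))


def track_branch_by_ramp(params: ModelParams, values: Sequence[float],
                         window: float = 600.0, transient: float = 150.0,
                         initial_state: Optional[DynamicState] = None,
                         rtol: float = 1e-8, atol: float = 1e-10,
                         dt_out: float = 0.05,
                         ) -> list[RegimeSummary]:
    """Quasi-static sweep of the bath concentration with attractor hand-over.

    At each value in ``values`` (traversed in the given order, so an
    ascending list is an up-sweep and a descending list a down-sweep) the
    model is integrated for ``transient + window`` seconds starting from the
    final state of the previous value, and the post-transient window is
    classified.  The first value starts from the polished resting state
    unless ``initial_state`` is given.
    """
    out: list[RegimeSummary] = []
    state = initial_state
    for kb in values:
        p = params.replace(K_bath=float(kb))
        if state is None:
            state = dynamics_resting(p)
        traj = simulate(p, variant="bath", t_end=transient + window,
                        initial_state=state, dt_out=dt_out,
                        rtol=rtol, atol=atol)
        out.append(classify_regime(traj, p, parameter=float(kb),
                                   transient=transient))
        state = traj.final_state()
    return out


def dynamics_resting(params: ModelParams) -> DynamicState:
    """Bath-variant start state: the closed resting point lifted to the bath
    variant (dNK = 0).  For elevated bath concentrations this is simply a
    physiological cold start; the attractor reached is then classified."""
    from .dynamics import resting_state
    ref = params.replace(K_bath=params.K_e0)
    st = resting_state(ref, variant="bath")
    return DynamicState("bath", st.V, st.n, st.K_i, st.Cl_i, dNK=st.dNK)
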