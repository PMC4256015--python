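"""Potassium regulation by glial buffering or diffusive bath coupling.

Both schemes act on the potassium gain/loss variable dNK (per ECS volume):

* glial buffering: K_e + B <-> KB with a potassium-dependent forward rate
  lambda_k(K_e) and a constant (much slower) backward rate lambda_bb.  The
  free buffer B and dNK are both integrated; bound buffer is B0 - B, and
  dNK + (B0 - B) is conserved along trajectories (built-in solver check).
* bath coupling: d dNK/dt = lambda_diff * (K_bath - K_e).

Only one scheme is active per simulation, selected by the state variant.
"""

from __future__ import annotations

from typing import Union

import numpy as np

from .params import ModelParams
from .state import DynamicState, DerivedIonState

__all__ = ["buffer_rate", "reservoir_rhs"]

ArrayLike = Union[float, np.ndarray]


def buffer_rate(K_e: ArrayLike, params: ModelParams) -> ArrayLike:
    """Forward glial buffering rate lambda_k(K_e) in 1/(mM*s).

    Sigmoidal in K_e: negligible at the physiological resting level and
    saturating at lambda_buf for spreading-depression-level potassium, with
    midpoint ``buf_mid`` (15 mM) and steepness ``buf_steep`` (1.09 mM).
    """
    out = params.lambda_buf / (
        1.0 + np.exp((params.buf_mid - np.asarray(K_e, float)) / params.buf_steep))
    return out if np.ndim(out) else float(out)


def reservoir_rhs(state: DynamicState, derived: DerivedIonState,
                  params: ModelParams) -> tuple[float, float]:
    """Slow-variable rates ``(d dNK/dt, dB/dt)`` in mM/s.

    Buffered variant: dB/dt = -lambda_k(K_e)*K_e*B + lambda_bb*(B0 - B) and
    d dNK/dt = dB/dt (potassium bound by the buffer is the system's loss).
    Bath variant: d dNK/dt = lambda_diff*(K_bath - K_e), dB/dt unused (0).
    """
    if state.variant == "closed":
        raise ValueError("reservoir_rhs is undefined for the closed variant")
    K_e = derived.K_e
    if state.variant == "buffered":
        dB = (-buffer_rate(K_e, params) * K_e * state.B
              + params.lambda_bb * (params.B0 - state.B))
        return float(dB), float(dB)
    # bath
    d_dNK = params.lambda_diff * (params.K_bath - K_e)
    return float(d_dNK), 0.0
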