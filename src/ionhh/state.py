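"""Dynamic state, constraint algebra and the derived ionic state.

Only four membrane variables are integrated (V, n, K_i, Cl_i) plus up to two
slow reservoir variables (the potassium gain/loss dNK and the free buffer B).
The remaining four concentrations follow algebraically:

* Na_i from electroneutrality of transmembrane fluxes — the intracellular
  charge concentration Na_i + K_i - Cl_i stays at its reference value;
* Na_e, Cl_e from per-species mass conservation with the ICS/ECS volume ratio;
* K_e from potassium mass conservation plus the reservoir gain/loss dNK
  (expressed per ECS volume):  K_e = K_e0 - (w_i/w_e)(K_i - K_i0) + dNK.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np

from .params import ModelParams

__all__ = [
    "VARIANTS", "DynamicState", "DerivedIonState",
    "nernst_potential", "dependent_state", "PhysicalDomainError",
]

VARIANTS = ("closed", "buffered", "bath")


class PhysicalDomainError(ValueError):
    """A derived concentration came out non-positive: the state left the
    physically meaningful domain of the model."""


@dataclass
class DynamicState:
    """The integrated variables of one model variant.

    ``dNK`` is the potassium gained (positive) or lost (negative) by the
    neuron+ECS system through reservoirs, expressed as a concentration with
    respect to the ECS volume.  For the closed variant it is a fixed
    parameter; for the buffered and bath variants it is integrated.  ``B``
    (free glial buffer, per ECS volume) exists only in the buffered variant.
    """

    variant: str
    V: float
    n: float
    K_i: float
    Cl_i: float
    dNK: float = 0.0
    B: Optional[float] = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.variant == "buffered" and self.B is None:
            raise ValueError("buffered variant requires a buffer concentration B")

    def replace(self, **kw) -> "DynamicState":
        return replace(self, **kw)

    def to_vector(self) -> np.ndarray:
        """Pack into the 6-slot vector used by the integrator core."""
        return np.array(
            [self.V, self.n, self.K_i, self.Cl_i, self.dNK,
             self.B if self.B is not None else 0.0], dtype=float)

    @classmethod
    def from_vector(cls, y: np.ndarray, variant: str) -> "DynamicState":
        B = float(y[5]) if variant == "buffered" else None
        return cls(variant, float(y[0]), float(y[1]), float(y[2]), float(y[3]),
                   float(y[4]), B)


@dataclass
class DerivedIonState:
    """Concentrations, Nernst potentials, gating values and currents implied
    by a :class:`DynamicState` through the constraint algebra."""

    Na_i: float
    Na_e: float
    K_e: float
    Cl_e: float
    E_Na: float
    E_K: float
    E_Cl: float
    m_inf: float
    h: float
    n_inf: float
    tau_n: float
    I_Na: float
    I_K: float
    I_Cl: float
    Ip: float


def nernst_potential(z: int, c_in: float, c_out: float, params: ModelParams) -> float:
    """Nernst potential (mV) of an ion with valence ``z`` at concentrations
    ``c_in``/``c_out`` (mM): (RTF/z) * ln(c_out/c_in)."""
    if z not in (1, -1):
        raise ValueError(f"valence must be +1 or -1, got {z}")
    if not (c_in > 0 and c_out > 0):
        raise PhysicalDomainError(
            f"non-positive concentration in Nernst potential: c_in={c_in}, c_out={c_out}")
    return params.RTF / z * math.log(c_out / c_in)


def _derived_concentrations(K_i: float, Cl_i: float, dNK: float,
                            p: ModelParams) -> tuple[float, float, float, float]:
    r = p.vol_ratio
    Na_i = p.Na_i0 + (p.K_i0 - K_i) + (Cl_i - p.Cl_i0)
    Na_e = p.Na_e0 - r * (Na_i - p.Na_i0)
    K_e = p.K_e0 - r * (K_i - p.K_i0) + dNK
    Cl_e = p.Cl_e0 - r * (Cl_i - p.Cl_i0)
    return Na_i, Na_e, K_e, Cl_e


def dependent_state(state: DynamicState, params: ModelParams,
                    pump_on: bool = True) -> DerivedIonState:
    """Resolve the constraint algebra: full ionic state for a dynamic state.

    Raises :class:`PhysicalDomainError` if any derived concentration is
    non-positive.
    """
    from . import membrane  # deferred to avoid an import cycle

    Na_i, Na_e, K_e, Cl_e = _derived_concentrations(
        state.K_i, state.Cl_i, state.dNK, params)
    for name, c in (("Na_i", Na_i), ("Na_e", Na_e), ("K_i", state.K_i),
                    ("K_e", K_e), ("Cl_i", state.Cl_i), ("Cl_e", Cl_e)):
        if not (c > 0 and math.isfinite(c)):
            raise PhysicalDomainError(f"derived concentration {name}={c} is not positive")

    E_Na = nernst_potential(1, Na_i, Na_e, params)
    E_K = nernst_potential(1, state.K_i, K_e, params)
    E_Cl = nernst_potential(-1, state.Cl_i, Cl_e, params)
    m_inf, n_inf, tau_n, h = membrane.gating(state.V, state.n, params)
    I_Na, I_K, I_Cl, Ip = membrane.currents_raw(
        state.V, state.n, Na_i, K_e, E_Na, E_K, E_Cl, params, pump_on=pump_on)
    return DerivedIonState(
        Na_i=Na_i, Na_e=Na_e, K_e=K_e, Cl_e=Cl_e,
        E_Na=E_Na, E_K=E_K, E_Cl=E_Cl,
        m_inf=float(m_inf), h=float(h), n_inf=float(n_inf), tau_n=float(tau_n),
        I_Na=I_Na, I_K=I_K, I_Cl=I_Cl, Ip=Ip)
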