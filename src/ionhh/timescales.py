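"""Characteristic time scales of the model, and the GHK flux used for the
transmembrane ion time scale.

The hierarchy (for the reference parameters):

* membrane potential: tau_V = Cm / g_total, with gating-variable products in
  the gated conductances approximated by 0.1 — sub-millisecond;
* potassium activation: tau_n(V)/phi at the resting potential — milliseconds;
* transmembrane ion dynamics: tau_ion = omega_i / (A_mem * P) for a typical
  channel permeability P — seconds.  This follows from writing the ion rate
  equation with the Goldman-Hodgkin-Katz (GHK) flux, where the prefactor
  groups into a rate A*P/omega times a dimensionless function of u = zV/RTF
  and the concentrations;
* forward glial buffering: 1/(lambda_buf * B0) — tens of seconds;
* diffusive bath exchange: 1/lambda_diff — tens of seconds;
* backward buffering: 1/lambda_bb — hours.

GHK currents appear only here; the dynamical equations use Nernst-form
currents throughout.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np

from . import membrane
from .params import ModelParams
from .state import PhysicalDomainError

__all__ = ["ghk_current", "characteristic_timescales", "TimescaleReport"]


def ghk_current(V, c_in, c_out, z: int, P: float, params: ModelParams):
    """Goldman-Hodgkin-Katz current density (uA/cm^2).

    I = P * z * F * u * (c_in - c_out * exp(-u)) / (1 - exp(-u)),
    u = z*V/RTF.  With P in cm/s, F in C/mol and concentrations in mM the
    numerical value is directly in uA/cm^2.  Continuous at u = 0 via series
    expansion; vanishes at the Nernst potential of (c_in, c_out, z).
    """
    c_in = np.asarray(c_in, float)
    c_out = np.asarray(c_out, float)
    if np.any(c_in <= 0) or np.any(c_out <= 0):
        raise PhysicalDomainError("GHK current requires positive concentrations")
    u = z * np.asarray(V, float) / params.RTF
    small = np.abs(u) < 1e-7
    us = np.where(small, 1.0, u)
    frac = np.where(
        small,
        # series of u*(c_in - c_out*exp(-u))/(1-exp(-u)) around u=0
        (c_in - c_out) + u * (c_in + c_out) / 2.0,
        us * (c_in - c_out * np.exp(-us)) / (-np.expm1(-us)))
    out = P * z * params.F * frac
    return out if np.ndim(out) else float(out)


@dataclass
class TimescaleReport:
    """Characteristic times with the formula and inputs each came from."""

    tau_V: float               # ms
    tau_n: float               # ms
    tau_ion: float             # s
    tau_forward_buffer: float  # s
    tau_backward_buffer: float # s
    tau_diff: float            # s
    provenance: dict[str, str]

    def ordering_ok(self) -> bool:
        """tau_V < tau_n < tau_ion < tau_fwd_buffer < tau_bwd_buffer
        (membrane times in ms, ion/reservoir times in s)."""
        return (self.tau_V < self.tau_n
                and self.tau_n / 1000.0 < self.tau_ion
                and self.tau_ion < self.tau_forward_buffer
                and self.tau_forward_buffer < self.tau_backward_buffer)

    def to_dict(self) -> dict:
        return {
            "tau_V_ms": self.tau_V, "tau_n_ms": self.tau_n,
            "tau_ion_s": self.tau_ion,
            "tau_forward_buffer_s": self.tau_forward_buffer,
            "tau_backward_buffer_s": self.tau_backward_buffer,
            "tau_diff_s": self.tau_diff,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def characteristic_timescales(params: ModelParams,
                              gating_occupancy: float = 0.1,
                              P_typical: float = 1e-5,
                              V_ref: float | None = None) -> TimescaleReport:
    """Compute the full time-scale report.

    ``gating_occupancy`` replaces the products of gating variables in the
    channel conductance/permeability (0.1 is representative of the active
    membrane); ``P_typical`` (cm/s) is the typical gated-channel
    permeability entering the GHK-based ion time scale.
    """
    if gating_occupancy <= 0 or P_typical <= 0:
        raise ValueError("gating_occupancy and P_typical must be positive")
    p = params
    g_tot = (p.gNa_l + p.gNa_g * gating_occupancy
             + p.gK_l + p.gK_g * gating_occupancy + p.gCl_l)  # mS/cm^2
    tau_V = p.Cm / g_tot  # uF/mS = ms

    if V_ref is None:
        V_ref = -p.RTF * math.log(p.Cl_e0 / p.Cl_i0)  # resting potential
    an = float(membrane.alpha_n(V_ref))
    bn = float(membrane.beta_n(V_ref))
    tau_n = 1.0 / (an + bn) / p.phi  # ms

    # omega/A in um = 1e-4 cm; over P in cm/s -> seconds
    tau_ion = (p.omega_i / p.A_mem) * 1e-4 / P_typical

    tau_fb = 1.0 / (p.lambda_buf * p.B0)
    tau_bb = 1.0 / p.lambda_bb
    tau_diff = 1.0 / p.lambda_diff

    prov = {
        "tau_V": f"Cm/g_total, gating products ~= {gating_occupancy}; "
                 f"g_total = {g_tot:.4g} mS/cm^2",
        "tau_n": f"1/(phi*(alpha_n+beta_n)) at V = {V_ref:.2f} mV",
        "tau_ion": f"(omega_i/A_mem)/P with P = {P_typical:g} cm/s "
                   f"(GHK flux grouping)",
        "tau_forward_buffer": "1/(lambda_buf*B0)",
        "tau_backward_buffer": "1/lambda_bb",
        "tau_diff": "1/lambda_diff",
    }
    return TimescaleReport(tau_V=tau_V, tau_n=tau_n, tau_ion=tau_ion,
                           tau_forward_buffer=tau_fb,
                           tau_backward_buffer=tau_bb,
                           tau_diff=tau_diff, provenance=prov)
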