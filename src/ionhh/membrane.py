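"""Gating functions, channel currents and the Na/K-ATPase pump current.

The gating rate functions are the shifted Hodgkin-Huxley exponentials of the
Cressman/Barreto single-compartment family.  Sodium activation m is slaved
adiabatically to its asymptotic value m_inf(V); sodium inactivation h is tied
to the potassium activation n through the fixed functional relation
h(n) = 1.1 - 1/(1 + exp(-8 (n - 0.4))), which mirrors the anticorrelation of
h and n along spiking trajectories and produces depolarization block (h -> 0.1)
for large n.
"""

from __future__ import annotations

from typing import Union

import numpy as np

from .params import ModelParams
from .state import DynamicState, DerivedIonState

__all__ = ["alpha_m", "beta_m", "alpha_n", "beta_n", "h_of_n",
           "gating", "pump_current", "currents_raw", "currents"]

ArrayLike = Union[float, np.ndarray]

#: half-width of the series-expansion window around the removable
#: singularities of the alpha rate functions
_SING_EPS = 1e-7


def _x_over_one_minus_exp(x: ArrayLike) -> ArrayLike:
    """x / (1 - exp(-x)), with the removable singularity at x = 0 evaluated
    by its series 1 + x/2 + x^2/12 within |x| < _SING_EPS."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < _SING_EPS
    xs = np.where(small, 1.0, x)  # avoid 0/0 warnings
    out = np.where(small, 1.0 + x / 2.0 + x * x / 12.0,
                   xs / (-np.expm1(-xs)))
    return out if out.ndim else float(out)


def alpha_m(V: ArrayLike) -> ArrayLike:
    return _x_over_one_minus_exp(0.1 * (np.asarray(V, float) + 30.0))


def beta_m(V: ArrayLike) -> ArrayLike:
    V = np.asarray(V, float)
    out = 4.0 * np.exp(-(V + 55.0) / 18.0)
    return out if out.ndim else float(out)


def alpha_n(V: ArrayLike) -> ArrayLike:
    return 0.1 * _x_over_one_minus_exp(0.1 * (np.asarray(V, float) + 34.0))


def beta_n(V: ArrayLike) -> ArrayLike:
    V = np.asarray(V, float)
    out = 0.125 * np.exp(-(V + 44.0) / 80.0)
    return out if out.ndim else float(out)


def h_of_n(n: ArrayLike) -> ArrayLike:
    """Sodium inactivation slaved to potassium activation."""
    n = np.asarray(n, float)
    out = 1.1 - 1.0 / (1.0 + np.exp(-8.0 * (n - 0.4)))
    return out if out.ndim else float(out)


def gating(V: ArrayLike, n: ArrayLike, params: ModelParams | None = None
           ) -> tuple[ArrayLike, ArrayLike, ArrayLike, ArrayLike]:
    """Asymptotic gating values and the n time scale.

    Returns ``(m_inf, n_inf, tau_n, h)`` with
    m_inf = alpha_m/(alpha_m+beta_m), n_inf = alpha_n/(alpha_n+beta_n),
    tau_n = 1/(alpha_n+beta_n) (ms; the rate equation for n carries the
    additional factor phi), and h = h_of_n(n).
    """
    am, bm = alpha_m(V), beta_m(V)
    an, bn = alpha_n(V), beta_n(V)
    m_inf = am / (am + bm)
    n_inf = an / (an + bn)
    tau_n = 1.0 / (an + bn)
    return m_inf, n_inf, tau_n, h_of_n(n)


def pump_current(Na_i: ArrayLike, K_e: ArrayLike, params: ModelParams) -> ArrayLike:
    """ATPase pump current (uA/cm^2), saturating sigmoidally in the
    intracellular sodium and extracellular potassium concentrations."""
    out = (params.rho_pump
           / (1.0 + np.exp((25.0 - np.asarray(Na_i, float)) / 3.0))
           / (1.0 + np.exp(5.5 - np.asarray(K_e, float))))
    return out if np.ndim(out) else float(out)


def currents_raw(V: float, n: float, Na_i: float, K_e: float,
                 E_Na: float, E_K: float, E_Cl: float,
                 params: ModelParams, pump_on: bool = True
                 ) -> tuple[float, float, float, float]:
    """Species currents (uA/cm^2) from scalar inputs.

    The pump's 3:2 stoichiometry is carried inside the species currents:
    I_Na includes +3*Ip, I_K includes -2*Ip, so the net membrane current
    I_Na + I_K + I_Cl contains the electrogenic +Ip.
    """
    m_inf, n_inf, tau_n, h = gating(V, n, params)
    Ip = pump_current(Na_i, K_e, params) if pump_on else 0.0
    I_Na = (params.gNa_l + params.gNa_g * m_inf ** 3 * h) * (V - E_Na) + 3.0 * Ip
    I_K = (params.gK_l + params.gK_g * n ** 4) * (V - E_K) - 2.0 * Ip
    I_Cl = params.gCl_l * (V - E_Cl)
    return float(I_Na), float(I_K), float(I_Cl), float(Ip)


def currents(state: DynamicState, derived: DerivedIonState, params: ModelParams,
             pump_on: bool = True) -> tuple[float, float, float, float]:
    """Species currents ``(I_Na, I_K, I_Cl, Ip)`` for a dynamic state and its
    derived ionic state.  ``pump_on=False`` forces Ip = 0 (protocol hook)."""
    return currents_raw(state.V, state.n, derived.Na_i, derived.K_e,
                        derived.E_Na, derived.E_K, derived.E_Cl,
                        params, pump_on=pump_on)
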