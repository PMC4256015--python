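"""Model constants and the reference parameter set.

The model works in the unit system ms / mV / mM / uA/cm^2, with compartment
volumes in um^3 and the membrane area in um^2.  Reservoir rates are stated
per second (as usual for glial buffering and bath coupling) and converted to
per millisecond only when the right-hand side is assembled.

The conversion factor ``gamma`` maps a membrane current density to a
concentration rate: ``dc/dt = gamma * I / omega`` in mM/ms with I in uA/cm^2
and omega in um^3.  In this unit system ``gamma = 10 * A_mem / F``.
"""

from __future__ import annotations

import dataclasses
import json
import math
import pathlib
from dataclasses import dataclass, field
from typing import Any

import yaml

__all__ = ["ModelParams", "table1", "validate_params", "ValidationReport"]


@dataclass
class ModelParams:
    """All physical constants of the ion-based membrane model.

    Attributes
    ----------
    Cm : membrane capacitance (uF/cm^2)
    phi : gating time-scale parameter (1/ms)
    gNa_l, gNa_g : Na+ leak and maximal gated conductance (mS/cm^2)
    gK_l, gK_g : K+ leak and maximal gated conductance (mS/cm^2)
    gCl_l : Cl- leak conductance (mS/cm^2)
    rho_pump : maximal Na/K-ATPase pump current (uA/cm^2)
    Na_i0 ... Cl_e0 : reference (physiological resting) concentrations (mM)
    omega_i, omega_e : intra-/extracellular volumes (um^3)
    A_mem : membrane surface area (um^2)
    F : Faraday constant (C/mol)
    gamma : current-to-flux conversion factor, dc/dt = gamma*I/omega (see above)
    RTF : thermal voltage RT/F (mV); default corresponds to T = 310 K
    lambda_buf : forward buffering rate scale (1/(mM*s))
    lambda_bb : backward buffering rate (1/s)
    lambda_diff : diffusive bath coupling strength (1/s)
    K_bath : potassium concentration of the extracellular bath (mM)
    B0 : initial free buffer concentration (mM, per ECS volume)
    buf_mid, buf_steep : midpoint (mM) and steepness (mM) of the sigmoidal
        potassium dependence of the forward buffering rate
    """

    Cm: float = 1.0
    phi: float = 3.0
    gNa_l: float = 0.0175
    gNa_g: float = 100.0
    gK_l: float = 0.05
    gK_g: float = 40.0
    gCl_l: float = 0.02
    rho_pump: float = 6.8
    Na_i0: float = 25.23
    Na_e0: float = 125.31
    K_i0: float = 129.26
    K_e0: float = 4.0
    Cl_i0: float = 9.9
    Cl_e0: float = 123.27
    omega_i: float = 2160.0
    omega_e: float = 720.0
    A_mem: float = 922.0
    F: float = 96485.0
    gamma: float = 9.556e-2
    RTF: float = 26.71
    lambda_buf: float = 5e-5
    lambda_bb: float = 5e-5
    lambda_diff: float = 3e-2
    K_bath: float = 4.0
    B0: float = 500.0
    buf_mid: float = 15.0
    buf_steep: float = 1.09

    # ---- derived conveniences -------------------------------------------

    @property
    def vol_ratio(self) -> float:
        """ICS/ECS volume ratio omega_i/omega_e."""
        return self.omega_i / self.omega_e

    @property
    def gamma_over_wi(self) -> float:
        """Concentration rate per unit current density, gamma/omega_i (mM/ms per uA/cm^2)."""
        return self.gamma / self.omega_i

    def gamma_expected(self) -> float:
        """gamma implied by the membrane geometry, 10*A_mem/F in this unit system."""
        return 10.0 * self.A_mem / self.F

    def replace(self, **kwargs: Any) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)

    # ---- (de)serialization ----------------------------------------------

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def save(self, path: str | pathlib.Path) -> None:
        path = pathlib.Path(path)
        payload = {"units": UNITS, "params": self.to_dict()}
        if path.suffix in (".yml", ".yaml"):
            path.write_text(yaml.safe_dump(payload, sort_keys=False))
        else:
            path.write_text(json.dumps(payload, indent=2))

    @classmethod
    def load(cls, path: str | pathlib.Path) -> "ModelParams":
        path = pathlib.Path(path)
        text = path.read_text()
        payload = yaml.safe_load(text)
        if "params" in payload:
            payload = payload["params"]
        return cls.from_dict(payload)


#: unit annotations written alongside serialized parameter sets
UNITS = {
    "Cm": "uF/cm^2", "phi": "1/ms",
    "gNa_l": "mS/cm^2", "gNa_g": "mS/cm^2", "gK_l": "mS/cm^2",
    "gK_g": "mS/cm^2", "gCl_l": "mS/cm^2", "rho_pump": "uA/cm^2",
    "Na_i0": "mM", "Na_e0": "mM", "K_i0": "mM", "K_e0": "mM",
    "Cl_i0": "mM", "Cl_e0": "mM",
    "omega_i": "um^3", "omega_e": "um^3", "A_mem": "um^2", "F": "C/mol",
    "gamma": "um^2*mol/C (so that gamma*I/omega is mM/ms)", "RTF": "mV",
    "lambda_buf": "1/(mM*s)", "lambda_bb": "1/s", "lambda_diff": "1/s",
    "K_bath": "mM", "B0": "mM", "buf_mid": "mM", "buf_steep": "mM",
}

_PRESETS: dict[str, ModelParams] = {}


def table1() -> ModelParams:
    """The reference parameter set of the reduced ion-based model."""
    return ModelParams()


_PRESETS["table1"] = table1()


def get_preset(name: str) -> ModelParams:
    try:
        return dataclasses.replace(_PRESETS[name])
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(_PRESETS)}") from None


# ---------------------------------------------------------------------------
# validation


@dataclass
class ValidationReport:
    checks: list[tuple[str, bool, str]] = field(default_factory=list)

    def add(self, name: str, ok: bool, detail: str = "") -> None:
        self.checks.append((name, bool(ok), detail))

    @property
    def ok(self) -> bool:
        return all(ok for _, ok, _ in self.checks)

    def failures(self) -> list[str]:
        return [name for name, ok, _ in self.checks if not ok]

    def __str__(self) -> str:
        lines = []
        for name, ok, detail in self.checks:
            mark = "PASS" if ok else "FAIL"
            lines.append(f"[{mark}] {name}" + (f": {detail}" if detail else ""))
        return "\n".join(lines)


_POSITIVE_FIELDS = (
    "Cm", "phi", "gNa_l", "gNa_g", "gK_l", "gK_g", "gCl_l", "rho_pump",
    "Na_i0", "Na_e0", "K_i0", "K_e0", "Cl_i0", "Cl_e0",
    "omega_i", "omega_e", "A_mem", "F", "gamma", "RTF",
    "lambda_buf", "lambda_bb", "lambda_diff", "K_bath", "B0", "buf_steep",
)


def validate_params(params: ModelParams) -> ValidationReport:
    """Structural consistency checks on a parameter set.

    Checks strict positivity of all physical quantities, consistency of the
    current-to-flux conversion factor with the membrane geometry (to 0.1%),
    and charge/mass consistency of the reference state.
    """
    rep = ValidationReport()
    for name in _POSITIVE_FIELDS:
        v = getattr(params, name)
        rep.add(f"positive:{name}", math.isfinite(v) and v > 0, f"{name}={v}")

    expected = params.gamma_expected()
    rel = abs(params.gamma - expected) / expected
    rep.add("gamma_consistency", rel < 1e-3,
            f"gamma={params.gamma:.6g}, 10*A/F={expected:.6g}, rel. dev. {rel:.2e}")

    # the reference state must have a well-defined intracellular charge
    # concentration shared by Na+, K+ and Cl- (used by the constraint algebra)
    ref_charge = params.Na_i0 + params.K_i0 - params.Cl_i0
    rep.add("reference_charge_finite", math.isfinite(ref_charge) and ref_charge > 0,
            f"Na_i0+K_i0-Cl_i0={ref_charge:.4g} mM")
    return rep
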