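"""Fixed-point continuation and bifurcation detection.

The fast (transmembrane) subsystem is continued in one parameter:

* closed model: x = (V, n, K_i, Cl_i) with the potassium gain/loss dNK as
  the bifurcation parameter;
* clamped chloride: the chloride current is set to zero and Cl_i becomes a
  fixed parameter, x = (V, n, K_i), continued in dNK — used for the Hopf
  line that marks the repolarization threshold;
* bath model: x = (V, n, K_i, Cl_i, dNK) continued in the bath
  concentration K_bath.

Pseudo-arclength predictor-corrector with finite-difference Jacobians,
eigenvalue monitoring, and bisection refinement of Hopf (complex pair
crossing the imaginary axis) and limit points (fold with a real eigenvalue
through zero).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from . import _core
from .params import ModelParams
from .state import DynamicState, PhysicalDomainError

#: exceptions signalling that an evaluation left the physical domain
_DOMAIN_ERRORS = (FloatingPointError, PhysicalDomainError)

__all__ = ["newton", "FixedPoint", "find_fixed_point", "Branch",
           "BifurcationPoint", "continue_fixed_points",
           "hopf_line_clamped_chloride", "NewtonError"]


class NewtonError(RuntimeError):
    def __init__(self, msg: str, residual_history: list[float]):
        super().__init__(msg + f" (residual history: {residual_history})")
        self.residual_history = residual_history


def fd_jacobian(f: Callable[[np.ndarray], np.ndarray], x: np.ndarray,
                rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference Jacobian with per-component adaptive step."""
    x = np.asarray(x, float)
    f0 = np.asarray(f(x), float)
    J = np.empty((f0.size, x.size))
    for i in range(x.size):
        h = rel_step * max(abs(x[i]), 1.0)
        xp = x.copy()
        xm = x.copy()
        xp[i] += h
        xm[i] -= h
        J[:, i] = (np.asarray(f(xp)) - np.asarray(f(xm))) / (2.0 * h)
    return J


def newton(f: Callable[[np.ndarray], np.ndarray], x0: np.ndarray,
           tol: float = 1e-12, max_iter: int = 60,
           ) -> tuple[np.ndarray, list[float]]:
    """Damped Newton iteration; returns the root and the residual history."""
    x = np.asarray(x0, float).copy()
    hist: list[float] = []
    try:
        fx = np.asarray(f(x), float)
    except _DOMAIN_ERRORS:
        raise NewtonError("initial guess outside the physical domain", hist) from None
    res = float(np.max(np.abs(fx)))
    hist.append(res)
    for _ in range(max_iter):
        if res < tol:
            return x, hist
        try:
            J = fd_jacobian(f, x)
        except _DOMAIN_ERRORS:
            raise NewtonError("Jacobian stencil left the physical domain", hist) from None
        try:
            dx = np.linalg.solve(J, -fx)
        except np.linalg.LinAlgError as exc:
            raise NewtonError(f"singular Jacobian: {exc}", hist) from None
        lam = 1.0
        for _ in range(12):
            x_new = x + lam * dx
            try:
                f_new = np.asarray(f(x_new), float)
            except _DOMAIN_ERRORS:
                lam *= 0.5
                continue
            res_new = float(np.max(np.abs(f_new)))
            if np.isfinite(res_new) and (res_new < res or res_new < tol):
                break
            lam *= 0.5
        else:
            # FD-Jacobian noise floor: accept stagnation at tiny residuals
            if res < max(1e3 * tol, 1e-8):
                return x, hist
            raise NewtonError("line search failed", hist)
        x, fx, res = x_new, f_new, res_new
        hist.append(res)
    if res < tol:
        return x, hist
    raise NewtonError("Newton did not converge", hist)


# ---------------------------------------------------------------------------
# fast-subsystem wrappers around the compiled RHS


class FastSystem:
    """f(x, p) for one continuation setting, plus state (un)packing."""

    def __init__(self, params: ModelParams, parameter: str = "dNK",
                 clamp_Cl: Optional[float] = None):
        if parameter not in ("dNK", "K_bath"):
            raise ValueError("parameter must be 'dNK' or 'K_bath'")
        if parameter == "K_bath" and clamp_Cl is not None:
            raise ValueError("chloride clamping is a closed-model analysis")
        self.params = params
        self.parameter = parameter
        self.clamp_Cl = clamp_Cl
        self.pa = _core.pack_params(params, clamp_cl=clamp_Cl is not None)
        self.prot = _core.no_protocol()
        if parameter == "dNK":
            self.dim = 3 if clamp_Cl is not None else 4
            self.variant_code = _core.V_CLOSED
        else:
            self.dim = 5
            self.variant_code = _core.V_BATH
        self._dy = np.zeros(6)

    def full_y(self, x: np.ndarray, p: float) -> np.ndarray:
        y = np.zeros(6)
        if self.parameter == "dNK":
            if self.clamp_Cl is not None:
                y[0], y[1], y[2] = x[0], x[1], x[2]
                y[3] = self.clamp_Cl
            else:
                y[:4] = x
            y[4] = p
        else:
            y[:5] = x
            self.pa[_core.IP_KBATH] = p
        return y

    def __call__(self, x: np.ndarray, p: float) -> np.ndarray:
        y = self.full_y(x, p)
        bad = _core.rhs(0.0, y, self.pa, self.variant_code, self.prot, self._dy)
        if bad != 0:
            raise FloatingPointError("state outside the physical domain")
        if self.parameter == "dNK":
            if self.clamp_Cl is not None:
                return np.array([self._dy[0], self._dy[1], self._dy[2]])
            return self._dy[:4].copy()
        return self._dy[:5].copy()

    def jacobian(self, x: np.ndarray, p: float) -> np.ndarray:
        return fd_jacobian(lambda z: self(z, p), np.asarray(x, float))

    def state(self, x: np.ndarray, p: float) -> DynamicState:
        y = self.full_y(x, p)
        variant = "bath" if self.parameter == "K_bath" else "closed"
        return DynamicState.from_vector(y, variant)

    #: scales used to non-dimensionalize arclength (mV, -, mM, ...)
    def scales(self) -> np.ndarray:
        if self.dim == 3:
            return np.array([20.0, 0.1, 5.0])
        if self.dim == 4:
            return np.array([20.0, 0.1, 5.0, 5.0])
        return np.array([20.0, 0.1, 5.0, 5.0, 5.0])


@dataclass
class FixedPoint:
    x: np.ndarray
    p: float
    eigvals: np.ndarray
    residual: float

    @property
    def stable(self) -> bool:
        return bool(np.all(self.eigvals.real < 0.0))


def find_fixed_point(guess: DynamicState, params: ModelParams,
                     clamped: Optional[dict] = None,
                     parameter: str = "dNK") -> FixedPoint:
    """Newton-solve the fast subsystem from a state guess.

    ``clamped``: optionally ``{"Cl_i": value}`` to clamp chloride (zero
    chloride current) for the Hopf-line analysis.  The continuation
    parameter value is read off the guess (its dNK, or params.K_bath).
    """
    clamp_Cl = clamped.get("Cl_i") if clamped else None
    sys_ = FastSystem(params, parameter=parameter, clamp_Cl=clamp_Cl)
    if parameter == "dNK":
        p = guess.dNK
        x0 = (np.array([guess.V, guess.n, guess.K_i]) if clamp_Cl is not None
              else np.array([guess.V, guess.n, guess.K_i, guess.Cl_i]))
    else:
        p = params.K_bath
        x0 = np.array([guess.V, guess.n, guess.K_i, guess.Cl_i, guess.dNK])
    x, hist = newton(lambda z: sys_(z, p), x0)
    eig = np.linalg.eigvals(sys_.jacobian(x, p))
    return FixedPoint(x=x, p=p, eigvals=eig, residual=hist[-1])


# ---------------------------------------------------------------------------
# branches and bifurcation points


@dataclass
class BifurcationPoint:
    kind: str          # "HB" or "LP"
    label: str         # e.g. "HB1"
    p: float
    x: np.ndarray
    eigvals: np.ndarray

    def to_dict(self) -> dict:
        return {"kind": self.kind, "label": self.label, "p": float(self.p),
                "x": [float(v) for v in self.x],
                "eigvals_re": [float(v) for v in self.eigvals.real],
                "eigvals_im": [float(v) for v in self.eigvals.imag]}


@dataclass
class Branch:
    parameter: str
    p: np.ndarray
    x: np.ndarray            # (n_points, dim)
    eigvals: np.ndarray      # (n_points, dim) complex
    stable: np.ndarray       # (n_points,) bool
    bifurcations: list[BifurcationPoint] = field(default_factory=list)
    clamp_Cl: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        cols = {"p": self.p}
        names = (["V", "n", "K_i"] if self.x.shape[1] == 3 else
                 ["V", "n", "K_i", "Cl_i"] if self.x.shape[1] == 4 else
                 ["V", "n", "K_i", "Cl_i", "dNK"])
        for j, nm in enumerate(names):
            cols[nm] = self.x[:, j]
        cols["max_re_eig"] = self.eigvals.real.max(axis=1)
        cols["stable"] = self.stable.astype(int)
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.12g")

    def bifurcations_json(self) -> str:
        return json.dumps([b.to_dict() for b in self.bifurcations], indent=2)

    def labels(self) -> list[str]:
        return [b.label for b in self.bifurcations]


def _n_unstable(eig: np.ndarray) -> int:
    return int(np.sum(eig.real > 0.0))


def _hopf_test(eig: np.ndarray, imag_tol: float = 1e-9) -> float:
    """Signed distance of the complex pair nearest the imaginary axis.

    Falls back to the largest real part when no complex eigenvalues exist
    (keeps the test function defined along the whole branch).
    """
    cplx = eig[np.abs(eig.imag) > imag_tol]
    if cplx.size == 0:
        return float(np.max(eig.real))
    return float(cplx.real[np.argmin(np.abs(cplx.real))])


def continue_fixed_points(start: DynamicState | FixedPoint, params: ModelParams,
                          parameter: str = "dNK",
                          p_range: tuple[float, float] = (-5.0, 25.0),
                          direction: int = +1,
                          clamped: Optional[dict] = None,
                          ds0: float = 0.02, ds_max: float = 0.25,
                          ds_min: float = 1e-9, max_points: int = 20000,
                          p_tol: float = 1e-6,
                          stop_after_stable: Optional[float] = None,
                          ) -> Branch:
    """Pseudo-arclength continuation of fixed points with HB/LP detection.

    ``direction`` picks the initial sense of parameter change.  Detected
    bifurcations are refined by bisection to ``p_tol`` in the parameter and
    labelled HB1, LP1, ... in traversal order.  ``stop_after_stable``: stop
    once the branch has stayed stable for that much parameter beyond the
    last bifurcation (used to terminate on the stable FES branch).
    """
    clamp_Cl = clamped.get("Cl_i") if clamped else None
    sys_ = FastSystem(params, parameter=parameter, clamp_Cl=clamp_Cl)
    scl_x = sys_.scales()
    scl_p = 1.0

    if isinstance(start, FixedPoint):
        x0, p0 = start.x.copy(), start.p
    else:
        fp = find_fixed_point(start, params, clamped=clamped, parameter=parameter)
        x0, p0 = fp.x, fp.p

    def corrector(z_pred: np.ndarray, tang: np.ndarray,
                  z_ref: np.ndarray, ds: float) -> np.ndarray:
        def g(z):
            r = sys_(z[:-1] * scl_x, z[-1] * scl_p)
            arc = float(tang @ (z - z_ref)) - ds
            return np.append(r, arc)
        z, _ = newton(g, z_pred, tol=1e-11, max_iter=14)
        return z

    # scaled state vector z = [x/scl, p/scl_p]
    z = np.append(x0 / scl_x, p0 / scl_p)
    J = sys_.jacobian(x0, p0)
    eig = np.linalg.eigvals(J)

    ps = [p0]
    xs = [x0.copy()]
    eigs = [np.sort_complex(eig)]
    stab = [bool(np.all(eig.real < 0))]

    # initial tangent from the bordered system
    fp_col = fd_jacobian(lambda q: sys_(x0, q[0]), np.array([p0]))
    dxdp = np.linalg.solve(J, -fp_col[:, 0])
    tang = np.append(dxdp * 1.0 / scl_x * scl_p, 1.0)
    tang /= np.linalg.norm(tang)
    if direction < 0:
        tang = -tang

    hb_count = 0
    lp_count = 0
    bifs: list[BifurcationPoint] = []
    ds = ds0
    stable_run_start: Optional[float] = None

    def eval_point(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = z[:-1] * scl_x
        p = z[-1] * scl_p
        return x, np.linalg.eigvals(sys_.jacobian(x, p))

    def refine(z_a: np.ndarray, z_b: np.ndarray, test: Callable[[np.ndarray], float]
               ) -> Optional[np.ndarray]:
        """Bisection along the secant, re-converging onto the branch."""
        try:
            ga = test(z_a)
            gb = test(z_b)
        except _DOMAIN_ERRORS:
            return None
        if ga == 0.0:
            return z_a
        if ga * gb > 0:
            return None
        sec = (z_b - z_a)
        nrm = np.linalg.norm(sec)
        if nrm == 0:
            return z_a
        sec = sec / nrm
        lo, hi = z_a, z_b
        for _ in range(60):
            zm_pred = 0.5 * (lo + hi)
            try:
                zm = corrector(zm_pred, sec, zm_pred, 0.0)
                gm = test(zm)
            except (NewtonError, *_DOMAIN_ERRORS):
                return None
            if ga * gm <= 0:
                hi = zm
                gb = gm
            else:
                lo = zm
                ga = gm
            if abs(hi[-1] - lo[-1]) * scl_p < p_tol and \
               np.linalg.norm(hi - lo) < 1e-7:
                break
        return 0.5 * (lo + hi)

    for _ in range(max_points):
        accepted = False
        while not accepted:
            z_pred = z + ds * tang
            try:
                z_new = corrector(z_pred, tang, z, ds)
                x_new, eig_new = eval_point(z_new)
                accepted = True
            except (NewtonError, *_DOMAIN_ERRORS):
                ds *= 0.4
                if ds < ds_min:
                    return Branch(parameter, np.array(ps), np.array(xs),
                                  np.array(eigs), np.array(stab), bifs, clamp_Cl)
        p_new = z_new[-1] * scl_p

        nu_old = _n_unstable(eigs[-1])
        nu_new = _n_unstable(eig_new)
        tang_new = z_new - z
        tang_new /= np.linalg.norm(tang_new)

        if nu_new != nu_old:
            dn = nu_new - nu_old
            if abs(dn) == 2:
                zr = refine(z, z_new, lambda q: _hopf_test(eval_point(q)[1]))
                if zr is not None:
                    xr, er = eval_point(zr)
                    hb_count += 1
                    bifs.append(BifurcationPoint("HB", f"HB{hb_count}",
                                                 zr[-1] * scl_p, xr, er))
            else:
                # a real eigenvalue through zero flips the sign of det(J)
                zr = refine(z, z_new,
                            lambda q: float(np.prod(eval_point(q)[1]).real))
                if zr is not None:
                    xr, er = eval_point(zr)
                    lp_count += 1
                    bifs.append(BifurcationPoint("LP", f"LP{lp_count}",
                                                 zr[-1] * scl_p, xr, er))
            stable_run_start = None

        z = z_new
        tang = tang_new
        ps.append(p_new)
        xs.append(x_new)
        eigs.append(np.sort_complex(eig_new))
        stab.append(bool(np.all(eig_new.real < 0)))

        # step adaptation: cheap heuristic on turning rate
        ds = min(ds * 1.3, ds_max)

        if not (p_range[0] <= p_new <= p_range[1]):
            break
        if stop_after_stable is not None:
            if stab[-1]:
                if stable_run_start is None:
                    stable_run_start = p_new
                elif abs(p_new - stable_run_start) >= stop_after_stable:
                    break
            else:
                stable_run_start = None

    return Branch(parameter, np.array(ps), np.array(xs), np.array(eigs),
                  np.array(stab), bifs, clamp_Cl)


# ---------------------------------------------------------------------------
# the clamped-chloride Hopf line


def _fes_state_clamped(params: ModelParams, Cl_i: float, dNK: float,
                       settle: float = 150.0) -> Optional[FixedPoint]:
    """Find the stable free-energy-starved fixed point of the chloride-
    clamped fast subsystem at a given dNK by relaxation + Newton polish."""
    from .dynamics import simulate  # deferred

    # depolarized seed consistent with mass conservation: K_i at reference
    # puts K_e = K_e0 + dNK (elevated), Na_e stays positive for Cl_i <= 32
    y0 = DynamicState("closed", V=-25.0, n=0.55, K_i=params.K_i0,
                      Cl_i=Cl_i, dNK=dNK)
    pa_params = params
    try:
        # direct relaxation onto the attractor, chloride clamped
        sys_ = FastSystem(pa_params, parameter="dNK", clamp_Cl=Cl_i)
        x = np.array([y0.V, y0.n, y0.K_i])
        # crude forward-Euler-free relaxation: integrate the clamped system
        # with the compiled core (closed variant, clamped flag)
        prot = _core.no_protocol()
        t_samp = np.array([settle * _core.MS_PER_S])
        out = np.empty((1, 6))
        spikes = np.empty(0)
        yfull = sys_.full_y(x, dNK)
        status, yend, _, _ = _core.integrate_segment(
            yfull, 0.0, settle * _core.MS_PER_S, sys_.pa, sys_.variant_code,
            prot, 1e-8, 1e-10, 20.0, t_samp, out, spikes, 0, 0.0, 2.0,
            200_000_000)
        if status != _core.STATUS_OK:
            return None
        x = np.array([yend[0], yend[1], yend[2]])
        xfix, hist = newton(lambda q: sys_(q, dNK), x)
        eig = np.linalg.eigvals(sys_.jacobian(xfix, dNK))
        fp = FixedPoint(x=xfix, p=dNK, eigvals=eig, residual=hist[-1])
        # must be the depolarized branch
        if fp.x[0] < -50.0:
            return None
        return fp
    except (NewtonError, FloatingPointError):
        return None


def hopf_line_clamped_chloride(Cl_grid: Sequence[float], params: ModelParams,
                               dNK_start: float = 20.0,
                               p_range: tuple[float, float] = (-150.0, 60.0),
                               ) -> list[tuple[float, Optional[BifurcationPoint]]]:
    """Hopf point terminating the FES branch, per clamped Cl_i value.

    For each grid value the chloride current is removed, Cl_i is fixed, and
    the stable FES branch is continued towards decreasing potassium content
    until it loses stability in a Hopf bifurcation.  Grid values whose FES
    branch cannot be found are reported with ``None``.
    """
    out: list[tuple[float, Optional[BifurcationPoint]]] = []
    for Cl in Cl_grid:
        fp = _fes_state_clamped(params, Cl, dNK_start)
        if fp is None or not fp.stable:
            out.append((float(Cl), None))
            continue
        br = continue_fixed_points(
            fp, params, parameter="dNK", p_range=p_range, direction=-1,
            clamped={"Cl_i": Cl}, ds0=0.05)
        hbs = [b for b in br.bifurcations if b.kind == "HB"]
        out.append((float(Cl), hbs[0] if hbs else None))
    return out
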