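"""Named scenarios: one-call reproductions of the package's headline
experiments, written to disk with a reproducibility manifest."""

from __future__ import annotations

import json
import logging
import pathlib
from typing import Any, Callable, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .continuation import continue_fixed_points, hopf_line_clamped_chloride
from .dynamics import Protocol, depolarization_metrics, resting_state, simulate
from .experiments import sd_episode, sla_sweep
from .params import ModelParams, get_preset
from .timescales import characteristic_timescales

log = logging.getLogger("ionhh")

__all__ = ["run_scenario", "available_scenarios", "load_config"]


def load_config(path) -> dict:
    text = pathlib.Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError("scenario config must be a mapping")
    return cfg


def _params_from_config(cfg: dict) -> ModelParams:
    p = get_preset(cfg.get("preset", "table1"))
    overrides = cfg.get("params", {})
    if overrides:
        unknown = set(overrides) - set(p.to_dict())
        if unknown:
            raise ValueError(f"unknown parameter override(s): {sorted(unknown)}")
        p = p.replace(**{k: float(v) for k, v in overrides.items()})
    return p


def _write_manifest(outdir: pathlib.Path, name: str, params: ModelParams,
                    extra: dict[str, Any]) -> None:
    manifest = {
        "scenario": name,
        "code_version": __version__,
        "params": params.to_dict(),
        **extra,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def _sc_closed_bistability(p: ModelParams, outdir: pathlib.Path, cfg: dict) -> dict:
    t_end = float(cfg.get("t_end", 500.0))
    rest = resting_state(p, "closed")
    tr1 = simulate(p, "closed", t_end=t_end, initial_state=rest)
    # reach FES via a superthreshold potassium bolus in the closed system
    fes_seed = rest.replace(dNK=rest.dNK)
    prot = Protocol(K_bolus=(1.0, float(cfg.get("bolus", 15.0))))
    tr2 = simulate(p, "closed", protocol=prot, t_end=t_end, initial_state=fes_seed)
    tr1.to_csv(outdir / "resting.csv")
    tr2.to_csv(outdir / "fes.csv")
    summary = {
        "resting_V_drift": float(np.max(np.abs(tr1.V - tr1.V[0]))),
        "fes_final_V": float(tr2.V[-1]),
        "fes_final_K_e": float(tr2.K_e[-1]),
        "bistable": bool(np.max(np.abs(tr1.V - tr1.V[0])) < 1.0
                         and tr2.V[-1] > -50.0),
    }
    log.info("closed bistability: %s", summary)
    return summary


def _sc_sd_pump_off(p: ModelParams, outdir: pathlib.Path, cfg: dict) -> dict:
    ep = sd_episode(p, t_end=float(cfg.get("t_end", 300.0)))
    ep.trajectory.to_csv(outdir / "trajectory.csv")
    summary = {"duration_s": ep.duration, "onset_s": ep.onset,
               "offset_s": ep.offset, "peak_K_e_mM": ep.peak_K_e,
               "min_Na_e_mM": ep.min_Na_e}
    log.info("SD (pump off): depolarized for %.1f s", ep.duration)
    return summary


def _sc_sd_k_bolus(p: ModelParams, outdir: pathlib.Path, cfg: dict) -> dict:
    bolus = float(cfg.get("bolus", 12.0))
    prot = Protocol(K_bolus=(20.0, bolus))
    traj = simulate(p, "buffered", protocol=prot,
                    t_end=float(cfg.get("t_end", 300.0)), dt_out=0.01)
    traj.to_csv(outdir / "trajectory.csv")
    phases = depolarization_metrics(traj)
    main = max(phases, key=lambda ph: ph.duration) if phases else None
    summary = {"bolus_mM": bolus,
               "duration_s": main.duration if main else 0.0,
               "peak_K_e_mM": main.peak_K_e if main else None}
    log.info("SD (K bolus %.1f mM): %s", bolus, summary)
    return summary


def _sc_dnk_continuation(p: ModelParams, outdir: pathlib.Path, cfg: dict) -> dict:
    rest = resting_state(p, "closed")
    br = continue_fixed_points(rest, p, parameter="dNK",
                               p_range=tuple(cfg.get("range", (-80.0, 60.0))),
                               direction=+1, max_points=8000)
    br.to_csv(outdir / "branch.csv")
    (outdir / "bifurcations.json").write_text(br.bifurcations_json())
    summary = {"labels": br.labels(),
               "points": [dict(label=b.label, dNK=b.p) for b in br.bifurcations]}
    log.info("dNK continuation: %s", summary["labels"])
    return summary


def _sc_kbath_continuation(p: ModelParams, outdir: pathlib.Path, cfg: dict) -> dict:
    p0 = p.replace(K_bath=4.0)
    rest = resting_state(p0, "bath")
    br = continue_fixed_points(rest, p0, parameter="K_bath",
                               p_range=tuple(cfg.get("range", (2.0, 30.0))),
                               direction=+1, max_points=8000)
    br.to_csv(outdir / "branch.csv")
    (outdir / "bifurcations.json").write_text(br.bifurcations_json())
    summary = {"labels": br.labels(),
               "points": [dict(label=b.label, K_bath=b.p) for b in br.bifurcations]}
    log.info("K_bath continuation: %s", summary["labels"])
    return summary


def _sc_hopf_line(p: ModelParams, outdir: pathlib.Path, cfg: dict) -> dict:
    grid = cfg.get("grid", [8, 12, 16, 20, 24, 28, 32])
    line = hopf_line_clamped_chloride(grid, p)
    rows = []
    for cl, hb in line:
        if hb is None:
            rows.append({"Cl_i": cl, "found": 0})
        else:
            ke = p.K_e0 - p.vol_ratio * (hb.x[2] - p.K_i0) + hb.p
            rows.append({"Cl_i": cl, "found": 1, "dNK": hb.p,
                         "V": hb.x[0], "K_e": ke})
    pd.DataFrame(rows).to_csv(outdir / "hopf_line.csv", index=False,
                              float_format="%.12g")
    summary = {"n_found": sum(r["found"] for r in rows), "n_grid": len(grid)}
    log.info("Hopf line: %d/%d", summary["n_found"], summary["n_grid"])
    return summary


def _sc_kbath_sweep(p: ModelParams, outdir: pathlib.Path, cfg: dict) -> dict:
    res = sla_sweep(p, kb_values=cfg.get("values"),
                    window=float(cfg.get("window", 600.0)))
    pd.DataFrame([r.to_dict() for r in res]).to_csv(
        outdir / "sweep.csv", index=False, float_format="%.12g")
    atlas = {f"{r.parameter:g}": r.label for r in res}
    (outdir / "atlas.json").write_text(json.dumps(atlas, indent=2))
    return {"labels": atlas}


def _sc_timescale_report(p: ModelParams, outdir: pathlib.Path, cfg: dict) -> dict:
    rep = characteristic_timescales(p)
    (outdir / "timescales.json").write_text(rep.to_json())
    log.info("timescales: %s", rep.to_dict())
    return rep.to_dict()


_SCENARIOS: dict[str, Callable] = {
    "closed_bistability": _sc_closed_bistability,
    "sd_pump_off": _sc_sd_pump_off,
    "sd_k_bolus": _sc_sd_k_bolus,
    "dnk_continuation": _sc_dnk_continuation,
    "kbath_continuation": _sc_kbath_continuation,
    "hopf_line": _sc_hopf_line,
    "kbath_sweep": _sc_kbath_sweep,
    "timescale_report": _sc_timescale_report,
}


def available_scenarios() -> list[str]:
    return sorted(_SCENARIOS)


def run_scenario(name: str, outdir, config: Optional[dict] = None) -> dict:
    """Run a named scenario, writing artifacts and a manifest to ``outdir``.

    Returns the scenario's summary dictionary (also stored in the manifest).
    """
    if name not in _SCENARIOS:
        raise KeyError(f"unknown scenario {name!r}; available: "
                       f"{available_scenarios()}")
    cfg = dict(config or {})
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    p = _params_from_config(cfg)
    log.info("running scenario %s -> %s", name, outdir)
    summary = _SCENARIOS[name](p, outdir, cfg)
    _write_manifest(outdir, name, p, {"config": cfg, "summary": summary})
    return summary
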