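"""YAML serialisation of scenarios (SI units throughout)."""

from __future__ import annotations

from pathlib import Path

import yaml

from .engine import Scenario
from .physchem import ActivityModel, Component, Environment
from .spray_source import DropletDistribution, JetGeometry


def component_to_dict(c: Component) -> dict:
    out = {
        "name": c.name,
        "M": c.M,
        "psat": {float(t): float(p) for t, p in c.psat},
        "D": c.D,
        "Vm": c.Vm,
    }
    if c.beta is not None:
        out["beta"] = c.beta
    if c.activity.kind != "ideal":
        act: dict = {"kind": c.activity.kind}
        if c.activity.kind == "polynomial":
            act["coefficients"] = list(c.activity.coefficients)
        else:
            act["x_grid"] = list(c.activity.x_grid)
            act["gamma_grid"] = list(c.activity.gamma_grid)
        out["activity"] = act
    return out


def component_from_dict(d: dict) -> Component:
    act = d.get("activity")
    if act is None:
        activity = ActivityModel()
    elif act["kind"] == "polynomial":
        activity = ActivityModel(kind="polynomial", coefficients=tuple(act["coefficients"]))
    else:
        activity = ActivityModel(
            kind="table",
            x_grid=tuple(act["x_grid"]),
            gamma_grid=tuple(act["gamma_grid"]),
        )
    return Component(
        name=d["name"],
        M=float(d["M"]),
        psat={float(t): float(p) for t, p in d["psat"].items()},
        D=float(d["D"]),
        Vm=float(d["Vm"]),
        beta=float(d["beta"]) if "beta" in d else None,
        activity=activity,
    )


def scenario_to_dict(sc: Scenario) -> dict:
    env = sc.env
    out = {
        "name": sc.name,
        "mode": sc.mode,
        "room": {"V_room": sc.V_room, "F": sc.F, "h_room": sc.h_room},
        "ventilation": {
            "Q_vent": float(sc.Q_vent),
            "C_vent": [float(v) for v in sc.C_vent],
            "C_init": [float(v) for v in sc.C_init],
        },
        "components": [component_to_dict(c) for c in sc.components],
        "w_pr": list(sc.w_pr),
        "application": [list(iv) for iv in sc.application],
        "t_expo": sc.t_expo,
        "distribution": {
            "d_m": sc.distribution.d_m,
            "gsd": sc.distribution.gsd,
            "n_classes": sc.distribution.n_classes,
        },
        "environment": {
            "T_room": env.T_room,
            "T_dr": env.T_dr,
            "rho_air": env.rho_air,
            "eta_air": env.eta_air,
            "nu_air": env.nu_air,
            "g": env.g,
        },
        "surfaces": {
            "floor_evap_fraction": sc.floor_evap_fraction,
            "residue_mode": sc.residue_mode,
            "SC": sc.SC,
        },
        "numerics": {"dt": sc.dt, "dt_post": sc.dt_post, "IM": sc.IM,
                     "K_crit": sc.K_crit},
    }
    if sc.mode == "wall":
        out["wall"] = {"W": sc.W}
        jet = sc.jet
        out["jet"] = {
            "D0": jet.D0,
            "opening_angle_full": jet.opening_angle_full,
            "s": jet.s,
            "v0": jet.v0,
            "Q_nozzle": jet.Q_nozzle,
        }
    return out


def scenario_from_dict(d: dict) -> Scenario:
    comps = tuple(component_from_dict(c) for c in d["components"])
    envd = d.get("environment", {})
    env = Environment(**envd)
    dist = DropletDistribution(**d["distribution"])
    jet = None
    if d.get("jet"):
        jet = JetGeometry(**{k: v for k, v in d["jet"].items() if v is not None})
    room = d["room"]
    ventd = d.get("ventilation", {})
    surf = d.get("surfaces", {})
    num = d.get("numerics", {})
    sc = Scenario(
        mode=d["mode"],
        V_room=float(room["V_room"]),
        F=float(room["F"]),
        h_room=room.get("h_room"),
        components=comps,
        w_pr=tuple(d["w_pr"]),
        application=tuple(tuple(iv) for iv in d["application"]),
        t_expo=float(d["t_expo"]),
        distribution=dist,
        env=env,
        Q_vent=float(ventd.get("Q_vent", 0.0)),
        C_vent=tuple(ventd.get("C_vent", (0.0, 0.0))),
        C_init=tuple(ventd.get("C_init", (0.0, 0.0))),
        W=d.get("wall", {}).get("W") if d.get("wall") else None,
        jet=jet,
        SC=surf.get("SC"),
        floor_evap_fraction=float(surf.get("floor_evap_fraction", 1.0)),
        residue_mode=surf.get("residue_mode", "settle"),
        dt=float(num.get("dt", 0.2)),
        dt_post=float(num.get("dt_post", 2.0)),
        IM=int(num.get("IM", 20)),
        K_crit=float(num.get("K_crit", 0.3)),
        name=d.get("name", "scenario"),
    )
    sc.validate()
    return sc


def save_scenario(sc: Scenario, path) -> None:
    Path(path).write_text(yaml.safe_dump(scenario_to_dict(sc), sort_keys=False))


def load_scenario(path) -> Scenario:
    return scenario_from_dict(yaml.safe_load(Path(path).read_text()))
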