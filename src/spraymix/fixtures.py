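"""Reference scenarios: the peroxide wall-spray example and the 19 room-spray
evaluation experiments.

Everything is generated programmatically from the published input tables so
every module of the package can be exercised without external data:

* ``worked_example_h2o2`` — disinfection of an animal housing by spraying a
  7.4% w/w aqueous hydrogen peroxide solution onto a 20 m^2 wall in a
  150 m^3 room.
* ``koch_experiment(i)`` — one of 19 controlled room-spraying experiments
  in a 11.2 x 4.5 x 4.0 m storage room (aqueous 0.2% dysprosium acetate +
  1% NaCl, 4 x 1 min spraying with 1 min pauses, 30 min follow-up), with
  the measured 37-min time-weighted averages for the nonvolatile aerosol
  (Respicon) and the water vapour (hygrometer).
* ``toy_*`` — minimal single-purpose scenarios for tests and oracles.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .engine import Scenario
from .physchem import (
    ActivityModel,
    Component,
    Environment,
    vapour_concentration_from_rh,
    water_saturation_pressure,
    wet_bulb_temperature,
)
from .spray_source import DropletDistribution, JetGeometry

# -- substance property sets -------------------------------------------------

#: Liquid molar volume of water, m^3/mol (density 1000 kg/m^3).
VM_WATER = 1.8e-5
#: Liquid molar volume of hydrogen peroxide, m^3/mol (pure density 1450 kg/m^3).
VM_H2O2 = 0.034 / 1450.0


def water_h2o2_components() -> tuple[Component, Component]:
    """Water and hydrogen peroxide with the reference property values.

    Saturation pressures are tabulated at room temperature (293 K) and at
    the droplet surface temperature (283.8 K); the droplet-evaporation
    lookup at the Hubbard reference temperature resolves to the nearest of
    the two.  Activity models are ideal (the mixture is only mildly
    nonideal; nonideal models can be supplied per component).
    """
    water = Component(
        name="H2O",
        M=0.018,
        psat={293.0: 2308.0, 283.8: 1276.0},
        D=2.4e-5,
        Vm=VM_WATER,
        beta=2.4e-3,
    )
    h2o2 = Component(
        name="H2O2",
        M=0.034,
        psat={293.0: 179.0, 283.8: 88.0},
        D=1.8e-5,
        Vm=VM_H2O2,
        beta=2.2e-3,
    )
    return water, h2o2


def worked_example_h2o2(**overrides) -> Scenario:
    """Wall-spraying of 7.4% w/w aqueous hydrogen peroxide (reference case).

    150 m^3 room, 0.125 m^3/s ventilation, 8 g/s release for 300 s onto a
    20 m^2 wall, hollow-cone nozzle (mass median diameter 250 um, GSD 1.8,
    5 size classes, full cone angle 25 deg, 0.4 m nozzle-wall distance,
    1 mm nozzle, v0 = 12.7 m/s), 5 h exposure window, floor evaporation
    restricted to 3/4 of the floor area.
    """
    env = Environment(T_room=293.0, T_dr=283.8)
    sc = Scenario(
        mode="wall",
        V_room=150.0,
        F=60.0,
        h_room=2.5,
        W=20.0,
        SC=0.06,
        Q_vent=0.125,
        components=water_h2o2_components(),
        w_pr=(0.926, 0.074),
        application=((0.0, 300.0, 8e-3),),
        t_expo=18000.0,
        distribution=DropletDistribution(d_m=250e-6, gsd=1.8, n_classes=5),
        jet=JetGeometry(D0=1e-3, opening_angle_full=25.0, s=0.4, v0=12.7,
                        Q_nozzle=0.6e-3 / 60.0),
        env=env,
        floor_evap_fraction=0.75,
        dt=0.2,
        dt_post=2.0,
        IM=20,
        name="worked-example-h2o2-wall-spray",
    )
    return replace(sc, **overrides) if overrides else sc


# -- room-spray evaluation experiments ---------------------------------------

#: (nozzle, release rate g/s, MMD um, temperature degC, initial RH %,
#:  measured inhalable nonvolatile aerosol mg/m^3, reference model aerosol
#:  estimate mg/m^3, measured water vapour mg/m^3, reference model vapour
#:  estimate mg/m^3) — 37-min time-weighted averages.
TABLE4_ROWS: tuple[tuple, ...] = (
    ("Flat fan",      19.6, 400, 16.1, 38, 0.32, 0.43,  7227,  9031),
    ("Flat fan",      15.4, 470, 16.3, 38, 0.30, 0.29,  7729,  8252),
    ("Flat fan",      10.0, 600, 16.6, 42, 0.03, 0.11,  7168,  8200),
    ("Flat fan",       5.0, 250, 16.7, 44, 0.30, 0.34,  7494,  9250),
    ("Flat fan",       4.2, 400, 17.0, 44, 0.13, 0.12,  7487,  8700),
    ("Flat fan",       2.7, 500, 17.5, 45, 0.04, 0.056, 7269,  8735),
    ("Flat fan",      10.4, 340, 18.3, 39, 0.34, 0.31,  8247,  9870),
    ("Flat fan",       8.3, 380, 17.7, 43, 0.16, 0.22,  7807,  9510),
    ("Flat fan",       5.4, 420, 19.3, 43, 0.06, 0.14,  8750,  9880),
    ("Hollow cone",   14.2, 280, 18.0, 43, 0.71, 0.58,  9630, 11220),
    ("Hollow cone",   11.3, 300, 17.9, 40, 0.45, 0.42,  9421, 11210),
    ("Hollow cone",    6.0, 290, 18.1, 40, 0.26, 0.28,  8611,  9525),
    ("Hollow cone",    9.8, 230, 18.2, 42, 0.72, 0.79, 10673, 11110),
    ("Hollow cone",    8.1, 270, 17.7, 45, 0.40, 0.41, 10660, 10385),
    ("Hollow cone",    5.8, 340, 19.2, 45, 0.16, 0.19,  9356, 10415),
    ("Cold fogger",    5.5, 130, 20.1, 45, 1.87, 2.32, 10210, 11954),
    ("Cold fogger",   13.3, 140, 19.0, 40, 3.39, 4.69, 11516, 13540),
    ("Cold fogger",    7.9, 110, 18.6, 42, 4.41, 5.12, 10138, 12488),
    ("Therm. fogger",  7.3,  50, 21.4, 33, 15.7, 17.1, 10080, 12261),
)

TABLE4_COLUMNS = (
    "nozzle", "release_rate_g_s", "mmd_um", "temperature_C", "init_rh_percent",
    "measured_aerosol_mg_m3", "reference_aerosol_mg_m3",
    "measured_vapour_mg_m3", "reference_vapour_mg_m3",
)

#: Room of the evaluation experiments: 11.2 x 4.5 x 4.0 m.
KOCH_ROOM_VOLUME = 11.2 * 4.5 * 4.0
KOCH_FLOOR_AREA = 11.2 * 4.5
#: Nonvolatile mass fraction of the sprayed formulation (0.2% dysprosium
#: acetate + 1% NaCl, pooled).
KOCH_NONVOLATILE_W = 0.012
#: Pooled nonvolatile pseudo-component: mass-weighted molar mass and molar
#: volume of dysprosium acetate (339.6 g/mol, ~2000 kg/m^3 assumed) and
#: NaCl (58.44 g/mol, 2165 kg/m^3).
M_NONVOLATILE = (0.2 * 0.3396 + 1.0 * 0.05844) / 1.2
VM_NONVOLATILE = (0.2 * 0.3396 / 2000.0 + 1.0 * 0.05844 / 2165.0) / 1.2


def table4_frame() -> pd.DataFrame:
    """The packaged evaluation data set as a DataFrame."""
    return pd.DataFrame(list(TABLE4_ROWS), columns=list(TABLE4_COLUMNS))


def koch_components(T_room: float, T_ref: float) -> tuple[Component, Component]:
    """Water plus the pooled nonvolatile residue for one experiment.

    The water saturation-pressure table carries Magnus values at the room
    temperature (surface evaporation) and at the droplet reference
    temperature.
    """
    water = Component(
        name="H2O",
        M=0.018,
        psat={T_room: water_saturation_pressure(T_room),
              T_ref: water_saturation_pressure(T_ref)},
        D=2.4e-5,
        Vm=VM_WATER,
        beta=2.4e-3,
    )
    residue = Component(
        name="residue",
        M=M_NONVOLATILE,
        psat={T_room: 0.0},
        D=1.0e-5,
        Vm=VM_NONVOLATILE,
    )
    return water, residue


def koch_experiment(row_index: int, Q_vent: float = 0.0, dt: float = 0.05,
                    n_classes: int = 5, droplet_cooling: bool = False) -> tuple[Scenario, dict]:
    """Scenario and measured values for evaluation experiment ``row_index``.

    ``row_index`` is 1-based (1..19).  By default the droplet surface
    temperature equals the room temperature: the measured aerosol is the
    nonvolatile residue, which spends almost all of its airborne lifetime
    at thermal equilibrium with the room; ``droplet_cooling=True`` instead
    uses a psychrometric wet-bulb estimate.  Ventilation defaults to zero
    (sealed storage room) but can be overridden.
    """
    if not (1 <= row_index <= len(TABLE4_ROWS)):
        raise ValueError(f"row_index must be 1..{len(TABLE4_ROWS)}")
    row = dict(zip(TABLE4_COLUMNS, TABLE4_ROWS[row_index - 1]))
    T_room = row["temperature_C"] + 273.15
    T_dr = wet_bulb_temperature(T_room, row["init_rh_percent"]) if droplet_cooling else T_room
    env = Environment(T_room=T_room, T_dr=T_dr)
    comps = koch_components(T_room, env.T_ref)
    c_init_water = vapour_concentration_from_rh(row["init_rh_percent"], T_room)
    rate = row["release_rate_g_s"] * 1e-3
    spray = tuple(
        (120.0 * k, 120.0 * k + 60.0, rate) for k in range(4)
    )
    sc = Scenario(
        mode="room",
        V_room=KOCH_ROOM_VOLUME,
        F=KOCH_FLOOR_AREA,
        h_room=4.0,
        Q_vent=Q_vent,
        components=comps,
        w_pr=(1.0 - KOCH_NONVOLATILE_W, KOCH_NONVOLATILE_W),
        application=spray,
        t_expo=420.0 + 1800.0,
        distribution=DropletDistribution(
            d_m=row["mmd_um"] * 1e-6, gsd=1.8, n_classes=n_classes
        ),
        env=env,
        C_init=(c_init_water, 0.0),
        dt=dt,
        dt_post=2.0,
        IM=20,
        name=f"room-spray-experiment-{row_index:02d}",
    )
    measured = {
        "nozzle": row["nozzle"],
        "aerosol_mg_m3": row["measured_aerosol_mg_m3"],
        "vapour_mg_m3": row["measured_vapour_mg_m3"],
        "reference_aerosol_mg_m3": row["reference_aerosol_mg_m3"],
        "reference_vapour_mg_m3": row["reference_vapour_mg_m3"],
    }
    return sc, measured


# -- small synthetic scenarios for tests and oracles --------------------------


def toy_components(
    psat1: float = 2308.0,
    psat2: float = 0.0,
    T: float = 293.0,
    M=(0.018, 0.05),
    Vm=(1.8e-5, 3e-5),
    D=(2.4e-5, 1.0e-5),
    beta=(2.4e-3, 1.0e-3),
    activity=(None, None),
) -> tuple[Component, Component]:
    """A configurable volatile/nonvolatile pair for synthetic test scenarios."""
    out = []
    for i, p in enumerate((psat1, psat2)):
        out.append(
            Component(
                name=f"comp{i + 1}",
                M=M[i],
                psat={T: p},
                D=D[i],
                Vm=Vm[i],
                beta=beta[i],
                activity=activity[i] or ActivityModel(),
            )
        )
    return tuple(out)


def toy_single_pulse(
    psat1: float = 0.0,
    psat2: float = 0.0,
    d_m: float = 100e-6,
    gsd: float = 1.8,
    n_classes: int = 1,
    rate: float = 1e-3,
    duration: float = 4.0,
    t_expo: float = 600.0,
    V_room: float = 150.0,
    F: float = 60.0,
    Q_vent: float = 0.0,
    g: float = 9.81,
    dt: float = 0.2,
    dt_post: float = 2.0,
    IM: int = 20,
    w_pr: tuple[float, float] = (1.0, 0.0),
    T: float = 293.0,
    **overrides,
) -> Scenario:
    """Room-mode scenario releasing a single pulse (duration = IM*dt)."""
    env = Environment(T_room=T, T_dr=T, g=g)
    sc = Scenario(
        mode="room",
        V_room=V_room,
        F=F,
        Q_vent=Q_vent,
        components=toy_components(psat1=psat1, psat2=psat2, T=T),
        w_pr=w_pr,
        application=((0.0, duration, rate),),
        t_expo=t_expo,
        distribution=DropletDistribution(d_m=d_m, gsd=gsd, n_classes=n_classes),
        env=env,
        dt=dt,
        dt_post=dt_post,
        IM=IM,
        name="toy-single-pulse",
    )
    return replace(sc, **overrides) if overrides else sc
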