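"""Scenario representation and the extended forward-Euler simulation engine.

Continuous spraying is approximated by discrete release pulses injected
every ``IM * dt`` seconds, each split into lognormal size classes.  Every
live (pulse, class) state carries its own aerosol concentration, droplet
diameter and liquid composition, and all states are advanced together with
the room vapour, the floor film and (for wall spraying) the wall area
elements by a fully explicit Euler scheme: every rate within a step reads
the room state from the start of that step.  After the application the
step size switches to the coarser ``dt_post`` once no droplet pulse is
alive any more (droplet evaporation is fast compared to surface films).

Two numerical guards keep the explicit scheme physical without changing
the model:

* per-step loss capping — the combined ventilation + settling +
  evaporation loss of a pulse is rescaled proportionally when it would
  overdraw the pulse's airborne mass within one step, so mass is routed to
  the same sinks but never goes negative;
* a quasi-equilibrium closure for hygroscopic residue droplets — once the
  volatile component of a droplet with a nonvolatile core relaxes to its
  Raoult equilibrium faster than the time step, the composition is set
  directly to that equilibrium (conserving the nonvolatile core exactly
  and exchanging the implied volatile mass with the vapour phase) instead
  of taking an unstable explicit step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .physchem import (
    Component,
    Environment,
    R_GAS,
    mixture_density,
    mole_fractions_from_mass,
)
from .spray_source import (
    DropletDistribution,
    JetGeometry,
    K_CRIT_DEFAULT,
    discretise_distribution,
    impaction_parameter,
    inhalable_fraction,
    transfer_efficiency,
)
from .surfaces import film_step_array


class ScenarioError(ValueError):
    """Raised when a scenario fails validation."""


class InstabilityError(RuntimeError):
    """Raised when the explicit integration produces non-finite state."""


@dataclass(frozen=True)
class Scenario:
    """Complete description of one spraying exposure situation (SI units).

    ``application`` is a list of ``(start, end, release_rate)`` intervals in
    seconds and kg/s; pulses are injected every ``IM * dt`` inside each
    interval, each carrying ``rate * IM * dt`` of liquid.  ``w_pr`` are the
    product mass fractions of the two components.  In ``wall`` mode each
    pulse is split by the impaction module into a deposited part (routed to
    that pulse's wall area element) and an airborne overspray part.
    """

    mode: str                                  # "room" | "wall"
    V_room: float                              # room volume, m^3
    F: float                                   # floor area, m^2
    components: tuple[Component, Component]
    w_pr: tuple[float, float]                  # product mass fractions
    application: tuple[tuple[float, float, float], ...]
    t_expo: float                              # simulated exposure time, s
    distribution: DropletDistribution
    env: Environment = field(default_factory=Environment)
    Q_vent: float = 0.0                        # ventilation flow, m^3/s
    C_vent: tuple[float, float] = (0.0, 0.0)   # supply-air vapour conc., kg/m^3
    C_init: tuple[float, float] = (0.0, 0.0)   # initial vapour conc., kg/m^3
    W: float | None = None                     # sprayed wall area, m^2 (wall mode)
    jet: JetGeometry | None = None             # jet geometry (wall mode)
    SC: float | None = None                    # nominal surface coverage, kg/m^2
    floor_evap_fraction: float = 1.0
    residue_mode: str = "settle"               # "settle" | "airborne"
    dt: float = 0.2                            # spraying-phase step, s
    dt_post: float = 2.0                       # post-spraying step, s
    IM: int = 20                               # pulse spacing in units of dt
    K_crit: float = K_CRIT_DEFAULT
    h_room: float | None = None
    name: str = "scenario"
    d_min: float = 0.5e-6                      # droplet termination diameter, m
    mass_min: float = 1e-15                    # pulse termination mass, kg

    def validate(self) -> None:
        if self.mode not in ("room", "wall"):
            raise ScenarioError(f"mode must be 'room' or 'wall', got {self.mode!r}")
        if len(self.components) != 2:
            raise ScenarioError("exactly two components are required")
        if abs(sum(self.w_pr) - 1.0) > 1e-9 or any(w < 0 for w in self.w_pr):
            raise ScenarioError("product mass fractions must be nonnegative and sum to 1")
        if self.V_room <= 0 or self.F <= 0:
            raise ScenarioError("room volume and floor area must be positive")
        if self.dt <= 0 or self.dt_post < self.dt:
            raise ScenarioError("need dt > 0 and dt_post >= dt")
        if self.IM < 1 or int(self.IM) != self.IM:
            raise ScenarioError("IM must be a positive integer")
        if not (0.0 < self.floor_evap_fraction <= 1.0):
            raise ScenarioError("floor_evap_fraction must be in (0, 1]")
        if self.residue_mode not in ("settle", "airborne"):
            raise ScenarioError("residue_mode must be 'settle' or 'airborne'")
        if self.Q_vent < 0 or any(c < 0 for c in self.C_init) or any(c < 0 for c in self.C_vent):
            raise ScenarioError("ventilation and concentrations must be nonnegative")
        last_end = 0.0
        for start, end, rate in self.application:
            if end <= start or rate < 0:
                raise ScenarioError("application intervals need end > start and rate >= 0")
            if start < last_end - 1e-12:
                raise ScenarioError("application intervals must be ordered and disjoint")
            last_end = end
        if self.application and self.t_expo < last_end:
            raise ScenarioError("t_expo must cover the application schedule")
        if self.mode == "wall":
            if self.jet is None or self.W is None or self.W <= 0:
                raise ScenarioError("wall mode requires a jet geometry and W > 0")
        T = self.env.T_room
        for comp in self.components:
            if not comp.nonvolatile and comp.beta is None:
                raise ScenarioError(
                    f"volatile component {comp.name} needs a surface mass-transfer "
                    "coefficient beta"
                )
            if not comp.nonvolatile:
                comp.psat_at(T)          # fail loudly now, not mid-run
                comp.psat_at(self.env.T_ref)

    @property
    def application_end(self) -> float:
        return max((end for _, end, _ in self.application), default=0.0)

    def pulse_schedule(self) -> list[tuple[float, float]]:
        """(injection time, liquid mass kg) for every release pulse."""
        spacing = self.IM * self.dt
        out = []
        for start, end, rate in self.application:
            n = max(int(round((end - start) / spacing)), 1)
            for j in range(n):
                t = start + j * spacing
                if t < end - 1e-9:
                    out.append((t, rate * spacing))
        return out

    def product_mole_fraction_1(self) -> float:
        return float(mole_fractions_from_mass(np.array(self.w_pr), self.components)[0])

    def product_density(self) -> float:
        x1 = self.product_mole_fraction_1()
        return mixture_density(np.array([x1, 1.0 - x1]), self.components)


@dataclass
class SimulationResult:
    """Time series and bookkeeping of one simulation run.

    ``frame`` columns: t [s]; A_total, A_inh, A_<name>, A_inh_<name>,
    C_<name> [kg/m^3]; rate_settle, rate_evap_<name>, rate_floor_evap_<name>,
    rate_wall_evap_<name> [kg/s]; m_floor_<name>, m_wall_<name> [kg].
    """

    frame: pd.DataFrame
    scenario: Scenario
    metadata: dict

    def twa(self, column: str, window: tuple[float, float] | None = None) -> float:
        return time_weighted_average(self, column, window)


def run(scenario: Scenario, record_every: int = 1) -> SimulationResult:
    """Simulate a scenario and return the assembled result."""
    scenario.validate()
    return _Simulation(scenario, record_every).run()


def time_weighted_average(
    result: SimulationResult, column: str, window: tuple[float, float] | None = None
) -> float:
    """Trapezoidal time average of a result column over ``window`` seconds."""
    t = result.frame["t"].to_numpy()
    y = result.frame[column].to_numpy()
    if window is None:
        window = (float(t[0]), float(t[-1]))
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty averaging window")
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
        raise ValueError("window outside the simulated span")
    grid = np.concatenate([[t0], t[(t > t0) & (t < t1)], [t1]])
    yi = np.interp(grid, t, y)
    return float(np.trapezoid(yi, grid) / (t1 - t0))


def mass_audit(result: SimulationResult, scenario: Scenario | None = None) -> dict:
    """Mass ledger of a finished run and its relative closure error.

    Inputs (released liquid, initial and supplied vapour) are compared with
    the final inventory (airborne aerosol and vapour, floor and wall films)
    plus the time-integrated ventilation outflow.
    """
    md = result.metadata
    mass_in = md["released_airborne"] + md["released_wall"] + md["initial_vapour"] + md["supply_in"]
    mass_out = (
        md["final_aerosol"]
        + md["final_vapour"]
        + md["final_floor"]
        + md["final_wall"]
        + md["vented_aerosol"]
        + md["vented_vapour"]
        + md["clamp_loss"]
    )
    closure = abs(mass_in - mass_out) / mass_in if mass_in > 0 else abs(mass_out)
    return {
        "released": md["released_airborne"] + md["released_wall"],
        "released_airborne": md["released_airborne"],
        "released_wall": md["released_wall"],
        "initial_vapour": md["initial_vapour"],
        "supply_in": md["supply_in"],
        "airborne_aerosol": md["final_aerosol"],
        "airborne_vapour": md["final_vapour"],
        "on_floor": md["final_floor"],
        "on_wall": md["final_wall"],
        "vented": md["vented_aerosol"] + md["vented_vapour"],
        "closure_error": closure,
    }


def surface_coverage_check(scenario: Scenario, result: SimulationResult) -> float | None:
    """Compare deposited wall mass per area with the nominal coverage SC.

    Returns the realised coverage (kg/m^2) and warns when it deviates from
    the configured SC by more than 50%.  SC itself never enters the
    dynamics.
    """
    if scenario.mode != "wall" or scenario.W is None:
        return None
    realised = result.metadata["released_wall"] / scenario.W
    if scenario.SC:
        if not (0.5 * scenario.SC <= realised <= 1.5 * scenario.SC):
            warnings.warn(
                f"deposited mass per wall area {realised:.3g} kg/m^2 deviates from "
                f"nominal surface coverage {scenario.SC:.3g} kg/m^2 by more than 50%",
                stacklevel=2,
            )
    return realised


def _solve_x_gamma(component: Component, target: np.ndarray) -> np.ndarray:
    """Solve x * gamma(x) = target on [0, 1] (vectorised, monotone models)."""
    target = np.asarray(target, dtype=float)
    if component.activity.kind == "ideal":
        return np.clip(target, 0.0, 1.0 - 1e-9)
    lo = np.zeros_like(target)
    hi = np.full_like(target, 1.0 - 1e-9)
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        val = mid * np.asarray(component.activity.gamma(mid))
        lo = np.where(val < target, mid, lo)
        hi = np.where(val >= target, mid, hi)
    return 0.5 * (lo + hi)


class _Simulation:
    def __init__(self, sc: Scenario, record_every: int = 1):
        self.sc = sc
        self.record_every = max(int(record_every), 1)
        env = sc.env
        self.V = sc.V_room
        self.Q = sc.Q_vent
        self.T_r = env.T_ref
        self.T_room = env.T_room
        c1, c2 = sc.components
        self.comps = sc.components
        self.M = np.array([c1.M, c2.M])
        self.Vm = np.array([c1.Vm, c2.Vm])
        self.D = np.array([c1.D, c2.D])
        self.p_dr = np.array([c1.psat_at(self.T_r) if not c1.nonvolatile else 0.0,
                              c2.psat_at(self.T_r) if not c2.nonvolatile else 0.0])
        self.beta = np.array([c.beta if c.beta is not None else 0.0 for c in sc.components])
        self.volatile = self.p_dr > 0

        # hygroscopic-residue closure applies when exactly one component is
        # nonvolatile at droplet temperature
        if self.volatile[0] and not self.volatile[1]:
            self.iv, self.inv = 0, 1
        elif self.volatile[1] and not self.volatile[0]:
            self.iv, self.inv = 1, 0
        else:
            self.iv = self.inv = None

        self.x1_init = sc.product_mole_fraction_1()
        self.rho_init = sc.product_density()

        classes = discretise_distribution(sc.distribution)
        self.classes = classes
        self.n_c = len(classes)
        self.d_init = np.array([c.d_median for c in classes])
        self.I_c = inhalable_fraction(self.d_init)

        if sc.mode == "wall":
            K = impaction_parameter(self.d_init, sc.jet, self.rho_init, env)
            self.xi = np.asarray(transfer_efficiency(K, sc.K_crit))
        else:
            self.xi = np.zeros(self.n_c)

        self.schedule = sc.pulse_schedule()
        self.n_p = len(self.schedule)
        n_states = self.n_p * self.n_c

        self.A = np.zeros(n_states)
        self.d = np.full(n_states, 1e-6)
        self.x1 = np.full(n_states, self.x1_init)
        self.alive = np.zeros(n_states, dtype=bool)
        self.I_state = np.tile(self.I_c, self.n_p)
        self.C = np.array(sc.C_init, dtype=float)
        self.m_F = np.zeros(2)
        if sc.mode == "wall" and self.n_p > 0:
            self.dW = sc.W / self.n_p
            self.m_W = np.zeros((self.n_p, 2))
        else:
            self.dW = 0.0
            self.m_W = np.zeros((0, 2))

        self.audit = {
            "released_airborne": 0.0,
            "released_wall": 0.0,
            "initial_vapour": float(np.sum(self.C) * self.V),
            "supply_in": 0.0,
            "vented_aerosol": 0.0,
            "vented_vapour": 0.0,
            "clamp_loss": 0.0,
        }
        names = [c.name for c in sc.components]
        self.columns = (
            ["t", "A_total", "A_inh"]
            + [f"A_{n}" for n in names]
            + [f"A_inh_{n}" for n in names]
            + [f"C_{n}" for n in names]
            + ["rate_settle"]
            + [f"rate_evap_{n}" for n in names]
            + [f"rate_floor_evap_{n}" for n in names]
            + [f"rate_wall_evap_{n}" for n in names]
            + [f"m_floor_{n}" for n in names]
            + [f"m_wall_{n}" for n in names]
        )
        self.records: list[list[float]] = []
        self.n_steps = 0
        self.n_alive = 0

    # -- helpers -----------------------------------------------------------

    def _inject(self, p: int, mass: float) -> None:
        sc = self.sc
        base = p * self.n_c
        mass_c = mass / self.n_c
        w = np.array(sc.w_pr)
        deposited = float(np.sum(self.xi * mass_c))
        airborne_c = (1.0 - self.xi) * mass_c
        sl = slice(base, base + self.n_c)
        self.A[sl] = airborne_c / self.V
        self.d[sl] = self.d_init
        self.x1[sl] = self.x1_init
        live = airborne_c > 0
        self.alive[sl] = live
        self.n_alive += int(live.sum())
        self.audit["released_airborne"] += float(airborne_c.sum())
        if deposited > 0:
            self.m_W[p] += deposited * w
            self.audit["released_wall"] += deposited

    def _gamma(self, i: int, x):
        return np.asarray(self.comps[i].activity.gamma(x))

    # -- main loop ---------------------------------------------------------

    def run(self) -> SimulationResult:
        sc = self.sc
        app_end = sc.application_end
        t = 0.0
        next_p = 0
        k = 0
        while t < sc.t_expo - 1e-9:
            while next_p < self.n_p and self.schedule[next_p][0] <= t + 1e-9:
                self._inject(next_p, self.schedule[next_p][1])
                next_p += 1
            dt = sc.dt if (t < app_end - 1e-9 or self.n_alive > 0) else sc.dt_post
            dt = min(dt, sc.t_expo - t)
            self._step(t, dt, record=(k % self.record_every == 0))
            t += dt
            k += 1
            if k % 256 == 0 and not np.isfinite(self.A.sum() + self.C.sum()):
                raise InstabilityError(
                    f"non-finite state at t = {t:.3f} s; the explicit scheme is "
                    f"unstable at dt = {dt:g} s — reduce dt/dt_post"
                )
        self._step(t, 0.0, record=True)  # final state snapshot, no update
        if not np.isfinite(self.A.sum() + self.C.sum() + self.m_F.sum()):
            raise InstabilityError("non-finite final state; reduce dt/dt_post")
        frame = pd.DataFrame(self.records, columns=self.columns)
        md = dict(self.audit)
        md.update(
            final_aerosol=float(self.A.sum() * self.V),
            final_vapour=float(self.C.sum() * self.V),
            final_floor=float(self.m_F.sum()),
            final_wall=float(self.m_W.sum()),
            n_steps=self.n_steps,
            n_pulses=self.n_p,
            n_classes=self.n_c,
            T_ref=self.T_r,
        )
        return SimulationResult(frame=frame, scenario=sc, metadata=md)

    # -- one explicit Euler step -------------------------------------------

    def _step(self, t: float, dt: float, record: bool) -> None:
        sc = self.sc
        V = self.V
        A, d, x1, alive = self.A, self.d, self.x1, self.alive
        M1, M2 = self.M
        V1, V2 = self.Vm
        D1, D2 = self.D
        p1, p2 = self.p_dr
        T = self.T_r
        C = self.C

        x2 = 1.0 - x1
        Mbar = M1 * x1 + M2 * x2
        Vbar = V1 * x1 + V2 * x2
        rho = Mbar / Vbar
        w1 = x1 * M1 / Mbar
        g1 = self._gamma(0, x1)
        g2 = self._gamma(1, x2)
        Ceq1 = M1 * p1 * x1 * g1 / (R_GAS * T)
        Ceq2 = M2 * p2 * x2 * g2 / (R_GAS * T)
        dC1 = Ceq1 - C[0]
        dC2 = Ceq2 - C[1]

        vent = self.Q * A
        vsed = sc.env.g * rho * d * d / (18.0 * sc.env.eta_air)
        sett = sc.F * vsed * A
        inv_d2rho = 1.0 / (d * d * rho)
        ev1 = 12.0 * D1 * V * A * dC1 * inv_d2rho
        ev2 = 12.0 * D2 * V * A * dC2 * inv_d2rho

        # hygroscopic-residue stiffness: relaxation rate of the volatile
        # mole fraction toward Raoult equilibrium
        stiff = np.zeros_like(alive)
        if self.iv is not None and dt > 0:
            xv = x1 if self.iv == 0 else x2
            gv = g1 if self.iv == 0 else g2
            Dv, pv = self.D[self.iv], self.p_dr[self.iv]
            k_relax = 12.0 * Vbar * (1.0 - xv) * Dv * pv * gv / (d * d * R_GAS * T)
            stiff = alive & (k_relax * dt > 1.0)
            if np.any(stiff):
                ev1 = np.where(stiff, 0.0, ev1)
                ev2 = np.where(stiff, 0.0, ev2)

        # condensation cap: droplets cannot absorb more vapour than present
        if dt > 0:
            for i, ev in enumerate((ev1, ev2)):
                neg = np.sum(np.clip(-ev, 0.0, None))
                budget = 0.9 * C[i] * V / dt
                if neg * dt > 0 and neg > budget:
                    scale = budget / neg
                    if i == 0:
                        ev1 = np.where(ev1 < 0, ev1 * scale, ev1)
                    else:
                        ev2 = np.where(ev2 < 0, ev2 * scale, ev2)

            # loss caps: bulk removal (ventilation + settling) cannot exceed
            # the pulse mass, and each component's evaporation cannot exceed
            # that component's share of what remains — otherwise a drying
            # droplet would evaporate its nonvolatile core into the vapour
            avail = A * V / dt
            bulk = vent + sett
            with np.errstate(invalid="ignore", divide="ignore"):
                scale = np.where(bulk > avail, np.where(bulk > 0, avail / bulk, 1.0), 1.0)
            vent = vent * scale
            sett = sett * scale
            budget_ev = np.maximum(avail - vent - sett, 0.0)
            ev1 = np.minimum(ev1, budget_ev * w1)
            ev2 = np.minimum(ev2, budget_ev * (1.0 - w1))

        # dead states carry A = 0 and hence contribute nothing to any rate
        evap_i = np.array([float(ev1.sum()), float(ev2.sum())])
        sett_total = float(sett.sum())
        sett_i = np.array([float((sett * w1).sum()), float((sett * (1.0 - w1)).sum())])

        # surface films (explicit in C); floor fed by this step's settling
        floor_real = np.zeros(2)
        wall_real = np.zeros(2)
        if dt > 0:
            F_eff = sc.F * sc.floor_evap_fraction
            m_new, realised = film_step_array(
                self.m_F, F_eff, self.beta, sett_i, C, self.comps, self.T_room, dt
            )
            floor_next = m_new[0]
            floor_real = realised[0]
            wall_next = self.m_W
            if self.m_W.shape[0]:
                wall_next, wreal = film_step_array(
                    self.m_W, self.dW, self.beta, np.zeros_like(self.m_W), C,
                    self.comps, self.T_room, dt,
                )
                wall_real = wreal.sum(axis=0)

        if record:
            Aa = np.where(alive, A, 0.0)
            row = [
                t,
                float(Aa.sum()),
                float((Aa * self.I_state).sum()),
                float((Aa * w1).sum()),
                float((Aa * (1.0 - w1)).sum()),
                float((Aa * w1 * self.I_state).sum()),
                float((Aa * (1.0 - w1) * self.I_state).sum()),
                float(C[0]),
                float(C[1]),
                sett_total,
                float(evap_i[0]),
                float(evap_i[1]),
                float(floor_real[0]),
                float(floor_real[1]),
                float(wall_real[0]),
                float(wall_real[1]),
                float(self.m_F[0]),
                float(self.m_F[1]),
                float(self.m_W[:, 0].sum()),
                float(self.m_W[:, 1].sum()),
            ]
            self.records.append(row)

        if dt <= 0:
            return

        # Euler update of the per-pulse component masses; diameter and
        # composition follow from the updated moles (this reproduces the
        # SRMM derivative equations to first order in dt but keeps each
        # component's mass balance exact under the caps and clamps)
        mP = A * V
        m1 = mP * w1
        m2 = mP - m1
        m1n = np.maximum(m1 - dt * (ev1 + (vent + sett) * w1), 0.0)
        m2n = np.maximum(m2 - dt * (ev2 + (vent + sett) * (1.0 - w1)), 0.0)
        A_new = (m1n + m2n) / V
        mol1 = m1n / M1
        mol2 = m2n / M2
        tot = mol1 + mol2
        upd = alive & ~stiff & (tot > 0) & (mP > 0)
        x1_new = np.where(upd, mol1 / np.maximum(tot, 1e-300), x1)
        # ventilation/settling remove whole droplets, evaporation shrinks them
        with np.errstate(invalid="ignore", divide="ignore"):
            f_keep = np.clip(1.0 - dt * (vent + sett) / np.maximum(mP, 1e-300), 1e-12, 1.0)
            N_dr = 6.0 * mP / (np.pi * rho * d**3)
            vol_new = mol1 * V1 + mol2 * V2
            d_candidate = np.cbrt(6.0 * vol_new / (np.pi * np.maximum(N_dr * f_keep, 1e-300)))
        d_new = np.where(upd, d_candidate, d)

        C_new = C + dt * (
            (evap_i + floor_real + wall_real) / V - self.Q * (C - np.array(sc.C_vent)) / V
        )

        # quasi-equilibrium closure for stiff residue states
        if np.any(stiff):
            idx = np.nonzero(stiff)[0]
            iv, inv = self.iv, self.inv
            mP = A[idx] * V
            wv = w1[idx] if iv == 0 else (1.0 - w1[idx])
            n_v = mP * wv / self.M[iv]
            n_nv = mP * (1.0 - wv) / self.M[inv]
            target = C[iv] * R_GAS * T / (self.M[iv] * self.p_dr[iv])
            x_star = _solve_x_gamma(self.comps[iv], np.full(idx.shape, target))
            n_v_new = n_nv * x_star / (1.0 - x_star)
            dm_v = (n_v_new - n_v) * self.M[iv]
            absorb = np.clip(dm_v, 0.0, None).sum()
            budget = 0.25 * C[iv] * V
            if absorb > budget and absorb > 0:
                f = budget / absorb
                dm_v = np.where(dm_v > 0, dm_v * f, dm_v)
                n_v_new = n_v + dm_v / self.M[iv]
            N_dr = 6.0 * mP / (np.pi * rho[idx] * d[idx] ** 3)
            vol_new = n_v_new * self.Vm[iv] + n_nv * self.Vm[inv]
            d_new[idx] = np.cbrt(6.0 * vol_new / (np.pi * N_dr))
            x_v_new = n_v_new / (n_v_new + n_nv)
            x1_new[idx] = x_v_new if iv == 0 else 1.0 - x_v_new
            mP_new = n_v_new * self.M[iv] + n_nv * self.M[inv]
            # closure exchange plus this step's (already scaled) vent/settle
            A_new[idx] = mP_new / V - dt * (vent[idx] + sett[idx]) / V
            C_new[iv] -= float(dm_v.sum()) / V

        # pulse termination --------------------------------------------------
        mass_new = A_new * V
        w1_new = x1_new * M1 / (x1_new * M1 + (1.0 - x1_new) * M2)
        if sc.residue_mode == "settle":
            small_d = d_new < sc.d_min
        else:
            nonvol_mass = mass_new * np.where(self.volatile[0], 1.0 - w1_new, w1_new) \
                if self.iv is not None else np.zeros_like(mass_new)
            small_d = (d_new < sc.d_min) & (nonvol_mass < sc.mass_min)
        dying = alive & (small_d | (mass_new < sc.mass_min) | (d_new <= 0))
        if np.any(dying):
            r1 = mass_new[dying] * w1_new[dying]
            r2 = mass_new[dying] * (1.0 - w1_new[dying])
            for i, r in enumerate((float(np.clip(r1, 0, None).sum()),
                                   float(np.clip(r2, 0, None).sum()))):
                if r <= 0:
                    continue
                if self.volatile[i]:
                    C_new[i] += r / V
                else:
                    floor_next = floor_next.copy()
                    floor_next[i] += r
            A_new[dying] = 0.0
            d_new[dying] = np.maximum(d_new[dying], 1e-9)
            self.n_alive -= int(dying.sum())
            alive = alive & ~dying
            self.alive = alive

        # clamps and bookkeeping --------------------------------------------
        neg_C = np.clip(-C_new, 0.0, None)
        self.audit["clamp_loss"] += float(neg_C.sum() * V) * -1.0
        C_new = np.maximum(C_new, 0.0)
        A_new = np.maximum(A_new, 0.0)

        self.audit["vented_aerosol"] += dt * float(vent.sum())
        self.audit["vented_vapour"] += dt * self.Q * float(C.sum())
        self.audit["supply_in"] += dt * self.Q * float(np.sum(sc.C_vent))

        self.A = np.where(alive, A_new, 0.0)
        self.d = np.maximum(d_new, 1e-9)
        self.x1 = x1_new
        self.C = C_new
        self.m_F = floor_next
        if self.m_W.shape[0]:
            self.m_W = wall_next
        self.n_steps += 1
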