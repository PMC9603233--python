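"""Per-pulse aerosol rates: ventilation, settling, binary droplet evaporation.

Droplet evaporation follows the simplified rapid-mixing model (SRMM) for
two-component droplets: no concentration gradient inside the droplet, an
effective gas-phase diffusion flux per component, Raoult's law with
activity coefficients at the droplet surface, and — as the central
extension — a finite far-field vapour concentration (backpressure) that
slows, stops or reverses evaporation as the room air loads up.

All functions are vectorised over pulse states: ``A`` (aerosol mass
concentration of the pulse, kg/m^3), ``d`` (droplet diameter, m) and
``x1`` (mole fraction of component 1 in the droplet) may be scalars or
equal-length arrays.  Evaporation rates are positive when mass leaves the
droplets (the vapour phase gains what the aerosol loses).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .physchem import Component, Environment, R_GAS

#: Diameter above which the uncorrected Stokes settling law overestimates
#: drag-limited fall speeds (no correction is applied; a warning is issued).
STOKES_LIMIT_D = 50e-6


@dataclass
class PulseState:
    """State of one release pulse x size class."""

    l: int
    c: int
    A: float      # aerosol mass concentration contributed by this pulse, kg/m^3
    d: float      # current droplet diameter, m
    x1: float     # mole fraction of component 1 in the droplet liquid
    alive: bool = True


@dataclass
class RoomState:
    """Room-air vapour state: per-component concentration (kg/m^3) and time."""

    C: np.ndarray
    t: float = 0.0


def _as_arrays(*vals):
    return [np.asarray(v, dtype=float) for v in vals]


def _maybe_scalar(out, *inputs):
    if all(np.ndim(i) == 0 for i in inputs):
        return float(out)
    return out


def binary_props(components: Sequence[Component], T: float):
    """Per-component (M, psat(T), D, Vm) arrays for a binary pair."""
    M = np.array([c.M for c in components])
    psat = np.array([c.psat_at(T) for c in components])
    D = np.array([c.D for c in components])
    Vm = np.array([c.Vm for c in components])
    return M, psat, D, Vm


def droplet_density(x1, components: Sequence[Component]):
    """Liquid density of the droplet from molar volumes, kg/m^3."""
    x1 = np.asarray(x1, dtype=float)
    M1, M2 = components[0].M, components[1].M
    V1, V2 = components[0].Vm, components[1].Vm
    x2 = 1.0 - x1
    out = (M1 * x1 + M2 * x2) / (V1 * x1 + V2 * x2)
    return _maybe_scalar(out, x1)


def ventilation_loss_rate(A, Q_vent: float):
    """Aerosol mass loss rate to the exhaust, kg/s: Q_vent * A."""
    A = np.asarray(A, dtype=float)
    return _maybe_scalar(Q_vent * A, A)


def settling_velocity(d, rho_dr, env: Environment, warn: bool = True):
    """Stokes settling velocity v = g rho d^2 / (18 eta), m/s.

    No slip or Reynolds-number correction is applied; above ~50 um the
    uncorrected law overestimates the fall speed (warned once).
    """
    d, rho_dr = _as_arrays(d, rho_dr)
    if warn and np.any(d > STOKES_LIMIT_D):
        warnings.warn(
            "Stokes settling applied to droplets above 50 um without drag "
            "correction; fall speeds are overestimated",
            stacklevel=2,
        )
    out = env.g * rho_dr * d**2 / (18.0 * env.eta_air)
    return _maybe_scalar(out, d, rho_dr)


def mass_fraction_1(x1, components: Sequence[Component]):
    """Mass fraction of component 1 in the droplet liquid."""
    x1 = np.asarray(x1, dtype=float)
    M1, M2 = components[0].M, components[1].M
    out = x1 * M1 / (x1 * M1 + (1.0 - x1) * M2)
    return _maybe_scalar(out, x1)


def settling_loss_rate(
    A, d, x1, F: float, components: Sequence[Component], env: Environment
):
    """Sedimentation mass loss rate to the floor, kg/s, and its component split.

    Returns ``(total, per_component)`` with ``per_component`` of shape
    (2, ...) scaling the total by the instantaneous mass fractions.
    """
    A, d, x1 = _as_arrays(A, d, x1)
    rho = droplet_density(x1, components)
    total = F * settling_velocity(d, rho, env, warn=False) * A
    w1 = mass_fraction_1(x1, components)
    per_comp = np.stack([np.asarray(total) * w1, np.asarray(total) * (1.0 - w1)])
    return _maybe_scalar(total, A, d, x1), per_comp


def droplet_count(A, V_room: float, d, rho_dr):
    """Number of droplets represented by a pulse: N = 6 A V / (pi rho d^3)."""
    A, d, rho_dr = _as_arrays(A, d, rho_dr)
    if np.any(d <= 0):
        raise ValueError("droplet diameter must be positive")
    out = 6.0 * A * V_room / (np.pi * rho_dr * d**3)
    return _maybe_scalar(out, A, d, rho_dr)


def equilibrium_concentrations(x1, components: Sequence[Component], T: float):
    """Per-component Raoult equilibrium vapour concentrations at the surface.

    Shape (2, ...): C_eq_i = M_i p*_i(T) x_i gamma_i(x_i) / (R T).
    """
    x1 = np.asarray(x1, dtype=float)
    M, psat, _, _ = binary_props(components, T)
    x2 = 1.0 - x1
    g1 = components[0].activity.gamma(x1)
    g2 = components[1].activity.gamma(x2)
    return np.stack(
        [
            M[0] * psat[0] * x1 * g1 / (R_GAS * T),
            M[1] * psat[1] * x2 * g2 / (R_GAS * T),
        ]
    )


def droplet_evaporation_rates(
    A, d, x1, C_room, components: Sequence[Component], V_room: float, T: float
):
    """Per-component evaporation rate of a pulse, kg/s (shape (2, ...)).

    rate_i = 12 D_i V_room A (C_eq_i - C_room_i) / (d^2 rho_dr); positive
    while evaporating, negative under condensational growth (backpressure
    exceeding the surface equilibrium).
    """
    A, d, x1 = _as_arrays(A, d, x1)
    C_room = np.asarray(C_room, dtype=float)
    _, _, D, _ = binary_props(components, T)
    rho = np.asarray(droplet_density(x1, components))
    C_eq = equilibrium_concentrations(x1, components, T)
    dC = C_eq - C_room.reshape(2, *([1] * A.ndim))
    return 12.0 * D.reshape(2, *([1] * A.ndim)) * V_room * A * dC / (d**2 * rho)


def diameter_derivative(d, x1, C_room, components: Sequence[Component], T: float):
    """SRMM diameter rate dd/dt, m/s (negative while evaporating).

    Equivalent mole-balance form: dd/dt = -(4/d) sum_i V_i D_i
    (C_eq_i - C_room_i)/M_i.
    """
    d, x1 = _as_arrays(d, x1)
    C_room = np.asarray(C_room, dtype=float)
    M, _, D, Vm = binary_props(components, T)
    C_eq = equilibrium_concentrations(x1, components, T)
    dC = C_eq - C_room.reshape(2, *([1] * d.ndim))
    out = -(4.0 / d) * (Vm[0] * D[0] * dC[0] / M[0] + Vm[1] * D[1] * dC[1] / M[1])
    return _maybe_scalar(out, d, x1)


def composition_derivative(d, x1, C_room, components: Sequence[Component], T: float):
    """SRMM composition rate dx1/dt, 1/s.

    Mole-balance form: with per-droplet molar fluxes dn_i/dt proportional
    to D_i (C_eq_i - C_room_i)/M_i,
    dx1/dt = -(12 Vbar / d^2) [ (1-x1) D1 dC1/M1 - x1 D2 dC2/M2 ],
    where Vbar = V1 x1 + V2 (1-x1) is the mixture molar volume.
    """
    d, x1 = _as_arrays(d, x1)
    C_room = np.asarray(C_room, dtype=float)
    M, _, D, Vm = binary_props(components, T)
    C_eq = equilibrium_concentrations(x1, components, T)
    dC = C_eq - C_room.reshape(2, *([1] * d.ndim))
    Vbar = Vm[0] * x1 + Vm[1] * (1.0 - x1)
    out = -(12.0 * Vbar / d**2) * (
        (1.0 - x1) * D[0] * dC[0] / M[0] - x1 * D[1] * dC[1] / M[1]
    )
    return _maybe_scalar(out, d, x1)
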