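"""Liquid-film mass balances on the floor and on sprayed wall elements.

The floor is a single well-mixed film fed by droplet sedimentation; the
sprayed wall is resolved into area elements, each fed once (by the spray
pulse that targets it) and evaporating independently afterwards.  Film
evaporation is demand-driven (Raoult equilibrium at the film surface minus
the room backpressure, times a mass-transfer coefficient), is clamped at
zero (no condensation onto surfaces), and is capped so a film can never be
driven below empty within a step — droplets arriving on an exhausted film
evaporate instantaneously.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .physchem import Component, R_GAS


@dataclass
class SurfaceFilm:
    """A liquid film: area (m^2), per-component mass m (kg) and beta (m/s)."""

    area: float
    m: np.ndarray
    beta: np.ndarray
    label: str = "floor"

    def __post_init__(self) -> None:
        self.m = np.asarray(self.m, dtype=float).copy()
        self.beta = np.asarray(self.beta, dtype=float)
        if self.area <= 0:
            raise ValueError("film area must be positive")
        if np.any(self.m < 0):
            raise ValueError("film masses must be nonnegative")


def film_mole_fractions(m, components: Sequence[Component]) -> np.ndarray:
    """Mole fractions of the film liquid (rowwise for 2-D input).

    An empty film returns zeros rather than raising: a zero composition
    gives zero equilibrium concentration and hence zero demand.
    """
    m = np.asarray(m, dtype=float)
    M = np.array([c.M for c in components])
    moles = m / M
    tot = moles.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.where(tot > 0, moles / np.where(tot > 0, tot, 1.0), 0.0)
    return x


def _demand_rates(m, area, beta, C_room, components, T):
    """Uncapped evaporation demand per component, clamped at >= 0."""
    m = np.atleast_2d(np.asarray(m, dtype=float))
    x = film_mole_fractions(m, components)
    M = np.array([c.M for c in components])
    psat = np.array([c.psat_at(T) for c in components])
    gamma = np.stack(
        [np.asarray(components[i].activity.gamma(x[..., i])) for i in range(2)], axis=-1
    )
    C_eq = M * psat * x * gamma / (R_GAS * T)
    area = np.asarray(area, dtype=float).reshape(-1, 1)
    demand = area * np.asarray(beta) * (C_eq - np.asarray(C_room, dtype=float))
    return np.clip(demand, 0.0, None)


def film_evaporation_rate(
    film: SurfaceFilm, C_room, components: Sequence[Component], T: float
) -> np.ndarray:
    """Per-component evaporation demand of a film, kg/s (no inflow cap)."""
    return _demand_rates(film.m, film.area, film.beta, C_room, components, T)[0]


def film_step_array(
    m: np.ndarray,
    area,
    beta: np.ndarray,
    inflow: np.ndarray,
    C_room: np.ndarray,
    components: Sequence[Component],
    T: float,
    dt: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance film masses one explicit Euler step; vectorised over films.

    ``m`` and ``inflow`` have shape (n_films, 2).  The evaporation demand is
    evaluated on the post-deposition pool ``m + dt*inflow`` (so freshly
    arriving mass on an empty film can evaporate instantaneously) and the
    realised rate is capped at ``inflow + m/dt``, which empties the film
    exactly to zero and never below.  Returns ``(m_new, realised_rates)``.
    """
    m = np.atleast_2d(np.asarray(m, dtype=float))
    inflow = np.atleast_2d(np.asarray(inflow, dtype=float))
    demand = _demand_rates(m + dt * inflow, area, beta, C_room, components, T)
    realised = np.minimum(demand, inflow + m / dt)
    m_new = np.maximum(m + dt * (inflow - realised), 0.0)
    return m_new, realised


def floor_step(
    film: SurfaceFilm,
    deposition_inflow: np.ndarray,
    C_room,
    components: Sequence[Component],
    T: float,
    dt: float,
) -> np.ndarray:
    """Advance the floor film by one step (in place); returns realised rates."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    inflow = np.asarray(deposition_inflow, dtype=float)
    if np.any(inflow < 0):
        raise ValueError("deposition inflow must be nonnegative")
    m_new, realised = film_step_array(
        film.m, film.area, film.beta, inflow, np.asarray(C_room, float), components, T, dt
    )
    film.m = m_new[0]
    return realised[0]


def wall_step(
    elements: list[SurfaceFilm],
    impaction_inflow: np.ndarray,
    C_room,
    components: Sequence[Component],
    T: float,
    dt: float,
) -> np.ndarray:
    """Advance all wall area elements one step; returns total realised rates.

    ``impaction_inflow`` has shape (n_elements, 2); during spraying only the
    element targeted by the current pulse receives a nonzero inflow.
    """
    inflow = np.asarray(impaction_inflow, dtype=float)
    if inflow.shape != (len(elements), 2):
        raise ValueError(
            f"inflow shape {inflow.shape} does not match {len(elements)} elements"
        )
    total = np.zeros(2)
    for film, infl in zip(elements, inflow):
        total += floor_step(film, infl, C_room, components, T, dt)
    return total
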