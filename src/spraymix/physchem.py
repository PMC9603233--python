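"""Substance properties and binary-mixture thermodynamics.

This module holds everything the dynamics modules share: chemical
components with their tabulated saturation pressures, activity-coefficient
models for nonideal liquid mixtures, the ambient-air environment, and the
small set of thermodynamic conversions (mole/mass fractions, mixture
density from liquid molar volumes, Raoult-law equilibrium vapour
concentrations, Hubbard's 1/3-rule reference temperature).

All quantities are SI: kg, m, s, K, Pa, mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

#: Universal gas constant, J/(mol K).
R_GAS = 8.314462618

#: Molar mass of water used by the humidity helpers, kg/mol.
M_WATER = 0.018


class CompositionError(ValueError):
    """Raised when a liquid composition is undefined (e.g. all masses zero)."""


class PropertyLookupError(LookupError):
    """Raised when a tabulated property is requested at an uncovered temperature."""


@dataclass(frozen=True)
class ActivityModel:
    """Activity coefficient gamma(x) of a component in a binary liquid.

    Three kinds are supported:

    ``ideal``
        gamma = 1 everywhere (Raoult's law).
    ``polynomial``
        gamma(x) = sum_k coefficients[k] * x**k.
    ``table``
        linear interpolation through (x_grid, gamma_grid) support points.

    ``x`` is always the mole fraction of the component the model belongs to.
    """

    kind: str = "ideal"
    coefficients: tuple[float, ...] = ()
    x_grid: tuple[float, ...] = ()
    gamma_grid: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("ideal", "polynomial", "table"):
            raise ValueError(f"unknown activity model kind {self.kind!r}")
        if self.kind == "polynomial" and not self.coefficients:
            raise ValueError("polynomial activity model needs coefficients")
        if self.kind == "table":
            if len(self.x_grid) != len(self.gamma_grid) or len(self.x_grid) < 2:
                raise ValueError("table activity model needs matching x/gamma grids")
            if any(g <= 0 for g in self.gamma_grid):
                raise ValueError("activity coefficients must be positive")

    def gamma(self, x):
        """Evaluate gamma at mole fraction ``x`` (scalar or array)."""
        x = np.asarray(x, dtype=float)
        if self.kind == "ideal":
            out = np.ones_like(x)
        elif self.kind == "polynomial":
            out = np.polynomial.polynomial.polyval(x, self.coefficients)
        else:
            out = np.interp(x, self.x_grid, self.gamma_grid)
        if np.any(out <= 0):
            raise ValueError("activity model returned nonpositive gamma")
        return out if out.ndim else float(out)


IDEAL = ActivityModel()


@dataclass(frozen=True)
class Component:
    """One chemical species of the binary mixture.

    Parameters
    ----------
    name:
        Label used in result columns and scenario files.
    M:
        Molar mass, kg/mol.
    psat:
        Saturation vapour pressure table, {temperature K: pressure Pa}.
        A nonvolatile species can be declared with ``{0.0: 0.0}`` plus
        ``nonvolatile=True`` or simply an all-zero table.
    D:
        Binary diffusion coefficient in air, m^2/s.
    Vm:
        Liquid molar volume, m^3/mol.
    beta:
        Surface mass-transfer coefficient, m/s.  Directly settable because
        the published power-law correlation (see
        :func:`mass_transfer_coefficient`) cannot be reconciled with the
        reference values in SI units; required for volatile components
        taking part in surface evaporation.
    activity:
        Activity-coefficient model, default ideal.
    """

    name: str
    M: float
    psat: tuple[tuple[float, float], ...]
    D: float
    Vm: float
    beta: float | None = None
    activity: ActivityModel = field(default_factory=ActivityModel)

    def __post_init__(self) -> None:
        if isinstance(self.psat, Mapping):
            object.__setattr__(
                self, "psat", tuple(sorted((float(t), float(p)) for t, p in self.psat.items()))
            )
        else:
            object.__setattr__(
                self, "psat", tuple(sorted((float(t), float(p)) for t, p in self.psat))
            )
        if self.M <= 0 or self.D <= 0 or self.Vm <= 0:
            raise ValueError(f"component {self.name}: M, D, Vm must be positive")
        if any(p < 0 for _, p in self.psat):
            raise ValueError(f"component {self.name}: psat must be nonnegative")

    @property
    def nonvolatile(self) -> bool:
        return all(p == 0.0 for _, p in self.psat)

    def psat_at(self, T: float, atol: float = 5.0) -> float:
        """Saturation pressure at temperature ``T``.

        The nearest tabulated temperature within ``atol`` kelvin is used;
        outside that window a :class:`PropertyLookupError` is raised rather
        than extrapolating.  Nonvolatile components return 0 at any T.
        """
        if self.nonvolatile:
            return 0.0
        temps = np.array([t for t, _ in self.psat])
        idx = int(np.argmin(np.abs(temps - T)))
        if abs(temps[idx] - T) > atol:
            raise PropertyLookupError(
                f"component {self.name}: no saturation pressure tabulated within "
                f"{atol} K of {T:.2f} K (have {list(temps)})"
            )
        return self.psat[idx][1]


@dataclass(frozen=True)
class Environment:
    """Ambient air and physical constants.

    ``T_dr`` is the droplet surface temperature (an input, typically below
    room temperature because of evaporative cooling); droplet evaporation
    properties are evaluated at the Hubbard reference temperature
    ``T_dr + (T_room - T_dr)/3``, surface films at ``T_room``.
    """

    T_room: float = 293.0
    T_dr: float = 293.0
    rho_air: float = 1.2
    eta_air: float = 1.82e-5
    nu_air: float = 1.53e-5
    g: float = 9.81
    R: float = R_GAS

    def __post_init__(self) -> None:
        for name in ("T_room", "T_dr", "rho_air", "eta_air", "nu_air", "R"):
            if getattr(self, name) <= 0:
                raise ValueError(f"Environment.{name} must be positive")
        if self.g < 0:
            raise ValueError("Environment.g must be nonnegative")

    @property
    def T_ref(self) -> float:
        """Hubbard 1/3-rule reference temperature for droplet evaporation."""
        return reference_temperature(self.T_dr, self.T_room)


def mole_fractions_from_mass(masses, components: Sequence[Component]) -> np.ndarray:
    """Convert per-component masses (kg) to mole fractions.

    Raises :class:`CompositionError` when every mass is zero.
    """
    masses = np.asarray(masses, dtype=float)
    if np.any(masses < 0):
        raise CompositionError("negative component mass")
    M = np.array([c.M for c in components])
    moles = masses / M
    total = moles.sum()
    if total <= 0:
        raise CompositionError("all component masses are zero: composition undefined")
    return moles / total


def mass_fractions_from_mole(x, components: Sequence[Component]) -> np.ndarray:
    """Convert mole fractions to mass fractions (inverse of the above)."""
    x = np.asarray(x, dtype=float)
    M = np.array([c.M for c in components])
    w = x * M
    return w / w.sum()


def mixture_density(x, components: Sequence[Component]) -> float:
    """Liquid mixture density from molar volumes, rho = sum(M x)/sum(Vm x)."""
    x = np.asarray(x, dtype=float)
    M = np.array([c.M for c in components])
    Vm = np.array([c.Vm for c in components])
    return float((M * x).sum() / (Vm * x).sum())


def reference_temperature(T_dr: float, T_room: float) -> float:
    """Hubbard's 1/3 rule: T_r = T_dr + (T_room - T_dr)/3."""
    return T_dr + (T_room - T_dr) / 3.0


def equilibrium_vapour_concentration(
    comp: Component, x, T: float, gamma=None
) -> float | np.ndarray:
    """Raoult-law equilibrium vapour concentration M p* x gamma(x) / (R T), kg/m^3."""
    x = np.asarray(x, dtype=float)
    if gamma is None:
        gamma = comp.activity.gamma(x)
    psat = comp.psat_at(T)
    out = comp.M * psat * x * gamma / (R_GAS * T)
    return out if out.ndim else float(out)


def mass_transfer_coefficient(v_air: float, D: float, nu: float, X: float) -> float:
    """Surface mass-transfer coefficient power law, m/s.

    beta = 0.011 v^0.96 D^0.19 / (nu^0.14 X^0.04) with air speed ``v_air``
    over the film, diffusivity ``D``, kinematic viscosity ``nu`` and
    characteristic length ``X``.  Note: the source correlation is not
    dimensionally consistent in SI units and does not reproduce the
    reference beta values; it is provided as a helper only, and scenario
    components should carry measured/literature betas directly.
    """
    return 0.011 * v_air**0.96 * D**0.19 / (nu**0.14 * X**0.04)


def water_saturation_pressure(T: float) -> float:
    """Magnus-type saturation pressure of water, Pa, valid 0..40 degC.

    Alduchov & Eskridge coefficients; used only to convert relative
    humidity to vapour concentrations when building scenarios, never in
    the core balance equations.
    """
    Tc = T - 273.15
    if not (0.0 <= Tc <= 40.0):
        raise ValueError(f"Magnus helper valid for 0..40 degC, got {Tc:.1f} degC")
    return float(610.94 * np.exp(17.625 * Tc / (Tc + 243.04)))


def vapour_concentration_from_rh(rh_percent: float, T: float) -> float:
    """Water vapour mass concentration (kg/m^3) from relative humidity (%)."""
    if not (0.0 <= rh_percent <= 100.0):
        raise ValueError("relative humidity must be within 0..100%")
    p = rh_percent / 100.0 * water_saturation_pressure(T)
    return float(p * M_WATER / (R_GAS * T))


def wet_bulb_temperature(T: float, rh_percent: float) -> float:
    """Psychrometric wet-bulb temperature estimate, K.

    Solves p*(Tw) - e = gamma_ps (T - Tw) with the Magnus saturation curve,
    ambient vapour pressure e from the relative humidity and a standard
    psychrometric constant of 65 Pa/K.  Used as a simple estimate of the
    surface temperature of evaporating water droplets.
    """
    from scipy.optimize import brentq

    e = rh_percent / 100.0 * water_saturation_pressure(T)
    gamma_ps = 65.0

    def f(Tw):
        return water_saturation_pressure(Tw) - e - gamma_ps * (T - Tw)

    lo = max(273.15, T - 30.0)
    if f(lo) > 0:  # already saturated or nearly so
        return T
    return float(brentq(f, lo, T, xtol=1e-6))
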