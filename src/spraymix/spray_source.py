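"""Spray release: droplet size classes, jet dynamics and the impaction split.

The released spray is discretised into ``N_c`` size classes of equal mass
share under a lognormal mass distribution.  For wall-directed spraying a
full-cone turbulent round-jet model gives the flow mean velocity at the
target, from which an inertial impaction parameter K decides — via a hard
threshold at K = 0.3 — whether a size class deposits on the wall or stays
airborne as overspray.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

from .physchem import Environment

#: Impaction-parameter threshold above which droplets deposit on the target.
K_CRIT_DEFAULT = 0.3


class GeometryError(ValueError):
    """Raised when the jet geometry admits no critical diameter in range."""


@dataclass(frozen=True)
class DropletDistribution:
    """Lognormal droplet mass distribution.

    ``d_m`` is the mass median diameter (m), ``gsd`` the geometric standard
    deviation, ``n_classes`` the number of equal-mass size classes.
    """

    d_m: float
    gsd: float
    n_classes: int = 5

    def __post_init__(self) -> None:
        if self.d_m <= 0:
            raise ValueError("mass median diameter must be positive")
        if self.gsd <= 1:
            raise ValueError("geometric standard deviation must exceed 1")
        if self.n_classes < 1:
            raise ValueError("need at least one size class")

    def quantile(self, q) -> np.ndarray:
        """Diameter at mass-CDF quantile(s) q."""
        return self.d_m * np.exp(norm.ppf(q) * math.log(self.gsd))


@dataclass(frozen=True)
class SizeClass:
    index: int           # 1-based class index
    d_lower: float       # lower boundary diameter, m (0 for the first class)
    d_upper: float       # upper boundary diameter, m (inf for the last class)
    d_median: float      # class mass-median diameter, m
    mass_share: float    # fraction of the release rate carried by this class


def discretise_distribution(dist: DropletDistribution) -> list[SizeClass]:
    """Split the distribution into ``n_classes`` classes of mass share 1/N_c.

    Boundaries sit at the mass-CDF quantiles k/N_c, class medians at the
    mid-quantiles (2c - 1)/(2 N_c).
    """
    n = dist.n_classes
    bounds = dist.quantile(np.arange(1, n) / n) if n > 1 else np.array([])
    medians = dist.quantile((2 * np.arange(1, n + 1) - 1) / (2 * n))
    lowers = np.concatenate([[0.0], bounds])
    uppers = np.concatenate([bounds, [np.inf]])
    return [
        SizeClass(c + 1, float(lowers[c]), float(uppers[c]), float(medians[c]), 1.0 / n)
        for c in range(n)
    ]


def inhalable_fraction(d) -> float | np.ndarray:
    """ISO inhalable fraction I(d) = 0.5 (1 + exp(-0.06 d[um])), d in metres."""
    d = np.asarray(d, dtype=float)
    out = 0.5 * (1.0 + np.exp(-0.06 * d * 1e6))
    return out if out.ndim else float(out)


def initial_velocity(Q_nozzle: float, D0: float) -> float:
    """Liquid velocity at the injector tip: v0 = Q / (pi D0^2 / 4)."""
    return Q_nozzle / (math.pi * D0**2 / 4.0)


@dataclass(frozen=True)
class JetGeometry:
    """Full-cone round jet from a circular nozzle aimed at a wall.

    ``opening_angle_full`` is the full cone angle in degrees (the scenario
    convention); the jet equations use the half-angle.  ``v0`` may be given
    directly or derived from the volumetric nozzle flow ``Q_nozzle``.
    """

    D0: float
    opening_angle_full: float
    s: float
    v0: float | None = None
    Q_nozzle: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.opening_angle_full < 180.0):
            raise ValueError("full opening angle must be in (0, 180) degrees")
        if self.D0 <= 0 or self.s <= 0:
            raise ValueError("nozzle diameter and wall distance must be positive")
        if self.v0 is None and self.Q_nozzle is None:
            raise ValueError("either v0 or Q_nozzle must be given")

    @property
    def half_angle_rad(self) -> float:
        return math.radians(self.opening_angle_full / 2.0)

    @property
    def initial_speed(self) -> float:
        if self.v0 is not None:
            return self.v0
        return initial_velocity(self.Q_nozzle, self.D0)

    def cross_section_diameter(self, s: float | None = None) -> float:
        """Geometric spray cone diameter D(s) = D0 + 2 s tan(theta_half)."""
        s = self.s if s is None else s
        return self.D0 + 2.0 * s * math.tan(self.half_angle_rad)


def flow_mean_velocity(
    d, jet: JetGeometry, rho_dr: float, env: Environment, s: float | None = None
):
    """Mean two-phase flow velocity of the jet at distance s from the nozzle.

    Zero-slip entrainment model for a full-cone turbulent round jet; decays
    from v0 at the nozzle as ambient air is entrained.
    """
    d = np.asarray(d, dtype=float)
    s = jet.s if s is None else s
    v0 = jet.initial_speed
    tan_t = math.tan(jet.half_angle_rad)
    r = env.rho_air / rho_dr
    root = np.sqrt(1.0 + 4.0 * r + 16.0 * s * r * tan_t / d + 16.0 * s**2 * r * tan_t**2 / d**2)
    out = 2.0 * v0 / (1.0 + root)
    return out if out.ndim else float(out)


def impaction_parameter_from_velocity(
    vbar, d, D_s: float, rho_dr: float, eta: float
):
    """Impaction parameter K = (1/18) vbar rho_dr d^2 / (D(s) eta)."""
    vbar = np.asarray(vbar, dtype=float)
    d = np.asarray(d, dtype=float)
    out = vbar * rho_dr * d**2 / (18.0 * D_s * eta)
    return out if out.ndim else float(out)


def impaction_parameter(d, jet: JetGeometry, rho_dr: float, env: Environment):
    """K for droplets of diameter ``d`` at the wall distance of ``jet``."""
    vbar = flow_mean_velocity(d, jet, rho_dr, env)
    return impaction_parameter_from_velocity(
        vbar, d, jet.cross_section_diameter(), rho_dr, env.eta_air
    )


def critical_diameter(
    jet: JetGeometry,
    rho_dr: float,
    env: Environment,
    K_crit: float = K_CRIT_DEFAULT,
    bracket: tuple[float, float] = (1e-7, 5e-2),
) -> float:
    """Droplet diameter at which K(d) = K_crit; larger droplets deposit."""
    lo, hi = bracket
    f = lambda d: impaction_parameter(d, jet, rho_dr, env) - K_crit
    if f(lo) * f(hi) > 0:
        raise GeometryError(
            "impaction parameter does not cross the critical value inside "
            f"[{lo:g}, {hi:g}] m for this geometry"
        )
    return float(brentq(f, lo, hi, rtol=1e-12))


def transfer_efficiency(K, K_crit: float = K_CRIT_DEFAULT):
    """Deposition efficiency xi(K): hard step, 1 where K >= K_crit else 0."""
    K = np.asarray(K, dtype=float)
    out = (K >= K_crit).astype(float)
    return out if out.ndim else float(out)


def split_release(
    release_rate_per_class,
    classes: list[SizeClass],
    jet: JetGeometry,
    rho_dr: float,
    env: Environment,
    K_crit: float = K_CRIT_DEFAULT,
) -> tuple[np.ndarray, np.ndarray]:
    """Split per-class release rates into (deposited, overspray) rates.

    xi is evaluated at each class's median diameter; mass is conserved
    exactly: deposited + overspray = input per class.
    """
    rates = np.asarray(release_rate_per_class, dtype=float)
    if np.any(rates < 0):
        raise ValueError("release rates must be nonnegative")
    d_med = np.array([sc.d_median for sc in classes])
    xi = transfer_efficiency(impaction_parameter(d_med, jet, rho_dr, env), K_crit)
    deposited = rates * xi
    return deposited, rates - deposited
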