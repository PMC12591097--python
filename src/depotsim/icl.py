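"""Inflammatory cell layer (ICL): thickness kinetics and diffusion barrier.

A foreign-body reaction to an injected suspension wraps the depot in a layer
of immune cells that the dissolved drug must cross before it can reach the
systemic circulation. The layer grows, peaks and resolves over weeks; its
thickness is modelled as a gamma-like pulse ``A * t * exp(-B * t)`` (after an
optional onset lag), and the barrier it presents is a diffusive conductance
``kappa * SA * D_icl * fu_icl / thickness(t)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ICLParams",
    "DepotGeometry",
    "icl_thickness",
    "icl_diffusivity",
    "icl_fraction_unbound",
    "depot_surface_area",
    "calibrate_depot_density",
    "icl_conductance",
]

#: seconds per hour, used to convert cm^3/s conductances to mL/h
_S_PER_H = 3600.0


@dataclass
class ICLParams:
    """Parameters of the inflammatory-cell-layer barrier.

    ``a`` (cm/h) sets the magnitude and ``b`` (1/h) the rate of the thickness
    pulse; the peak thickness a/(b*e) occurs at t_lag + 1/b. ``kappa`` is a
    dimensionless scale on the conductance absorbing the unknown
    proportionality between the layer's physical properties and its
    permeability; it is calibrated together with ``a`` and ``b``.
    """

    a: float = 2.09e-6  # cm/h
    b: float = 0.012  # 1/h
    t_lag: float = 0.0  # h
    surface_area: float = 2.32  # cm^2
    d_icl: float = 1.12e-6  # cm^2/s
    fu_icl: float = 0.0034245  # fraction
    kappa: float = 1.0
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("a must be >= 0")
        if self.b <= 0:
            raise ValueError("b must be > 0")
        if self.t_lag < 0:
            raise ValueError("t_lag must be >= 0")
        if self.surface_area <= 0:
            raise ValueError("surface_area must be > 0")
        if not 0 < self.fu_icl <= 1:
            raise ValueError("fu_icl must be in (0, 1]")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")


@dataclass
class DepotGeometry:
    """Spherical-depot geometry inputs."""

    particle_density: float = 1.774  # g/cm^3
    prodrug_dose: float = 0.0  # mg

    def __post_init__(self) -> None:
        if self.particle_density <= 0:
            raise ValueError("particle_density must be > 0")


def icl_thickness(t, p: ICLParams):
    """ICL thickness (cm) at time ``t`` (h). Vectorized over ``t``.

    Zero before the onset lag, then ``a * (t - t_lag) * exp(-b * (t - t_lag))``:
    continuous, non-negative, with a single interior maximum and decay to zero.
    """
    t = np.asarray(t, dtype=float)
    tau = np.maximum(t - p.t_lag, 0.0)
    out = p.a * tau * np.exp(-p.b * tau)
    return out if out.ndim else float(out)


def icl_diffusivity(logd74: float) -> float:
    """Drug diffusivity inside the ICL (cm^2/s) from logD at pH 7.4.

    The correlation is a constant 10^-5.9514 cm^2/s on its only defined
    branch, logD(7.4) > 3. For less lipophilic compounds no correlation is
    available and a measured/user value must be supplied instead.
    """
    if logd74 <= 3:
        raise ValueError(
            "ICL diffusivity correlation is defined only for logD(7.4) > 3; "
            "supply d_icl explicitly for this compound"
        )
    return 10.0 ** -5.9514


def icl_fraction_unbound(logd74: float) -> float:
    """Fraction of drug unbound within the ICL, 1/(2.12 * exp(0.523 * logD)).

    Strictly decreasing in lipophilicity; clamped to (0, 1].
    """
    return min(1.0, 1.0 / (2.12 * math.exp(0.523 * logd74)))


def depot_surface_area(prodrug_dose_mg: float, density: float) -> float:
    """Outer surface area (cm^2) of a single spherical depot.

    The depot is a sphere whose volume is the injected solid mass over its
    density: SA = (36*pi)^(1/3) * (Dose/rho)^(2/3). Scales as dose^(2/3).
    """
    if prodrug_dose_mg <= 0 or density <= 0:
        raise ValueError("dose and density must be > 0")
    volume_cm3 = prodrug_dose_mg / 1000.0 / density
    return (36.0 * math.pi) ** (1.0 / 3.0) * volume_cm3 ** (2.0 / 3.0)


def calibrate_depot_density(prodrug_dose_mg: float, surface_area_cm2: float) -> float:
    """Particle density (g/cm^3) that makes the spherical-depot surface area
    match a known value at a known dose. Inverts :func:`depot_surface_area`."""
    if prodrug_dose_mg <= 0 or surface_area_cm2 <= 0:
        raise ValueError("dose and surface area must be > 0")
    volume = (surface_area_cm2 / (36.0 * math.pi) ** (1.0 / 3.0)) ** 1.5
    return prodrug_dose_mg / 1000.0 / volume


def icl_conductance(t, p: ICLParams):
    """Diffusive conductance of the ICL barrier, mL/h. Vectorized over ``t``.

    G(t) = kappa * SA * D_icl * fu_icl / thickness(t), with D_icl converted
    from cm^2/s to cm^2/h. Only the unbound species in the layer permeates,
    hence the multiplicative fu_icl. Returns +inf where the layer has zero
    thickness (no barrier).
    """
    if not p.enabled:
        raise ValueError("icl_conductance called with ICL disabled")
    th = np.asarray(icl_thickness(t, p), dtype=float)
    num = p.kappa * p.surface_area * (p.d_icl * _S_PER_H) * p.fu_icl
    with np.errstate(divide="ignore"):
        out = np.where(th > 0.0, num / np.where(th > 0.0, th, 1.0), np.inf)
    return out if out.ndim else float(out)
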