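"""Drug-level parameters and closed-form physicochemical calculators.

The simulator deals with two species: the parent drug (aripiprazole, AR, in the
reference scenarios) and an ester prodrug (aripiprazole lauroxil, AR-L) that is
injected as a suspension and cleaved to the parent in the systemic circulation.
Both are monoprotic bases, so pH-dependent quantities use the single-pKa
Henderson–Hasselbalch convention throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "DrugProperties",
    "DispositionParams",
    "FormulationDose",
    "compute_logd",
    "solubility_at_ph",
    "estimate_aqueous_diffusivity",
    "blend_missed_injection",
    "prodrug_dose",
]

#: Routes understood by the depot model.
ROUTES = ("iv_infusion", "im_solution", "im_suspension")


@dataclass
class DrugProperties:
    """Physicochemical parameters of a single (monoprotic basic) compound.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"AR"`` or ``"AR-L"``.
    mw : float
        Molecular mass, g/mol.
    logp : float
        Octanol/water partition coefficient (log10).
    pka : float
        Basic pKa (single ionizable center).
    rbp : float
        Blood-to-plasma concentration ratio.
    fup : float
        Fraction unbound in plasma (fraction, not percent).
    s_ref : float
        Aqueous solubility (mg/mL) measured at ``ph_ref``.
    ph_ref : float
        pH at which ``s_ref`` was measured.
    solubility_factor : float
        Maximum fold enhancement of the intrinsic solubility by ionization;
        caps the pH-solubility curve.
    d_aq_override : float, optional
        Aqueous diffusion coefficient in cm^2/s. When absent a molecular-
        weight correlation is used (see :func:`estimate_aqueous_diffusivity`).
    """

    name: str
    mw: float
    logp: float
    pka: float
    rbp: float
    fup: float
    s_ref: float
    ph_ref: float = 7.0
    solubility_factor: float = 1.0
    d_aq_override: Optional[float] = None

    def __post_init__(self) -> None:
        if self.mw <= 0:
            raise ValueError("mw must be > 0")
        if not 0 < self.fup <= 1:
            raise ValueError("fup must be in (0, 1]")
        if self.rbp <= 0:
            raise ValueError("rbp must be > 0")
        if self.s_ref <= 0:
            raise ValueError("s_ref must be > 0")
        if self.solubility_factor < 1:
            raise ValueError("solubility_factor must be >= 1")

    @property
    def d_aq(self) -> float:
        """Aqueous diffusion coefficient, cm^2/s."""
        if self.d_aq_override is not None:
            return self.d_aq_override
        return estimate_aqueous_diffusivity(self.mw)

    def logd(self, ph: float) -> float:
        """Distribution coefficient logD at the given pH."""
        return compute_logd(self.logp, self.pka, ph)


@dataclass
class DispositionParams:
    """Three-compartment systemic disposition with linear hepatic clearance.

    All volumes and clearances are body-weight normalized (L/kg, L/h/kg);
    micro rate constants are in 1/h. ``body_weight`` converts them to
    absolute amounts for the simulation.
    """

    vc: float  # central volume, L/kg
    clh: float  # hepatic clearance, L/h/kg
    k12: float
    k21: float
    k13: float
    k31: float
    body_weight: float = 70.0  # kg

    def __post_init__(self) -> None:
        for name in ("vc", "clh", "k12", "k21", "k13", "k31", "body_weight"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def clearance_l_h(self) -> float:
        """Absolute clearance, L/h."""
        return self.clh * self.body_weight

    @property
    def vc_l(self) -> float:
        """Absolute central volume, L."""
        return self.vc * self.body_weight

    @property
    def vss(self) -> float:
        """Steady-state distribution volume, L/kg (moment identity)."""
        return self.vc * (1.0 + self.k12 / self.k21 + self.k13 / self.k31)


@dataclass
class FormulationDose:
    """Dose and formulation descriptor for one administration."""

    ar_equivalent_dose: float  # mg of parent drug
    route: str = "im_suspension"
    is_prodrug: bool = True
    injection_volume: Optional[float] = None  # mL, IM routes
    infusion_duration: Optional[float] = None  # h, IV only

    def __post_init__(self) -> None:
        if self.ar_equivalent_dose <= 0:
            raise ValueError("ar_equivalent_dose must be > 0")
        if self.route not in ROUTES:
            raise ValueError(f"route must be one of {ROUTES}")
        if self.route.startswith("im"):
            if self.injection_volume is None or self.injection_volume <= 0:
                raise ValueError("IM routes require injection_volume > 0")
        if self.route == "iv_infusion":
            if self.infusion_duration is None or self.infusion_duration <= 0:
                raise ValueError("iv_infusion requires infusion_duration > 0")


def compute_logd(logp: float, pka: float, ph: float) -> float:
    """Distribution coefficient of a monoprotic base.

    logD(pH) = logP - log10(1 + 10^(pKa - pH)); approaches logP when the
    compound is fully un-ionized (pH >> pKa).
    """
    return logp - math.log10(1.0 + 10.0 ** (pka - ph))


def solubility_at_ph(drug: DrugProperties, ph: float) -> float:
    """Total aqueous solubility (mg/mL) of a monoprotic base at ``ph``.

    The intrinsic (neutral-species) solubility is inferred from the
    reference measurement, S_int = s_ref / (1 + 10^(pKa - ph_ref)), and
    scaled by the ionization term at the requested pH. The enhancement is
    capped at ``solubility_factor`` times the intrinsic solubility.
    """
    s_int = drug.s_ref / (1.0 + 10.0 ** (drug.pka - drug.ph_ref))
    s = s_int * (1.0 + 10.0 ** (drug.pka - ph))
    return min(s, s_int * drug.solubility_factor)


def estimate_aqueous_diffusivity(mw: float) -> float:
    """Aqueous diffusion coefficient (cm^2/s) from molecular weight.

    Standard empirical power law D = 9.9e-5 * MW^-0.453 for small organic
    molecules in water at 37 C.
    """
    if mw <= 0:
        raise ValueError("mw must be > 0")
    return 9.9e-5 * mw ** -0.453


def blend_missed_injection(
    kp_muscle: float, kp_adipose: float, fut_muscle: float, fut_adipose: float
) -> tuple[float, float]:
    """Partition parameters for a partially missed (muscle/adipose) injection.

    Returns the arithmetic midpoints of the muscle and adipose tissue/plasma
    partition coefficients and tissue fractions unbound — the convention used
    when a gluteal injection may straddle muscle and subcutaneous fat.
    """
    if min(kp_muscle, kp_adipose, fut_muscle, fut_adipose) <= 0:
        raise ValueError("all blending inputs must be > 0")
    return (kp_muscle + kp_adipose) / 2.0, (fut_muscle + fut_adipose) / 2.0


def prodrug_dose(ar_equivalent: float, mw_prodrug: float, mw_parent: float) -> float:
    """Prodrug mass (mg) molar-equivalent to a parent-drug dose (mg)."""
    if min(ar_equivalent, mw_prodrug, mw_parent) <= 0:
        raise ValueError("all inputs must be > 0")
    return ar_equivalent * mw_prodrug / mw_parent
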