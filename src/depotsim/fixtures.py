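"""Named reference scenarios and the packaged observed-PK table.

The fixture scenarios encode the aripiprazole (AR) / aripiprazole lauroxil
(AR-L) reference cases the model was built around: a 2 mg IV infusion and a
5 mg IM solution of the parent, and the 150/300/400 mg-eq IM suspension
doses of the prodrug. Observed mean PK metrics ship as a small CSV so the
validation tables are regenerable and auditable.
"""

from __future__ import annotations

import importlib.resources
from functools import lru_cache
from typing import Dict

import pandas as pd

from .depot import DepotPhysiology, Scenario
from .dissolution import DissolutionSettings, ParticleSizeDistribution
from .drugs import DispositionParams, DrugProperties, FormulationDose
from .icl import ICLParams, icl_diffusivity, icl_fraction_unbound, depot_surface_area
from .metrics import PKMetrics

__all__ = [
    "aripiprazole",
    "aripiprazole_lauroxil",
    "reference_disposition",
    "build_scenario",
    "observed_table",
    "observed_metrics",
    "FIXTURE_NAMES",
    "INJECTION_VOLUMES_ML",
    "DEPOT_DENSITY",
]

#: particle/depot density (g/cm^3) calibrated so the spherical-depot surface
#: area reproduces 2.32 cm^2 at the 400 mg-eq prodrug dose
DEPOT_DENSITY = 1.774

#: injection volumes (mL) per labelled dose
INJECTION_VOLUMES_ML = {
    "ar_im_solution_5mg": 0.67,
    "arl_im_150": 0.805,
    "arl_im_300": 1.6,
    "arl_im_400": 2.13,
}

FIXTURE_NAMES = (
    "ar_iv_2mg",
    "ar_im_solution_5mg",
    "arl_im_150",
    "arl_im_300",
    "arl_im_400",
)

_HORIZONS = {
    "iv_infusion": 72.0,
    "im_solution": 168.0,
    "im_suspension": 2136.0,
}


def aripiprazole() -> DrugProperties:
    """Parent drug: aripiprazole."""
    return DrugProperties(
        name="AR",
        mw=448.38,
        logp=5.2,
        pka=7.6,
        rbp=0.61,
        fup=0.0317,
        s_ref=0.004,
        ph_ref=7.0,
        solubility_factor=660.92,
    )


def aripiprazole_lauroxil() -> DrugProperties:
    """Prodrug: aripiprazole lauroxil (depot species of the suspension)."""
    return DrugProperties(
        name="AR-L",
        mw=660.73,
        logp=9.8,
        pka=7.47,
        rbp=0.64,
        fup=0.002,
        s_ref=0.0003,
        ph_ref=7.0,
        solubility_factor=10200.0,
    )


def reference_disposition(body_weight: float = 70.0) -> DispositionParams:
    """Fitted three-compartment disposition of aripiprazole."""
    return DispositionParams(
        vc=1.5825,
        clh=0.03028,
        k12=0.22832,
        k21=0.17345,
        k13=0.01108,
        k31=0.001911,
        body_weight=body_weight,
    )


def _suspension_scenario(dose_mg_eq: float, name: str, icl_enabled: bool) -> Scenario:
    arl = aripiprazole_lauroxil()
    ar = aripiprazole()
    logd74 = arl.logd(7.4)
    prodrug_mg = dose_mg_eq * arl.mw / ar.mw
    icl = ICLParams(
        a=2.09e-6,
        b=0.012,
        t_lag=0.0,
        surface_area=depot_surface_area(prodrug_mg, DEPOT_DENSITY),
        d_icl=icl_diffusivity(logd74),
        fu_icl=icl_fraction_unbound(logd74),
        kappa=1.0,
        enabled=icl_enabled,
    )
    return Scenario(
        name=name,
        drug=arl,
        parent=ar,
        disposition=reference_disposition(),
        dose=FormulationDose(
            ar_equivalent_dose=dose_mg_eq,
            route="im_suspension",
            is_prodrug=True,
            injection_volume=INJECTION_VOLUMES_ML[name],
        ),
        depot=DepotPhysiology(kp=4.28, fut=2.25e-8),
        psd=ParticleSizeDistribution(
            mean_radius_um=14.18, sd_radius_um=7.4, n_bins=20, density=DEPOT_DENSITY
        ),
        dissolution=DissolutionSettings(h_uwl_um=65.0, d_aq=arl.d_aq),
        icl=icl,
        horizon_h=_HORIZONS["im_suspension"],
    )


def build_scenario(name: str, icl_enabled: bool = True) -> Scenario:
    """Construct a named fixture scenario.

    ``icl_enabled`` applies to the suspension fixtures only; the solution and
    IV fixtures never carry an ICL.
    """
    if name == "ar_iv_2mg":
        return Scenario(
            name=name,
            drug=aripiprazole(),
            disposition=reference_disposition(),
            dose=FormulationDose(
                ar_equivalent_dose=2.0,
                route="iv_infusion",
                is_prodrug=False,
                infusion_duration=0.5,
            ),
            horizon_h=_HORIZONS["iv_infusion"],
            output_dt_h=0.25,
        )
    if name == "ar_im_solution_5mg":
        return Scenario(
            name=name,
            drug=aripiprazole(),
            disposition=reference_disposition(),
            dose=FormulationDose(
                ar_equivalent_dose=5.0,
                route="im_solution",
                is_prodrug=False,
                injection_volume=INJECTION_VOLUMES_ML[name],
            ),
            depot=DepotPhysiology(kp=1.84, fut=0.0012),
            horizon_h=_HORIZONS["im_solution"],
            output_dt_h=0.25,
        )
    if name in ("arl_im_150", "arl_im_300", "arl_im_400"):
        dose = float(name.rsplit("_", 1)[1])
        return _suspension_scenario(dose, name, icl_enabled)
    raise KeyError(f"unknown fixture '{name}'; choose from {FIXTURE_NAMES}")


@lru_cache(maxsize=1)
def observed_table() -> pd.DataFrame:
    """Long-format observed mean PK metrics shipped with the package."""
    ref = importlib.resources.files("depotsim").joinpath("data/observed_pk.csv")
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path)


def observed_metrics() -> Dict[str, PKMetrics]:
    """Observed metrics keyed by fixture label.

    ``t_last`` is set to the fixture horizon: the clinical sampling windows
    are not available, so simulated AUC0-t is evaluated to the horizon.
    """
    table = observed_table()
    out: Dict[str, PKMetrics] = {}
    for label, grp in table.groupby("label"):
        vals = dict(zip(grp["metric"], grp["value"]))
        route = build_scenario(label).dose.route
        out[label] = PKMetrics(
            cmax=vals["cmax"],
            tmax=vals["tmax"],
            auc0t=vals["auc0t"],
            t_last=_HORIZONS[route],
        )
    return out
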