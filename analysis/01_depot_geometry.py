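#!/usr/bin/env python
"""Closed-form inputs of the depot model: logD, ICL constants, geometry.

Derives everything that does not need an ODE solve — the prodrug's
distribution coefficient at plasma pH, its diffusivity and unbound fraction
inside the inflammatory cell layer, the spherical-depot surface areas with
the density calibrated on the 400 mg-eq dose, and the effective depot fluid
volumes — and writes the table to results/depot_geometry.csv.
"""

from pathlib import Path

import pandas as pd

from depotsim import (
    calibrate_depot_density,
    depot_surface_area,
    effective_depot_volume,
    icl_diffusivity,
    icl_fraction_unbound,
    prodrug_dose,
)
from depotsim.fixtures import INJECTION_VOLUMES_ML, aripiprazole_lauroxil

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

arl = aripiprazole_lauroxil()
logd74 = arl.logd(7.4)
d_icl = icl_diffusivity(logd74)
fu_icl = icl_fraction_unbound(logd74)
print(f"AR-L logD(7.4) = {logd74:.4f}  (logP {arl.logp}, pKa {arl.pka})")
print(f"ICL diffusivity  = {d_icl:.4g} cm^2/s  (constant on the logD>3 branch)")
print(f"ICL unbound frac = {fu_icl*100:.4f} %")

dose400 = prodrug_dose(400.0, 660.73, 448.38)
rho = calibrate_depot_density(dose400, 2.32)
print(f"\nDepot density calibrated on the 400 mg-eq dose: {rho:.3f} g/cm^3")

rows = []
for label, dose_eq in (("arl_im_150", 150.0), ("arl_im_300", 300.0), ("arl_im_400", 400.0)):
    prodrug_mg = prodrug_dose(dose_eq, 660.73, 448.38)
    rows.append(
        {
            "dose_mg_eq": dose_eq,
            "prodrug_dose_mg": round(prodrug_mg, 2),
            "injection_volume_ml": INJECTION_VOLUMES_ML[label],
            "depot_volume_ml": round(
                effective_depot_volume(INJECTION_VOLUMES_ML[label], 0.118), 2
            ),
            "surface_area_cm2": float(f"{depot_surface_area(prodrug_mg, rho):.3g}"),
        }
    )
table = pd.DataFrame(rows)
table.to_csv(OUT / "depot_geometry.csv", index=False)
print("\n", table.to_string(index=False))
print(f"\nwrote {OUT / 'depot_geometry.csv'}")
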