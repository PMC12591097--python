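#!/usr/bin/env python
"""Parameter sensitivity sweeps around the calibrated 300 mg-eq scenario.

One-at-a-time sweeps of the layer kinetics (onset lag, magnitude A, rate B)
and the formulation particle size, each over its published exploration
range, writing long-format tables results/psa_<parameter>.csv. The particle
size sweep also reports exposure split into the barrier window (first
300 h) and the full horizon.
"""

import json
from pathlib import Path

from depotsim import SweepSpec, fixtures, sweep
from depotsim.calibration import apply_params

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

fit_path = OUT / "icl_fit.json"
if not fit_path.exists():
    raise SystemExit("run 03_calibrate_icl.py first (results/icl_fit.json missing)")
params = json.loads(fit_path.read_text())["params"]

base = apply_params(fixtures.build_scenario("arl_im_300"), params)

sweeps = {
    "icl_lag": SweepSpec("icl.t_lag", vmin=0.0, vmax=1500.0, n=6, scale="linear"),
    "icl_a": SweepSpec("icl.a", vmin=2.09e-8, vmax=2.09e-4, n=8, scale="log"),
    "icl_b": SweepSpec("icl.b", vmin=0.003, vmax=0.07, n=8, scale="log"),
    "particle_radius": SweepSpec(
        "psd.mean_radius_um", vmin=1.54, vmax=75.0, n=8, scale="log"
    ),
}

for name, spec in sweeps.items():
    table = sweep(spec, base)
    table.to_csv(OUT / f"psa_{name}.csv", index=False, float_format="%.6g")
    print(f"\n== {name} ({spec.parameter}) ==")
    print(
        table[["value", "cmax", "tmax", "auc0t", "cum_absorbed_300h"]]
        .to_string(index=False)
    )

print(f"\nwrote {len(sweeps)} sweep tables under {OUT}")
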