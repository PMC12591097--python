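#!/usr/bin/env python
"""Validate the calibrated ICL kinetics on the other dose levels.

Applies the 400 mg-eq-fitted layer kinetics unchanged to the 150 and
300 mg-eq scenarios (dose-specific geometry only), tabulates fold errors
against the observed metrics, and writes results/validation.csv plus the
with-ICL plasma profiles.
"""

import json
from pathlib import Path

from depotsim import fixtures, simulate, validate_doses
from depotsim.calibration import apply_params
from depotsim.io import write_profile

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

fit_path = OUT / "icl_fit.json"
if not fit_path.exists():
    raise SystemExit("run 03_calibrate_icl.py first (results/icl_fit.json missing)")
params = json.loads(fit_path.read_text())["params"]

labels = ("arl_im_150", "arl_im_300", "arl_im_400")
observed = fixtures.observed_metrics()
scenarios = {label: fixtures.build_scenario(label) for label in labels}

table = validate_doses(params, scenarios, {k: observed[k] for k in labels})
table.to_csv(OUT / "validation.csv", index=False, float_format="%.6g")
print(table.to_string(index=False))

worst = max(abs(table.fe_cmax - 1).max(), abs(table.fe_auc - 1).max())
print(f"\nmax |FE-1| over Cmax and AUC0-t: {100*worst:.1f}% "
      f"({'within' if worst <= 0.25 else 'OUTSIDE'} the 25% acceptance band)")

for label in labels:
    write_profile(
        simulate(apply_params(scenarios[label], params)),
        OUT / f"profile_{label}_icl.csv",
        stride=12,
    )
print(f"wrote {OUT / 'validation.csv'} and per-dose profiles")
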