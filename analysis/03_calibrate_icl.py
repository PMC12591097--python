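#!/usr/bin/env python
"""Calibrate the inflammatory-cell-layer kinetics on the 400 mg-eq dose.

Fits (A, B, kappa) — thickness magnitude, thickness rate and the
conductance scale — to the observed Cmax/AUC0-t/Tmax of the 400 mg-eq
suspension by bounded relative least squares, and stores the fitted
parameters in results/icl_fit.json for the validation step.
"""

import json
from pathlib import Path

from depotsim import FitTarget, fit_icl, fixtures, pk_metrics, simulate
from depotsim.calibration import apply_params

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

observed = fixtures.observed_metrics()
template = fixtures.build_scenario("arl_im_400")
target = FitTarget(kind="metrics", metrics=observed["arl_im_400"])

fit = fit_icl(template, target)
print("fitted ICL parameters (400 mg-eq):")
for k, v in fit.params.items():
    print(f"  {k:6s} = {v:.4g}")
print(f"objective {fit.objective:.3e}, converged={fit.converged}")

sim = pk_metrics(simulate(apply_params(template, fit.params)),
                 t_last=observed["arl_im_400"].t_last)
obs = observed["arl_im_400"]
print(f"400 mg-eq after calibration: Cmax {sim.cmax:.1f} (obs {obs.cmax}), "
      f"AUC {sim.auc0t:.0f} (obs {obs.auc0t:.0f}), Tmax {sim.tmax:.0f} (obs {obs.tmax})")

payload = {
    "params": fit.params,
    "objective": fit.objective,
    "converged": fit.converged,
    "free": list(fit.free),
    "bounds": {k: list(v) for k, v in fit.bounds.items()},
}
(OUT / "icl_fit.json").write_text(json.dumps(payload, indent=2) + "\n")
print(f"wrote {OUT / 'icl_fit.json'}")
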