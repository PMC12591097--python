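"""One-at-a-time parameter sensitivity sweeps.

Each sweep varies a single scenario parameter over a value grid (all else
held at baseline), simulates, and tabulates the PK metrics. Sweeps are
embarrassingly parallel in principle; here they run sequentially but are
order-independent by construction.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .depot import Scenario, SolverError, simulate
from .metrics import pk_metrics

__all__ = ["SweepSpec", "sweep", "set_scenario_param"]

#: parameter paths understood by :func:`set_scenario_param`
_KNOWN_PREFIXES = ("icl.", "psd.", "dissolution.", "depot.", "drug.", "dose.")


@dataclass
class SweepSpec:
    """A one-parameter sweep definition.

    ``parameter`` is a dotted path into the scenario (e.g. ``"icl.a"``,
    ``"psd.mean_radius_um"``, ``"drug.s_ref"``, ``"depot.perfusion"``).
    Either an explicit ``values`` list or a (min, max, n, scale) grid.
    """

    parameter: str
    values: Optional[Sequence[float]] = None
    vmin: Optional[float] = None
    vmax: Optional[float] = None
    n: int = 8
    scale: str = "log"

    def __post_init__(self) -> None:
        if not self.parameter.startswith(_KNOWN_PREFIXES):
            raise ValueError(f"unknown parameter path: {self.parameter}")
        if self.values is None:
            if self.vmin is None or self.vmax is None:
                raise ValueError("need either values or (vmin, vmax)")
            if self.n < 2:
                raise ValueError("n must be >= 2 for a range sweep")
            if self.scale not in ("linear", "log"):
                raise ValueError("scale must be 'linear' or 'log'")

    def grid(self) -> np.ndarray:
        if self.values is not None:
            return np.asarray(list(self.values), dtype=float)
        if self.scale == "log":
            return np.geomspace(self.vmin, self.vmax, self.n)
        return np.linspace(self.vmin, self.vmax, self.n)


def set_scenario_param(scenario: Scenario, path: str, value: float) -> Scenario:
    """Deep-copy ``scenario`` with one dotted-path parameter replaced."""
    block, _, attr = path.partition(".")
    new = copy.deepcopy(scenario)
    target = getattr(new, block)
    if target is None:
        raise ValueError(f"scenario has no '{block}' block")
    if not hasattr(target, attr):
        raise ValueError(f"'{block}' has no attribute '{attr}'")
    setattr(target, attr, value)
    return new


def sweep(spec: SweepSpec, base: Scenario, t_last: Optional[float] = None) -> pd.DataFrame:
    """Run the sweep; one simulation per value.

    Returns a long-format table (parameter, value, cmax, tmax, auc0t,
    cum_absorbed_300h, error). Individual solver failures are recorded in
    the ``error`` column and the sweep continues.
    """
    rows = []
    for value in spec.grid():
        row = {"parameter": spec.parameter, "value": float(value)}
        try:
            scenario = set_scenario_param(base, spec.parameter, float(value))
            result = simulate(scenario)
            m = pk_metrics(result, t_last=t_last)
            i300 = int(np.searchsorted(result.t, min(300.0, result.t[-1])))
            row.update(
                cmax=m.cmax,
                tmax=m.tmax,
                auc0t=m.auc0t,
                cum_absorbed_300h=float(result.absorbed_mg[i300]),
                error="",
            )
        except (SolverError, ValueError) as exc:
            row.update(cmax=np.nan, tmax=np.nan, auc0t=np.nan,
                       cum_absorbed_300h=np.nan, error=str(exc))
        rows.append(row)
    return pd.DataFrame(rows)
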