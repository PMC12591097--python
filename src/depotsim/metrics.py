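"""Non-compartmental PK metrics and fold-error validation arithmetic."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .depot import SimulationResult

__all__ = [
    "PKMetrics",
    "ValidationRow",
    "pk_metrics",
    "fold_error",
    "within_band",
]


@dataclass
class PKMetrics:
    """Cmax (ng/mL), Tmax (h), AUC from 0 to t_last (ng*h/mL)."""

    cmax: float
    tmax: float
    auc0t: float
    t_last: float

    def __post_init__(self) -> None:
        if self.cmax < 0 or self.auc0t < 0:
            raise ValueError("cmax and auc0t must be >= 0")
        if not 0 <= self.tmax <= self.t_last:
            raise ValueError("tmax must lie in [0, t_last]")


@dataclass
class ValidationRow:
    """Observed vs simulated metrics for one dose level."""

    label: str
    observed: PKMetrics
    simulated: PKMetrics

    @property
    def fe_cmax(self) -> float:
        return fold_error(self.simulated.cmax, self.observed.cmax)

    @property
    def fe_auc(self) -> float:
        return fold_error(self.simulated.auc0t, self.observed.auc0t)

    @property
    def fe_tmax(self) -> float:
        return fold_error(self.simulated.tmax, self.observed.tmax)


def pk_metrics(result: SimulationResult, t_last: Optional[float] = None) -> PKMetrics:
    """Standard NCA on the dense simulated grid.

    Cmax is the grid maximum on [0, t_last], Tmax the *first* time attaining
    it (plateaus resolve to their onset), and AUC0-t the linear trapezoid.
    """
    t, cp = result.t, result.cp
    if len(t) == 0:
        raise ValueError("empty profile")
    if t_last is None:
        t_last = float(t[-1])
    if t_last > t[-1] + 1e-9:
        raise ValueError("t_last exceeds the simulated horizon")
    mask = t <= t_last + 1e-12
    t, cp = t[mask], cp[mask]
    i_max = int(np.argmax(cp))
    auc = float(np.trapezoid(cp, t))
    return PKMetrics(
        cmax=float(cp[i_max]), tmax=float(t[i_max]), auc0t=auc, t_last=float(t[-1])
    )


def fold_error(simulated: float, observed: float) -> float:
    """Simulated/observed ratio of a PK metric."""
    if observed <= 0:
        raise ValueError("observed must be > 0")
    return simulated / observed


def within_band(fe: float, band_percent: float = 25.0) -> bool:
    """Whether a fold error passes the symmetric acceptance band.

    True iff |FE - 1| * 100 <= band; e.g. FE in [0.75, 1.25] for the
    standard 25% band.
    """
    if fe <= 0:
        raise ValueError("fold error must be > 0")
    return abs(fe - 1.0) * 100.0 <= band_percent
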