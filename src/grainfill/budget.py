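"""Source-sink redistribution budget for grain filling.

During filling, an element arriving in the grain either comes from
concurrent root uptake or is remobilized from stores in vegetative
tissues. The apparent redistribution from the flag leaf and node I (the
uppermost stem node, a xylem-to-phloem transfer hub) is estimated from
their net accumulation between 5 and 30 DAF,

    dC_i = C30_i - C5_i,

where a negative value marks the tissue as a *source* (net export during
filling) and a positive one as a *sink*. Each source tissue's contribution
ratio to the grain is

    R_i = |dC_i| / C30_grain * 100 (%)

and the remainder, 100 - sum(R_i over sources), is attributed to "other
sources" (stem transport, continued root absorption). Applying R_i to a
sink tissue would count an inflow as a contribution, so sinks are assigned
R_i = 0 and reported by role instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import GrainContentSeries
from .exceptions import UnitError, ValidationError

__all__ = ["net_accumulation", "contribution_ratio", "assemble_budget", "TissueBudget"]

GRAIN = "grain"
VEGETATIVE = ("flag_leaf", "node_I")


def net_accumulation(c5: float, c30: float) -> float:
    """Signed net accumulation dC = C30 - C5 over grain filling."""
    if c5 < 0 or c30 < 0:
        raise ValidationError("contents must be >= 0")
    return c30 - c5


def contribution_ratio(delta_c: float, c30_grain: float) -> float:
    """Contribution ratio R = |dC| / C30_grain * 100, in percent."""
    if not c30_grain > 0:
        raise ValidationError("C30(grain) must be positive")
    return abs(delta_c) / c30_grain * 100.0


@dataclass
class TissueBudget:
    """Per-tissue net accumulation and contribution ratios for one element.

    ``per_tissue`` maps tissue -> dict(C5, C30, delta, role, R_percent);
    grain has no role/R. ``other_sources`` is the remainder percentage, a
    bookkeeping quantity rather than a measurement.
    """

    element: str
    unit: str
    per_tissue: dict = field(default_factory=dict)
    other_sources: float = np.nan
    clamped: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tissue, d in self.per_tissue.items():
            rows.append(
                {
                    "element": self.element,
                    "tissue": tissue,
                    "C5": d["C5"],
                    "C30": d["C30"],
                    "deltaC": d["delta"],
                    "role": d.get("role", ""),
                    "R_percent": d.get("R_percent", np.nan),
                    "other_sources_percent": self.other_sources,
                    "unit": self.unit,
                }
            )
        return pd.DataFrame(rows)


def assemble_budget(
    series_by_tissue: dict[str, GrainContentSeries],
    t_start: int = 5,
    t_end: int = 30,
) -> TissueBudget:
    """Build the redistribution budget from grain + vegetative time series.

    C5 and C30 are taken as replicate means of observed contents at 5 and
    30 DAF (the budget is defined on measured endpoints, not on fitted
    curves). Only tissues with negative net accumulation are counted as
    sources; if the sources nominally exceed the grain's gain, the "other
    sources" remainder is floored at zero with a warning.
    """
    if GRAIN not in series_by_tissue:
        raise ValidationError("a grain series is required")
    units = {s.unit for s in series_by_tissue.values()}
    if len(units) > 1:
        raise UnitError(f"mixed units across tissues: {sorted(units)}")
    elements = {s.element for s in series_by_tissue.values()}
    if len(elements) > 1:
        raise ValidationError(f"mixed elements in one budget: {sorted(elements)}")

    endpoints = {}
    for tissue, series in series_by_tissue.items():
        means = series.replicate_means()
        for t in (t_start, t_end):
            if t not in means.index:
                raise ValidationError(
                    f"{tissue}: missing {t} DAF observations "
                    f"(have {list(means.index)})"
                )
        endpoints[tissue] = (float(means.loc[t_start]), float(means.loc[t_end]))

    c5g, c30g = endpoints[GRAIN]
    if not c30g > 0:
        raise ValidationError("grain content at 30 DAF must be positive")

    budget = TissueBudget(
        element=next(iter(elements)),
        unit=next(iter(units)),
    )
    budget.per_tissue[GRAIN] = {
        "C5": c5g, "C30": c30g, "delta": net_accumulation(c5g, c30g),
    }
    total_sources = 0.0
    for tissue, (c5, c30) in endpoints.items():
        if tissue == GRAIN:
            continue
        delta = net_accumulation(c5, c30)
        if delta < 0:
            role, r = "source", contribution_ratio(delta, c30g)
        else:
            role, r = "sink", 0.0
        total_sources += r
        budget.per_tissue[tissue] = {
            "C5": c5, "C30": c30, "delta": delta, "role": role, "R_percent": r,
        }
    other = 100.0 - total_sources
    if other < 0:
        warnings.warn(
            f"{budget.element}: source contributions sum to "
            f"{total_sources:.1f}% of grain content at 30 DAF; "
            "'other sources' floored at 0",
            stacklevel=2,
        )
        other = 0.0
        budget.clamped = True
    budget.other_sources = other
    return budget
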