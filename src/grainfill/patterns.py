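"""Accumulation-pattern classification.

Elements load into the developing grain on different schedules. Three
patterns are distinguished by where the accumulation-rate peak falls
relative to the sampling window [t_first, t_last]:

* **early** — the rate peaks at or before the first sampling time
  (typical of K, B, Mn, Ca: loaded rapidly before/at 5 DAF, then tailing
  off);
* **mid** — the rate peaks inside the window, broadly tracking dry matter
  (N, P, S, Mg, Cu, Zn, Mo, As, Cd);
* **sustained** — the rate is still rising at the last sampling time
  (Fe: continued increase through to maturation).

For a converged logistic fit the rate peak is exactly the inflection time
x_c, so the rule reduces to comparing x_c with the window. Boundary ties
(x_c exactly at t_first or t_last) resolve to early / sustained. When the
logistic fit fails, an empirical fallback classifies the sign trend of
finite-difference rates instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import GrainContentSeries
from .exceptions import NotConvergedError, ValidationError
from .kinetics import LogisticGrowthResults

__all__ = [
    "PatternLabel",
    "classify_pattern",
    "classify_empirical",
    "classify_series",
    "summarize_patterns",
]

PATTERNS = ("early", "mid", "sustained")

#: Spearman-rho cutoffs for the empirical (fit-free) fallback: rates that
#: decrease monotonically enough are "early", increase enough "sustained".
FALLBACK_RHO = 0.5


@dataclass(frozen=True)
class PatternLabel:
    element: str
    pattern: str
    t_peak: float
    delta_vs_drymatter: float
    basis: str  # "fitted" or "empirical-fallback"

    def __post_init__(self):
        if self.pattern not in PATTERNS:
            raise ValidationError(f"unknown pattern {self.pattern!r}")


def classify_pattern(
    fit: LogisticGrowthResults,
    drymatter_fit: LogisticGrowthResults,
    window: tuple[float, float],
    element: str = "",
) -> PatternLabel:
    """Label an element from its fitted rate peak relative to the window.

    ``delta_vs_drymatter`` is t_peak(element) - t_peak(dry matter), in days;
    it quantifies the "slightly earlier/later than dry matter" remarks that
    only make sense for mid-pattern elements but is reported for all.
    """
    if drymatter_fit is None:
        raise NotConvergedError("a converged dry-matter fit is required")
    if not fit.converged or not drymatter_fit.converged:
        raise NotConvergedError(
            "classify_pattern requires converged fits; use classify_empirical"
        )
    t_first, t_last = window
    t_peak = fit.peak_rate()[0]
    if t_peak <= t_first:
        pattern = "early"
    elif t_peak >= t_last:
        pattern = "sustained"
    else:
        pattern = "mid"
    delta = t_peak - drymatter_fit.peak_rate()[0]
    return PatternLabel(element=element, pattern=pattern, t_peak=t_peak,
                        delta_vs_drymatter=delta, basis="fitted")


def classify_empirical(
    series: GrainContentSeries,
    window: tuple[float, float],
    drymatter_t_peak: float = np.nan,
) -> PatternLabel:
    """Fit-free fallback: classify the trend of finite-difference rates.

    Rates between successive replicate means are computed and their rank
    trend against interval midpoints tested. "Early" requires the rate to
    be falling from the very start: the largest rate in the first interval
    and Spearman rho <= -0.5. "Sustained" is the mirror image (largest rate
    in the last interval, rho >= +0.5). Everything else — in particular a
    hump with its peak inside the window — is mid. The rate-peak estimate
    is the midpoint of the interval with the largest finite-difference
    rate.
    """
    means = series.replicate_means()
    if len(means) < 3:
        raise ValidationError("empirical classification needs >= 3 time points")
    t = means.index.to_numpy(dtype=float)
    m = means.to_numpy()
    rate = np.diff(m) / np.diff(t)
    mid = 0.5 * (t[:-1] + t[1:])
    if np.ptp(rate) == 0:  # all rates tied: no trend
        rho = 0.0
    else:
        rho = stats.spearmanr(mid, rate).statistic
    peak_interval = int(np.argmax(rate))
    if rho <= -FALLBACK_RHO and peak_interval == 0:
        pattern = "early"
    elif rho >= FALLBACK_RHO and peak_interval == len(rate) - 1:
        pattern = "sustained"
    else:
        pattern = "mid"
    t_peak = float(mid[peak_interval])
    return PatternLabel(
        element=series.element, pattern=pattern, t_peak=t_peak,
        delta_vs_drymatter=t_peak - drymatter_t_peak,
        basis="empirical-fallback",
    )


def classify_series(
    series: GrainContentSeries,
    fit: LogisticGrowthResults,
    drymatter_fit: LogisticGrowthResults,
    window: tuple[float, float],
) -> PatternLabel:
    """Classify from the fit when converged, else fall back to the trend rule."""
    if fit is not None and fit.converged and drymatter_fit.converged:
        return classify_pattern(fit, drymatter_fit, window, element=series.element)
    dm_peak = drymatter_fit.peak_rate()[0] if drymatter_fit.converged else np.nan
    return classify_empirical(series, window, drymatter_t_peak=dm_peak)


def summarize_patterns(labels) -> pd.DataFrame:
    """Per-pattern counts and element lists, in fixed pattern order."""
    labels = list(labels)
    if not labels:
        raise ValidationError("at least one pattern label is required")
    rows = []
    for pattern in PATTERNS:
        elems = sorted(l.element for l in labels if l.pattern == pattern)
        rows.append(
            {"pattern": pattern, "count": len(elems), "elements": ",".join(elems)}
        )
    return pd.DataFrame(rows)
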