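"""Study design and core data containers.

The time coordinate throughout the package is DAF (days after
fertilization), an integer number of days. Element contents are expressed
per grain (or per whole tissue for vegetative organs) in one of four unit
scales: mg, ug, ng or pg. Units are carried as strings and never converted;
accumulation-rate units derive as ``<content unit> d-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ValidationError, UnitError

#: Closed set of per-grain content units. "ug" is the ASCII spelling of
#: micrograms; the Greek-mu spellings are normalized to it on input.
ALLOWED_UNITS = ("mg", "ug", "ng", "pg")

_UNIT_ALIASES = {"μg": "ug", "µg": "ug"}


def normalize_unit(unit: str) -> str:
    """Map unit spellings onto the closed unit set, validating membership."""
    u = _UNIT_ALIASES.get(str(unit).strip(), str(unit).strip())
    if u not in ALLOWED_UNITS:
        raise UnitError(
            f"unknown content unit {unit!r}; expected one of {ALLOWED_UNITS}"
        )
    return u


@dataclass(frozen=True)
class StudyDesign:
    """Sampling layout of a grain-filling time course.

    Parameters
    ----------
    time_points
        Sampling times in DAF, strictly increasing integers.
    replicates
        Number of biological replicates per time point (>= 2).
    tissues
        Tissue labels sampled (e.g. ``grain``, ``flag_leaf``, ``node_I``).
    element_units
        Mapping of element label to its content unit. May be empty for
        designs that only describe an expression time course.
    """

    time_points: tuple[int, ...]
    replicates: int
    tissues: tuple[str, ...] = ("grain",)
    element_units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        tp = tuple(int(t) for t in self.time_points)
        if len(tp) < 2 or any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValidationError("time_points must be strictly increasing")
        if self.replicates < 2:
            raise ValidationError("replicates must be >= 2")
        units = {e: normalize_unit(u) for e, u in self.element_units.items()}
        if len(set(units)) != len(units):
            raise ValidationError("element labels must be unique")
        object.__setattr__(self, "time_points", tp)
        object.__setattr__(self, "element_units", units)
        object.__setattr__(self, "tissues", tuple(self.tissues))

    @property
    def window(self) -> tuple[int, int]:
        """(first, last) sampling time — the observation window in DAF."""
        return self.time_points[0], self.time_points[-1]

    @property
    def elements(self) -> tuple[str, ...]:
        return tuple(self.element_units)


#: The sampling design of the field study this package models: grain,
#: flag leaf and node I collected at 7 times across grain filling with
#: 4 replicates for element determination.
DEFAULT_IONOME_DESIGN = StudyDesign(
    time_points=(5, 9, 13, 17, 21, 25, 30),
    replicates=4,
    tissues=("grain", "flag_leaf", "node_I"),
)

#: Transcriptome sampling: five stages spanning active filling, 3 replicates.
DEFAULT_EXPRESSION_DESIGN = StudyDesign(
    time_points=(5, 9, 13, 17, 21),
    replicates=3,
    tissues=("grain",),
)


class GrainContentSeries:
    """Replicated content measurements over DAF for one element x tissue.

    Observations are stored long-form: one row per (daf, replicate) with a
    non-negative content ``value`` in ``unit`` per grain (or per tissue).
    """

    def __init__(
        self,
        element: str,
        tissue: str,
        unit: str,
        daf: Sequence[int],
        replicate: Sequence[int],
        value: Sequence[float],
        metadata: dict | None = None,
    ):
        self.element = str(element)
        self.tissue = str(tissue)
        self.unit = normalize_unit(unit)
        daf = np.asarray(daf, dtype=int)
        replicate = np.asarray(replicate, dtype=int)
        value = np.asarray(value, dtype=float)
        if not (len(daf) == len(replicate) == len(value)):
            raise ValidationError("daf, replicate and value must be equal length")
        if len(value) == 0:
            raise ValidationError("empty series")
        if np.any(value < 0) or not np.all(np.isfinite(value)):
            raise ValidationError(
                f"{self.element}/{self.tissue}: contents must be finite and >= 0"
            )
        order = np.lexsort((replicate, daf))
        self.daf = daf[order]
        self.replicate = replicate[order]
        self.value = value[order]
        #: Free-form provenance, e.g. ground-truth parameters from a simulator.
        self.metadata = dict(metadata or {})

    def __repr__(self):  # pragma: no cover - cosmetic
        return (
            f"GrainContentSeries({self.element}/{self.tissue}, unit={self.unit}, "
            f"n={len(self.value)}, daf={sorted(set(self.daf.tolist()))})"
        )

    def __len__(self):
        return len(self.value)

    @property
    def times(self) -> np.ndarray:
        """Distinct sampling times, ascending."""
        return np.unique(self.daf)

    def replicate_means(self) -> pd.Series:
        """Mean content per DAF, indexed by DAF (ascending)."""
        return pd.Series(self.value).groupby(pd.Series(self.daf)).mean()

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "element": self.element,
                "tissue": self.tissue,
                "daf": self.daf,
                "replicate": self.replicate,
                "value": self.value,
                "unit": self.unit,
            }
        )
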