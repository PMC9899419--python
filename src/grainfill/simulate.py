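"""Synthetic data with the statistical structure of a grain-filling study.

Every downstream stage of the pipeline can be exercised against known
ground truth generated here: element contents following logistic
trajectories in the three accumulation archetypes, vegetative-tissue
series with prescribed source/sink behavior, and FPKM matrices with genes
planted on known temporal profiles. Ground truth always travels with the
data (series metadata, truth tables) so recovery can be checked exactly.

Replicate noise on contents is multiplicative lognormal parameterized by a
coefficient of variation (contents are positive and field data are
reported as mean +/- SE on positive scales). Expression noise is likewise
multiplicative lognormal on the FPKM scale; read-count dispersion is
deliberately not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (
    DEFAULT_EXPRESSION_DESIGN,
    DEFAULT_IONOME_DESIGN,
    GrainContentSeries,
    StudyDesign,
)
from .exceptions import ValidationError
from .kinetics import logistic
from .trends import ExpressionMatrix

__all__ = [
    "ElementArchetype",
    "ProfilePlant",
    "DEFAULT_PANEL",
    "simulate_grain_series",
    "simulate_panel",
    "simulate_tissue_budget",
    "simulate_expression",
]

ARCHETYPES = ("early", "mid", "sustained")

#: Default replicate noise for element contents. Field replicate scatter is
#: study-specific; a 10% CV is a realistic magnitude for replicated
#: per-grain element determinations.
DEFAULT_NOISE_CV = 0.10


@dataclass(frozen=True)
class ElementArchetype:
    """Ground-truth logistic parameters for one simulated element.

    ``label`` encodes where the inflection x_c sits relative to the
    sampling window: early (x_c at or before the first sampling time), mid
    (inside the window) or sustained (at or after the last time).
    """

    element: str
    label: str
    a: float  # asymptotic content, in `unit`
    k: float  # growth rate, d-1
    x_c: float  # inflection, DAF
    unit: str = "ug"
    noise_cv: float = DEFAULT_NOISE_CV

    def __post_init__(self):
        if self.label not in ARCHETYPES:
            raise ValidationError(f"unknown archetype label {self.label!r}")
        if self.a <= 0 or self.k <= 0:
            raise ValidationError("a and k must be positive")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")

    def validate_against(self, design: StudyDesign):
        t_first, t_last = design.window
        ok = {
            "early": self.x_c <= t_first,
            "mid": t_first < self.x_c < t_last,
            "sustained": self.x_c >= t_last,
        }[self.label]
        if not ok:
            raise ValidationError(
                f"{self.element}: x_c={self.x_c} inconsistent with "
                f"label {self.label!r} for window {design.window}"
            )


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Multiplicative noise with mean 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def simulate_grain_series(
    archetype: ElementArchetype,
    design: StudyDesign = DEFAULT_IONOME_DESIGN,
    seed: int | np.random.Generator = 0,
    tissue: str = "grain",
) -> GrainContentSeries:
    """Replicated logistic content trajectory with lognormal replicate noise."""
    archetype.validate_against(design)
    rng = np.random.default_rng(seed)
    times = np.repeat(design.time_points, design.replicates)
    reps = np.tile(np.arange(1, design.replicates + 1), len(design.time_points))
    mean = logistic(times, archetype.a, archetype.k, archetype.x_c)
    values = mean * _lognormal_factors(rng, archetype.noise_cv, len(times))
    return GrainContentSeries(
        element=archetype.element,
        tissue=tissue,
        unit=archetype.unit,
        daf=times,
        replicate=reps,
        value=values,
        metadata={
            "truth_a": archetype.a,
            "truth_k": archetype.k,
            "truth_x_c": archetype.x_c,
            "truth_label": archetype.label,
            "noise_cv": archetype.noise_cv,
        },
    )


def _panel(noise_cv: float = DEFAULT_NOISE_CV) -> list[ElementArchetype]:
    """A 14-entry panel shaped like a rice grain-filling ionome plus dry matter.

    Archetype membership follows the field picture: K, B, Mn, Ca load
    early; dry matter and N, P, S, Mg, Cu, Zn, Mo, As, Cd peak mid-filling;
    Fe keeps rising to the end of the window. Asymptotes are set so the
    peak accumulation rates (a*k/4) fall on realistic per-grain scales for
    each unit.
    """
    A = ElementArchetype
    mk = lambda e, lab, a, k, xc, u: A(e, lab, a, k, xc, u, noise_cv)
    return [
        # early: inflection at/before the first sampling time (5 DAF)
        mk("K", "early", 0.55, 0.45, 4.0, "mg"),
        mk("Ca", "early", 8.0, 0.50, 3.0, "ug"),
        mk("B", "early", 1.2, 0.40, 4.5, "ug"),
        mk("Mn", "early", 18.0, 0.35, 4.5, "ug"),
        # mid: inflection inside the window, tracking dry matter
        mk("drymatter", "mid", 18.0, 0.30, 13.0, "mg"),
        mk("N", "mid", 160.0, 0.30, 13.0, "ug"),
        mk("P", "mid", 52.0, 0.30, 13.0, "ug"),
        mk("Mg", "mid", 21.0, 0.30, 13.0, "ug"),
        mk("S", "mid", 24.0, 0.30, 11.0, "ug"),
        mk("Cu", "mid", 68.0, 0.30, 11.0, "ng"),
        mk("Zn", "mid", 440.0, 0.30, 11.0, "ng"),
        mk("Mo", "mid", 4.0, 0.30, 14.0, "ng"),
        mk("Cd", "mid", 100.0, 0.30, 11.0, "pg"),
        # sustained: rate still rising at the last sampling time (30 DAF)
        mk("Fe", "sustained", 1400.0, 0.15, 31.0, "ng"),
    ]


DEFAULT_PANEL: tuple[ElementArchetype, ...] = tuple(_panel())

#: Inflection-time ranges used when drawing random archetypes. Early
#: elements invert well before the first sampling time, mid elements within
#: the active filling phase, sustained ones beyond the window — mirroring
#: the element panel, where inflections sit well inside or outside the
#: window rather than on its edges.
XC_RANGES = {"early": (1.0, 4.5), "mid": (9.0, 21.0), "sustained": (30.5, 40.0)}


def random_archetype(
    label: str,
    rng: np.random.Generator,
    element: str = "X",
    design: StudyDesign = DEFAULT_IONOME_DESIGN,
    noise_cv: float = DEFAULT_NOISE_CV,
) -> ElementArchetype:
    """Draw a random archetype of the given class for recovery experiments."""
    lo, hi = XC_RANGES[label]
    return ElementArchetype(
        element=element,
        label=label,
        a=float(rng.uniform(5.0, 50.0)),
        k=float(rng.uniform(0.2, 0.5)),
        x_c=float(rng.uniform(lo, hi)),
        unit="ug",
        noise_cv=noise_cv,
    )


def simulate_panel(
    design: StudyDesign = DEFAULT_IONOME_DESIGN,
    seed: int = 0,
    archetypes=None,
    noise_cv: float | None = None,
) -> list[GrainContentSeries]:
    """Simulate a full element panel (default: the 14-entry study-like panel)."""
    if archetypes is None:
        archetypes = _panel(DEFAULT_NOISE_CV if noise_cv is None else noise_cv)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(archetypes))
    return [
        simulate_grain_series(arch, design, np.random.default_rng(child))
        for arch, child in zip(archetypes, children)
    ]


def simulate_tissue_budget(
    element: str,
    source_fraction: float,
    node_fraction: float,
    design: StudyDesign = DEFAULT_IONOME_DESIGN,
    seed: int | np.random.Generator = 0,
    unit: str = "ug",
    grain_archetype: ElementArchetype | None = None,
    noise_cv: float = 0.0,
) -> dict[str, GrainContentSeries]:
    """Grain + vegetative series with prescribed source/sink structure.

    The grain accumulates along a logistic trajectory reaching content G at
    the last sampling time; the flag leaf changes by -source_fraction * G
    and node I by -node_fraction * G, linearly in time. Because the
    contribution ratio is normalized by the grain content at the end of
    filling, the downstream budget recovers the planted fractions exactly
    in the zero-noise case. Negative fractions make a tissue a sink (its
    content increases), emulating elements such as Ca and Mn for which the
    flag leaf imports rather than exports.
    """
    for name, f in (("source_fraction", source_fraction),
                    ("node_fraction", node_fraction)):
        if not -1.0 <= f <= 1.0:
            raise ValidationError(f"{name} must be in [-1, 1]")
    if not source_fraction + node_fraction <= 1.0:
        raise ValidationError("fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    if grain_archetype is None:
        grain_archetype = ElementArchetype(
            element, "mid", a=20.0, k=0.3, x_c=13.0, unit=unit,
            noise_cv=noise_cv,
        )
    grain = simulate_grain_series(grain_archetype, design, rng)
    t = np.asarray(design.time_points, dtype=float)
    t_first, t_last = design.window
    w = logistic(t, grain_archetype.a, grain_archetype.k, grain_archetype.x_c)
    gain = w[-1]  # grain content at the end of filling (the Ri denominator)

    out = {"grain": grain}
    for tissue, frac in (("flag_leaf", source_fraction),
                         ("node_I", node_fraction)):
        loss = frac * gain
        # baseline keeps the trajectory comfortably positive
        c0 = max(2.0 * abs(loss), 0.25 * gain)
        mean = c0 - loss * (t - t_first) / (t_last - t_first)
        times = np.repeat(design.time_points, design.replicates)
        reps = np.tile(np.arange(1, design.replicates + 1),
                       len(design.time_points))
        values = np.repeat(mean, design.replicates) * _lognormal_factors(
            rng, noise_cv, len(times)
        )
        out[tissue] = GrainContentSeries(
            element=element, tissue=tissue, unit=unit,
            daf=times, replicate=reps, value=values,
            metadata={"truth_fraction": frac, "truth_gain": gain},
        )
    return out


@dataclass(frozen=True)
class ProfilePlant:
    """Design of a planted-profile expression simulation.

    ``shapes`` are integer temporal templates (starting at 0); each planted
    gene's stage mean is ``baseline * 2**shape[t]``, i.e. the shape is the
    log2 fold change against the first stage. ``noise_cv`` is the CV of
    multiplicative lognormal noise on FPKM; ``n_null`` flat genes carry no
    temporal signal.
    """

    shapes: tuple[tuple[int, ...], ...] = ((0, -1, -2, -3, -4),
                                           (0, 1, 2, 3, 4),
                                           (0, 1, 2, 1, 0))
    genes_per_shape: int = 200
    n_null: int = 100
    baseline_fpkm: tuple[float, float] = (10.0, 200.0)  # log-uniform range
    noise_cv: float = 0.10

    def __post_init__(self):
        if self.genes_per_shape < 1 and self.n_null < 1:
            raise ValidationError("at least one gene must be simulated")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        for s in self.shapes:
            if s[0] != 0:
                raise ValidationError("profile shapes must start at 0")


def simulate_expression(
    plant: ProfilePlant = ProfilePlant(),
    design: StudyDesign = DEFAULT_EXPRESSION_DESIGN,
    seed: int | np.random.Generator = 0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """FPKM matrix with genes planted on known temporal profiles.

    Returns (matrix, truth) where ``truth`` has one row per gene with its
    planted shape (or ``null``). Shapes must match the number of design
    time points.
    """
    T = len(design.time_points)
    for s in plant.shapes:
        if len(s) != T:
            raise ValidationError(
                f"shape {s} has {len(s)} stages but the design has {T}"
            )
    rng = np.random.default_rng(seed)
    lo, hi = plant.baseline_fpkm
    rows, truth_rows, gene_ids = [], [], []
    gid = 0
    for si, shape in enumerate(plant.shapes):
        fold = 2.0 ** np.asarray(shape, dtype=float)
        for _ in range(plant.genes_per_shape):
            base = np.exp(rng.uniform(np.log(lo), np.log(hi)))
            stage_mean = base * fold
            noise = _lognormal_factors(
                rng, plant.noise_cv, (T, design.replicates)
            )
            rows.append((stage_mean[:, None] * noise).ravel())
            gene_ids.append(f"gene{gid:05d}")
            truth_rows.append({"gene_id": gene_ids[-1], "shape_index": si,
                               "shape": " ".join(map(str, shape))})
            gid += 1
    for _ in range(plant.n_null):
        base = np.exp(rng.uniform(np.log(lo), np.log(hi)))
        noise = _lognormal_factors(rng, plant.noise_cv, (T, design.replicates))
        rows.append((base * noise).ravel())
        gene_ids.append(f"gene{gid:05d}")
        truth_rows.append({"gene_id": gene_ids[-1], "shape_index": -1,
                           "shape": "null"})
        gid += 1

    columns = [
        f"{daf}DAF_r{rep}"
        for daf in design.time_points
        for rep in range(1, design.replicates + 1)
    ]
    values = pd.DataFrame(rows, index=pd.Index(gene_ids, name="gene_id"),
                          columns=columns)
    samples = pd.DataFrame(
        {
            "daf": [d for d in design.time_points
                    for _ in range(design.replicates)],
            "replicate": [r for _ in design.time_points
                          for r in range(1, design.replicates + 1)],
        },
        index=pd.Index(columns, name="sample"),
    )
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    return ExpressionMatrix(values, samples), truth
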