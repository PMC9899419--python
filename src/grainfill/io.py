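"""Table I/O and run configuration.

Element tables are long (tidy): one row per measurement with columns
``element, tissue, daf, replicate, value, unit``. Expression matrices are
wide gene x sample TSVs with a ``gene_id`` column and sample columns named
``<daf>DAF_r<rep>``. Units are carried as strings and validated against a
closed set; they are never converted.
"""

from __future__ import annotations

import dataclasses
import re
from pathlib import Path

import pandas as pd
import yaml

from .design import GrainContentSeries, StudyDesign, normalize_unit
from .exceptions import SchemaError, UnitError, ValidationError
from .trends import DEFAULT_C, DEFAULT_EPS, DEFAULT_M, DEFAULT_THRESHOLD, ExpressionMatrix

CONTENT_COLUMNS = ("element", "tissue", "daf", "replicate", "value", "unit")

_SAMPLE_RE = re.compile(r"^(\d+)DAF_r(\d+)$")


@dataclasses.dataclass
class RunConfig:
    """Options controlling a pipeline run; serialized next to the outputs."""

    seed: int = 0
    out_dir: str = "grainfill_out"
    # logistic fit options
    fit_max_iter: int = 500
    fit_xtol: float = 1e-8
    # trend options
    stem_c: int = DEFAULT_C
    stem_m: int = DEFAULT_M
    stem_eps: float = DEFAULT_EPS
    stem_threshold: float = DEFAULT_THRESHOLD
    stem_mode: str = "exact"
    stem_n_perm: int = 1000
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise SchemaError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def read_content_table(path, design: StudyDesign | None = None):
    """Read a tidy element-content table into GrainContentSeries.

    One series is produced per (element, tissue) pair. A mixed unit within
    an element raises; a DAF outside the design's time points raises when a
    design is given.
    """
    path = Path(path)
    import csv

    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, csv.Error):
        raise SchemaError(f"{path}: empty or undelimited file") from None
    missing = [c for c in CONTENT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    if len(df) == 0:
        raise SchemaError(f"{path}: table has no rows")
    df["unit"] = df["unit"].map(normalize_unit)
    for element, sub in df.groupby("element"):
        if sub["unit"].nunique() > 1:
            raise UnitError(
                f"{path}: element {element!r} has mixed units "
                f"{sorted(sub['unit'].unique())}"
            )
    if design is not None:
        bad = set(df["daf"].astype(int)) - set(design.time_points)
        if bad:
            raise ValidationError(
                f"{path}: DAF values {sorted(bad)} not in design "
                f"{design.time_points}"
            )
    series = []
    for (element, tissue), sub in df.groupby(["element", "tissue"], sort=True):
        series.append(
            GrainContentSeries(
                element=element,
                tissue=tissue,
                unit=sub["unit"].iloc[0],
                daf=sub["daf"].astype(int).to_numpy(),
                replicate=sub["replicate"].astype(int).to_numpy(),
                value=sub["value"].astype(float).to_numpy(),
            )
        )
    return series


def write_content_table(series_list, path):
    """Write GrainContentSeries back to the tidy CSV dialect (round-trips)."""
    df = pd.concat([s.to_frame() for s in series_list], ignore_index=True)
    df.to_csv(path, index=False, float_format="%.12g")


def parse_sample_names(names) -> pd.DataFrame:
    """Parse ``<daf>DAF_r<rep>`` sample names into (daf, replicate) metadata."""
    rows = {}
    for name in names:
        m = _SAMPLE_RE.match(str(name))
        if not m:
            raise SchemaError(
                f"sample name {name!r} does not match '<daf>DAF_r<rep>'"
            )
        rows[name] = {"daf": int(m.group(1)), "replicate": int(m.group(2))}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample"
    return out


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a gene x sample FPKM TSV with ``<daf>DAF_r<rep>`` headers."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file") from None
    if "gene_id" not in df.columns:
        raise SchemaError(f"{path}: missing 'gene_id' column")
    df = df.set_index("gene_id")
    samples = parse_sample_names(df.columns)
    return ExpressionMatrix(df, samples)


def write_expression_matrix(matrix: ExpressionMatrix, path):
    matrix.values.to_csv(path, sep="\t", index_label="gene_id",
                         float_format="%.12g")
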