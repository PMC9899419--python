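"""Pipeline orchestration: fit -> classify -> budget -> trend -> spatial.

Each stage reads the tidy tables produced by :mod:`grainfill.io` (or by the
simulators), writes one CSV/TSV result table to the output directory, and
appends to a machine-readable JSON summary. Outputs are written with fixed
decimal formatting so identical inputs + seed reproduce byte-identical
files.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import budget as budget_mod
from . import trends
from .design import DEFAULT_IONOME_DESIGN, StudyDesign
from .io import RunConfig, read_content_table, read_expression_matrix
from .kinetics import fit_logistic
from .patterns import classify_series, summarize_patterns
from .stats import POSITION_RANKS, anova_tukey, regress_with_ci

log = logging.getLogger("grainfill")

FLOAT_FMT = "%.10g"


def _write(df: pd.DataFrame, path: Path):
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def fit_stage(series_list, config: RunConfig) -> pd.DataFrame:
    """Fit the logistic model to every grain series; one row per element."""
    rows = []
    fits = {}
    for s in series_list:
        if s.tissue != "grain":
            continue
        res = fit_logistic(s, max_iter=config.fit_max_iter,
                           xtol=config.fit_xtol)
        fits[s.element] = (s, res)
        row = {
            "element": s.element, "unit": s.unit, "converged": res.converged,
            "a": res.a, "k": res.k, "x_c": res.x_c,
            "se_a": res.bse[0], "se_k": res.bse[1], "se_x_c": res.bse[2],
            "r_squared": res.rsquared,
        }
        if res.converged:
            t_peak, peak = res.peak_rate()
            row["t_peak"] = t_peak
            row["peak_rate"] = peak
        else:
            row["t_peak"] = np.nan
            row["peak_rate"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows), fits


def classify_stage(fits, window) -> pd.DataFrame:
    if "drymatter" not in fits:
        raise ValueError("classification requires a 'drymatter' series")
    _, dm_fit = fits["drymatter"]
    labels = []
    for element, (series, res) in fits.items():
        if element == "drymatter":
            continue
        labels.append(classify_series(series, res, dm_fit, window))
    table = pd.DataFrame(
        [
            {
                "element": l.element, "pattern": l.pattern, "t_peak": l.t_peak,
                "delta_vs_drymatter": l.delta_vs_drymatter, "basis": l.basis,
            }
            for l in labels
        ]
    ).sort_values("element", ignore_index=True)
    return table, summarize_patterns(labels)


def budget_stage(series_list, window=(5, 30)) -> pd.DataFrame:
    """Assemble per-element tissue budgets from a multi-tissue table."""
    by_element = {}
    for s in series_list:
        by_element.setdefault(s.element, {})[s.tissue] = s
    frames = []
    for element in sorted(by_element):
        tissues = by_element[element]
        if "grain" not in tissues or len(tissues) < 2:
            continue
        b = budget_mod.assemble_budget(tissues, t_start=window[0],
                                       t_end=window[1])
        frames.append(b.to_frame())
    if not frames:
        raise ValueError("no element had grain plus vegetative series")
    return pd.concat(frames, ignore_index=True)


def trend_stage(matrix, config: RunConfig, out_dir: Path | None = None):
    """STEM-style profile mining plus PCA on a loaded expression matrix."""
    kept, ratios = trends.log2_ratio_filter(
        matrix, threshold=config.stem_threshold, eps=config.stem_eps
    )
    T = len(matrix.times)
    candidates = trends.generate_candidate_profiles(T, c=config.stem_c)
    profiles = trends.select_model_profiles(candidates, m=config.stem_m)
    assignment = trends.assign_genes(ratios.loc[kept], profiles)
    significance = trends.profile_significance(
        assignment, ratios.loc[kept], mode=config.stem_mode,
        n_perm=config.stem_n_perm, alpha=config.alpha, seed=config.seed,
    )
    scores, evr = trends.pca_samples(matrix)
    if out_dir is not None:
        assignment.assignments.reset_index(names="gene_id").to_csv(
            out_dir / "trend_assignments.tsv", sep="\t", index=False,
            float_format=FLOAT_FMT,
        )
        significance.to_csv(out_dir / "trend_profiles.tsv", sep="\t",
                            index=False, float_format=FLOAT_FMT)
        scores.reset_index().to_csv(out_dir / "pca_scores.tsv", sep="\t",
                                    index=False, float_format=FLOAT_FMT)
    return {
        "n_genes": len(matrix.genes),
        "n_filtered": int(len(kept)),
        "assignment": assignment,
        "significance": significance,
        "pca_scores": scores,
        "explained_variance": evr,
    }


def spatial_stage(table: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    """Regressions of grain values on panicle position or seed-setting rate.

    Expects tidy columns ``element, position (A-G) or rate, value``;
    positions are encoded as ranks 1-7. Returns one regression row per
    element plus ANOVA/Tukey letters across groups.
    """
    if "position" in table.columns:
        x_raw = table["position"].map(POSITION_RANKS)
        if x_raw.isna().any():
            raise ValueError("positions must be labels A-G")
        group_col = "position"
    elif "rate" in table.columns:
        x_raw = table["rate"].astype(float)
        group_col = "rate"
    else:
        raise ValueError("need a 'position' or 'rate' column")
    rows = []
    for element, sub in table.groupby("element", sort=True):
        x = x_raw.loc[sub.index].to_numpy(dtype=float)
        y = sub["value"].to_numpy(dtype=float)
        reg = regress_with_ci(x, y, level=0.95)
        groups = {
            str(g): s["value"].to_numpy(dtype=float)
            for g, s in sub.groupby(group_col)
        }
        at = anova_tukey(groups, alpha=config.alpha)
        rows.append(
            {
                "element": element, "slope": reg.slope,
                "intercept": reg.intercept, "r": reg.r, "p": reg.pvalue,
                "n": reg.n, "anova_p": at.pvalue,
                "letters": ";".join(f"{g}={l}" for g, l in
                                    sorted(at.letters.items())),
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(
    config: RunConfig,
    content_table=None,
    budget_table=None,
    expression_table=None,
    spatial_table=None,
    design: StudyDesign = DEFAULT_IONOME_DESIGN,
) -> dict:
    """Execute requested stages in order, writing tables and a JSON summary.

    Stages with no input are skipped and logged as such. A failed stage
    aborts downstream stages (the exception propagates after logging).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out_dir / "run_config.yaml")
    summary: dict = {"seed": config.seed, "stages": {}}
    t0 = time.perf_counter()

    def _stage(name, fn):
        start = time.perf_counter()
        try:
            result = fn()
        except Exception:
            log.error("stage %s failed; downstream stages aborted", name)
            raise
        log.info("stage %s finished in %.2fs", name, time.perf_counter() - start)
        return result

    fits = None
    if content_table is not None:
        series = (read_content_table(content_table, design)
                  if not isinstance(content_table, list) else content_table)
        fit_table, fits = _stage("fit", lambda: fit_stage(series, config))
        _write(fit_table, out_dir / "fits.csv")
        summary["stages"]["fit"] = {
            "n_elements": int(len(fit_table)),
            "n_converged": int(fit_table["converged"].sum()),
        }
        label_table, pattern_summary = _stage(
            "classify", lambda: classify_stage(fits, design.window)
        )
        _write(label_table, out_dir / "patterns.csv")
        _write(pattern_summary, out_dir / "pattern_summary.csv")
        summary["stages"]["classify"] = {
            row["pattern"]: int(row["count"])
            for _, row in pattern_summary.iterrows()
        }
    else:
        log.info("stage fit/classify skipped: no content table")
        summary["stages"]["fit"] = "skipped"
        summary["stages"]["classify"] = "skipped"

    if budget_table is not None:
        series = (read_content_table(budget_table, design)
                  if not isinstance(budget_table, list) else budget_table)
        btable = _stage("budget", lambda: budget_stage(series, design.window))
        _write(btable, out_dir / "budget.csv")
        summary["stages"]["budget"] = {
            "n_elements": int(btable["element"].nunique())
        }
    else:
        log.info("stage budget skipped: no budget table")
        summary["stages"]["budget"] = "skipped"

    if expression_table is not None:
        matrix = (read_expression_matrix(expression_table)
                  if not isinstance(expression_table, trends.ExpressionMatrix)
                  else expression_table)
        tr = _stage("trend", lambda: trend_stage(matrix, config, out_dir))
        sig = tr["significance"]
        summary["stages"]["trend"] = {
            "n_genes": tr["n_genes"],
            "n_filtered": tr["n_filtered"],
            "n_profiles": int(len(sig)),
            "n_significant": int(sig["significant"].sum()),
            "pc1_explained_percent": round(
                float(tr["explained_variance"][0]) * 100.0, 6
            ),
        }
    else:
        log.info("stage trend skipped: no expression matrix")
        summary["stages"]["trend"] = "skipped"

    if spatial_table is not None:
        table = (pd.read_csv(spatial_table)
                 if not isinstance(spatial_table, pd.DataFrame)
                 else spatial_table)
        stable = _stage("spatial", lambda: spatial_stage(table, config))
        _write(stable, out_dir / "spatial.csv")
        summary["stages"]["spatial"] = {"n_elements": int(len(stable))}
    else:
        log.info("stage spatial skipped: no spatial table")
        summary["stages"]["spatial"] = "skipped"

    log.info("pipeline finished in %.2fs", time.perf_counter() - t0)
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
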