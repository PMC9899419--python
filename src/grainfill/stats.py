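"""Group statistics for panicle-position and seed-setting-rate analyses.

Grain element concentrations vary with position along the panicle (primary
rachis branches A-G, apical to basal, encoded as equally spaced ranks 1-7)
and with sink capacity (seed setting rates of 50/75/100% imposed by
spikelet pruning). These effects are summarized by Z-score
standardization, ordinary least-squares regression with a Pearson
correlation test and a t-based confidence band for the mean response, and
one-way ANOVA followed by Tukey HSD comparisons with a compact letter
display.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .exceptions import ValidationError

__all__ = ["zscore", "regress_with_ci", "RegressionResult", "anova_tukey",
           "AnovaTukeyResult", "POSITION_RANKS"]

#: Panicle positions A-G mapped to equally spaced ranks.
POSITION_RANKS = {p: i + 1 for i, p in enumerate("ABCDEFG")}


def zscore(values) -> np.ndarray:
    """Standardize with the sample (n-1) SD: output has mean 0, SD 1."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("z-score requires >= 2 values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValidationError("z-score undefined for a constant series")
    return (x - x.mean()) / sd


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r: float
    pvalue: float
    stderr: float
    n: int
    level: float
    _x: np.ndarray = None
    _y: np.ndarray = None

    def conf_band(self, grid) -> tuple[np.ndarray, np.ndarray]:
        """Pointwise t confidence band for the mean response on a grid."""
        grid = np.asarray(grid, dtype=float)
        x, y = self._x, self._y
        n = self.n
        yhat_obs = self.intercept + self.slope * x
        mse = float(np.sum((y - yhat_obs) ** 2)) / (n - 2)
        sxx = float(np.sum((x - x.mean()) ** 2))
        se = np.sqrt(mse * (1.0 / n + (grid - x.mean()) ** 2 / sxx))
        tq = sps.t.ppf(0.5 + self.level / 2.0, n - 2)
        yhat = self.intercept + self.slope * grid
        return yhat - tq * se, yhat + tq * se


def regress_with_ci(x, y, level: float = 0.95) -> RegressionResult:
    """OLS of y on x with Pearson r, its t-test p-value, and a CI band."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-d arrays of equal length")
    if len(x) < 3:
        raise ValidationError("regression requires >= 3 points")
    if np.ptp(x) == 0:
        raise ValidationError("x must not be constant")
    if not 0.0 < level < 1.0:
        raise ValidationError("confidence level must be in (0, 1)")
    fit = sps.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r=float(fit.rvalue), pvalue=float(fit.pvalue),
        stderr=float(fit.stderr), n=len(x), level=level, _x=x, _y=y,
    )


@dataclass
class AnovaTukeyResult:
    means: pd.Series
    f_stat: float
    pvalue: float
    tukey: pd.DataFrame  # group1, group2, meandiff, q, p_adj, reject
    letters: dict

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean": self.means,
                "letters": pd.Series(self.letters),
            }
        )


def _compact_letters(groups: list, nonsig: set) -> dict:
    """Insert-and-absorb compact letter display.

    ``groups`` are ordered by descending mean; ``nonsig`` holds unordered
    pairs that are NOT significantly different. Groups sharing a letter are
    not significantly different.
    """
    columns = [set(groups)]  # start: all groups share one letter
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1:]:
            if frozenset((g1, g2)) in nonsig:
                continue
            new_cols = []
            for col in columns:
                if g1 in col and g2 in col:
                    new_cols.extend([col - {g1}, col - {g2}])
                else:
                    new_cols.append(col)
            # absorb columns contained in another
            columns = [
                c for c in new_cols
                if c and not any(c < o for o in new_cols if o is not c)
            ]
            # deduplicate while keeping order
            seen, dedup = [], []
            for c in columns:
                if c not in seen:
                    seen.append(c)
                    dedup.append(c)
            columns = dedup
    # order columns by the best-ranked member so 'a' goes with the top mean
    rank = {g: i for i, g in enumerate(groups)}
    columns.sort(key=lambda c: min(rank[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for letter, col in zip(alphabet, columns):
        for g in groups:
            if g in col:
                letters[g] += letter
    return letters


def anova_tukey(groups: dict, alpha: float = 0.05) -> AnovaTukeyResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons and letters.

    ``groups`` maps group label to its replicate values. The Tukey q
    statistic per pair is |mean difference| / sqrt(MSE/2 * (1/n1 + 1/n2))
    (the Tukey-Kramer form, which reduces to dmean/sqrt(MSE/n) for equal
    group sizes).
    """
    if len(groups) < 2:
        raise ValidationError("ANOVA requires >= 2 groups")
    for label, vals in groups.items():
        if len(vals) < 2:
            raise ValidationError(f"group {label!r} needs >= 2 values")
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    f_stat, pvalue = sps.f_oneway(*arrays)

    values = np.concatenate(arrays)
    codes = np.concatenate([[g] * len(a) for g, a in zip(labels, arrays)])
    tk = pairwise_tukeyhsd(values, codes, alpha=alpha)
    tukey = pd.DataFrame(
        tk.summary().data[1:],
        columns=[str(c) for c in tk.summary().data[0]],
    )
    # recompute the studentized-range q statistic for reporting
    n_total = len(values)
    k = len(labels)
    group_means = {g: a.mean() for g, a in zip(labels, arrays)}
    sse = sum(float(np.sum((a - a.mean()) ** 2)) for a in arrays)
    mse = sse / (n_total - k)
    qs = []
    for _, row in tukey.iterrows():
        g1, g2 = row["group1"], row["group2"]
        n1, n2 = len(groups[g1]), len(groups[g2])
        se = np.sqrt(mse / 2.0 * (1.0 / n1 + 1.0 / n2))
        qs.append(abs(group_means[g1] - group_means[g2]) / se)
    tukey["q"] = qs

    means = pd.Series(group_means).sort_values(ascending=False)
    nonsig = {
        frozenset((row["group1"], row["group2"]))
        for _, row in tukey.iterrows()
        if not row["reject"]
    }
    letters = _compact_letters(list(means.index), nonsig)
    return AnovaTukeyResult(
        means=means, f_stat=float(f_stat), pvalue=float(pvalue),
        tukey=tukey, letters=letters,
    )
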