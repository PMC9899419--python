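"""Short time-series expression profile mining for the grain transcriptome.

The transcriptome of the developing grain is sampled at five stages
(5-21 DAF, three replicates each). With so few time points, conventional
clustering overfits; instead, genes are matched against a fixed library of
*model profiles* — integer-valued temporal templates that start at 0 and
change by at most ``c`` units between consecutive stages — and profile
membership is tested against a permutation null, following the approach of
the Short Time-series Expression Miner (STEM).

Pipeline:

1. FPKM normalization of counts (if starting from counts).
2. Replicate means per stage, then log2 ratios against the first stage:
   ``e_gt = log2((F_gt + eps) / (F_g,t1 + eps))`` with pseudo-value
   ``eps`` (default 1 FPKM) so silent genes are well defined.
3. Filter: keep genes with ``max_t |e_gt| >= threshold`` (default 1, i.e.
   a two-fold change somewhere in the course).
4. Enumerate all ``(2c+1)^(T-1) - 1`` candidate profiles, select ``m``
   maximally distinct representatives (greedy max-min under correlation
   distance), and assign each filtered gene to the profile its trajectory
   correlates with best.
5. Per-profile significance: expected profile size under all ``T!``
   permutations of the time order, with a binomial tail p-value and
   Bonferroni control over the ``m`` profiles.

PCA of samples and hierarchical clustering of Z-scored expression are
provided as supporting views of the same matrix.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA

from .exceptions import ValidationError

__all__ = [
    "ExpressionMatrix",
    "fpkm_normalize",
    "log2_ratio_filter",
    "generate_candidate_profiles",
    "select_model_profiles",
    "assign_genes",
    "profile_significance",
    "ProfileAssignment",
    "pca_samples",
    "zscore_rows",
    "hierarchical_cluster",
]

DEFAULT_EPS = 1.0  # pseudo-FPKM added before log2 ratios
DEFAULT_THRESHOLD = 1.0  # |log2 ratio| filter
DEFAULT_C = 2  # max unit change between stages
DEFAULT_M = 20  # number of selected model profiles


class ExpressionMatrix:
    """Gene x sample FPKM matrix with (daf, replicate) sample metadata.

    ``values`` is a DataFrame indexed by gene id with one column per
    sample; ``samples`` is a DataFrame (index = sample name) with integer
    ``daf`` and ``replicate`` columns.
    """

    def __init__(self, values: pd.DataFrame, samples: pd.DataFrame):
        if values.index.duplicated().any():
            dup = values.index[values.index.duplicated()][0]
            raise ValidationError(f"duplicate gene_id {dup!r}")
        if (values.to_numpy() < 0).any():
            raise ValidationError("FPKM values must be non-negative")
        if not set(values.columns) == set(samples.index):
            raise ValidationError("sample metadata does not match matrix columns")
        # order columns by (daf, replicate) for a canonical layout
        samples = samples.loc[values.columns].sort_values(["daf", "replicate"])
        self.values = values[samples.index].astype(float)
        self.samples = samples

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def times(self) -> np.ndarray:
        return np.unique(self.samples["daf"].to_numpy())

    def replicate_means(self) -> pd.DataFrame:
        """Mean FPKM per (gene, daf): genes x stages, stages ascending."""
        groups = self.values.T.groupby(self.samples["daf"])
        return groups.mean().T.sort_index(axis=1)

    def log2_ratios(self, eps: float = DEFAULT_EPS) -> pd.DataFrame:
        """log2((F_t + eps)/(F_t1 + eps)) on replicate means; column t1 is 0."""
        if eps <= 0:
            raise ValidationError("eps must be positive")
        means = self.replicate_means()
        logm = np.log2(means + eps)
        return logm.sub(logm.iloc[:, 0], axis=0)


def fpkm_normalize(
    counts: pd.DataFrame,
    lengths: pd.Series,
    library_sizes: pd.Series,
    samples: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """FPKM = count * 1e9 / (gene length in bp * mapped fragments in library).

    ``samples`` supplies (daf, replicate) metadata; if omitted, the count
    column names are parsed as ``<daf>DAF_r<rep>``.
    """
    lengths = lengths.reindex(counts.index)
    library_sizes = library_sizes.reindex(counts.columns)
    if lengths.isna().any() or (lengths <= 0).any():
        raise ValidationError("every gene needs a positive length")
    if library_sizes.isna().any() or (library_sizes <= 0).any():
        raise ValidationError("every sample needs a positive library size")
    fpkm = counts.mul(1e9).div(lengths, axis=0).div(library_sizes, axis=1)
    if samples is None:
        from .io import parse_sample_names  # local import avoids a cycle

        samples = parse_sample_names(counts.columns)
    return ExpressionMatrix(fpkm, samples)


def log2_ratio_filter(
    matrix: ExpressionMatrix,
    threshold: float = DEFAULT_THRESHOLD,
    eps: float = DEFAULT_EPS,
) -> tuple[pd.Index, pd.DataFrame]:
    """Keep genes whose trajectory moves by >= threshold log2 units.

    Returns (kept gene index, full log2-ratio matrix). The filter is
    inclusive at the boundary and monotone in the threshold.
    """
    ratios = matrix.log2_ratios(eps=eps)
    kept = ratios.index[ratios.abs().max(axis=1) >= threshold]
    return kept, ratios


# --------------------------------------------------------------------------
# model profiles
# --------------------------------------------------------------------------

def generate_candidate_profiles(T: int, c: int = DEFAULT_C) -> np.ndarray:
    """All integer profiles of length T starting at 0 with steps in [-c, c].

    The all-zero (flat) profile is excluded, leaving (2c+1)^(T-1) - 1
    candidates, returned lexicographically sorted as an (n, T) int array.
    """
    if T < 2 or c < 1:
        raise ValidationError("need T >= 2 time points and c >= 1")
    steps = range(-c, c + 1)
    profiles = []
    for diffs in itertools.product(steps, repeat=T - 1):
        if all(d == 0 for d in diffs):
            continue
        profiles.append((0, *itertools.accumulate(diffs)))
    profiles.sort()
    return np.array(profiles, dtype=int)


def _standardize_rows(arr: np.ndarray) -> np.ndarray:
    """Center rows and scale to unit norm, so dot products are Pearson r."""
    arr = np.asarray(arr, dtype=float)
    centered = arr - arr.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return centered / norms


def _profile_distance_matrix(profiles: np.ndarray) -> np.ndarray:
    z = _standardize_rows(profiles)
    corr = np.clip(z @ z.T, -1.0, 1.0)
    return 1.0 - corr


def select_model_profiles(candidates: np.ndarray, m: int = DEFAULT_M) -> np.ndarray:
    """Greedy max-min selection of m mutually distinct model profiles.

    Distance is 1 - Pearson correlation of the profile value vectors. The
    two most distant candidates seed the set; each following pick maximizes
    its minimum distance to the current set. All ties break toward the
    lexicographically smaller profile, and the returned array is sorted
    lexicographically so profile ids 0..m-1 are reproducible.
    """
    candidates = np.asarray(candidates, dtype=int)
    n = len(candidates)
    if m > n:
        raise ValidationError(f"cannot select {m} profiles from {n} candidates")
    if m == n:
        return candidates[np.lexsort(candidates.T[::-1])]
    dist = _profile_distance_matrix(candidates)
    # candidates arrive sorted lexicographically (generate_candidate_profiles)
    # so index order is lexicographic order; ties — including floating-point
    # near-ties between exactly anticorrelated pairs — resolve to the
    # smallest index pair.
    tol = 1e-9
    iu = np.triu_indices(n, k=1)
    flat = dist[iu]
    best = int(np.argmax(flat >= flat.max() - tol))
    selected = [int(iu[0][best]), int(iu[1][best])]
    remaining = [i for i in range(n) if i not in selected]
    min_dist = np.minimum(dist[selected[0]], dist[selected[1]])
    while len(selected) < m:
        cand_scores = min_dist[remaining]
        pick = remaining[int(np.argmax(cand_scores >= cand_scores.max() - tol))]
        selected.append(pick)
        remaining.remove(pick)
        min_dist = np.minimum(min_dist, dist[pick])
    chosen = candidates[sorted(selected)]
    return chosen[np.lexsort(chosen.T[::-1])]


@dataclass
class ProfileAssignment:
    """Gene-to-profile memberships plus excluded (flat) genes."""

    assignments: pd.DataFrame  # index gene; columns profile, correlation, distance
    profiles: np.ndarray  # (m, T) selected model profiles
    n_excluded: int = 0

    def profile_sizes(self) -> pd.Series:
        m = len(self.profiles)
        counts = self.assignments["profile"].value_counts()
        return counts.reindex(range(m), fill_value=0).sort_index()


def _correlation_assign(ratio_values: np.ndarray, zp: np.ndarray) -> tuple:
    """Argmax-correlation assignment; returns (idx of usable rows, best, corr)."""
    zg = _standardize_rows(ratio_values)
    usable = ~np.isnan(zg).any(axis=1)
    corr = np.clip(zg[usable] @ zp.T, -1.0, 1.0)
    best = np.argmax(corr, axis=1)  # ties -> lowest profile id
    return usable, best, corr[np.arange(len(best)), best]


def assign_genes(ratios: pd.DataFrame, profiles: np.ndarray) -> ProfileAssignment:
    """Assign each filtered gene to its best-correlated model profile.

    Genes with a constant ratio vector have undefined correlation and are
    excluded (their count is recorded). Ties go to the lowest profile id.
    """
    if len(ratios) == 0:
        raise ValidationError("no genes to assign")
    profiles = np.asarray(profiles, dtype=int)
    if len(profiles) == 0:
        raise ValidationError("no model profiles supplied")
    zp = _standardize_rows(profiles)
    usable, best, best_corr = _correlation_assign(ratios.to_numpy(), zp)
    n_excluded = int((~usable).sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} gene(s) with constant trajectories excluded "
            "from profile assignment",
            stacklevel=2,
        )
    assignments = pd.DataFrame(
        {
            "profile": best.astype(int),
            "correlation": best_corr,
            "distance": 1.0 - best_corr,
        },
        index=ratios.index[usable],
    )
    return ProfileAssignment(
        assignments=assignments, profiles=profiles, n_excluded=n_excluded
    )


def profile_significance(
    assignment: ProfileAssignment,
    ratios: pd.DataFrame,
    mode: str = "exact",
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int | None = None,
) -> pd.DataFrame:
    """Permutation significance of profile sizes.

    The null model permutes the time order of each gene's stage means and
    re-derives ratios against the (new) first stage; because
    ``log2((F_s + eps)/(F_r + eps)) = e_s - e_r``, permuted ratio vectors
    are computed directly from the observed ones. The expected size of each
    profile is the mean assigned count over all T! permutations (``exact``
    mode, the default; 120 permutations for T = 5) or over ``n_perm``
    sampled permutations (``sampled`` mode, seeded). The p-value is the
    binomial tail P(X >= observed | n genes, expected/n); a profile is
    flagged significant when p < alpha / m (Bonferroni over the m
    profiles).
    """
    ratios = ratios.loc[assignment.assignments.index]
    vals = ratios.to_numpy(dtype=float)
    n_genes, T = vals.shape
    m = len(assignment.profiles)
    zp = _standardize_rows(assignment.profiles)

    if mode == "exact":
        if T > 7:
            raise ValidationError(
                "exact mode enumerates T! time orders and is limited to "
                "T <= 7; use mode='sampled'"
            )
        perms = list(itertools.permutations(range(T)))
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(T) for _ in range(int(n_perm))]
    else:
        raise ValidationError(f"unknown mode {mode!r}")

    counts = np.zeros((len(perms), m))
    for pi, perm in enumerate(perms):
        permuted = vals[:, list(perm)]
        permuted = permuted - permuted[:, [0]]
        usable, best, _ = _correlation_assign(permuted, zp)
        counts[pi] = np.bincount(best, minlength=m)
    expected = counts.mean(axis=0)

    observed = assignment.profile_sizes().to_numpy()
    p_null = np.clip(expected / n_genes, 1e-300, 1.0)
    pvals = stats.binom.sf(observed - 1, n_genes, p_null)
    out = pd.DataFrame(
        {
            "profile": np.arange(m),
            "shape": [
                " ".join(str(v) for v in prof) for prof in assignment.profiles
            ],
            "size": observed,
            "expected": expected,
            "pvalue": pvals,
            "significant": pvals < alpha / m,
        }
    )
    return out


# --------------------------------------------------------------------------
# supporting views
# --------------------------------------------------------------------------

def pca_samples(matrix: ExpressionMatrix) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples on log2(FPKM + 1), gene-centered.

    Returns (scores DataFrame indexed by sample, explained-variance
    fractions). Developmental stage should dominate PC1 when stages differ
    more than replicates do.
    """
    X = np.log2(matrix.values.to_numpy().T + 1.0)  # samples x genes
    if X.shape[0] < 2:
        raise ValidationError("PCA requires at least two samples")
    n_comp = min(X.shape[0], X.shape[1])
    pca = PCA(n_components=n_comp, svd_solver="full")
    scores = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return (
        pd.DataFrame(scores, index=matrix.values.columns, columns=cols),
        pca.explained_variance_ratio_,
    )


def zscore_rows(values: pd.DataFrame) -> pd.DataFrame:
    """Row-wise Z-score (population SD); zero-variance rows dropped with a warning."""
    arr = values.to_numpy(dtype=float)
    sd = arr.std(axis=1)
    flat = sd == 0
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance row(s) excluded from Z-scoring",
            stacklevel=2,
        )
    arr = arr[~flat]
    z = (arr - arr.mean(axis=1, keepdims=True)) / sd[~flat][:, None]
    return pd.DataFrame(z, index=values.index[~flat], columns=values.columns)


def hierarchical_cluster(
    values: pd.DataFrame, metric: str = "euclidean"
) -> tuple[np.ndarray, list]:
    """Agglomerative clustering of rows with average linkage.

    ``metric`` is Euclidean by default (correlation distance available as
    an option). Returns the SciPy linkage matrix and the dendrogram leaf
    order as row labels; SciPy's linkage on a fixed input is deterministic.
    """
    if len(values) < 2:
        raise ValidationError("clustering requires >= 2 rows")
    if metric not in ("euclidean", "correlation"):
        raise ValidationError("metric must be 'euclidean' or 'correlation'")
    Z = hierarchy.linkage(values.to_numpy(dtype=float), method="average",
                          metric=metric)
    leaves = hierarchy.leaves_list(Z)
    return Z, [values.index[i] for i in leaves]


def linkage_to_newick(Z: np.ndarray, labels: list) -> str:
    """Render a linkage matrix as a Newick string (heights as branch lengths)."""
    n = len(labels)
    heights = {i: 0.0 for i in range(n)}
    nodes = {i: str(labels[i]) for i in range(n)}
    for i, (a, b, h, _) in enumerate(Z):
        a, b = int(a), int(b)
        la = max(h - heights[a], 0.0)
        lb = max(h - heights[b], 0.0)
        idx = n + i
        nodes[idx] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
        heights[idx] = h
    return nodes[n + len(Z) - 1] + ";"
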