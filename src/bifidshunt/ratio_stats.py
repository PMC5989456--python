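"""Endproduct ratios and comparative statistics.

Ratios are computed per replicate (never as ratios of group means), then
compared across carbohydrate sources and strains with one-way or two-way
ANOVA and Tukey's HSD.  Multivariate structure is summarized with PCA on
centered (optionally unit-scaled) data and Ward/Euclidean hierarchical
clustering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import statsmodels.api as sm
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .stoichiometry import RatioSet, _safe_ratio

__all__ = [
    "compute_ratios",
    "anova_tukey",
    "AnovaResult",
    "pca",
    "OrdinationResult",
    "hierarchical_cluster",
    "ClusteringResult",
    "zscore_scale",
]

RATIO_DEFS = {
    "aa_la": ("acetate", "lactate"),
    "fa_la": ("formate", "lactate"),
    "fa_aa": ("formate", "acetate"),
    "et_la": ("ethanol", "lactate"),
}


def compute_ratios(concentrations) -> RatioSet:
    """Endproduct molar ratios for one replicate's mM concentrations.

    ``concentrations`` maps analyte name to mM.  A ratio whose denominator
    is zero (or whose analytes are missing) is flagged undefined and must
    be excluded, not zero-filled, downstream.
    """
    values, flags = {}, {}
    for name, (num, den) in RATIO_DEFS.items():
        if num in concentrations and den in concentrations:
            values[name], flags[name] = _safe_ratio(
                concentrations[num], concentrations[den]
            )
        else:
            values[name], flags[name] = float("nan"), False
    return RatioSet(
        **values, **{f"{k}_defined": v for k, v in flags.items()}
    )


@dataclass
class AnovaResult:
    anova_table: pd.DataFrame
    tukey: pd.DataFrame
    design: str
    alpha: float


def _tukey_frame(values, labels, alpha: float) -> pd.DataFrame:
    res = pairwise_tukeyhsd(np.asarray(values, dtype=float), labels, alpha=alpha)
    frame = pd.DataFrame(
        res.summary().data[1:], columns=res.summary().data[0]
    )
    frame["p-adj"] = res.pvalues
    return frame


def anova_tukey(
    data: pd.DataFrame,
    value: str = "value",
    factor_a: str = "factor_a",
    factor_b: str | None = None,
    alpha: float = 0.05,
) -> AnovaResult:
    """One-way or two-way ANOVA with Tukey HSD multiple comparisons.

    One-way: F = MS_between / MS_within across levels of ``factor_a``,
    followed by all-pairs Tukey HSD (Tukey-Kramer for unbalanced groups).
    Two-way: type-II sums of squares for both main effects and the
    interaction, with Tukey simple-effects comparisons of ``factor_a``
    within each level of ``factor_b`` and vice versa, plus main-effect
    comparisons pooled over the other factor.

    Zero residual variance is reported as a boundary case (F = inf, p = 0)
    rather than an error.
    """
    df = data.dropna(subset=[value]).copy()
    if df[factor_a].nunique() < 2:
        raise ValueError("ANOVA requires >= 2 groups")
    if factor_b is None:
        groups = [g[value].to_numpy() for _, g in df.groupby(factor_a, sort=True)]
        if min(len(g) for g in groups) < 1:
            raise ValueError("each group needs at least one value")
        k = len(groups)
        n = sum(len(g) for g in groups)
        grand = np.concatenate(groups).mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        dfb, dfw = k - 1, n - k
        if dfw < 1:
            raise ValueError("residual degrees of freedom must be >= 1")
        msb, msw = ssb / dfb, ssw / dfw
        if msw == 0:
            f_stat = np.inf if msb > 0 else 0.0
            p = 0.0 if msb > 0 else 1.0
        else:
            f_stat = msb / msw
            p = float(stats.f.sf(f_stat, dfb, dfw))
        table = pd.DataFrame(
            {
                "sum_sq": [ssb, ssw],
                "df": [dfb, dfw],
                "F": [f_stat, np.nan],
                "PR(>F)": [p, np.nan],
            },
            index=[factor_a, "Residual"],
        )
        tukey = _tukey_frame(df[value], df[factor_a], alpha)
        tukey.insert(0, "comparison", "all")
        return AnovaResult(table, tukey, design="one_way", alpha=alpha)

    model = ols(
        f"Q('{value}') ~ C(Q('{factor_a}')) * C(Q('{factor_b}'))", data=df
    ).fit()
    table = sm.stats.anova_lm(model, typ=2)
    pieces = []
    for fac, other in ((factor_a, factor_b), (factor_b, factor_a)):
        main = _tukey_frame(df[value], df[fac], alpha)
        main.insert(0, "comparison", f"main:{fac}")
        pieces.append(main)
        for level, sub in df.groupby(other, sort=True):
            if sub[fac].nunique() < 2:
                continue
            simple = _tukey_frame(sub[value], sub[fac], alpha)
            simple.insert(0, "comparison", f"{fac}|{other}={level}")
            pieces.append(simple)
    tukey = pd.concat(pieces, ignore_index=True)
    return AnovaResult(table, tukey, design="two_way", alpha=alpha)


@dataclass
class OrdinationResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray


def pca(matrix: pd.DataFrame, scale: bool = False) -> OrdinationResult:
    """Principal component analysis by SVD of the centered data matrix.

    Columns are mean-centered and, when ``scale`` is set, divided by their
    sample SD.  Loading signs are canonicalized so the largest-magnitude
    element of each component is positive.  Missing growth values should be
    encoded as 0 upstream (config-switchable to row exclusion there).
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA requires >= 2 samples and >= 2 variables")
    if np.isnan(X).any():
        raise ValueError("matrix contains NaN")
    Xc = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            names = [str(matrix.columns[i]) for i in zero]
            raise ValueError(f"constant column(s) cannot be unit-scaled: {names}")
        Xc = Xc / sd
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|.| loading element positive per component
    signs = np.sign(vt[np.arange(vt.shape[0]), np.argmax(np.abs(vt), axis=1)])
    signs[signs == 0] = 1.0
    vt = vt * signs[:, None]
    u = u * signs[None, :]
    scores = u * s
    var = s**2 / (X.shape[0] - 1)
    var_explained = var / (Xc.var(axis=0, ddof=1).sum())
    ncomp = s.size
    comp_names = [f"PC{i+1}" for i in range(ncomp)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(vt.T, index=matrix.columns, columns=comp_names),
        variance_explained=var_explained,
    )


@dataclass
class ClusteringResult:
    linkage: np.ndarray
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def merges(self) -> list[frozenset]:
        """Leaf-label sets of the merged clusters, in merge order."""
        n = len(self.labels)
        clusters = {i: frozenset([i]) for i in range(n)}
        out = []
        for step, (a, b, *_rest) in enumerate(self.linkage):
            merged = clusters[int(a)] | clusters[int(b)]
            clusters[n + step] = merged
            out.append(merged)
        return out

    def to_newick(self) -> str:
        """Serialize the dendrogram as a Newick string with branch lengths
        derived from merge heights."""
        tree = sch.to_tree(self.linkage)

        def walk(node, parent_height: float) -> str:
            length = parent_height - (0.0 if node.is_leaf() else node.dist)
            if node.is_leaf():
                length = parent_height
                return f"{self.labels[node.id]}:{length:.12g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{parent_height - node.dist:.12g}"

        body = walk(tree, tree.dist)
        return f"{body[:body.rfind(':')]};"


def hierarchical_cluster(
    matrix: pd.DataFrame, method: str = "ward", metric: str = "euclidean"
) -> ClusteringResult:
    """Agglomerative clustering of samples (rows); Ward/Euclidean default.

    Ward linkage merges the pair whose union minimally increases total
    within-cluster variance; with Euclidean distances the merge heights are
    monotone nondecreasing.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("clustering requires >= 2 samples")
    if np.isnan(X).any():
        raise ValueError("matrix contains NaN")
    Z = sch.linkage(X, method=method, metric=metric)
    return ClusteringResult(linkage=Z, labels=[str(i) for i in matrix.index])


def zscore_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-variable mean-centering and division by the sample SD (the
    scaling applied to metabolite heatmaps)."""
    return (matrix - matrix.mean()) / matrix.std(ddof=1)
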