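"""Alpha/beta diversity and FDR-corrected distance comparisons.

Chao1 richness (bias-corrected by default), Bray-Curtis dissimilarity,
principal coordinate analysis, Spearman correlation matrices with
Benjamini-Hochberg adjustment, and rank-sum comparisons of distance
groups (replicate vs intra-subject vs inter-subject).

Standard statistics are delegated to scikit-bio, scipy and statsmodels;
this module owns the grouping and multiple-testing bookkeeping around
them.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import braycurtis as _braycurtis
from skbio import DistanceMatrix
from skbio.diversity.alpha import chao1 as _skbio_chao1
from statsmodels.stats.multitest import multipletests

__all__ = [
    "chao1",
    "bray_curtis",
    "bray_curtis_matrix",
    "pcoa",
    "spearman",
    "distance_group_labels",
    "compare_distance_groups",
    "alpha_correlation_matrix",
]


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness estimate from one sample's feature counts.

    Bias-corrected form: S_obs + f1*(f1-1) / (2*(f2+1)), with f1/f2 the
    singleton/doubleton counts; finite even when no doubletons exist.
    """
    arr = np.asarray(counts)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    return float(_skbio_chao1(arr.astype(int), bias_corrected=bias_corrected))


def bray_curtis(u, v) -> float:
    """Bray-Curtis dissimilarity: 1 - 2*sum(min(u,v)) / (sum u + sum v)."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError("vectors must share a feature index")
    if (u < 0).any() or (v < 0).any():
        raise ValueError("abundances must be non-negative")
    return float(_braycurtis(u, v))


def bray_curtis_matrix(matrix: pd.DataFrame) -> DistanceMatrix:
    """All-pairs Bray-Curtis distances for a features x samples matrix."""
    data = matrix.T.to_numpy(dtype=float)
    n = data.shape[0]
    dm = np.zeros((n, n))
    for i, j in combinations(range(n), 2):
        dm[i, j] = dm[j, i] = _braycurtis(data[i], data[j])
    return DistanceMatrix(dm, ids=list(matrix.columns))


def pcoa(dm: DistanceMatrix | pd.DataFrame, k: int | None = None):
    """Classical scaling (principal coordinate analysis) of a distance matrix.

    Eigendecomposition of the double-centered -D^2/2 matrix. Negative
    eigenvalues (non-Euclidean input, common for Bray-Curtis) are
    reported, not corrected or zeroed; coordinates are returned for
    positive-eigenvalue axes only, ordered by decreasing eigenvalue, up
    to ``k`` axes. On a Euclidean-embeddable matrix the full embedding
    reproduces the input distances.

    Returns (coordinates DataFrame, eigenvalues Series).
    """
    if isinstance(dm, DistanceMatrix):
        ids = list(dm.ids)
        d = dm.data
    else:
        ids = list(dm.index)
        d = dm.to_numpy(dtype=float)
    if not np.allclose(d, d.T):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (d**2) @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    axes = [f"PC{i + 1}" for i in range(n)]
    eig = pd.Series(eigvals, index=axes, name="eigenvalue")
    tol = 1e-12 * max(1.0, abs(eigvals[0]))
    pos = eigvals > tol
    coords = pd.DataFrame(
        eigvecs[:, pos] * np.sqrt(eigvals[pos]),
        index=pd.Index(ids, name="sample_id"),
        columns=[a for a, p in zip(axes, pos) if p],
    )
    if k is not None:
        coords = coords.iloc[:, :k]
    return coords, eig


def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 observations")
    return float(stats.spearmanr(x, y).statistic)


def distance_group_labels(meta: pd.DataFrame) -> "callable":
    """Default grouping rule for distance comparisons.

    Same subject and site -> "replicate"; same subject, different site ->
    "intra_subject"; different subjects -> "inter_subject".
    """
    m = meta.set_index("sample_id") if "sample_id" in meta.columns else meta

    def rule(a: str, b: str) -> str:
        if m.loc[a, "subject"] != m.loc[b, "subject"]:
            return "inter_subject"
        if "site" in m.columns and m.loc[a, "site"] == m.loc[b, "site"]:
            return "replicate"
        return "intra_subject"

    return rule


def compare_distance_groups(
    dm: DistanceMatrix | pd.DataFrame,
    meta: pd.DataFrame,
    grouping=None,
    test: str = "ranksum",
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Pairwise tests between groups of pairwise distances, BH-adjusted.

    Each off-diagonal distance is assigned a group label by the grouping
    rule (default: replicate / intra_subject / inter_subject from the
    sample metadata); groups are compared pairwise with a two-sided
    Mann-Whitney rank-sum test (``test="ttest"`` and ``"permutation"``
    are available) and p-values are Benjamini-Hochberg adjusted across
    the comparisons.
    """
    if isinstance(dm, DistanceMatrix):
        dmat = pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
    else:
        dmat = dm
    rule = grouping if grouping is not None else distance_group_labels(meta)

    groups: dict[str, list[float]] = {}
    ids = list(dmat.index)
    for a, b in combinations(ids, 2):
        groups.setdefault(rule(a, b), []).append(float(dmat.loc[a, b]))
    if len(groups) < 2:
        raise ValueError("need at least two distance groups to compare")

    rows = []
    for ga, gb in combinations(sorted(groups), 2):
        xa, xb = np.array(groups[ga]), np.array(groups[gb])
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"group {ga if len(xa) < 2 else gb} has fewer than 2 distances")
        if test == "ranksum":
            stat, p = stats.mannwhitneyu(xa, xb, alternative=alternative)
        elif test == "ttest":
            stat, p = stats.ttest_ind(xa, xb, equal_var=False, alternative=alternative)
        elif test == "permutation":
            res = stats.permutation_test(
                (xa, xb),
                lambda u, v, axis=-1: np.mean(u, axis=axis) - np.mean(v, axis=axis),
                permutation_type="independent",
                alternative=alternative,
                n_resamples=9999,
                random_state=0,
            )
            stat, p = res.statistic, res.pvalue
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(
            {
                "group_a": ga,
                "group_b": gb,
                "n_a": len(xa),
                "n_b": len(xb),
                "median_a": float(np.median(xa)),
                "median_b": float(np.median(xb)),
                "statistic": float(stat),
                "p_value": float(p),
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def alpha_correlation_matrix(alpha: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlations between community-type alpha diversities.

    ``alpha`` holds one column per community type (e.g. virome VC,
    metagenome mVC, bacteriome) and one row per sample; at least three
    shared samples are required per pair. Returns (rho matrix, BH-adjusted
    p matrix over the upper triangle, mirrored).
    """
    cols = list(alpha.columns)
    if alpha.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    praw = pd.DataFrame(np.nan, index=cols, columns=cols)
    pairs = list(combinations(cols, 2))
    pvals = []
    for a, b in pairs:
        sub = alpha[[a, b]].dropna()
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 shared samples for ({a}, {b})")
        r, p = stats.spearmanr(sub[a], sub[b])
        rho.loc[a, b] = rho.loc[b, a] = r
        pvals.append(p)
    if pvals:
        padj = multipletests(pvals, method="fdr_bh")[1]
        for (a, b), p in zip(pairs, padj):
            praw.loc[a, b] = praw.loc[b, a] = p
    return rho, praw
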