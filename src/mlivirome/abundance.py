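"""Coverage, masking, normalization and aggregation of contig abundances.

Turns alignment summaries (the four-column idxstats layout) and per-base
depth tables into filtered abundance matrices:

- horizontal coverage (breadth) per contig per sample,
- the 75% breadth mask (sub-threshold counts set to zero, per sample),
- RPKM and relative-abundance normalization,
- a 0.01% minimum relative-abundance prevalence filter,
- rarefaction (subsampling without replacement) to a common depth,
- aggregation of contig counts into viral clusters,
- sharedness classification of viral contigs across samples/subjects,
- contamination fold-decrease audits (e.g. host reads, metagenome vs
  virome).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "breadth_from_coverage",
    "breadth_from_depth",
    "compute_breadth",
    "apply_breadth_mask",
    "rpkm_normalize",
    "relative_abundance",
    "prevalence_filter",
    "rarefy",
    "aggregate_by_cluster",
    "classify_sharedness",
    "contamination_fold",
    "coverage_to_counts",
]

COVERAGE_COLUMNS = ["contig_id", "sample_id", "length_bp", "mapped_reads", "covered_positions"]


def _validate_coverage(cov: pd.DataFrame) -> None:
    missing = [c for c in COVERAGE_COLUMNS if c not in cov.columns]
    if missing:
        raise ValueError(f"coverage table missing column(s): {missing}")
    if (cov["covered_positions"] > cov["length_bp"]).any():
        raise ValueError("covered_positions exceeds length_bp")
    if (cov[["length_bp", "mapped_reads", "covered_positions"]] < 0).any().any():
        raise ValueError("coverage table contains negative values")


def breadth_from_coverage(cov: pd.DataFrame) -> pd.DataFrame:
    """Breadth matrix (contigs x samples) from a long coverage table.

    breadth = covered_positions / length_bp; contig/sample combinations
    absent from the table get breadth 0.
    """
    _validate_coverage(cov)
    b = cov.assign(breadth=cov["covered_positions"] / cov["length_bp"])
    return b.pivot_table(
        index="contig_id", columns="sample_id", values="breadth", fill_value=0.0, aggfunc="max"
    )


# alias matching the operation name used in the docs
compute_breadth = breadth_from_coverage


def breadth_from_depth(depth: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Breadth matrix from a per-base depth table.

    ``depth`` has columns (contig_id, sample_id, position, depth) with
    1-based positions; a position is covered iff its depth >= 1.
    Duplicate positions are counted once.
    """
    for c in ("contig_id", "sample_id", "position", "depth"):
        if c not in depth.columns:
            raise ValueError(f"depth table missing column {c!r}")
    covered = (
        depth[depth["depth"] >= 1]
        .drop_duplicates(["contig_id", "sample_id", "position"])
        .groupby(["contig_id", "sample_id"])
        .size()
        .unstack(fill_value=0)
    )
    covered = covered.reindex(lengths.index, fill_value=0)
    return covered.div(lengths, axis=0).fillna(0.0)


def coverage_to_counts(cov: pd.DataFrame) -> pd.DataFrame:
    """Mapped-read count matrix (contigs x samples) from a coverage table."""
    _validate_coverage(cov)
    return cov.pivot_table(
        index="contig_id", columns="sample_id", values="mapped_reads", fill_value=0, aggfunc="sum"
    ).astype(np.int64)


def apply_breadth_mask(
    counts: pd.DataFrame, breadth: pd.DataFrame, threshold: float = 0.75
) -> pd.DataFrame:
    """Zero counts where a contig's per-sample breadth is below threshold.

    Masking is per sample: a contig may survive in one sample and be
    zeroed in another. Breadth exactly at the threshold is kept.
    """
    b = breadth.reindex(index=counts.index, columns=counts.columns)
    if b.isna().any().any():
        raise ValueError("breadth matrix does not cover every count entry")
    return counts.where(b >= threshold, 0)


def rpkm_normalize(
    counts: pd.DataFrame, lengths: pd.Series, library_sizes: pd.Series
) -> pd.DataFrame:
    """Reads per kilobase of contig per million mapped reads.

    rpkm = count * 1e9 / (length_bp * library_size).
    """
    L = lengths.reindex(counts.index)
    lib = library_sizes.reindex(counts.columns)
    if (L <= 0).any() or L.isna().any():
        raise ValueError("lengths must be > 0 for every feature")
    if (lib <= 0).any() or lib.isna().any():
        raise ValueError("library sizes must be > 0 for every sample")
    return counts.astype(float).mul(1e9).div(L, axis=0).div(lib, axis=1)


def relative_abundance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Column-normalize to relative abundances (empty samples stay 0)."""
    tot = matrix.sum(axis=0)
    safe = tot.replace(0, np.nan)
    return matrix.div(safe, axis=1).fillna(0.0)


def prevalence_filter(matrix: pd.DataFrame, min_rel: float = 1e-4) -> pd.DataFrame:
    """Drop features never reaching ``min_rel`` relative abundance anywhere.

    Relative abundance is computed per sample on the matrix as supplied
    (RPKM for viral features, counts for the bacteriome). A feature is
    kept if its relative abundance is >= min_rel in at least one sample
    ("minimum 0.01%" read as inclusive).
    """
    if matrix.empty:
        return matrix.copy()
    if (matrix < 0).any().any():
        raise ValueError("abundance matrix must be non-negative")
    rel = relative_abundance(matrix)
    keep = (rel >= min_rel).any(axis=1)
    return matrix.loc[keep]


def rarefy(
    counts: pd.DataFrame,
    depth: int | str = "min",
    seed: int = 0,
    replicates: int = 1,
) -> pd.DataFrame:
    """Subsample each sample's reads without replacement to a common depth.

    ``depth="min"`` uses the smallest column total (the sample with the
    lowest number of mapped reads). Every rarefied column sums exactly to
    the target depth. With ``replicates > 1`` the mean over independent
    draws is returned (a sensitivity analysis; no longer integer counts).
    """
    arr = counts.to_numpy()
    if not np.issubdtype(arr.dtype, np.integer):
        if not np.allclose(arr, np.rint(arr)):
            raise ValueError("rarefaction requires integer counts")
        arr = np.rint(arr).astype(np.int64)
    totals = arr.sum(axis=0)
    target = int(totals.min()) if depth == "min" else int(depth)
    if (totals < target).any():
        shallow = counts.columns[totals < target].tolist()
        raise ValueError(f"sample(s) shallower than target depth {target}: {shallow}")
    rng = np.random.default_rng(seed)
    acc = np.zeros(arr.shape, dtype=float)
    for _ in range(replicates):
        out = np.empty(arr.shape, dtype=np.int64)
        for j in range(arr.shape[1]):
            out[:, j] = rng.multivariate_hypergeometric(arr[:, j], target)
        acc += out
    acc /= replicates
    result = pd.DataFrame(acc, index=counts.index, columns=counts.columns)
    return result.astype(np.int64) if replicates == 1 else result


def aggregate_by_cluster(matrix: pd.DataFrame, membership: pd.Series) -> pd.DataFrame:
    """Sum feature rows into clusters; unclustered features stay singletons.

    ``membership`` maps feature id -> cluster id (missing/NaN entries
    become singleton clusters named after the feature). Column totals are
    conserved exactly.
    """
    clusters = membership.reindex(matrix.index)
    clusters = clusters.where(clusters.notna(), pd.Series(matrix.index, index=matrix.index))
    out = matrix.groupby(clusters).sum()
    out.index.name = "cluster_id"
    return out


def classify_sharedness(presence: pd.DataFrame, meta: pd.DataFrame) -> pd.Series:
    """Label each present VC as sample_specific / subject_specific / shared.

    ``presence`` is a boolean contigs x samples matrix (presence meaning
    >= 75% horizontal coverage in that sample); ``meta`` maps sample_id
    (index or column) to subject. A VC present in >= 2 subjects is
    "shared"; in >= 2 samples of exactly one subject, "subject_specific";
    in exactly one sample, "sample_specific". VCs present nowhere get NA.
    """
    m = meta.set_index("sample_id") if "sample_id" in meta.columns else meta
    subj = m["subject"].reindex(presence.columns)
    if subj.isna().any():
        missing = presence.columns[subj.isna()].tolist()
        raise KeyError(f"sample(s) missing from metadata: {missing}")
    p = presence.astype(bool)
    n_samples = p.sum(axis=1)
    n_subjects = p.T.groupby(subj).any().sum(axis=0)
    labels = pd.Series(pd.NA, index=presence.index, dtype="object", name="sharedness")
    labels[n_samples == 1] = "sample_specific"
    labels[(n_samples >= 2) & (n_subjects == 1)] = "subject_specific"
    labels[n_subjects >= 2] = "shared"
    return labels


def contamination_fold(
    prop_source: pd.Series | np.ndarray | float,
    prop_virome: pd.Series | np.ndarray | float,
) -> tuple[np.ndarray, float]:
    """Per-sample fold-decrease of a contaminant and the cohort mean.

    fold = proportion in the source assay / proportion in the virome; a
    zero virome proportion yields +inf for that sample. The summary is
    the arithmetic mean of per-sample folds (mean of folds, not fold of
    means), over the finite entries.
    """
    src = np.atleast_1d(np.asarray(prop_source, dtype=float))
    vir = np.atleast_1d(np.asarray(prop_virome, dtype=float))
    if src.shape != vir.shape:
        raise ValueError("proportion vectors must have the same shape")
    if (src < 0).any() or (vir < 0).any():
        raise ValueError("proportions must be non-negative")
    with np.errstate(divide="ignore"):
        folds = np.where(vir > 0, src / np.where(vir > 0, vir, 1.0), np.inf)
    finite = folds[np.isfinite(folds)]
    mean_fold = float(finite.mean()) if finite.size else float("inf")
    return folds, mean_fold
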