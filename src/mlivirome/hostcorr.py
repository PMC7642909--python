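"""Phage-host abundance correlation against an unpaired null.

Each viral contig (VC) is paired with its single best predicted bacterial
host (assignment accepted at p <= 0.05). Pairs are restricted to hosts
actually observed in the bacteriome, VC abundances come from the virome
assay and host abundances from the metagenome assay of the same samples,
and a Spearman correlation is computed per pair across the shared
samples. The paired correlations are then tested (one-sided rank-sum,
"paired > unpaired") against a null built from every VC x non-predicted
observed host combination. Rank-based throughout, so the comparison is
invariant to monotone transforms of the abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "assign_hosts",
    "restrict_to_observed",
    "pair_correlations",
    "null_correlations",
    "compare_paired_vs_null",
    "PairCorrelationSet",
]


@dataclass
class PairCorrelationSet:
    """Per-pair Spearman correlations plus exclusion bookkeeping."""

    table: pd.DataFrame  # columns: contig_id, host_taxon, rho, n_samples, is_true_pair
    n_degenerate: int = 0  # pairs dropped because a vector was constant
    flags: list[str] = field(default_factory=list)

    @property
    def rhos(self) -> np.ndarray:
        return self.table["rho"].to_numpy()


def assign_hosts(predictions: pd.DataFrame, alpha: float = 0.05) -> pd.Series:
    """Accept each contig's best host prediction at p <= alpha.

    ``predictions`` has one best-hit row per contig with columns
    contig_id, host_taxon, p_value. Contigs whose best prediction has
    p > alpha are left unassigned (absent from the returned map).
    """
    req = {"contig_id", "host_taxon", "p_value"}
    if not req <= set(predictions.columns):
        raise ValueError(f"predictions need columns {sorted(req)}")
    if predictions["contig_id"].duplicated().any():
        raise ValueError("expected one best-hit row per contig")
    ok = predictions[predictions["p_value"] <= alpha]
    return ok.set_index("contig_id")["host_taxon"]


def restrict_to_observed(
    host_map: pd.Series, bacteriome_taxa
) -> tuple[pd.Series, int]:
    """Keep VC-host pairs whose host appears in the bacteriome.

    Returns (restricted map, number of unique retained hosts).
    """
    observed = set(bacteriome_taxa)
    kept = host_map[host_map.isin(observed)]
    return kept, kept.nunique()


def _rank_rows(df: pd.DataFrame) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 1, df.to_numpy(dtype=float))


def _pairwise_spearman(vc: pd.DataFrame, host: pd.DataFrame) -> np.ndarray:
    """Spearman rho between every VC row and every host row (shared columns)."""
    rv = _rank_rows(vc)
    rh = _rank_rows(host)
    rv = rv - rv.mean(axis=1, keepdims=True)
    rh = rh - rh.mean(axis=1, keepdims=True)
    sv = np.sqrt((rv**2).sum(axis=1))
    sh = np.sqrt((rh**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = (rv @ rh.T) / np.outer(sv, sh)
    return corr  # NaN rows/cols mark constant (degenerate) vectors


def _shared_samples(vc_abund, host_abund, meta=None, sample_filter=None) -> list[str]:
    shared = [s for s in vc_abund.columns if s in host_abund.columns]
    if sample_filter is not None:
        if callable(sample_filter):
            m = meta.set_index("sample_id") if meta is not None and "sample_id" in meta.columns else meta
            shared = [s for s in shared if sample_filter(s, m)]
        else:
            shared = [s for s in shared if s in set(sample_filter)]
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples between the VC and host matrices")
    return shared


def pair_correlations(
    vc_abund: pd.DataFrame,
    host_abund: pd.DataFrame,
    pairs: pd.Series,
    meta: pd.DataFrame | None = None,
    sample_filter=None,
) -> PairCorrelationSet:
    """Spearman rho for each predicted VC-host pair across shared samples.

    ``pairs`` maps contig_id -> host_taxon; ``sample_filter`` optionally
    restricts the sample set (an iterable of sample ids to keep, or a
    callable ``(sample_id, meta) -> bool`` — e.g. excluding one subject).
    Degenerate pairs (constant VC or host vector) are excluded and
    counted.
    """
    shared = _shared_samples(vc_abund, host_abund, meta, sample_filter)
    pairs = pairs[pairs.index.isin(vc_abund.index) & pairs.isin(host_abund.index)]
    if pairs.empty:
        raise ValueError("no usable VC-host pairs")
    vc = vc_abund.loc[pairs.index, shared]
    host = host_abund.loc[pairs.to_numpy(), shared]
    corr = _pairwise_spearman(vc, host)
    rho = np.diag(corr)
    ok = ~np.isnan(rho)
    table = pd.DataFrame(
        {
            "contig_id": pairs.index[ok],
            "host_taxon": pairs.to_numpy()[ok],
            "rho": rho[ok],
            "n_samples": len(shared),
            "is_true_pair": True,
        }
    )
    return PairCorrelationSet(table=table, n_degenerate=int((~ok).sum()))


def null_correlations(
    vc_abund: pd.DataFrame,
    host_abund: pd.DataFrame,
    pairs: pd.Series,
    meta: pd.DataFrame | None = None,
    sample_filter=None,
    max_null: int | None = None,
    seed: int = 0,
) -> PairCorrelationSet:
    """Spearman rho for every VC against each observed host EXCEPT its own.

    The null has (#paired VCs) x (#hosts - 1) entries when no vector is
    degenerate; ``max_null`` subsamples it for very large designs.
    """
    shared = _shared_samples(vc_abund, host_abund, meta, sample_filter)
    pairs = pairs[pairs.index.isin(vc_abund.index) & pairs.isin(host_abund.index)]
    hosts = pd.Index(pd.unique(pairs.to_numpy()))
    hosts = hosts[hosts.isin(host_abund.index)]
    if len(hosts) < 2:
        raise ValueError("need at least 2 observed hosts to build an unpaired null")
    vc = vc_abund.loc[pairs.index, shared]
    hmat = host_abund.loc[hosts, shared]
    corr = _pairwise_spearman(vc, hmat)

    host_pos = {h: j for j, h in enumerate(hosts)}
    rows = []
    n_deg = 0
    for i, (cid, own) in enumerate(pairs.items()):
        for j, h in enumerate(hosts):
            if j == host_pos[own]:
                continue
            r = corr[i, j]
            if np.isnan(r):
                n_deg += 1
                continue
            rows.append((cid, h, r))
    table = pd.DataFrame(rows, columns=["contig_id", "host_taxon", "rho"])
    table["n_samples"] = len(shared)
    table["is_true_pair"] = False
    if max_null is not None and len(table) > max_null:
        table = table.sample(n=max_null, random_state=seed).reset_index(drop=True)
    return PairCorrelationSet(table=table, n_degenerate=n_deg)


def compare_paired_vs_null(
    paired: PairCorrelationSet,
    null: PairCorrelationSet,
    alternative: str = "greater",
) -> dict:
    """Rank-sum test of paired vs unpaired correlation distributions.

    One-sided by default (paired correlations higher than the unpaired
    null). Returns the U statistic, p-value, set sizes and the median
    difference as the effect summary.
    """
    x, y = paired.rhos, null.rhos
    if x.size == 0 or y.size == 0:
        raise ValueError("both correlation sets must be nonempty")
    stat, p = stats.mannwhitneyu(x, y, alternative=alternative)
    return {
        "statistic": float(stat),
        "p_value": float(p),
        "n_paired": int(x.size),
        "n_null": int(y.size),
        "median_paired": float(np.median(x)),
        "median_null": float(np.median(y)),
        "median_difference": float(np.median(x) - np.median(y)),
        "alternative": alternative,
    }
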