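"""Rule-based identification of viral contigs from multi-source evidence.

A contig is *retained* as a putative viral contig (VC) when at least one
inclusion rule fires and no removal rule applies:

inclusion (OR-combined)
    DETECTOR       positive detector call (category 1 or 2) or circularity
    VIRAL_DB       best hit to a reference viral genome set or the
                   crAssphage contig set at e-value < 1e-10
    PVOG_DENSITY   >= 3 ORFs with a pVOG hit AND >= 2 such hits per kb
    LONG_UNKNOWN   length >= 3 kb with no nt-database hit (e-value < 1e-10)

removal (always wins over inclusion)
    RIBOSOMAL      >= 3 ORFs aligning to ribosomal proteins
    LOW_BREADTH    horizontal coverage < 75% in every sample

Boundary semantics follow the printed thresholds exactly: strict "<" for
e-values, inclusive ">=" for counts, lengths, hits/kb density and the 75%
breadth. Absent evidence fields mean "no hit" (e-value +inf, counts 0,
flags false). Decisions are a pure function of one evidence record and
its breadth row; contigs are assumed pre-dereplicated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TriageThresholds",
    "rule_detector",
    "rule_viral_db",
    "rule_pvog_density",
    "rule_long_unknown",
    "rule_ribosomal_exclusion",
    "triage_contigs",
    "EVIDENCE_COLUMNS",
]

INCLUSION_RULES = ("DETECTOR", "VIRAL_DB", "PVOG_DENSITY", "LONG_UNKNOWN")
REMOVAL_REASONS = ("RIBOSOMAL", "LOW_BREADTH")

EVIDENCE_COLUMNS = [
    "length_bp",
    "detector_category",
    "is_circular",
    "viral_db_min_evalue",
    "crass_min_evalue",
    "n_orfs",
    "n_pvog_orfs",
    "has_nt_hit",
    "n_ribosomal_orfs",
]


@dataclass(frozen=True)
class TriageThresholds:
    """Selection thresholds; defaults are the published values."""

    viral_db_max_evalue: float = 1e-10
    min_pvog_orfs: int = 3
    min_pvog_per_kb: float = 2.0
    long_unknown_min_bp: int = 3_000
    min_ribosomal_orfs_exclude: int = 3
    min_breadth: float = 0.75
    min_contig_bp: int = 1_001


_DEFAULT = TriageThresholds()


def _get(ev, key, default):
    v = ev.get(key, default) if hasattr(ev, "get") else getattr(ev, key, default)
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return default
    return v


def rule_detector(ev) -> bool:
    """Positive detector call: category 1 or 2, or a circular contig."""
    cat = _get(ev, "detector_category", np.inf)
    return bool(cat in (1, 2) or _get(ev, "is_circular", False))


def rule_viral_db(ev, thresholds: TriageThresholds = _DEFAULT) -> bool:
    """Viral-database hit: best reference-viral or crAssphage e-value < 1e-10."""
    best = min(
        _get(ev, "viral_db_min_evalue", np.inf), _get(ev, "crass_min_evalue", np.inf)
    )
    return bool(best < thresholds.viral_db_max_evalue)


def rule_pvog_density(ev, thresholds: TriageThresholds = _DEFAULT) -> bool:
    """pVOG density: >= 3 pVOG-matching ORFs at >= 2 hits per kb of contig.

    Density uses the exact length in bp (hits * 1000 / length_bp), not a
    rounded kb figure.
    """
    n = _get(ev, "n_pvog_orfs", 0)
    length = _get(ev, "length_bp", 0)
    if length <= 0:
        raise ValueError("length_bp must be > 0")
    return bool(
        n >= thresholds.min_pvog_orfs and n * 1000.0 / length >= thresholds.min_pvog_per_kb
    )


def rule_long_unknown(ev, thresholds: TriageThresholds = _DEFAULT) -> bool:
    """Long unknown: >= 3 kb with no nt-database alignment at e-value < 1e-10."""
    return bool(
        _get(ev, "length_bp", 0) >= thresholds.long_unknown_min_bp
        and not _get(ev, "has_nt_hit", False)
    )


def rule_ribosomal_exclusion(ev, thresholds: TriageThresholds = _DEFAULT) -> bool:
    """Exclude contigs with >= 3 ORFs aligning to ribosomal proteins."""
    return bool(_get(ev, "n_ribosomal_orfs", 0) >= thresholds.min_ribosomal_orfs_exclude)


def triage_contigs(
    evidence: pd.DataFrame,
    breadth: pd.DataFrame | pd.Series,
    thresholds: TriageThresholds = _DEFAULT,
) -> pd.DataFrame:
    """Apply all selection and removal rules to an evidence table.

    Parameters
    ----------
    evidence
        One row per contig (index = contig_id) with the ContigEvidence
        columns; missing columns/values default to "no evidence".
        Contigs shorter than ``min_contig_bp`` are dropped with a warning
        (they would not have entered clustering upstream).
    breadth
        Per-contig per-sample horizontal-coverage fractions in [0, 1]
        (DataFrame contigs x samples, or a Series of per-contig maxima).
        Every evidence contig must have at least one breadth entry.

    Returns
    -------
    DataFrame indexed by contig_id with columns ``retained`` (bool),
    ``inclusion_rules_fired`` and ``removal_reasons`` (semicolon-joined),
    and ``max_breadth``.
    """
    ev = evidence.copy()
    short = ev.index[ev["length_bp"] < thresholds.min_contig_bp]
    if len(short):
        warnings.warn(
            f"dropping {len(short)} contig(s) shorter than {thresholds.min_contig_bp} bp "
            "at ingest (below the clustering length cutoff)",
            stacklevel=2,
        )
        ev = ev.drop(index=short)

    if isinstance(breadth, pd.DataFrame):
        max_breadth = breadth.max(axis=1)
    else:
        max_breadth = breadth
    max_breadth = max_breadth.reindex(ev.index)
    if max_breadth.isna().any():
        missing = max_breadth.index[max_breadth.isna()].tolist()
        raise KeyError(f"contig(s) missing from the breadth table: {missing[:5]}")

    rows = []
    for cid, rec in ev.iterrows():
        fired = []
        if rule_detector(rec):
            fired.append("DETECTOR")
        if rule_viral_db(rec, thresholds):
            fired.append("VIRAL_DB")
        if rule_pvog_density(rec, thresholds):
            fired.append("PVOG_DENSITY")
        if rule_long_unknown(rec, thresholds):
            fired.append("LONG_UNKNOWN")
        reasons = []
        if rule_ribosomal_exclusion(rec, thresholds):
            reasons.append("RIBOSOMAL")
        if not (max_breadth.loc[cid] >= thresholds.min_breadth):
            reasons.append("LOW_BREADTH")
        rows.append(
            (
                cid,
                bool(fired) and not reasons,
                ";".join(fired),
                ";".join(reasons),
                float(max_breadth.loc[cid]),
            )
        )
    out = pd.DataFrame(
        rows,
        columns=["contig_id", "retained", "inclusion_rules_fired", "removal_reasons", "max_breadth"],
    ).set_index("contig_id")
    return out
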