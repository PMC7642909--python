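"""Independent brute-force re-statement of the viral-contig selection rules.

Deliberately coded from scratch (plain dict/float logic, no pandas, no
imports from the package) so it can serve as an oracle for the triage
engine on randomized inputs.
"""

import math


def oracle_decision(rec: dict, max_breadth: float) -> dict:
    """Evaluate every selection/removal rule by direct transcription."""

    def num(key):
        v = rec.get(key)
        if v is None:
            return None
        if isinstance(v, float) and math.isnan(v):
            return None
        return v

    fired = []

    cat = num("detector_category")
    if (cat is not None and int(cat) in (1, 2)) or bool(rec.get("is_circular")):
        fired.append("DETECTOR")

    evs = [e for e in (num("viral_db_min_evalue"), num("crass_min_evalue")) if e is not None]
    if any(e < 1e-10 for e in evs):
        fired.append("VIRAL_DB")

    n_pvog = num("n_pvog_orfs") or 0
    length = rec["length_bp"]
    if n_pvog >= 3 and (n_pvog / (length / 1000.0)) >= 2.0:
        fired.append("PVOG_DENSITY")

    if length >= 3000 and not bool(rec.get("has_nt_hit")):
        fired.append("LONG_UNKNOWN")

    reasons = []
    if (num("n_ribosomal_orfs") or 0) >= 3:
        reasons.append("RIBOSOMAL")
    if max_breadth < 0.75:
        reasons.append("LOW_BREADTH")

    return {
        "retained": len(fired) > 0 and len(reasons) == 0,
        "inclusion_rules_fired": fired,
        "removal_reasons": reasons,
    }


def random_evidence_records(rng, n: int):
    """Randomized evidence records + breadth maxima, boundary-value heavy."""
    records = []
    breadths = []
    for i in range(n):
        length = int(rng.choice([1001, 1400, 1600, 2999, 3000, 5000]) if rng.random() < 0.4
                     else rng.integers(1001, 50_000))
        n_orfs = max(1, int(length // rng.integers(300, 800)))
        rec = {
            "contig_id": f"c{i:05d}",
            "length_bp": length,
            "detector_category": float(rng.choice([math.nan, 1, 2, 3])),
            "is_circular": bool(rng.random() < 0.2),
            "viral_db_min_evalue": float(rng.choice(
                [math.nan, 1e-12, 1e-10, 1e-8, 10 ** rng.uniform(-30, 0)])),
            "crass_min_evalue": float(rng.choice(
                [math.nan, 1e-12, 1e-10, 10 ** rng.uniform(-30, 0)])),
            "n_orfs": n_orfs,
            "n_pvog_orfs": int(rng.integers(0, n_orfs + 1)),
            "has_nt_hit": bool(rng.random() < 0.5),
            "n_ribosomal_orfs": int(rng.choice([0, 1, 2, 3, 4])),
        }
        records.append(rec)
        breadths.append(float(rng.choice([0.0, 0.5, 0.7499, 0.75, 0.9, 1.0])))
    return records, breadths
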