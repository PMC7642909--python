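"""End-to-end orchestration: simulate -> triage -> abundance -> spike ->
diversity -> host correlation -> report.

A single seeded configuration drives every stage; outputs are TSV files
plus a machine-readable JSON manifest recording the configuration, seed,
per-file SHA-256 digests and headline counts, so a rerun with the same
configuration and seed reproduces identical digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import abundance as ab
from . import diversity as dv
from . import hostcorr as hc
from . import spike as sp
from . import synthetic as syn
from . import triage as tr

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "validate_inputs", "ValidationReport"]


@dataclass(frozen=True)
class PipelineConfig:
    """Full synthetic-run configuration (flat sections per stage)."""

    community: syn.CommunityConfig = syn.CommunityConfig()
    # spike stage: titration of one sample at the standard titers
    spike_titers: tuple[float, ...] = (1e5, 1e6, 1e7)
    spike_genome_bp: float = 135_041.0  # a ~135 kb Campylobacter phage genome
    true_viral_load: float = 6e8  # particles/ml, the order observed at the colonic MLI
    spike_reads_total: int = 1_000_000
    # host-correlation stage
    pair_rho: float = 0.8
    host_noise_sdlog: float = 0.5
    # triage thresholds
    thresholds: tr.TriageThresholds = tr.TriageThresholds()

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML config; keys mirror the dataclass fields per section.

    Sections: ``community`` (CommunityConfig fields, with
    ``evidence_error_rates`` as a nested mapping), ``spike``, ``hostcorr``,
    ``triage``.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    comm_kw = dict(raw.get("community", {}))
    if "evidence_error_rates" in comm_kw:
        comm_kw["evidence_error_rates"] = syn.EvidenceErrorRates(**comm_kw["evidence_error_rates"])
    for dist_key in ("viral_length_dist", "abundance_dist"):
        if dist_key in comm_kw:
            comm_kw[dist_key] = syn.LogNormalParams(**comm_kw[dist_key])
    if "sites" in comm_kw:
        comm_kw["sites"] = tuple(comm_kw["sites"])
    cfg = PipelineConfig(community=syn.CommunityConfig(**comm_kw))
    spike_kw = dict(raw.get("spike", {}))
    if "titers" in spike_kw:
        # YAML 1.1 only parses exponents written with a sign ("2.0e+8");
        # coerce so plain scientific notation works too
        spike_kw["spike_titers"] = tuple(float(t) for t in spike_kw.pop("titers"))
    for key in ("spike_genome_bp", "true_viral_load"):
        if key in spike_kw:
            spike_kw[key] = float(spike_kw[key])
    if "spike_reads_total" in spike_kw:
        spike_kw["spike_reads_total"] = int(float(spike_kw["spike_reads_total"]))
    hk = raw.get("hostcorr", {})
    tk = raw.get("triage", {})
    return cfg.replace(
        **spike_kw,
        **{k: hk[k] for k in ("pair_rho", "host_noise_sdlog") if k in hk},
        **({"thresholds": tr.TriageThresholds(**tk)} if tk else {}),
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_pipeline(config: PipelineConfig | str | Path, outdir: str | Path, verbose: bool = False) -> dict:
    """Run every stage on a synthetic community and write outputs + manifest.

    Returns the manifest dict (also written to ``manifest.json``).
    """
    if not isinstance(config, PipelineConfig):
        config = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config.community
    seeds = np.random.SeedSequence(cfg.seed).generate_state(8) % (2**31)
    log: list[str] = []
    counts_summary: dict = {}

    # --- simulate ------------------------------------------------------
    contigs, abund, truth = syn.generate_community(cfg)
    counts = syn.simulate_read_counts(abund, contigs["length_bp"], cfg.reads_per_sample, int(seeds[0]))
    coverage = syn.simulate_coverage(counts, contigs["length_bp"], cfg.read_length_bp, int(seeds[1]))
    evidence = syn.simulate_evidence(contigs, cfg.evidence_error_rates, int(seeds[2]))
    _write(contigs, outdir / "contigs.tsv")
    _write(abund, outdir / "abundance_true.tsv")
    _write(counts, outdir / "counts.tsv")
    _write(coverage, outdir / "coverage.tsv", index=False)
    _write(evidence, outdir / "evidence.tsv")
    meta = pd.DataFrame(
        {
            "sample_id": counts.columns,
            "subject": [s.split("-")[0] for s in counts.columns],
            "site": [s.split("-")[1] for s in counts.columns],
            "assay": "virome",
            "replicate": "r1",
        }
    )
    _write(meta, outdir / "meta.tsv", index=False)
    log.append(f"simulate: {len(contigs)} contigs, {counts.shape[1]} samples, {cfg.reads_per_sample} reads/sample")
    counts_summary.update(contigs_in=len(contigs), samples=int(counts.shape[1]), reads_per_sample=cfg.reads_per_sample)

    # --- triage --------------------------------------------------------
    breadth = ab.breadth_from_coverage(coverage)
    decisions = tr.triage_contigs(evidence, breadth, config.thresholds)
    _write(decisions, outdir / "decisions.tsv")
    retained = decisions.index[decisions["retained"]]
    labels = truth.labels.reindex(decisions.index)
    tp = int((labels.loc[retained] == "viral").sum())
    fp = len(retained) - tp
    fn = int((labels == "viral").sum()) - tp
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    log.append(f"triage: {len(retained)}/{len(decisions)} retained (precision {precision:.3f}, recall {recall:.3f})")
    if verbose:
        for rule in tr.INCLUSION_RULES:
            only = decisions["inclusion_rules_fired"].eq(rule) & decisions["retained"]
            log.append(f"  rule {rule}: uniquely rescued {int(only.sum())} contigs")
    counts_summary.update(contigs_retained=len(retained), triage_precision=precision, triage_recall=recall)

    # --- abundance -----------------------------------------------------
    vc_counts = counts.loc[retained]
    masked = ab.apply_breadth_mask(vc_counts, breadth.loc[retained], config.thresholds.min_breadth)
    lib = counts.sum(axis=0)
    rpkm = ab.rpkm_normalize(masked, contigs["length_bp"], lib)
    rpkm = ab.prevalence_filter(rpkm)
    rarefied = ab.rarefy(counts, "min", seed=int(seeds[3]))
    presence = breadth.loc[retained] >= config.thresholds.min_breadth
    shared = ab.classify_sharedness(presence, meta)
    _write(rpkm, outdir / "vc_rpkm.tsv")
    _write(rarefied, outdir / "counts_rarefied.tsv")
    shared.to_frame().to_csv(outdir / "sharedness.tsv", sep="\t")
    log.append(f"abundance: {rpkm.shape[0]} VCs after masking+prevalence filter; rarefied to {int(rarefied.sum(axis=0).min())} reads")

    # --- spike ---------------------------------------------------------
    reads_spike = [
        syn.simulate_spike(t, config.spike_genome_bp, config.true_viral_load,
                           cfg.mean_phage_genome_bp, config.spike_reads_total, int(seeds[4]) + i)[0]
        for i, t in enumerate(config.spike_titers)
    ]
    design = sp.SpikeDesign(
        phage_id="spike_phage",
        spike_genome_bp=config.spike_genome_bp,
        titers=config.spike_titers,
        reads_total=tuple([config.spike_reads_total] * len(config.spike_titers)),
        reads_spike=tuple(reads_spike),
        mean_genome_bp=cfg.mean_phage_genome_bp,
    )
    est = sp.fit_titration(design)
    pd.DataFrame(
        {
            "titer": list(est.per_titer),
            "load_estimate": list(est.per_titer.values()),
            "combined_mean": est.mean,
            "combined_sd": est.sd,
            "r_squared": est.r_squared,
        }
    ).to_csv(outdir / "viral_load.tsv", sep="\t", index=False)
    log.append(f"spike: load {est.mean:.3g} +/- {est.sd:.3g} /ml (true {config.true_viral_load:.3g}), R^2 {est.r_squared:.4f}")
    counts_summary.update(viral_load_mean=est.mean, viral_load_sd=est.sd, viral_load_true=config.true_viral_load)

    # --- diversity -----------------------------------------------------
    alpha = rarefied.apply(dv.chao1, axis=0).rename("chao1")
    dm = dv.bray_curtis_matrix(rpkm)
    coords, eig = dv.pcoa(dm, k=2)
    comparison = dv.compare_distance_groups(dm, meta)
    alpha.to_frame().to_csv(outdir / "chao1.tsv", sep="\t")
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(outdir / "braycurtis.tsv", sep="\t")
    _write(coords, outdir / "pcoa.tsv")
    comparison.to_csv(outdir / "distance_groups.tsv", sep="\t", index=False)
    log.append(
        "diversity: " + "; ".join(
            f"{r.group_a} vs {r.group_b}: p_adj={r.p_adjusted:.2e}" for r in comparison.itertuples()
        )
    )

    # --- host correlation ---------------------------------------------
    rng = np.random.default_rng(int(seeds[5]))
    host_map = pd.Series(truth.true_host)
    host_map = host_map[host_map.index.isin(rpkm.index)]
    manifest_extra: dict = {}
    if host_map.nunique() >= 2 and len(host_map) >= 2:
        # planted bacteriome: each host taxon tracks the summed abundance of
        # its member VCs, blurred by log-normal noise
        taxa = sorted(host_map.unique())
        host_abund = pd.DataFrame(
            {
                s: [
                    abund.loc[host_map.index[host_map == t], s].sum()
                    * np.exp(rng.normal(0, config.host_noise_sdlog))
                    for t in taxa
                ]
                for s in abund.columns
            },
            index=taxa,
        )
        preds = pd.DataFrame(
            {
                "contig_id": host_map.index,
                "host_taxon": host_map.to_numpy(),
                "p_value": rng.uniform(0, 0.05, len(host_map)),
            }
        )
        assigned = hc.assign_hosts(preds)
        restricted, n_hosts = hc.restrict_to_observed(assigned, host_abund.index)
        paired = hc.pair_correlations(rpkm, host_abund, restricted)
        null = hc.null_correlations(rpkm, host_abund, restricted, max_null=50_000, seed=int(seeds[6]))
        test = hc.compare_paired_vs_null(paired, null)
        paired.table.to_csv(outdir / "host_pairs.tsv", sep="\t", index=False)
        null.table.to_csv(outdir / "host_null.tsv", sep="\t", index=False)
        log.append(
            f"hostcorr: {test['n_paired']} pairs / {n_hosts} hosts; paired median rho "
            f"{test['median_paired']:.3f} vs null {test['median_null']:.3f}, p={test['p_value']:.3g}"
        )
        manifest_extra["hostcorr"] = test
    else:
        log.append("hostcorr: skipped (fewer than 2 observed hosts)")

    # --- manifest + report --------------------------------------------
    outputs = sorted(p.name for p in outdir.glob("*.tsv"))
    manifest = {
        "seed": cfg.seed,
        "config": _config_dict(config),
        "counts": counts_summary,
        "digests": {name: _sha256(outdir / name) for name in outputs},
        **manifest_extra,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    (outdir / "report.txt").write_text("\n".join(log) + "\n")
    return manifest


def _config_dict(config: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        return obj

    return enc(config)


# ---------------------------------------------------------------------------
# input validation


@dataclass
class ValidationReport:
    errors: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors

    def __str__(self) -> str:
        lines = [f"ERROR: {e}" for e in self.errors] + [f"WARNING: {w}" for w in self.warnings]
        return "\n".join(lines) if lines else "all inputs valid"


_SCHEMAS: dict[str, dict] = {
    "evidence": {
        "required": ["contig_id", "length_bp"],
        "optional": tr.EVIDENCE_COLUMNS,
        "checks": [
            ("length_bp", lambda s: (s >= 1).all(), "length_bp must be >= 1"),
            ("n_pvog_orfs", lambda s: (s >= 0).all(), "n_pvog_orfs must be >= 0"),
            ("n_ribosomal_orfs", lambda s: (s >= 0).all(), "n_ribosomal_orfs must be >= 0"),
            ("viral_db_min_evalue", lambda s: (s.dropna() > 0).all(), "e-values must be > 0"),
            ("crass_min_evalue", lambda s: (s.dropna() > 0).all(), "e-values must be > 0"),
        ],
    },
    "coverage": {
        "required": ab.COVERAGE_COLUMNS,
        "optional": [],
        "checks": [
            ("mapped_reads", lambda s: (s >= 0).all(), "mapped_reads must be >= 0"),
            ("covered_positions", lambda s: (s >= 0).all(), "covered_positions must be >= 0"),
        ],
    },
    "breadth": {
        "required": [],
        "optional": [],
        "checks": [(None, lambda df: ((df >= 0) & (df <= 1)).all().all(), "breadth must be in [0, 1]")],
    },
    "matrix": {
        "required": [],
        "optional": [],
        "checks": [(None, lambda df: (df >= 0).all().all(), "abundances must be non-negative")],
    },
    "meta": {
        "required": ["sample_id", "subject"],
        "optional": ["site", "assay", "replicate"],
        "checks": [
            ("sample_id", lambda s: not s.duplicated().any(), "sample_id must be unique"),
            ("site", lambda s: s.dropna().isin(["TI", "PC", "DC"]).all(), "site must be TI/PC/DC"),
        ],
    },
    "predictions": {
        "required": ["contig_id", "host_taxon", "p_value"],
        "optional": [],
        "checks": [
            ("p_value", lambda s: ((s >= 0) & (s <= 1)).all(), "p_value must be in [0, 1]"),
        ],
    },
    "design": {
        "required": ["titer", "reads_total", "reads_spike"],
        "optional": [],
        "checks": [
            ("titer", lambda s: (s > 0).all(), "titers must be > 0"),
            ("reads_spike", lambda s: (s >= 0).all(), "reads_spike must be >= 0"),
        ],
    },
}


def validate_inputs(files: dict[str, str | Path]) -> ValidationReport:
    """Schema-check input TSVs: columns, types and range invariants.

    ``files`` maps a schema kind (evidence, coverage, breadth, matrix,
    meta, predictions, design) to a TSV path. Missing required columns or
    out-of-range values are hard errors; unknown extra columns are
    warnings.
    """
    report = ValidationReport()
    for kind, path in files.items():
        if kind not in _SCHEMAS:
            report.warnings.append(f"{path}: unknown input kind {kind!r}, skipped")
            continue
        path = Path(path)
        if not path.exists():
            report.errors.append(f"{path}: file not found")
            continue
        schema = _SCHEMAS[kind]
        index_col = 0 if kind in ("breadth", "matrix") else None
        try:
            df = pd.read_csv(path, sep="\t", index_col=index_col)
        except Exception as exc:  # malformed TSV is a hard error
            report.errors.append(f"{path}: unreadable ({exc})")
            continue
        missing = [c for c in schema["required"] if c not in df.columns]
        if missing:
            report.errors.append(f"{path}: missing required column(s) {missing}")
            continue
        known = set(schema["required"]) | set(schema["optional"])
        if known:
            extra = [c for c in df.columns if c not in known]
            if extra:
                report.warnings.append(f"{path}: unknown column(s) {extra} ignored")
        for col, check, msg in schema["checks"]:
            try:
                target = df if col is None else (df[col] if col in df.columns else None)
                if target is None:
                    continue
                if not bool(check(target)):
                    report.errors.append(f"{path}: {msg}")
            except Exception as exc:
                report.errors.append(f"{path}: check on {col!r} failed ({exc})")
    return report
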