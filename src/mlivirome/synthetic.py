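"""Synthetic gut-virome communities with known ground truth.

Emulates the structure of a multi-subject, multi-site mucosal-luminal
interface (MLI) virome study: a pool of viral and bacterial contigs with
subject-specific, site-varying abundance profiles; multinomial read
sampling; uniform read placement for breadth-of-coverage; multi-source
per-contig evidence with controllable error rates; an exogenous spike-in
phage at known pfu/ml; and phage-host abundance pairs with a planted
Spearman correlation.

Every generator is deterministic under a fixed seed. A single community
seed fans out to per-stage child seeds via :class:`numpy.random.SeedSequence`
spawning, so each stage is independently reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LogNormalParams",
    "EvidenceErrorRates",
    "CommunityConfig",
    "GroundTruth",
    "generate_community",
    "simulate_read_counts",
    "simulate_depth_profile",
    "simulate_coverage",
    "simulate_evidence",
    "simulate_spike",
    "expected_spike_fraction",
    "simulate_host_pairs",
]

# scale (natural-log units) applied to the unit effect scalars; an effect of
# 1.0 corresponds to a log-normal perturbation with sigma = 1 (roughly
# e-fold changes between subjects/sites)
_EFFECT_LOG_SCALE = 1.0


@dataclass(frozen=True)
class LogNormalParams:
    """Log-normal distribution parameters on the natural-log scale."""

    meanlog: float
    sdlog: float

    def __post_init__(self) -> None:
        if self.sdlog < 0:
            raise ValueError("sdlog must be >= 0")


@dataclass(frozen=True)
class EvidenceErrorRates:
    """Per-rule error probabilities for the evidence simulator.

    fn_inclusion
        Probability that a truly viral contig carries no inclusion signal
        (detector, viral-database hit, or pVOG density).
    fp_inclusion
        Probability that a bacterial contig carries a spurious inclusion
        signal.
    fn_exclusion
        Probability that a bacterial contig fires neither the
        ribosomal-protein exclusion nor an nt-database hit.
    fp_ribosomal
        Probability that a viral contig is wrongly given >= 3 ribosomal
        protein ORFs (and so is excluded downstream).
    """

    fn_inclusion: float = 0.0
    fp_inclusion: float = 0.0
    fn_exclusion: float = 0.0
    fp_ribosomal: float = 0.0

    def __post_init__(self) -> None:
        for name in ("fn_inclusion", "fp_inclusion", "fn_exclusion", "fp_ribosomal"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class CommunityConfig:
    """Parameters of a synthetic multi-subject MLI virome community.

    Defaults mirror the study design this generator emulates: five
    subjects sampled at proximal (PC) and distal (DC) colon, read lengths
    around 200 bp, a mean phage genome of 40 kb, and strong inter-subject
    with weaker intra-subject (site) variation.
    """

    n_subjects: int = 5
    sites: tuple[str, ...] = ("PC", "DC")
    n_viral_contigs: int = 500
    n_bacterial_contigs: int = 200
    viral_length_dist: LogNormalParams = LogNormalParams(meanlog=8.3, sdlog=0.8)
    mean_phage_genome_bp: int = 40_000
    abundance_dist: LogNormalParams = LogNormalParams(meanlog=0.0, sdlog=0.5)
    subject_effect: float = 0.8
    site_effect: float = 0.3
    reads_per_sample: int = 100_000
    read_length_bp: int = 200
    evidence_error_rates: EvidenceErrorRates = EvidenceErrorRates()
    host_assignment_rate: float = 0.82
    n_host_taxa: int = 20
    seed: int = 0

    min_contig_bp: int = 1_001
    max_contig_bp: int = 150_000

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.n_viral_contigs < 1:
            raise ValueError("n_subjects and n_viral_contigs must be >= 1")
        if self.n_bacterial_contigs < 0:
            raise ValueError("n_bacterial_contigs must be >= 0")
        if not self.sites:
            raise ValueError("at least one site is required")
        if not set(self.sites) <= {"TI", "PC", "DC"}:
            raise ValueError("sites must be a subset of {TI, PC, DC}")
        for name in ("subject_effect", "site_effect"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.reads_per_sample < 0:
            raise ValueError("reads_per_sample must be >= 0")
        if self.read_length_bp < 1:
            raise ValueError("read_length_bp must be >= 1")

    def replace(self, **kwargs) -> "CommunityConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class GroundTruth:
    """Planted truth for a synthetic community."""

    labels: pd.Series  # contig_id -> "viral" | "bacterial"
    true_host: dict = field(default_factory=dict)  # contig_id -> host taxon
    true_viral_load: dict = field(default_factory=dict)  # sample_id -> particles/ml
    true_pair_rho: float | None = None

    def viral_ids(self) -> pd.Index:
        return self.labels.index[self.labels == "viral"]

    def bacterial_ids(self) -> pd.Index:
        return self.labels.index[self.labels == "bacterial"]


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s)) for s in np.random.SeedSequence(seed).spawn(n)]


def generate_community(
    config: CommunityConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate a contig table, a per-sample abundance matrix and ground truth.

    The abundance model is a per-contig log-normal baseline, a per-subject
    multiplicative log-normal perturbation scaled by ``subject_effect`` and
    an independent per-sample (site) perturbation scaled by ``site_effect``.
    With ``subject_effect > site_effect`` samples from one subject are more
    similar to each other than to other subjects' samples by construction.

    Returns
    -------
    contigs : DataFrame with columns contig_id, label, length_bp, true_host
    abundance : DataFrame (contigs x samples) of relative abundance weights
    truth : GroundTruth
    """
    cfg = config
    rng_len, rng_base, rng_subj, rng_site, rng_host = _child_rngs(cfg.seed, 5)

    n_total = cfg.n_viral_contigs + cfg.n_bacterial_contigs
    contig_ids = [f"VC_{i:05d}" for i in range(cfg.n_viral_contigs)] + [
        f"BC_{i:05d}" for i in range(cfg.n_bacterial_contigs)
    ]
    labels = pd.Series(
        ["viral"] * cfg.n_viral_contigs + ["bacterial"] * cfg.n_bacterial_contigs,
        index=pd.Index(contig_ids, name="contig_id"),
        name="label",
    )

    lengths = np.exp(
        rng_len.normal(cfg.viral_length_dist.meanlog, cfg.viral_length_dist.sdlog, n_total)
    )
    lengths = np.clip(np.rint(lengths), cfg.min_contig_bp, cfg.max_contig_bp).astype(np.int64)

    samples = [
        f"{chr(ord('A') + s)}-{site}" for s in range(cfg.n_subjects) for site in cfg.sites
    ]
    subject_of = np.repeat(np.arange(cfg.n_subjects), len(cfg.sites))

    base = np.exp(
        rng_base.normal(cfg.abundance_dist.meanlog, cfg.abundance_dist.sdlog, n_total)
    )
    subj_pert = np.exp(
        cfg.subject_effect
        * _EFFECT_LOG_SCALE
        * rng_subj.standard_normal((n_total, cfg.n_subjects))
    )
    site_pert = np.exp(
        cfg.site_effect * _EFFECT_LOG_SCALE * rng_site.standard_normal((n_total, len(samples)))
    )
    abund = base[:, None] * subj_pert[:, subject_of] * site_pert

    abundance = pd.DataFrame(abund, index=labels.index, columns=samples)

    # planted phage-host assignments over a fixed pool of bacterial taxa
    taxa = [f"taxon_{k:03d}" for k in range(cfg.n_host_taxa)]
    true_host: dict[str, str] = {}
    for cid in labels.index[: cfg.n_viral_contigs]:
        if rng_host.random() < cfg.host_assignment_rate:
            true_host[cid] = taxa[rng_host.integers(cfg.n_host_taxa)]

    contigs = pd.DataFrame(
        {
            "label": labels,
            "length_bp": lengths,
            "true_host": pd.Series(true_host).reindex(labels.index),
        }
    )
    contigs.index.name = "contig_id"

    truth = GroundTruth(labels=labels, true_host=true_host)
    return contigs, abundance, truth


def simulate_read_counts(
    abundance: pd.DataFrame,
    contig_lengths: pd.Series,
    reads_per_sample: int,
    seed: int,
) -> pd.DataFrame:
    """Multinomial read sampling: P(read hits contig) ~ abundance x length.

    Column sums equal ``reads_per_sample`` exactly.
    """
    if reads_per_sample < 0:
        raise ValueError("reads_per_sample must be >= 0")
    lengths = contig_lengths.reindex(abundance.index)
    if lengths.isna().any():
        raise ValueError("every contig needs a length")
    weights = abundance.to_numpy(dtype=float) * lengths.to_numpy(dtype=float)[:, None]
    if (weights < 0).any():
        raise ValueError("abundances must be non-negative")
    col_tot = weights.sum(axis=0)
    if reads_per_sample > 0 and (col_tot <= 0).any():
        bad = abundance.columns[col_tot <= 0].tolist()
        raise ValueError(f"all-zero sample column(s): {bad}")

    rng = np.random.default_rng(seed)
    counts = np.zeros(abundance.shape, dtype=np.int64)
    if reads_per_sample > 0:
        for j in range(abundance.shape[1]):
            counts[:, j] = rng.multinomial(reads_per_sample, weights[:, j] / col_tot[j])
    return pd.DataFrame(counts, index=abundance.index, columns=abundance.columns)


def simulate_depth_profile(
    read_count: int,
    contig_length: int,
    read_length: int,
    seed: int | np.random.Generator,
) -> int:
    """Covered positions after placing reads uniformly at random.

    Reads start uniformly on ``[0, contig_length - read_length]`` and the
    covered-base count is the exact size of the union of the read
    intervals, so the breadth of each realization is exact (no per-base
    Poisson approximation).
    """
    if read_length > contig_length:
        raise ValueError("read_length must be <= contig_length")
    if read_count < 0:
        raise ValueError("read_count must be >= 0")
    if read_count == 0:
        return 0
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    starts = rng.integers(0, contig_length - read_length + 1, size=read_count)
    starts.sort()
    ends = starts + read_length
    # union of sorted intervals: new coverage of read i is min(read_length,
    # end_i - max end so far)
    running_end = np.maximum.accumulate(ends)
    gains = np.minimum(ends[1:], running_end[1:]) - np.maximum(starts[1:], running_end[:-1])
    covered = read_length + int(np.clip(gains, 0, read_length).sum())
    return covered


def simulate_coverage(
    counts: pd.DataFrame,
    contig_lengths: pd.Series,
    read_length: int,
    seed: int,
) -> pd.DataFrame:
    """Long-format coverage table for a count matrix.

    Returns rows of (contig_id, sample_id, length_bp, mapped_reads,
    covered_positions) — the CoverageTable layout consumed by the
    abundance module.
    """
    rng = np.random.default_rng(seed)
    lengths = contig_lengths.reindex(counts.index).astype(int)
    records = []
    arr = counts.to_numpy()
    for i, cid in enumerate(counts.index):
        L = int(lengths.iloc[i])
        rl = min(read_length, L)
        for j, sid in enumerate(counts.columns):
            n = int(arr[i, j])
            cov = simulate_depth_profile(n, L, rl, rng) if n else 0
            records.append((cid, sid, L, n, cov))
    return pd.DataFrame(
        records,
        columns=["contig_id", "sample_id", "length_bp", "mapped_reads", "covered_positions"],
    )


def simulate_evidence(
    contigs: pd.DataFrame,
    error_rates: EvidenceErrorRates,
    seed: int,
) -> pd.DataFrame:
    """Per-contig evidence table with planted signals and error rates.

    Viral contigs carry at least one inclusion signal (detector call,
    viral-database hit, or pVOG density) with probability
    ``1 - fn_inclusion``; bacterial contigs fire the ribosomal-protein
    exclusion together with an nt-database hit with probability
    ``1 - fn_exclusion``. At all-zero error rates, downstream triage
    (ignoring coverage) recovers the planted labels exactly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for cid, row in contigs.iterrows():
        L = int(row["length_bp"])
        viral = row["label"] == "viral"
        n_orfs = max(1, int(round(L / 400)))  # ~2.5 genes/kb, typical phage density

        detector_category = np.nan
        is_circular = False
        viral_db_evalue = np.nan
        crass_evalue = np.nan
        n_pvog = 0
        has_nt_hit = False
        n_ribo = 0

        if viral:
            if rng.random() >= error_rates.fn_inclusion:
                fire_det = rng.random() < 0.7
                fire_db = rng.random() < 0.5
                fire_pvog = rng.random() < 0.5
                if not (fire_det or fire_db or fire_pvog):
                    fire_det = True
                if fire_det:
                    if rng.random() < 0.8:
                        detector_category = int(rng.integers(1, 3))  # category 1 or 2
                    else:
                        is_circular = True
                        detector_category = 3
                if fire_db:
                    ev = 10.0 ** rng.uniform(-40, -11)
                    if rng.random() < 0.2:
                        crass_evalue = ev
                    else:
                        viral_db_evalue = ev
                if fire_pvog:
                    need = max(3, int(np.ceil(2 * L / 1000)))
                    n_pvog = int(min(n_orfs, rng.integers(need, max(need + 1, n_orfs + 1))))
                else:
                    n_pvog = int(rng.integers(0, 3))
            has_nt_hit = rng.random() < 0.5  # many phages are in nt; irrelevant to inclusion
            if rng.random() < error_rates.fp_ribosomal:
                n_ribo = 3
        else:
            if rng.random() >= error_rates.fn_exclusion:
                n_ribo = int(rng.integers(3, 9))
                has_nt_hit = True
            if rng.random() < error_rates.fp_inclusion:
                if rng.random() < 0.5:
                    detector_category = int(rng.integers(1, 3))
                else:
                    viral_db_evalue = 10.0 ** rng.uniform(-20, -11)
            n_pvog = 0

        # keep the ContigEvidence invariants: ORF-count fields never exceed n_orfs
        n_orfs = max(n_orfs, n_pvog, n_ribo)
        rows.append(
            (
                cid,
                L,
                detector_category,
                is_circular,
                viral_db_evalue,
                crass_evalue,
                n_orfs,
                n_pvog,
                has_nt_hit,
                n_ribo,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig_id",
            "length_bp",
            "detector_category",
            "is_circular",
            "viral_db_min_evalue",
            "crass_min_evalue",
            "n_orfs",
            "n_pvog_orfs",
            "has_nt_hit",
            "n_ribosomal_orfs",
        ],
    ).set_index("contig_id")


def write_contig_fasta(contigs: pd.DataFrame, path, seed: int) -> int:
    """Write dummy (random-sequence) contigs of the generated lengths.

    Sequences carry no signal — homology evidence lives in the evidence
    table — but give downstream tooling something of the right shape to
    chew on. Returns the number of records written.
    """
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    records = []
    for cid, row in contigs.iterrows():
        seq = rng.choice(alphabet, size=int(row["length_bp"])).tobytes().decode()
        records.append(SeqRecord(Seq(seq), id=str(cid), description=f"label={row['label']}"))
    return SeqIO.write(records, str(path), "fasta")


def expected_spike_fraction(
    titer: float,
    spike_genome_bp: float,
    true_load: float,
    mean_genome_bp: float,
) -> float:
    """Expected spike read fraction under the DNA-mass model.

    Sequenced-read share is proportional to (particles/ml) x (genome bp):
    f = titer*spike_bp / (titer*spike_bp + load*mean_bp).
    """
    if min(titer, spike_genome_bp, true_load, mean_genome_bp) <= 0:
        raise ValueError("all spike model quantities must be > 0")
    spike_mass = titer * spike_genome_bp
    endo_mass = true_load * mean_genome_bp
    return spike_mass / (spike_mass + endo_mass)


def simulate_spike(
    titer: float,
    spike_genome_bp: float,
    true_load: float,
    mean_genome_bp: float,
    reads_total: int,
    seed: int,
) -> tuple[int, int]:
    """Binomial spike read sampling at the mass-model expected fraction.

    Returns (reads_spike, reads_endogenous) with
    reads_spike ~ Binomial(reads_total, f).
    """
    if reads_total <= 0:
        raise ValueError("reads_total must be > 0")
    f = expected_spike_fraction(titer, spike_genome_bp, true_load, mean_genome_bp)
    rng = np.random.default_rng(seed)
    reads_spike = int(rng.binomial(reads_total, f))
    return reads_spike, reads_total - reads_spike


def simulate_host_pairs(
    n_pairs: int,
    n_samples: int,
    rho: float,
    seed: int,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Paired VC/host abundance vectors with planted rank correlation.

    A Gaussian copula is used: each pair is drawn from a bivariate normal
    with Pearson r = 2*sin(pi*rho/6), which has population Spearman
    correlation exactly ``rho``; abundances are the exponential of the
    normals (monotone, rank-preserving). Unpaired VC/host combinations
    are independent.

    Returns (vc_matrix, host_matrix, pair_map) where pair_map maps each
    VC id to its true host id.
    """
    if n_samples < 3:
        raise ValueError("n_samples must be >= 3")
    if not -1.0 <= rho <= 1.0:
        raise ValueError("|rho| must be <= 1")
    rng = np.random.default_rng(seed)
    r = 2.0 * np.sin(np.pi * rho / 6.0)
    z1 = rng.standard_normal((n_pairs, n_samples))
    z2 = rng.standard_normal((n_pairs, n_samples))
    x = z1
    y = r * z1 + np.sqrt(max(0.0, 1.0 - r * r)) * z2

    vc_ids = [f"vc_{i:04d}" for i in range(n_pairs)]
    host_ids = [f"host_{i:04d}" for i in range(n_pairs)]
    samples = [f"s{j}" for j in range(n_samples)]
    vc = pd.DataFrame(np.exp(x), index=vc_ids, columns=samples)
    host = pd.DataFrame(np.exp(y), index=host_ids, columns=samples)
    pair_map = dict(zip(vc_ids, host_ids))
    return vc, host, pair_map
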