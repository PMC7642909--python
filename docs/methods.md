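# Methods

This note documents the models, rules and numerical choices behind
`mlivirome`, and what its synthetic tests do and do not establish.

## Triage rules

Decisions are a pure function of one contig's evidence record and its
per-sample breadth row. Inclusion rules are OR-combined; removal rules
are applied afterwards and always win — the selection criteria are
listed first and removals phrased as subsequent filters, so a
ribosomal-rich contig is rejected even with a positive detector call.

Boundary semantics are taken literally from the printed thresholds:
strict `<` for e-values (a hit at exactly 10⁻¹⁰ does not count),
inclusive `≥` for counts, lengths, hits/kb density and the 75% breadth.
pVOG density uses the exact length in bp (`n·1000/length_bp`), never a
rounded kb value. Absent evidence fields mean "no hit" (e-value +∞,
counts 0, flags false): a missing detector column is a negative call,
not missing data. Contigs shorter than 1,001 bp are dropped at ingest
with a warning, mirroring the upstream convention that only contigs
longer than 1 kb enter clustering. Dereplication and clustering
themselves are upstream tools' business; inputs are assumed
pre-dereplicated.

Two readings were genuinely open and are resolved as follows: a
detector "circular" call counts as positive regardless of category
(the disjunction reading of "positive (category 1 or 2) or circular"),
and the ≥3 kb unknown rule requires absence of *significant* nt hits
(e-value < 10⁻¹⁰), matching the threshold printed for that alignment
step. Both behaviours are covered by boundary tests.

## Abundance processing

Breadth masking is per sample — a contig can survive in one sample and
be zeroed in another. The 75% masking boundary is treated as inclusive
(≥), exposed as a flag since the printed text does not resolve a tie at
exactly 0.75. The 0.01% prevalence floor is likewise inclusive
("minimum" read as the lowest admissible value). The prevalence filter
operates on whatever mode the matrix is in (RPKM for viral features,
counts/relative for the bacteriome), since RPKM is the mode paired with
that filter for viral data. Rarefaction is a single
multivariate-hypergeometric draw (sampling reads without replacement)
at a fixed seed; a `replicates` option averages several draws as a
sensitivity analysis. Contamination summaries report the mean of
per-sample fold-decreases, not the fold of mean proportions; zero
virome proportions yield +∞ and are excluded from the mean.

## Spike-in load model

The sequencer is assumed to sample DNA mass: a particle population at
concentration `c` with genome length `g` contributes reads in
proportion to `c·g`. Hence the expected spike read fraction is
`f = T·s/(T·s + L·m)` and the inverse estimator
`L = T·((1−f)/f)·(s/m)`, with `m = 40 kb` as the conventional mean
phage genome. This inverse is exact: plugging the expected fraction for
a known load returns that load to machine precision, which the tests
assert at 10⁻⁹ relative error. The titration "±" is the SD of the
per-titer estimates (three titers → mean ± SD); the SE of the titration
slope is a possible alternative not used by default. The spike fraction
denominator is total high-quality reads after host removal but before
spike-read removal, since host and spike reads are removed in the same
preprocessing step and the fraction must be computed before it. The
spike-absence threshold defaults to one read per million (10⁻⁶):
single-read signals at that level are classified "trace" rather than
contamination.

## Diversity

Chao1 uses the bias-corrected form `S_obs + f₁(f₁−1)/(2(f₂+1))`
(finite when doubletons are absent); the classic form is available via
`bias_corrected=False`. PCoA is classical scaling of the
double-centered −D²/2 matrix; negative eigenvalues (Bray–Curtis is
generally non-Euclidean) are reported unchanged and coordinates use
positive-eigenvalue axes only. scikit-bio's implementation zeroes
negative eigenvalues, so the decomposition is done directly here, with
scikit-bio retained as a cross-check in the tests. The distance-group
test is a two-sided Mann–Whitney rank-sum with Benjamini–Hochberg
correction; the underlying test for the published comparisons is not
named, so t-test and permutation alternatives are selectable. Distances
within a group are treated as exchangeable even though they share
samples — the standard practice in this kind of analysis — and the
permutation option exists precisely because that assumption is
optimistic.

## Phage–host correlation

The null is every (VC, observed-host) combination excluding each VC's
own predicted host, giving `#VCs × (#hosts − 1)` null correlations,
with optional subsampling for very large designs. The test is one-sided
(paired correlations higher), rank-based throughout, hence invariant to
monotone transforms of the abundances. Degenerate (constant) vectors
make Spearman undefined and are excluded with a logged count.

## Synthetic community generator

The generator emulates a multi-subject, multi-site MLI virome study:
each contig gets a log-normal baseline abundance, a per-subject
log-normal perturbation scaled by `subject_effect` and an independent
per-sample perturbation scaled by `site_effect` (effect 1.0 ≡ σ = 1 on
the natural-log scale). Reads are a multinomial draw with probability ∝
abundance × length; coverage places reads uniformly at random so each
realization's breadth is the exact size of the union of read intervals
(mean breadth follows the Lander–Waterman expectation 1 − e^(−c));
evidence signals are planted per the true label with four controllable
error rates; the spike-in is a binomial draw at the mass-model
fraction; host pairs use a Gaussian copula (Pearson r = 2·sin(πρ/6)),
which targets the Spearman correlation ρ exactly.

Default sizes are the study design being emulated: 5 subjects × 2
colonic sites, ~200 bp reads, a 40 kb mean phage genome, titers
10⁵/10⁶/10⁷ pfu/ml and a true load of 6×10⁸ particles/ml (the order
measured at the proximal colon). Effect sizes are free parameters —
intra- vs inter-subject effect magnitudes are not calibrated to any
deposited dataset — and default to strong subject (0.8) and weaker site
(0.3) structure.

Two deliberate departures from realistic data:

- **Abundance heterogeneity is moderate** (log-normal σ = 0.5 baseline).
  Real viromes are heavier-tailed; with heavy tails, many genuinely
  viral contigs fall below the 75% breadth filter at 10⁵ reads/sample
  and triage "recall" against planted labels is dominated by sequencing
  depth rather than by the rule engine. The default world is therefore
  depth-saturated by design, so that end-to-end precision/recall
  measure the evidence rules at their stated error rates. A green
  end-to-end test does *not* establish that real low-abundance viruses
  survive breadth filtering.
- **No sequence-level simulation**: no FASTQ reads, no MDA amplification
  bias (which over-represents small circular ssDNA viruses in real VLP
  data), no assembly artefacts beyond the evidence error rates.

In the pipeline's host-correlation stage each planted host taxon's
abundance tracks the summed abundance of its member phages times
log-normal noise (σ = 0.5). With many phages per taxon, any single
paired correlation is diluted toward zero even though the paired-vs-null
test retains power — the same dilution expected in real data where one
bacterial species hosts many phages.

## Determinism

Every generator takes a seed; a community seed fans out to per-stage
child seeds via `numpy.random.SeedSequence`, so stages are
independently reproducible and a rerun with the same config + seed
reproduces byte-identical outputs (asserted on the manifest's SHA-256
digests).

## Known limitations

- Upstream tools (assembly, detectors, aligners, ORF callers, host
  predictors, clustering) are consumed as tables, never wrapped or
  reimplemented; garbage evidence in, garbage triage out.
- The load estimator assumes unbiased mass-proportional sequencing of
  spike and endogenous particles; extraction or amplification biases
  (e.g. MDA) shift estimates multiplicatively and are not modelled.
- Enveloped and RNA viruses are out of scope, as in the underlying
  VLP-DNA protocol.
- BAM ingestion is intentionally absent; the toolkit consumes the
  text alignment summaries (idxstats-style) and per-base depth tables.
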