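# mlivirome

A toolkit for analysing gut virome sequencing of the intestinal
mucosal–luminal interface (MLI): rule-based identification of viral
contigs from multi-source evidence, breadth-of-coverage and RPKM
abundance processing, absolute viral load estimation from an exogenous
spike-in phage, diversity statistics, and phage–host abundance
correlation tested against an unpaired null. A synthetic-community
generator with known ground truth stands in for sequencing data, so the
whole pipeline is testable on a laptop.

It is aimed at bioinformaticians running virus-like-particle (VLP)
virome studies who already have upstream outputs in hand — assembly,
detector calls (e.g. VirSorter), BLAST/HMMER hits, ORF predictions,
alignment summaries, host predictions (e.g. WIsH) — and need the
downstream triage, normalization and statistics to be explicit,
auditable and reproducible.

## What it computes

**Viral contig triage.** A contig is retained as a viral contig (VC)
when at least one inclusion rule fires and no removal rule applies:

- *detector*: positive call (category 1 or 2) or circularity;
- *viral database*: best hit to a reference viral genome set or the
  crAssphage set at e-value < 10⁻¹⁰;
- *pVOG density*: ≥ 3 ORFs with a prokaryotic-viral-orthologous-group
  hit and ≥ 2 such hits per kb of contig;
- *long unknown*: ≥ 3 kb with no nt-database hit at e-value < 10⁻¹⁰;

removal: ≥ 3 ORFs matching ribosomal proteins, or horizontal coverage
(breadth) < 75% in every sample. Removal always wins. Every decision
records the rules that fired.

**Abundance.** breadth = covered positions / contig length; per-sample
counts with breadth < 75% are zeroed; RPKM = count·10⁹/(length·library);
features never reaching 0.01% relative abundance are dropped; samples
can be rarefied (without replacement) to the shallowest library; contig
counts aggregate into viral clusters; per-VC presence is classified as
sample-specific / subject-specific / shared.

**Spike-in viral load.** With a phage of genome length `s` spiked at
titer `T` (pfu/ml) and spike read fraction `f`, under a DNA-mass model
the endogenous load with assumed mean phage genome `m` (default 40 kb)
is

```
load = T · (1 − f)/f · s/m        [particles/ml]
```

A titration series (10⁵/10⁶/10⁷ pfu/ml) gives mean ± SD and an OLS R²
linearity check; unspiked samples are classified absent/trace/present.

**Diversity.** Chao1 (bias-corrected), Bray–Curtis, PCoA (negative
eigenvalues reported, not corrected), and Mann–Whitney comparisons of
replicate / intra-subject / inter-subject distance groups with
Benjamini–Hochberg correction.

**Phage–host correlation.** Best host predictions accepted at p ≤ 0.05,
restricted to hosts observed in the bacteriome; Spearman rho per VC–host
pair across paired samples; one-sided rank-sum test of paired rho
against all VC × non-predicted-host combinations.

## Worked example

Run the full synthetic pipeline (5 subjects × 2 colonic sites, 500
viral + 200 bacterial contigs, 10⁵ reads/sample, 1% evidence error
rates):

```
$ mlivirome run --seed 1 --out runs/demo
```

which prints (numbers from an actual run; the default config matches
`scripts/acceptance.py --seed 1` up to error rates):

```
simulate: 700 contigs, 10 samples, 100000 reads/sample
triage: 497/700 retained (precision 0.998, recall 0.992)
abundance: 497 VCs after masking+prevalence filter; rarefied to 100000 reads
spike: load 6.02e+08 +/- 6.84e+06 /ml (true 6e+08), R^2 1.0000
diversity: inter_subject vs intra_subject: p_adj=1.64e-06
hostcorr: 390 pairs / 20 hosts; paired median rho 0.036 vs null -0.006, p=0.00612
```

Reading this: the triage engine recovered 497 of the 500 planted viral
contigs, losing ~1% to simulated evidence errors and rejecting all but
one bacterial contig. The spike titration recovered the planted load of
6×10⁸ particles/ml within ~1% with a perfectly linear titration.
Inter-subject Bray–Curtis distances significantly exceed intra-subject
ones (the planted subject structure), and the paired VC–host
correlations sit significantly above the unpaired null — the median
paired rho is small because each host taxon's abundance aggregates many
phages, diluting any single pair.

Each stage is also available standalone (`mlivirome triage`,
`abundance`, `spike`, `diversity`, `hostcorr`, `validate`) on your own
TSV tables; see `--help` for the expected columns.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the default synthetic pipeline from scratch — community
generation, read/coverage/evidence simulation, triage, abundance
processing, spike-in titration, diversity and host-correlation testing —
prints the stage report, and writes the results JSON.
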